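"""End-to-end orchestration: simulate -> preprocess -> measure -> stats.

One config plus one master seed reproduces a complete analysis bundle:
per-subject BrainVision files (optional), epoch containers, the peak-measure
table, cohort table, the statistics reports and a JSON run manifest.
Per-subject child seeds derive from the master seed by subject index, so a
subject's data does not depend on cohort size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, erp, io, preproc, stats, synth

logger = logging.getLogger("p300kit")

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "save_epochs",
    "load_epochs",
    "load_config",
]


@dataclass
class RunConfig:
    """Full run configuration: session, cohort model, preprocessing, stats."""

    session: synth.SessionConfig = field(default_factory=synth.SessionConfig)
    model: synth.GroupModel = field(default_factory=synth.GroupModel)
    preproc: preproc.PreprocSettings = field(default_factory=preproc.PreprocSettings)
    peak_window_ms: tuple[float, float] = (300.0, 600.0)
    fdr_q: float = 0.05
    alpha: float = 0.05
    count_tolerance: float = 0.10
    seed: int = 0
    output_dir: str = "p300kit_run"
    write_raw: bool = True
    write_epochs: bool = True


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {
            ("/".join(k) if isinstance(k, tuple) else k): _encode(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _encode(cfg)


def _tuple_keys(d: dict) -> dict:
    return {(tuple(k.split("/")) if "/" in k else k): v for k, v in d.items()}


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a (possibly partial) nested dict."""
    raw = dict(raw or {})
    session = synth.SessionConfig(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in raw.get("session", {}).items()
    })
    m = dict(raw.get("model", {}))
    if "peaks" in m:
        m["peaks"] = {
            g: {k: tuple(v) for k, v in _tuple_keys(cells).items()}
            for g, cells in m["peaks"].items()
        }
    if "neuropsych" in m:
        m["neuropsych"] = {
            t: {g: tuple(v) for g, v in per.items()}
            for t, per in m["neuropsych"].items()
        }
    if "demographics" in m:
        m["demographics"] = {
            t: {g: tuple(v) for g, v in per.items()}
            for t, per in m["demographics"].items()
        }
    for key in ("coupling", "count_error"):
        if key in m:
            m[key] = {k: tuple(v) for k, v in m[key].items()}
    if "latency_bounds" in m:
        m["latency_bounds"] = tuple(m["latency_bounds"])
    if "render_defaults" in m and m["render_defaults"] is not None:
        rd = dict(m["render_defaults"])
        rd["latency"] = {k: v for k, v in _tuple_keys(rd.get("latency", {})).items()}
        rd["amplitude"] = {
            k: v for k, v in _tuple_keys(rd.get("amplitude", {})).items()
        }
        m["render_defaults"] = synth.SubjectERPParams(**rd)
    model = synth.GroupModel(**m)
    pp = dict(raw.get("preproc", {}))
    if "rejection" in pp:
        pp["rejection"] = preproc.RejectionCriteria(**pp["rejection"])
    for key in ("band", "epoch_window_ms", "baseline_ms", "eeg_channels"):
        if key in pp:
            pp[key] = tuple(pp[key])
    settings = preproc.PreprocSettings(**pp)
    top = {
        k: v
        for k, v in raw.items()
        if k not in ("session", "model", "preproc")
    }
    if "peak_window_ms" in top:
        top["peak_window_ms"] = tuple(top["peak_window_ms"])
    return RunConfig(session=session, model=model, preproc=settings, **top)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_encode(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Epoch container


def save_epochs(epochs: preproc.EpochSet, path: str | Path) -> Path:
    """Write an epoch set as a named-array archive (.npz).

    Layout: data (epochs x channels x time, µV), time_ms, condition (str),
    retained (bool), channels (str), sampling_rate, subject_id.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        data=epochs.data,
        time_ms=epochs.time_ms,
        condition=np.array(epochs.condition, dtype=str),
        retained=epochs.retained,
        channels=np.array(epochs.channel_labels, dtype=str),
        sampling_rate=np.array(epochs.sampling_rate),
        subject_id=np.array(epochs.subject_id),
    )
    return path


def load_epochs(path: str | Path) -> preproc.EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return preproc.EpochSet(
            data=z["data"],
            time_ms=z["time_ms"],
            condition=z["condition"].astype(object),
            retained=z["retained"].astype(bool),
            channel_labels=[str(c) for c in z["channels"]],
            sampling_rate=float(z["sampling_rate"]),
            subject_id=str(z["subject_id"]),
        )


# ---------------------------------------------------------------------------
# Statistics bundle on measured cohorts


def run_stats(
    peaks: pd.DataFrame,
    cohort: io.CohortTable,
    fdr_q: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Run the full statistics battery on a measured cohort.

    Returns a dict of DataFrames: group comparison t-tests (+ chi-square on
    sex), mixed ANOVA per measure, simple-effect post-hocs on latency when
    the condition x group interaction is significant, and the FDR-corrected
    correlation battery.
    """
    df = cohort.df
    hc = df[df["group"] == "HC"]
    mci = df[df["group"] == "MCI"]

    rows = []
    for var in ["age", "education", *cohort.score_columns(), "reported_count"]:
        if var not in df.columns:
            continue
        x = hc[var].dropna()
        y = mci[var].dropna()
        try:
            res = stats.ttest_independent(x, y)
            rows.append(
                {
                    "variable": var,
                    "test": "independent t (pooled)",
                    "stat": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
        except ValueError as exc:
            rows.append(
                {"variable": var, "test": f"undefined ({exc})", "stat": np.nan,
                 "df": np.nan, "p": np.nan}
            )
    if "sex" in df.columns:
        tab = [
            [int((hc["sex"] == "F").sum()), int((hc["sex"] == "M").sum())],
            [int((mci["sex"] == "F").sum()), int((mci["sex"] == "M").sum())],
        ]
        try:
            chi = stats.chi_square_2x2(tab)
            rows.append(
                {"variable": "sex", "test": "chi-square", "stat": chi["chi2"],
                 "df": chi["df"], "p": chi["p"]}
            )
        except ValueError as exc:
            rows.append(
                {"variable": "sex", "test": f"undefined ({exc})",
                 "stat": np.nan, "df": np.nan, "p": np.nan}
            )
    ttests = pd.DataFrame(rows)

    posthoc = None
    if peaks["group"].nunique() >= 2:
        anovas = {
            m: stats.mixed_anova_2x3x2(peaks, value=m)
            for m in ("amplitude", "latency")
        }
        inter = anovas["latency"].set_index("effect").loc["condition x group"]
        if inter["p"] < alpha:
            posthoc = stats.simple_effects_posthoc(peaks, value="latency")
        inter_f, inter_p = float(inter["F"]), float(inter["p"])
    else:
        anovas = {"amplitude": None, "latency": None}
        inter_f = inter_p = float("nan")

    correlations = stats.correlation_battery(peaks, cohort, q=fdr_q)
    return {
        "ttests": ttests,
        "anova_amplitude": anovas["amplitude"],
        "anova_latency": anovas["latency"],
        "posthoc_latency": posthoc,
        "correlations": correlations,
        "interaction_p": inter_p,
        "interaction_F": inter_f,
    }


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class RunResult:
    cohort: io.CohortTable
    peaks: pd.DataFrame
    reports: dict
    excluded: list[dict]
    grand_averages: dict
    manifest: dict
    output_dir: Path | None


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the whole analysis chain under one config and seed.

    Subjects failing the minimum-epoch rule or the behavioral count-accuracy
    rule are excluded from the statistics and listed in the manifest.  Any
    stage error is re-raised annotated with the stage and subject id.
    """
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        (out_dir / "raw").mkdir(parents=True, exist_ok=True)
        (out_dir / "epochs").mkdir(parents=True, exist_ok=True)

    all_peaks: list[erp.PeakMeasure] = []
    erps_by_group: dict[str, list[erp.SubjectERP]] = {}
    excluded: list[dict] = []
    subject_reports: dict[str, dict] = {}

    for row, params, rec in synth.iter_subject_recordings(
        cfg.model, cfg.session, cfg.seed
    ):
        sid = row["id"]
        try:
            if out_dir and cfg.write_raw:
                io.write_brainvision(rec, out_dir / "raw" / sid)
            epochs, report = preproc.preprocess_subject(
                rec, cfg.preproc, seed=cfg.seed, subject_id=sid
            )
            subject_reports[sid] = report
            if out_dir and cfg.write_epochs:
                save_epochs(epochs, out_dir / "epochs" / f"{sid}_epochs.npz")
            if not all(report["min_epochs_ok"].values()):
                excluded.append({"id": sid, "reason": "min_epochs"})
                continue
            if not synth.check_count_accuracy(
                int(row["reported_count"]),
                int(row["true_target_count"]),
                cfg.count_tolerance,
            ):
                excluded.append({"id": sid, "reason": "count_accuracy"})
                continue
            subject_erp = erp.average_epochs(epochs, subject_id=sid, group=row["group"])
            erps_by_group.setdefault(row["group"], []).append(subject_erp)
            all_peaks.extend(
                erp.measure_peak(subject_erp, window_ms=cfg.peak_window_ms)
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at subject {sid}: {exc}") from exc

    cohort, _ = synth.simulate_cohort_params(cfg.model, cfg.session, cfg.seed)
    analyzed_ids = {p.subject_id for p in all_peaks}
    cohort_analyzed = io.CohortTable(
        cohort.df[cohort.df["id"].isin(analyzed_ids)].reset_index(drop=True)
    )
    peaks = erp.peaks_to_frame(all_peaks)
    grand_averages = {g: erp.grand_average(es) for g, es in erps_by_group.items()}

    reports = run_stats(peaks, cohort_analyzed, fdr_q=cfg.fdr_q, alpha=cfg.alpha)

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": config_to_dict(cfg),
        "excluded_subjects": excluded,
        "n_subjects_analyzed": len(analyzed_ids),
        "interaction_F_latency": reports["interaction_F"],
        "interaction_p_latency": reports["interaction_p"],
        "subject_reports": subject_reports,
    }

    if out_dir:
        io.write_table(cohort, out_dir / "cohort.tsv")
        peaks.to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
        reports["ttests"].to_csv(out_dir / "ttests.tsv", sep="\t", index=False)
        for measure in ("amplitude", "latency"):
            table = reports[f"anova_{measure}"]
            if table is not None:
                table.to_csv(
                    out_dir / f"anova_{measure}.tsv", sep="\t", index=False
                )
        if reports["posthoc_latency"] is not None:
            reports["posthoc_latency"].to_csv(
                out_dir / "posthoc.tsv", sep="\t", index=False
            )
        reports["correlations"].to_csv(
            out_dir / "correlations.tsv", sep="\t", index=False
        )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        cohort=cohort,
        peaks=peaks,
        reports=reports,
        excluded=excluded,
        grand_averages=grand_averages,
        manifest=manifest,
        output_dir=out_dir,
    )
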