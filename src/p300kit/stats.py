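"""Group-statistics battery for the oddball P300 analysis.

Covers the published analysis plan: pooled-variance independent-samples
t-tests (raw data or summary statistics), Pearson chi-square for the sex
table, the 2 (group) x 2 (condition) x 3 (anterior-posterior electrode)
mixed-design repeated-measures ANOVA with Greenhouse-Geisser epsilons,
Bonferroni-corrected simple-effect post-hocs on electrode-averaged latency,
and Pearson brain-behavior correlations with Benjamini-Hochberg FDR
correction per (population x condition) family.

The ANOVA uses the univariate sums-of-squares decomposition: the between
stratum tests group against subjects-within-group; each within-subject
effect (and its group interaction) is tested against the matching
effect-by-subject-within-group error stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortTable, SCORE_COLUMNS

__all__ = [
    "TTestResult",
    "ttest_independent",
    "ttest_from_summary",
    "paired_ttest",
    "chi_square_2x2",
    "mixed_anova_2x3x2",
    "mixed_anova_cells",
    "simple_effects_posthoc",
    "pearson_correlation",
    "bh_fdr_adjust",
    "correlation_battery",
    "BATTERY_TESTS",
]

#: Cognitive tests entering the correlation battery (GDS, the depression
#: screener, is excluded by default but can be passed explicitly).
BATTERY_TESTS = [c for c in SCORE_COLUMNS if c != "GDS"]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    se: float


def ttest_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2)) with df = n1 + n2 - 2;
    two-sided p.  Zero pooled variance with equal means gives t = 0, p = 1;
    with unequal means it is an error (the statistic is undefined).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample must have n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    diff = m1 - m2
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0, 0.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(diff), se)


def ttest_independent(x, y, pooled: bool = True) -> TTestResult:
    """Two-sample t-test on raw samples (Student by default, Welch option).

    The pooled variant is algebraically identical to
    :func:`ttest_from_summary` applied to the samples' own moments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must have n >= 2")
    if pooled:
        return ttest_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se = float(np.sqrt(v1 / n1 + v2 / n2))
    if se == 0.0:
        if x.mean() == y.mean():
            return TTestResult(0.0, n1 + n2 - 2, 1.0, 0.0, 0.0)
        raise ValueError("zero variance with unequal means: t undefined")
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    t = (x.mean() - y.mean()) / se
    return TTestResult(
        float(t), float(df), float(2 * sps.t.sf(abs(t), df)),
        float(x.mean() - y.mean()), se,
    )


def paired_ttest(x, y) -> TTestResult:
    """Paired t-test on matched samples (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired samples must match in length with n >= 2")
    d = x - y
    n = len(d)
    se = float(d.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        if d.mean() == 0.0:
            return TTestResult(0.0, n - 1, 1.0, 0.0, 0.0)
        raise ValueError("zero variance of differences with nonzero mean")
    t = d.mean() / se
    return TTestResult(
        float(t), float(n - 1), float(2 * sps.t.sf(abs(t), n - 1)),
        float(d.mean()), se,
    )


def chi_square_2x2(table) -> dict:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin; chi-square undefined")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA


def _gg_epsilon(scores_by_group: list[np.ndarray]) -> float:
    """Greenhouse-Geisser epsilon from per-subject scores (n_s x k levels),
    pooled within groups."""
    k = scores_by_group[0].shape[1]
    if k < 3:
        return 1.0
    n_total = sum(v.shape[0] for v in scores_by_group)
    g = len(scores_by_group)
    pooled = np.zeros((k, k))
    for v in scores_by_group:
        c = v - v.mean(axis=0, keepdims=True)
        pooled += c.T @ c
    pooled /= max(n_total - g, 1)
    # orthonormal contrasts via Helmert-like basis
    contrasts = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    m = contrasts.T @ pooled @ contrasts
    tr = np.trace(m)
    denom = (k - 1) * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr**2 / denom))


def mixed_anova_cells(
    cells_by_group: dict[str, np.ndarray],
    within1: str = "condition",
    within2: str = "AP",
) -> pd.DataFrame:
    """Mixed ANOVA from per-group cell arrays of shape (n_subj, L1, L2).

    *within1* has L1 levels (condition: 2), *within2* L2 levels
    (anterior-posterior electrode: 3); groups are the dict keys.  Returns
    the ANOVA table with one row per effect and per error stratum.
    """
    groups = list(cells_by_group)
    Ys = [np.asarray(cells_by_group[g], dtype=float) for g in groups]
    if any(y.ndim != 3 for y in Ys):
        raise ValueError("each group array must be (subjects, L1, L2)")
    L1, L2 = Ys[0].shape[1], Ys[0].shape[2]
    if any(y.shape[1:] != (L1, L2) for y in Ys):
        raise ValueError("groups disagree on within-cell layout")
    if any(not np.all(np.isfinite(y)) for y in Ys):
        raise ValueError("missing cells are not supported (no imputation)")
    ns = [y.shape[0] for y in Ys]
    if len(groups) < 2:
        raise ValueError("mixed ANOVA needs at least two groups")
    if min(ns) < 2:
        raise ValueError("each group needs >= 2 subjects")
    N, G = sum(ns), len(groups)

    allY = np.concatenate(Ys, axis=0)  # N x L1 x L2
    grand = allY.mean()
    # marginal means weighted by subject (each subject weight 1)
    m_c = allY.mean(axis=(0, 2))  # L1
    m_a = allY.mean(axis=(0, 1))  # L2
    m_ca = allY.mean(axis=0)  # L1 x L2

    P = [y.mean(axis=(1, 2)) for y in Ys]  # subject means
    Gm = [p.mean() for p in P]
    Mg_c = [y.mean(axis=(0, 2)) for y in Ys]  # group x L1
    Mg_a = [y.mean(axis=(0, 1)) for y in Ys]
    Mg_ca = [y.mean(axis=0) for y in Ys]  # group: L1 x L2
    P_c = [y.mean(axis=2) for y in Ys]  # subjects x L1
    P_a = [y.mean(axis=1) for y in Ys]

    # between stratum
    ss_group = L1 * L2 * sum(n * (gm - grand) ** 2 for n, gm in zip(ns, Gm))
    ss_subj = L1 * L2 * sum(((p - gm) ** 2).sum() for p, gm in zip(P, Gm))

    # within1 (condition) stratum
    ss_c = L2 * N * ((m_c - grand) ** 2).sum()
    ss_cg = L2 * sum(
        n * ((mg - gm - m_c + grand) ** 2).sum()
        for n, mg, gm in zip(ns, Mg_c, Gm)
    )
    ss_err_c = L2 * sum(
        ((pc - p[:, None] - mg[None, :] + gm) ** 2).sum()
        for pc, p, mg, gm in zip(P_c, P, Mg_c, Gm)
    )

    # within2 (AP) stratum
    ss_a = L1 * N * ((m_a - grand) ** 2).sum()
    ss_ag = L1 * sum(
        n * ((mg - gm - m_a + grand) ** 2).sum()
        for n, mg, gm in zip(ns, Mg_a, Gm)
    )
    ss_err_a = L1 * sum(
        ((pa - p[:, None] - mg[None, :] + gm) ** 2).sum()
        for pa, p, mg, gm in zip(P_a, P, Mg_a, Gm)
    )

    # within1 x within2 stratum
    inter_pop = m_ca - m_c[:, None] - m_a[None, :] + grand
    ss_ca = N * (inter_pop**2).sum()
    ss_cag = 0.0
    ss_err_ca = 0.0
    for n, y, mgca, mgc, mga, gm, pc, pa, p in zip(
        ns, Ys, Mg_ca, Mg_c, Mg_a, Gm, P_c, P_a, P
    ):
        inter_g = mgca - mgc[:, None] - mga[None, :] + gm
        ss_cag += n * ((inter_g - inter_pop) ** 2).sum()
        resid = (
            y
            - pc[:, :, None]
            - pa[:, None, :]
            + p[:, None, None]
            - inter_g[None, :, :]
        )
        ss_err_ca += (resid**2).sum()

    df = {
        "group": G - 1,
        "subjects(group)": N - G,
        within1: L1 - 1,
        f"{within1} x group": (L1 - 1) * (G - 1),
        f"{within1} x subjects(group)": (L1 - 1) * (N - G),
        within2: L2 - 1,
        f"{within2} x group": (L2 - 1) * (G - 1),
        f"{within2} x subjects(group)": (L2 - 1) * (N - G),
        f"{within1} x {within2}": (L1 - 1) * (L2 - 1),
        f"{within1} x {within2} x group": (L1 - 1) * (L2 - 1) * (G - 1),
        f"{within1} x {within2} x subjects(group)": (L1 - 1) * (L2 - 1) * (N - G),
    }
    ss = {
        "group": ss_group,
        "subjects(group)": ss_subj,
        within1: ss_c,
        f"{within1} x group": ss_cg,
        f"{within1} x subjects(group)": ss_err_c,
        within2: ss_a,
        f"{within2} x group": ss_ag,
        f"{within2} x subjects(group)": ss_err_a,
        f"{within1} x {within2}": ss_ca,
        f"{within1} x {within2} x group": ss_cag,
        f"{within1} x {within2} x subjects(group)": ss_err_ca,
    }
    error_of = {
        "group": "subjects(group)",
        within1: f"{within1} x subjects(group)",
        f"{within1} x group": f"{within1} x subjects(group)",
        within2: f"{within2} x subjects(group)",
        f"{within2} x group": f"{within2} x subjects(group)",
        f"{within1} x {within2}": f"{within1} x {within2} x subjects(group)",
        f"{within1} x {within2} x group": f"{within1} x {within2} x subjects(group)",
    }

    eps_a = _gg_epsilon(P_a)
    diffs = [y[:, 1:, :].mean(axis=1) - y[:, 0, :] for y in Ys] if L1 == 2 else None
    eps_ca = _gg_epsilon(diffs) if diffs is not None else np.nan
    eps = {
        within2: eps_a,
        f"{within2} x group": eps_a,
        f"{within1} x {within2}": eps_ca,
        f"{within1} x {within2} x group": eps_ca,
    }

    rows = []
    for effect, err in error_of.items():
        if ss[err] <= 0:
            raise ValueError(
                f"degenerate input: zero error sum of squares in stratum {err!r}"
            )
        ms_eff = ss[effect] / df[effect]
        ms_err = ss[err] / df[err]
        f = ms_eff / ms_err
        p = float(sps.f.sf(f, df[effect], df[err]))
        rows.append(
            {
                "effect": effect,
                "ss": ss[effect],
                "df1": df[effect],
                "df2": df[err],
                "F": float(f),
                "p": p,
                "partial_eta2": ss[effect] / (ss[effect] + ss[err]),
                "gg_epsilon": eps.get(effect, np.nan),
            }
        )
    for err in dict.fromkeys(error_of.values()):
        rows.append(
            {
                "effect": err,
                "ss": ss[err],
                "df1": df[err],
                "df2": np.nan,
                "F": np.nan,
                "p": np.nan,
                "partial_eta2": np.nan,
                "gg_epsilon": np.nan,
            }
        )
    return pd.DataFrame(rows)


def mixed_anova_2x3x2(
    data: pd.DataFrame,
    value: str = "latency",
    subject: str = "subject_id",
    group: str = "group",
    condition: str = "condition",
    channel: str = "channel",
) -> pd.DataFrame:
    """Mixed ANOVA from a long table (one row per subject x cell).

    Requires complete, balanced within-subject cells (every subject
    contributes every condition x channel combination exactly once).
    """
    conds = sorted(data[condition].unique())
    chans = sorted(data[channel].unique())
    cells_by_group: dict[str, np.ndarray] = {}
    for g, sub in data.groupby(group, sort=True):
        try:
            wide = sub.pivot(index=subject, columns=[condition, channel], values=value)
        except ValueError as exc:
            raise ValueError(f"duplicate subject x cell rows in group {g}") from exc
        wide = wide.reindex(columns=pd.MultiIndex.from_product([conds, chans]))
        if wide.isna().any().any():
            raise ValueError(f"missing cells in group {g}; no imputation performed")
        cells_by_group[g] = wide.to_numpy().reshape(len(wide), len(conds), len(chans))
    return mixed_anova_cells(cells_by_group)


def simple_effects_posthoc(
    peaks: pd.DataFrame,
    value: str = "latency",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Simple-effect decomposition of the condition x group interaction.

    On electrode-averaged *value* per subject x condition: paired t-tests
    (target vs non-target) within each group, and pooled independent
    t-tests (HC vs MCI) within each condition.  Bonferroni multiplier =
    family size (default: the 4 tests), adjusted p capped at 1.
    """
    avg = (
        peaks.groupby(["subject_id", "group", "condition"], sort=True)[value]
        .mean()
        .unstack("condition")
    )
    rows = []
    for g in sorted(avg.index.get_level_values("group").unique()):
        sub = avg.xs(g, level="group")
        res = paired_ttest(sub["target"], sub["nontarget"])
        rows.append({"contrast": f"target vs nontarget within {g}", **res.__dict__})
    for cond in ("target", "nontarget"):
        by_group = {
            g: avg.xs(g, level="group")[cond]
            for g in sorted(avg.index.get_level_values("group").unique())
        }
        gnames = list(by_group)
        res = ttest_independent(by_group[gnames[0]], by_group[gnames[1]])
        rows.append(
            {"contrast": f"{gnames[0]} vs {gnames[1]} within {cond}", **res.__dict__}
        )
    out = pd.DataFrame(rows).rename(columns={"p": "p_raw"})
    m = family_size or len(out)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    return out


# ---------------------------------------------------------------------------
# Correlations and FDR


def pearson_correlation(x, y) -> dict:
    """Pearson r with two-sided p; pairwise deletion of missing values.

    A zero-variance variable or n < 3 yields an undefined-result record
    (``defined=False``, r and p NaN) rather than an exception, so that the
    caller can exclude it from an FDR family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": n, "defined": False}
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": n, "defined": True}


def bh_fdr_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p, significant flags at *q*) in the input order.
    NaN entries are excluded from the family and return NaN / False.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        pv = p[ok]
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[ok] = out
    flags = np.where(np.isfinite(adj), adj <= q, False).astype(bool)
    return adj, flags


def correlation_battery(
    peaks: pd.DataFrame,
    cohort: CohortTable,
    tests: list[str] | None = None,
    q: float = 0.05,
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz"),
) -> pd.DataFrame:
    """Brain-behavior Pearson correlations with per-panel FDR correction.

    For each population (HC, MCI, whole) x condition x channel x measure
    (amplitude, latency) x neuropsychological test: Pearson r and raw p;
    BH-FDR is applied within each (population x condition) panel and rows
    are flagged at the corrected criterion.  Undefined correlations (e.g. a
    test with no variance in a group) are emitted with ``defined=False``
    and excluded from the family.
    """
    tests = list(BATTERY_TESTS if tests is None else tests)
    tests = [t for t in tests if t in cohort.df.columns]
    merged = peaks.merge(
        cohort.df[["id", *tests]], left_on="subject_id", right_on="id", how="inner"
    )
    rows = []
    for population in ("HC", "MCI", "whole"):
        pop = merged if population == "whole" else merged[merged["group"] == population]
        for cond in ("target", "nontarget"):
            sub = pop[pop["condition"] == cond]
            for ch in channels:
                at = sub[sub["channel"] == ch]
                for measure in ("amplitude", "latency"):
                    for test in tests:
                        res = pearson_correlation(at[measure], at[test])
                        rows.append(
                            {
                                "population": population,
                                "condition": cond,
                                "channel": ch,
                                "measure": measure,
                                "test": test,
                                **res,
                            }
                        )
    report = pd.DataFrame(rows)
    report["p_fdr"] = np.nan
    report["significant"] = False
    for (_, _), idx in report.groupby(["population", "condition"]).groups.items():
        adj, flags = bh_fdr_adjust(report.loc[idx, "p"].to_numpy(), q=q)
        report.loc[idx, "p_fdr"] = adj
        report.loc[idx, "significant"] = flags
    return report
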