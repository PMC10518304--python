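"""BrainVision EEG file I/O and cohort-table I/O.

The BrainVision Core Data Format stores one recording as a triplet:
an INI-style ``.vhdr`` header, a ``.vmrk`` marker file and a raw binary
``.eeg`` payload.  The writer emits IEEE float32, multiplexed,
little-endian; the reader additionally accepts 16-bit integer payloads
scaled by the per-channel resolution, and vectorized sample order.

Internally sample indices are 0-based; BrainVision marker positions are
1-based and converted at the boundary.
"""

from __future__ import annotations

import configparser
import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventMarker",
    "ContinuousRecording",
    "CohortTable",
    "DEFAULT_CODE_MAP",
    "SCORE_COLUMNS",
    "read_brainvision",
    "write_brainvision",
    "read_table",
    "write_table",
]

#: Default stimulus-code map.  BrainVision stimulus codes are site-specific;
#: this convention ("S  1" = standard, "S  2" = deviant) is configurable in
#: both the reader and the writer.
DEFAULT_CODE_MAP = {"S  1": "nontarget", "S  2": "target"}

#: Neuropsychological score columns of a cohort table, in canonical order.
SCORE_COLUMNS = [
    "MMSE",
    "GDS",
    "OVMPT-T",
    "OVMPT-IR",
    "OVMPT-FR",
    "OVMPT-TR",
    "DS-Forward",
    "DS-Backward",
    "Stroop-Int",
    "Animal",
    "BNT-15",
]


@dataclass
class EventMarker:
    """A stimulus event: 0-based sample offset, condition and marker code."""

    sample_index: int
    condition: str  # "target" or "nontarget"
    code: str = ""

    def __post_init__(self):
        if self.sample_index < 0:
            raise ValueError(f"sample_index must be >= 0, got {self.sample_index}")
        if self.condition not in ("target", "nontarget"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG in microvolts with stimulus markers."""

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray  # channels x samples, microvolts
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} data rows"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        n = self.data.shape[1]
        prev = -1
        for ev in self.events:
            if not (0 <= ev.sample_index < n):
                raise ValueError(
                    f"event at sample {ev.sample_index} outside recording of {n} samples"
                )
            if ev.sample_index <= prev:
                raise ValueError("event sample indices must be strictly increasing")
            prev = ev.sample_index

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the trace of a single channel by label."""
        return self.data[self.channel_labels.index(label)]

    def copy_with(self, data: np.ndarray) -> "ContinuousRecording":
        """New recording sharing labels/rate/events with replaced data."""
        return ContinuousRecording(
            list(self.channel_labels), self.sampling_rate, data, list(self.events)
        )


# ---------------------------------------------------------------------------
# BrainVision triplets


def write_brainvision(
    rec: ContinuousRecording,
    base_path: str | Path,
    code_map: dict[str, str] | None = None,
) -> tuple[Path, Path, Path]:
    """Write *rec* as a BrainVision triplet ``base.vhdr/.vmrk/.eeg``.

    The payload is IEEE float32, multiplexed, little-endian, resolution 1 µV.
    The marker file carries one "New Segment" marker followed by one
    "Stimulus" marker per event.  Returns the three paths written.
    """
    if not rec.channel_labels:
        raise ValueError("cannot write a recording with no channels")
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    cond_to_code = {v: k for k, v in code_map.items()}

    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    sampling_interval_us = 1e6 / rec.sampling_rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by p300kit",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(rec.channel_labels)}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, ev in enumerate(rec.events, start=2):
        code = ev.code or cond_to_code[ev.condition]
        # BrainVision positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,{code},{ev.sample_index + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_ini(text: str) -> configparser.ConfigParser:
    # Strip the free-text identification line(s) before the first section.
    body = text[text.index("[") :]
    cp = configparser.ConfigParser(interpolation=None, strict=False)
    cp.optionxform = str  # keep key case
    cp.read_file(_stdio.StringIO(body))
    return cp


_MARKER_RE = re.compile(r"^Mk\d+$")


def read_brainvision(
    header_path: str | Path,
    code_map: dict[str, str] | None = None,
) -> ContinuousRecording:
    """Read a BrainVision triplet into a :class:`ContinuousRecording`.

    Supports IEEE_FLOAT_32 and INT_16 payloads, MULTIPLEXED or VECTORIZED
    orientation.  Sample values are scaled to microvolts by the per-channel
    resolution declared in the header.  "Stimulus" markers become
    :class:`EventMarker` objects via *code_map* (default
    :data:`DEFAULT_CODE_MAP`); unknown stimulus codes raise.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    cp = _parse_ini(vhdr.read_text(encoding="utf-8"))

    common = cp["Common Infos"]
    eeg = vhdr.parent / common["DataFile"]
    vmrk = vhdr.parent / common["MarkerFile"] if "MarkerFile" in common else None
    if not eeg.exists():
        raise FileNotFoundError(f"data file referenced by header not found: {eeg}")
    if vmrk is not None and not vmrk.exists():
        raise FileNotFoundError(f"marker file referenced by header not found: {vmrk}")
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError(f"unsupported DataFormat {common.get('DataFormat')!r}")

    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ValueError(f"unsupported DataOrientation {orientation!r}")

    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    if fmt == "IEEE_FLOAT_32":
        dtype = np.dtype("<f4")
    elif fmt == "INT_16":
        dtype = np.dtype("<i2")
    else:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")

    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        raw = cp["Channel Infos"][f"Ch{i}"]
        parts = raw.split(",")
        labels.append(parts[0])
        res = parts[2].strip() if len(parts) > 2 else ""
        resolutions.append(float(res) if res else 1.0)

    flat = np.fromfile(eeg, dtype=dtype)
    if flat.size % n_ch:
        raise ValueError(
            f"{eeg.name}: {flat.size} values is not a multiple of {n_ch} channels"
        )
    n_samp = flat.size // n_ch
    if orientation == "MULTIPLEXED":
        data = flat.reshape(n_samp, n_ch).T.astype(float)
    else:
        data = flat.reshape(n_ch, n_samp).astype(float)
    data *= np.asarray(resolutions)[:, None]

    events: list[EventMarker] = []
    if vmrk is not None:
        mcp = _parse_ini(vmrk.read_text(encoding="utf-8"))
        for key, val in mcp["Marker Infos"].items():
            if not _MARKER_RE.match(key):
                continue
            parts = val.split(",")
            mtype, desc = parts[0], parts[1]
            if mtype != "Stimulus":
                continue
            pos = int(parts[2]) - 1  # to 0-based
            if not (0 <= pos < n_samp):
                raise ValueError(
                    f"marker {key} at position {pos + 1} beyond {n_samp} samples"
                )
            if desc not in code_map:
                raise ValueError(f"stimulus code {desc!r} not in code map")
            events.append(EventMarker(pos, code_map[desc], code=desc))
    events.sort(key=lambda ev: ev.sample_index)
    return ContinuousRecording(labels, fs, data, events)


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass
class CohortTable:
    """Per-subject cohort table: group, demographics, scores, counts.

    Backed by a :class:`pandas.DataFrame` with one row per subject.
    Required columns: ``id``, ``group`` (HC or MCI).  Score columns may hold
    missing values (NaN), never zero-as-missing.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        for col in ("id", "group"):
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad = set(df["group"].unique()) - {"HC", "MCI"}
        if bad:
            raise ValueError(f"group values outside {{HC, MCI}}: {sorted(bad)}")
        if "reported_count" in df.columns:
            counts = df["reported_count"].dropna()
            if (counts < 0).any():
                raise ValueError("reported_count must be >= 0")
        self.df = df.reset_index(drop=True)

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.df["group"].value_counts().to_dict()

    def scores(self, test: str, group: str | None = None) -> pd.Series:
        """Score column for one test, optionally restricted to a group."""
        sub = self.df if group is None else self.df[self.df["group"] == group]
        return sub[test]

    def score_columns(self) -> list[str]:
        return [c for c in SCORE_COLUMNS if c in self.df.columns]


def read_table(path: str | Path) -> CohortTable:
    """Read a tab-separated cohort table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return CohortTable(df)


def write_table(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort table as TSV; round-trips through :func:`read_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, sep="\t", index=False)
    return path
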