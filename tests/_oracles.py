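"""Independent oracles used by the test suite.

These deliberately take different computational routes from the library:
the ANOVA oracle partitions sums of squares by sequential least-squares
regression on dummy-coded design columns, never via marginal means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _dummies(values) -> np.ndarray:
    levels = sorted(pd.unique(values))
    return np.column_stack([(np.asarray(values) == lv).astype(float) for lv in levels])


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.column_stack([a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])])


def anova_ss_by_regression(df: pd.DataFrame, value: str = "latency") -> dict[str, float]:
    """Sequential (Type I) sum-of-squares partition of the mixed design.

    Fits an expanding sequence of least-squares models over dummy columns
    (grand mean, group, subject, condition, condition x group,
    condition x subject, AP, AP x group, AP x subject, condition x AP,
    condition x AP x group) and reports each term's RSS drop.  The final
    residual is the condition x AP x subject stratum.
    """
    y = df[value].to_numpy(dtype=float)
    S = _dummies(df["subject_id"])
    G = _dummies(df["group"])
    C = _dummies(df["condition"])
    A = _dummies(df["channel"])
    one = np.ones((len(y), 1))

    blocks = [
        ("grand", one),
        ("group", G),
        ("subjects(group)", S),
        ("condition", C),
        ("condition x group", _interact(C, G)),
        ("condition x subjects(group)", _interact(C, S)),
        ("AP", A),
        ("AP x group", _interact(A, G)),
        ("AP x subjects(group)", _interact(A, S)),
        ("condition x AP", _interact(C, A)),
        ("condition x AP x group", _interact(_interact(C, A), G)),
    ]
    ss = {}
    X = np.empty((len(y), 0))
    prev_rss = float(y @ y)
    for name, cols in blocks:
        X = np.column_stack([X, cols])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(resid @ resid)
        ss[name] = prev_rss - rss
        prev_rss = rss
    ss["condition x AP x subjects(group)"] = prev_rss
    del ss["grand"]
    return ss


def bh_adjust_reference(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up definition: adj_i = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj
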