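"""Group-comparison statistics: Kruskal-Wallis (tie-corrected), Dunn's post
hoc pairwise test, Welch's one-way ANOVA, and mean +/- s.e.m. summaries.

Kruskal-Wallis goes through scipy (midranks, tie correction, chi-square
reference); Dunn's test and Welch's ANOVA are computed directly from their
closed formulas since no installed library provides them.  p-values are
floored at the smallest positive double rather than reported as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "welch_anova",
    "mean_sem",
]

P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    pairwise: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = {
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "method": self.method,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for i, g in enumerate(gs):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return gs


def _floor_p(p: float) -> float:
    if p <= 0:
        logger.info("p-value underflow; flooring at %.3g", P_FLOOR)
        return P_FLOOR
    return min(1.0, float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        return TestResult(0.0, len(gs) - 1, 1.0, "kruskal-wallis")
    h, p = stats.kruskal(*gs)
    return TestResult(float(h), len(gs) - 1, _floor_p(p), "kruskal-wallis")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: str = "bonferroni",
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled midranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt( [N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j) )
    with T = sum(t^3 - t) over tie groups; two-sided normal p, adjusted over
    all k(k-1)/2 pairs by the chosen method (none / bonferroni / holm).
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    gs = _check_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(gs))]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 1.0 if se == 0 else float(2.0 * stats.norm.sf(abs(z)))
            rows.append(
                {"group_i": labels[i], "group_j": labels[j], "z": float(z), "p_raw": p_raw}
            )
    m = len(rows)
    if adjust == "none" or m == 0:
        for r in rows:
            r["p_adjusted"] = r["p_raw"]
    elif adjust == "bonferroni":
        for r in rows:
            r["p_adjusted"] = min(1.0, m * r["p_raw"])
    else:  # holm step-down
        order = np.argsort([r["p_raw"] for r in rows])
        running = 0.0
        for rank, idx in enumerate(order):
            adj = (m - rank) * rows[idx]["p_raw"]
            running = max(running, adj)
            rows[idx]["p_adjusted"] = min(1.0, running)
    out = pd.DataFrame(rows)
    out.attrs["adjust"] = adjust
    return out


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    With w_i = n_i/s_i^2, W = sum w_i, and the weighted grand mean xbar_w:

        F = [sum w_i (xbar_i - xbar_w)^2 / (k-1)]
            / [1 + 2(k-2)/(k^2-1) * A],   A = sum (1 - w_i/W)^2/(n_i - 1)

    with df = (k-1, (k^2-1)/(3A)).
    """
    gs = _check_groups(groups)
    k = len(gs)
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    n = np.array([g.size for g in gs], dtype=float)
    means = np.array([g.mean() for g in gs])
    variances = np.array([np.var(g, ddof=1) for g in gs])
    w = n / variances
    W = w.sum()
    grand = np.sum(w * means) / W
    a = np.sum((1.0 - w / W) ** 2 / (n - 1.0))
    numerator = np.sum(w * (means - grand) ** 2) / (k - 1)
    denominator = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * a
    f_stat = float(numerator / denominator)
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * a)
    p = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(f_stat, (df1, float(df2)), _floor_p(p), "welch-anova")


def mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, s.e.m., n); s.e.m. uses the n-1 sample s.d., and 0 when n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if v.size == 1:
        logger.info("single observation: s.e.m. reported as 0 by convention")
        return float(v[0]), 0.0, 1
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
    return float(v.mean()), sem, int(v.size)
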