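"""Split-fluorophore (BiFC) scoring.

Cells are classified channel-positive when intensity strictly exceeds
`factor` (default 3.5) times the cell's own background; equality at the
boundary is negative.  Venus intensities of transfection-marker-positive
(Cy3-positive) cells are normalized to the mean of the control group, and
groups are compared by Welch's one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .groupstats import TestResult, mean_sem, welch_anova

__all__ = [
    "BiFCRecord",
    "BiFCResult",
    "classify",
    "normalize_to_control",
    "bifc_pipeline",
    "DEFAULT_FACTOR",
]

DEFAULT_FACTOR = 3.5
REQUIRED_COLUMNS = ("cell_id", "group", "background", "cy3", "venus")


@dataclass(frozen=True)
class BiFCRecord:
    cell_id: str
    group: str
    background: float
    cy3: float
    venus: float


@dataclass
class BiFCResult:
    per_cell: pd.DataFrame  # cell_id, group, cy3_positive, venus_positive, venus_norm
    per_group: pd.DataFrame  # group, mean, sem, n
    test: TestResult
    factor: float
    control_group: str

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "control_group": self.control_group,
            "boundary_rule": "strictly greater than factor x background",
            "per_group": self.per_group.to_dict(orient="records"),
            "test": self.test.as_dict(),
        }


def classify(rec: BiFCRecord, factor: float = DEFAULT_FACTOR) -> tuple[bool, bool]:
    """(cy3_positive, venus_positive): intensity > factor * background, strict."""
    if rec.background <= 0:
        raise ValueError(f"cell {rec.cell_id}: background must be positive")
    threshold = factor * rec.background
    return rec.cy3 > threshold, rec.venus > threshold


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (records["background"] <= 0).any():
        bad = records.loc[records["background"] <= 0, "cell_id"].tolist()
        raise ValueError(f"non-positive background for cells {bad}")
    return records


def normalize_to_control(
    records: pd.DataFrame, control_group: str, factor: float = DEFAULT_FACTOR
) -> pd.DataFrame:
    """Gate on Cy3-positive cells and divide Venus by the control-group mean.

    Returns the gated table with cy3_positive, venus_positive and venus_norm
    columns; only Cy3-positive cells survive into downstream summaries.
    """
    records = _validate(records).copy()
    threshold = factor * records["background"]
    records["cy3_positive"] = records["cy3"] > threshold
    records["venus_positive"] = records["venus"] > threshold
    gated = records[records["cy3_positive"]].copy()
    control = gated[gated["group"] == control_group]
    if control.empty:
        raise ValueError(
            f"control group {control_group!r} has no Cy3-positive cells"
        )
    scale = float(control["venus"].mean())
    gated["venus_norm"] = gated["venus"] / scale
    return gated


def bifc_pipeline(
    records: pd.DataFrame, control_group: str, factor: float = DEFAULT_FACTOR
) -> BiFCResult:
    """Gate, normalize, summarize per group, and test by Welch's ANOVA."""
    gated = normalize_to_control(records, control_group, factor)
    group_names = list(dict.fromkeys(gated["group"]))
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups after Cy3 gating")
    rows = []
    values = []
    for name in group_names:
        v = gated.loc[gated["group"] == name, "venus_norm"].to_numpy()
        mean, sem, n = mean_sem(v)
        rows.append({"group": name, "mean": mean, "sem": sem, "n": n})
        values.append(v)
    test = welch_anova(values)
    return BiFCResult(
        per_cell=gated,
        per_group=pd.DataFrame(rows),
        test=test,
        factor=factor,
        control_group=control_group,
    )
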