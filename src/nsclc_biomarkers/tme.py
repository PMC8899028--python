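"""PD-L1 TPS tiering, immune-cell density quantification, group comparisons.

TPS (tumor proportion score) is the percentage of viable tumor cells with
PD-L1 membrane staining; it is tiered as negative (<1%), intermediate
positive ([1%, 50%)) and strong positive (>=50%). Intermediate is taken as
the full interval [1, 50) so that the three tiers partition [0, 100].

Immune densities come from multiplex immunofluorescence: positively stained
cells per square millimeter per compartment (tumor, stroma, total). The
total compartment sums counts and areas before dividing.
"""

from __future__ import annotations

from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

TPS_TIERS = ("negative", "intermediate_positive", "strong_positive")
CELL_TYPES = ("CD8_T", "M1_TAM", "M2_TAM", "CD56bright_NK", "CD56dim_NK")
COMPARTMENTS = ("tumor", "stroma", "total")

#: Tier boundaries in TPS percent: negative < 1 <= intermediate < 50 <= strong.
DEFAULT_TPS_BOUNDS = (1.0, 50.0)


def classify_tps(tps: float, bounds: tuple[float, float] = DEFAULT_TPS_BOUNDS) -> str:
    """Tier a TPS percentage; the three tiers partition [0, 100]."""
    if not 0.0 <= tps <= 100.0:
        raise ValueError(f"TPS out of range [0, 100]: {tps}")
    low, high = bounds
    if tps < low:
        return "negative"
    if tps >= high:
        return "strong_positive"
    return "intermediate_positive"


class TPSRecord(BaseModel):
    sample_id: str
    tps: float = Field(ge=0.0, le=100.0)
    tier: str

    @model_validator(mode="after")
    def _tier_consistent(self) -> "TPSRecord":
        if self.tier != classify_tps(self.tps):
            raise ValueError(f"tier {self.tier!r} inconsistent with tps {self.tps}")
        return self


class ImmuneDensityRecord(BaseModel):
    """Cell count, area, and density for one cell type in one compartment."""

    sample_id: str
    cell_type: Literal["CD8_T", "M1_TAM", "M2_TAM", "CD56bright_NK", "CD56dim_NK"]
    compartment: Literal["tumor", "stroma", "total"]
    count: int = Field(ge=0)
    area_mm2: float = Field(gt=0.0)
    density: float = Field(ge=0.0)
    percent_of_nucleated: float | None = Field(default=None, ge=0.0, le=100.0)

    @model_validator(mode="after")
    def _density_consistent(self) -> "ImmuneDensityRecord":
        if abs(self.density - self.count / self.area_mm2) > 1e-9:
            raise ValueError("density != count / area_mm2")
        return self


def compute_density(
    count: int, area_mm2: float, n_nucleated: int | None = None
) -> tuple[float, float | None]:
    """Cells per mm² and, if requested, percent of all nucleated cells."""
    if area_mm2 <= 0:
        raise ValueError(f"area must be positive, got {area_mm2}")
    if count < 0:
        raise ValueError("count must be non-negative")
    density = count / area_mm2
    percent = None
    if n_nucleated is not None:
        if n_nucleated == 0:
            raise ValueError("cannot compute percent of nucleated cells: n_nucleated is 0")
        if n_nucleated < count:
            raise ValueError("n_nucleated must be >= count")
        percent = 100.0 * count / n_nucleated
    return density, percent


class ComparisonResult(NamedTuple):
    statistic: float
    p_value: float
    method_used: str


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: Literal["auto", "welch_t", "student_t", "anova"] = "auto",
) -> ComparisonResult:
    """Two-group t test (Welch by default) or one-way ANOVA for more groups.

    ``auto`` selects Welch's t for two groups and one-way ANOVA for more.
    Returns the test statistic, the two-sided p-value, and which method ran.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    for name, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]

    if method == "auto":
        method = "welch_t" if len(groups) == 2 else "anova"
    if method in ("welch_t", "student_t"):
        if len(groups) != 2:
            raise ValueError(f"{method} requires exactly 2 groups, got {len(groups)}")
        res = stats.ttest_ind(groups[0], groups[1], equal_var=(method == "student_t"))
        return ComparisonResult(float(res.statistic), float(res.pvalue), method)
    if method == "anova":
        res = stats.f_oneway(*groups)
        return ComparisonResult(float(res.statistic), float(res.pvalue), "anova")
    raise ValueError(f"unknown method: {method!r}")


def adjust_pvalues(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Optional multiple-testing adjustment (Benjamini-Hochberg by default).

    Not applied anywhere by default; exposed for users who want it.
    """
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method=method)[1])
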