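"""Tumor mutational burden: counting, classification, cross-assay cutoff harmonization.

TMB is the count of somatic coding SNVs and indels (synonymous and
nonsynonymous, excluding designated driver mutations) divided by the size of
the interrogated coding region in megabases. A WES cutoff of 10 mut/Mb
defines TMB-High; the equivalent cutoff for a smaller targeted panel is
obtained by quantile matching on a reference population: the panel cutoff is
the quantile of the panel TMB distribution at the WES TMB-Low proportion, so
the two assays classify the same fraction of the reference as TMB-Low.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .variants import VariantCall

#: Default WES cutoff in mutations per megabase (TMB-High when >= cutoff).
DEFAULT_WES_CUTOFF = 10.0


class AssaySpec(BaseModel):
    """A sequencing assay and the coding footprint TMB is normalized by."""

    name: str
    coding_region_size_mb: float = Field(gt=0.0)
    tmb_cutoff: float | None = None

    @classmethod
    def wes(cls, cutoff: float | None = DEFAULT_WES_CUTOFF) -> "AssaySpec":
        return cls(name="wes", coding_region_size_mb=35.0, tmb_cutoff=cutoff)

    @classmethod
    def panel733(cls, cutoff: float | None = None) -> "AssaySpec":
        return cls(name="panel733", coding_region_size_mb=2.2, tmb_cutoff=cutoff)


class TMBResult(BaseModel):
    sample_id: str
    value: float = Field(ge=0.0)
    n_counted: int = Field(ge=0)
    assay: str
    classification: str | None = None

    @model_validator(mode="after")
    def _classification_vocab(self) -> "TMBResult":
        if self.classification not in (None, "TMB-High", "TMB-Low"):
            raise ValueError(f"bad TMB classification: {self.classification!r}")
        return self


DriverKey = tuple[str, str]


def load_default_driver_list() -> set[DriverKey]:
    """Canonical hotspot driver list shipped with the package.

    Entries are (gene, protein_change); (gene, "*") marks a whole gene as
    driver regardless of the specific alteration.
    """
    text = resources.files("nsclc_biomarkers.data").joinpath("default_drivers.tsv").read_text()
    drivers: set[DriverKey] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, hgvs = line.split("\t")
        drivers.add((gene, hgvs))
    return drivers


def read_driver_list(path: str | Path) -> set[DriverKey]:
    drivers: set[DriverKey] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, hgvs = line.split("\t")
            drivers.add((gene, hgvs))
    return drivers


def is_driver_mutation(variant: VariantCall, driver_list: set[DriverKey]) -> bool:
    return (
        (variant.gene, variant.hgvs_p) in driver_list
        or (variant.gene, "*") in driver_list
        or variant.is_driver
    )


def compute_tmb(
    variants: Iterable[VariantCall],
    assay: AssaySpec,
    driver_list: set[DriverKey] | None = None,
    sample_id: str | None = None,
) -> TMBResult:
    """Mutations per megabase over the assay's coding footprint.

    ``variants`` must already have passed the tmb filter profile (silent
    variants retained, amplifications excluded by consequence class). Driver
    mutations are excluded from the count.
    """
    if assay.coding_region_size_mb <= 0:
        raise ValueError("coding_region_size_mb must be positive")
    driver_list = driver_list if driver_list is not None else set()
    variants = list(variants)
    counted = [v for v in variants if not is_driver_mutation(v, driver_list)]
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else ""
    n = len(counted)
    return TMBResult(
        sample_id=sample_id,
        value=n / assay.coding_region_size_mb,
        n_counted=n,
        assay=assay.name,
    )


def classify_tmb(result: TMBResult, cutoff: float) -> TMBResult:
    """TMB-High iff value >= cutoff (boundary inclusive)."""
    if cutoff <= 0:
        raise ValueError("TMB cutoff must be positive")
    return result.model_copy(
        update={"classification": "TMB-High" if result.value >= cutoff else "TMB-Low"}
    )


class HarmonizationResult(NamedTuple):
    p: float
    panel_cutoff: float
    warning: str | None = None


def harmonize_cutoff(
    wes_reference_values: Sequence[float],
    wes_cutoff: float,
    panel_reference_values: Sequence[float],
) -> HarmonizationResult:
    """Quantile-match a WES TMB cutoff onto a panel TMB distribution.

    ``p`` is the fraction of WES reference values strictly below the WES
    cutoff (the WES TMB-Low proportion). The panel cutoff is the empirical
    p-quantile of the panel reference values, with linear interpolation
    between order statistics, so the panel classifies (up to 1/n) the same
    fraction of the reference as TMB-Low.
    """
    wes = np.asarray(wes_reference_values, dtype=float)
    panel = np.asarray(panel_reference_values, dtype=float)
    if wes.size == 0 or panel.size == 0:
        raise ValueError("reference value lists must be non-empty")
    if wes_cutoff <= 0:
        raise ValueError("wes_cutoff must be positive")
    p = float(np.mean(wes < wes_cutoff))
    warning = None
    if p == 0.0:
        warning = "no WES reference value below cutoff; panel cutoff set to minimum"
    elif p == 1.0:
        warning = "all WES reference values below cutoff; panel cutoff set to maximum"
    panel_cutoff = float(np.quantile(panel, p, method="linear"))
    return HarmonizationResult(p=p, panel_cutoff=panel_cutoff, warning=warning)


def write_tmb_table(results: Iterable[TMBResult], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "assay", "n_counted", "tmb", "class"])
        for r in results:
            writer.writerow(
                [r.sample_id, r.assay, r.n_counted, f"{r.value:.6g}", r.classification or ""]
            )
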