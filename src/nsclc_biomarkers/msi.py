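"""Microsatellite instability scoring from per-locus read-length histograms.

Each microsatellite locus contributes a histogram of read counts over repeat
lengths, compared against a panel-of-normals baseline histogram for the same
locus. A locus is called unstable when a sufficient fraction of its reads sit
at repeat lengths essentially absent from the baseline (novel lengths). The
MSI score is the fraction of unstable loci among the 30 best-covered loci;
MSI-H is a score >= 0.4, otherwise MSS.
"""

from __future__ import annotations

import logging
from typing import Sequence

from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

#: Score at or above which a sample is called MSI-H.
MSI_H_CUTOFF = 0.4
#: Number of best-covered loci evaluated per sample.
DEFAULT_N_LOCI = 30
#: Baseline frequency below which a repeat length counts as novel.
DEFAULT_NOVEL_SUPPORT_MIN = 0.01
#: Novel-length read fraction at or above which a locus is unstable.
DEFAULT_INSTABILITY_FRACTION_MIN = 0.20


class MicrosatelliteLocusProfile(BaseModel):
    """Read-length histogram at one locus plus its panel-of-normals baseline."""

    locus_id: str
    reference_modal_length: int = Field(ge=1)
    histogram: dict[int, int]
    baseline_histogram: dict[int, int]
    coverage: int = Field(ge=0)

    @model_validator(mode="after")
    def _counts_consistent(self) -> "MicrosatelliteLocusProfile":
        if any(c < 0 for c in self.histogram.values()):
            raise ValueError("negative read count in histogram")
        if any(c < 0 for c in self.baseline_histogram.values()):
            raise ValueError("negative count in baseline histogram")
        if self.coverage != sum(self.histogram.values()):
            raise ValueError(
                f"coverage {self.coverage} != histogram total {sum(self.histogram.values())}"
            )
        return self


class MSIResult(BaseModel):
    sample_id: str
    n_loci_evaluated: int = Field(ge=1)
    n_unstable: int = Field(ge=0)
    score: float = Field(ge=0.0, le=1.0)
    classification: str

    @model_validator(mode="after")
    def _consistent(self) -> "MSIResult":
        expected = self.n_unstable / self.n_loci_evaluated
        if abs(self.score - expected) > 1e-12:
            raise ValueError("score inconsistent with unstable/evaluated counts")
        expected_cls = "MSI-H" if self.score >= MSI_H_CUTOFF else "MSS"
        if self.classification != expected_cls:
            raise ValueError("classification inconsistent with score")
        return self


def select_msi_loci(
    loci: Sequence[MicrosatelliteLocusProfile], k: int = DEFAULT_N_LOCI
) -> list[MicrosatelliteLocusProfile]:
    """The k loci with the highest coverage (ties broken by locus_id, logged)."""
    if not loci:
        raise ValueError("no microsatellite loci provided")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(loci, key=lambda l: (-l.coverage, l.locus_id))
    if len(loci) < k:
        logger.warning(
            "only %d microsatellite loci available (requested %d); using all",
            len(loci),
            k,
        )
        return list(ranked)
    if len(ranked) > k and ranked[k - 1].coverage == ranked[k].coverage:
        logger.warning(
            "coverage tie at selection boundary (coverage=%d); broken by locus_id",
            ranked[k - 1].coverage,
        )
    return ranked[:k]


def call_locus_instability(
    locus: MicrosatelliteLocusProfile,
    novel_support_min: float = DEFAULT_NOVEL_SUPPORT_MIN,
    instability_fraction_min: float = DEFAULT_INSTABILITY_FRACTION_MIN,
) -> bool:
    """Unstable iff the read fraction at baseline-novel repeat lengths is high.

    A repeat length is novel when its baseline (panel-of-normals) frequency is
    below ``novel_support_min``. The locus is unstable when novel-length reads
    make up at least ``instability_fraction_min`` of its coverage.
    """
    if locus.coverage <= 0:
        raise ValueError(f"locus {locus.locus_id} has zero coverage")
    if not locus.baseline_histogram:
        raise ValueError(f"locus {locus.locus_id} has an empty baseline histogram")
    baseline_total = sum(locus.baseline_histogram.values())
    novel_reads = 0
    for length, count in locus.histogram.items():
        baseline_freq = locus.baseline_histogram.get(length, 0) / baseline_total
        if baseline_freq < novel_support_min:
            novel_reads += count
    return novel_reads / locus.coverage >= instability_fraction_min


def compute_msi_score(
    selected_loci: Sequence[MicrosatelliteLocusProfile],
    calls: Sequence[bool],
    sample_id: str = "",
) -> MSIResult:
    """MSI score = unstable fraction over evaluated loci; MSI-H iff >= 0.4."""
    if len(selected_loci) != len(calls):
        raise ValueError("instability calls not aligned with selected loci")
    n = len(selected_loci)
    if n == 0:
        raise ValueError("no loci evaluated")
    n_unstable = int(sum(bool(c) for c in calls))
    score = n_unstable / n
    return MSIResult(
        sample_id=sample_id,
        n_loci_evaluated=n,
        n_unstable=n_unstable,
        score=score,
        classification="MSI-H" if score >= MSI_H_CUTOFF else "MSS",
    )


def score_sample(
    loci: Sequence[MicrosatelliteLocusProfile],
    sample_id: str = "",
    k: int = DEFAULT_N_LOCI,
    novel_support_min: float = DEFAULT_NOVEL_SUPPORT_MIN,
    instability_fraction_min: float = DEFAULT_INSTABILITY_FRACTION_MIN,
) -> MSIResult:
    """Select loci, call instability per locus, and score one sample."""
    selected = select_msi_loci(loci, k=k)
    calls = [
        call_locus_instability(l, novel_support_min, instability_fraction_min)
        for l in selected
    ]
    return compute_msi_score(selected, calls, sample_id=sample_id)
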