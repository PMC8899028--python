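"""EGFR mutation subtype classification from protein-level HGVS.

The subtype vocabulary is the one used clinically for NSCLC: the common
sensitizing alterations (exon 19 in-frame deletions, L858R), the resistance
mutation T790M, the recurrent uncommon point mutations (G719A/C/S collapsed
to G719X, S768I, L861Q), in-frame exon 20 insertions/duplications (20ins),
everything else (including amplification) as other_uncommon, and sample-level
labels wildtype / multiple.

Residue ranges follow the canonical EGFR transcript (NM_005228 numbering):
exon 18 codons 688-728, exon 19 codons 729-761, exon 20 codons 762-823,
exon 21 codons 824-875. The exon 19 and 20 windows drive the 19del and
20ins rules below.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel

from .variants import VariantCall

SUBTYPE_LABELS: tuple[str, ...] = (
    "wildtype",
    "19del",
    "L858R",
    "T790M",
    "G719X",
    "S768I",
    "L861Q",
    "20ins",
    "other_uncommon",
    "multiple",
)

EXON19_RANGE = (729, 761)
EXON20_RANGE = (762, 823)

_EXACT_POINT = {
    "L858R": "L858R",
    "T790M": "T790M",
    "S768I": "S768I",
    "L861Q": "L861Q",
    "G719A": "G719X",
    "G719C": "G719X",
    "G719S": "G719X",
}

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter"
)
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_RE_SUB = re.compile(r"^p\.([A-Z\*])(\d+)([A-Z\*])$")
_RE_SUB3 = re.compile(rf"^p\.({_AA3})(\d+)({_AA3})$")
_RE_DEL = re.compile(r"^p\.([A-Z])(\d+)(?:_([A-Z])(\d+))?del(?:ins([A-Z]+))?$")
_RE_INSDUP = re.compile(r"^p\.([A-Z])(\d+)_([A-Z])(\d+)(?:ins([A-Z]+)|dup)$")
_RE_DUP1 = re.compile(r"^p\.([A-Z])(\d+)dup$")
_RE_FS = re.compile(r"^p\.([A-Z])(\d+)[A-Za-z\*]*fs.*$")


class HGVSParseError(ValueError):
    """Raised for protein HGVS strings that are not syntactically valid."""

    def __init__(self, hgvs: str):
        super().__init__(f"unparseable protein HGVS string: {hgvs!r}")
        self.hgvs = hgvs


class EGFRSubtype(BaseModel):
    """Sample-level subtype label and the alterations that produced it."""

    label: str
    constituent_alterations: list[str]


def _normalize(hgvs: str) -> str:
    h = hgvs.strip()
    if h and not h.startswith("p."):
        h = "p." + h
    m = _RE_SUB3.match(h)
    if m:  # fold 3-letter substitutions down to 1-letter
        return f"p.{_AA3_TO_1[m.group(1)]}{m.group(2)}{_AA3_TO_1[m.group(3)]}"
    return h


def classify_variant(variant: VariantCall) -> str:
    """Per-alteration EGFR category (no sample-level wildtype/multiple)."""
    if variant.consequence == "amplification":
        return "other_uncommon"
    h = _normalize(variant.hgvs_p)
    if not h:
        raise HGVSParseError(variant.hgvs_p)

    m = _RE_SUB.match(h)
    if m:
        key = f"{m.group(1)}{m.group(2)}{m.group(3)}"
        return _EXACT_POINT.get(key, "other_uncommon")

    m = _RE_DEL.match(h)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        is_delins = m.group(5) is not None
        in_frame = variant.consequence in ("inframe_indel", "inframe_insertion_dup")
        if (
            (in_frame or is_delins or variant.consequence == "other")
            and EXON19_RANGE[0] <= start
            and end <= EXON19_RANGE[1]
        ):
            return "19del"
        # frameshifting deletions and out-of-window deletions are uncommon
        return "other_uncommon"

    m = _RE_INSDUP.match(h)
    if m:
        start, end = int(m.group(2)), int(m.group(4))
        if EXON20_RANGE[0] <= start and end <= EXON20_RANGE[1]:
            return "20ins"
        return "other_uncommon"

    m = _RE_DUP1.match(h)
    if m:
        pos = int(m.group(2))
        if EXON20_RANGE[0] <= pos <= EXON20_RANGE[1]:
            return "20ins"
        return "other_uncommon"

    if _RE_FS.match(h):
        return "other_uncommon"

    raise HGVSParseError(variant.hgvs_p)


def classify_egfr(egfr_variants: Sequence[VariantCall]) -> EGFRSubtype:
    """Sample-level EGFR subtype from that sample's EGFR alterations.

    Deterministic and order-insensitive: one distinct per-variant category
    gives that label, two or more give ``multiple``, none gives ``wildtype``.
    """
    if not egfr_variants:
        return EGFRSubtype(label="wildtype", constituent_alterations=[])
    categories = {classify_variant(v) for v in egfr_variants}
    constituents = sorted(
        v.hgvs_p if v.hgvs_p else f"{v.gene}:amplification" for v in egfr_variants
    )
    label = "multiple" if len(categories) >= 2 else next(iter(categories))
    return EGFRSubtype(label=label, constituent_alterations=constituents)


def tabulate_subtype_frequencies(
    labels: Iterable[str],
    denominator_mode: str = "all",
    denominator: int | None = None,
) -> pd.DataFrame:
    """Subtype frequency table (label, count, percent) over a cohort.

    ``denominator_mode='all'`` uses every sample; ``'mutated_only'`` restricts
    rows and the denominator to samples with any EGFR alteration. Percents are
    rounded to two decimals; counts partition the denominator.

    Published cohort tables sometimes count a patient in several subtype rows
    (so row counts exceed the number of patients) while still reporting
    percentages of the patient total; pass that total as ``denominator`` to
    reproduce such tables. The partition invariant then no longer applies.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty cohort: no subtype labels to tabulate")
    unknown = set(labels) - set(SUBTYPE_LABELS)
    if unknown:
        raise ValueError(f"unknown subtype label(s): {sorted(unknown)}")
    if denominator_mode not in ("all", "mutated_only"):
        raise ValueError(f"unknown denominator_mode: {denominator_mode!r}")

    if denominator_mode == "mutated_only":
        labels = [lab for lab in labels if lab != "wildtype"]
        if not labels:
            raise ValueError("no EGFR-mutated samples for mutated_only tabulation")
    counts = Counter(labels)
    if denominator is None:
        denominator = len(labels)
    elif denominator < 1:
        raise ValueError("denominator must be a positive integer")
    rows = [
        {
            "label": lab,
            "count": counts[lab],
            "percent": round(100.0 * counts[lab] / denominator, 2),
        }
        for lab in SUBTYPE_LABELS
        if counts[lab] > 0
    ]
    table = pd.DataFrame(rows, columns=["label", "count", "percent"])
    table.attrs["denominator"] = denominator
    return table
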