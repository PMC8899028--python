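"""Annotated somatic variant calls: data model, filter cascade, tabular I/O.

Variants arrive already annotated (gene symbol, protein-level HGVS,
consequence class, allele frequency, population frequencies). The filter
cascade removes low-AF calls, likely-germline calls common in population
databases, and consequence classes outside the retained set. Two profiles
exist because reporting excludes silent variants while mutational-burden
counting includes them.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, Field, field_validator, model_validator

Consequence = Literal[
    "missense",
    "stopgain",
    "stoploss",
    "silent",
    "frameshift_indel",
    "inframe_indel",
    "inframe_insertion_dup",
    "amplification",
    "other",
]

CONSEQUENCE_VOCABULARY: frozenset[str] = frozenset(
    [
        "missense",
        "stopgain",
        "stoploss",
        "silent",
        "frameshift_indel",
        "inframe_indel",
        "inframe_insertion_dup",
        "amplification",
        "other",
    ]
)

#: Consequence classes retained for clinical reporting: stopgain, missense,
#: frameshift and non-frameshift (in-frame) indels, plus amplifications
#: (reported as gene-level events).
REPORTING_CONSEQUENCES: frozenset[str] = frozenset(
    [
        "missense",
        "stopgain",
        "frameshift_indel",
        "inframe_indel",
        "inframe_insertion_dup",
        "amplification",
    ]
)

#: Consequence classes counted toward mutational burden: all coding SNVs and
#: indels including silent and stop-loss; amplifications are not SNVs/indels.
TMB_CONSEQUENCES: frozenset[str] = frozenset(
    [
        "missense",
        "silent",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "inframe_indel",
        "inframe_insertion_dup",
    ]
)


class VariantCall(BaseModel):
    """One annotated somatic alteration in one sample.

    Coordinates are 1-based fully closed (VCF convention). Amplification
    records carry empty ``ref``/``alt`` and usually an empty ``hgvs_p``.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int = Field(ge=1)
    ref: str
    alt: str
    hgvs_p: str = ""
    consequence: Consequence
    allele_frequency: float = Field(ge=0.0, le=1.0)
    depth: int = Field(ge=0)
    pop_freqs: dict[str, float] = Field(default_factory=dict)
    is_driver: bool = False

    @field_validator("pop_freqs")
    @classmethod
    def _pop_freqs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for db, f in v.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"population frequency for {db!r} outside [0, 1]: {f}")
        return v

    @model_validator(mode="after")
    def _amplification_has_no_alleles(self) -> "VariantCall":
        if self.consequence == "amplification" and (self.ref or self.alt):
            raise ValueError("amplification records must have empty ref/alt")
        return self

    def max_pop_freq(self) -> float:
        """Maximum frequency across annotated population databases (0 if none)."""
        return max(self.pop_freqs.values(), default=0.0)


class FilterProfile(BaseModel):
    """Thresholds and retained consequence classes for one filtering purpose.

    ``min_af`` keeps calls with allele fraction >= the bound (inclusive);
    ``max_pop_freq`` drops calls whose maximum population frequency exceeds
    the bound (strictly greater is removed, i.e. likely germline/common).
    """

    min_af: float = Field(default=0.05, ge=0.0, le=1.0)
    max_pop_freq: float = Field(default=0.015, ge=0.0, le=1.0)
    retained_consequences: frozenset[str]
    purpose: Literal["reporting", "tmb"]

    @field_validator("retained_consequences")
    @classmethod
    def _non_empty_known(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("retained_consequences must be non-empty")
        unknown = v - CONSEQUENCE_VOCABULARY
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
        return v

    @classmethod
    def reporting(cls, **overrides) -> "FilterProfile":
        return cls(
            retained_consequences=REPORTING_CONSEQUENCES, purpose="reporting", **overrides
        )

    @classmethod
    def tmb(cls, **overrides) -> "FilterProfile":
        return cls(retained_consequences=TMB_CONSEQUENCES, purpose="tmb", **overrides)


def filter_variants(
    variants: Iterable[VariantCall], profile: FilterProfile
) -> list[VariantCall]:
    """Apply the somatic filter cascade; order-preserving, idempotent.

    A variant survives iff its allele frequency meets ``min_af``, its maximum
    population frequency does not exceed ``max_pop_freq``, and its consequence
    class is retained. Amplifications have no meaningful allele fraction and
    are exempt from the AF rule under the reporting profile.
    """
    variants = list(variants)
    bad = [
        (i, v.consequence)
        for i, v in enumerate(variants)
        if v.consequence not in CONSEQUENCE_VOCABULARY
    ]
    if bad:
        raise ValueError(f"unknown consequence in input rows: {bad}")

    kept: list[VariantCall] = []
    for v in variants:
        af_exempt = v.consequence == "amplification" and profile.purpose == "reporting"
        if not af_exempt and v.allele_frequency < profile.min_af:
            continue
        if v.max_pop_freq() > profile.max_pop_freq:
            continue
        if v.consequence not in profile.retained_consequences:
            continue
        kept.append(v)
    return kept


MAF_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_p",
    "consequence",
    "af",
    "depth",
    "popfreq_1kg",
    "popfreq_esp6500",
    "is_driver",
]

#: Default INFO keys used when reading annotated VCF.
DEFAULT_VCF_INFO_KEYS: dict[str, str] = {
    "gene": "GENE",
    "hgvs_p": "HGVSP",
    "consequence": "CONSEQ",
    "af": "AF",
    "popfreq_1kg": "POP_1KG",
    "popfreq_esp6500": "POP_ESP",
    "driver": "DRIVER",
}


class VariantIOError(ValueError):
    """Raised for malformed or incomplete variant input files."""


def _variant_from_maf_row(row: Mapping[str, str], line_no: int) -> VariantCall:
    try:
        return VariantCall(
            sample_id=row["sample_id"],
            gene=row["gene"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            hgvs_p=row["hgvs_p"],
            consequence=row["consequence"],
            allele_frequency=float(row["af"]),
            depth=int(row["depth"]),
            pop_freqs={
                "1kg": float(row["popfreq_1kg"]),
                "esp6500": float(row["popfreq_esp6500"]),
            },
            is_driver=row["is_driver"].strip().lower() in ("1", "true", "yes"),
        )
    except (ValueError, KeyError) as exc:
        raise VariantIOError(f"malformed variant row at line {line_no}: {exc}") from exc


def read_variants(
    path: str | Path,
    format: Literal["maf-tsv", "vcf"] = "maf-tsv",
    vcf_info_keys: Mapping[str, str] | None = None,
    vcf_sample_id: str | None = None,
) -> list[VariantCall]:
    """Read annotated variant calls from a MAF-like TSV or an annotated VCF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "maf-tsv":
        return _read_maf_tsv(path)
    if format == "vcf":
        return _read_vcf(path, vcf_info_keys or DEFAULT_VCF_INFO_KEYS, vcf_sample_id)
    raise ValueError(f"unknown variant format: {format!r}")


def _read_maf_tsv(path: Path) -> list[VariantCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in MAF_COLUMNS if c not in header]
        if missing:
            raise VariantIOError(f"missing required column(s) in {path}: {missing}")
        return [_variant_from_maf_row(row, i) for i, row in enumerate(reader, start=2)]


def _read_vcf(
    path: Path, info_keys: Mapping[str, str], sample_id: str | None
) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else path.stem
    out: list[VariantCall] = []
    for rec in vcf:
        conseq = rec.INFO.get(info_keys["consequence"])
        if conseq is None:
            raise VariantIOError(
                f"VCF record {rec.CHROM}:{rec.POS} lacks consequence annotation "
                f"(INFO key {info_keys['consequence']!r})"
            )
        af = rec.INFO.get(info_keys["af"])
        if af is None:
            raise VariantIOError(
                f"VCF record {rec.CHROM}:{rec.POS} lacks allele-frequency annotation "
                f"(INFO key {info_keys['af']!r})"
            )
        pop_freqs = {}
        for db, key in (("1kg", info_keys["popfreq_1kg"]), ("esp6500", info_keys["popfreq_esp6500"])):
            val = rec.INFO.get(key)
            if val is not None:
                pop_freqs[db] = float(val)
        out.append(
            VariantCall(
                sample_id=sample_id,
                gene=str(rec.INFO.get(info_keys["gene"], "")),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF or "",
                alt=rec.ALT[0] if rec.ALT else "",
                hgvs_p=str(rec.INFO.get(info_keys["hgvs_p"], "")),
                consequence=str(conseq),
                allele_frequency=float(af),
                depth=int(rec.INFO.get("DP", 0) or 0),
                pop_freqs=pop_freqs,
                is_driver=bool(rec.INFO.get(info_keys["driver"], False)),
            )
        )
    return out


def write_variants(variants: Iterable[VariantCall], path: str | Path) -> None:
    """Write variants as MAF-like TSV (inverse of ``read_variants`` for maf-tsv)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MAF_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.sample_id,
                    v.gene,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.hgvs_p,
                    v.consequence,
                    repr(v.allele_frequency),
                    v.depth,
                    repr(v.pop_freqs.get("1kg", 0.0)),
                    repr(v.pop_freqs.get("esp6500", 0.0)),
                    str(v.is_driver).lower(),
                ]
            )
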