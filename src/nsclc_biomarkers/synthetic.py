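"""Synthetic NSCLC cohorts with the statistical structure the pipeline assumes.

The generator emulates, per sample: an EGFR subtype drawn from configured
frequencies together with protein-level HGVS alterations that the subtyping
module maps back to the drawn label (round-trip property); subtype-
conditional log-normal TMB on a WES-like and a panel-like assay; a small
MSI-H fraction whose microsatellite read-length histograms are perturbed
away from the panel-of-normals baseline; a PD-L1 TPS mixture over tiers;
log-normal immune densities per cell type and compartment with an
EGFR-dependent CD8 shift; and exponential progression-free survival whose
hazard is multiplied up by stratum flags (EGFR mutated, CD8-low), with
independent uniform censoring.

One global integer seed drives everything; sub-generators derive child seeds
by fixed offsets so regeneration with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .egfr import SUBTYPE_LABELS
from .msi import MicrosatelliteLocusProfile
from .survival import SurvivalRecord, median_split
from .tme import ImmuneDensityRecord, TPSRecord, classify_tps
from .variants import VariantCall

_SEED_MOD = 2**31

# fixed child-seed offsets per sub-generator
_OFFSETS = {
    "subtype": 1,
    "variants": 2,
    "tmb": 3,
    "msi": 4,
    "tps": 5,
    "density": 6,
    "survival": 7,
}

# Representative alterations per subtype category: (hgvs_p, consequence).
# Each entry classifies back to its category under the subtyping rules.
_SUBTYPE_REPRESENTATIVES: dict[str, list[tuple[str, str]]] = {
    "19del": [
        ("p.E746_A750del", "inframe_indel"),
        ("p.L747_P753delinsS", "inframe_indel"),
        ("p.L747_T751del", "inframe_indel"),
    ],
    "L858R": [("p.L858R", "missense")],
    "T790M": [("p.T790M", "missense")],
    "G719X": [
        ("p.G719A", "missense"),
        ("p.G719C", "missense"),
        ("p.G719S", "missense"),
    ],
    "S768I": [("p.S768I", "missense")],
    "L861Q": [("p.L861Q", "missense")],
    "20ins": [
        ("p.A767_V769dup", "inframe_insertion_dup"),
        ("p.D770_N771insSVD", "inframe_insertion_dup"),
        ("p.P772_H773dup", "inframe_insertion_dup"),
    ],
    "other_uncommon": [
        ("p.N468K", "missense"),
        ("p.E709A", "missense"),
        ("p.R451H", "missense"),
        ("p.H870R", "missense"),
        ("p.V774M", "missense"),
        ("", "amplification"),
    ],
}

_MULTIPLE_POOL = ["19del", "L858R", "T790M", "G719X", "S768I", "L861Q", "20ins"]


class SurvivalParams(BaseModel):
    baseline_hazard: float = Field(gt=0.0)
    hazard_ratios: dict[str, float] = Field(default_factory=dict)
    censoring_max_months: float = Field(gt=0.0, default=60.0)

    @field_validator("hazard_ratios")
    @classmethod
    def _positive_ratios(cls, v: dict[str, float]) -> dict[str, float]:
        for k, hr in v.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio for {k!r} must be positive")
        return v


class CohortConfig(BaseModel):
    """Full parameterization of one synthetic cohort draw."""

    n_samples: int = Field(ge=0)
    seed: int
    subtype_probs: dict[str, float]
    tmb_params: dict[str, dict[str, tuple[float, float]]]
    msi_h_prob: float = Field(ge=0.0, le=1.0)
    msi_n_loci: int = Field(ge=1, default=100)
    mss_profile_cap: int = Field(ge=0, default=200)
    tps_mixture: dict[str, tuple[float, float, float]]
    density_params: dict[str, dict[str, dict[str, tuple[float, float]]]]
    survival_params: SurvivalParams

    @field_validator("subtype_probs")
    @classmethod
    def _probs_valid(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(SUBTYPE_LABELS)
        if unknown:
            raise ValueError(f"subtype_probs has unknown labels: {sorted(unknown)}")
        for lab, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"subtype_probs[{lab!r}] outside [0, 1]: {p}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_probs must sum to 1 (got {total!r})")
        return v

    @field_validator("tmb_params", "density_params")
    @classmethod
    def _sdlogs_positive(cls, v):
        def walk(node, path):
            if isinstance(node, dict):
                for k, sub in node.items():
                    walk(sub, f"{path}.{k}")
            else:
                meanlog, sdlog = node
                if sdlog <= 0:
                    raise ValueError(f"sd-log at {path} must be > 0, got {sdlog}")

        walk(v, "params")
        return v

    @field_validator("tps_mixture")
    @classmethod
    def _tier_weights_valid(cls, v):
        for lab, weights in v.items():
            if any(w < 0 for w in weights):
                raise ValueError(f"tps_mixture[{lab!r}] has negative weight")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"tps_mixture[{lab!r}] weights must sum to 1")
        return v

    @model_validator(mode="after")
    def _subtype_coverage(self) -> "CohortConfig":
        for lab, p in self.subtype_probs.items():
            if p > 0 and lab != "wildtype":
                if lab not in self.tmb_params:
                    raise ValueError(f"tmb_params missing subtype {lab!r}")
                if lab not in self.tps_mixture:
                    raise ValueError(f"tps_mixture missing subtype {lab!r}")
        if "wildtype" not in self.tmb_params or "wildtype" not in self.tps_mixture:
            raise ValueError("parameters for subtype 'wildtype' are required")
        return self

    @classmethod
    def default(cls, **overrides) -> "CohortConfig":
        """The shipped default parameter file, with optional field overrides."""
        raw = yaml.safe_load(
            resources.files("nsclc_biomarkers.data")
            .joinpath("default_cohort.yaml")
            .read_text()
        )
        raw.update(overrides)
        return cls.model_validate(raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


class SampleProfile(BaseModel):
    """Per-sample biomarker bundle produced by the generator."""

    sample_id: str
    egfr_subtype: str
    tmb_wes: float = Field(ge=0.0)
    tmb_panel: float = Field(ge=0.0)
    msi_status: str
    tps: float = Field(ge=0.0, le=100.0)
    tps_tier: str


@dataclass
class SyntheticCohort:
    """One generated cohort plus provenance; regeneration is bit-identical."""

    config: CohortConfig
    samples: list[SampleProfile] = field(default_factory=list)
    variants: list[VariantCall] = field(default_factory=list)
    msi_profiles: dict[str, list[MicrosatelliteLocusProfile]] = field(default_factory=dict)
    densities: list[ImmuneDensityRecord] = field(default_factory=list)
    survival: list[SurvivalRecord] = field(default_factory=list)

    @property
    def provenance(self) -> dict:
        return {"config": json.loads(self.config.canonical_json()),
                "config_hash": self.config.config_hash(),
                "seed": self.config.seed}


def _child_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng((seed + _OFFSETS[name]) % _SEED_MOD)


def _draw_tier(rng: np.random.Generator, weights: tuple[float, float, float]) -> float:
    """TPS percentage drawn from the tier mixture (uniform within tier)."""
    tier = rng.choice(3, p=np.asarray(weights) / np.sum(weights))
    if tier == 0:
        return float(rng.uniform(0.0, 1.0))
    if tier == 1:
        return float(rng.uniform(1.0, 50.0))
    return float(rng.uniform(50.0, 100.0))


def _egfr_variants_for(
    sample_id: str, label: str, rng: np.random.Generator
) -> list[VariantCall]:
    if label == "wildtype":
        return []
    if label == "multiple":
        cats = rng.choice(len(_MULTIPLE_POOL), size=2, replace=False)
        categories = [_MULTIPLE_POOL[int(c)] for c in cats]
    else:
        categories = [label]
    out = []
    for cat in categories:
        reps = _SUBTYPE_REPRESENTATIVES[cat]
        hgvs, conseq = reps[int(rng.integers(len(reps)))]
        amp = conseq == "amplification"
        out.append(
            VariantCall(
                sample_id=sample_id,
                gene="EGFR",
                chrom="7",
                pos=55191822 if not amp else 55019017,
                ref="" if amp else "A",
                alt="" if amp else "T",
                hgvs_p=hgvs,
                consequence=conseq,
                allele_frequency=1.0 if amp else float(rng.uniform(0.05, 0.6)),
                depth=int(rng.integers(200, 2000)),
                pop_freqs={"1kg": 0.0, "esp6500": 0.0},
                is_driver=not amp,
            )
        )
    return out


def generate_msi_profiles(
    sample_status: str,
    n_loci: int,
    seed: int,
    coverage_range: tuple[int, int] = (300, 900),
    perturb_prob: float = 0.7,
    novel_mass: float = 0.4,
) -> list[MicrosatelliteLocusProfile]:
    """Per-locus read-length histograms for one sample.

    MSS samples draw multinomially from the panel-of-normals shape (with a
    tiny stutter mass at adjacent lengths, well under the instability
    threshold). MSI-H samples shift ``novel_mass`` of the reads at a
    ``perturb_prob`` fraction of loci to shorter, baseline-novel repeat
    lengths, so the expected downstream score (~perturb_prob) clears the 0.4
    MSI-H boundary.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if sample_status not in ("MSS", "MSI-H"):
        raise ValueError(f"sample_status must be 'MSS' or 'MSI-H', got {sample_status!r}")
    rng = np.random.default_rng(seed % _SEED_MOD)
    baseline_coverage = 1000
    base_shape = np.array([0.05, 0.2, 0.5, 0.2, 0.05])
    stutter = 0.002  # per-side novel stutter mass in tumor reads
    profiles: list[MicrosatelliteLocusProfile] = []
    for i in range(n_loci):
        modal = int(rng.integers(10, 26))
        lengths = np.arange(modal - 2, modal + 3)
        baseline_counts = np.round(base_shape * baseline_coverage).astype(int)
        coverage = int(rng.integers(coverage_range[0], coverage_range[1] + 1))

        tumor_lengths = np.concatenate([lengths, [modal - 3, modal + 3]])
        probs = np.concatenate([base_shape * (1 - 2 * stutter), [stutter, stutter]])
        if sample_status == "MSI-H" and rng.random() < perturb_prob:
            # deletion-type instability: mass moves to shorter novel lengths
            tumor_lengths = np.concatenate([tumor_lengths, [modal - 4, modal - 5]])
            probs = np.concatenate([probs * (1 - novel_mass), [novel_mass / 2, novel_mass / 2]])
        counts = rng.multinomial(coverage, probs / probs.sum())
        histogram = {
            int(l): int(c) for l, c in zip(tumor_lengths, counts) if c > 0
        }
        profiles.append(
            MicrosatelliteLocusProfile(
                locus_id=f"MS{i:03d}",
                reference_modal_length=modal,
                histogram=histogram,
                baseline_histogram={
                    int(l): int(c) for l, c in zip(lengths, baseline_counts)
                },
                coverage=int(sum(histogram.values())),
            )
        )
    return profiles


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from the configured distributions."""
    cohort = SyntheticCohort(config=config)
    n = config.n_samples
    if n == 0:
        return cohort
    seed = config.seed
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    labels_order = [lab for lab in SUBTYPE_LABELS if config.subtype_probs.get(lab, 0) > 0]
    probs = np.array([config.subtype_probs[lab] for lab in labels_order])
    rng_sub = _child_rng(seed, "subtype")
    subtype_idx = rng_sub.choice(len(labels_order), size=n, p=probs / probs.sum())
    subtypes = [labels_order[int(i)] for i in subtype_idx]

    rng_var = _child_rng(seed, "variants")
    for sid, lab in zip(sample_ids, subtypes):
        cohort.variants.extend(_egfr_variants_for(sid, lab, rng_var))

    rng_tmb = _child_rng(seed, "tmb")
    tmb_wes = np.empty(n)
    tmb_panel = np.empty(n)
    for i, lab in enumerate(subtypes):
        params = config.tmb_params[lab]
        mw, sw = params["wes"]
        mp, sp = params["panel"]
        tmb_wes[i] = rng_tmb.lognormal(mw, sw)
        tmb_panel[i] = rng_tmb.lognormal(mp, sp)

    rng_msi = _child_rng(seed, "msi")
    msi_status = np.where(rng_msi.random(n) < config.msi_h_prob, "MSI-H", "MSS")
    mss_budget = config.mss_profile_cap
    for sid, status in zip(sample_ids, msi_status):
        if status == "MSS":
            if mss_budget <= 0:
                continue
            mss_budget -= 1
        child_seed = int(rng_msi.integers(_SEED_MOD))
        cohort.msi_profiles[sid] = generate_msi_profiles(
            str(status), config.msi_n_loci, child_seed
        )

    rng_tps = _child_rng(seed, "tps")
    tps_values = [
        _draw_tier(rng_tps, config.tps_mixture[lab]) for lab in subtypes
    ]

    rng_den = _child_rng(seed, "density")
    cd8_tumor_density: dict[str, float] = {}
    for sid, lab in zip(sample_ids, subtypes):
        group = "wildtype" if lab == "wildtype" else "mutated"
        area_by_comp = {
            "tumor": round(float(rng_den.uniform(0.6, 1.4)), 3),
            "stroma": round(float(rng_den.uniform(0.6, 1.4)), 3),
        }
        nucleated_density = 2500.0  # nucleated cells per mm2, all compartments
        for cell_type, comps in config.density_params.items():
            counts = {}
            for comp in ("tumor", "stroma"):
                meanlog, sdlog = comps[comp][group]
                target_density = rng_den.lognormal(meanlog, sdlog)
                area = area_by_comp[comp]
                count = int(rng_den.poisson(target_density * area))
                counts[comp] = count
                n_nucleated = max(count, int(round(nucleated_density * area)))
                cohort.densities.append(
                    ImmuneDensityRecord(
                        sample_id=sid,
                        cell_type=cell_type,
                        compartment=comp,
                        count=count,
                        area_mm2=area,
                        density=count / area,
                        percent_of_nucleated=100.0 * count / n_nucleated,
                    )
                )
            total_area = area_by_comp["tumor"] + area_by_comp["stroma"]
            total_count = counts["tumor"] + counts["stroma"]
            cohort.densities.append(
                ImmuneDensityRecord(
                    sample_id=sid,
                    cell_type=cell_type,
                    compartment="total",
                    count=total_count,
                    area_mm2=total_area,
                    density=total_count / total_area,
                    percent_of_nucleated=100.0
                    * total_count
                    / max(total_count, int(round(nucleated_density * total_area))),
                )
            )
            if cell_type == "CD8_T":
                cd8_tumor_density[sid] = counts["tumor"] / area_by_comp["tumor"]

    cd8_split = (
        median_split(cd8_tumor_density) if len(cd8_tumor_density) >= 2 else {}
    )

    rng_surv = _child_rng(seed, "survival")
    sp = config.survival_params
    for i, (sid, lab) in enumerate(zip(sample_ids, subtypes)):
        hazard = sp.baseline_hazard
        strata = {
            "egfr": "mutated" if lab != "wildtype" else "wildtype",
            "tmb_wes": "high" if tmb_wes[i] >= 10.0 else "low",
            "cd8_tumor": cd8_split.get(sid, "high"),
        }
        if lab != "wildtype":
            hazard *= sp.hazard_ratios.get("egfr_mutated", 1.0)
        if strata["cd8_tumor"] == "low":
            hazard *= sp.hazard_ratios.get("cd8_tumor_low", 1.0)
        t_event = rng_surv.exponential(1.0 / hazard)
        t_censor = rng_surv.uniform(0.0, sp.censoring_max_months)
        cohort.survival.append(
            SurvivalRecord(
                sample_id=sid,
                time_months=round(min(t_event, t_censor), 4),
                event=bool(t_event <= t_censor),
                strata=strata,
            )
        )

    for i, (sid, lab) in enumerate(zip(sample_ids, subtypes)):
        cohort.samples.append(
            SampleProfile(
                sample_id=sid,
                egfr_subtype=lab,
                tmb_wes=float(tmb_wes[i]),
                tmb_panel=float(tmb_panel[i]),
                msi_status=str(msi_status[i]),
                tps=tps_values[i],
                tps_tier=classify_tps(tps_values[i]),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text tables; byte-identical across reruns."""
    from .variants import write_variants

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "variants": outdir / "variants.tsv",
        "msi": outdir / "msi_histograms.tsv",
        "mif": outdir / "mif_densities.tsv",
        "survival": outdir / "survival.tsv",
        "provenance": outdir / "provenance.json",
    }
    with open(paths["cohort"], "w") as fh:
        fh.write("sample_id\tegfr_subtype\ttmb_wes\ttmb_panel\tmsi_status\ttps\ttps_tier\n")
        for s in cohort.samples:
            fh.write(
                f"{s.sample_id}\t{s.egfr_subtype}\t{s.tmb_wes:.6f}\t{s.tmb_panel:.6f}"
                f"\t{s.msi_status}\t{s.tps:.4f}\t{s.tps_tier}\n"
            )
    write_variants(cohort.variants, paths["variants"])
    with open(paths["msi"], "w") as fh:
        fh.write("sample_id\tlocus\trepeat_length\tread_count\tbaseline_count\n")
        for sid in sorted(cohort.msi_profiles):
            for prof in cohort.msi_profiles[sid]:
                lengths = sorted(set(prof.histogram) | set(prof.baseline_histogram))
                for l in lengths:
                    fh.write(
                        f"{sid}\t{prof.locus_id}\t{l}\t{prof.histogram.get(l, 0)}"
                        f"\t{prof.baseline_histogram.get(l, 0)}\n"
                    )
    with open(paths["mif"], "w") as fh:
        fh.write(
            "sample_id\tcell_type\tcompartment\tcount\tarea_mm2\tdensity\tpercent_of_nucleated\n"
        )
        for r in cohort.densities:
            fh.write(
                f"{r.sample_id}\t{r.cell_type}\t{r.compartment}\t{r.count}"
                f"\t{r.area_mm2:.3f}\t{r.density:.6f}\t{r.percent_of_nucleated:.6f}\n"
            )
    with open(paths["survival"], "w") as fh:
        strat_keys = sorted({k for r in cohort.survival for k in r.strata})
        fh.write("sample_id\ttime_months\tevent\t" + "\t".join(strat_keys) + "\n")
        for r in cohort.survival:
            strata = "\t".join(r.strata.get(k, "") for k in strat_keys)
            fh.write(f"{r.sample_id}\t{r.time_months:.4f}\t{int(r.event)}\t{strata}\n")
    with open(paths["provenance"], "w") as fh:
        json.dump(cohort.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def densities_frame(records: Iterable[ImmuneDensityRecord]):
    import pandas as pd

    return pd.DataFrame([r.model_dump() for r in records])


def tps_records(cohort: SyntheticCohort) -> list[TPSRecord]:
    return [
        TPSRecord(sample_id=s.sample_id, tps=s.tps, tier=s.tps_tier)
        for s in cohort.samples
    ]
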