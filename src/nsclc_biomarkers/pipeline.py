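"""End-to-end report generation over a cohort's input tables.

Ties the stages together in the order the analysis runs: variant filtering
and EGFR subtyping, TMB classification with cross-assay cutoff
harmonization, MSI scoring, TPS tiering, immune-density group comparisons,
and biomarker-stratified survival. Each stage writes its tables into its own
subdirectory; a provenance JSON records the config hash so any output can be
traced to the exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .egfr import classify_egfr, tabulate_subtype_frequencies
from .msi import score_sample, MicrosatelliteLocusProfile
from .survival import (
    SurvivalRecord,
    cox_univariate,
    km_curve_frame,
    km_estimate,
    logrank_test,
    median_split,
)
from .tmb import (
    AssaySpec,
    DEFAULT_WES_CUTOFF,
    TMBResult,
    classify_tmb,
    harmonize_cutoff,
)
from .tme import compare_groups
from .variants import FilterProfile, filter_variants, read_variants

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Paths and thresholds for one pipeline run."""

    cohort_path: Path
    variants_path: Path
    msi_path: Path | None = None
    mif_path: Path | None = None
    survival_path: Path | None = None
    output_dir: Path
    wes_cutoff: float = Field(default=DEFAULT_WES_CUTOFF, gt=0.0)
    msi_cutoff: float = Field(default=0.4, gt=0.0, le=1.0)
    seed: int = 0

    def config_hash(self) -> str:
        # hash the analysis inputs and thresholds; where the report is written
        # must not change its identity
        fields = self.model_dump(mode="json")
        fields.pop("output_dir")
        payload = json.dumps({k: str(v) for k, v in fields.items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_msi_profiles(path: Path) -> dict[str, list[MicrosatelliteLocusProfile]]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "locus", "repeat_length", "read_count", "baseline_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MSI histogram table missing column(s): {sorted(missing)}")
    out: dict[str, list[MicrosatelliteLocusProfile]] = defaultdict(list)
    for (sid, locus), grp in df.groupby(["sample_id", "locus"], sort=True):
        hist = {
            int(l): int(c)
            for l, c in zip(grp["repeat_length"], grp["read_count"])
            if c > 0
        }
        baseline = {
            int(l): int(c)
            for l, c in zip(grp["repeat_length"], grp["baseline_count"])
            if c > 0
        }
        modal = max(baseline, key=baseline.get) if baseline else 1
        out[str(sid)].append(
            MicrosatelliteLocusProfile(
                locus_id=str(locus),
                reference_modal_length=modal,
                histogram=hist,
                baseline_histogram=baseline,
                coverage=sum(hist.values()),
            )
        )
    return dict(out)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; deterministic given inputs."""
    for name in ("cohort_path", "variants_path", "msi_path", "mif_path", "survival_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p}")
    out = Path(config.output_dir)
    chash = config.config_hash()
    written: dict[str, Path] = {}

    cohort = pd.read_csv(config.cohort_path, sep="\t")
    variants = read_variants(config.variants_path, format="maf-tsv")

    # --- stage: subtyping ---------------------------------------------------
    reporting = filter_variants(variants, FilterProfile.reporting())
    egfr_by_sample: dict[str, list] = defaultdict(list)
    for v in reporting:
        if v.gene == "EGFR":
            egfr_by_sample[v.sample_id].append(v)
    labels = {
        sid: classify_egfr(egfr_by_sample.get(sid, [])).label
        for sid in cohort["sample_id"]
    }
    label_list = [labels[sid] for sid in cohort["sample_id"]]
    for mode in ("all", "mutated_only"):
        try:
            table = tabulate_subtype_frequencies(label_list, denominator_mode=mode)
        except ValueError:
            continue
        path = out / "subtypes" / f"subtype_frequencies_{mode}.tsv"
        _write_tsv(table, path, chash)
        written[f"subtypes_{mode}"] = path

    # --- stage: TMB ----------------------------------------------------------
    wildtype_mask = pd.Series(label_list, index=cohort.index) == "wildtype"
    wes_ref = cohort.loc[wildtype_mask, "tmb_wes"].tolist()
    panel_ref = cohort.loc[wildtype_mask, "tmb_panel"].tolist()
    harm = harmonize_cutoff(wes_ref, config.wes_cutoff, panel_ref)
    if harm.warning:
        logger.warning("harmonization: %s", harm.warning)
    tmb_rows = []
    for _, row in cohort.iterrows():
        for assay, cutoff in (("wes", config.wes_cutoff), ("panel", harm.panel_cutoff)):
            res = classify_tmb(
                TMBResult(
                    sample_id=row["sample_id"],
                    value=float(row[f"tmb_{assay}"]),
                    n_counted=0,
                    assay=assay,
                ),
                cutoff,
            )
            tmb_rows.append(
                {
                    "sample_id": res.sample_id,
                    "assay": assay,
                    "subtype": labels[row["sample_id"]],
                    "tmb": res.value,
                    "class": res.classification,
                }
            )
    tmb_df = pd.DataFrame(tmb_rows)
    by_subtype = (
        tmb_df.groupby(["assay", "subtype"])
        .agg(
            n=("tmb", "size"),
            mean_tmb=("tmb", "mean"),
            tmb_high_fraction=("class", lambda s: (s == "TMB-High").mean()),
        )
        .reset_index()
    )
    path = out / "tmb" / "tmb_by_subtype.tsv"
    _write_tsv(by_subtype, path, chash)
    written["tmb_by_subtype"] = path
    path = out / "tmb" / "harmonization.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "wes_cutoff": config.wes_cutoff,
                "tmb_low_proportion": harm.p,
                "panel_cutoff": harm.panel_cutoff,
                "warning": harm.warning,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    written["harmonization"] = path

    # --- stage: MSI -----------------------------------------------------------
    if config.msi_path is not None:
        profiles = _read_msi_profiles(Path(config.msi_path))
        msi_rows = [
            {
                "sample_id": sid,
                "n_loci": r.n_loci_evaluated,
                "n_unstable": r.n_unstable,
                "msi_score": r.score,
                "class": r.classification,
            }
            for sid, loci in sorted(profiles.items())
            for r in [score_sample(loci, sample_id=sid)]
        ]
        path = out / "msi" / "msi_results.tsv"
        _write_tsv(pd.DataFrame(msi_rows), path, chash)
        written["msi"] = path

    # --- stage: TPS × subtype --------------------------------------------------
    if "tps_tier" in cohort.columns:
        cross = (
            pd.crosstab(
                pd.Series(label_list, name="subtype"),
                cohort["tps_tier"],
            )
            .reset_index()
        )
        path = out / "tps" / "tps_by_subtype.tsv"
        _write_tsv(cross, path, chash)
        written["tps_by_subtype"] = path

    # --- stage: TIME comparisons -------------------------------------------------
    if config.mif_path is not None:
        mif = pd.read_csv(config.mif_path, sep="\t")
        if "density" not in mif.columns:
            mif["density"] = mif["count"] / mif["area_mm2"]
        mif["egfr_group"] = mif["sample_id"].map(
            lambda sid: "mutated" if labels.get(sid, "wildtype") != "wildtype" else "wildtype"
        )
        rows = []
        for (cell_type, comp), grp in mif.groupby(["cell_type", "compartment"], sort=True):
            by_group = {
                g: sub["density"].tolist() for g, sub in grp.groupby("egfr_group")
            }
            if len(by_group) < 2 or any(len(v) < 2 for v in by_group.values()):
                continue
            res = compare_groups(by_group, method="auto")
            rows.append(
                {
                    "grouping": "egfr_mutated_vs_wildtype",
                    "cell_type": cell_type,
                    "compartment": comp,
                    "method": res.method_used,
                    "statistic": res.statistic,
                    "p": res.p_value,
                }
            )
        path = out / "time" / "density_comparisons.tsv"
        _write_tsv(pd.DataFrame(rows), path, chash)
        written["time_comparisons"] = path

    # --- stage: survival --------------------------------------------------------
    if config.survival_path is not None:
        surv = pd.read_csv(config.survival_path, sep="\t")
        strat_cols = [
            c for c in surv.columns if c not in ("sample_id", "time_months", "event")
        ]
        records = [
            SurvivalRecord(
                sample_id=row["sample_id"],
                time_months=float(row["time_months"]),
                event=bool(row["event"]),
                strata={c: str(row[c]) for c in strat_cols},
            )
            for _, row in surv.iterrows()
        ]
        surv_results = []
        for var in strat_cols:
            groups = defaultdict(list)
            for r in records:
                groups[r.strata[var]].append(r)
            if len(groups) != 2:
                continue
            (la, ga), (lb, gb) = sorted(groups.items())
            try:
                lr = logrank_test(ga, gb)
            except ValueError as exc:
                logger.warning("log-rank skipped for %s: %s", var, exc)
                continue
            indicator = {r.sample_id: float(r.strata[var] == lb) for r in records}
            try:
                cox = cox_univariate(records, indicator)
                hr, lo, hi = cox.hazard_ratio, cox.ci_low, cox.ci_high
            except (ValueError, RuntimeError) as exc:
                logger.warning("Cox skipped for %s: %s", var, exc)
                hr = lo = hi = float("nan")
            surv_results.append(
                {
                    "stratification": var,
                    "group_a": la,
                    "group_b": lb,
                    "logrank_chi2": lr.chi_square,
                    "logrank_p": lr.p_value,
                    "hr_b_vs_a": hr,
                    "hr_ci_low": lo,
                    "hr_ci_high": hi,
                }
            )
            for lab, grp in ((la, ga), (lb, gb)):
                curve = km_estimate(grp)
                path = out / "survival" / f"km_{var}_{lab}.tsv"
                _write_tsv(km_curve_frame(curve), path, chash)
                written[f"km_{var}_{lab}"] = path
        path = out / "survival" / "tests.tsv"
        _write_tsv(pd.DataFrame(surv_results), path, chash)
        written["survival_tests"] = path

    # --- provenance ---------------------------------------------------------------
    path = out / "provenance.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg_fields = config.model_dump(mode="json")
    cfg_fields.pop("output_dir")  # identity of the report, not its location
    with open(path, "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "config": {k: str(v) for k, v in cfg_fields.items()},
                "package_version": __version__,
                "outputs": {
                    k: str(Path(v).relative_to(out)) for k, v in sorted(written.items())
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    written["provenance"] = path
    return written
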