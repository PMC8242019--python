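"""End-to-end orchestration: simulate -> phenotype -> associate -> MR.

Runs the four analysis strata ({never, ever} smoking x {high, low} inferred
rice consumption, high-rice primary and low-rice as negative control), the
sensitivity suite, and emits auditable TSV/JSON reports with an exclusion
ledger and realized thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import DEFAULT_COVARIATES, association_scan
from .errors import ValidationError
from .instrument_catalog import InstrumentSet, ld_from_dosages, load_instruments
from .mr_estimator import mr_table
from .phenotyping import (
    MEDICATION_FACTOR,
    RICE_PERCENTILE,
    ReferenceModel,
    default_reference_model,
    phenotype_cohort,
)
from .synthetic_cohort import SimulationConfig, simulate_cohort, write_truth

ASTHMA_TRAITS = ("lifetime_asthma", "current_asthma", "past_asthma")
SPIRO_TRAITS = ("fev1_below_lln", "fvc_below_lln", "fev1_fvc_below_lln", "pef_below_lln")

STRATA_ORDER = (
    "never_smoker_high_rice",
    "ever_smoker_high_rice",
    "never_smoker_low_rice",
    "ever_smoker_low_rice",
)


@dataclass
class RunConfig:
    """Everything one analysis run depends on. No hidden defaults: the full
    effective config is echoed into the report."""

    out_dir: str
    seed: int = 0
    instruments_path: str | None = None
    cohort_path: str | None = None
    reference_model_path: str | None = None
    simulation: dict = field(default_factory=dict)
    rice_percentile: float = RICE_PERCENTILE
    broaden_asthma: bool = False
    continuous_outcomes: bool = False
    percent_predicted_outcomes: bool = False
    medication_mode: str = "scale"
    medication_factor: float = MEDICATION_FACTOR
    strict_quality: bool = False
    pc_variance_threshold: float = 0.99
    use_cluster_random_effects: bool = False
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class RunReport:
    config: dict
    exclusion_ledger: dict
    realized: dict
    n_cells: int
    n_ok_cells: int
    fingerprint: str
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _exclusion_masks(pheno: pd.DataFrame) -> tuple[pd.Series, pd.Series, dict]:
    """Analysis-arm inclusion masks plus the ordered exclusion ledger.

    Filter order: genotype availability -> smoking answered -> diet answered
    -> arm-specific (asthma answered | spirometry effort/quality/medication).
    """
    n_input = len(pheno)
    dosage_cols = [c for c in pheno.columns if c.startswith("dosage_")]
    has_geno = pheno[dosage_cols].notna().all(axis=1)
    base = has_geno.copy()
    ledger_common = [("input", n_input), ("missing genotype", int((~has_geno).sum()))]

    smoking_ok = pheno["smoking_class"] != "excluded"
    ledger_common.append(("smoking unanswered", int((base & ~smoking_ok).sum())))
    base &= smoking_ok

    diet_ok = pheno["rice_class"] != "excluded"
    ledger_common.append(("diet recall missing", int((base & ~diet_ok).sum())))
    base &= diet_ok

    asthma_ok = pheno["asthma_category"] != "missing"
    asthma_mask = base & asthma_ok
    spiro_mask = base & pheno["spirometry_included"]

    ledger = {
        "common": [{"filter": f, "removed": r} for f, r in ledger_common],
        "asthma_arm": {
            "after_common": int(base.sum()),
            "removed_asthma_unanswered": int((base & ~asthma_ok).sum()),
            "final_n": int(asthma_mask.sum()),
        },
        "spirometry_arm": {
            "after_common": int(base.sum()),
            "removed_quality_effort_medication": int((base & ~pheno["spirometry_included"]).sum()),
            "final_n": int(spiro_mask.sum()),
        },
        "input_n": n_input,
    }
    return asthma_mask, spiro_mask, ledger


def _trait_columns(pheno: pd.DataFrame, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Append analysis trait columns (NaN outside the relevant arm/cases)."""
    out = pheno.copy()
    cat = out["asthma_category"]
    none = cat == "none"

    lifetime = pd.Series(np.nan, index=out.index)
    lifetime[cat.isin(["past", "current"])] = 1.0
    lifetime[none] = 0.0
    current = pd.Series(np.nan, index=out.index)
    current[cat == "current"] = 1.0
    current[none] = 0.0
    past = pd.Series(np.nan, index=out.index)
    past[cat == "past"] = 1.0
    past[none] = 0.0
    out["lifetime_asthma"] = lifetime
    out["current_asthma"] = current
    out["past_asthma"] = past

    traits: dict[str, tuple[str, str]] = {t: (t, "binomial") for t in ASTHMA_TRAITS}
    if cfg.continuous_outcomes:
        for m in ("fev1", "fvc", "pef"):
            traits[f"{m}_continuous"] = (f"{m}_corrected", "gaussian")
    elif cfg.percent_predicted_outcomes:
        for m in ("fev1", "fvc", "pef"):
            traits[f"{m}_pct_predicted"] = (f"{m}_pct_predicted", "gaussian")
    else:
        for t in SPIRO_TRAITS:
            out[t] = out[t].astype(float)
            traits[t] = (t, "binomial")
    return out, traits


def run(config: RunConfig) -> RunReport:
    """Execute one full analysis and write all intermediates to ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)

    instruments: InstrumentSet = load_instruments(config.instruments_path)

    ref = (
        ReferenceModel.from_tsv(config.reference_model_path)
        if config.reference_model_path
        else default_reference_model()
    )

    if config.cohort_path:
        cohort = pd.read_csv(config.cohort_path, sep="\t")
        for c in ("asthma_ever", "asthma_doctor", "asthma_still", "asthma_med_use"):
            cohort[c] = cohort[c].astype("boolean")
        from .synthetic_cohort import build_cluster_matrices

        clusters = build_cluster_matrices(cohort) if config.use_cluster_random_effects else None
        truth = None
    else:
        sim_dict = dict(config.simulation)
        sim_dict.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig.from_dict(sim_dict)
        cohort, clusters, truth = simulate_cohort(
            sim_cfg,
            ref=ref,
            instruments=instruments,
            build_clusters=config.use_cluster_random_effects,
        )
        write_truth(truth, os.path.join(config.out_dir, "truth.json"))

    dosage_cols = [f"dosage_{v.rsid}" for v in instruments.variants]
    rho = ld_from_dosages(cohort[dosage_cols].to_numpy(), rsids=instruments.rsids)

    pheno, realized = phenotype_cohort(
        cohort,
        ref,
        broaden_asthma=config.broaden_asthma,
        medication_mode=config.medication_mode,
        medication_factor=config.medication_factor,
        strict_quality=config.strict_quality,
        rice_percentile=config.rice_percentile,
    )
    asthma_mask, spiro_mask, ledger = _exclusion_masks(pheno)
    pheno, traits = _trait_columns(pheno, config)

    # arm masks folded into the trait columns: NaN rows are dropped per trait
    for t in ASTHMA_TRAITS:
        pheno.loc[~asthma_mask, t] = np.nan
    for name, (col, _) in traits.items():
        if name not in ASTHMA_TRAITS:
            pheno.loc[~spiro_mask, col] = np.nan

    strata = {}
    for name in STRATA_ORDER:
        smoking = "never" if name.startswith("never") else "ever"
        rice = "high" if "high_rice" in name else "low"
        strata[name] = (
            (pheno["smoking_class"] == smoking) & (pheno["rice_class"] == rice)
        ).to_numpy()

    cluster_arg = clusters if config.use_cluster_random_effects else None
    assoc = association_scan(
        pheno,
        instruments,
        traits,
        strata=strata,
        cluster_matrices=cluster_arg,
        covariates=config.covariates,
    )
    estimates = mr_table(assoc, instruments, rho, config.pc_variance_threshold)
    gaussian_traits = [t for t, (_, fam) in traits.items() if fam == "gaussian"]
    if gaussian_traits:
        # continuous outcomes are reported on the trait's own scale, not as OR
        mask_g = estimates["trait"].isin(gaussian_traits)
        estimates.loc[mask_g, ["or", "ci_low", "ci_high"]] = np.nan

    pheno_path = os.path.join(config.out_dir, "phenotyped_cohort.tsv")
    assoc_path = os.path.join(config.out_dir, "associations.tsv")
    mr_path = os.path.join(config.out_dir, "mr_estimates.tsv")
    pheno.to_csv(pheno_path, sep="\t", index=False, float_format="%.10g")
    assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.10g")
    estimates.to_csv(mr_path, sep="\t", index=False, float_format="%.10g")

    digest = hashlib.sha256()
    for path in (assoc_path, mr_path):
        with open(path, "rb") as fh:
            digest.update(fh.read())

    realized["ld_matrix"] = np.round(rho.r, 10).tolist()
    realized["n_tests_per_stratum"] = int(len(traits) * len(instruments) )
    report = RunReport(
        config=config.to_dict(),
        exclusion_ledger=ledger,
        realized=realized,
        n_cells=len(estimates),
        n_ok_cells=int((estimates["status"] == "ok").sum()),
        fingerprint=digest.hexdigest(),
    )
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


SENSITIVITY_TOGGLES: dict[str, dict] = {
    "broadened_asthma": {"broaden_asthma": True},
    "continuous_outcomes": {"continuous_outcomes": True},
    "percent_predicted": {"percent_predicted_outcomes": True},
    "medication_covariate": {"medication_mode": "covariate"},
    "medication_excluded": {"medication_mode": "exclude"},
    "strict_quality": {"strict_quality": True},
}


def sensitivity_suite(config: RunConfig) -> dict[str, RunReport]:
    """Baseline run plus one rerun per sensitivity toggle."""
    reports = {"baseline": run(config)}
    for name, overrides in SENSITIVITY_TOGGLES.items():
        sub = dataclasses.replace(
            config, out_dir=os.path.join(config.out_dir, "sensitivity", name), **overrides
        )
        if sub.medication_mode == "covariate":
            sub = dataclasses.replace(sub, covariates=tuple(config.covariates) + ("med_use_covariate",))
        reports[name] = run(sub)
    return reports


def exclusion_ledger(pheno: pd.DataFrame) -> dict:
    """Standalone ordered exclusion count table for a phenotyped cohort."""
    return _exclusion_masks(pheno)[2]
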