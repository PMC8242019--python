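"""Synthetic cohort generator.

Produces participant-level tables with the statistical structure the analysis
assumes: three instrument SNVs with configurable LD, metabolite percentages
closing to 100, household/sibship/block-group clustering, smoking and
rice-consumption strata, spirometry tied to a reference model, and binary
pulmonary outcomes whose log-odds depend on %iAs only in the high-rice
stratum (the low-rice stratum is a negative control by construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import FeasibilityError, ValidationError
from .instrument_catalog import InstrumentSet, METABOLITES, load_instruments
from .phenotyping import (
    ANCESTRY_GROUPS,
    LLN_QUANTILE,
    MEDICATION_FACTOR,
    ReferenceModel,
    default_reference_model,
    stratum_key,
)
from scipy.stats import norm

#: Binary traits with a directly controlled generative log-odds model.
CONTROLLED_TRAITS: tuple[str, ...] = ("asthma", "fvc", "fev1_fvc", "pef")

_Z_LLN = float(norm.ppf(LLN_QUANTILE))  # ~ -1.6449


def dprime_r2(maf_a: float, maf_b: float, dprime: float) -> float:
    """r-squared implied by MAFs and a (positive) D' under random mating."""
    d = dprime * min(maf_a * (1 - maf_b), (1 - maf_a) * maf_b)
    return d * d / (maf_a * (1 - maf_a) * maf_b * (1 - maf_b))


def partner_maf_for_ld(maf_a: float, dprime: float, r2: float) -> float:
    """Partner allele frequency q < p making (D', r^2) jointly attainable.

    Solves on the branch where Dmax = (1-p) q, i.e. the partner allele is the
    rarer of the two; raises if the pair of targets is infeasible.
    """
    p = maf_a
    c = dprime**2 * (1 - p) / p
    if c <= 0:
        raise FeasibilityError("maf_a and dprime must be positive")
    ratio = r2 / c
    q = ratio / (1 + ratio)
    if not 0 < q < 1 or (1 - p) * q > p * (1 - q):
        raise FeasibilityError(
            f"no partner MAF below {maf_a} attains D'={dprime} with r2={r2}"
        )
    realized = dprime_r2(p, q, dprime)
    if abs(realized - r2) > 1e-9:
        raise FeasibilityError("LD target solve failed")
    return q


#: Default allele frequencies. Not published for the source populations; the
#: chr10 pair is chosen so that D' = 0.87 yields r^2 = 0.28 exactly, the
#: chr21 variant frequency is arbitrary. All overridable.
DEFAULT_MAF: tuple[float, float, float] = (0.45, partner_maf_for_ld(0.45, 0.87, 0.28), 0.12)

DEFAULT_THETA = {t: 0.0 for t in CONTROLLED_TRAITS}
DEFAULT_BASELINE = {
    "asthma": float(np.log(0.15 / 0.85)),
    "fvc": float(np.log(0.05 / 0.95)),
    "fev1_fvc": float(np.log(0.05 / 0.95)),
    "pef": float(np.log(0.05 / 0.95)),
}


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort."""

    n_participants: int = 2000
    maf: tuple[float, float, float] = DEFAULT_MAF
    target_dprime: float = 0.87
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    baseline_logodds: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    frac_high_rice: float = 0.2
    frac_ever_smoker: float = 0.4
    household_size_range: tuple[int, int] = (1, 4)
    sibling_pair_fraction: float = 0.1
    variance_components: dict = field(
        default_factory=lambda: {"household": 0.0, "block_group": 0.0, "polygenic": 0.0}
    )
    seed: int = 0

    # metabolite model; intercepts give adult urinary profiles, noise is the
    # unexplained within-person variation. The iAs/MMA noise correlation is
    # not published; 0.3 is a placeholder.
    metabolite_intercepts: tuple[float, float] = (9.0, 12.0)  # iAs, MMA
    metabolite_noise_sd: tuple[float, float] = (3.0, 3.0)
    metabolite_noise_corr: float = 0.3
    effects_are_marginal: bool = True  # treat instrument betas as marginal GWAS effects

    # questionnaire nuisance parameters
    doctor_diagnosis_prob: float = 0.94
    asthma_missing_rate: float = 0.02
    still_asthma_prob: float = 0.45
    med_use_prob_still: float = 0.65
    med_use_prob_past: float = 0.08
    n_smoking_nonresponse: int = 0
    n_diet_nonresponse: int = 0

    max_simplex_resample: int = 100

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not 0 <= self.target_dprime <= 1:
            raise FeasibilityError(f"D' must be in [0, 1], got {self.target_dprime}")
        for name in ("frac_high_rice", "frac_ever_smoker", "sibling_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for m in self.maf:
            if not 0 < m < 1:
                raise ValidationError(f"allele frequencies must be in (0, 1), got {m}")
        lo, hi = self.household_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("household_size_range must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf"] = list(self.maf)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf", "household_size_range", "metabolite_intercepts", "metabolite_noise_sd"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ClusterMatrices:
    """Dense covariance kernels for the random effects (unit self-relatedness)."""

    kinship: np.ndarray
    household: np.ndarray
    block_group: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "kinship": self.kinship,
            "household": self.household,
            "block_group": self.block_group,
        }


@dataclass
class HaplotypeSample:
    """Two-locus haplotypes sampled under a target D'."""

    haplotypes: np.ndarray  # (n_hap, 2) 0/1 alleles
    frequencies: dict[str, float]
    counts: dict[str, int]

    def realized_d(self) -> float:
        h = self.haplotypes
        pa = h[:, 0].mean()
        pb = h[:, 1].mean()
        pab = float((h[:, 0] * h[:, 1]).mean())
        return pab - pa * pb

    def realized_dprime(self) -> float:
        h = self.haplotypes
        pa, pb = h[:, 0].mean(), h[:, 1].mean()
        d = self.realized_d()
        if d >= 0:
            dmax = min(pa * (1 - pb), (1 - pa) * pb)
        else:
            dmax = min(pa * pb, (1 - pa) * (1 - pb))
        return float(d / dmax) if dmax > 0 else 0.0

    def realized_r2(self) -> float:
        h = self.haplotypes
        pa, pb = h[:, 0].mean(), h[:, 1].mean()
        denom = pa * (1 - pa) * pb * (1 - pb)
        return float(self.realized_d() ** 2 / denom) if denom > 0 else 0.0


def simulate_haplotypes(
    maf_a: float,
    maf_b: float,
    target_dprime: float,
    n_hap: int,
    rng: np.random.Generator | int | None = None,
) -> HaplotypeSample:
    """Sample two-locus haplotypes whose expected D' equals the target.

    The four haplotype frequencies solve D = D' * Dmax for the given allele
    margins; haplotypes are then drawn multinomially.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for m in (maf_a, maf_b):
        if not 0 < m < 1:
            raise FeasibilityError(f"allele frequency must be in (0, 1), got {m}")
    if not 0 <= target_dprime <= 1:
        raise FeasibilityError(
            f"target D' must be in [0, 1], got {target_dprime}; "
            "negative association is expressed by recoding an allele"
        )
    dmax = min(maf_a * (1 - maf_b), (1 - maf_a) * maf_b)
    d = target_dprime * dmax
    freqs = {
        "AB": maf_a * maf_b + d,
        "Ab": maf_a * (1 - maf_b) - d,
        "aB": (1 - maf_a) * maf_b - d,
        "ab": (1 - maf_a) * (1 - maf_b) + d,
    }
    if min(freqs.values()) < -1e-12:
        raise FeasibilityError(
            f"haplotype frequencies negative for D'={target_dprime} at "
            f"MAFs ({maf_a}, {maf_b}); admissible D' range is [0, 1]"
        )
    probs = np.clip([freqs["AB"], freqs["Ab"], freqs["aB"], freqs["ab"]], 0, None)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_hap, probs)
    alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    haplotypes = np.repeat(alleles, counts, axis=0)
    rng.shuffle(haplotypes, axis=0)
    return HaplotypeSample(
        haplotypes=haplotypes,
        frequencies={k: float(v) for k, v in freqs.items()},
        counts={k: int(c) for k, c in zip(("AB", "Ab", "aB", "ab"), counts)},
    )


def dosage_covariance(maf: Sequence[float], target_dprime: float) -> np.ndarray:
    """Covariance of the three dosages under HWE (chr10 pair linked, chr21 free)."""
    maf = list(maf)
    cov = np.zeros((3, 3))
    for i, m in enumerate(maf):
        cov[i, i] = 2 * m * (1 - m)
    dmax = min(maf[0] * (1 - maf[1]), (1 - maf[0]) * maf[1])
    cov[0, 1] = cov[1, 0] = 2 * target_dprime * dmax
    return cov


def marginal_to_direct(
    marginal: np.ndarray, maf: Sequence[float], target_dprime: float
) -> np.ndarray:
    """Direct (joint) per-allele effects whose marginal regressions equal ``marginal``.

    GWAS effect sizes are marginal single-variant slopes; with correlated
    variants the generative model must use joint effects b = C^-1 D m where C
    is the dosage covariance and D its diagonal, so that single-variant
    regressions recover the published values.
    """
    cov = dosage_covariance(maf, target_dprime)
    return np.linalg.solve(cov, np.diag(np.diag(cov)) @ np.asarray(marginal, dtype=float))


def _assign_clusters(n: int, cfg: SimulationConfig, rng: np.random.Generator):
    """Household/sibling/block-group labels.

    Sibling pairs occupy two-person households; everyone else fills households
    of random size; households are chunked into block groups.
    """
    n_pairs = int(round(cfg.sibling_pair_fraction * n / 2))
    n_pairs = min(n_pairs, n // 2)
    household_id = np.empty(n, dtype=np.int64)
    sibling_of = np.full(n, -1, dtype=np.int64)
    idx = 0
    house = 0
    for _ in range(n_pairs):
        household_id[idx] = household_id[idx + 1] = house
        sibling_of[idx + 1] = idx
        idx += 2
        house += 1
    lo, hi = cfg.household_size_range
    while idx < n:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n - idx)
        household_id[idx : idx + size] = house
        idx += size
        house += 1
    n_house = house
    houses_per_block = 8
    block_of_house = np.arange(n_house) // houses_per_block
    block_group_id = block_of_house[household_id]
    # shuffle participant order so cluster structure is not index-sorted
    perm = rng.permutation(n)
    return household_id[perm], block_group_id[perm], _remap_siblings(sibling_of, perm)


def _remap_siblings(sibling_of: np.ndarray, perm: np.ndarray) -> np.ndarray:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    out = np.full(len(perm), -1, dtype=np.int64)
    for new_pos, old_pos in enumerate(perm):
        old_sib = sibling_of[old_pos]
        if old_sib >= 0:
            out[new_pos] = inv[old_sib]
    return out


def _cluster_effect(labels: np.ndarray, var: float, rng: np.random.Generator) -> np.ndarray:
    if var <= 0:
        return np.zeros(len(labels))
    uniq, inverse = np.unique(labels, return_inverse=True)
    draws = rng.normal(0.0, np.sqrt(var), size=len(uniq))
    return draws[inverse]


def _polygenic_effect(sibling_of: np.ndarray, var: float, rng: np.random.Generator) -> np.ndarray:
    if var <= 0:
        return np.zeros(len(sibling_of))
    n = len(sibling_of)
    z = rng.normal(size=n)
    out = z.copy()
    for i in range(n):
        j = sibling_of[i]
        if j >= 0:  # cor(z_i, z_j) = 0.5 for declared siblings
            out[i] = np.sqrt(0.5) * z[j] + np.sqrt(0.5) * z[i]
    return np.sqrt(var) * out


def _truncated_z(below: np.ndarray, rng: np.random.Generator, upper_clip: np.ndarray) -> np.ndarray:
    """Reference z-scores: below the LLN z-cut for cases, above it otherwise."""
    n = len(below)
    z = np.empty(n)
    n_case = int(below.sum())
    if n_case:
        z[below] = truncnorm.rvs(-3.0, _Z_LLN, size=n_case, random_state=rng)
    n_ctrl = n - n_case
    if n_ctrl:
        u = rng.uniform(size=n_ctrl)
        hi = np.minimum(upper_clip[~below], 4.0)
        lo = _Z_LLN
        cdf_lo, cdf_hi = norm.cdf(lo), norm.cdf(hi)
        z[~below] = norm.ppf(cdf_lo + u * (cdf_hi - cdf_lo))
    return z


def simulate_cohort(
    config: SimulationConfig,
    ref: ReferenceModel | None = None,
    instruments: InstrumentSet | None = None,
    build_clusters: bool = True,
) -> tuple[pd.DataFrame, ClusterMatrices | None, dict]:
    """Generate a cohort table, its cluster kernels, and the generative truth.

    See the module docstring for the generative structure. ``theta`` applies
    per percentage point of %iAs (centered) and only to participants in the
    high-rice stratum.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if ref is None:
        ref = default_reference_model()
    if instruments is None:
        instruments = load_instruments()

    # --- genotypes -------------------------------------------------------
    hap = simulate_haplotypes(config.maf[0], config.maf[1], config.target_dprime, 2 * n, rng)
    h = hap.haplotypes
    dosage = np.empty((n, 3), dtype=float)
    dosage[:, 0] = h[0::2, 0] + h[1::2, 0]
    dosage[:, 1] = h[0::2, 1] + h[1::2, 1]
    dosage[:, 2] = rng.binomial(2, config.maf[2], size=n)

    # --- metabolites -----------------------------------------------------
    marg_iAs = instruments.beta_vector("iAs")
    marg_MMA = instruments.beta_vector("MMA")
    if config.effects_are_marginal:
        b_iAs = marginal_to_direct(marg_iAs, config.maf, config.target_dprime)
        b_MMA = marginal_to_direct(marg_MMA, config.maf, config.target_dprime)
    else:
        b_iAs, b_MMA = marg_iAs.copy(), marg_MMA.copy()

    sd_i, sd_m = config.metabolite_noise_sd
    rho = config.metabolite_noise_corr
    noise_cov = np.array([[sd_i**2, rho * sd_i * sd_m], [rho * sd_i * sd_m, sd_m**2]])
    gen_iAs = config.metabolite_intercepts[0] + dosage @ b_iAs
    gen_MMA = config.metabolite_intercepts[1] + dosage @ b_MMA

    noise = rng.multivariate_normal([0.0, 0.0], noise_cov, size=n, method="cholesky")
    pct_iAs = gen_iAs + noise[:, 0]
    pct_MMA = gen_MMA + noise[:, 1]
    for attempt in range(config.max_simplex_resample + 1):
        pct_DMA = 100.0 - pct_iAs - pct_MMA
        bad = (pct_iAs < 0) | (pct_MMA < 0) | (pct_DMA < 0) | (pct_iAs > 100) | (pct_MMA > 100)
        if not bad.any():
            break
        if attempt == config.max_simplex_resample:
            raise FeasibilityError(
                "metabolite simplex resampling exhausted; metabolite noise too large"
            )
        redraw = rng.multivariate_normal(
            [0.0, 0.0], noise_cov, size=int(bad.sum()), method="cholesky"
        )
        pct_iAs[bad] = gen_iAs[bad] + redraw[:, 0]
        pct_MMA[bad] = gen_MMA[bad] + redraw[:, 1]
    pct_DMA = 100.0 - pct_iAs - pct_MMA
    # nudge DMA by the float residual so pct_iAs + pct_MMA + pct_DMA sums to
    # 100.0 exactly under left-to-right addition
    for _ in range(4):
        resid = 100.0 - (pct_iAs + pct_MMA + pct_DMA)
        if not np.any(resid):
            break
        pct_DMA = pct_DMA + resid

    # --- clustering ------------------------------------------------------
    household_id, block_group_id, sibling_of = _assign_clusters(n, config, rng)

    # --- demographics / covariates --------------------------------------
    ancestry = rng.choice(ANCESTRY_GROUPS, size=n, p=[0.30, 0.11, 0.09, 0.17, 0.2, 0.13])
    pcs = rng.normal(size=(n, 5))
    pcs[:, 0] += pd.Categorical(ancestry, categories=ANCESTRY_GROUPS).codes * 0.5
    sampling_weight = np.exp(rng.normal(0.0, 0.4, size=n))
    sex = np.where(rng.uniform(size=n) < 0.5, "M", "F")
    age = rng.uniform(18.0, 74.0, size=n)
    height = rng.normal(167.0, 8.0, size=n) + np.where(sex == "M", 6.0, 0.0)
    height = np.clip(height, 146.0, 199.0)

    # --- exposure strata -------------------------------------------------
    grain = np.exp(rng.normal(0.6, 0.7, size=n))
    if config.frac_high_rice >= 1.0:
        high_rice = np.ones(n, dtype=bool)
    elif config.frac_high_rice <= 0.0:
        high_rice = np.zeros(n, dtype=bool)
    else:
        cut = np.quantile(grain, 1.0 - config.frac_high_rice)
        high_rice = grain > cut

    ever_smoker = rng.uniform(size=n) < config.frac_ever_smoker
    current = ever_smoker & (rng.uniform(size=n) < 0.55)
    smoking = np.where(current, "current", np.where(ever_smoker, "former", "never"))
    cigarettes = np.where(
        ever_smoker,
        100 + rng.integers(0, 200000, size=n),
        rng.integers(0, 100, size=n),
    ).astype(float)
    smoking_answered = np.ones(n, dtype=bool)
    if config.n_smoking_nonresponse:
        drop = rng.choice(n, size=min(config.n_smoking_nonresponse, n), replace=False)
        smoking_answered[drop] = False
    if config.n_diet_nonresponse:
        drop = rng.choice(n, size=min(config.n_diet_nonresponse, n), replace=False)
        grain[drop] = np.nan

    # --- binary trait indicators ----------------------------------------
    centered_iAs = pct_iAs - pct_iAs.mean()
    vc = config.variance_components
    indicators: dict[str, np.ndarray] = {}
    for trait in CONTROLLED_TRAITS:
        eta = np.full(n, config.baseline_logodds[trait])
        eta = eta + config.theta.get(trait, 0.0) * centered_iAs * high_rice
        eta += _cluster_effect(household_id, vc.get("household", 0.0), rng)
        eta += _cluster_effect(block_group_id, vc.get("block_group", 0.0), rng)
        eta += _polygenic_effect(sibling_of, vc.get("polygenic", 0.0), rng)
        indicators[trait] = rng.uniform(size=n) < expit(eta)

    # --- asthma questionnaire -------------------------------------------
    affected = indicators["asthma"]
    ever_asthma = pd.array(affected, dtype="boolean")
    doctor = pd.array(
        affected & (rng.uniform(size=n) < config.doctor_diagnosis_prob), dtype="boolean"
    )
    still = pd.array(affected & (rng.uniform(size=n) < config.still_asthma_prob), dtype="boolean")
    med_p = np.where(np.asarray(still, dtype=bool), config.med_use_prob_still, config.med_use_prob_past)
    med_use = pd.array(affected & (rng.uniform(size=n) < med_p), dtype="boolean")
    if config.asthma_missing_rate > 0:
        miss = rng.uniform(size=n) < config.asthma_missing_rate
        ever_asthma[miss] = pd.NA

    # --- spirometry ------------------------------------------------------
    strata = [stratum_key(e, s, a, hgt) for e, s, a, hgt in zip(ancestry, sex, age, height)]
    loc, scale = {}, {}
    for m in ("fvc", "fev1_fvc", "pef"):
        loc[m], scale[m] = ref.lookup(strata, m)

    fvc_true = loc["fvc"] + scale["fvc"] * _truncated_z(
        indicators["fvc"], rng, np.full(n, 4.0)
    )
    ratio_cap = (0.995 - loc["fev1_fvc"]) / scale["fev1_fvc"]
    ratio_true = loc["fev1_fvc"] + scale["fev1_fvc"] * _truncated_z(
        indicators["fev1_fvc"], rng, ratio_cap
    )
    pef_true = loc["pef"] + scale["pef"] * _truncated_z(indicators["pef"], rng, np.full(n, 4.0))
    fev1_true = ratio_true * fvc_true

    med_bool = np.asarray(med_use.fillna(False), dtype=bool)
    inflate = np.where(med_bool, 1.0 / MEDICATION_FACTOR, 1.0)
    fev1_obs = fev1_true * inflate  # medicated participants blow better than truth
    fvc_obs = fvc_true * inflate

    effort_maximal = rng.uniform(size=n) < 0.95
    fvc_quality = rng.choice(list("ABCDF"), size=n, p=[0.5, 0.3, 0.13, 0.05, 0.02])

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "dosage_rs9527": dosage[:, 0],
            "dosage_rs11191527": dosage[:, 1],
            "dosage_rs61735836": dosage[:, 2],
            "ancestry_group": ancestry,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
            "pc4": pcs[:, 3],
            "pc5": pcs[:, 4],
            "sampling_weight": sampling_weight,
            "household_id": household_id,
            "block_group_id": block_group_id,
            "sibling_of": sibling_of,
            "smoking": smoking,
            "smoking_answered": smoking_answered,
            "cigarettes_lifetime": cigarettes,
            "grain_servings": grain,
            "pct_iAs": pct_iAs,
            "pct_MMA": pct_MMA,
            "pct_DMA": pct_DMA,
            "asthma_ever": ever_asthma,
            "asthma_doctor": doctor,
            "asthma_still": still,
            "asthma_med_use": med_use,
            "fev1_ml": fev1_obs,
            "fvc_ml": fvc_obs,
            "pef_ml_s": pef_true,
            "fvc_quality": fvc_quality,
            "effort_maximal": effort_maximal,
            "age_years": age,
            "height_cm": height,
            "sex": sex,
            "ethnic_background": ancestry,
        }
    )

    clusters = build_cluster_matrices(cohort) if build_clusters else None

    truth = {
        "config": config.to_dict(),
        "direct_beta_iAs": [float(x) for x in b_iAs],
        "direct_beta_MMA": [float(x) for x in b_MMA],
        "marginal_beta_iAs": [float(x) for x in marg_iAs],
        "marginal_beta_MMA": [float(x) for x in marg_MMA],
        "haplotype_frequencies": hap.frequencies,
        "realized_dprime": hap.realized_dprime(),
        "realized_r2": hap.realized_r2(),
        "mean_pct_iAs": float(pct_iAs.mean()),
        "n_high_rice": int(high_rice.sum()),
        "trait_prevalence": {t: float(indicators[t].mean()) for t in CONTROLLED_TRAITS},
    }
    return cohort, clusters, truth


def build_cluster_matrices(cohort: pd.DataFrame) -> ClusterMatrices:
    """Dense kernels from cluster labels.

    Household/block-group entries are 1 for same-label pairs; kinship has a
    unit diagonal and 0.5 for declared sibling pairs (GRM-style scaling so
    that variance components read as variances).
    """
    n = len(cohort)
    house = cohort["household_id"].to_numpy()
    block = cohort["block_group_id"].to_numpy()
    household = (house[:, None] == house[None, :]).astype(float)
    block_group = (block[:, None] == block[None, :]).astype(float)
    kinship = np.eye(n)
    sib = cohort["sibling_of"].to_numpy()
    positions = {pid: i for i, pid in enumerate(cohort["id"].to_numpy())}
    ids = cohort["id"].to_numpy()
    for i in range(n):
        s = sib[i]
        if s is None or (isinstance(s, float) and np.isnan(s)) or s < 0:
            continue
        if s not in positions and int(s) not in positions:
            raise ValidationError(f"sibling_of for id {ids[i]} references unknown id {s}")
        j = positions.get(s, positions.get(int(s)))
        kinship[i, j] = kinship[j, i] = 0.5
    return ClusterMatrices(kinship=kinship, household=household, block_group=block_group)


def write_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_cluster_triplets(clusters: ClusterMatrices, path: str) -> None:
    """Sparse (matrix, i, j, value) TSV of all nonzero kernel entries, i <= j."""
    with open(path, "w") as fh:
        fh.write("matrix\ti\tj\tvalue\n")
        for name, mat in clusters.as_dict().items():
            ii, jj = np.nonzero(np.triu(mat))
            for i, j in zip(ii, jj):
                fh.write(f"{name}\t{i}\t{j}\t{mat[i, j]:g}\n")


def write_vcf(cohort: pd.DataFrame, instruments: InstrumentSet, path: str) -> None:
    """Minimal uncompressed VCF of the instrument variants with DS dosages.

    The counted (ALT) allele is the instrument's effect allele, matching the
    cohort dosage columns.
    """
    ids = [str(i) for i in cohort["id"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for v in instruments.variants:
            ds = cohort[f"dosage_{v.rsid}"].to_numpy()
            fields = [v.chrom, str(v.pos), v.rsid, v.ref_allele, v.effect_allele, ".", "PASS", ".", "DS"]
            fh.write("\t".join(fields) + "\t" + "\t".join(f"{d:g}" for d in ds) + "\n")


def dosages_from_vcf(path: str, rsids: Sequence[str]) -> pd.DataFrame:
    """Read effect-allele dosages for the given rsids from a minimal VCF.

    Accepts DS directly or sums GT allele codes; returns one ``dosage_<rsid>``
    column per requested variant.
    """
    wanted = set(rsids)
    found: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.rstrip("\n").split("\t")
            rsid = parts[2]
            if rsid not in wanted:
                continue
            fmt = parts[8].split(":")
            samples = parts[9:]
            if "DS" in fmt:
                k = fmt.index("DS")
                vals = np.array([float(s.split(":")[k]) for s in samples])
            elif "GT" in fmt:
                k = fmt.index("GT")
                vals = np.array(
                    [
                        sum(int(a) for a in s.split(":")[k].replace("|", "/").split("/"))
                        for s in samples
                    ],
                    dtype=float,
                )
            else:
                raise ValidationError(f"{rsid}: VCF record carries neither DS nor GT")
            found[rsid] = vals
    missing = wanted - set(found)
    if missing:
        raise ValidationError(f"variant(s) absent from VCF: {', '.join(sorted(missing))}")
    return pd.DataFrame({f"dosage_{r}": found[r] for r in rsids})
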