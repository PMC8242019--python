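"""Participant classification rules.

Smoking strata, asthma categories, the anti-asthmatic medication correction,
spirometry quality filtering, lower-limit-of-normal (LLN) thresholds,
percent-predicted transforms, and rice-exposure classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateInputError, StratumLookupError, ValidationError

MEASURES: tuple[str, ...] = ("fev1", "fvc", "fev1_fvc", "pef")

#: Default multiplicative correction applied to FEV1/FVC of participants on
#: anti-asthmatic medication, estimating their unmedicated values. Literature
#: derived (attenuated for imperfect adherence); overridable in configs.
MEDICATION_FACTOR: float = 0.88

#: Default percentile cutoff separating high from low inferred rice consumers.
RICE_PERCENTILE: float = 80.0

LLN_QUANTILE: float = 0.05

AGE_BANDS: tuple[tuple[float, float], ...] = ((18, 40), (40, 60), (60, 200))
HEIGHT_BANDS: tuple[tuple[float, float], ...] = ((0, 160), (160, 175), (175, 300))

ANCESTRY_GROUPS: tuple[str, ...] = (
    "Mexican",
    "Central American",
    "Dominican",
    "Puerto Rican",
    "Cuban",
    "South American",
)


def _band_label(value: float, bands: tuple[tuple[float, float], ...]) -> str:
    for lo, hi in bands:
        if lo <= value < hi:
            return f"{lo:g}-{hi:g}"
    raise StratumLookupError(f"value {value} falls outside all bands {bands}")


def stratum_key(ethnic_background: str, sex: str, age_years: float, height_cm: float) -> str:
    """Reference-cell key for one participant (ethnicity x sex x age x height band)."""
    return "|".join(
        [
            str(ethnic_background),
            str(sex),
            _band_label(float(age_years), AGE_BANDS),
            _band_label(float(height_cm), HEIGHT_BANDS),
        ]
    )


@dataclass
class ReferenceModel:
    """Normal reference distributions of spirometry measures in healthy adults.

    One (location, scale) pair per stratum cell and measure; the LLN is the
    5th percentile of the cell's distribution. Stored as a DataFrame indexed
    by ``stratum`` with columns ``{measure}_loc`` / ``{measure}_scale``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        needed = [f"{m}_{k}" for m in MEASURES for k in ("loc", "scale")]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise ValidationError(f"reference model missing column(s): {', '.join(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("reference model has duplicate stratum keys")
        for m in MEASURES:
            if (self.table[f"{m}_scale"] <= 0).any():
                raise ValidationError(f"non-positive scale for measure {m}")

    def cell(self, stratum: str, measure: str) -> tuple[float, float]:
        if measure not in MEASURES:
            raise ValidationError(f"unknown measure {measure!r}")
        try:
            row = self.table.loc[stratum]
        except KeyError as exc:
            raise StratumLookupError(f"no reference cell for stratum {stratum!r}") from exc
        return float(row[f"{measure}_loc"]), float(row[f"{measure}_scale"])

    def lookup(self, strata: Sequence[str], measure: str) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (location, scale) lookup for a sequence of stratum keys."""
        if measure not in MEASURES:
            raise ValidationError(f"unknown measure {measure!r}")
        sub = self.table[[f"{measure}_loc", f"{measure}_scale"]].reindex(strata)
        if sub[f"{measure}_loc"].isna().any():
            bad = sorted({s for s, miss in zip(strata, sub[f"{measure}_loc"].isna()) if miss})
            raise StratumLookupError(f"no reference cell for stratum key(s): {bad[:3]}")
        return (
            sub[f"{measure}_loc"].to_numpy(dtype=float),
            sub[f"{measure}_scale"].to_numpy(dtype=float),
        )

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceModel":
        table = pd.read_csv(path, sep="\t", index_col="stratum")
        return cls(table=table)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="stratum")


def default_reference_model() -> ReferenceModel:
    """Parametric reference distributions spanning every simulator stratum.

    Locations follow simple additive sex/age/height trends with plausible
    adult magnitudes (mL, mL/s, ratio); they stand in for published reference
    equations, which are out of scope.
    """
    rows = {}
    for eth in ANCESTRY_GROUPS:
        for sex in ("F", "M"):
            for alo, ahi in AGE_BANDS:
                for hlo, hhi in HEIGHT_BANDS:
                    age_mid = min((alo + ahi) / 2.0, 70.0)
                    height_mid = min(max((hlo + hhi) / 2.0, 150.0), 185.0)
                    sex_add = 700.0 if sex == "M" else 0.0
                    fvc_loc = 2300.0 + sex_add + 28.0 * (height_mid - 165.0) - 22.0 * (age_mid - 45.0)
                    ratio_loc = 0.84 - 0.0012 * (age_mid - 45.0)
                    fev1_loc = ratio_loc * fvc_loc
                    pef_loc = 6500.0 + 1200.0 * (sex == "M") + 40.0 * (height_mid - 165.0) - 30.0 * (age_mid - 45.0)
                    key = "|".join(
                        [eth, sex, f"{alo:g}-{ahi:g}", f"{hlo:g}-{hhi:g}"]
                    )
                    # scales proportional to location keep simulated volumes
                    # positive even in the smallest reference cells
                    fvc_scale = 0.13 * fvc_loc
                    ratio_scale = 0.055
                    # delta-method scale for the product fev1 = ratio * fvc
                    fev1_scale = fev1_loc * np.sqrt(
                        (fvc_scale / fvc_loc) ** 2 + (ratio_scale / ratio_loc) ** 2
                    )
                    rows[key] = {
                        "fvc_loc": fvc_loc,
                        "fvc_scale": fvc_scale,
                        "fev1_loc": fev1_loc,
                        "fev1_scale": fev1_scale,
                        "fev1_fvc_loc": ratio_loc,
                        "fev1_fvc_scale": ratio_scale,
                        "pef_loc": pef_loc,
                        "pef_scale": 0.18 * pef_loc,
                    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "stratum"
    return ReferenceModel(table=table)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_smoking(cigarettes_lifetime, current_smoker, answered) -> np.ndarray | str:
    """Never/ever smoking class; non-responders are excluded.

    Never-smoking means fewer than 100 lifetime cigarettes; former smokers
    are grouped with ever smokers.
    """
    cigs = np.atleast_1d(np.asarray(cigarettes_lifetime, dtype=float))
    ans = np.atleast_1d(np.asarray(answered, dtype=bool))
    if np.any(cigs[ans] < 0):
        raise ValidationError("negative lifetime cigarette count")
    out = np.where(~ans, "excluded", np.where(cigs < 100, "never", "ever"))
    if np.isscalar(cigarettes_lifetime) or np.ndim(cigarettes_lifetime) == 0:
        return str(out[0])
    return out


def classify_asthma(ever, doctor, still, med_use_last_year, broaden: bool = False):
    """Asthma category: none / past / current / missing.

    Lifetime asthma requires an affirmative history plus doctor diagnosis
    (history alone under ``broaden``, the sensitivity definition). Lifetime
    cases are current if still asthmatic or on anti-asthmatic medication in
    the past year, past otherwise. Missing answers propagate to ``missing``.
    """
    scalar = np.isscalar(ever) or ever is None or np.ndim(ever) == 0
    ever = pd.array(np.atleast_1d(ever), dtype="boolean")
    doctor = pd.array(np.atleast_1d(doctor), dtype="boolean")
    still = pd.array(np.atleast_1d(still), dtype="boolean")
    med = pd.array(np.atleast_1d(med_use_last_year), dtype="boolean")

    n = len(ever)
    out = np.full(n, "missing", dtype=object)
    ever_known = ~ever.isna()
    out[ever_known & (ever == False)] = "none"  # noqa: E712

    if broaden:
        lifetime = ever_known & (ever == True)  # noqa: E712
    else:
        lifetime = ever_known & (ever == True) & ~doctor.isna() & (doctor == True)  # noqa: E712
        not_lifetime = ever_known & (ever == True) & ~doctor.isna() & (doctor == False)  # noqa: E712
        out[not_lifetime] = "none"

    lifetime = np.asarray(lifetime, dtype=bool)
    still_yes = np.asarray((still == True).fillna(False), dtype=bool)  # noqa: E712
    med_yes = np.asarray((med == True).fillna(False), dtype=bool)  # noqa: E712
    still_known = np.asarray(~still.isna() | ~med.isna(), dtype=bool)
    current = lifetime & (still_yes | med_yes)
    past = lifetime & ~(still_yes | med_yes) & still_known
    out[current] = "current"
    out[past] = "past"
    if scalar:
        return str(out[0])
    return out


def correct_for_medication(
    fev1_ml,
    fvc_ml,
    med_use,
    mode: str = "scale",
    factor: float = MEDICATION_FACTOR,
):
    """Adjust spirometry volumes of medicated participants.

    ``scale`` multiplies FEV1 and FVC of medication users by ``factor``
    (default 0.88), estimating their unmedicated values; ``covariate`` leaves
    volumes unchanged (medication use is exported as a confounder);
    ``exclude`` flags medicated rows out of the spirometry analysis.

    Returns ``(fev1, fvc, excluded)`` arrays (or scalars for scalar input).
    """
    if mode not in ("scale", "covariate", "exclude"):
        raise ValidationError(f"unknown medication mode {mode!r}")
    scalar = np.isscalar(fev1_ml) or np.ndim(fev1_ml) == 0
    fev1 = np.atleast_1d(np.asarray(fev1_ml, dtype=float)).copy()
    fvc = np.atleast_1d(np.asarray(fvc_ml, dtype=float)).copy()
    med = np.atleast_1d(np.asarray(med_use, dtype=bool))
    if np.any(fev1 <= 0) or np.any(fvc <= 0):
        raise ValidationError("spirometry volumes must be positive")
    excluded = np.zeros(len(fev1), dtype=bool)
    if mode == "scale":
        fev1[med] *= factor
        fvc[med] *= factor
    elif mode == "exclude":
        excluded = med.copy()
    if scalar:
        return float(fev1[0]), float(fvc[0]), bool(excluded[0])
    return fev1, fvc, excluded


_VALID_GRADES = frozenset("ABCDF")


def spirometry_inclusion(effort_maximal, fvc_quality, strict: bool = False):
    """Include iff effort was maximal and FVC quality is A/B/C (A/B if strict)."""
    scalar = np.isscalar(fvc_quality) or np.ndim(fvc_quality) == 0
    effort = np.atleast_1d(np.asarray(effort_maximal, dtype=bool))
    grades = np.atleast_1d(np.asarray(fvc_quality, dtype=object))
    unknown = sorted({str(g) for g in grades if str(g) not in _VALID_GRADES})
    if unknown:
        raise ValidationError(f"unknown FVC quality grade(s): {', '.join(unknown)}")
    ok_grades = {"A", "B"} if strict else {"A", "B", "C"}
    included = effort & np.array([str(g) in ok_grades for g in grades])
    if scalar:
        return bool(included[0])
    return included


def lln_threshold(ref: ReferenceModel, stratum: str, measure: str) -> float:
    """5th percentile of the stratum's reference distribution for a measure."""
    loc, scale = ref.cell(stratum, measure)
    return float(norm.ppf(LLN_QUANTILE, loc=loc, scale=scale))


def classify_below_lln(value, threshold) -> np.ndarray | bool:
    """Strictly below the LLN counts as dysfunction; boundary equality is normal."""
    value = np.asarray(value, dtype=float)
    below = value < np.asarray(threshold, dtype=float)
    if below.ndim == 0:
        return bool(below)
    return below


def percent_predicted(value, reference_loc) -> np.ndarray | float:
    """100 x observed / reference location."""
    loc = np.asarray(reference_loc, dtype=float)
    if np.any(loc <= 0):
        raise ValidationError("reference location must be positive")
    pct = 100.0 * np.asarray(value, dtype=float) / loc
    if pct.ndim == 0:
        return float(pct)
    return pct


def classify_rice(
    grain_servings, percentile: float = RICE_PERCENTILE
) -> tuple[np.ndarray, float]:
    """High/low inferred rice consumption by an empirical percentile cutoff.

    The cutoff is the given empirical percentile (linear-interpolation
    definition) of the analyzed sample's grain-servings totals; strictly
    above the cutoff is ``high``. Participants with missing totals are
    ``excluded``. Returns ``(labels, realized_cutoff)``.
    """
    if not 0 < percentile < 100:
        raise ValidationError(f"percentile must be in (0, 100), got {percentile}")
    servings = np.atleast_1d(np.asarray(grain_servings, dtype=float))
    valid = np.isfinite(servings)
    if not valid.any():
        raise DegenerateInputError("all grain-servings totals are missing")
    cutoff = float(np.percentile(servings[valid], percentile))
    labels = np.full(len(servings), "excluded", dtype=object)
    labels[valid & (servings > cutoff)] = "high"
    labels[valid & (servings <= cutoff)] = "low"
    return labels, cutoff


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def phenotype_cohort(
    cohort: pd.DataFrame,
    ref: ReferenceModel,
    broaden_asthma: bool = False,
    medication_mode: str = "scale",
    medication_factor: float = MEDICATION_FACTOR,
    strict_quality: bool = False,
    rice_percentile: float = RICE_PERCENTILE,
) -> tuple[pd.DataFrame, dict]:
    """Apply every classification rule to a cohort table.

    Returns the cohort with appended phenotype columns plus a dict of realized
    thresholds (rice cutoff, per-stratum LLNs used).
    """
    out = cohort.copy()

    out["smoking_class"] = classify_smoking(
        out["cigarettes_lifetime"].to_numpy(),
        (out["smoking"] == "current").to_numpy(),
        out["smoking_answered"].to_numpy(dtype=bool),
    )
    out["asthma_category"] = classify_asthma(
        out["asthma_ever"],
        out["asthma_doctor"],
        out["asthma_still"],
        out["asthma_med_use"],
        broaden=broaden_asthma,
    )
    rice_labels, rice_cutoff = classify_rice(
        out["grain_servings"].to_numpy(), percentile=rice_percentile
    )
    out["rice_class"] = rice_labels

    med = out["asthma_med_use"].fillna(False).to_numpy(dtype=bool)
    fev1, fvc, med_excluded = correct_for_medication(
        out["fev1_ml"].to_numpy(),
        out["fvc_ml"].to_numpy(),
        med,
        mode=medication_mode,
        factor=medication_factor,
    )
    out["fev1_corrected"] = fev1
    out["fvc_corrected"] = fvc
    out["fev1_fvc_corrected"] = fev1 / fvc
    out["pef_corrected"] = out["pef_ml_s"].to_numpy()  # PEF is never corrected
    out["medication_excluded"] = med_excluded
    out["med_use_covariate"] = med.astype(float)  # for the covariate sensitivity mode

    out["spirometry_included"] = (
        spirometry_inclusion(
            out["effort_maximal"].to_numpy(dtype=bool),
            out["fvc_quality"].to_numpy(),
            strict=strict_quality,
        )
        & ~med_excluded
    )

    strata = [
        stratum_key(e, s, a, h)
        for e, s, a, h in zip(
            out["ethnic_background"], out["sex"], out["age_years"], out["height_cm"]
        )
    ]
    out["reference_stratum"] = strata

    z05 = float(norm.ppf(LLN_QUANTILE))
    lln_used: dict[str, dict[str, float]] = {}
    unique_strata = sorted(set(strata))
    for measure in MEASURES:
        locs, scales = ref.lookup(strata, measure)
        thresholds = locs + z05 * scales
        u_locs, u_scales = ref.lookup(unique_strata, measure)
        for key, ul, us in zip(unique_strata, u_locs, u_scales):
            lln_used.setdefault(key, {})[measure] = float(ul + z05 * us)
        values = out[f"{measure}_corrected"].to_numpy()
        out[f"{measure}_below_lln"] = classify_below_lln(values, thresholds)
        if measure != "fev1_fvc":
            out[f"{measure}_pct_predicted"] = percent_predicted(values, locs)

    realized = {
        "rice_cutoff": rice_cutoff,
        "rice_percentile": rice_percentile,
        "medication_mode": medication_mode,
        "medication_factor": medication_factor,
        "lln_thresholds": lln_used,
    }
    return out, realized


def asthma_partition_ok(categories: Iterable[str]) -> bool:
    """Categories must partition the cohort into the four known classes."""
    cats = pd.Series(list(categories))
    return bool(cats.isin(["none", "past", "current", "missing"]).all())
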