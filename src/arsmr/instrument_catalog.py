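"""Literature instrument handling.

Loads the published SNV -> urinary-arsenic-metabolite weight table, validates
it, harmonizes allele coding against a cohort, and computes the LD (signed
correlation) matrix among the instrument variants from dosages.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, HarmonizationError, ValidationError

METABOLITES: tuple[str, ...] = ("iAs", "MMA", "DMA")

_REQUIRED_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "ref_allele"] + [
    f"{kind}_{met}" for met in METABOLITES for kind in ("beta", "se")
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("G", "C"))}


@dataclass(frozen=True)
class VariantRecord:
    """One instrument variant with its allele coding (positions on hg19)."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    ref_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.ref_allele:
            raise ValidationError(f"{self.rsid}: effect and reference allele are identical")
        if self.pos <= 0:
            raise ValidationError(f"{self.rsid}: position must be positive, got {self.pos}")


@dataclass
class ExposureWeights:
    """Per-metabolite effect sizes (percentage points per effect-allele copy)."""

    beta: dict[str, float]
    se: dict[str, float]

    def __post_init__(self) -> None:
        for met in METABOLITES:
            if met not in self.beta or met not in self.se:
                raise ValidationError(f"missing weights for metabolite {met}")
            if not np.isfinite(self.beta[met]):
                raise ValidationError(f"non-finite beta for {met}")
            if not (np.isfinite(self.se[met]) and self.se[met] > 0):
                raise ValidationError(f"se for {met} must be positive, got {self.se[met]}")


@dataclass
class InstrumentSet:
    """Ordered instrument variants with aligned exposure weights.

    Ordering is significant: every downstream matrix (LD, Psi, Sigma) is
    indexed in this order.
    """

    variants: list[VariantRecord]
    weights: list[ExposureWeights]

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.weights):
            raise ValidationError("variants and weights must align one-to-one")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsid(s): {', '.join(dupes)}")

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)

    def beta_vector(self, metabolite: str) -> np.ndarray:
        """Exposure betas for one metabolite, in variant order."""
        if metabolite not in METABOLITES:
            raise ValidationError(f"unknown metabolite {metabolite!r}")
        return np.array([w.beta[metabolite] for w in self.weights], dtype=float)

    def se_vector(self, metabolite: str) -> np.ndarray:
        if metabolite not in METABOLITES:
            raise ValidationError(f"unknown metabolite {metabolite!r}")
        return np.array([w.se[metabolite] for w in self.weights], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, w in zip(self.variants, self.weights):
            row = {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "ref_allele": v.ref_allele,
            }
            for met in METABOLITES:
                row[f"beta_{met}"] = w.beta[met]
                row[f"se_{met}"] = w.se[met]
            rows.append(row)
        return pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)


@dataclass
class LdMatrix:
    """Signed pairwise correlation between instrument dosages."""

    r: np.ndarray
    rsids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError("LD matrix must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-10):
            raise ValidationError("LD entries must lie in [-1, 1]")
        self.r = r


def bundled_instrument_path() -> str:
    """Path of the packaged literature weight table."""
    return str(resources.files("arsmr.data") / "instrument_weights.tsv")


def load_instruments(path: str | None = None) -> InstrumentSet:
    """Read a tab-separated instrument table, preserving row order.

    Parameters
    ----------
    path:
        TSV with columns ``rsid, chrom, pos, effect_allele, ref_allele,
        beta_iAs, se_iAs, beta_MMA, se_MMA, beta_DMA, se_DMA``. When omitted
        the bundled literature table is used.
    """
    if path is None:
        path = bundled_instrument_path()
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse instrument table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"instrument table missing column(s): {', '.join(missing)}")

    variants: list[VariantRecord] = []
    weights: list[ExposureWeights] = []
    for _, row in table.iterrows():
        cells = row[[f"{k}_{m}" for m in METABOLITES for k in ("beta", "se")]]
        if cells.isna().any():
            raise ValidationError(f"{row['rsid']}: missing beta/se cell")
        variants.append(
            VariantRecord(
                rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                ref_allele=str(row["ref_allele"]).upper(),
            )
        )
        weights.append(
            ExposureWeights(
                beta={m: float(row[f"beta_{m}"]) for m in METABOLITES},
                se={m: float(row[f"se_{m}"]) for m in METABOLITES},
            )
        )
    return InstrumentSet(variants=variants, weights=weights)


def compositional_audit(instruments: InstrumentSet, tol: float = 0.05) -> pd.DataFrame:
    """Per-variant sum of the three metabolite betas with a pass flag.

    The three percentages partition total urinary arsenic, so each variant's
    betas should sum to ~0; a large sum flags a transcription error.
    """
    sums = sum(instruments.beta_vector(m) for m in METABOLITES)
    return pd.DataFrame(
        {
            "rsid": instruments.rsids,
            "beta_sum": np.round(sums, 10),
            "passes": np.abs(sums) <= tol + 1e-12,
        }
    )


def harmonize(instruments: InstrumentSet, cohort_coding: Mapping[str, str]) -> InstrumentSet:
    """Align instrument weights to the allele counted by the cohort dosages.

    Where the cohort counts the instrument's reference allele, all three betas
    are sign-flipped and the allele labels swapped. Strand-ambiguous (A/T,
    G/C) variants are refused outright rather than guessed: a silent strand
    error would flip the causal direction.
    """
    new_variants: list[VariantRecord] = []
    new_weights: list[ExposureWeights] = []
    for variant, weight in zip(instruments.variants, instruments.weights):
        counted = cohort_coding.get(variant.rsid)
        if counted is None:
            raise HarmonizationError(f"no cohort allele coding supplied for {variant.rsid}")
        counted = counted.upper()
        if frozenset((variant.effect_allele, variant.ref_allele)) in _AMBIGUOUS_PAIRS:
            raise HarmonizationError(
                f"{variant.rsid}: strand-ambiguous allele pair "
                f"{variant.effect_allele}/{variant.ref_allele}; refusing to harmonize"
            )
        if counted == variant.effect_allele:
            new_variants.append(variant)
            new_weights.append(copy.deepcopy(weight))
        elif counted == variant.ref_allele:
            new_variants.append(
                VariantRecord(
                    rsid=variant.rsid,
                    chrom=variant.chrom,
                    pos=variant.pos,
                    effect_allele=variant.ref_allele,
                    ref_allele=variant.effect_allele,
                )
            )
            new_weights.append(
                ExposureWeights(
                    beta={m: -weight.beta[m] for m in METABOLITES},
                    se=dict(weight.se),
                )
            )
        else:
            raise HarmonizationError(
                f"{variant.rsid}: cohort counts allele {counted!r}, which matches neither "
                f"{variant.effect_allele} nor {variant.ref_allele}"
            )
    return InstrumentSet(variants=new_variants, weights=new_weights)


def ld_from_dosages(dosages: np.ndarray, rsids: Sequence[str] | None = None) -> LdMatrix:
    """Pairwise sample correlation of dosage columns (composite r).

    Diagonal is forced to exactly 1. Columns with zero variance are rejected
    by name.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2:
        raise ValidationError("dosages must be a 2-D (n x J) array")
    n, j = dosages.shape
    if n < 2:
        raise ValidationError("need at least 2 samples to estimate LD")
    names = list(rsids) if rsids is not None else [f"variant_{k}" for k in range(j)]
    if len(names) != j:
        raise ValidationError("rsids length does not match dosage columns")
    variances = dosages.var(axis=0, ddof=1)
    dead = [names[k] for k in range(j) if variances[k] <= 0]
    if dead:
        raise DegenerateInputError(f"zero-variance dosage column(s): {', '.join(dead)}")
    r = np.corrcoef(dosages, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return LdMatrix(r=r, rsids=names)
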