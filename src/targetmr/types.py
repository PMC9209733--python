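"""Core domain types for two-sample Mendelian randomization.

The analysis operates entirely on GWAS summary statistics: one
:class:`AssociationRecord` per variant-trait association, merged across an
exposure study and one or more outcome studies into
:class:`HarmonizedPair` objects that share an effect-allele orientation.
Causal estimates (:class:`MREstimate`) and pooled results
(:class:`MetaResult`) are kept on the log-odds scale for binary outcomes
and back-transformed to odds ratios only for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "HarmonizationError",
    "COMPLEMENT",
    "VALID_BASES",
    "StudyMeta",
    "AssociationRecord",
    "SelectionCriteria",
    "LDMatrix",
    "HarmonizedPair",
    "InstrumentSet",
    "MREstimate",
    "MetaResult",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ValidationError(ValueError):
    """A record or parameter violates a domain invariant."""


class ConfigurationError(ValueError):
    """Run configuration is inconsistent (missing columns, missing LD, ...)."""


class HarmonizationError(ValueError):
    """Exposure and outcome associations cannot be placed on a common allele."""


def _check_allele(allele: str, name: str) -> str:
    a = str(allele).strip().upper()
    if len(a) != 1 or a not in VALID_BASES:
        raise ValidationError(f"{name} must be a single base A/C/G/T, got {allele!r}")
    return a


@dataclass(frozen=True)
class StudyMeta:
    """Cohort-level metadata for one GWAS.

    ``n_cases``/``n_controls`` are zero for quantitative traits; for binary
    traits ``n`` must equal their sum.
    """

    label: str
    trait: str
    n: int = 0
    n_cases: int = 0
    n_controls: int = 0
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.n_cases and self.n_controls:
            total = self.n_cases + self.n_controls
            if self.n and self.n != total:
                raise ValidationError(
                    f"n ({self.n}) != n_cases + n_controls ({total}) for {self.label!r}"
                )
            if not self.n:
                object.__setattr__(self, "n", total)


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-trait summary association.

    ``beta`` is the per-effect-allele effect: SD units for quantitative
    traits, log-odds for binary traits. ``eaf`` refers to ``effect_allele``.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pvalue: Optional[float] = None
    n: int = 0
    n_cases: int = 0
    n_controls: int = 0
    trait: str = ""
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.rsid}: se must be positive and finite, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.rsid}: eaf must lie strictly in (0,1), got {self.eaf}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.rsid}: pvalue must lie in (0,1], got {self.pvalue}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"{self.rsid}: unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases < 1 or self.n_controls < 1:
                raise ValidationError(f"{self.rsid}: binary trait requires n_cases>=1 and n_controls>=1")
            if self.n and self.n != self.n_cases + self.n_controls:
                raise ValidationError(f"{self.rsid}: n != n_cases + n_controls")

    @property
    def maf(self) -> Optional[float]:
        """Minor-allele frequency, if the EAF is known."""
        return None if self.eaf is None else min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class SelectionCriteria:
    """Instrument-selection thresholds.

    Defaults: genome-wide significance 5e-8, MAF floor 0.01 (strict '>'),
    LD pruning at r-squared 0.3, palindromic variants dropped.
    """

    p_max: float = 5e-8
    maf_min: float = 0.01
    ld_r2_max: float = 0.3
    drop_palindromic: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1):
            raise ValidationError("p_max must lie in (0,1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValidationError("maf_min must lie in [0,0.5)")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValidationError("ld_r2_max must lie in [0,1]")


class LDMatrix:
    """Symmetric matrix of squared correlations (r^2) between variants."""

    def __init__(self, rsids: Sequence[str], r2: np.ndarray):
        rsids = tuple(rsids)
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(rsids), len(rsids)):
            raise ValidationError("r2 matrix shape does not match rsid count")
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsids in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal must be 1")
        if r2.size and (r2.min() < -1e-12 or r2.max() > 1 + 1e-12):
            raise ValidationError("LD r2 values must lie in [0,1]")
        self.rsids = rsids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {r: i for i, r in enumerate(rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(f"variant {exc.args[0]!r} missing from LD matrix") from None

    def subset(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[r] for r in rsids]
        return LDMatrix(rsids, self.r2[np.ix_(idx, idx)])


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations expressed on one shared effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    exposure_eaf: Optional[float] = None
    outcome_eaf: Optional[float] = None
    palindromic: bool = False
    orientation_action: str = "none"
    exposure: str = ""
    outcome: str = ""
    outcome_trait_type: str = "binary"

    def __post_init__(self) -> None:
        if not (self.exposure_se > 0):
            raise ValidationError(f"{self.rsid}: exposure_se must be positive")
        if not (self.outcome_se > 0):
            raise ValidationError(f"{self.rsid}: outcome_se must be positive")
        if self.orientation_action not in (
            "none",
            "allele_swap",
            "strand_flip",
            "strand_flip_and_swap",
        ):
            raise ValidationError(f"unknown orientation_action {self.orientation_action!r}")

    @property
    def wald_point(self) -> float:
        return self.outcome_beta / self.exposure_beta


@dataclass(frozen=True)
class InstrumentSet:
    """Result of instrument selection on the exposure side.

    ``selection_log`` holds one ``(rsid, retained, reason)`` triple per
    candidate, in input order.
    """

    records: tuple
    ld: LDMatrix
    selection_log: tuple

    @property
    def rsids(self) -> tuple:
        return tuple(r.rsid for r in self.records)


@dataclass(frozen=True)
class MREstimate:
    """A Wald-ratio or IVW causal estimate on the log scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    odds_ratio: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError("estimate se must be positive")
        if not (self.ci_low < self.beta < self.ci_high):
            raise ValidationError("confidence interval must bracket the point estimate")
        if self.odds_ratio is not None and not math.isclose(
            self.odds_ratio, math.exp(self.beta), rel_tol=1e-9
        ):
            raise ValidationError("odds_ratio must equal exp(beta)")

    @property
    def is_binary_outcome(self) -> bool:
        return self.odds_ratio is not None


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with Cochran's Q, I-squared and (random model) tau-squared."""

    model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q: float
    df: int
    q_pvalue: float
    i2: float
    tau2: float
    k: int
    exposure: str = ""
    outcome: str = ""
    odds_ratio: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValidationError(f"unknown meta model {self.model!r}")
        if self.q < 0 or not (0 <= self.i2 <= 100) or self.tau2 < 0:
            raise ValidationError("heterogeneity statistics out of range")
        if self.model == "fixed" and self.tau2 != 0:
            raise ValidationError("fixed-effects model requires tau2 == 0")
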