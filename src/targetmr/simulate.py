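"""Synthetic two-sample GWAS generator with known causal ground truth.

The generator produces what a two-sample MR analysis consumes: per-variant
summary statistics from two disjoint cohorts. In the exposure cohort a
standardized quantitative exposure is built additively from genotype
dosages plus Gaussian noise scaled so the total variance is one. In an
independent outcome cohort the same genetic architecture drives the
exposure, and a binary outcome is drawn from a logistic model with a
specified causal log-odds per SD of exposure (plus optional per-variant
direct, i.e. pleiotropic, effects). Per-variant summary scans (linear for
the exposure, logistic for the outcome) then yield association records in
the canonical format, together with the sample LD matrix.

Genotypes honour target allele frequencies and pairwise LD via a Gaussian
copula: two latent haplotypes per person are drawn from a multivariate
normal and dichotomized at the allele-frequency quantile. Because
dichotomization attenuates correlation, the latent correlation for each
variant pair is solved numerically (bivariate-normal orthant probability)
so that the realized Pearson dosage correlation matches ``pairwise_r``.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import AssociationRecord, ConfigurationError, LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_traits",
    "summary_scan",
    "generate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample study.

    variants: (rsid, effect-allele frequency, per-allele effect on the
    standardized exposure, in SD). pairwise_r: latent correlation matrix
    between variant dosages (identity when omitted). gamma: causal log-odds
    of the outcome per SD of exposure. intercept: baseline log-odds, which
    sets the outcome prevalence. direct_effects: per-variant log-odds
    bypassing the exposure (violations of the exclusion restriction).
    """

    n_exposure: int
    n_outcome: int
    variants: Tuple[Tuple[str, float, float], ...]
    gamma: float
    intercept: float = -2.5
    pairwise_r: Optional[np.ndarray] = None
    direct_effects: Optional[Tuple[float, ...]] = None
    seed: int = 0
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(tuple(v) for v in self.variants))
        if not self.variants:
            raise ConfigurationError("at least one variant is required")
        for rsid, eaf, _ in self.variants:
            if not (0.0 < eaf < 1.0):
                raise ConfigurationError(f"{rsid}: eaf must lie in (0,1)")
        m = len(self.variants)
        if self.pairwise_r is not None:
            r = np.asarray(self.pairwise_r, dtype=float)
            if r.shape != (m, m):
                raise ConfigurationError("pairwise_r shape must match variant count")
            if not np.allclose(r, r.T):
                raise ConfigurationError("pairwise_r must be symmetric")
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise ConfigurationError("pairwise_r must be positive semi-definite")
            object.__setattr__(self, "pairwise_r", r)
        if self.direct_effects is not None and len(self.direct_effects) != m:
            raise ConfigurationError("direct_effects length must match variant count")

    @property
    def eafs(self) -> np.ndarray:
        return np.array([v[1] for v in self.variants])

    @property
    def effects(self) -> np.ndarray:
        return np.array([v[2] for v in self.variants])

    @property
    def rsids(self) -> Tuple[str, ...]:
        return tuple(v[0] for v in self.variants)

    def genetic_variance(self) -> float:
        """Model variance of the genetic exposure component (incl. LD terms)."""
        sd = np.sqrt(2.0 * self.eafs * (1.0 - self.eafs))
        r = self.pairwise_r if self.pairwise_r is not None else np.eye(len(self.variants))
        cov = r * np.outer(sd, sd)
        return float(self.effects @ cov @ self.effects)


@dataclass(frozen=True)
class SimulatedStudy:
    """Summary statistics from both cohorts plus the generating truth."""

    exposure_assocs: Tuple[AssociationRecord, ...]
    outcome_assocs: Tuple[AssociationRecord, ...]
    ld: LDMatrix
    config: SimulationConfig
    seed: int

    @property
    def true_gamma(self) -> float:
        return self.config.gamma


def _alleles_for(index: int) -> Tuple[str, str]:
    # deterministic non-palindromic allele labels per variant position
    pairs = [("C", "A"), ("A", "G"), ("G", "T"), ("T", "C")]
    return pairs[index % len(pairs)]


@functools.lru_cache(maxsize=256)
def _latent_rho(target_r: float, p1: float, p2: float) -> float:
    """Latent bivariate-normal correlation whose dichotomized indicators
    have Pearson correlation ``target_r`` at marginal frequencies p1, p2."""
    if target_r == 0.0:
        return 0.0
    z1, z2 = stats.norm.ppf([p1, p2])
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [z1, z2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - p1 * p2) / denom - target_r

    lo, hi = -0.9999, 0.9999
    if gap(lo) * gap(hi) > 0:
        raise ConfigurationError(
            f"dosage correlation {target_r:.3g} unattainable at frequencies "
            f"{p1:.3g}, {p2:.3g}"
        )
    from scipy.optimize import brentq

    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_genotypes(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n x m) dosage matrix of 0/1/2 effect-allele counts.

    Two latent MVN haplotypes per person are thresholded at the normal
    quantile of each allele frequency and summed (Hardy-Weinberg within
    variant, Gaussian-copula LD between variants). ``config.pairwise_r``
    is interpreted as the target Pearson correlation between dosages; the
    latent correlation is adjusted per pair to hit it.
    """
    m = len(config.variants)
    target = config.pairwise_r if config.pairwise_r is not None else np.eye(m)
    r = np.eye(m)
    eafs = config.eafs
    for i in range(m):
        for j in range(i + 1, m):
            r[i, j] = r[j, i] = _latent_rho(float(target[i, j]), eafs[i], eafs[j])
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise ConfigurationError(
            "latent correlation implied by pairwise_r is not positive semi-definite"
        )
    try:
        chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("pairwise_r is not positive semi-definite") from exc
    thresholds = stats.norm.ppf(config.eafs)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        z = rng.standard_normal((n, m)) @ chol.T
        dosage += (z < thresholds).astype(np.int8)
    return dosage


def simulate_traits(
    dosages: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Build the standardized exposure and the binary outcome for one cohort.

    The exposure is the centred additive genetic score plus Gaussian noise
    with variance ``1 - var(G)`` so the total model variance is one. The
    outcome is Bernoulli with logit ``intercept + gamma * exposure +
    direct_effects . dosage``.
    """
    g_var = config.genetic_variance()
    if g_var >= 1.0:
        raise ConfigurationError(
            f"genetic variance {g_var:.3g} >= 1; effects are not on the SD scale"
        )
    centred = dosages - 2.0 * config.eafs
    exposure = centred @ config.effects + rng.normal(0.0, math.sqrt(1.0 - g_var), len(dosages))
    logit = config.intercept + config.gamma * exposure
    if config.direct_effects is not None:
        logit = logit + dosages @ np.asarray(config.direct_effects)
    outcome = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))
    return exposure, outcome


def summary_scan(
    dosages: np.ndarray,
    trait: np.ndarray,
    trait_type: str,
    rsids: Optional[Sequence[str]] = None,
    trait_label: str = "",
) -> List[AssociationRecord]:
    """Per-variant univariate association scan, one record per variant.

    Quantitative traits use simple linear regression (closed form);
    binary traits use per-variant logistic regression with an intercept.
    Monomorphic variants are skipped with a log entry.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(trait) != n:
        raise ConfigurationError("trait length must match dosage rows")
    rsids = list(rsids) if rsids is not None else [f"sim{j+1}" for j in range(m)]
    is_binary = trait_type == "binary"
    n_cases = int(np.sum(trait)) if is_binary else 0
    n_controls = n - n_cases if is_binary else 0

    records: List[AssociationRecord] = []
    for j in range(m):
        d = dosages[:, j]
        eaf = float(d.mean() / 2.0)
        if eaf <= 0.0 or eaf >= 1.0:
            logger.warning("variant %s monomorphic in this cohort; skipped", rsids[j])
            continue
        ea, oa = _alleles_for(j)
        if is_binary:
            fit = sm.Logit(trait, sm.add_constant(d)).fit(disp=0)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            pvalue = float(fit.pvalues[1])
        else:
            dc = d - d.mean()
            yc = trait - trait.mean()
            sxx = float(dc @ dc)
            beta = float(dc @ yc) / sxx
            resid = yc - beta * dc
            sigma2 = float(resid @ resid) / (n - 2)
            se = math.sqrt(sigma2 / sxx)
            pvalue = float(2.0 * stats.t.sf(abs(beta) / se, df=n - 2))
        records.append(
            AssociationRecord(
                rsid=rsids[j],
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                pvalue=max(pvalue, 5e-324),
                n=n,
                n_cases=n_cases,
                n_controls=n_controls,
                trait=trait_label,
                trait_type=trait_type,
            )
        )
    return records


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genotypes -> traits -> scans, both cohorts.

    The exposure and outcome cohorts use independent genotype draws (no
    shared individuals, the defining feature of a two-sample design). All
    randomness descends from ``config.seed`` through a spawned seed
    sequence, so identical configs give identical studies.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_exp, rng_out = (np.random.default_rng(s) for s in ss.spawn(2))

    dos_exp = simulate_genotypes(config, config.n_exposure, rng_exp)
    exposure, _ = simulate_traits(dos_exp, config, rng_exp)
    exposure_assocs = summary_scan(
        dos_exp, exposure, "quantitative", config.rsids, config.exposure_label
    )

    dos_out = simulate_genotypes(config, config.n_outcome, rng_out)
    _, outcome = simulate_traits(dos_out, config, rng_out)
    outcome_assocs = summary_scan(
        dos_out, outcome, "binary", config.rsids, config.outcome_label
    )

    corr = np.corrcoef(dos_exp.astype(float), rowvar=False)
    corr = np.atleast_2d(corr)
    ld = LDMatrix(config.rsids, np.clip(corr**2, 0.0, 1.0))
    logger.info(
        "generated study: %d exposure / %d outcome samples, %d variants, gamma=%.3g",
        config.n_exposure, config.n_outcome, len(config.variants), config.gamma,
    )
    return SimulatedStudy(
        exposure_assocs=tuple(exposure_assocs),
        outcome_assocs=tuple(outcome_assocs),
        ld=ld,
        config=config,
        seed=config.seed,
    )
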