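"""Estimation of t-haplotype drive (transmission ratio distortion) from litters.

The unit of analysis is the litter: each litter contributes a binomial
vector (number of +/t pups, number of +/+ pups).  The point estimate of
drive for a cross type is the pooled +/t proportion, equivalently the
inverse-logit intercept of an intercept-only binomial fit; confidence
intervals use a quasi-likelihood (quasibinomial) dispersion estimated from
the litter-level Pearson statistic, so litters that are more variable than
binomial widen the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetics import Genotype, expected_het_proportion

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class LitterGenotypeCount:
    """Genotyped pups of one litter: counts inheriting / not inheriting t."""

    litter_id: str
    sire_gt: Genotype
    dam_gt: Genotype
    n_het: int
    n_wt: int

    def __post_init__(self) -> None:
        if self.n_het < 0 or self.n_wt < 0:
            raise ValueError("pup counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_het + self.n_wt


@dataclass(frozen=True)
class DriveEstimate:
    """Drive estimate for one cross type with a 95% confidence interval."""

    tau_hat: float
    ci_low: float
    ci_high: float
    n_litters: int
    n_offspring: int
    dispersion: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.tau_hat <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class TestResult:
    """A generic test statistic with degrees of freedom and p-value."""

    statistic: float
    df: float
    p_value: float
    method: str
    extra: dict = field(default_factory=dict, compare=False)


def _pearson_dispersion(ks: np.ndarray, ns: np.ndarray, p: float) -> float:
    """Litter-level Pearson quasi-likelihood dispersion, floored at 1."""
    if len(ks) < 2 or p <= 0.0 or p >= 1.0:
        return 1.0
    resid2 = (ks - ns * p) ** 2 / (ns * p * (1.0 - p))
    phi = float(resid2.sum() / (len(ks) - 1))
    return max(phi, 1.0)


def estimate_trd(litters: list[LitterGenotypeCount]) -> DriveEstimate:
    """Estimate drive from litters of a single cross type.

    The point estimate is the pooled +/t proportion over all genotyped
    pups (identical to the intercept-only binomial GLM fit).  The interval
    is Wald on the logit scale with the quasibinomial dispersion, mapped
    back through the inverse logit.  At the boundaries (all pups +/t or
    all +/+) an exact Clopper-Pearson interval is used instead, since the
    logit is undefined there.
    """
    litters = [l for l in litters if l.n >= 1]
    if not litters:
        raise ValueError("need at least one litter with at least one genotyped pup")
    ks = np.array([l.n_het for l in litters], dtype=float)
    ns = np.array([l.n for l in litters], dtype=float)
    k, n = float(ks.sum()), float(ns.sum())
    p = k / n
    phi = _pearson_dispersion(ks, ns, p)

    if p in (0.0, 1.0):
        lo, hi = _clopper_pearson(int(k), int(n))
        return DriveEstimate(p, lo, hi, len(litters), int(n), phi)

    se_logit = math.sqrt(phi / (n * p * (1.0 - p)))
    eta = math.log(p / (1.0 - p))
    lo = _expit(eta - Z95 * se_logit)
    hi = _expit(eta + Z95 * se_logit)
    return DriveEstimate(p, lo, hi, len(litters), int(n), phi)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def compare_cross_types(
    groups: dict[str, list[LitterGenotypeCount]],
) -> list[TestResult]:
    """Test whether drive differs among cross types.

    Fits a litter-level binomial GLM with cross type as the only factor and
    reports (i) the overall deviance chi-squared against the intercept-only
    model and (ii) pairwise contrasts between each group and the first on
    the logit scale, as t statistics using the quasibinomial dispersion.
    """
    if len(groups) < 2:
        raise ValueError("need at least two cross types to compare")
    rows = []
    for label, litters in groups.items():
        for l in litters:
            if l.n >= 1:
                rows.append((label, l.n_het, l.n_wt))
    df = pd.DataFrame(rows, columns=["group", "n_het", "n_wt"])
    if df["group"].nunique() < 2:
        raise ValueError("need litters in at least two groups")

    endog = df[["n_het", "n_wt"]].to_numpy(dtype=float)
    # reference level = first key of `groups` (insertion order)
    cats = pd.Categorical(df["group"], categories=list(groups))
    X = pd.get_dummies(cats, drop_first=True, dtype=float)
    X = sm.add_constant(X)
    full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, np.ones((len(df), 1)), family=sm.families.Binomial()).fit()

    k = X.shape[1]
    results = [
        TestResult(
            statistic=float(null.deviance - full.deviance),
            df=k - 1,
            p_value=float(stats.chi2.sf(null.deviance - full.deviance, k - 1)),
            method="deviance chi-squared, cross type factor",
        )
    ]
    # pairwise contrasts vs the reference level, quasibinomial scale
    phi = max(float(full.pearson_chi2 / full.df_resid), 1.0) if full.df_resid > 0 else 1.0
    for name in X.columns:
        if name == "const":
            continue
        coef = float(full.params[name])
        se = float(full.bse[name]) * math.sqrt(phi)
        t = coef / se
        p = 2 * float(stats.t.sf(abs(t), full.df_resid))
        results.append(
            TestResult(t, full.df_resid, p, f"contrast {name} vs reference",
                       extra={"coef": coef, "se": se})
        )
    return results


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test of k successes in n trials against p0.

    The two-sided p-value sums the probabilities of all outcomes no more
    likely than the observed one (small-probability inclusion rule with a
    1 + 1e-7 relative tolerance on ties).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    res = stats.binomtest(k, n, p0, alternative="two-sided")
    return TestResult(float(k) / n, n, float(res.pvalue), "exact binomial test")


@dataclass(frozen=True)
class ExpectedVsObserved:
    """Comparison of the lethality-adjusted expectation with an observed CI."""

    expected: float
    observed: float
    ci_low: float
    ci_high: float
    overlaps: bool


def observed_vs_expected(
    tau_ref: DriveEstimate, het_cross: DriveEstimate
) -> ExpectedVsObserved:
    """Compare the +/t x +/t birth proportion against its drive expectation.

    ``tau_ref`` is the drive estimate from +/t sire x +/+ dam crosses, where
    every pup's paternal allele is observable.  Under recessive lethality
    the expected viable +/t proportion in a +/t x +/t cross is
    ``expected_het_proportion(tau_ref.tau_hat)``; the report flags whether
    that expectation falls inside the observed confidence interval of the
    double-heterozygote cross.
    """
    expected = expected_het_proportion(tau_ref.tau_hat)
    overlaps = het_cross.ci_low <= expected <= het_cross.ci_high
    return ExpectedVsObserved(
        expected=expected,
        observed=het_cross.tau_hat,
        ci_low=het_cross.ci_low,
        ci_high=het_cross.ci_high,
        overlaps=overlaps,
    )
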