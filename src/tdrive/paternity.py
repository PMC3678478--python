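"""Paternity-bias analysis in a wild population segregating for the t haplotype.

Given a roster of monitored adults and per-pup parentage assignments, this
module builds the analysis table (each pup with dam/sire genotypes and the
fraction of candidate sires that were +/t in the month before birth), and
runs the battery of mate-choice tests:

* 2x2 contingency tests (Yates-corrected Pearson chi-squared) of sire
  genotype against dam genotype, on pups or on singly-sired litters;
* the virtual-pup correction, which inflates the (+/t dam, +/t sire) cell
  by 1/(1-m) to restore the t/t conceptions that died before sampling;
* litter-level binomial models (random dam intercept fitted by maximum
  likelihood with Gauss-Hermite quadrature, falling back to a fixed-effects
  fit when the variance collapses) and pup-level logistic models, with
  significance assessed by nested-model deviance differences;
* the litter-size-stratified bootstrap for the multiple-paternity rate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genetics import Genotype
from .transmission import TestResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WildIndividual:
    """A monitored adult: identity, sex, t-locus genotype, detection interval."""

    id: str
    sex: str  # "M" or "F"
    genotype: Genotype
    first_seen: date
    last_seen: date

    def __post_init__(self) -> None:
        if self.last_seen < self.first_seen:
            raise ValueError(f"{self.id}: last_seen before first_seen")

    def detected_in(self, start: date, end: date) -> bool:
        """True if the detection interval intersects (start, end]."""
        return self.first_seen <= end and self.last_seen > start


@dataclass(frozen=True)
class PaternityRow:
    """One pup with parentage, genotypes, and the candidate-male covariate."""

    pup_id: str
    litter_id: str
    birth_date: date
    year: int
    dam_id: str
    dam_gt: Genotype
    sire_id: str
    sire_gt: Genotype
    prop_het_males: float


@dataclass(frozen=True)
class CorrectionFactor:
    """Expected fraction of a +/t x +/t litter lost to t/t mortality.

    The default 0.403 is the red-scar estimate of prenatal loss from the
    laboratory crosses, the best available measure of how many pups of
    such litters die before they can be sampled.
    """

    m: float = 0.403

    def __post_init__(self) -> None:
        if not 0.0 <= self.m < 1.0:
            raise ValueError(f"m must lie in [0, 1), got {self.m}")


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    B: int
    seed: int | None


# ---------------------------------------------------------------------------
# covariate construction
# ---------------------------------------------------------------------------

def build_paternity_table(
    pups: pd.DataFrame,
    roster: Sequence[WildIndividual],
    window_days: int = 30,
) -> list[PaternityRow]:
    """Attach genotypes and the +/t candidate-male fraction to each pup.

    ``pups`` needs columns pup_id, litter_id, birth_date (datetime.date or
    ISO string), dam_id, sire_id.  Candidate sires for a litter are the
    males whose detection interval intersects the half-open window
    (birth - window_days, birth]; ``prop_het_males`` is the +/t fraction
    among them, computed once per litter and attached to every pup.

    Pups whose litter has no candidate males, or whose dam or sire is
    missing from the roster, are excluded with a logged warning.
    """
    by_id = {ind.id: ind for ind in roster}
    males = sorted((i for i in roster if i.sex == "M"), key=lambda i: i.id)

    litter_prop: dict[str, float] = {}
    rows: list[PaternityRow] = []
    for rec in pups.to_dict("records"):
        birth = rec["birth_date"]
        if isinstance(birth, str):
            birth = date.fromisoformat(birth)
        elif isinstance(birth, pd.Timestamp):
            birth = birth.date()
        lid = str(rec["litter_id"])
        if lid not in litter_prop:
            start = birth - timedelta(days=window_days)
            cand = [m for m in males if m.detected_in(start, birth)] if window_days > 0 \
                else [m for m in males if m.first_seen <= birth <= m.last_seen]
            if not cand:
                litter_prop[lid] = float("nan")
                logger.warning("litter %s: no candidate males in window; excluded", lid)
            else:
                litter_prop[lid] = sum(
                    1 for m in cand if m.genotype == Genotype.HET
                ) / len(cand)
        prop = litter_prop[lid]
        if math.isnan(prop):
            continue
        dam = by_id.get(str(rec["dam_id"]))
        sire = by_id.get(str(rec["sire_id"]))
        if dam is None or sire is None:
            logger.warning("pup %s: dam or sire missing from roster; excluded",
                           rec["pup_id"])
            continue
        if dam.genotype not in (Genotype.WT, Genotype.HET) or \
                sire.genotype not in (Genotype.WT, Genotype.HET):
            logger.warning("pup %s: unknown parental genotype; excluded", rec["pup_id"])
            continue
        rows.append(
            PaternityRow(
                pup_id=str(rec["pup_id"]),
                litter_id=lid,
                birth_date=birth,
                year=birth.year,
                dam_id=dam.id,
                dam_gt=dam.genotype,
                sire_id=sire.id,
                sire_gt=sire.genotype,
                prop_het_males=prop,
            )
        )
    return rows


def rows_to_frame(rows: Iterable[PaternityRow]) -> pd.DataFrame:
    """PaternityRow collection as a DataFrame (one row per pup)."""
    return pd.DataFrame(
        {
            "pup_id": r.pup_id,
            "litter_id": r.litter_id,
            "birth_date": r.birth_date,
            "year": r.year,
            "dam_id": r.dam_id,
            "dam_gt": r.dam_gt.value,
            "sire_id": r.sire_id,
            "sire_gt": r.sire_gt.value,
            "prop_het_males": r.prop_het_males,
        }
        for r in rows
    )


# ---------------------------------------------------------------------------
# contingency tests and the virtual-pup correction
# ---------------------------------------------------------------------------

def chi2_yates(table: Sequence[Sequence[float]], correction: bool = True) -> TestResult:
    """Pearson chi-squared on a 2x2 table, Yates-corrected by default.

    The corrected statistic is sum((|O-E| - min(0.5, |O-E|))^2 / E) with
    df = 1; with ``correction=False`` the plain Pearson statistic is used.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in table")
    expected = np.outer(rows, cols) / n
    d = np.abs(t - expected)
    if correction:
        d = d - np.minimum(0.5, d)
    chi2 = float((d * d / expected).sum())
    label = "Pearson chi-squared" + (" (Yates)" if correction else "")
    return TestResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), label)


@dataclass(frozen=True)
class CorrectedCounts:
    """Observed and mortality-corrected sire-genotype counts by dam genotype."""

    observed: pd.DataFrame   # index dam_gt, columns ["het_sired", "wt_sired"]
    corrected: pd.DataFrame
    m: float

    def proportion_het_sired(self, corrected: bool = True) -> pd.Series:
        t = self.corrected if corrected else self.observed
        return t["het_sired"] / t.sum(axis=1)


def correct_for_lethality(
    counts: pd.DataFrame, m: CorrectionFactor | float = CorrectionFactor()
) -> CorrectedCounts:
    """Add virtual pups to the (+/t dam, +/t sire) cell.

    Pups of +/t dams sired by +/t males are undercounted because the t/t
    fraction died before sampling.  The corrected count divides that single
    cell by (1 - m), leaving every other cell unchanged; proportions are
    then recomputed.  ``counts`` has dam genotype ("HET"/"WT") as index and
    columns ``het_sired`` and ``wt_sired``.
    """
    mval = m.m if isinstance(m, CorrectionFactor) else float(m)
    if not 0.0 <= mval < 1.0:
        raise ValueError(f"m must lie in [0, 1), got {mval}")
    obs = counts.astype(float).copy()
    if (obs < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    corr = obs.copy()
    if "HET" in corr.index:
        corr.loc["HET", "het_sired"] = obs.loc["HET", "het_sired"] / (1.0 - mval)
    return CorrectedCounts(observed=obs, corrected=corr, m=mval)


def paternity_counts(table: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Pup counts of het- vs wt-sired offspring by dam genotype."""
    df = table if year is None else table[table["year"] == year]
    out = pd.DataFrame(0, index=["HET", "WT"], columns=["het_sired", "wt_sired"])
    for dam_gt in ("HET", "WT"):
        sub = df[df["dam_gt"] == dam_gt]
        out.loc[dam_gt, "het_sired"] = int((sub["sire_gt"] == "HET").sum())
        out.loc[dam_gt, "wt_sired"] = int((sub["sire_gt"] == "WT").sum())
    return out


def singly_sired_analysis(table: pd.DataFrame) -> dict[str, TestResult]:
    """Dam-genotype vs sire-genotype tests restricted to single-sire litters.

    A litter is singly sired when every pup has the same assigned sire.
    The unit of analysis is the litter; per-year 2x2 tables (dam genotype x
    sire genotype) are tested with the Yates-corrected chi-squared, plus a
    pooled table over years.  Years where either dam genotype has no litter
    are skipped with a warning.
    """
    litters = (
        table.groupby("litter_id")
        .agg(
            year=("year", "first"),
            dam_gt=("dam_gt", "first"),
            n_sires=("sire_id", "nunique"),
            sire_gt=("sire_gt", "first"),
        )
        .reset_index()
    )
    single = litters[litters["n_sires"] == 1]
    results: dict[str, TestResult] = {}

    def tab(df: pd.DataFrame) -> np.ndarray:
        return np.array(
            [
                [((df.dam_gt == d) & (df.sire_gt == "HET")).sum(),
                 ((df.dam_gt == d) & (df.sire_gt == "WT")).sum()]
                for d in ("HET", "WT")
            ],
            dtype=float,
        )

    def test_or_none(t: np.ndarray, label: str) -> TestResult | None:
        if (t.sum(axis=1) == 0).any():
            warnings.warn(f"{label}: no singly-sired litters for one dam "
                          "genotype, skipped")
            return None
        if (t.sum(axis=0) == 0).any():
            # every litter sired by one genotype: no association to test
            return TestResult(0.0, 1, 1.0, "Pearson chi-squared (Yates)")
        return chi2_yates(t)

    for year, df in single.groupby("year"):
        res = test_or_none(tab(df), f"year {year}")
        if res is not None:
            results[str(year)] = res
    res = test_or_none(tab(single), "pooled")
    if res is not None:
        results["pooled"] = res
    return results


# ---------------------------------------------------------------------------
# litter- and pup-level binomial models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for t in terms:
        if t == "dam_gt":
            cols.append((df["dam_gt"] == "HET").to_numpy(float))
        elif t == "prop_het_males":
            cols.append(df["prop_het_males"].to_numpy(float))
        elif t == "interaction":
            cols.append(
                (df["dam_gt"] == "HET").to_numpy(float)
                * df["prop_het_males"].to_numpy(float)
            )
        elif t == "year":
            years = sorted(df["year"].unique())
            for y in years[1:]:
                cols.append((df["year"] == y).to_numpy(float))
        else:
            raise ValueError(f"unknown term {t!r}")
    return np.column_stack(cols)


def _binom_loglik(beta: np.ndarray, X: np.ndarray, k: np.ndarray,
                  n: np.ndarray) -> float:
    eta = X @ beta
    return float(k @ eta - n @ np.logaddexp(0.0, eta))


def _fit_fixed(X: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, float]:
    """ML logistic fit for binomial counts; returns (beta, loglik)."""
    def nll(b):
        return -_binom_loglik(b, X, k, n)

    def grad(b):
        mu = special.expit(X @ b)
        return -(X.T @ (k - n * mu))

    b0 = np.zeros(X.shape[1])
    res = optimize.minimize(nll, b0, jac=grad, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    return res.x, -float(res.fun)


def _fit_mixed(X: np.ndarray, k: np.ndarray, n: np.ndarray,
               groups: np.ndarray, n_quad: int = 25) -> tuple[np.ndarray, float, float]:
    """ML binomial logistic with a group random intercept.

    The marginal likelihood integrates the Gaussian random effect per group
    with Gauss-Hermite quadrature.  Returns (beta, sigma, loglik); sigma is
    the random-intercept SD.  Falls back to the fixed fit (sigma = 0) when
    the variance collapses or optimization fails.
    """
    # hermegauss integrates g(x) e^{-x^2/2}; dividing the weights by
    # sqrt(2*pi) turns the sum into an expectation under N(0, 1)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    logw = np.log(weights) - 0.5 * math.log(2 * math.pi)

    uniq, inv = np.unique(groups, return_inverse=True)
    G = len(uniq)

    def nmll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = math.exp(log_sigma)
        eta = X @ beta
        # observation x node conditional log-likelihood, summed per group
        e = eta[:, None] + sigma * nodes[None, :]
        ll_obs = k[:, None] * e - n[:, None] * np.logaddexp(0.0, e)
        ll_grp = np.zeros((G, len(nodes)))
        np.add.at(ll_grp, inv, ll_obs)
        return -float(special.logsumexp(ll_grp + logw[None, :], axis=1).sum())

    b_fix, ll_fix = _fit_fixed(X, k, n)
    theta0 = np.append(b_fix, math.log(0.5))
    try:
        res = optimize.minimize(nmll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6,
                                         "fatol": 1e-8})
        beta, sigma = res.x[:-1], math.exp(res.x[-1])
        ll = -float(res.fun)
        if not res.success and ll < ll_fix:
            raise RuntimeError("mixed fit failed to improve")
    except Exception:  # pragma: no cover - defensive fallback
        return b_fix, 0.0, ll_fix
    if sigma < 1e-4 or ll < ll_fix - 1e-6:
        return b_fix, 0.0, ll_fix
    return beta, sigma, ll


FULL_TERMS = ("dam_gt", "prop_het_males", "interaction", "year")


@dataclass
class ModelFit:
    """A fitted binomial model with nested-deviance term tests."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    loglik: float
    sigma: float                      # random-intercept SD (0 = fixed-effects)
    lr_tests: dict[str, TestResult] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _litter_table(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.assign(het_sired=(table["sire_gt"] == "HET").astype(int))
        .groupby("litter_id")
        .agg(
            dam_id=("dam_id", "first"),
            dam_gt=("dam_gt", "first"),
            year=("year", "first"),
            prop_het_males=("prop_het_males", "first"),
            k=("het_sired", "sum"),
            n=("het_sired", "size"),
        )
        .reset_index()
    )


def _lr_tests(
    df: pd.DataFrame,
    k: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray | None,
    terms: Sequence[str] = FULL_TERMS,
) -> ModelFit:
    def fit(ts: Sequence[str]) -> tuple[np.ndarray, float, float]:
        X = _design(df, ts)
        if groups is None:
            b, ll = _fit_fixed(X, k, n)
            return b, 0.0, ll
        return _fit_mixed(X, k, n, groups)

    beta_full, sigma, ll_full = fit(terms)
    out = ModelFit(tuple(terms), beta_full, ll_full, sigma)
    for t in terms:
        reduced = [x for x in terms if x != t]
        # dropping a main effect marginal to the interaction is not a
        # nested comparison of interest; drop the interaction with it
        if t in ("dam_gt", "prop_het_males") and "interaction" in reduced:
            base = [x for x in terms if x != "interaction"]
            _, _, ll_base = fit(base)
            _, _, ll_red = fit([x for x in base if x != t])
            chi2 = 2.0 * (ll_base - ll_red)
        else:
            _, _, ll_red = fit(reduced)
            chi2 = 2.0 * (ll_full - ll_red)
        chi2 = max(chi2, 0.0)
        df_t = 1 if t != "year" else max(df["year"].nunique() - 1, 1)
        out.lr_tests[t] = TestResult(
            chi2, df_t, float(stats.chi2.sf(chi2, df_t)),
            f"LR test, drop {t}",
        )
    return out


def litter_level_model(table: pd.DataFrame, mixed: bool = True) -> ModelFit:
    """Litter-level binomial model of the +/t-sired fraction of each litter.

    Response: (pups sired by +/t males, pups sired by +/+ males) per litter.
    Fixed effects: dam genotype, +/t male availability, their interaction,
    and year; dam identity enters as a random intercept (ML with
    Gauss-Hermite quadrature) when ``mixed`` and more than one litter per
    dam exists.  Each term's significance is the chi-squared (df 1)
    deviance difference between nested ML fits.
    """
    lt = _litter_table(table)
    k = lt["k"].to_numpy(float)
    n = lt["n"].to_numpy(float)
    use_mixed = mixed and lt["dam_id"].duplicated().any()
    groups = lt["dam_id"].to_numpy() if use_mixed else None
    fit = _lr_tests(lt, k, n, groups)
    if use_mixed and fit.sigma == 0.0:
        fit.flags.append("random-intercept variance collapsed to 0; fixed-effects fit")
    return fit


def pup_level_model(table: pd.DataFrame) -> ModelFit:
    """Pup-level logistic model: is each pup sired by a +/t male?

    Treats every pup as an independent fertilization with the same fixed
    effects as the litter-level model.  Complete separation or a constant
    covariate is flagged; in that case coefficients come from a weakly
    ridge-penalized fit while the reported LR tests still use the ML
    deviances of the estimable nested models.
    """
    df = table.reset_index(drop=True)
    k = (df["sire_gt"] == "HET").to_numpy(float)
    n = np.ones(len(df))
    terms = list(FULL_TERMS)
    flags: list[str] = []
    if df["prop_het_males"].nunique() <= 1:
        flags.append("prop_het_males constant; interaction inestimable")
        terms = [t for t in terms if t not in ("prop_het_males", "interaction")]
    if df["year"].nunique() <= 1:
        terms = [t for t in terms if t != "year"]
    fit = _lr_tests(df, k, n, None, terms)
    fit.flags.extend(flags)
    # complete separation: the ML fit predicts every pup's sire genotype
    # perfectly, driving |eta| unbounded
    eta = _design(df, terms) @ fit.coefficients
    separated = np.abs(eta).min() > 10 and np.all((eta > 0) == (k > 0.5))
    if separated:
        fit.flags.append("possible complete separation; ridge-penalized coefficients")
        X = _design(df, terms)
        lam = 1e-3

        def nll_pen(b):
            return -_binom_loglik(b, X, k, n) + lam * float(b @ b)

        res = optimize.minimize(nll_pen, np.zeros(X.shape[1]), method="BFGS")
        fit.coefficients = res.x
    return fit


def incidence_curves(
    fit: ModelFit, prop_grid: np.ndarray | None = None, year: int | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Fitted P(sire is +/t) against +/t male availability, by dam genotype."""
    if prop_grid is None:
        prop_grid = np.linspace(0.0, 1.0, 51)
    rows = []
    terms = fit.terms
    for dam_gt in ("WT", "HET"):
        df = pd.DataFrame({
            "dam_gt": dam_gt,
            "prop_het_males": prop_grid,
            "year": year if year is not None else (years[0] if years else 0),
        })
        X = _design(df, [t for t in terms if t != "year"])
        n_year = len(fit.coefficients) - X.shape[1]
        Xfull = np.column_stack([X] + [np.zeros((len(df), n_year))]) if n_year else X
        p = special.expit(Xfull @ fit.coefficients)
        rows.append(pd.DataFrame({"dam_gt": dam_gt, "prop_het_males": prop_grid,
                                  "p_het_sired": p}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# multiple paternity
# ---------------------------------------------------------------------------

def multiple_paternity_rate(
    table: pd.DataFrame,
    min_size: int = 2,
    B: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Multiple-paternity rate with a litter-size-stratified bootstrap CI.

    Eligible litters have at least ``min_size`` pups (singleton litters
    cannot reveal a second sire).  The point estimate is the fraction of
    eligible litters with >= 2 assigned sires.  The percentile CI resamples
    litters with replacement within litter-size strata, so the resampled
    datasets preserve the litter-size composition that limits detectability.
    """
    litters = (
        table.groupby("litter_id")
        .agg(size=("pup_id", "size"), n_sires=("sire_id", "nunique"))
        .reset_index()
    )
    elig = litters[litters["size"] >= min_size]
    if elig.empty:
        raise ValueError("no litters of the minimum size")
    multi = (elig["n_sires"] >= 2).to_numpy()
    point = float(multi.mean())

    rng = np.random.default_rng(seed)
    sizes = elig["size"].to_numpy()
    boots = np.empty(B)
    strata = [multi[sizes == s] for s in np.unique(sizes)]
    for b in range(B):
        hits = tot = 0
        for arr in strata:
            res = arr[rng.integers(0, len(arr), size=len(arr))]
            hits += int(res.sum())
            tot += len(arr)
        boots[b] = hits / tot
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return BootstrapResult(point, float(lo), float(hi), B, seed)
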