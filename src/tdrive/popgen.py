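"""Marker summaries: allele frequencies, heterozygosity, and exact HWE tests.

Implements the statistics used to characterize MHC-linked and neutral
microsatellite variation in +/t versus +/+ mice: allele frequencies,
observed heterozygosity, the small-sample unbiased expected heterozygosity
(2n/(2n-1)) * (1 - sum p_i^2), conditional exact Hardy-Weinberg tests (full
enumeration for small genotype arrays, seeded Monte-Carlo permutation
otherwise), Fisher's method for combining p-values across loci, and exact
tests of allelic differentiation between two groups.

Because every +/t individual carries exactly one copy of the t-linked
allele at loci inside the t haplotype, those loci show observed
heterozygosity 1.0 and a strong heterozygote excess in the +/t class —
the signature these tests are designed to pick up.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .transmission import TestResult

AllelePair = tuple[str, str]


@dataclass(frozen=True)
class MarkerGenotype:
    """One individual's unordered allele pair at one locus."""

    individual: str
    t_class: str        # "WT" or "HET"
    locus: str
    allele1: str
    allele2: str

    @property
    def pair(self) -> AllelePair:
        a, b = sorted((str(self.allele1), str(self.allele2)))
        return a, b

    @property
    def heterozygous(self) -> bool:
        return self.allele1 != self.allele2


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus, per-group summary in the layout of a variability table."""

    locus: str
    group: str
    n: int
    alleles: tuple[str, ...]
    frequencies: tuple[float, ...]
    h_obs: float
    h_exp: float
    hwe_p: float
    direction: str  # "excess" | "deficit" | "none"


# ---------------------------------------------------------------------------
# frequencies and heterozygosity
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: Sequence[MarkerGenotype]) -> dict[str, float]:
    """Allele frequencies (counts / 2n) at one locus for one group."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    counts: Counter[str] = Counter()
    for g in genotypes:
        counts[str(g.allele1)] += 1
        counts[str(g.allele2)] += 1
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())}


def counts_from_frequencies(freqs: Sequence[float], n: int,
                            tol: float = 0.05) -> list[int]:
    """Back-convert printed (rounded) allele frequencies to integer counts.

    Rounds each frequency times 2n to the nearest integer and repairs any
    rounding drift on the largest-remainder allele so the counts sum to 2n.
    Raises if a rounded count sits further than ``tol`` * 2n from its input,
    which would mean the frequencies cannot come from a sample of size n.
    """
    two_n = 2 * n
    raw = np.asarray(freqs, dtype=float) * two_n
    counts = np.rint(raw).astype(int)
    drift = two_n - counts.sum()
    if drift != 0:
        order = np.argsort(-(raw - np.floor(raw)))
        counts[order[0]] += drift
    if (np.abs(counts - raw) > tol * two_n).any() or (counts < 0).any():
        raise ValueError("frequencies inconsistent with sample size")
    return counts.tolist()


def unbiased_expected_het(freqs: Sequence[float], n: int) -> float:
    """Small-sample unbiased expected heterozygosity (gene diversity).

    H_exp = (2n / (2n - 1)) * (1 - sum p_i^2), the unbiased estimator of
    expected heterozygosity for a sample of n diploids.
    """
    if n < 2:
        raise ValueError("need at least two individuals")
    p = np.asarray(list(freqs), dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    return float(2 * n / (2 * n - 1) * (1.0 - (p * p).sum()))


def observed_het(genotypes: Sequence[MarkerGenotype]) -> float:
    """Fraction of individuals heterozygous at the locus."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    return sum(g.heterozygous for g in genotypes) / len(genotypes)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def _genotype_counts(genotypes: Sequence[MarkerGenotype]) -> Counter[AllelePair]:
    return Counter(g.pair for g in genotypes)


def _log_prob(gcounts: dict[AllelePair, int], acounts: dict[str, int]) -> float:
    """Log conditional probability of a genotype array given allele counts."""
    n = sum(gcounts.values())
    two_n = sum(acounts.values())
    h = sum(c for (a, b), c in gcounts.items() if a != b)
    lp = gammaln(n + 1) - sum(gammaln(c + 1) for c in gcounts.values())
    lp += h * math.log(2.0)
    lp += sum(gammaln(c + 1) for c in acounts.values()) - gammaln(two_n + 1)
    return lp


def _het_count(gcounts: dict[AllelePair, int]) -> int:
    return sum(c for (a, b), c in gcounts.items() if a != b)


def _enumerate_arrays(acounts: dict[str, int]):
    """Yield every genotype-count array consistent with the allele counts."""
    alleles = sorted(acounts)
    pairs = [(alleles[i], alleles[j]) for i in range(len(alleles))
             for j in range(i, len(alleles))]

    def rec(idx: int, remaining: dict[str, int], current: dict[AllelePair, int]):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield dict(current)
            return
        a, b = pairs[idx]
        if a == b:
            mx = remaining[a] // 2
        else:
            mx = min(remaining[a], remaining[b])
        for c in range(mx + 1):
            rem = dict(remaining)
            if a == b:
                rem[a] -= 2 * c
            else:
                rem[a] -= c
                rem[b] -= c
            current[(a, b)] = c
            yield from rec(idx + 1, rem, current)
        current.pop((a, b), None)

    yield from rec(0, dict(acounts), {})


def _array_space_bound(acounts: dict[str, int]) -> float:
    """Crude upper bound on the number of genotype arrays."""
    k = len(acounts)
    n_pairs = k * (k + 1) // 2
    n = sum(acounts.values()) // 2
    return math.comb(n + n_pairs - 1, n_pairs - 1)


def hwe_exact_test(
    genotypes: Sequence[MarkerGenotype],
    alternative: str = "two-sided",
    max_enumeration: int = 1_000_000,
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Conditional exact test of Hardy-Weinberg proportions at one locus.

    Conditions on the observed allele counts.  Two-sided p-values sum the
    conditional probabilities of all genotype arrays no more probable than
    the observed one (relative tolerance 1 + 1e-7); one-sided alternatives
    ("excess" / "deficit") order arrays by their total heterozygote count.
    Full enumeration is used while the array space stays below
    ``max_enumeration``; beyond that a seeded Monte-Carlo permutation of the
    2n allele copies with ``n_permutations`` shuffles is used.

    A monomorphic locus returns p = 1 with a "monomorphic" method label.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two individuals")
    if alternative not in ("two-sided", "excess", "deficit"):
        raise ValueError(f"unknown alternative {alternative!r}")
    gcounts = dict(_genotype_counts(genotypes))
    acounts: Counter[str] = Counter()
    for (a, b), c in gcounts.items():
        acounts[a] += c
        acounts[b] += c
    if len(acounts) < 2:
        return TestResult(0.0, 0, 1.0, "HWE exact (monomorphic)")

    h_obs = _het_count(gcounts)
    lp_obs = _log_prob(gcounts, acounts)

    if _array_space_bound(dict(acounts)) <= max_enumeration:
        p = 0.0
        for arr in _enumerate_arrays(dict(acounts)):
            lp = _log_prob(arr, acounts)
            h = _het_count(arr)
            if alternative == "two-sided":
                include = lp <= lp_obs + math.log(1 + 1e-7)
            elif alternative == "excess":
                include = h >= h_obs
            else:
                include = h <= h_obs
            if include:
                p += math.exp(lp)
        p = min(p, 1.0)
        method = f"HWE exact enumeration ({alternative})"
    else:
        rng = np.random.default_rng(seed)
        alleles = np.array(
            [a for a, c in acounts.items() for _ in range(c)], dtype=object
        )
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(alleles)
            arr: Counter[AllelePair] = Counter()
            for i in range(0, len(alleles), 2):
                a, b = sorted((alleles[i], alleles[i + 1]))
                arr[(a, b)] += 1
            if alternative == "two-sided":
                hit = _log_prob(arr, acounts) <= lp_obs + math.log(1 + 1e-7)
            elif alternative == "excess":
                hit = _het_count(arr) >= h_obs
            else:
                hit = _het_count(arr) <= h_obs
            hits += hit
        p = (hits + 1) / (n_permutations + 1)
        method = f"HWE Monte-Carlo ({alternative}, {n_permutations} permutations)"
    return TestResult(float(h_obs), len(genotypes), float(p), method)


def fishers_method(p_values: Sequence[float]) -> TestResult:
    """Combine independent p-values: chi2 = -2 sum(ln p), df = 2k."""
    ps = np.asarray(list(p_values), dtype=float)
    if len(ps) == 0:
        raise ValueError("no p-values supplied")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros before combining")
    chi2 = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return TestResult(chi2, df, float(stats.chi2.sf(chi2, df)), "Fisher's method")


# ---------------------------------------------------------------------------
# differentiation between groups
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a contingency table given margins."""
    r, c, n = table.sum(axis=1), table.sum(axis=0), table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def differentiation_exact_test(
    genotypes: Sequence[MarkerGenotype],
    groups: tuple[str, str] = ("WT", "HET"),
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> dict[str, TestResult]:
    """Exact tests of allelic differentiation between two groups.

    Per locus, builds the 2 x (alleles) table of allele counts and computes
    a Fisher-type probability test: the p-value is the fraction of tables
    (obtained by permuting group labels over allele copies) whose
    conditional probability does not exceed the observed one.  2x2 tables
    use the fully exact hypergeometric test.  Loci monomorphic across both
    groups are skipped.  A global result combines the per-locus p-values
    with Fisher's method under the key ``"global"``.
    """
    rng = np.random.default_rng(seed)
    by_locus: dict[str, list[MarkerGenotype]] = {}
    for g in genotypes:
        by_locus.setdefault(g.locus, []).append(g)
    results: dict[str, TestResult] = {}
    for locus, gs in sorted(by_locus.items()):
        alleles = sorted({str(a) for g in gs for a in (g.allele1, g.allele2)})
        if len(alleles) < 2:
            continue
        idx = {a: i for i, a in enumerate(alleles)}
        table = np.zeros((2, len(alleles)), dtype=int)
        labels, copies = [], []
        for g in gs:
            if g.t_class not in groups:
                continue
            row = groups.index(g.t_class)
            for a in (g.allele1, g.allele2):
                table[row, idx[str(a)]] += 1
                labels.append(row)
                copies.append(idx[str(a)])
        if table.sum(axis=1).min() == 0:
            continue
        if len(alleles) == 2:
            _, p = stats.fisher_exact(table)
            results[locus] = TestResult(float(table[0, 0]), 1, float(p),
                                        "Fisher exact 2x2")
            continue
        lp_obs = _table_log_prob(table)
        labels_arr = np.asarray(labels)
        copies_arr = np.asarray(copies)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels_arr)
            t = np.zeros_like(table)
            np.add.at(t, (perm, copies_arr), 1)
            hits += _table_log_prob(t) <= lp_obs + 1e-9
        p = (hits + 1) / (n_permutations + 1)
        results[locus] = TestResult(
            float(lp_obs), len(alleles) - 1, float(p),
            f"allelic differentiation MC ({n_permutations} permutations)",
        )
    if results:
        results["global"] = fishers_method([r.p_value for r in results.values()])
    return results


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def summarize_locus(
    genotypes: Sequence[MarkerGenotype],
    locus: str,
    group: str,
    seed: int | None = None,
) -> LocusSummary:
    """Full per-locus, per-group summary (frequencies, H_obs, H_exp, HWE)."""
    gs = [g for g in genotypes if g.locus == locus and g.t_class == group]
    if not gs:
        raise ValueError(f"no genotypes for locus {locus!r} group {group!r}")
    freqs = allele_frequencies(gs)
    n = len(gs)
    h_obs = observed_het(gs)
    h_exp = unbiased_expected_het(list(freqs.values()), n) if n >= 2 else float("nan")
    hwe = hwe_exact_test(gs, seed=seed) if len(freqs) > 1 else None
    if hwe is None:
        p, direction = 1.0, "none"
    else:
        p = hwe.p_value
        direction = "excess" if h_obs > h_exp else ("deficit" if h_obs < h_exp else "none")
    return LocusSummary(
        locus=locus, group=group, n=n,
        alleles=tuple(freqs), frequencies=tuple(freqs.values()),
        h_obs=h_obs, h_exp=h_exp, hwe_p=p, direction=direction,
    )


def summarize_all(
    genotypes: Sequence[MarkerGenotype], seed: int | None = None
) -> list[LocusSummary]:
    """Summaries for every (locus, group) combination present in the data."""
    keys = sorted({(g.locus, g.t_class) for g in genotypes})
    return [summarize_locus(genotypes, locus, group, seed=seed)
            for locus, group in keys]
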