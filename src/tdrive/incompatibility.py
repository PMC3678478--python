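"""Cost of genetic incompatibility from litter sizes and uterine scars.

A +/t x +/t mating is genetically incompatible: under drive tau through
the sire, a fraction tau/2 of conceptions are t/t and die prenatally.
The cost is quantified three ways, mirroring post-partum uterine scar
scoring: litter size at birth, red scars (implantation sites of live-born
pups), and excess yellow scars (implanted embryos that died and were
resorbed).  All comparisons are litter-level; confidence intervals for
cost ratios use a nonparametric bootstrap over litters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genetics import Genotype
from .transmission import TestResult

CrossType = tuple[Genotype, Genotype]  # (sire_gt, dam_gt)


@dataclass
class LabCrossRecord:
    """One laboratory mating cross with its litter and scar outcomes.

    ``red_scars + yellow_scars`` equals the number of implanted embryos when
    scars were scored; scar fields are None for crosses where the dam's
    uterus was not examined (experiment 1).
    """

    cross_id: str
    sire_gt: Genotype
    dam_gt: Genotype
    litter_size_birth: int
    red_scars: int | None = None
    yellow_scars: int | None = None
    days_to_birth: float | None = None
    n_weaned: int | None = None
    experiment: int = 1
    pup_genotypes: list[Genotype] | None = None

    def __post_init__(self) -> None:
        if self.sire_gt not in (Genotype.WT, Genotype.HET):
            raise ValueError("inviable/sterile sire genotype")
        if self.dam_gt not in (Genotype.WT, Genotype.HET):
            raise ValueError("inviable dam genotype")
        if self.litter_size_birth < 0:
            raise ValueError("litter size must be nonnegative")
        for v in (self.red_scars, self.yellow_scars):
            if v is not None and v < 0:
                raise ValueError("scar counts must be nonnegative")

    @property
    def cross(self) -> CrossType:
        return (self.sire_gt, self.dam_gt)

    @property
    def implantations(self) -> int | None:
        if self.red_scars is None or self.yellow_scars is None:
            return None
        return self.red_scars + self.yellow_scars

    @property
    def fecund(self) -> bool:
        """Whether the cross yielded any offspring (or implanted embryo)."""
        if self.implantations is not None:
            return self.implantations > 0
        return self.litter_size_birth > 0


@dataclass(frozen=True)
class CostEstimate:
    """Fractional litter-size reduction attributable to incompatibility."""

    method: str                # "birth_litter" | "red_scar" | "yellow_scar_excess"
    perspective: str           # "female" | "male"
    reduction: float
    ci_low: float | None
    ci_high: float | None
    n_focal: int
    n_reference: int


HETXHET: CrossType = (Genotype.HET, Genotype.HET)


def _reference_cross(perspective: str) -> CrossType:
    # female perspective: +/t dam mated to +/+ sire; male: +/t sire to +/+ dam
    if perspective == "female":
        return (Genotype.WT, Genotype.HET)
    if perspective == "male":
        return (Genotype.HET, Genotype.WT)
    raise ValueError(f"perspective must be 'female' or 'male', got {perspective!r}")


def _values(records: Iterable[LabCrossRecord], cross: CrossType,
            measure: str) -> np.ndarray:
    out = []
    for r in records:
        if r.cross != cross or not r.fecund:
            continue
        v = r.litter_size_birth if measure == "birth_litter" else r.red_scars
        if v is not None:
            out.append(float(v))
    return np.asarray(out)


def cost_from_births(
    records: Sequence[LabCrossRecord],
    perspective: str = "female",
    measure: str = "birth_litter",
    B: int = 10_000,
    seed: int | None = None,
) -> CostEstimate:
    """Incompatibility cost as 1 - mean(focal)/mean(reference).

    The focal group is the +/t x +/t cross; the reference is the cross in
    which the focal sex mates a +/+ partner instead.  ``measure`` selects
    litter size at birth (``"birth_litter"``) or red scar counts
    (``"red_scar"``).  The percentile bootstrap resamples litters within
    each group independently (B resamples).
    """
    if measure not in ("birth_litter", "red_scar"):
        raise ValueError(f"unknown measure {measure!r}")
    focal = _values(records, HETXHET, measure)
    ref = _values(records, _reference_cross(perspective), measure)
    if len(focal) < 2 or len(ref) < 2:
        raise ValueError("need at least two litters in each group")
    if ref.mean() == 0:
        raise ValueError("reference group mean is zero; cost undefined")
    reduction = 1.0 - focal.mean() / ref.mean()

    rng = np.random.default_rng(seed)
    idx_f = rng.integers(0, len(focal), size=(B, len(focal)))
    idx_r = rng.integers(0, len(ref), size=(B, len(ref)))
    mf = focal[idx_f].mean(axis=1)
    mr = ref[idx_r].mean(axis=1)
    ok = mr > 0
    boots = 1.0 - mf[ok] / mr[ok]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CostEstimate(measure, perspective, float(reduction), float(lo),
                        float(hi), len(focal), len(ref))


def cost_from_yellow(records: Sequence[LabCrossRecord]) -> CostEstimate:
    """Incompatibility cost from the excess of resorbed embryos.

    Yellow scars mark embryos that implanted but died.  The excess of the
    +/t x +/t mean yellow count over the mean of all other crosses pooled,
    divided by the overall mean number of implantations (red + yellow),
    estimates the fraction of potential litter size lost to t/t mortality.
    """
    focal, other, totals = [], [], []
    for r in records:
        if r.yellow_scars is None or r.red_scars is None or not r.fecund:
            continue
        totals.append(r.red_scars + r.yellow_scars)
        (focal if r.cross == HETXHET else other).append(float(r.yellow_scars))
    if not focal or not other:
        raise ValueError("scar counts required in focal and comparison crosses")
    excess = float(np.mean(focal) - np.mean(other))
    reduction = excess / float(np.mean(totals))
    return CostEstimate("yellow_scar_excess", "female", reduction, None, None,
                        len(focal), len(other))


def fecundity_test(records: Sequence[LabCrossRecord]) -> TestResult:
    """Chi-squared test of fecundity (any offspring) across cross types.

    Builds the 2 x (cross types) table of fecund / non-fecund crosses and
    applies Pearson's chi-squared without continuity correction.
    """
    crosses = sorted({r.cross for r in records}, key=lambda c: (c[0].value, c[1].value))
    if len(crosses) < 2:
        raise ValueError("need at least two cross types")
    table = np.array(
        [
            [sum(1 for r in records if r.cross == c and r.fecund) for c in crosses],
            [sum(1 for r in records if r.cross == c and not r.fecund) for c in crosses],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any():
        raise ValueError("empty cross-type group")
    if (table.sum(axis=1) == 0).any():
        # every cross fecund (or none): no variation to test
        return TestResult(0.0, len(crosses) - 1, 1.0,
                          "fecundity chi-squared (degenerate)")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), int(df), float(p), "fecundity chi-squared")


def compare_group_means(
    groups: dict[str, Sequence[float]],
    reference: str | None = None,
) -> list[TestResult]:
    """One-way ANOVA across groups plus pairwise t contrasts.

    Returns the overall F test first, followed by Welch-free pooled-variance
    t contrasts of every other group against ``reference`` (default: the
    first group), using the ANOVA residual degrees of freedom — the contrast
    form of a one-way linear model.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    n_total = sum(len(a) for a in arrays.values())
    df_resid = n_total - len(labels)
    if df_resid < 1:
        raise ValueError("not enough observations for residual df")
    f_stat, p = stats.f_oneway(*arrays.values())
    out = [TestResult(float(f_stat), len(labels) - 1, float(p),
                      f"one-way ANOVA F({len(labels) - 1},{df_resid})")]

    ref = reference if reference is not None else labels[0]
    if ref not in arrays:
        raise ValueError(f"reference group {ref!r} not present")
    # pooled residual variance from all groups (ANOVA MSE)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_resid
    a_ref = arrays[ref]
    for g in labels:
        if g == ref:
            continue
        a = arrays[g]
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(a_ref)))
        t = (a.mean() - a_ref.mean()) / se
        out.append(
            TestResult(float(t), df_resid, 2 * float(stats.t.sf(abs(t), df_resid)),
                       f"contrast {g} vs {ref}")
        )
    return out


def validate_scar_consistency(records: Iterable[LabCrossRecord]) -> list[str]:
    """Return ids of records whose red scar count is below litter size.

    Red scars mark live births, so ``red_scars >= litter_size_birth`` is
    expected up to perinatal deaths; a red count *below* litter size is a
    scoring inconsistency worth flagging.
    """
    bad = []
    for r in records:
        if r.red_scars is not None and r.red_scars < r.litter_size_birth:
            bad.append(r.cross_id)
    return bad
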