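"""Seeded generators of laboratory-cross and wild-population datasets.

No raw data accompany the analyses this package implements, so every stage
is exercised on simulated data with the statistical structure the real
study system exhibits: strong paternal drive (tau about 0.9 through +/t
sires, weaker through +/t dams' mates in double-heterozygote crosses),
Mendelian maternal transmission, prenatal death of every t/t conception,
a mean of about 7.6 implantations per pregnancy with a small background
loss per embryo, a +/t male fraction around 0.55-0.65, roughly a third of
litters with multiple sires, and a t-linked marker allele that every +/t
individual carries exactly once and no +/+ individual carries at all.

All generators take a single seed and derive independent substreams from
it; identical configurations and seeds yield identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import Genotype, TransmissionParams, offspring_distribution
from .incompatibility import LabCrossRecord
from .paternity import WildIndividual
from .popgen import MarkerGenotype
from .transmission import LitterGenotypeCount

logger = logging.getLogger(__name__)

CrossKey = tuple[str, str]  # (sire_gt, dam_gt) as "WT"/"HET"

#: Default sire transmission probabilities per cross.  Drive through +/t
#: sires mated to +/+ dams is 0.897; in double-heterozygote crosses the
#: female background suppresses drive to an effective 0.728, the value
#: whose viable +/t proportion at birth is 0.786.
DEFAULT_TAU: dict[CrossKey, float] = {
    ("HET", "WT"): 0.897,
    ("HET", "HET"): 0.728,
    ("WT", "WT"): 0.0,
    ("WT", "HET"): 0.0,
}


@dataclass
class LabSimConfig:
    """Configuration of the laboratory cross simulator.

    Defaults follow the study conditions: about 30 crosses per type,
    mean 7.58 implantations, background per-embryo loss 0.088
    (0.67 expected yellow scars / 7.58 implantations), 79.3% of crosses
    fecund, and cross-specific sire tau as in ``DEFAULT_TAU``.
    ``dispersion`` is the negative-binomial shape for implantation counts
    (None = Poisson).
    """

    n_crosses: Mapping[CrossKey, int] = field(
        default_factory=lambda: {("HET", "WT"): 30, ("WT", "HET"): 32,
                                 ("HET", "HET"): 32, ("WT", "WT"): 30}
    )
    mean_implantations: float = 7.58
    dispersion: float | None = None
    background_loss: float = 0.088
    fecund_prob: float = 0.793
    tau: Mapping[CrossKey, float] | float = field(
        default_factory=lambda: dict(DEFAULT_TAU)
    )
    dam_tau: float = 0.5
    lethal: bool = True
    seed: int | None = None

    def tau_for(self, cross: CrossKey) -> float:
        if isinstance(self.tau, Mapping):
            return self.tau.get(cross, DEFAULT_TAU.get(cross, 0.0))
        return float(self.tau) if cross[0] == "HET" else 0.0

    def __post_init__(self) -> None:
        for p in (self.background_loss, self.fecund_prob, self.dam_tau):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 0 for n in self.n_crosses.values()):
            raise ValueError("cross counts must be nonnegative")


def _draw_implantations(rng: np.random.Generator, cfg: LabSimConfig) -> int:
    if cfg.dispersion is None:
        return int(rng.poisson(cfg.mean_implantations))
    k = cfg.dispersion
    p = k / (k + cfg.mean_implantations)
    return int(rng.negative_binomial(k, p))


def simulate_lab_experiment(cfg: LabSimConfig) -> list[LabCrossRecord]:
    """Simulate mating crosses with uterine-scar bookkeeping.

    For each cross: the number of implanted embryos is drawn, each embryo
    receives a genotype from the conception-stage transmission model, dies
    if t/t (when lethality is on) or independently with the background loss
    probability; survivors are the litter at birth (= red scars) and deaths
    are the yellow scars.  Surviving pups' genotypes are recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[LabCrossRecord] = []
    i = 0
    for cross, n in sorted(cfg.n_crosses.items()):
        sire, dam = Genotype(cross[0]), Genotype(cross[1])
        params = TransmissionParams(tau=cfg.tau_for(cross), dam_tau=cfg.dam_tau,
                                    lethal=cfg.lethal)
        dist = offspring_distribution(sire, dam, params, stage="conception")
        gts = list(dist)
        probs = np.array([dist[g] for g in gts])
        for _ in range(n):
            i += 1
            if rng.random() >= cfg.fecund_prob:
                records.append(LabCrossRecord(
                    cross_id=f"c{i:04d}", sire_gt=sire, dam_gt=dam,
                    litter_size_birth=0, red_scars=0, yellow_scars=0,
                    experiment=2))
                continue
            n_impl = _draw_implantations(rng, cfg)
            survivors: list[Genotype] = []
            n_dead = 0
            for g_idx in rng.choice(len(gts), size=n_impl, p=probs):
                g = gts[g_idx]
                if (g == Genotype.TT and cfg.lethal) or \
                        rng.random() < cfg.background_loss:
                    n_dead += 1
                else:
                    survivors.append(g)
            records.append(LabCrossRecord(
                cross_id=f"c{i:04d}", sire_gt=sire, dam_gt=dam,
                litter_size_birth=len(survivors),
                red_scars=len(survivors), yellow_scars=n_dead,
                n_weaned=len(survivors), experiment=2,
                pup_genotypes=survivors,
            ))
    return records


def lab_records_to_litters(records: Sequence[LabCrossRecord]) -> list[LitterGenotypeCount]:
    """Convert simulated crosses with pup genotypes into litter counts."""
    out = []
    for r in records:
        pups = getattr(r, "pup_genotypes", None)
        if not pups:
            continue
        n_het = sum(1 for g in pups if g == Genotype.HET)
        out.append(LitterGenotypeCount(
            litter_id=r.cross_id, sire_gt=r.sire_gt, dam_gt=r.dam_gt,
            n_het=n_het, n_wt=len(pups) - n_het,
        ))
    return out


# ---------------------------------------------------------------------------
# wild population
# ---------------------------------------------------------------------------

PreferenceFn = Callable[[Genotype, float], float]


def frequency_proportional(dam_gt: Genotype, het_frac: float) -> float:
    """Random mating: P(sire is +/t) equals the +/t fraction of candidates."""
    return het_frac


@dataclass
class WildSimConfig:
    """Configuration of the wild-population simulator.

    A fixed roster of adults is active over ``months`` monthly time steps;
    each month every female conceives with probability ``breed_prob``, a
    sire is chosen among the males present by the preference function
    (default: frequency-proportional), and with probability
    ``multiple_paternity_prob`` a second, independently chosen sire splits
    the litter.  Pup genotypes follow the transmission model; t/t
    conceptions are removed before output (they die before sampling) while
    the true parentage of surviving pups is retained.
    """

    months: int = 12
    n_males: int = 30
    n_females: int = 30
    het_male_frac: float | Sequence[float] = 0.6
    het_female_frac: float = 0.5
    breed_prob: float = 0.25
    mean_litter_conceived: float = 7.58
    background_loss: float = 0.088
    multiple_paternity_prob: float = 0.3
    preference: PreferenceFn | Mapping[str, float] = frequency_proportional
    tau: float = 0.897
    dam_tau: float = 0.5
    lethal: bool = True
    start: date = date(2004, 1, 1)
    seed: int | None = None

    def het_frac_at(self, month: int) -> float:
        if np.isscalar(self.het_male_frac):
            return float(self.het_male_frac)  # type: ignore[arg-type]
        return float(self.het_male_frac[month])

    def preference_prob(self, dam_gt: Genotype, het_frac: float) -> float:
        if callable(self.preference):
            return float(self.preference(dam_gt, het_frac))
        return float(self.preference[dam_gt.value])

    def __post_init__(self) -> None:
        for p in (self.breed_prob, self.background_loss,
                  self.multiple_paternity_prob, self.het_female_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def simulate_wild_population(
    cfg: WildSimConfig,
) -> tuple[list[WildIndividual], pd.DataFrame]:
    """Simulate a monitored population and its pup parentage table.

    Returns the adult roster and a per-pup DataFrame with columns
    pup_id, litter_id, birth_date, dam_id, sire_id — the schema the
    paternity table builder consumes.  Months with no candidate males skip
    that female's litter with a logged warning.
    """
    rng = np.random.default_rng(cfg.seed)

    # Males enter and leave the population on staggered tenures so the
    # monthly +/t fraction among candidates varies; each male's genotype is
    # HET with the trajectory probability at his entry month.
    males: list[WildIndividual] = []
    for i in range(cfg.n_males):
        start_m = int(rng.integers(-2, max(cfg.months - 1, 1)))
        dur = int(rng.integers(4, 13))
        gt = Genotype.HET if rng.random() < cfg.het_frac_at(
            min(max(start_m, 0), cfg.months - 1)) else Genotype.WT
        males.append(WildIndividual(
            f"M{i:03d}", "M", gt,
            cfg.start + timedelta(days=30 * start_m),
            cfg.start + timedelta(days=30 * (start_m + dur)),
        ))
    n_het_f = int(round(cfg.n_females * cfg.het_female_frac))
    females = [
        WildIndividual(f"F{i:03d}", "F",
                       Genotype.HET if i < n_het_f else Genotype.WT,
                       cfg.start - timedelta(days=40),
                       cfg.start + timedelta(days=30 * cfg.months + 60))
        for i in range(cfg.n_females)
    ]
    roster = males + females

    pup_rows = []
    litter_no = 0
    for month in range(cfg.months):
        birth = cfg.start + timedelta(days=30 * month + 19)
        window_start = birth - timedelta(days=30)
        present = [m for m in males if m.detected_in(window_start, birth)]
        het_males = [m for m in present if m.genotype == Genotype.HET]
        wt_males = [m for m in present if m.genotype == Genotype.WT]
        het_frac = len(het_males) / len(present) if present else float("nan")
        for dam in females:
            if rng.random() >= cfg.breed_prob:
                continue
            if not present:
                logger.warning("month %d: no candidate males; litter skipped", month)
                continue
            litter_no += 1
            lid = f"L{litter_no:04d}"

            def pick_sire() -> WildIndividual:
                p_het = cfg.preference_prob(dam.genotype, het_frac)
                pool = het_males if (het_males and (not wt_males or rng.random() < p_het)) \
                    else wt_males
                return pool[rng.integers(0, len(pool))]

            sires = [pick_sire()]
            if rng.random() < cfg.multiple_paternity_prob:
                second = pick_sire()
                if second.id != sires[0].id:
                    sires.append(second)

            n_conceived = int(rng.poisson(cfg.mean_litter_conceived))
            for j in range(n_conceived):
                sire = sires[int(rng.integers(0, len(sires)))]
                params = TransmissionParams(tau=cfg.tau, dam_tau=cfg.dam_tau,
                                            lethal=cfg.lethal)
                dist = offspring_distribution(sire.genotype, dam.genotype,
                                              params, stage="conception")
                gts = list(dist)
                g = gts[int(rng.choice(len(gts), p=list(dist.values())))]
                if g == Genotype.TT and cfg.lethal:
                    continue  # dies before sampling
                if rng.random() < cfg.background_loss:
                    continue
                pup_rows.append({
                    "pup_id": f"{lid}p{j}",
                    "litter_id": lid,
                    "birth_date": birth,
                    "dam_id": dam.id,
                    "sire_id": sire.id,
                    "pup_gt": g.value,
                })
    pups = pd.DataFrame(
        pup_rows,
        columns=["pup_id", "litter_id", "birth_date", "dam_id", "sire_id", "pup_gt"],
    )
    return roster, pups


# ---------------------------------------------------------------------------
# marker genotypes
# ---------------------------------------------------------------------------

@dataclass
class LocusConfig:
    """One locus: per-class allele frequencies, optionally t-linked.

    For a t-linked locus the first allele is the t-specific allele: every
    +/t individual carries exactly one copy (so its frequency in the +/t
    class must be 0.5) and +/+ individuals never carry it.
    """

    name: str
    freqs: Mapping[str, Sequence[float]]  # t-class -> frequency vector
    alleles: Sequence[str] | None = None
    t_linked: bool = False

    def allele_names(self, k: int) -> list[str]:
        if self.alleles is not None:
            return list(self.alleles)
        return [str(i + 1) for i in range(k)]


@dataclass
class MarkerSimConfig:
    """Configuration of the marker-genotype simulator."""

    loci: Sequence[LocusConfig]
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 15, "HET": 14}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for locus in self.loci:
            for cls, f in locus.freqs.items():
                if abs(sum(f) - 1.0) > 1e-6:
                    raise ValueError(f"{locus.name}/{cls}: frequencies must sum to 1")
            if locus.t_linked:
                het = locus.freqs.get("HET")
                if het is None or abs(het[0] - 0.5) > 1e-9:
                    raise ValueError(
                        f"{locus.name}: t-linked allele frequency must be 0.5 "
                        "in the HET class"
                    )
                wt = locus.freqs.get("WT")
                if wt is not None and wt[0] != 0.0:
                    raise ValueError(
                        f"{locus.name}: t-linked allele must be absent in WT"
                    )


def simulate_marker_genotypes(cfg: MarkerSimConfig) -> list[MarkerGenotype]:
    """Draw individual genotypes per locus and t-class.

    +/+ individuals are drawn at Hardy-Weinberg proportions from their
    class frequency vector.  At t-linked loci, +/t individuals carry
    exactly one copy of the t-specific allele; the second allele is drawn
    from the remaining frequencies renormalized, so observed heterozygosity
    in that class is 1.  At unlinked loci +/t individuals are drawn at HW
    proportions like any other sample.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[MarkerGenotype] = []
    for locus in cfg.loci:
        for cls, n in sorted(cfg.n_per_class.items()):
            if cls not in locus.freqs:
                continue
            f = np.asarray(locus.freqs[cls], dtype=float)
            names = locus.allele_names(len(f))
            for i in range(n):
                ind = f"{cls}{i:03d}"
                if locus.t_linked and cls == "HET":
                    rest = f[1:] / f[1:].sum()
                    a2 = names[1 + rng.choice(len(rest), p=rest)]
                    pair = (names[0], a2)
                else:
                    pair = tuple(names[j] for j in rng.choice(len(f), size=2, p=f))
                out.append(MarkerGenotype(ind, cls, locus.name, pair[0], pair[1]))
    return out
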