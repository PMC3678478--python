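"""Transmission genetics of the mouse t haplotype.

The t haplotype is a selfish variant of chromosome 17 that drives through
heterozygous (+/t) males: a +/t sire transmits the t-bearing gamete with
probability ``tau`` > 0.5 (transmission ratio distortion, TRD), while
transmission through dams is Mendelian unless configured otherwise.  The
haplotype carries a recessive lethal, so t/t conceptions die before birth
and never appear among live-born or sampled animals.

This module is the pure probability core used by the simulators and
estimators: genotype algebra, gamete distributions, exact offspring
genotype distributions at conception and at birth, and the expected
viable proportion of +/t offspring in a double-heterozygote cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Genotype(str, Enum):
    """Diploid state at the t locus: wild-type, t-carrier, or t/t homozygote."""

    WT = "WT"    # +/+
    HET = "HET"  # +/t
    TT = "TT"    # t/t — dies prenatally when lethality is enabled


#: Genotypes that can appear as parents of a cross (t/t males are sterile
#: and t/t females are never sampled alive under full lethality).
VIABLE_PARENTS = (Genotype.WT, Genotype.HET)


@dataclass(frozen=True)
class TransmissionParams:
    """Parameters of t transmission through a mating pair.

    Parameters
    ----------
    tau
        Probability that a +/t sire transmits the t allele (TRD).
    dam_tau
        Probability that a +/t dam transmits the t allele.  Defaults to 0.5
        (Mendelian): female transmission shows no drive, but keeping it a
        parameter lets crosses with distorted female transmission be modeled.
    lethal
        If True, t/t conceptions die before birth and birth-stage
        distributions are renormalized over the surviving genotypes.
    """

    tau: float = 0.9
    dam_tau: float = 0.5
    lethal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not 0.0 <= self.dam_tau <= 1.0:
            raise ValueError(f"dam_tau must lie in [0, 1], got {self.dam_tau}")


def gamete_t_probability(parent: Genotype, t_prob: float) -> float:
    """Probability that a gamete from ``parent`` carries the t allele.

    ``t_prob`` is the transmission probability applying to a heterozygous
    parent (``tau`` for sires, ``dam_tau`` for dams); it is ignored for
    wild-type parents.
    """
    if parent == Genotype.WT:
        return 0.0
    if parent == Genotype.HET:
        return float(t_prob)
    raise ValueError("inviable/sterile parent: t/t cannot contribute to a cross")


def offspring_distribution(
    sire: Genotype,
    dam: Genotype,
    params: TransmissionParams,
    stage: str = "birth",
) -> dict[Genotype, float]:
    """Exact offspring genotype distribution for a single cross.

    The conception-stage distribution is the outer product of the parental
    gamete distributions.  At the birth stage, t/t zygotes are removed and
    the distribution renormalized whenever ``params.lethal`` is set.

    Parameters
    ----------
    sire, dam
        Parental genotypes; must be WT or HET.
    params
        Transmission parameters (sire tau, dam tau, lethality flag).
    stage
        ``"conception"`` or ``"birth"``.

    Returns
    -------
    dict
        Mapping genotype -> probability, summing to 1.
    """
    if stage not in ("conception", "birth"):
        raise ValueError(f"stage must be 'conception' or 'birth', got {stage!r}")
    ps = gamete_t_probability(sire, params.tau)
    pd = gamete_t_probability(dam, params.dam_tau)

    dist = {
        Genotype.WT: (1.0 - ps) * (1.0 - pd),
        Genotype.HET: ps * (1.0 - pd) + (1.0 - ps) * pd,
        Genotype.TT: ps * pd,
    }
    if stage == "birth" and params.lethal:
        dist[Genotype.TT] = 0.0
        total = dist[Genotype.WT] + dist[Genotype.HET]
        if total <= 0.0:
            raise ValueError("no viable offspring: all conceptions are t/t")
        dist = {g: p / total for g, p in dist.items()}
    return dist


def expected_het_proportion(tau: float) -> float:
    """Expected +/t proportion at birth in a +/t x +/t cross under lethality.

    With sire transmission ``tau`` and Mendelian dams, conceptions are t/t
    with probability tau/2, +/t with probability 1/2, and +/+ with
    probability (1 - tau)/2.  Removing the inviable t/t class leaves

        0.5 / (0.5 + (1 - tau) / 2)

    which increases strictly with tau and reaches 1 at tau = 1.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    return 0.5 / (0.5 + (1.0 - tau) / 2.0)


def tau_from_het_proportion(p_het: float) -> float:
    """Inverse of :func:`expected_het_proportion`.

    Returns the sire transmission probability tau implied by an observed
    viable +/t proportion ``p_het`` in a double-heterozygote cross
    (tau = 2 - 1/p_het).  Useful for back-calculating an effective tau from
    a birth-stage proportion.
    """
    if not 0.5 <= p_het <= 1.0:
        raise ValueError(f"p_het must lie in [0.5, 1], got {p_het}")
    return 2.0 - 1.0 / p_het
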