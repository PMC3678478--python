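import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import tdrive as td
from tdrive.genetics import Genotype


@pytest.fixture(scope="session")
def lab_records():
    """Simulated scar-scored crosses at the default study conditions."""
    cfg = td.LabSimConfig(seed=42)
    return td.simulate_lab_experiment(cfg)


@pytest.fixture(scope="session")
def wild_data():
    """A simulated monitored population with random (frequency-proportional) mating."""
    cfg = td.WildSimConfig(seed=7, months=18, breed_prob=0.3)
    roster, pups = td.simulate_wild_population(cfg)
    return roster, pups


@pytest.fixture(scope="session")
def paternity_table(wild_data):
    roster, pups = wild_data
    rows = td.build_paternity_table(pups, roster, window_days=30)
    return td.rows_to_frame(rows)


@pytest.fixture(scope="session")
def marker_genotypes():
    """Two t-linked loci and one neutral locus for 15 WT / 14 HET mice."""
    loci = [
        td.LocusConfig(
            "D17Mit28",
            {"WT": [0.0, 0.233, 0.067, 0.367, 0.333],
             "HET": [0.5, 0.036, 0.107, 0.25, 0.107]},
            t_linked=True,
        ),
        td.LocusConfig(
            "Aalpha",
            {"WT": [0.0, 0.167, 0.067, 0.766],
             "HET": [0.5, 0.036, 0.0, 0.464]},
            t_linked=True,
        ),
        td.LocusConfig(
            "neutral1",
            {"WT": [0.4, 0.3, 0.3], "HET": [0.4, 0.3, 0.3]},
        ),
    ]
    return td.simulate_marker_genotypes(td.MarkerSimConfig(loci=loci, seed=5))


def make_litters(pairs, sire=Genotype.HET, dam=Genotype.WT):
    """Litter counts from a list of (n_het, n_wt) tuples."""
    return [
        td.LitterGenotypeCount(f"l{i}", sire, dam, h, w)
        for i, (h, w) in enumerate(pairs)
    ]
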