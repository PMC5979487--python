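import numpy as np
import pytest

from plastdiff.plastome_io import Feature, Plastome
from plastdiff.pipeline import run_compare
from plastdiff.synthetic_plastomes import simulate_pair, small_config


def make_plastome(seq, features=(), regions=None, genome_id="toy"):
    """Toy plastome helper; defaults to a degenerate all-LSC partition."""
    n = len(seq)
    if regions is None:
        regions = {"LSC": (0, n), "IRb": (n, n), "SSC": (n, n), "IRa": (n, n)}
    return Plastome(genome_id, seq, regions, list(features))


@pytest.fixture(scope="session")
def toy_factory():
    return make_plastome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated pair shared across tests."""
    cfg = small_config(seed=11)
    genome_a, genome_b, manifest = simulate_pair(cfg)
    return cfg, genome_a, genome_b, manifest


@pytest.fixture(scope="session")
def sim_small_report(sim_small):
    _, genome_a, genome_b, _ = sim_small
    return run_compare(genome_a, genome_b)


@pytest.fixture(scope="session")
def sim_full():
    """One study-scale simulated pair (160 kb, 75 SNPs / 80 indels)."""
    from plastdiff.synthetic_plastomes import SimConfig

    cfg = SimConfig(seed=42)
    genome_a, genome_b, manifest = simulate_pair(cfg)
    return cfg, genome_a, genome_b, manifest


def random_dna(rng, n, gc=0.38):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def dna_factory():
    return random_dna


def feature(name, ftype, strand, exons):
    return Feature(name, ftype, strand, [tuple(e) for e in exons])
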