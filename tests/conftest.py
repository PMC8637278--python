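import numpy as np
import pytest

from stepscore import Allele, EpletRegistry, HlaWorld, make_hla_world

AA = "ACDEFGHIKLMNPQRSTVWY"


def _seq(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def world() -> HlaWorld:
    """Default synthetic world shared by read-only tests."""
    return make_hla_world(seed=1)


@pytest.fixture(scope="session")
def hwe_world() -> HlaWorld:
    """Two-haplotype world realizing the 0.2 / 0.1 frequency configuration.

    Both haplotypes carry the same A and B antigens and differ only in the
    DRB1 allele (two alleles of the same DR4 serology), so the serological
    typing (A1, B1, DR4) is compatible with exactly three genotypes.
    """
    rng = np.random.default_rng(99)
    base = _seq(rng, 24)
    drb1_a = base[:-1] + ("A" if base[-1] != "A" else "C")
    alleles = (
        Allele("A", "A*01:01", "A1", _seq(rng, 24)),
        Allele("B", "B*01:01", "B1", _seq(rng, 24)),
        Allele("DRB1", "DRB1*04:01", "DR4", base),
        Allele("DRB1", "DRB1*04:05", "DR4", drb1_a),
    )
    registry = EpletRegistry(eplets={
        "A*01:01": {"eA1"}, "B*01:01": {"eB1"},
        "DRB1*04:01": {"eD1", "eD2"}, "DRB1*04:05": {"eD1", "eD3"},
    })
    return HlaWorld(
        loci=("A", "B", "DRB1"),
        alleles=alleles,
        haplotypes=(
            (("A*01:01", "B*01:01", "DRB1*04:01"), 0.2),
            (("A*01:01", "B*01:01", "DRB1*04:05"), 0.1),
        ),
        eplet_registry=registry,
        predictor_seed=7,
    )


def random_world(seed: int, n_haplotypes: int = 6) -> HlaWorld:
    """Small random world for oracle-equivalence sweeps."""
    return make_hla_world(
        seed=seed,
        n_alleles_per_locus={"A": 3, "B": 3, "DRB1": 4},
        seq_len=30,
        n_haplotypes=n_haplotypes,
    )
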