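"""Weighted indirectly-presentable T-cell epitope (PIRCHE-II style) sets.

A candidate T-cell epitope is a 9-residue core peptide from a *target* HLA
protein (a donor mismatch or an antibody-identified immunizer) that

* is absent from every HLA protein of the recipient ("non-self"), and
* is predicted to be presented by one of the recipient's two HLA-DRB1
  molecules (the only presenting locus considered).

Because recipients are typed serologically, both the recipient's own
genotype and a serological target resolve to several weighted high-resolution
candidates; a (core, presenter) pair's weight is the total probability mass
of the joint configurations that produce it, capped at 1.

Presentation is delegated to a pluggable :class:`PresentationPredictor`.  The
default is a deterministic per-DRB1 position-weight-matrix surrogate seeded
from the reference world, so the whole pipeline runs without external
prediction services; an adapter implementing the same one-method contract can
substitute a NetMHCIIpan-class tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Protocol, Sequence

import numpy as np

from .hla_core import AA_ALPHABET, LOCUS_GROUP, Allele, HlaError, SerologicalTyping, UnknownAlleleError
from .imputation import enumerate_genotypes

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_world import HlaWorld

CORE_LENGTH = 9

#: origin tag for donor-derived ("recall") epitope sets
ORIGIN_DONOR = "DONOR"


class PresentationPredictor(Protocol):
    """Deterministic (core 9-mer, DRB1 allele name) -> presented contract."""

    def presented(self, core: str, drb1: str) -> bool:  # pragma: no cover
        ...


@dataclass(frozen=True)
class PeptideRecord:
    """One presentable epitope: a 9-mer core on a specific DRB1 presenter."""

    core: str
    presenter: str
    source_allele: str
    weight: float
    origin: str = ORIGIN_DONOR

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH:
            raise ValueError(f"core must be {CORE_LENGTH} residues: {self.core!r}")

    def key(self) -> tuple[str, str]:
        return (self.core, self.presenter)


@dataclass(frozen=True)
class PircheResult:
    """A weighted epitope set; the score is the sum of the weights."""

    peptides: tuple[PeptideRecord, ...]

    @property
    def score(self) -> float:
        return float(sum(p.weight for p in self.peptides))


class PwmPredictor:
    """Seeded position-weight-matrix presentation surrogate.

    Each DRB1 allele gets an independent 9 x 20 standard-normal score matrix
    drawn from ``seed``; a core's score is the mean matrix entry over its
    residues and the allele-specific threshold is calibrated (on cores drawn
    from the same stream) so that a fraction `p_present` of random cores is
    presented.  Purely deterministic: identical inputs give identical outputs.
    """

    _CALIBRATION_CORES = 4000

    def __init__(self, drb1_alleles: Sequence[str], seed: int, p_present: float = 0.30):
        if not 0.0 < p_present < 1.0:
            raise ValueError("p_present must be in (0, 1)")
        self.p_present = p_present
        self.seed = int(seed)
        self._matrices: dict[str, np.ndarray] = {}
        self._thresholds: dict[str, float] = {}
        self._cache: dict[tuple[str, str], bool] = {}
        for i, name in enumerate(sorted(drb1_alleles)):
            rng = np.random.default_rng([self.seed, i])
            w = rng.normal(size=(CORE_LENGTH, len(AA_ALPHABET)))
            sample = rng.integers(0, len(AA_ALPHABET),
                                  size=(self._CALIBRATION_CORES, CORE_LENGTH))
            scores = w[np.arange(CORE_LENGTH), sample].mean(axis=1)
            self._matrices[name] = w
            self._thresholds[name] = float(np.quantile(scores, 1.0 - p_present))

    def presented(self, core: str, drb1: str) -> bool:
        key = (core, drb1)
        hit = self._cache.get(key)
        if hit is None:
            try:
                w = self._matrices[drb1]
            except KeyError:
                raise UnknownAlleleError(f"predictor has no matrix for {drb1!r}") from None
            idx = [AA_ALPHABET.index(aa) for aa in core]
            score = float(w[np.arange(CORE_LENGTH), idx].mean())
            hit = score >= self._thresholds[drb1]
            self._cache[key] = hit
        return hit


def derive_nonself_cores(target: Allele, self_proteome: set[str]) -> set[str]:
    """All 9-mer windows of `target` absent from every self protein.

    The self proteome is the set of the recipient's own HLA protein sequences
    (all considered loci) under the genotype configuration being evaluated;
    a window counts as self if it occurs as a substring of any of them.
    """
    seq = target.sequence
    if len(seq) < CORE_LENGTH:
        raise ValueError(f"{target.name}: sequence shorter than {CORE_LENGTH}")
    windows = {seq[i:i + CORE_LENGTH] for i in range(len(seq) - CORE_LENGTH + 1)}
    return {w for w in windows if not any(w in s for s in self_proteome)}


def _target_candidates(target: str, world: "HlaWorld") -> list[tuple[str, float]]:
    """Resolve a target token to weighted high-resolution alleles.

    A two-field allele name resolves to itself with weight 1; a serological
    label resolves to all alleles carrying it, weighted by their marginal
    haplotype frequency (uniform if none appears in a haplotype).
    """
    if target in world.allele_by_name:
        return [(target, 1.0)]
    members = [a.name for a in world.alleles if a.serology == target]
    if not members:
        raise UnknownAlleleError(f"target {target!r} is neither an allele nor a serology label")
    freqs = {name: world.allele_frequency(name) for name in members}
    total = sum(freqs.values())
    if total <= 0:
        return [(name, 1.0 / len(members)) for name in sorted(members)]
    return [(name, freqs[name] / total) for name in sorted(members)]


def pirche_for_targets(
    targets: Sequence[str],
    recipient_typing: SerologicalTyping,
    recipient_drb1: tuple[str, ...],
    world: "HlaWorld",
    predictor: PresentationPredictor,
    origin: str = ORIGIN_DONOR,
) -> PircheResult:
    """Weighted presentable-epitope set for a list of target HLA.

    Parameters
    ----------
    targets : sequence of str
        Allele names or serological labels of the immunizing / mismatched HLA.
    recipient_typing : SerologicalTyping
        The recipient's typing; its genotype candidates define the self
        proteome of each configuration.
    recipient_drb1 : tuple of str
        The recipient's extrapolated two-field DRB1 alleles — the only
        presenters considered.  A homozygous recipient passes one allele (or
        the same allele twice; duplicates are collapsed).
    predictor : PresentationPredictor
        Presentation oracle for (core, DRB1) pairs.
    origin : str
        Tag stored on every emitted record (e.g. ``"DONOR"`` or an
        immunizer bead id).

    Within one joint configuration a (core, presenter) pair counts once; its
    final weight is the summed probability of all configurations that produce
    it, capped at 1.
    """
    presenters = tuple(dict.fromkeys(recipient_drb1))
    for d in presenters:
        if d not in world.allele_by_name:
            raise UnknownAlleleError(f"recipient DRB1 {d!r} not in reference")
        if world.allele_by_name[d].locus != "DRB1":
            raise HlaError(f"presenter {d!r} is not a DRB1 allele")
    drb1_seqs = {world.allele_by_name[d].sequence for d in presenters}

    genotypes = enumerate_genotypes(recipient_typing, world)
    # Fixing the extrapolated DRB1 replaces each candidate's DRB1 alleles in
    # the self proteome; candidates that collide afterwards merge their weight.
    self_sets: dict[frozenset[str], float] = {}
    drb1_idx = world.loci.index("DRB1")
    for g in genotypes:
        seqs = {world.allele_by_name[n].sequence
                for i, n in enumerate(g.all_alleles())
                if (i % len(world.loci)) != drb1_idx
                and world.allele_by_name[n].locus != "DRB1"} | drb1_seqs
        key = frozenset(seqs)
        self_sets[key] = self_sets.get(key, 0.0) + g.weight

    acc: dict[tuple[str, str], float] = {}
    src: dict[tuple[str, str], str] = {}
    for target in targets:
        for allele_name, t_weight in _target_candidates(target, world):
            allele = world.allele_by_name[allele_name]
            for self_seqs, g_weight in self_sets.items():
                weight = g_weight * t_weight
                if weight <= 0.0:
                    continue
                for core in derive_nonself_cores(allele, set(self_seqs)):
                    for d in presenters:
                        if predictor.presented(core, d):
                            k = (core, d)
                            acc[k] = acc.get(k, 0.0) + weight
                            src.setdefault(k, allele_name)
    peptides = tuple(
        PeptideRecord(core=c, presenter=d, source_allele=src[(c, d)],
                      weight=min(w, 1.0), origin=origin)
        for (c, d), w in sorted(acc.items()))
    return PircheResult(peptides=peptides)
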