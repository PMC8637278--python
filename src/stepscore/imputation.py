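"""Serology-to-high-resolution genotype imputation and the DRB1 gate.

A serological typing is compatible with many two-field genotypes.  Candidate
genotypes are enumerated as unordered pairs of reference haplotypes whose
serological projection reproduces the typing, weighted by a Hardy-Weinberg
prior over haplotype frequencies (2*f1*f2 for heterozygous pairs) and
normalized to sum 1.

For the presenting locus the analysis needs a *single* two-field HLA-DRB1
allele per serological DR antigen.  Each DR label is therefore resolved to
the compatible allele most likely to be present in the true genotype; if that
likelihood falls below a confidence threshold (default 0.65) the label — and
in pipeline use, the recipient — is excluded rather than risk scoring against
a wrong presenter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from .hla_core import HlaError, SerologicalTyping

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_world import HlaWorld

#: sentinel returned when no DRB1 allele clears the confidence gate
EXCLUDED = "EXCLUDED"

#: default confidence required to fix a two-field DRB1 allele
DRB1_WEIGHT_THRESHOLD = 0.65

_TIE_EPS = 1e-12


class InsufficientTypingError(HlaError):
    """No reference haplotype pair is consistent with the typing."""


class Drb1ExclusionError(HlaError):
    """No DRB1 allele reached the confidence threshold for some DR label."""

    def __init__(self, typing: SerologicalTyping, extrapolations: dict):
        self.extrapolations = extrapolations
        failed = [lab for lab, e in extrapolations.items() if e.chosen is None]
        super().__init__(f"DRB1 weight below threshold for DR label(s) {failed}")


@dataclass(frozen=True)
class WeightedGenotype:
    """Unordered haplotype pair with its normalized posterior weight."""

    haplotype_1: tuple[str, ...]
    haplotype_2: tuple[str, ...]
    weight: float

    def alleles_at(self, locus_index: int) -> tuple[str, str]:
        return (self.haplotype_1[locus_index], self.haplotype_2[locus_index])

    def all_alleles(self) -> tuple[str, ...]:
        return self.haplotype_1 + self.haplotype_2


@dataclass(frozen=True)
class Drb1Extrapolation:
    """Resolution of one serological DR label to a two-field DRB1 allele.

    `chosen` is ``None`` when no allele reaches the threshold (or the top two
    tie exactly); `marginals` is the full exclusive weight distribution over
    compatible alleles and sums to 1.
    """

    label: str
    chosen: str | None
    max_weight: float
    marginals: Mapping[str, float]

    @property
    def excluded(self) -> bool:
        return self.chosen is None


def _projection_matches(world: "HlaWorld", haplo_pair, typing: SerologicalTyping) -> bool:
    """Does the serological projection of the pair reproduce the typing?

    Untyped locus groups are unconstrained (marginalized over).
    """
    from .hla_core import LOCUS_GROUP

    by_group: dict[str, set[str]] = {}
    for hap in haplo_pair:
        for locus, name in zip(world.loci, hap):
            by_group.setdefault(LOCUS_GROUP[locus], set()).add(world.serology_of(name))
    for group, labels in typing.labels.items():
        if by_group.get(group, set()) != set(labels):
            return False
    return True


def enumerate_genotypes(typing: SerologicalTyping, world: "HlaWorld") -> list[WeightedGenotype]:
    """Enumerate weighted high-resolution genotype candidates for a typing.

    Candidates are all unordered haplotype pairs consistent with the typing;
    the prior weight is ``f1*f2`` for homozygous pairs and ``2*f1*f2``
    otherwise (Hardy-Weinberg), renormalized to sum 1 over the candidates.

    Raises
    ------
    InsufficientTypingError
        If no haplotype pair is consistent with the typing.
    """
    haps = world.normalized_haplotypes()
    candidates: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    for i, (h1, f1) in enumerate(haps):
        for h2, f2 in haps[i:]:
            prior = f1 * f2 if h1 == h2 else 2.0 * f1 * f2
            if _projection_matches(world, (h1, h2), typing):
                candidates.append((h1, h2, prior))
    if not candidates:
        raise InsufficientTypingError(
            f"no haplotype pair consistent with typing {dict(typing.labels)}")
    total = sum(p for _, _, p in candidates)
    return [WeightedGenotype(h1, h2, p / total) for h1, h2, p in candidates]


def drb1_marginals(
    genotypes: list[WeightedGenotype], label: str, world: "HlaWorld"
) -> dict[str, float]:
    weights, _ = _drb1_weights(genotypes, label, world)
    return weights


def _drb1_weights(
    genotypes: list[WeightedGenotype], label: str, world: "HlaWorld"
) -> tuple[dict[str, float], dict[str, float]]:
    """Exclusive per-allele weights for one serological DR label.

    The weight of allele *a* is the total genotype weight for which *a* is the
    most plausible realization of `label`: alleles are ranked by their overall
    probability of being present in the genotype, and each genotype's weight
    is attributed to its highest-ranked present compatible allele.  Weights
    therefore sum to 1 and the top allele's weight equals the probability that
    this allele truly is in the genotype.
    """
    idx = world.loci.index("DRB1")
    presence: dict[str, float] = {}
    per_geno: list[tuple[float, set[str]]] = []
    for g in genotypes:
        compatible = {a for a in g.alleles_at(idx) if world.serology_of(a) == label}
        if not compatible:
            continue
        per_geno.append((g.weight, compatible))
        for a in compatible:
            presence[a] = presence.get(a, 0.0) + g.weight
    if not presence:
        raise InsufficientTypingError(f"no genotype realizes DR label {label!r}")
    rank = sorted(presence, key=lambda a: (-presence[a], a))
    order = {a: i for i, a in enumerate(rank)}
    weights = dict.fromkeys(rank, 0.0)
    for w, compatible in per_geno:
        weights[min(compatible, key=order.__getitem__)] += w
    return weights, presence


def extrapolate_drb1(
    typing: SerologicalTyping,
    world: "HlaWorld",
    threshold: float = DRB1_WEIGHT_THRESHOLD,
) -> dict[str, Drb1Extrapolation]:
    """Resolve each serological DR label to a two-field DRB1 allele, gated.

    For each DR label the exclusive marginal distribution over compatible
    DRB1 alleles is computed from the genotype candidates; the top allele is
    chosen iff its weight is at least `threshold`.  An exact tie between the
    two best alleles is never resolved by chance: the label is excluded.
    """
    if "DR" not in typing.labels:
        raise HlaError("typing has no DR locus group")
    genotypes = enumerate_genotypes(typing, world)
    out: dict[str, Drb1Extrapolation] = {}
    for label in typing.labels["DR"]:
        weights, presence = _drb1_weights(genotypes, label, world)
        ordered = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
        top_allele, top_w = ordered[0]
        # a tie is judged on genotype-presence probability: exclusive
        # attribution breaks presence ties by name, which must never decide
        # the extrapolation
        pres = sorted(presence.values(), reverse=True)
        tied = len(pres) > 1 and abs(pres[1] - pres[0]) <= _TIE_EPS
        chosen = top_allele if (top_w >= threshold and not tied) else None
        out[label] = Drb1Extrapolation(
            label=label, chosen=chosen, max_weight=top_w, marginals=weights)
    return out


def resolve_drb1(
    typing: SerologicalTyping,
    world: "HlaWorld",
    threshold: float = DRB1_WEIGHT_THRESHOLD,
) -> tuple[str, ...]:
    """Extrapolated DRB1 allele per DR label; raises if any label is gated out.

    Returns one allele name per serological DR label (one for homozygous-coded
    recipients, two otherwise).

    Raises
    ------
    Drb1ExclusionError
        If any DR label has no allele with weight >= `threshold`.
    """
    ext = extrapolate_drb1(typing, world, threshold)
    if any(e.excluded for e in ext.values()):
        raise Drb1ExclusionError(typing, ext)
    return tuple(e.chosen for e in ext.values())  # type: ignore[misc]


def max_weight_genotype(typing: SerologicalTyping, world: "HlaWorld") -> WeightedGenotype:
    """Single most likely genotype candidate (deterministic tie-break by name).

    Used where a downstream algorithm needs one fixed high-resolution typing
    (eplet counting) and no confidence gate applies.
    """
    genotypes = enumerate_genotypes(typing, world)
    return min(genotypes, key=lambda g: (-g.weight, tuple(sorted(g.all_alleles()))))
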