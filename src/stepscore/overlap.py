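"""PIRCHE-II overlap between immunizer and donor epitope sets; STEP score.

The central statistic: a donor-derived ("recall") epitope contributes to the
overlap iff the same 9-mer core, presented by the same recipient HLA-DRB1
molecule, also appears in the immunizer-derived set.  Shared peptides carry
the weight computed on the recall side; immunizer-side weights only decide
membership.  For a DRB1-homozygous recipient the comparison runs on the
single distinct allele, and a core shared with several positive beads counts
once.  The overlap score is the sum of the surviving recall weights and

    STEP = ln(overlap score + 1)

is its log transform, the covariate used in the survival models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .hla_core import HlaError
from .pirche import PeptideRecord, PircheResult


class OverlapContractError(HlaError):
    """A peptide names a presenter outside the recipient's DRB1 pair."""


@dataclass(frozen=True)
class OverlapResult:
    shared: tuple[PeptideRecord, ...]
    overlap_score: float
    step_score: float


def merge_duplicate_peptides(peptides: Sequence[PeptideRecord]) -> list[PeptideRecord]:
    """Merge records with the same (core, presenter), summing their weights.

    Output is canonically sorted by (core, presenter) so the result is
    independent of input order; the first-seen source allele and origin tag
    are retained on the merged record.
    """
    merged: dict[tuple[str, str], PeptideRecord] = {}
    for p in peptides:
        k = p.key()
        if k in merged:
            merged[k] = replace(merged[k], weight=merged[k].weight + p.weight)
        else:
            merged[k] = p
    return [merged[k] for k in sorted(merged)]


def step_transform(overlap: float) -> float:
    """STEP score: natural log of (overlap score + 1); domain overlap >= 0."""
    if overlap < 0:
        raise ValueError(f"overlap score must be non-negative, got {overlap}")
    return math.log1p(overlap)


def overlap_score(
    immunizers: PircheResult,
    recall: PircheResult,
    recipient_drb1: tuple[str, ...],
) -> OverlapResult:
    """Shared epitopes between immunizer and recall sets, per DRB1 presenter.

    `recall` must already be merged per (core, presenter) (see
    :func:`merge_duplicate_peptides`); the recall weight is allocated to each
    shared peptide.  Inputs are not mutated.

    Raises
    ------
    OverlapContractError
        If any peptide names a presenter outside `recipient_drb1`.
    """
    presenters = set(recipient_drb1)
    for p in (*immunizers.peptides, *recall.peptides):
        if p.presenter not in presenters:
            raise OverlapContractError(
                f"peptide {p.core} presented by {p.presenter}, not a recipient DRB1")
    # keys are (core, presenter): a core reaching the immunizer set from
    # several positive beads collapses to one key, so cross-bead duplicates
    # never double-count.
    immunizer_keys = {p.key() for p in immunizers.peptides}
    shared = tuple(p for p in merge_duplicate_peptides(recall.peptides)
                   if p.key() in immunizer_keys)
    score = float(sum(p.weight for p in shared))
    return OverlapResult(shared=shared, overlap_score=score,
                         step_score=step_transform(score))
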