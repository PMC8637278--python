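"""Luminex single-antigen bead (LSA) normalization and immunizer selection.

Each bead of a single-antigen panel carries one HLA protein (or one
alpha/beta heterodimer for DQ/DP); its mean fluorescence intensity (MFI)
reflects antibody binding in the recipient's serum.  Raw MFI is normalized
per recipient per locus group by dividing by the MFI of the lowest ranked
antigen (LRA) in that group, giving a ratio >= 1 with the group minimum
exactly 1.

Four selection approaches turn a normalized panel into the recipient's
theoretical immunizing HLA:

A. beads with ratio strictly above 5;
B. the bead(s) attaining the highest positive raw MFI of the whole panel
   (ties all included) — the default used downstream;
C. beads in the upper 5% of the recipient's ratio range,
   ``cutoff = min + (max - min) * (1 - 0.05)``, inclusive;
D. as C with the upper 1% of the range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .hla_core import HlaError, LOCUS_GROUPS


class BeadPanelError(HlaError):
    """Structural or normalization error in a bead panel."""


RATIO_THRESHOLD_A = 5.0
UPPER_RANGE_FRACTION = {"C": 0.05, "D": 0.01}
APPROACHES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class Bead:
    """One single-antigen bead; `alleles` has two entries for DQ/DP dimers."""

    bead_id: str
    locus_group: str
    alleles: tuple[str, ...]
    raw_mfi: float
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.locus_group not in LOCUS_GROUPS:
            raise BeadPanelError(f"bead {self.bead_id}: unknown locus group {self.locus_group!r}")
        if not 1 <= len(self.alleles) <= 2:
            raise BeadPanelError(f"bead {self.bead_id}: expected 1-2 chains")
        if self.raw_mfi < 0:
            raise BeadPanelError(f"bead {self.bead_id}: negative MFI")


@dataclass(frozen=True)
class BeadPanel:
    recipient_id: str
    beads: tuple[Bead, ...]

    def __post_init__(self) -> None:
        if not self.beads:
            raise BeadPanelError(f"panel {self.recipient_id}: no beads")

    @property
    def ratios(self) -> tuple[float, ...]:
        if any(b.ratio is None for b in self.beads):
            raise BeadPanelError(f"panel {self.recipient_id}: ratios not computed")
        return tuple(b.ratio for b in self.beads)  # type: ignore[misc]


@dataclass(frozen=True)
class ImmunizerSelection:
    """Beads selected as the theoretical immunizing HLA under one approach."""

    approach: str
    beads: tuple[Bead, ...]
    cutoffs: dict[str, float]

    def target_alleles(self) -> tuple[str, ...]:
        """All chains of the selected beads, deduplicated, order-stable."""
        return tuple(dict.fromkeys(a for b in self.beads for a in b.alleles))


def normalize_panel(panel: BeadPanel) -> BeadPanel:
    """Attach MFI/LRA ratios: raw MFI over the locus-group minimum.

    Idempotent on the ratios.  A locus group whose minimum raw MFI is not
    strictly positive cannot be normalized and raises (no epsilon fudging).
    """
    minima: dict[str, float] = {}
    for b in panel.beads:
        minima[b.locus_group] = min(minima.get(b.locus_group, np.inf), b.raw_mfi)
    bad = sorted(g for g, m in minima.items() if m <= 0)
    if bad:
        raise BeadPanelError(
            f"panel {panel.recipient_id}: lowest ranked antigen MFI <= 0 in locus group(s) {bad}")
    beads = tuple(replace(b, ratio=b.raw_mfi / minima[b.locus_group]) for b in panel.beads)
    return BeadPanel(recipient_id=panel.recipient_id, beads=beads)


def select_immunizers(panel: BeadPanel, approach: str) -> ImmunizerSelection:
    """Select the positive (immunizing) beads of a normalized panel.

    Approach A may legitimately select nothing (no bead above the absolute
    threshold); B always selects at least one bead.
    """
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}, got {approach!r}")
    ratios = panel.ratios
    cutoffs: dict[str, float] = {}
    if approach == "A":
        cutoffs["ratio"] = RATIO_THRESHOLD_A
        chosen = tuple(b for b in panel.beads if b.ratio > RATIO_THRESHOLD_A)
    elif approach == "B":
        positive = [b for b in panel.beads if b.raw_mfi > 0]
        if not positive:
            raise BeadPanelError(f"panel {panel.recipient_id}: no positive bead")
        top = max(b.raw_mfi for b in positive)
        cutoffs["raw_mfi"] = top
        chosen = tuple(b for b in positive if b.raw_mfi == top)
    else:
        lo, hi = min(ratios), max(ratios)
        cutoff = lo + (hi - lo) * (1.0 - UPPER_RANGE_FRACTION[approach])
        cutoffs["ratio"] = cutoff
        chosen = tuple(b for b in panel.beads if b.ratio >= cutoff)
    return ImmunizerSelection(approach=approach, beads=chosen, cutoffs=cutoffs)


def evaluate_approach_auc(
    step_scores: Sequence[float], failed_10y: Sequence[bool]
) -> float:
    """Rank-based (Mann-Whitney) AUC of a score against 10-year failure.

    Convention: higher score -> failure; tied scores earn half credit.  Both
    outcome classes must be present.
    """
    scores = np.asarray(step_scores, dtype=float)
    failed = np.asarray(failed_10y, dtype=bool)
    if scores.shape != failed.shape:
        raise ValueError("step_scores and failed_10y must have equal length")
    n_pos, n_neg = int(failed.sum()), int((~failed).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes are required to compute an AUC")
    u = stats.mannwhitneyu(scores[failed], scores[~failed], alternative="two-sided").statistic
    return float(u) / (n_pos * n_neg)
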