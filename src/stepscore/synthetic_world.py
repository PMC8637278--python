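"""Self-consistent synthetic HLA universe, bead panels and cohorts.

Real STEP analyses need IMGT/HLA protein sequences, NMDP haplotype frequency
tables, vendor Luminex panels and a transplant registry — none of which are
redistributable.  This module generates a closed stand-in world with known
ground truth so that every downstream stage (imputation, epitope derivation,
bead selection, overlap scoring, survival modelling) is exercisable and
testable end to end:

* a closed allele universe per locus, with serology groups of configurable
  size and mature-chain protein sequences that are identical except at a
  small set of polymorphic positions (so non-self 9-mers are guaranteed to
  exist between any two alleles of a locus);
* a haplotype frequency table over those alleles (Dirichlet frequencies,
  no linkage-disequilibrium structure);
* single-antigen bead panels in which a chosen immunizer allele carries the
  maximum raw MFI by construction, over a uniform background;
* cohorts whose failure times follow an exponential proportional-hazards
  model with a linear predictor over the standard transplant covariates —
  including the STEP score, which is computed through the real scoring
  pipeline, never sampled independently.

Every generator is a pure function of its seed and parameters.  Plain-text
writers/readers (FASTA, TSV, CSV) round-trip all generated objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hla_core import (AA_ALPHABET, EPLET_LOCI, LOCI, LOCUS_GROUP, Allele,
                       EpletRegistry, HlaError, SerologicalTyping,
                       UnknownAlleleError)
from .lsa import Bead, BeadPanel
from .survival import FOLLOW_UP_CAP_YEARS, CohortRecord

#: study-condition defaults for a generated world
DEFAULT_ALLELES_PER_LOCUS: dict[str, int] = {"A": 4, "B": 4, "C": 4, "DRB1": 6, "DQB1": 4}
DEFAULT_SEQ_LEN = 60
DEFAULT_N_HAPLOTYPES = 12
DEFAULT_ALLELES_PER_SEROLOGY = 2

#: study-condition defaults for generated bead panels
DEFAULT_SIGNAL_MFI = 5000.0
DEFAULT_BACKGROUND_MFI = (50.0, 500.0)

#: study-condition defaults for generated cohorts (rates per year)
DEFAULT_BASELINE_HAZARD = 0.02
DEFAULT_DEATH_RATE = 0.015


class ConfigurationError(HlaError, ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True, eq=False)
class HlaWorld:
    """A closed synthetic HLA reference (hashable by identity).

    `haplotypes` holds (allele-name tuple over `loci`, frequency) pairs;
    frequencies are renormalized to sum 1 on use.  `predictor_seed`
    parameterizes the surrogate presentation predictor tied to this world.
    """

    loci: tuple[str, ...]
    alleles: tuple[Allele, ...]
    haplotypes: tuple[tuple[tuple[str, ...], float], ...]
    eplet_registry: EpletRegistry
    predictor_seed: int
    predictor_p_present: float = 0.30
    allele_by_name: dict[str, Allele] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_by_name", {a.name: a for a in self.alleles})
        for hap, freq in self.haplotypes:
            if len(hap) != len(self.loci):
                raise ConfigurationError("haplotype arity does not match loci")
            for name in hap:
                if name not in self.allele_by_name:
                    raise ConfigurationError(f"haplotype references unknown allele {name!r}")
            if not 0.0 < freq <= 1.0:
                raise ConfigurationError(f"haplotype frequency {freq} outside (0, 1]")
        total = sum(f for _, f in self.haplotypes)
        if total > 1.0 + 1e-9:
            raise ConfigurationError(f"haplotype frequencies sum to {total} > 1")

    # -- lookups ------------------------------------------------------------
    def serology_of(self, allele_name: str) -> str:
        try:
            return self.allele_by_name[allele_name].serology
        except KeyError:
            raise UnknownAlleleError(f"unknown allele {allele_name!r}") from None

    @property
    def serology_map(self) -> dict[str, str]:
        return {a.name: a.serology for a in self.alleles}

    def normalized_haplotypes(self) -> list[tuple[tuple[str, ...], float]]:
        total = sum(f for _, f in self.haplotypes)
        return [(h, f / total) for h, f in self.haplotypes]

    def allele_frequency(self, allele_name: str) -> float:
        """Marginal haplotype frequency of an allele (0 if in no haplotype)."""
        return sum(f for h, f in self.normalized_haplotypes() if allele_name in h)

    def drb1_alleles(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles if a.locus == "DRB1")

    def locus_groups(self) -> tuple[str, ...]:
        seen = dict.fromkeys(LOCUS_GROUP[l] for l in self.loci)
        return tuple(seen)

    def serological_projection(self, haplo_pair: Sequence[tuple[str, ...]]) -> SerologicalTyping:
        """Serological typing of a haplotype pair (homozygous -> one label)."""
        labels: dict[str, list[str]] = {}
        for hap in haplo_pair:
            for locus, name in zip(self.loci, hap):
                group = LOCUS_GROUP[locus]
                ser = self.serology_of(name)
                labels.setdefault(group, [])
                if ser not in labels[group]:
                    labels[group].append(ser)
        return SerologicalTyping(labels={g: tuple(v) for g, v in labels.items()})

    def predictor(self):
        """The surrogate presentation predictor bound to this world (cached)."""
        from .pirche import PwmPredictor

        cached = getattr(self, "_predictor", None)
        if cached is None:
            cached = PwmPredictor(self.drb1_alleles(), seed=self.predictor_seed,
                                  p_present=self.predictor_p_present)
            object.__setattr__(self, "_predictor", cached)
        return cached


@dataclass(frozen=True)
class SyntheticCohortTruth:
    """Ground truth of a generated cohort (reproducible from the seed)."""

    seed: int
    immunizers: tuple[str, ...]
    overlap_scores: tuple[float, ...]
    step_scores: tuple[float, ...]
    betas: Mapping[str, float]
    baseline_hazard: float
    death_rate: float
    admin_censor_years: float


# ---------------------------------------------------------------------------
# world generation

def _base20_digits(i: int, n_digits: int) -> list[int]:
    digits = []
    for _ in range(n_digits):
        digits.append(i % 20)
        i //= 20
    return digits


def make_hla_world(
    seed: int,
    n_alleles_per_locus: Mapping[str, int] | None = None,
    seq_len: int = DEFAULT_SEQ_LEN,
    n_haplotypes: int = DEFAULT_N_HAPLOTYPES,
    alleles_per_serology: int = DEFAULT_ALLELES_PER_SEROLOGY,
    p_present: float = 0.30,
) -> HlaWorld:
    """Generate a synthetic HLA reference world, deterministic in `seed`.

    Sequences within a locus share a random base sequence and differ only at
    polymorphic positions, where each allele's residues encode its index —
    so any two alleles of a locus (in particular two alleles sharing a
    serology label) differ in at least one residue.
    """
    counts = dict(n_alleles_per_locus or DEFAULT_ALLELES_PER_LOCUS)
    if seq_len < 9:
        raise ConfigurationError(f"seq_len must be >= 9, got {seq_len}")
    if n_haplotypes < 1:
        raise ConfigurationError("n_haplotypes must be >= 1")
    for locus, cnt in counts.items():
        if locus not in LOCI:
            raise ConfigurationError(f"unknown locus {locus!r}")
        if cnt < 1:
            raise ConfigurationError(f"allele count for {locus} must be >= 1")
    loci = tuple(l for l in LOCI if l in counts)
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))

    alleles: list[Allele] = []
    poly_positions: dict[str, np.ndarray] = {}
    for locus in loci:
        n = counts[locus]
        base = rng.integers(0, 20, size=seq_len)
        n_digits = max(1, math.ceil(math.log(max(n, 2), 20)))
        k = min(seq_len, max(4, n_digits))
        positions = np.sort(rng.choice(seq_len, size=k, replace=False))
        offsets = rng.integers(0, 20, size=k)
        poly_positions[locus] = positions
        group = LOCUS_GROUP[locus]
        for i in range(n):
            residues = base.copy()
            digits = _base20_digits(i, k)
            for j, pos in enumerate(positions):
                residues[pos] = (digits[j] + offsets[j]) % 20
            ser_idx, within = divmod(i, alleles_per_serology)
            alleles.append(Allele(
                locus=locus,
                name=f"{locus}*{ser_idx + 1:02d}:{within + 1:02d}",
                serology=f"{group}{ser_idx + 1}",
                sequence="".join(aa[residues]),
            ))

    by_locus = {l: [a.name for a in alleles if a.locus == l] for l in loci}
    max_combos = int(np.prod([len(by_locus[l]) for l in loci]))
    target = min(n_haplotypes, max_combos)
    haps: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(haps) < target:
        h = tuple(by_locus[l][rng.integers(len(by_locus[l]))] for l in loci)
        if h not in seen:
            seen.add(h)
            haps.append(h)
    freqs = rng.dirichlet(np.ones(len(haps)))

    registry = {
        a.name: frozenset(f"{a.locus}:{int(p)}:{a.sequence[int(p)]}"
                          for p in poly_positions[a.locus])
        for a in alleles if a.locus in EPLET_LOCI
    }
    return HlaWorld(
        loci=loci,
        alleles=tuple(alleles),
        haplotypes=tuple((h, float(f)) for h, f in zip(haps, freqs)),
        eplet_registry=EpletRegistry(eplets=registry),
        predictor_seed=int(rng.integers(2 ** 31)),
        predictor_p_present=p_present,
    )


# ---------------------------------------------------------------------------
# bead panels

def _panel_bead_specs(world: HlaWorld) -> list[tuple[str, tuple[str, ...]]]:
    """Bead composition of a world panel: alpha/beta dimers where both chains
    of a DQ/DP group exist (paired by haplotype co-occurrence), single-chain
    beads otherwise."""
    specs: list[tuple[str, tuple[str, ...]]] = []
    paired: set[str] = set()
    for alpha, beta in (("DQA1", "DQB1"), ("DPA1", "DPB1")):
        if alpha in world.loci and beta in world.loci:
            ia, ib = world.loci.index(alpha), world.loci.index(beta)
            combos = dict.fromkeys((h[ia], h[ib]) for h, _ in world.haplotypes)
            group = LOCUS_GROUP[beta]
            specs.extend((group, pair) for pair in combos)
            paired |= {alpha, beta}
    for a in world.alleles:
        if a.locus not in paired:
            specs.append((LOCUS_GROUP[a.locus], (a.name,)))
    return specs


def make_bead_panel(
    world: HlaWorld,
    recipient_typing: SerologicalTyping,
    immunizer: str | Sequence[str],
    noise_seed: int,
    signal_mfi: float = DEFAULT_SIGNAL_MFI,
    background_mfi_range: tuple[float, float] = DEFAULT_BACKGROUND_MFI,
    recipient_id: str = "R0",
) -> BeadPanel:
    """Single-antigen bead panel with the immunizer planted at maximum MFI.

    Every bead draws a raw MFI uniformly from `background_mfi_range`; beads
    carrying an immunizer chain are set to `signal_mfi`, which must exceed
    the background maximum so the plant is the panel-wide argmax.
    """
    immunizers = (immunizer,) if isinstance(immunizer, str) else tuple(immunizer)
    for name in immunizers:
        if name not in world.allele_by_name:
            raise UnknownAlleleError(f"immunizer {name!r} not in world")
    lo, hi = background_mfi_range
    if not 0 < lo <= hi:
        raise ConfigurationError("background MFI range must satisfy 0 < low <= high")
    if signal_mfi <= hi:
        raise ConfigurationError("signal_mfi must exceed the background maximum")
    rng = np.random.default_rng(noise_seed)
    beads = []
    for idx, (group, chains) in enumerate(_panel_bead_specs(world)):
        raw = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        if any(c in immunizers for c in chains):
            raw = float(signal_mfi)
        beads.append(Bead(bead_id=f"BD{idx:03d}", locus_group=group,
                          alleles=chains, raw_mfi=raw))
    return BeadPanel(recipient_id=recipient_id, beads=tuple(beads))


# ---------------------------------------------------------------------------
# cohorts

def _draw_pair(rng, haps, probs) -> tuple[tuple[str, ...], tuple[str, ...]]:
    i, j = rng.choice(len(haps), size=2, p=probs)
    return haps[i], haps[j]


def make_cohort(
    world: HlaWorld,
    seed: int,
    n: int,
    betas: Mapping[str, float] | None = None,
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD,
    admin_censor_years: float = FOLLOW_UP_CAP_YEARS,
    death_rate: float = DEFAULT_DEATH_RATE,
    signal_mfi: float = DEFAULT_SIGNAL_MFI,
    background_mfi_range: tuple[float, float] = DEFAULT_BACKGROUND_MFI,
    p_missing_cit: float = 0.03,
    max_draws: int = 300,
    artifacts: dict | None = None,
) -> tuple[list[CohortRecord], SyntheticCohortTruth]:
    """Generate a cohort under an exponential proportional-hazards model.

    Each recipient gets genotype-consistent serological typings (resampled
    until the DRB1 confidence gate passes), a random non-self immunizer
    planted in a bead panel, and covariates; the STEP score and the other
    HLA-derived covariates are computed through the real scoring pipeline.
    The failure hazard is ``baseline_hazard * exp(sum(beta_k * x_k))`` with
    death (rate `death_rate`) and administrative censoring at
    `admin_censor_years` applied; the event is death-censored graft failure.

    If `artifacts` is a dict, the generated recipient/donor typings and bead
    panels are collected into it (keys ``recipients``, ``donors``,
    ``panels``) so they can be written to files for pipeline runs.
    """
    from .pipeline import ScoringEngine

    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be > 0")
    if not 0.0 <= admin_censor_years <= FOLLOW_UP_CAP_YEARS:
        raise ConfigurationError("admin_censor_years must be in [0, 10]")
    betas = dict(betas or {})
    rng = np.random.default_rng(seed)
    engine = ScoringEngine.for_world(world)
    norm = world.normalized_haplotypes()
    haps = [h for h, _ in norm]
    probs = np.array([f for _, f in norm])
    allele_names = [a.name for a in world.alleles]

    records: list[CohortRecord] = []
    immunizers: list[str] = []
    overlaps: list[float] = []
    steps: list[float] = []
    for i in range(n):
        # recipient typing must clear the DRB1 gate; resample if not
        for _ in range(max_draws):
            pair = _draw_pair(rng, haps, probs)
            recipient = world.serological_projection(pair)
            if engine.try_resolve_drb1(recipient) is not None:
                break
        else:
            raise ConfigurationError(
                "could not draw a recipient passing the DRB1 gate; "
                "world has no confidently imputable DR typing")
        donor = world.serological_projection(_draw_pair(rng, haps, probs))
        rec_labels = {lab for labs in recipient.labels.values() for lab in labs}
        candidates = [nm for nm in allele_names
                      if world.serology_of(nm) not in rec_labels]
        immunizer = candidates[rng.integers(len(candidates))] if candidates \
            else allele_names[rng.integers(len(allele_names))]
        panel = make_bead_panel(
            world, recipient, immunizer, noise_seed=int(rng.integers(2 ** 31)),
            signal_mfi=signal_mfi, background_mfi_range=background_mfi_range,
            recipient_id=f"R{i:04d}")
        scores = engine.score_recipient(recipient, donor, panel)
        if artifacts is not None:
            artifacts.setdefault("recipients", []).append(recipient)
            artifacts.setdefault("donors", []).append(donor)
            artifacts.setdefault("panels", []).append(panel)

        cov = {
            "donor_age": float(np.clip(rng.normal(50, 15), 5, 85)),
            "donor_sex": int(rng.integers(2)),
            "recipient_age": float(np.clip(rng.normal(50, 13), 18, 80)),
            "recipient_sex": int(rng.integers(2)),
            "tx_year": float(rng.integers(1995, 2006)),
            "hpra": float(rng.beta(1.2, 4.0) * 100),
            "repeat_tx": int(rng.random() < 0.2),
            "donation_dbd": int(rng.random() < 0.6),
            "cold_ischemia_h": float(np.clip(rng.normal(22, 8), 2, 50)),
            "hla_mismatches": float(scores.hla_mismatches),
            "eplet_mismatches": float(scores.eplet_mismatches),
            "ln_pirche": scores.ln_pirche,
            "step": scores.step_score,
        }
        lp = sum(b * cov[k] for k, b in betas.items())
        hazard = baseline_hazard * math.exp(lp)
        t_fail = rng.exponential(1.0 / hazard)
        t_death = rng.exponential(1.0 / death_rate) if death_rate > 0 else math.inf
        time = min(t_fail, t_death, admin_censor_years)
        event = int(time == t_fail and time < admin_censor_years)
        death = int(not event and time == t_death and time < admin_censor_years)
        missing_cit = rng.random() < p_missing_cit
        records.append(CohortRecord(
            recipient_id=f"R{i:04d}",
            **{**cov, "cold_ischemia_h": None if missing_cit else cov["cold_ischemia_h"]},
            time_years=float(time), event=event, death=death))
        immunizers.append(immunizer)
        overlaps.append(scores.overlap_score)
        steps.append(scores.step_score)

    truth = SyntheticCohortTruth(
        seed=seed, immunizers=tuple(immunizers), overlap_scores=tuple(overlaps),
        step_scores=tuple(steps), betas=betas, baseline_hazard=baseline_hazard,
        death_rate=death_rate, admin_censor_years=admin_censor_years)
    return records, truth


# ---------------------------------------------------------------------------
# plain-text writers / readers

def write_alleles_fasta(world: HlaWorld, path) -> None:
    recs = [SeqRecord(Seq(a.sequence), id=a.name, description=f"serology={a.serology}")
            for a in world.alleles]
    SeqIO.write(recs, str(path), "fasta")


def read_alleles_fasta(path, serology_map: Mapping[str, str]) -> tuple[Allele, ...]:
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        from .hla_core import locus_of
        alleles.append(Allele(locus=locus_of(name), name=name,
                              serology=serology_map[name], sequence=str(rec.seq)))
    return tuple(alleles)


def write_serology_csv(world: HlaWorld, path) -> None:
    pd.DataFrame({"allele": [a.name for a in world.alleles],
                  "serology": [a.serology for a in world.alleles]}).to_csv(path, index=False)


def read_serology_csv(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["allele"], df["serology"]))


def write_haplotypes_tsv(world: HlaWorld, path) -> None:
    rows = [{**dict(zip(world.loci, hap)), "frequency": freq}
            for hap, freq in world.haplotypes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path) -> tuple[tuple[str, ...], tuple[tuple[tuple[str, ...], float], ...]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    loci = tuple(c for c in df.columns if c != "frequency")
    haps = tuple((tuple(str(row[l]) for l in loci), float(row["frequency"]))
                 for _, row in df.iterrows())
    return loci, haps


def write_eplets_csv(world: HlaWorld, path) -> None:
    rows = [{"allele": name, "eplet_id": ep}
            for name, eps in sorted(world.eplet_registry.eplets.items())
            for ep in sorted(eps)]
    pd.DataFrame(rows, columns=["allele", "eplet_id"]).to_csv(path, index=False)


def read_eplets_csv(path) -> EpletRegistry:
    df = pd.read_csv(path, dtype=str)
    eplets: dict[str, set[str]] = {}
    for allele, ep in zip(df["allele"], df["eplet_id"]):
        eplets.setdefault(allele, set()).add(ep)
    return EpletRegistry(eplets={a: frozenset(e) for a, e in eplets.items()})


def world_from_files(fasta_path, serology_path, haplotypes_path, eplets_path,
                     predictor_seed: int, p_present: float = 0.30) -> HlaWorld:
    """Reassemble an :class:`HlaWorld` from its four text files."""
    serology = read_serology_csv(serology_path)
    alleles = read_alleles_fasta(fasta_path, serology)
    loci, haps = read_haplotypes_tsv(haplotypes_path)
    return HlaWorld(loci=loci, alleles=alleles, haplotypes=haps,
                    eplet_registry=read_eplets_csv(eplets_path),
                    predictor_seed=predictor_seed, predictor_p_present=p_present)


def write_typings_csv(path, rows: Iterable[tuple[str, str, SerologicalTyping]]) -> None:
    """Typing table: id, role (donor|recipient), one column per locus group."""
    out = []
    for rid, role, typing in rows:
        row = {"id": rid, "role": role}
        for group, labels in typing.labels.items():
            row[group] = ";".join(labels)
        out.append(row)
    cols = ["id", "role", "A", "B", "C", "DR", "DQ", "DP"]
    df = pd.DataFrame(out)
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False)


def read_typings_csv(path) -> list[tuple[str, str, SerologicalTyping]]:
    from .hla_core import parse_typing
    df = pd.read_csv(path, dtype=str).fillna("")
    return [(row["id"], row["role"], parse_typing(dict(row)))
            for _, row in df.iterrows()]


def write_bead_panels_csv(path, panels: Iterable[BeadPanel]) -> None:
    rows = []
    for panel in panels:
        for b in panel.beads:
            rows.append({"recipient_id": panel.recipient_id, "bead_id": b.bead_id,
                         "locus_group": b.locus_group, "allele_1": b.alleles[0],
                         "allele_2": b.alleles[1] if len(b.alleles) > 1 else "",
                         "raw_mfi": b.raw_mfi})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bead_panels_csv(path) -> list[BeadPanel]:
    df = pd.read_csv(path, dtype=str).fillna("")
    panels = []
    for rid, sub in df.groupby("recipient_id", sort=False):
        beads = tuple(
            Bead(bead_id=row["bead_id"], locus_group=row["locus_group"],
                 alleles=tuple(a for a in (row["allele_1"], str(row["allele_2"])) if a),
                 raw_mfi=float(row["raw_mfi"]))
            for _, row in sub.iterrows())
        panels.append(BeadPanel(recipient_id=str(rid), beads=beads))
    return panels


#: cohort-CSV columns carrying externally observed data (pipeline input)
OBSERVED_COHORT_COLUMNS = (
    "recipient_id", "donor_age", "donor_sex", "recipient_age", "recipient_sex",
    "tx_year", "hpra", "repeat_tx", "donation_dbd", "cold_ischemia_h",
    "time_years", "event", "death",
)


def write_cohort_csv(records: Sequence[CohortRecord], path,
                     columns: Sequence[str] | None = None) -> None:
    from .survival import records_to_frame
    df = records_to_frame(records)
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"recipient_id": str},
                       float_precision="round_trip")


def simulate_dataset(
    out_dir,
    seed: int,
    n: int,
    betas: Mapping[str, float] | None = None,
    world_kwargs: Mapping | None = None,
    cohort_kwargs: Mapping | None = None,
) -> dict[str, object]:
    """Generate a world + cohort and write all pipeline input files.

    Writes alleles FASTA, serology / eplet / typing / bead / cohort CSVs, the
    haplotype TSV and a ``truth.json`` with the generation ground truth under
    `out_dir`; returns a dict of the file paths plus the predictor seed,
    ready to assemble a pipeline configuration.  Deterministic in `seed`.
    """
    import dataclasses
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    world = make_hla_world(seed=int(rng.integers(2 ** 31)), **dict(world_kwargs or {}))
    artifacts: dict = {}
    records, truth = make_cohort(world, seed=int(rng.integers(2 ** 31)), n=n,
                                 betas=betas, artifacts=artifacts,
                                 **dict(cohort_kwargs or {}))
    paths = {
        "fasta": out / "alleles.fasta",
        "serology_csv": out / "serology.csv",
        "haplotypes_tsv": out / "haplotypes.tsv",
        "eplets_csv": out / "eplets.csv",
        "typings_csv": out / "typings.csv",
        "beads_csv": out / "beads.csv",
        "cohort_csv": out / "cohort.csv",
    }
    write_alleles_fasta(world, paths["fasta"])
    write_serology_csv(world, paths["serology_csv"])
    write_haplotypes_tsv(world, paths["haplotypes_tsv"])
    write_eplets_csv(world, paths["eplets_csv"])
    typing_rows = [(r.recipient_id, "recipient", t)
                   for r, t in zip(records, artifacts["recipients"])]
    typing_rows += [(r.recipient_id, "donor", t)
                    for r, t in zip(records, artifacts["donors"])]
    write_typings_csv(paths["typings_csv"], typing_rows)
    write_bead_panels_csv(paths["beads_csv"], artifacts["panels"])
    write_cohort_csv(records, paths["cohort_csv"], columns=OBSERVED_COHORT_COLUMNS)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
    return {**{k: str(v) for k, v in paths.items()},
            "predictor_seed": world.predictor_seed,
            "predictor_p_present": world.predictor_p_present}
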