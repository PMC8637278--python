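"""End-to-end orchestration: typings + beads -> STEP scores -> survival suite.

Stage order mirrors the analysis flow: parse typings, extrapolate the
recipient DRB1 (excluding low-confidence recipients), normalize bead panels,
select the theoretical immunizer, derive the immunizer and donor ("recall")
epitope sets, intersect them into the overlap / STEP score, attach antigen-
and eplet-mismatch covariates, and run the statistical layer.  Exclusions are
first-class results: every dropped recipient is logged with a reason and the
accounting must reconcile with the input count.
"""

from __future__ import annotations

import hashlib
import json
import math
import weakref
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import survival as sv
from .hla_core import (EPLET_LOCI, HighResTyping, SerologicalTyping,
                       count_broad_mismatches, count_eplet_mismatches)
from .imputation import (DRB1_WEIGHT_THRESHOLD, Drb1ExclusionError,
                         InsufficientTypingError, max_weight_genotype,
                         resolve_drb1)
from .lsa import APPROACHES, BeadPanel, evaluate_approach_auc, normalize_panel, select_immunizers
from .overlap import OverlapResult, overlap_score
from .pirche import PircheResult, pirche_for_targets

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_world import HlaWorld

# exclusion reasons (Fig.-1-style accounting)
EXCL_INSUFFICIENT_TYPING = "insufficient_typing"
EXCL_DRB1_BELOW_THRESHOLD = "drb1_below_threshold"
EXCL_NO_BEAD_PANEL = "no_bead_panel"
EXCL_NO_POSITIVE_BEADS = "no_positive_beads"


@dataclass(frozen=True)
class RecipientScores:
    """All HLA-derived covariates of one donor/recipient pair."""

    recipient_id: str
    drb1: tuple[str, ...]
    immunizer_targets: tuple[str, ...]
    overlap_score: float
    step_score: float
    pirche_score: float
    ln_pirche: float
    hla_mismatches: int
    eplet_mismatches: int
    n_shared: int


@dataclass
class ExclusionLog:
    """Recipient id -> exclusion reason; reconciles against the input count."""

    entries: dict[str, str] = field(default_factory=dict)

    def exclude(self, recipient_id: str, reason: str) -> None:
        self.entries[recipient_id] = reason

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in self.entries.values():
            out[reason] = out.get(reason, 0) + 1
        return out

    def reconcile(self, n_input: int, n_analyzed: int) -> None:
        if n_analyzed + len(self.entries) != n_input:
            raise RuntimeError(
                f"exclusion accounting broken: {n_analyzed} analyzed + "
                f"{len(self.entries)} excluded != {n_input} input")


class ScoringEngine:
    """Caches all per-typing intermediates of the scoring pipeline.

    One engine is bound to one reference world (and its predictor); results
    are pure functions of the inputs, so caching changes speed only.
    """

    _instances: "weakref.WeakKeyDictionary" = weakref.WeakKeyDictionary()

    def __init__(self, world: "HlaWorld", approach: str = "B",
                 drb1_threshold: float = DRB1_WEIGHT_THRESHOLD):
        self.world = world
        self.predictor = world.predictor()
        self.approach = approach
        self.drb1_threshold = drb1_threshold
        self._drb1: dict = {}
        self._recall: dict = {}
        self._immunizer: dict = {}
        self._eplets: dict = {}
        self._highres: dict = {}

    @classmethod
    def for_world(cls, world: "HlaWorld") -> "ScoringEngine":
        eng = cls._instances.get(world)
        if eng is None:
            eng = cls(world)
            cls._instances[world] = eng
        return eng

    # -- DRB1 gate ----------------------------------------------------------
    def try_resolve_drb1(self, typing: SerologicalTyping) -> tuple[str, ...] | None:
        """Extrapolated DRB1 pair, or None when the recipient is gated out."""
        key = typing.key()
        if key not in self._drb1:
            try:
                self._drb1[key] = resolve_drb1(typing, self.world, self.drb1_threshold)
            except (Drb1ExclusionError, InsufficientTypingError) as exc:
                self._drb1[key] = exc
        hit = self._drb1[key]
        return None if isinstance(hit, Exception) else hit

    # -- epitope sets ---------------------------------------------------------
    def donor_mismatch_labels(self, recipient: SerologicalTyping,
                              donor: SerologicalTyping) -> tuple[str, ...]:
        """Donor serological antigens absent from the recipient, all groups
        typed on both sides."""
        out = []
        for group in donor.groups:
            if group not in recipient.labels:
                continue
            rec = set(recipient.labels[group])
            out.extend(lab for lab in donor.labels[group] if lab not in rec)
        return tuple(out)

    def recall_set(self, recipient: SerologicalTyping, drb1: tuple[str, ...],
                   donor: SerologicalTyping) -> PircheResult:
        targets = self.donor_mismatch_labels(recipient, donor)
        key = (recipient.key(), drb1, targets)
        if key not in self._recall:
            self._recall[key] = pirche_for_targets(
                targets, recipient, drb1, self.world, self.predictor, origin="DONOR")
        return self._recall[key]

    def immunizer_set(self, recipient: SerologicalTyping, drb1: tuple[str, ...],
                      panel: BeadPanel) -> tuple[PircheResult, tuple[str, ...]]:
        selection = select_immunizers(normalize_panel(panel), self.approach)
        peptides = []
        for bead in selection.beads:
            key = (recipient.key(), drb1, bead.alleles)
            if key not in self._immunizer:
                self._immunizer[key] = pirche_for_targets(
                    bead.alleles, recipient, drb1, self.world, self.predictor,
                    origin=f"IMMUNIZER:{bead.bead_id}")
            peptides.extend(self._immunizer[key].peptides)
        return PircheResult(peptides=tuple(peptides)), selection.target_alleles()

    # -- covariates ----------------------------------------------------------
    def _highres_typing(self, typing: SerologicalTyping) -> HighResTyping:
        key = typing.key()
        if key not in self._highres:
            g = max_weight_genotype(typing, self.world)
            alleles: dict[str, tuple[str, ...]] = {}
            for idx, locus in enumerate(self.world.loci):
                if locus in EPLET_LOCI:
                    alleles[locus] = tuple(dict.fromkeys(g.alleles_at(idx)))
            self._highres[key] = HighResTyping(alleles=alleles)
        return self._highres[key]

    def eplet_mismatches(self, donor: SerologicalTyping,
                         recipient: SerologicalTyping) -> int:
        key = (donor.key(), recipient.key())
        if key not in self._eplets:
            self._eplets[key] = count_eplet_mismatches(
                self._highres_typing(donor), self._highres_typing(recipient),
                self.world.eplet_registry)
        return self._eplets[key]

    # -- full per-recipient scoring -------------------------------------------
    def score_recipient(self, recipient: SerologicalTyping,
                        donor: SerologicalTyping, panel: BeadPanel) -> RecipientScores:
        drb1 = self.try_resolve_drb1(recipient)
        if drb1 is None:
            raise self._drb1[recipient.key()]
        recall = self.recall_set(recipient, drb1, donor)
        immunizers, targets = self.immunizer_set(recipient, drb1, panel)
        ov: OverlapResult = overlap_score(immunizers, recall, drb1)
        return RecipientScores(
            recipient_id=panel.recipient_id,
            drb1=drb1,
            immunizer_targets=targets,
            overlap_score=ov.overlap_score,
            step_score=ov.step_score,
            pirche_score=recall.score,
            ln_pirche=math.log1p(recall.score),
            hla_mismatches=count_broad_mismatches(donor, recipient),
            eplet_mismatches=self.eplet_mismatches(donor, recipient),
            n_shared=len(ov.shared),
        )


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """File paths and analysis settings for a pipeline run."""

    typings_csv: str
    fasta: str
    serology_csv: str
    haplotypes_tsv: str
    eplets_csv: str
    beads_csv: str
    cohort_csv: str
    predictor_seed: int
    predictor_p_present: float = 0.30
    approach: str = "B"
    drb1_threshold: float = DRB1_WEIGHT_THRESHOLD
    step_cutoff: float | str = "youden"  # fixed number, or "youden"
    sle: float = 0.15
    sls: float = 0.15
    n_perm: int = 1000
    min_events: int = 5
    hr_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
    landmark_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("hr_grid", "landmark_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run

#: candidate variables of the multivariable model, in canonical order
MODEL_CANDIDATES = (
    "donor_age", "donor_sex", "recipient_age", "recipient_sex", "tx_year",
    "hpra", "repeat_tx", "donation_dbd", "cold_ischemia_h",
    "hla_mismatches", "eplet_mismatches", "ln_pirche", "step",
)


def score_cohort(config: PipelineConfig):
    """Stages 1-7: read inputs and compute per-recipient scores.

    Returns (scores DataFrame indexed by recipient, per-approach STEP table,
    exclusion log, cohort covariate DataFrame).
    """
    from . import synthetic_world as sw

    world = sw.world_from_files(config.fasta, config.serology_csv,
                                config.haplotypes_tsv, config.eplets_csv,
                                predictor_seed=config.predictor_seed,
                                p_present=config.predictor_p_present)
    engine = ScoringEngine(world, approach=config.approach,
                           drb1_threshold=config.drb1_threshold)
    typings = sw.read_typings_csv(config.typings_csv)
    recipients = {rid: t for rid, role, t in typings if role == "recipient"}
    donors = {rid: t for rid, role, t in typings if role == "donor"}
    panels = {p.recipient_id: p for p in sw.read_bead_panels_csv(config.beads_csv)}
    cohort_df = sw.read_cohort_csv(config.cohort_csv)

    exclusions = ExclusionLog()
    rows = []
    approach_rows = []
    for rid, recipient in recipients.items():
        if rid not in donors or rid not in panels:
            exclusions.exclude(rid, EXCL_NO_BEAD_PANEL)
            continue
        if engine.try_resolve_drb1(recipient) is None:
            reason = (EXCL_INSUFFICIENT_TYPING
                      if isinstance(engine._drb1[recipient.key()], InsufficientTypingError)
                      else EXCL_DRB1_BELOW_THRESHOLD)
            exclusions.exclude(rid, reason)
            continue
        scores = engine.score_recipient(recipient, donors[rid], panels[rid])
        rows.append({
            "recipient_id": rid,
            "drb1": ";".join(scores.drb1),
            "immunizer_targets": ";".join(scores.immunizer_targets),
            "overlap_score": scores.overlap_score,
            "step": scores.step_score,
            "ln_pirche": scores.ln_pirche,
            "hla_mismatches": scores.hla_mismatches,
            "eplet_mismatches": scores.eplet_mismatches,
            "n_shared": scores.n_shared,
        })
        # per-approach STEP for the AUC comparison
        drb1 = scores.drb1
        arow = {"recipient_id": rid}
        for approach in APPROACHES:
            alt = ScoringEngine(world, approach=approach,
                                drb1_threshold=config.drb1_threshold) \
                if approach != config.approach else engine
            try:
                imm, _ = alt.immunizer_set(recipient, drb1, panels[rid])
                recall = engine.recall_set(recipient, drb1, donors[rid])
                arow[f"step_{approach}"] = overlap_score(imm, recall, drb1).step_score
            except Exception:
                arow[f"step_{approach}"] = float("nan")
        approach_rows.append(arow)
    exclusions.reconcile(len(recipients), len(rows))
    scores_df = pd.DataFrame(rows)
    approaches_df = pd.DataFrame(approach_rows)
    return scores_df, approaches_df, exclusions, cohort_df


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write the result bundle under `out_dir`.

    Outputs (all plain text): per-recipient scores, univariate and stepwise
    Cox tables, KM curves by STEP group, ABS test, HR-vs-virtual-endpoint and
    landmark curves, per-approach AUCs, two-group baseline comparison,
    exclusion log (JSONL) and a run manifest.  Re-running with the same
    config and seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_df, approaches_df, exclusions, cohort_df = score_cohort(config)

    df = cohort_df.merge(scores_df, on="recipient_id", how="inner")
    _write_csv(scores_df, out / "scores.csv")
    _write_csv(approaches_df, out / "approach_steps.csv")
    with open(out / "exclusions.jsonl", "w") as fh:
        for rid, reason in sorted(exclusions.entries.items()):
            fh.write(json.dumps({"recipient_id": rid, "reason": reason}) + "\n")

    results = run_survival_suite(df, approaches_df, config, out)
    results = {"n_input": len(cohort_df), "n_analyzed": len(df),
               "exclusions": exclusions.counts(), **results}

    manifest = {"config": asdict(config), "config_hash": config.content_hash(),
                "results": _jsonable(results)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results


def run_survival_suite(df: pd.DataFrame, approaches_df: pd.DataFrame | None,
                       config: PipelineConfig, out_dir) -> dict:
    """Statistical layer on a merged cohort + scores table; writes CSVs.

    `df` must carry the covariate columns of :data:`MODEL_CANDIDATES` plus
    ``time_years`` and ``event``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # univariate Cox per candidate, with PH check and tt() where violated
    uni_rows = []
    for var in MODEL_CANDIDATES:
        try:
            fit = sv.cox_fit(df, [var])
            ph_p = sv.ph_check_schoenfeld(fit).get(var, float("nan"))
            if ph_p < 0.05:
                fit = sv.cox_fit(df, [var], time_transform={var: np.log1p})
            eff = fit.effects[var]
            uni_rows.append({"variable": var, "hr": eff.hr, "ci_low": eff.ci_low,
                             "ci_high": eff.ci_high, "p": eff.p, "ph_p": ph_p,
                             "time_dependent": bool(ph_p < 0.05)})
        except sv.SurvivalError as exc:
            uni_rows.append({"variable": var, "hr": float("nan"),
                             "ci_low": float("nan"), "ci_high": float("nan"),
                             "p": float("nan"), "ph_p": float("nan"),
                             "time_dependent": False, "error": str(exc)})
    _write_csv(pd.DataFrame(uni_rows), out / "cox_univariate.csv")

    # stepwise multivariable model
    model = sv.stepwise_select(df, MODEL_CANDIDATES, sle=config.sle, sls=config.sls)
    multi_rows = [{"variable": v, "hr": e.hr, "ci_low": e.ci_low,
                   "ci_high": e.ci_high, "p": e.p}
                  for v, e in model.effects.items()]
    _write_csv(pd.DataFrame(multi_rows,
                            columns=["variable", "hr", "ci_low", "ci_high", "p"]),
               out / "cox_multivariable.csv")
    results["selected_variables"] = list(model.variables)

    # STEP cut-point, KM by group, ABS test, baseline comparison
    failed = df["event"].astype(bool).to_numpy()
    if config.step_cutoff == "youden":
        cp = sv.youden_cutpoint_kernel(df["step"].to_numpy(), failed)
        cutoff, youden_j = cp.cutoff, cp.youden_j
    else:
        cutoff, youden_j = float(config.step_cutoff), float("nan")
    high = df["step"].to_numpy() > cutoff
    results["step_cutoff"] = cutoff
    results["youden_j"] = youden_j
    results["n_high"] = int(high.sum())
    results["n_low"] = int((~high).sum())

    km_rows = []
    for label, mask in (("low", ~high), ("high", high)):
        km = sv.km_estimate(df.loc[mask, "time_years"], df.loc[mask, "event"])
        for t, s in zip(km.event_times, km.survival):
            km_rows.append({"group": label, "time_years": t,
                            "survival": s, "cumulative_incidence": 1 - s})
    _write_csv(pd.DataFrame(km_rows), out / "km_curves.csv")

    try:
        abs_res = sv.abs_permutation_test(
            df["time_years"], df["event"], high.astype(int),
            n_perm=config.n_perm, seed=config.seed)
        results["abs_statistic"] = abs_res.statistic
        results["abs_p"] = abs_res.p_value
    except sv.SurvivalError as exc:
        results["abs_error"] = str(exc)

    try:
        results["group_compare_p"] = sv.group_compare(df, high)
    except sv.SurvivalError as exc:
        results["group_compare_error"] = str(exc)

    # categorized STEP model with forced covariates
    df_cat = df.assign(step_high=high.astype(int))
    try:
        forced = sv.cox_fit(df_cat, ["hla_mismatches", "eplet_mismatches",
                                     "ln_pirche", "step_high"])
        eff = forced.effects["step_high"]
        results["step_categorized_hr"] = eff.hr
        results["step_categorized_p"] = eff.p
    except sv.SurvivalError as exc:
        results["step_categorized_error"] = str(exc)

    # HR curves
    ve = sv.hr_virtual_endpoints(df, "step", config.hr_grid,
                                 min_events=config.min_events)
    lm = sv.hr_landmark(df, "step", config.landmark_grid,
                        min_events=config.min_events)
    _write_csv(pd.DataFrame([p.__dict__ for p in ve]), out / "hr_virtual_endpoints.csv")
    _write_csv(pd.DataFrame([p.__dict__ for p in lm]), out / "hr_landmark.csv")

    # per-approach AUC comparison of the bead-selection strategies
    if approaches_df is not None and len(approaches_df):
        auc_rows = []
        adf = approaches_df.merge(df[["recipient_id", "event"]], on="recipient_id")
        for approach in APPROACHES:
            col = adf[f"step_{approach}"]
            keep = col.notna()
            try:
                auc = evaluate_approach_auc(col[keep].to_numpy(),
                                            adf.loc[keep, "event"].astype(bool).to_numpy())
            except ValueError:
                auc = float("nan")
            auc_rows.append({"approach": approach, "auc": auc})
        _write_csv(pd.DataFrame(auc_rows), out / "approach_auc.csv")
        results["approach_auc"] = {r["approach"]: r["auc"] for r in auc_rows}
    return results


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
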