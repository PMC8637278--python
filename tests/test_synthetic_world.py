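import dataclasses
import math

import numpy as np
import pytest

import stepscore.synthetic_world as sw
from stepscore import (ScoringEngine, make_bead_panel, make_cohort,
                       make_hla_world, normalize_panel, records_to_frame,
                       select_immunizers)
from stepscore.synthetic_world import ConfigurationError


def world_fingerprint(w):
    return (w.loci, tuple((a.name, a.serology, a.sequence) for a in w.alleles),
            w.haplotypes, tuple(sorted(w.eplet_registry.eplets.items())),
            w.predictor_seed)


class TestMakeWorld:
    def test_same_seed_identical_worlds(self):
        assert world_fingerprint(make_hla_world(seed=1)) == \
            world_fingerprint(make_hla_world(seed=1))

    def test_different_seeds_differ_in_sequences(self):
        s1 = {a.sequence for a in make_hla_world(seed=1).alleles}
        s2 = {a.sequence for a in make_hla_world(seed=2).alleles}
        assert s1 != s2

    def test_serology_siblings_differ_in_sequence(self, world):
        by_serology = {}
        for a in world.alleles:
            by_serology.setdefault(a.serology, []).append(a)
        for group in by_serology.values():
            seqs = [a.sequence for a in group]
            assert len(set(seqs)) == len(seqs)

    def test_frequencies_normalized(self, world):
        assert sum(f for _, f in world.normalized_haplotypes()) == pytest.approx(1.0)

    def test_single_drb1_allele_forces_extrapolation(self):
        from stepscore import resolve_drb1
        w = make_hla_world(seed=3, n_alleles_per_locus={"A": 2, "B": 2, "DRB1": 1})
        haps = [h for h, _ in w.haplotypes]
        typing = w.serological_projection((haps[0], haps[-1]))
        assert resolve_drb1(typing, w) == ("DRB1*01:01",)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            make_hla_world(seed=1, n_alleles_per_locus={"A": 0, "B": 1, "DRB1": 1})
        with pytest.raises(ConfigurationError):
            make_hla_world(seed=1, seq_len=8)


class TestBeadPanels:
    def test_planted_immunizer_recovered_by_approach_b(self, world):
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        immunizer = next(a.name for a in world.alleles
                         if a.serology not in
                         {l for labs in typing.labels.values() for l in labs})
        panel = make_bead_panel(world, typing, immunizer, noise_seed=5)
        sel = select_immunizers(normalize_panel(panel), "B")
        assert sel.target_alleles() == (immunizer,)

    def test_zero_width_background_gives_unit_ratios_off_signal(self, world):
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        panel = make_bead_panel(world, typing, world.alleles[0].name, noise_seed=1,
                                background_mfi_range=(100.0, 100.0))
        norm = normalize_panel(panel)
        signal_group = world.alleles[0].locus
        for b in norm.beads:
            if world.alleles[0].name not in b.alleles and b.locus_group != "A":
                assert b.ratio == pytest.approx(1.0)

    def test_two_planted_immunizers_tie_at_max(self, world):
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        pair = [a.name for a in world.alleles[:2]]
        panel = make_bead_panel(world, typing, pair, noise_seed=2)
        sel = select_immunizers(normalize_panel(panel), "B")
        assert set(sel.target_alleles()) == set(pair)

    def test_signal_must_exceed_background(self, world):
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        with pytest.raises(ConfigurationError):
            make_bead_panel(world, typing, world.alleles[0].name, noise_seed=1,
                            signal_mfi=400.0, background_mfi_range=(50.0, 500.0))

    def test_unknown_immunizer_rejected(self, world):
        from stepscore import UnknownAlleleError
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        with pytest.raises(UnknownAlleleError):
            make_bead_panel(world, typing, "A*77:77", noise_seed=1)


class TestMakeCohort:
    def test_deterministic_in_seed(self, world):
        r1, t1 = make_cohort(world, seed=5, n=25)
        r2, t2 = make_cohort(world, seed=5, n=25)
        assert r1 == r2 and t1 == t2

    def test_null_betas_match_closed_form_failure_probability(self, world):
        lam, mu, horizon = 0.02, 0.015, 10.0
        n = 2000
        recs, _ = make_cohort(world, seed=6, n=n, betas={},
                              baseline_hazard=lam, death_rate=mu)
        p_fail = lam / (lam + mu) * (1 - math.exp(-(lam + mu) * horizon))
        observed = sum(r.event for r in recs) / n
        se = math.sqrt(p_fail * (1 - p_fail) / n)
        assert abs(observed - p_fail) <= 3 * se

    def test_zero_admin_censoring_degenerate(self, world):
        recs, _ = make_cohort(world, seed=7, n=10, admin_censor_years=0.0)
        assert all(r.time_years == 0.0 and r.event == 0 for r in recs)

    def test_step_computed_through_pipeline_not_sampled(self, world):
        artifacts = {}
        recs, truth = make_cohort(world, seed=8, n=15, artifacts=artifacts)
        engine = ScoringEngine.for_world(world)
        for rec, recipient, donor, panel in zip(
                recs, artifacts["recipients"], artifacts["donors"], artifacts["panels"]):
            scores = engine.score_recipient(recipient, donor, panel)
            assert rec.step == scores.step_score
            assert rec.ln_pirche == scores.ln_pirche

    def test_truth_records_planted_immunizers(self, world):
        artifacts = {}
        recs, truth = make_cohort(world, seed=9, n=10, artifacts=artifacts)
        for imm, panel in zip(truth.immunizers, artifacts["panels"]):
            sel = select_immunizers(normalize_panel(panel), "B")
            assert sel.target_alleles() == (imm,)

    def test_invalid_n_rejected(self, world):
        with pytest.raises(ConfigurationError):
            make_cohort(world, seed=1, n=0)


class TestRoundTrips:
    def test_world_files_round_trip(self, tmp_path, world):
        sw.write_alleles_fasta(world, tmp_path / "a.fasta")
        sw.write_serology_csv(world, tmp_path / "s.csv")
        sw.write_haplotypes_tsv(world, tmp_path / "h.tsv")
        sw.write_eplets_csv(world, tmp_path / "e.csv")
        back = sw.world_from_files(tmp_path / "a.fasta", tmp_path / "s.csv",
                                   tmp_path / "h.tsv", tmp_path / "e.csv",
                                   predictor_seed=world.predictor_seed)
        assert world_fingerprint(back) == world_fingerprint(world)

    def test_typings_round_trip(self, tmp_path, world):
        haps = [h for h, _ in world.haplotypes]
        typings = [(f"R{i}", "recipient",
                    world.serological_projection((haps[i], haps[i + 1])))
                   for i in range(4)]
        sw.write_typings_csv(tmp_path / "t.csv", typings)
        back = sw.read_typings_csv(tmp_path / "t.csv")
        assert [(r, role, t.labels) for r, role, t in back] == \
            [(r, role, t.labels) for r, role, t in typings]

    def test_bead_panels_round_trip(self, tmp_path, world):
        haps = [h for h, _ in world.haplotypes]
        typing = world.serological_projection((haps[0], haps[1]))
        panels = [make_bead_panel(world, typing, world.alleles[0].name,
                                  noise_seed=s, recipient_id=f"R{s}")
                  for s in range(3)]
        sw.write_bead_panels_csv(tmp_path / "b.csv", panels)
        assert sw.read_bead_panels_csv(tmp_path / "b.csv") == panels

    def test_cohort_round_trip(self, tmp_path, world):
        recs, _ = make_cohort(world, seed=11, n=12)
        sw.write_cohort_csv(recs, tmp_path / "c.csv")
        back = sw.read_cohort_csv(tmp_path / "c.csv")
        orig = records_to_frame(recs)
        assert np.allclose(back["step"], orig["step"])
        assert np.allclose(back["time_years"], orig["time_years"])
        assert list(back["recipient_id"]) == list(orig["recipient_id"])
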