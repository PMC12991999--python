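"""Synthetic cohort generator: CDR3 framing, bookkeeping, determinism,
stage dynamics."""

import numpy as np
import pytest

import tcrgvhd as t
from tcrgvhd.simulate import (
    StageTransition,
    _sample_cdr3_batch,
    subject_seed,
)


def fixed_length(n):
    return lambda rng: n


class TestSampleCdr3:
    def test_frame_residues(self):
        rng = np.random.default_rng(0)
        draws = [t.sample_cdr3(fixed_length(13), rng) for _ in range(500)]
        assert all(s[0] == "C" and s[-1] == "F" and len(s) == 13 for s in draws)

    def test_forced_motif_inside_protected_interior(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            s = t.sample_cdr3(fixed_length(13), rng, forced_motif="QGA")
            pos = s.find("QGA")
            assert 3 <= pos <= len(s) - 3 - 3
            assert s[0] == "C" and s[-1] == "F"

    def test_short_lengths_resampled_to_floor(self):
        lengths = iter([6, 5, 7, 11])
        rng = np.random.default_rng(2)
        s = t.sample_cdr3(lambda r: next(lengths), rng)
        assert len(s) == 11

    def test_motif_longer_than_interior_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(t.ConfigError):
            t.sample_cdr3(fixed_length(8), rng, forced_motif="QGAWQGA")

    def test_batch_obeys_frame_and_motif(self):
        rng = np.random.default_rng(4)
        batch = _sample_cdr3_batch(2000, rng, 14.5, 1.5, forced_motif="WQHY")
        assert all(s[0] == "C" and s[-1] == "F" for s in batch)
        assert all("WQHY" in s[3:-3] for s in batch)


class TestGenerateRepertoire:
    CFG = t.CohortConfig(
        n_per_group={"GVHD": 1},
        richness={"GVHD": 100},
        total_reads=10_000,
        motif_spike_fraction=0.0,
        planted_cdr3s=(),
    )

    def test_richness_and_depth_bookkeeping(self):
        rep = t.generate_repertoire(self.CFG, "GVHD", "GVHD_01")
        assert rep.richness == 100
        assert abs(rep.total_reads - 10_000) <= 100

    def test_same_seed_reproduces_exactly(self):
        a = t.generate_repertoire(self.CFG, "GVHD", "GVHD_01")
        b = t.generate_repertoire(self.CFG, "GVHD", "GVHD_01")
        assert t.repertoire.equal_repertoires(a, b)

    def test_uniform_exponent_gives_isi_near_richness(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 1},
            richness={"GVHD": 200},
            clone_size_exponent=0.0,
            total_reads=20_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
        )
        rep = t.generate_repertoire(cfg, "GVHD", "GVHD_01")
        # equal counts up to rounding: ISI == richness exactly
        assert t.inverse_simpson(rep) == pytest.approx(200, rel=1e-6)

    def test_infeasible_depth_raises(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 1},
            richness={"GVHD": 5_000},
            clone_size_exponent=2.0,
            total_reads=10_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
        )
        with pytest.raises(t.ConfigError, match="zero reads"):
            t.generate_repertoire(cfg, "GVHD", "GVHD_01")

    def test_spiked_groups_carry_panel_and_planted_clones(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 1, "NO_GVHD": 1},
            richness={"GVHD": 400, "NO_GVHD": 400},
            total_reads=40_000,
            motif_spike_fraction=0.05,
        )
        gv = t.generate_repertoire(cfg, "GVHD", "GVHD_01")
        ng = t.generate_repertoire(cfg, "NO_GVHD", "NO_GVHD_01")
        n_spiked = sum(
            any(m in c[3:-3] for m in cfg.motif_panel)
            for c in gv.clonotypes["cdr3_aa"]
        )
        expected = round(0.05 * (400 - len(cfg.planted_cdr3s)))
        assert n_spiked >= expected  # spiked plus chance hits
        assert set(cfg.planted_cdr3s) <= set(gv.clonotypes["cdr3_aa"])
        assert not (set(cfg.planted_cdr3s) & set(ng.clonotypes["cdr3_aa"]))


class TestGenerateCohort:
    def test_default_group_sizes_match_study_design(self):
        cfg = t.CohortConfig(
            richness={"GVHD": 60, "NO_GVHD": 60, "HI": 60, "GVHD_PRE": 60},
            total_reads=4_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
        )
        cohort = t.generate_cohort(cfg)
        by_group = {}
        for r in cohort:
            by_group[r.group] = by_group.get(r.group, 0) + 1
        assert by_group == {"GVHD": 15, "NO_GVHD": 13, "HI": 15, "GVHD_PRE": 3}

    def test_adding_a_subject_never_perturbs_others(self):
        base = dict(
            richness={"GVHD": 80, "NO_GVHD": 80},
            total_reads=5_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
            seed=9,
        )
        small = t.generate_cohort(
            t.CohortConfig(n_per_group={"GVHD": 2, "NO_GVHD": 2}, **base)
        )
        big = t.generate_cohort(
            t.CohortConfig(n_per_group={"GVHD": 3, "NO_GVHD": 2}, **base)
        )
        big_by_id = {r.sample_id: r for r in big}
        for rep in small:
            assert t.repertoire.equal_repertoires(rep, big_by_id[rep.sample_id])

    def test_distinct_master_seeds_share_almost_nothing(self):
        base = dict(
            n_per_group={"GVHD": 1},
            richness={"GVHD": 2_000},
            total_reads=100_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
        )
        a = t.generate_cohort(t.CohortConfig(seed=1, **base))[0]
        b = t.generate_cohort(t.CohortConfig(seed=2, **base))[0]
        overlap = set(a.clonotypes["cdr3_aa"]) & set(b.clonotypes["cdr3_aa"])
        assert len(overlap) / 2_000 < 0.01


class TestStageDynamics:
    CFG = t.CohortConfig(
        n_per_group={"GVHD": 1},
        richness={"GVHD": 300},
        total_reads=30_000,
        motif_spike_fraction=0.0,
        planted_cdr3s=(),
        stage_dynamics={
            (1, 0): StageTransition(),  # identity
            (1, 2): StageTransition(dominant_fold=0.0, dominant_top_n=20),
        },
    )

    def test_identity_transition_is_exact(self):
        rep = t.generate_repertoire(self.CFG, "GVHD", "GVHD_01", stage=1)
        out = t.apply_stage_dynamics(rep, 1, 0, self.CFG, np.random.default_rng(0))
        assert t.repertoire.equal_repertoires(
            out, t.repertoire.Repertoire(
                sample_id=out.sample_id, clonotypes=rep.clonotypes,
                subject_id=rep.subject_id, group=rep.group, stage=0)
        )

    def test_zero_fold_extinguishes_dominants(self):
        rep = t.generate_repertoire(self.CFG, "GVHD", "GVHD_01", stage=1)
        top20 = set(t.top_n_clonotypes(rep, 20))
        out = t.apply_stage_dynamics(rep, 1, 2, self.CFG, np.random.default_rng(0))
        assert not (top20 & set(out.keys()))

    def test_negative_fold_rejected(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 1},
            richness={"GVHD": 50},
            total_reads=2_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
            stage_dynamics={(1, 2): StageTransition(dominant_fold=-1.0)},
        )
        rep = t.generate_repertoire(cfg, "GVHD", "GVHD_01", stage=1)
        with pytest.raises(t.ConfigError):
            t.apply_stage_dynamics(rep, 1, 2, cfg, np.random.default_rng(0))

    def test_default_resolution_contracts_diversity(self):
        cfg = t.CohortConfig(
            n_per_group={"GVHD": 1},
            richness={"GVHD": 1_000},
            total_reads=60_000,
            motif_spike_fraction=0.0,
            planted_cdr3s=(),
            stages_per_group={"GVHD": (0, 1, 2)},
            seed=11,
        )
        stages = {r.stage: r for r in t.generate_cohort(cfg)}
        assert t.inverse_simpson(stages[2]) < t.inverse_simpson(stages[1])


class TestReference:
    def test_reference_is_motif_free_and_unit_counts(self):
        ref = t.generate_reference(3_000, seed=5)
        assert ref.richness == 3_000
        assert (ref.clonotypes["count"] == 1).all()
        panel_hits = sum(
            any(m in c for m in t.CohortConfig().motif_panel)
            for c in ref.clonotypes["cdr3_aa"]
        )
        assert panel_hits <= 2  # rare-letter motifs essentially absent

    def test_subject_seed_is_stable(self):
        a = subject_seed(7, "GVHD/GVHD_01").generate_state(4)
        b = subject_seed(7, "GVHD/GVHD_01").generate_state(4)
        assert (a == b).all()
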