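"""Superposition, boundary splicing, replication and ablation."""

import numpy as np
import pytest

import oracles
from cofilsev import geometry_analysis as ga
from cofilsev import synthetic_data as syn
from cofilsev.boundary_builder import (
    ablate_cofilins,
    cofilin_clusters,
    replicate_longitudinal,
    splice_boundary,
    superpose,
)
from cofilsev.errors import InputError, NumericalError, TopologyError


class TestSuperpose:
    def test_identity_when_mobile_equals_reference(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        t = superpose(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, 0.0, atol=1e-10)
        assert t.rmsd_after == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(40, 3))
        rot0, shift = oracles.random_rigid_transform(rng)
        mobile = ref @ rot0.T + shift
        t = superpose(mobile, ref)
        assert np.allclose(t.rotation, rot0.T, atol=1e-8)
        assert t.rmsd_after == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(t.apply(mobile), ref, atol=1e-8)

    def test_rotation_is_always_proper(self):
        # near-planar cloud plus its mirror image tempts an improper solution
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(25, 3)) * np.array([1.0, 1.0, 0.05])
        mobile = ref * np.array([1.0, 1.0, -1.0])
        t = superpose(mobile, ref)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_random_clouds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ref = rng.normal(scale=10.0, size=(50, 3))
            mobile = ref + rng.normal(scale=1.0, size=(50, 3))
            rot, shift = oracles.random_rigid_transform(rng)
            mobile = mobile @ rot.T + shift
            ours = superpose(mobile, ref).rmsd_after
            theirs = oracles.quaternion_superposition_rmsd(mobile, ref)
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_size_mismatch_and_degenerate_inputs(self):
        rng = np.random.default_rng(3)
        with pytest.raises(InputError):
            superpose(rng.normal(size=(10, 3)), rng.normal(size=(11, 3)))
        line = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(NumericalError):
            superpose(line, line)


class TestSpliceBoundary:
    @pytest.mark.parametrize("mode", ["slow", "fast"])
    def test_eighteen_actins_eight_cofilins(self, bare10, cofilactin12, mode):
        out = splice_boundary(bare10, cofilactin12, mode)
        assert len(out.actins) == 18
        assert len(out.cofilins) == 8
        assert out.positions == list(range(-8, 10))
        assert out.interfacial_index == 0

    @pytest.mark.parametrize("mode", ["slow", "fast"])
    def test_interfacial_subunits_touch_exactly_one_cofilin(
        self, bare10, cofilactin12, mode
    ):
        out = splice_boundary(bare10, cofilactin12, mode)
        assert len(out.cofilins_touching(0)) == 1
        assert len(out.cofilins_touching(1)) == 1

    def test_occupancy_sides_mirror_between_modes(self, slow_model, fast_model):
        assert all(k >= 0 for k in slow_model.cofilins)   # cluster on pointed side
        assert all(k < 0 for k in fast_model.cofilins)    # cluster on barbed side

    def test_cofilin_retention_rule(self, slow_model, fast_model):
        for out in (slow_model, fast_model):
            for k in out.cofilins:
                assert out.has_position(k) and out.has_position(k + 2)

    def test_slow_alignment_continuity(self, bare10, cofilactin12):
        # the aligned junction must not tear the filament apart
        out = splice_boundary(bare10, cofilactin12, "slow")
        integ = ga.interface_integrity(out, 0)
        assert not integ.ruptured.any()

    def test_fast_mode_flagged_for_relaxation(self, fast_model, slow_model):
        assert fast_model.boundary.requires_relaxation
        assert not slow_model.boundary.requires_relaxation

    def test_fast_alt_keeps_cofilins_bridging_into_bare(self, bare10, cofilactin12):
        out = splice_boundary(bare10, cofilactin12, "fast_alt")
        assert len(out.actins) == 18
        assert len(out.cofilins_touching(0)) == 1
        assert len(out.cofilins_touching(1)) == 1

    def test_too_short_inputs_rejected(self, cofilactin12):
        short = syn.make_bare_filament(5)
        with pytest.raises(TopologyError, match="at least"):
            splice_boundary(short, cofilactin12, "slow")
        short_cof = syn.make_cofilactin_filament(11)
        bare = syn.make_bare_filament(10)
        with pytest.raises(TopologyError, match="12"):
            splice_boundary(bare, short_cof, "fast")

    def test_cofilactin_without_occupancy_rejected(self, bare10):
        naked = syn.make_bare_filament(12)
        with pytest.raises(TopologyError, match="occupancy"):
            splice_boundary(bare10, naked, "slow")


class TestReplicateLongitudinal:
    def test_one_repeat_doubles_the_decorated_filament(self, cofilactin11):
        out = replicate_longitudinal(cofilactin11, 1)
        assert len(out.actins) == 22
        assert len(out.cofilins) == 20

    def test_zero_times_is_identity(self, cofilactin11):
        out = replicate_longitudinal(cofilactin11, 0)
        assert out.positions == cofilactin11.positions
        assert np.array_equal(
            out.subunit(3).coords, cofilactin11.subunit(3).coords
        )

    def test_junction_twist_matches_interior(self, cofilactin11):
        out = replicate_longitudinal(cofilactin11, 1)
        prof = ga.twist_profile(out)
        assert np.abs(prof.position_mean - 162.0).max() < 1e-6

    def test_aperiodic_input_rejected(self, slow_model):
        with pytest.raises(TopologyError, match="non-periodic"):
            replicate_longitudinal(slow_model, 1)


class TestAblateCofilins:
    def test_keep_empty_removes_all_and_preserves_actin(self, cofilactin11):
        out = ablate_cofilins(cofilactin11, set())
        assert len(out.cofilins) == 0
        for n in cofilactin11.positions:
            assert np.array_equal(
                out.subunit(n).coords, cofilactin11.subunit(n).coords
            )

    def test_keep_full_set_is_identity(self, cofilactin11):
        out = ablate_cofilins(cofilactin11, set(cofilactin11.cofilins))
        assert sorted(out.cofilins) == sorted(cofilactin11.cofilins)

    def test_longitudinal_and_lateral_pairs_form_single_clusters(self, cofilactin11):
        rep = replicate_longitudinal(cofilactin11, 1)
        longi = ablate_cofilins(rep, {5, 7})
        assert cofilin_clusters(longi) == [{5, 7}]
        lat = ablate_cofilins(rep, {5, 6})
        assert cofilin_clusters(lat) == [{5, 6}]
        split = ablate_cofilins(rep, {2, 9})
        assert cofilin_clusters(split) == [{2}, {9}]

    def test_keep_referencing_absent_cofilin_rejected(self, cofilactin11):
        with pytest.raises(TopologyError):
            ablate_cofilins(cofilactin11, {99})
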