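"""Observable estimators: twist, flatness/cleft, contacts, RMSD, stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from cofilsev import geometry_analysis as ga
from cofilsev import synthetic_data as syn
from cofilsev.errors import ConfigurationError, DomainError, InputError
from cofilsev.filament_model import ContactSpec, FilamentSystem, HelicalParams, Subunit


def _apply_rigid(system, rot, shift):
    out = system.copy()
    for sub in out.actins:
        sub.coords = sub.coords @ rot.T + shift
    for rec in out.cofilins.values():
        rec.coords = rec.coords @ rot.T + shift
    return out


class TestTwistProfile:
    def test_uniform_filament_value_stored_per_pair(self, bare18):
        prof = ga.twist_profile(bare18)
        assert list(prof.positions) == list(range(17))
        assert np.allclose(prof.values, 167.0, atol=1e-6)

    def test_identical_untransformed_subunits_give_zero(self):
        t = syn.bare_template(seed=0)
        system = FilamentSystem(
            actins=[Subunit(0, t, t.ca_coords), Subunit(1, t, t.ca_coords)]
        )
        assert ga.twist_profile(system).values[0, 0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("alpha", [10.0, 90.0, 162.0, 179.0])
    def test_known_rotation_angle_recovered(self, alpha):
        f = syn.make_bare_filament(2, helical=HelicalParams(alpha, 27.5))
        assert ga.twist_profile(f).values[0, 0] == pytest.approx(alpha, abs=1e-8)

    def test_projection_method_agrees_on_ideal_filament(self, bare18):
        prof = ga.twist_profile(bare18, method="projection")
        # azimuthal increment of 167 deg wraps to |delta| = 167
        assert np.allclose(prof.values, 167.0, atol=1e-6)

    def test_unknown_method_rejected(self, bare18):
        with pytest.raises(ConfigurationError):
            ga.twist_profile(bare18, method="euler")


class TestFlatnessAndCleft:
    def test_generator_round_trip(self):
        t = syn.make_subunit_template(-29.0, 25.0, seed=7)
        system = FilamentSystem(actins=[Subunit(0, t, t.ca_coords)])
        rec = ga.flatness_and_cleft(system, 0, 0)
        assert rec.phi == pytest.approx(-29.0, abs=1e-6)
        assert rec.d == pytest.approx(25.0, abs=1e-6)

    def test_mirror_negates_phi_preserves_d(self, bare18):
        mirrored = bare18.copy()
        for sub in mirrored.actins:
            sub.coords = sub.coords * np.array([1.0, 1.0, -1.0])
        a = ga.flatness_and_cleft(bare18, 0, 4)
        b = ga.flatness_and_cleft(mirrored, 0, 4)
        assert b.phi == pytest.approx(-a.phi, abs=1e-8)
        assert b.d == pytest.approx(a.d, abs=1e-8)

    def test_cofilin_subunit_is_domain_error(self, cofilactin11):
        rec = cofilactin11.cofilins[0]
        system = FilamentSystem(actins=[Subunit(0, rec.template, rec.coords)])
        with pytest.raises(DomainError):
            ga.flatness_and_cleft(system, 0, 0)

    def test_phi_profile_separates_conformations(self, bare18, cofilactin11):
        assert np.allclose(ga.phi_profile(bare18).values, -9.0, atol=1e-6)
        assert np.allclose(ga.phi_profile(cofilactin11).values, -28.9, atol=1e-6)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_dihedral_chirality_flips_under_mirror(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=5.0, size=(4, 3))
    try:
        phi = ga.signed_dihedral(*pts)
    except DomainError:
        return  # degenerate draw
    mirrored = pts * np.array([1.0, -1.0, 1.0])
    assert ga.signed_dihedral(*mirrored) == pytest.approx(-phi, abs=1e-8)


class TestContacts:
    def test_counts_match_brute_force_oracle_on_random_systems(self, bare10):
        sub_a, sub_b = bare10.subunit(0), bare10.subunit(2)
        spec = ContactSpec(selection_a="all", selection_b="all", cutoff=10.0)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 30, size=(30, 3))
            b = rng.uniform(0, 30, size=(40, 3))
            sys_rand = FilamentSystem(
                actins=[
                    Subunit(0, sub_a.template, _pad(a, sub_a)),
                    Subunit(1, sub_a.template, _pad(a, sub_a)),
                    Subunit(2, sub_b.template, _pad(b, sub_b)),
                ]
            )
            ours = ga.contact_count(sys_rand, 0, (0, 2), spec)
            theirs = oracles.brute_force_contacts(
                sys_rand.subunit(0).coords[0], sys_rand.subunit(2).coords[0], 10.0
            )
            assert ours == theirs

    def test_all_within_and_all_beyond_cutoff(self, bare10):
        tight = ContactSpec(selection_a="dloop", selection_b="all", cutoff=1e6)
        assert ga.contact_count(bare10, 0, (0, 2), tight) == 9 * 375
        none = ContactSpec(selection_a="dloop", selection_b="all", cutoff=1e-6)
        assert ga.contact_count(bare10, 0, (0, 2), none) == 0

    def test_dloop_profile_positive_and_uniform_on_bare(self, bare18):
        prof = ga.dloop_contact_profile(bare18)
        assert (prof.counts > 0).all()
        assert np.ptp(prof.counts) == 0  # helical symmetry: identical everywhere

    def test_dloop_profile_zero_on_retracted_dloops(self, cofilactin11):
        prof = ga.dloop_contact_profile(cofilactin11)
        assert (prof.counts == 0).all()

    def test_profile_consistent_with_per_pair_calls(self, bare18):
        prof = ga.dloop_contact_profile(bare18)
        for j, n in enumerate(prof.positions):
            assert prof.counts[0, j] == ga.contact_count(
                bare18, 0, (n, n + 2), ContactSpec()
            )


def _pad(points, sub):
    """Embed a small point cloud into a full-size subunit coordinate array."""
    coords = sub.coords[0].copy()
    coords[: len(points)] = points
    coords[len(points):] += 1e6  # park the rest far away
    return coords[None]


class TestInterfaceIntegrity:
    def test_intact_ideal_filament_has_no_ruptures(self, bare18, cofilactin11):
        for system in (bare18, cofilactin11):
            integ = ga.interface_integrity(system, 0)
            assert not integ.ruptured.any()
            assert (integ.n_contacts > 0).all()

    def test_translated_half_flags_exactly_junction_interfaces(self, bare18):
        broken = bare18.copy()
        for sub in broken.actins:
            if sub.position >= 9:
                sub.coords = sub.coords + np.array([500.0, 0.0, 0.0])
        integ = ga.interface_integrity(broken, 0)
        flagged = set(integ.loc[integ.ruptured, "n_barbed"])
        assert flagged == {7, 8}  # pairs (7,9) and (8,10) straddle the break

    def test_counts_equal_brute_force(self, cofilactin11):
        integ = ga.interface_integrity(cofilactin11, 0)
        row = integ.iloc[3]
        expect = oracles.brute_force_contacts(
            cofilactin11.subunit(int(row.n_barbed)).coords[0],
            cofilactin11.subunit(int(row.n_pointed)).coords[0],
            10.0,
        )
        assert row.n_contacts == expect


class TestRmsdSeries:
    def test_reference_frame_gives_zero_at_itself(self):
        f = syn.make_bare_filament(5, noise=syn.NoiseModel(0.3, 4, seed=2))
        series = ga.rmsd_series(f, [1, 2, 3], reference=0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-10)
        assert (series.values[1:] > 0).all()

    def test_rigid_motion_yields_zero_everywhere(self, bare10):
        rng = np.random.default_rng(4)
        rot, shift = oracles.random_rigid_transform(rng)
        frames = np.stack([bare10.subunit(0).coords[0],
                           bare10.subunit(0).coords[0] @ rot.T + shift])
        system = FilamentSystem(
            actins=[Subunit(0, bare10.subunit(0).template, frames)]
        )
        series = ga.rmsd_series(system, [0], reference=0)
        assert np.allclose(series.values, 0.0, atol=1e-8)

    def test_single_displaced_atom_bound(self):
        f = syn.make_bare_filament(3)
        coords = np.repeat(f.subunit(0).coords, 2, axis=0).copy()
        delta = 0.5
        coords[1, 10, 0] += delta
        system = FilamentSystem(actins=[Subunit(0, f.subunit(0).template, coords)])
        series = ga.rmsd_series(system, [0], reference=0)
        n_atoms = coords.shape[1]
        assert series.values[1] <= delta / np.sqrt(n_atoms) + 1e-12

    def test_mismatched_reference_rejected(self, bare10, cofilactin11):
        with pytest.raises(InputError):
            # reference lacks position 10
            ga.rmsd_series(cofilactin11, [10], reference=bare10)
        with pytest.raises(InputError):
            ga.rmsd_series(bare10, [], reference=0)


class TestPerPositionStats:
    def test_hand_computed_mean_and_population_sd(self):
        prof = ga.AngleProfile("x", [0], np.array([[1.0], [2.0], [3.0]]))
        stats = ga.per_position_stats(prof, last_k=3)
        assert stats["mean"].iloc[0] == pytest.approx(2.0)
        assert stats["sd"].iloc[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_frames_have_zero_sd(self):
        prof = ga.AngleProfile("x", [0, 1], np.full((5, 2), 7.0))
        assert (ga.per_position_stats(prof, 5)["sd"] == 0).all()

    def test_full_window_equals_whole_series(self):
        rng = np.random.default_rng(0)
        prof = ga.AngleProfile("x", [0, 1], rng.normal(size=(6, 2)))
        stats = ga.per_position_stats(prof, last_k=6)
        assert np.allclose(stats["mean"], prof.position_mean)
        assert np.allclose(stats["sd"], prof.position_sd)

    def test_invalid_window_rejected(self):
        prof = ga.AngleProfile("x", [0], np.zeros((3, 1)))
        with pytest.raises(ConfigurationError):
            ga.per_position_stats(prof, 0)
        with pytest.raises(ConfigurationError):
            ga.per_position_stats(prof, 4)


class TestRigidInvariance:
    def test_all_observables_invariant_under_global_motion(self, cofilactin11):
        rng = np.random.default_rng(12)
        rot, shift = oracles.random_rigid_transform(rng)
        moved = _apply_rigid(cofilactin11, rot, shift)

        twist0 = ga.twist_profile(cofilactin11).values
        twist1 = ga.twist_profile(moved).values
        assert np.allclose(twist0, twist1, atol=1e-8)

        rec0 = ga.flatness_and_cleft(cofilactin11, 0, 5)
        rec1 = ga.flatness_and_cleft(moved, 0, 5)
        assert rec1.phi == pytest.approx(rec0.phi, abs=1e-8)
        assert rec1.d == pytest.approx(rec0.d, abs=1e-8)

        c0 = ga.dloop_contact_profile(cofilactin11).counts
        c1 = ga.dloop_contact_profile(moved).counts
        assert np.array_equal(c0, c1)

        i0 = ga.interface_integrity(cofilactin11, 0).n_contacts
        i1 = ga.interface_integrity(moved, 0).n_contacts
        assert np.array_equal(i0.to_numpy(), i1.to_numpy())

    def test_noisy_mean_twist_recovers_prescription_within_3se(self):
        f = syn.make_bare_filament(18, noise=syn.NoiseModel(0.5, 200, seed=1))
        prof = ga.twist_profile(f)
        se = prof.position_sd / np.sqrt(prof.n_frames)
        assert (np.abs(prof.position_mean - 167.0) < 3.0 * se).all()
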