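import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from swellmd import md_geometry as md
from swellmd import synthetic_data as sd


def random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-10, 10, 3)
    return rot, trans


def make_traj(reference, frames):
    return md.Trajectory(topology=reference, frames=np.asarray(frames, dtype=float))


@pytest.fixture
def chain20_sites():
    return sd.generate_reference_structure(20, with_sidechain_sites=True)


class TestSelection:
    def test_parse_and_resolve(self, chain20_sites):
        idx = chain20_sites.select("name CA and resid 5-8")
        assert len(idx) == 4
        np.testing.assert_array_equal(chain20_sites.resids[idx], [5, 6, 7, 8])

    def test_comma_lists(self, chain20_sites):
        idx = chain20_sites.select("resid 1,3,10-12 and name CA")
        assert len(idx) == 5

    def test_chain_filter(self, chain20_sites):
        assert len(chain20_sites.select("chain A and name CA")) == 20
        with pytest.raises(md.SelectionError):
            chain20_sites.select("chain B")

    def test_empty_selection_raises(self, chain20_sites):
        with pytest.raises(md.SelectionError):
            chain20_sites.select("name XX")

    def test_unknown_keyword(self):
        with pytest.raises(md.SelectionError):
            md.parse_selection("foo bar")

    def test_span_residue_count(self):
        assert md.span_residue_count(818, 834) == 17
        assert md.span_residue_count(630, 856) == 227
        assert md.span_residue_count(5, 5) == 1
        with pytest.raises(ValueError):
            md.span_residue_count(10, 9)


class TestSuperpose:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3)) * 5
        moved, rmsd = md.superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved, coords, atol=1e-9)

    def test_rigid_invariance(self, rng):
        ref = rng.normal(size=(15, 3)) * 5
        rot, trans = random_rigid(rng)
        mobile = ref @ rot.T + trans
        moved, rmsd = md.superpose(mobile, ref)
        assert rmsd < 1e-6
        np.testing.assert_allclose(moved, ref, atol=1e-6)

    def test_matches_scipy_align_vectors_oracle(self, rng):
        # independent route: scipy's Kabsch implementation
        for _ in range(5):
            a = rng.normal(size=(8, 3)) * 4
            b = rng.normal(size=(8, 3)) * 4
            _, rmsd = md.superpose(a, b)
            rot, rssd = Rotation.align_vectors(
                b - b.mean(axis=0), a - a.mean(axis=0)
            )
            assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_beats_rotation_grid_oracle(self, rng):
        # no rotation on a coarse SO(3) grid does better than the closed form
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        _, best = md.superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        grid = np.deg2rad(np.arange(0, 360, 12))
        half = np.deg2rad(np.arange(0, 181, 12))
        found = np.inf
        for z1, x, z2 in itertools.product(grid, half, grid):
            rot = Rotation.from_euler("zxz", [z1, x, z2]).as_matrix()
            d = ac @ rot.T - bc
            found = min(found, np.sqrt(np.mean(np.sum(d * d, axis=1))))
        assert best <= found + 1e-9
        assert found - best < 0.05  # the grid approaches the optimum

    def test_no_reflection(self):
        # mirrored coordinates cannot be matched by a proper rotation
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirrored = ref * np.array([1, 1, -1])
        _, rmsd = md.superpose(mirrored, ref)
        assert rmsd > 0.1

    def test_too_few_atoms(self):
        with pytest.raises(md.FitError):
            md.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        with pytest.raises(md.FitError):
            md.superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_static_zero(self, chain10):
        traj = make_traj(chain10, np.repeat(chain10.coords[None], 4, axis=0))
        np.testing.assert_allclose(
            md.rmsd_series(traj, chain10, fit=False), 0.0, atol=1e-9
        )

    def test_static_zero_with_fit(self):
        ref = sd.generate_reference_structure(10, with_sidechain_sites=True)
        traj = make_traj(ref, np.repeat(ref.coords[None], 4, axis=0))
        series = md.rmsd_series(traj, ref, selection="name CA,NZ,OE1", fit=True)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_translation_norm_without_fit(self, chain10):
        shifted = chain10.coords + np.array([1.0, 2.0, 2.0])
        traj = make_traj(chain10, np.repeat(shifted[None], 3, axis=0))
        series = md.rmsd_series(traj, chain10, fit=False)
        np.testing.assert_allclose(series, 3.0, atol=1e-12)

    def test_translation_removed_by_fit(self, chain10):
        # collinear CA chain cannot be fitted; use a 3-D scaffold
        ref = sd.generate_reference_structure(10, with_sidechain_sites=True)
        shifted = ref.coords + np.array([1.0, 2.0, 2.0])
        traj = make_traj(ref, np.repeat(shifted[None], 3, axis=0))
        series = md.rmsd_series(traj, ref, selection="name CA,NZ,OE1", fit=True)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_fit_never_worse_than_no_fit(self, rng):
        ref = sd.generate_reference_structure(12, with_sidechain_sites=True)
        spec = sd.FluctuationSpec(
            n_frames=10, per_residue_sigma=rng.uniform(0.1, 0.8, 12),
            rigid_translation_per_frame=(0.3, 0.0, 0.1), seed=3,
        )
        traj = sd.generate_trajectory(ref, spec)
        sel = "name CA,NZ,OE1"
        with_fit = md.rmsd_series(traj, ref, selection=sel, fit=True)
        without = md.rmsd_series(traj, ref, selection=sel, fit=False)
        assert (with_fit <= without + 1e-9).all()

    def test_brute_force_agreement(self, rng, chain10):
        frames = chain10.coords[None] + rng.normal(size=(6, 10, 3))
        traj = make_traj(chain10, frames)
        series = md.rmsd_series(traj, chain10, fit=False)
        for f in range(6):
            acc = 0.0
            for i in range(10):
                d = frames[f, i] - chain10.coords[i]
                acc += d @ d
            assert series[f] == pytest.approx(np.sqrt(acc / 10), abs=1e-6)


class TestResidueRmsd:
    def test_static_zero(self, chain10):
        traj = make_traj(chain10, np.repeat(chain10.coords[None], 3, axis=0))
        prof = md.residue_rmsd(traj, chain10, fit=False)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)
        np.testing.assert_array_equal(prof.residue_ids, chain10.resids)

    def test_single_displaced_residue(self):
        ref = sd.generate_reference_structure(10, with_sidechain_sites=True)
        coords = ref.coords.copy()
        moved = coords.copy()
        moved[ref.resids == 5] += np.array([0.0, 2.0, 0.0])
        traj = make_traj(ref, np.repeat(moved[None], 4, axis=0))
        prof = md.residue_rmsd(
            traj, ref, selection="name CA",
            fit_selection="name CA,NZ,OE1 and resid 1-4,6-10",
        )
        vals = dict(zip(prof.residue_ids.tolist(), prof.values))
        assert vals[5] == pytest.approx(2.0, abs=0.05)
        others = [v for k, v in vals.items() if k != 5]
        assert max(others) < 0.05

    def test_profile_rms_equals_series_rms(self, rng):
        ref = sd.generate_reference_structure(8, with_sidechain_sites=True)
        spec = sd.FluctuationSpec(
            n_frames=25, per_residue_sigma=rng.uniform(0.1, 0.6, 8), seed=9
        )
        traj = sd.generate_trajectory(ref, spec)
        prof = md.residue_rmsd(traj, ref, selection="name CA",
                               fit_selection="name CA,NZ,OE1")
        series = md.rmsd_series(traj, ref, selection="name CA", fit=True,
                                fit_selection="name CA,NZ,OE1")
        assert np.sqrt(np.mean(prof.values**2)) == pytest.approx(
            np.sqrt(np.mean(series**2)), abs=1e-9
        )

    def test_window_error(self, chain10):
        traj = make_traj(chain10, np.repeat(chain10.coords[None], 3, axis=0))
        with pytest.raises(md.WindowError):
            md.residue_rmsd(traj, chain10, window=(0, 10), fit=False)


class TestRmsf:
    def test_static_zero_both_modes(self, chain10):
        traj = make_traj(chain10, np.repeat(chain10.coords[None], 3, axis=0))
        for mode in ("reference", "mean"):
            prof = md.rmsf(traj, chain10, mode=mode, fit=False)
            np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_sigma_recovery_both_modes(self, chain10):
        spec = sd.FluctuationSpec(
            n_frames=20_000, per_residue_sigma=np.full(10, 0.5), seed=42
        )
        traj = sd.generate_trajectory(chain10, spec)
        expected = 0.5 * np.sqrt(3.0)
        for mode in ("reference", "mean"):
            prof = md.rmsf(traj, chain10, mode=mode, fit=False)
            np.testing.assert_allclose(prof.values, expected, rtol=0.02)

    def test_constant_offset_distinguishes_modes(self, chain10):
        offset = chain10.coords + np.array([1.0, 0.0, 0.0])
        traj = make_traj(chain10, np.repeat(offset[None], 5, axis=0))
        ref_mode = md.rmsf(traj, chain10, mode="reference", fit=False)
        mean_mode = md.rmsf(traj, chain10, mode="mean", fit=False)
        np.testing.assert_allclose(ref_mode.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(mean_mode.values, 0.0, atol=1e-9)

    def test_unknown_mode(self, chain10):
        traj = make_traj(chain10, chain10.coords[None])
        with pytest.raises(ValueError, match="mode"):
            md.rmsf(traj, chain10, mode="median")


class TestRigidInvariance:
    def test_rmsd_profile_invariant_under_global_motion(self, rng):
        ref = sd.generate_reference_structure(12, with_sidechain_sites=True)
        spec = sd.FluctuationSpec(
            n_frames=12, per_residue_sigma=rng.uniform(0.05, 0.5, 12), seed=17
        )
        traj = sd.generate_trajectory(ref, spec)
        rot, trans = random_rigid(rng)
        moved = make_traj(ref, traj.frames @ rot.T + trans)
        sel, fit_sel = "name CA", "name CA,NZ,OE1"
        a = md.rmsd_series(traj, ref, selection=sel, fit=True, fit_selection=fit_sel)
        b = md.rmsd_series(moved, ref, selection=sel, fit=True, fit_selection=fit_sel)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestMinDistance:
    def test_two_fixed_atoms(self, chain20_sites):
        frames = np.repeat(chain20_sites.coords[None], 3, axis=0)
        traj = make_traj(chain20_sites, frames)
        # CA(1) and CA(2) are 3.8 A apart by construction
        ds = md.min_distance_series(traj, "resid 1 and name CA", "resid 2 and name CA")
        np.testing.assert_allclose(ds.values, 3.8, atol=1e-12)

    def test_matches_brute_force(self, rng):
        ref = sd.generate_reference_structure(35, with_sidechain_sites=True)
        frames = ref.coords[None] + rng.normal(size=(50, ref.n_atoms, 3)) * 2
        traj = make_traj(ref, frames)
        sel_a, sel_b = "resid 1-20 and name NZ", "resid 21-35 and name OE1"
        ia, ib = ref.select(sel_a), ref.select(sel_b)
        ds = md.min_distance_series(traj, sel_a, sel_b)
        for f in range(50):
            best = min(
                np.linalg.norm(frames[f, i] - frames[f, j])
                for i in ia for j in ib
            )
            assert ds.values[f] == pytest.approx(best, abs=1e-9)

    def test_shared_atom_raises(self, chain20_sites):
        with pytest.raises(md.SelectionError):
            md.min_distance_series(chain20_sites and make_traj(
                chain20_sites, chain20_sites.coords[None]
            ), "resid 1-5", "resid 5-8")

    def test_summary_over_trailing_window(self, chain20_sites):
        frames = np.repeat(chain20_sites.coords[None], 10, axis=0)
        frames[:5] += 100.0  # first half displaced together: same distances
        traj = make_traj(chain20_sites, frames)
        ds = md.min_distance_series(
            traj, "resid 1 and name CA", "resid 2 and name CA",
            summary_window=(5, 10),
        )
        assert ds.summary_mean == pytest.approx(3.8)
        assert ds.summary_sd == pytest.approx(0.0, abs=1e-12)


class TestSaltBridge:
    def _bridge_traj(self, distances):
        ref = sd.generate_reference_structure(2, spacing=10.0,
                                              with_sidechain_sites=True)
        nz = ref.select("resid 1 and name NZ")[0]
        oe = ref.select("resid 2 and name OE1")[0]
        frames = np.repeat(ref.coords[None], len(distances), axis=0)
        for f, d in enumerate(distances):
            frames[f, oe] = frames[f, nz] + np.array([d, 0.0, 0.0])
            # park every other acidic O far away
            other = ref.select("resid 1 and name OE1")[0]
            frames[f, other] = frames[f, nz] + np.array([0.0, 50.0, 0.0])
        return md.Trajectory(topology=ref, frames=frames)

    def test_alternating_half(self):
        traj = self._bridge_traj([3.5, 4.5] * 5)
        assert md.saltbridge_contact_fraction(traj, 1, 2) == pytest.approx(0.5)

    def test_boundary_exactly_4_not_contact(self):
        traj = self._bridge_traj([4.0] * 6)
        assert md.saltbridge_contact_fraction(traj, 1, 2) == 0.0

    def test_constant_contact(self):
        traj = self._bridge_traj([3.0] * 6)
        assert md.saltbridge_contact_fraction(traj, 1, 2) == 1.0

    def test_missing_sidechain_raises(self, chain10):
        traj = make_traj(chain10, chain10.coords[None])
        with pytest.raises(md.SelectionError):
            md.saltbridge_contact_fraction(traj, 1, 2)


class TestMinCalphaDistance:
    def test_span_containing_residue_is_zero(self, chain10):
        assert md.min_calpha_distance(chain10, 5, (1, 10)) == 0.0

    def test_constructed_spacing(self):
        # straight-line geometry: residue 4 to span 6-10 -> 2 * 3.8 A
        line = sd.generate_reference_structure(10, geometry="line")
        assert md.min_calpha_distance(line, 4, (6, 10)) == pytest.approx(7.6)

    def test_unresolved_raises(self, chain10):
        with pytest.raises(md.SelectionError):
            md.min_calpha_distance(chain10, 99, (1, 10))


class TestDataModel:
    def test_frame_atom_count_mismatch(self, chain10):
        with pytest.raises(ValueError):
            md.Trajectory(topology=chain10, frames=np.zeros((2, 5, 3)))

    def test_decreasing_times_rejected(self, chain10):
        with pytest.raises(ValueError):
            md.Trajectory(
                topology=chain10,
                frames=np.zeros((2, 10, 3)),
                frame_times=[1.0, 0.5],
            )

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            md.StructureModel(
                atom_names=["CA"], resids=[1], resnames=["UNK"],
                chains=["A"], coords=np.array([[np.inf, 0, 0]]),
            )
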