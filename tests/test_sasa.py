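import numpy as np
import pytest

import aprshield as a
from aprshield.sasa import expand_apr_mask, sphere_dots, unwrap

R_BEAD = 0.235
R_PROBE = 0.14
R_EXP = R_BEAD + R_PROBE  # 0.375
SPHERE_AREA = 4 * np.pi * R_EXP**2


def protein_frame(coords, radius=R_BEAD):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return a.BeadFrame(
        coordinates=coords,
        radii=np.full(n, radius),
        residue_index=np.arange(1, n + 1),
        molecule_tag=np.full(n, "protein"),
    )


class TestSphereDots:
    def test_unit_norm(self):
        dots = sphere_dots(960)
        np.testing.assert_allclose(np.linalg.norm(dots, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform_moments(self):
        dots = sphere_dots(960)
        assert np.abs(dots.mean(axis=0)).max() < 0.01


class TestShrakeRupley:
    @pytest.mark.parametrize("n_dots", [32, 96, 960, 3840])
    def test_single_bead_analytic(self, n_dots):
        frame = protein_frame([[0.0, 0.0, 0.0]])
        areas = a.shrake_rupley(frame, R_PROBE, n_dots)
        assert areas[0] == pytest.approx(SPHERE_AREA, rel=1e-12)

    def test_two_distant_beads_no_occlusion(self):
        frame = protein_frame([[0, 0, 0], [5.0, 0, 0]])
        areas = a.shrake_rupley(frame, R_PROBE, 960)
        np.testing.assert_allclose(areas, SPHERE_AREA, rtol=1e-12)

    def test_two_sphere_spherical_cap(self):
        d = R_EXP  # centres one expanded radius apart
        frame = protein_frame([[0, 0, 0], [d, 0, 0]])
        closed_form = 2 * (4 * np.pi * R_EXP**2 - 2 * np.pi * R_EXP * (R_EXP - d / 2))
        total = a.shrake_rupley(frame, R_PROBE, 960).sum()
        assert total == pytest.approx(closed_form, rel=0.01)
        high = a.shrake_rupley(frame, R_PROBE, 20000).sum()
        assert total == pytest.approx(high, rel=0.01)

    def test_fully_buried_bead(self):
        # small bead at the centre of a much larger one
        frame = a.BeadFrame(
            coordinates=np.zeros((2, 3)),
            radii=np.array([0.1, 1.0]),
            residue_index=np.array([1, 2]),
            molecule_tag=np.array(["protein", "protein"]),
        )
        areas = a.shrake_rupley(frame, R_PROBE, 960)
        assert areas[0] == 0.0

    def test_occlusion_monotonicity(self, cluster_factory, rng):
        for _ in range(10):
            n = int(rng.integers(5, 21))
            frame = cluster_factory(n)
            base = a.shrake_rupley(frame, R_PROBE, 240)
            extra = a.BeadFrame(
                coordinates=np.vstack([frame.coordinates, rng.normal(scale=0.5, size=3)]),
                radii=np.append(frame.radii, R_BEAD),
                residue_index=np.append(frame.residue_index, n + 1),
                molecule_tag=np.append(frame.molecule_tag, "protein"),
            )
            with_extra = a.shrake_rupley(extra, R_PROBE, 240)
            assert np.all(with_extra[:n] <= base + 1e-12)

    def test_dot_count_convergence(self, cluster_factory):
        frame = cluster_factory(15)
        coarse = a.shrake_rupley(frame, R_PROBE, 960).sum()
        fine = a.shrake_rupley(frame, R_PROBE, 3840).sum()
        assert abs(fine - coarse) / fine <= 0.01

    def test_excipient_occludes_but_contributes_no_area(self):
        # an excipient bead overlapping a protein bead reduces its area
        coords = np.array([[0, 0, 0], [R_EXP, 0, 0.0]])
        frame = a.BeadFrame(
            coordinates=coords,
            radii=np.full(2, R_BEAD),
            residue_index=np.array([1, 1]),
            molecule_tag=np.array(["protein", "excipient"]),
        )
        areas = a.shrake_rupley(frame, R_PROBE, 960)
        assert areas[1] == 0.0  # not part of the surface set
        assert 0 < areas[0] < SPHERE_AREA

    def test_solvent_ions_excluded_by_default(self):
        coords = np.array([[0, 0, 0], [R_EXP, 0, 0.0], [-R_EXP, 0, 0.0]])
        frame = a.BeadFrame(
            coordinates=coords,
            radii=np.full(3, R_BEAD),
            residue_index=np.array([1, 1, 1]),
            molecule_tag=np.array(["protein", "solvent", "ion"]),
        )
        areas = a.shrake_rupley(frame, R_PROBE, 960)
        assert areas[0] == pytest.approx(SPHERE_AREA, rel=1e-12)
        occluded = a.shrake_rupley(frame, R_PROBE, 960, include_solvent_occluders=True)
        assert occluded[0] < SPHERE_AREA

    def test_protein_only_occluders_flag(self):
        coords = np.array([[0, 0, 0], [R_EXP, 0, 0.0]])
        frame = a.BeadFrame(
            coordinates=coords,
            radii=np.full(2, R_BEAD),
            residue_index=np.array([1, 1]),
            molecule_tag=np.array(["protein", "excipient"]),
        )
        areas = a.shrake_rupley(frame, R_PROBE, 960, protein_only_occluders=True)
        assert areas[0] == pytest.approx(SPHERE_AREA, rel=1e-12)

    def test_empty_subset(self, cluster_factory):
        frame = cluster_factory(5)
        areas = a.shrake_rupley(frame, R_PROBE, 960, subset=np.zeros(5, dtype=bool))
        assert np.all(areas == 0)

    def test_low_dot_count_rejected(self, cluster_factory):
        with pytest.raises(ValueError, match="n_dots"):
            a.shrake_rupley(cluster_factory(3), R_PROBE, 16)


class TestBeadFrameValidation:
    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            a.BeadFrame(
                coordinates=np.zeros((1, 3)),
                radii=np.array([0.0]),
                residue_index=np.array([1]),
                molecule_tag=np.array(["protein"]),
            )

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            a.BeadFrame(
                coordinates=np.array([[np.nan, 0, 0]]),
                radii=np.array([1.0]),
                residue_index=np.array([1]),
                molecule_tag=np.array(["protein"]),
            )

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="tags"):
            a.BeadFrame(
                coordinates=np.zeros((1, 3)),
                radii=np.array([1.0]),
                residue_index=np.array([1]),
                molecule_tag=np.array(["lipid"]),
            )


class TestAprSasa:
    def test_mask_all_true_equals_total(self, cluster_factory):
        frame = cluster_factory(10)
        total, apr = a.apr_sasa(frame, np.ones(10, dtype=bool), n_dots=240)
        assert apr == pytest.approx(total)

    def test_mask_all_false_zero(self, cluster_factory):
        frame = cluster_factory(10)
        total, apr = a.apr_sasa(frame, np.zeros(10, dtype=bool), n_dots=240)
        assert apr == 0.0
        assert total > 0

    def test_additivity_against_per_bead_areas(self, cluster_factory, rng):
        frame = cluster_factory(10)
        mask = rng.random(10) < 0.5
        areas = a.shrake_rupley(frame, R_PROBE, 240)
        total, apr = a.apr_sasa(frame, mask, n_dots=240)
        assert total == pytest.approx(areas.sum(), rel=1e-12)
        assert apr == pytest.approx(areas[mask].sum(), rel=1e-12)

    def test_partition_additivity(self, cluster_factory, rng):
        frame = cluster_factory(12)
        labels = rng.integers(0, 3, size=12)
        total, _ = a.apr_sasa(frame, np.ones(12, dtype=bool), n_dots=240)
        parts = [a.apr_sasa(frame, labels == g, n_dots=240)[1] for g in range(3)]
        assert sum(parts) == pytest.approx(total, rel=1e-12)

    def test_mask_size_mismatch(self, cluster_factory):
        with pytest.raises(ValueError, match="mask length"):
            a.apr_sasa(cluster_factory(5), np.ones(7, dtype=bool))


class TestExpandAprMask:
    def test_expand_protein_only_mask(self):
        frame = a.BeadFrame(
            coordinates=np.zeros((3, 3)) + np.arange(3)[:, None],
            radii=np.full(3, R_BEAD),
            residue_index=np.array([1, 2, 1]),
            molecule_tag=np.array(["protein", "excipient", "protein"]),
        )
        full = expand_apr_mask(frame, np.array([True, False]))
        np.testing.assert_array_equal(full, [True, False, False])

    def test_bad_length(self, cluster_factory):
        with pytest.raises(ValueError, match="matches neither"):
            expand_apr_mask(cluster_factory(5), np.ones(3, dtype=bool))


def constant_trajectory(frame, k):
    return a.BeadTrajectory(frames=(frame,) * k, frame_times=np.arange(k, dtype=float))


class TestTrajectorySasa:
    def test_identical_frames_constant_series(self, cluster_factory):
        frame = cluster_factory(8)
        traj = constant_trajectory(frame, 4)
        series = a.trajectory_sasa(traj, np.ones(8, dtype=bool), n_dots=240)
        single_total, single_apr = a.apr_sasa(frame, np.ones(8, dtype=bool), n_dots=240)
        np.testing.assert_allclose(series.per_frame_total, single_total)
        assert series.mean_total == pytest.approx(single_total)
        assert series.mean_apr == pytest.approx(single_apr)

    def test_stride_counts(self, cluster_factory):
        traj = constant_trajectory(cluster_factory(5), 10)
        series = a.trajectory_sasa(traj, np.ones(5, dtype=bool), n_dots=240, stride=2)
        assert series.per_frame_total.size == 5

    def test_per_frame_oracle(self, cluster_factory, rng):
        frames = tuple(cluster_factory(6) for _ in range(3))
        traj = a.BeadTrajectory(
            frames=tuple(
                a.BeadFrame(
                    coordinates=f.coordinates,
                    radii=frames[0].radii,
                    residue_index=frames[0].residue_index,
                    molecule_tag=frames[0].molecule_tag,
                )
                for f in frames
            ),
            frame_times=np.arange(3, dtype=float),
        )
        mask = np.array([True, True, False, False, True, False])
        series = a.trajectory_sasa(traj, mask, n_dots=240)
        for k, frame in enumerate(traj.frames):
            total, apr = a.apr_sasa(frame, mask, n_dots=240)
            assert series.per_frame_total[k] == pytest.approx(total)
            assert series.per_frame_apr[k] == pytest.approx(apr)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="at least one frame"):
            a.BeadTrajectory(frames=(), frame_times=np.array([]))

    def test_changed_topology_rejected(self, cluster_factory):
        f1 = cluster_factory(5)
        f2 = a.BeadFrame(
            coordinates=f1.coordinates,
            radii=f1.radii * 2,
            residue_index=f1.residue_index,
            molecule_tag=f1.molecule_tag,
        )
        with pytest.raises(ValueError, match="topology"):
            a.BeadTrajectory(frames=(f1, f2), frame_times=np.array([0.0, 1.0]))


class TestShielding:
    def test_identical_series_zero(self, cluster_factory):
        frame = cluster_factory(8)
        traj = constant_trajectory(frame, 2)
        series = a.trajectory_sasa(traj, np.ones(8, dtype=bool), n_dots=240)
        result = a.shielding([series], [series])
        assert result.delta_apr_sasa == 0.0
        assert result.percent_reduction == 0.0

    def test_replicate_mean_arithmetic(self):
        result = a.shielding([50.0, 50.0], [40.0, 40.0])
        assert result.delta_apr_sasa == pytest.approx(10.0)
        assert result.percent_reduction == pytest.approx(20.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="at least one replicate"):
            a.shielding([], [50.0])


class TestConcentration:
    def test_paper_box(self):
        assert a.concentration(1, 30841.5) == pytest.approx(0.0538, abs=5e-5)

    def test_zero_molecules(self):
        assert a.concentration(0, 100.0) == 0.0

    def test_avogadro_identity(self):
        # 1 M corresponds to ~0.6022 molecules per nm^3
        assert a.concentration(1, 1.66053907) == pytest.approx(1000.0, rel=1e-6)

    def test_nonpositive_volume(self):
        with pytest.raises(ValueError, match="volume"):
            a.concentration(1, 0.0)


class TestExcipientCount:
    def test_zero_target(self):
        assert a.excipient_count(0.0, 734.0, 1e6) == 0

    def test_exact_division(self):
        # mass ratio chosen so the budget is exactly 7 molecules
        assert a.excipient_count(7 * 500.0 / 1e6, 500.0, 1e6) == 7

    def test_mass_balance_oracle(self):
        # 233,000 four-water beads at 72 g/mol -> 16.776e6 g/mol-of-box;
        # independent hand computation: 0.001 * 16.776e6 / 734 = 22.856 -> 23
        system_mass = 233_000 * 72.0
        assert a.excipient_count(0.001, 734.0, system_mass) == 23

    def test_zero_mw_rejected(self):
        with pytest.raises(ValueError, match="molecular weight"):
            a.excipient_count(0.001, 0.0, 1e6)


class TestUnwrap:
    def test_unwrap_restores_molecule(self):
        box = 10.0
        coords = np.array([[9.8, 5, 5], [0.2, 5, 5.0]])  # split across the boundary
        frame = a.BeadFrame(
            coordinates=coords,
            radii=np.full(2, R_BEAD),
            residue_index=np.array([1, 1]),
            molecule_tag=np.array(["protein", "protein"]),
            molecule_id=np.array([0, 0]),
            box_edge=box,
        )
        fixed = unwrap(frame)
        d = np.linalg.norm(fixed.coordinates[0] - fixed.coordinates[1])
        assert d == pytest.approx(0.4, abs=1e-9)

    def test_wholeness_warning(self):
        box = 10.0
        coords = np.array([[0.5, 5, 5], [9.5, 5, 5.0]])
        frame = a.BeadFrame(
            coordinates=coords,
            radii=np.full(2, R_BEAD),
            residue_index=np.array([1, 2]),
            molecule_tag=np.array(["protein", "protein"]),
            box_edge=box,
        )
        traj = a.BeadTrajectory(frames=(frame,), frame_times=np.array([0.0]))
        with pytest.warns(UserWarning, match="wrapped"):
            a.trajectory_sasa(traj, np.ones(2, dtype=bool), n_dots=240)
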