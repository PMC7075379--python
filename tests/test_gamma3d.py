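"""3D gamma index: closed-form cases, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import radbioqa as rb
from radbioqa import gamma3d as g3
from radbioqa.gamma3d import DoseGrid, GammaCriteria
from radbioqa.rb_core import ValidationError


def brute_force_gamma(reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria):
    """Unoptimized exhaustive oracle: independent interpolation and a full
    offset scan per reference point (no early exit, no active set)."""
    norm = criteria.norm_fraction * reference.values.max()
    dcrit = criteria.dose_pct / 100.0 * norm
    step, radius = criteria.step, criteria.radius
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    offsets = [
        (ox, oy, oz)
        for ox in axis
        for oy in axis
        for oz in axis
        if ox * ox + oy * oy + oz * oz <= radius**2 + 1e-9
    ]
    dx, dy, dz = evaluated.spacing
    x0, y0, z0 = evaluated.origin
    nz, ny, nx = evaluated.shape
    interp = RegularGridInterpolator(
        (
            z0 + np.arange(nz) * dz,
            y0 + np.arange(ny) * dy,
            x0 + np.arange(nx) * dx,
        ),
        evaluated.values,
        bounds_error=False,
        fill_value=np.nan,
    )
    x, y, z = reference.point_coordinates()
    gamma = np.full(reference.shape, np.inf)
    for idx in np.ndindex(reference.shape):
        rx, ry, rz, rd = x[idx], y[idx], z[idx], reference.values[idx]
        best = np.inf
        for ox, oy, oz in offsets:
            ev = interp([(rz + oz, ry + oy, rx + ox)])[0]
            if np.isnan(ev):
                continue
            g2 = (ox**2 + oy**2 + oz**2) / criteria.dta_mm**2 + (ev - rd) ** 2 / dcrit**2
            best = min(best, g2)
        gamma[idx] = np.sqrt(best)
    return gamma


@pytest.fixture
def flat_grid():
    return DoseGrid(np.full((10, 10, 10), 10.0), (2.5, 2.5, 2.5))


class TestGammaMap:
    def test_identical_grids_give_zero_gamma(self):
        rng = np.random.default_rng(0)
        grid = DoseGrid(rng.uniform(1, 10, (8, 8, 8)), (2.0, 2.0, 2.0))
        gamma, mask = g3.gamma_map(grid, grid, GammaCriteria(3, 3))
        assert mask.all()
        assert np.nanmax(gamma) == 0.0
        assert g3.pass_rate(gamma, mask) == 100.0

    def test_hot_voxel_at_exactly_dose_criterion(self):
        # spacing > dta with sampling on the voxel lattice: the nearest-point
        # dose term dominates and gamma is exactly 1 at the raised voxel
        vals = np.full((9, 9, 9), 10.0)
        ref = DoseGrid(vals, (4.0, 4.0, 4.0))
        criteria = GammaCriteria(3, 3, interp_step_mm=4.0, search_radius_mm=8.0)
        dcrit = 0.03 * 0.9 * 10.0
        ev_vals = vals.copy()
        ev_vals[4, 4, 4] += dcrit
        gamma, _ = g3.gamma_map(ref, DoseGrid(ev_vals, (4.0, 4.0, 4.0)), criteria)
        assert gamma[4, 4, 4] == pytest.approx(1.0, abs=1e-6)

    def test_ramp_shifted_by_dta_yields_unit_gamma(self):
        # pure distance-to-agreement problem: tight dose criterion forces the
        # search to the exactly-matching dose one dta away
        nx = 30
        profile = 1.0 + 0.2 * np.arange(nx)
        ref = DoseGrid(np.tile(profile, (6, 6, 1)), (2.0, 2.0, 2.0))
        shifted = 1.0 + 0.2 * (np.arange(nx) - 1.5)  # 3 mm shift at 2 mm spacing
        ev = DoseGrid(np.tile(np.maximum(shifted, 0), (6, 6, 1)), (2.0, 2.0, 2.0))
        criteria = GammaCriteria(0.01, 3, interp_step_mm=0.1)
        gamma, _ = g3.gamma_map(ref, ev, criteria)
        interior = gamma[:, :, 5:25]
        assert np.allclose(interior, 1.0, atol=0.05)

    def test_matches_exhaustive_oracle_on_small_grids(self):
        rng = np.random.default_rng(7)
        ref = DoseGrid(rng.uniform(0.5, 10, (7, 8, 9)), (3.0, 3.0, 3.0))
        ev = DoseGrid(
            ref.values * (1 + rng.normal(0, 0.03, ref.shape)).clip(0.5, 1.5),
            (3.0, 3.0, 3.0),
        )
        criteria = GammaCriteria(3, 3, interp_step_mm=1.5, search_radius_mm=4.5)
        gamma, mask = g3.gamma_map(ref, ev, criteria)
        oracle = brute_force_gamma(ref, ev, criteria)
        assert mask.all()
        assert np.allclose(gamma, oracle, atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        vals_ref = rng.uniform(1, 10, (8, 8, 8))
        vals_ev = vals_ref * (1 + rng.normal(0, 0.02, vals_ref.shape))
        criteria = GammaCriteria(3, 3, interp_step_mm=1.0)
        g_a, _ = g3.gamma_map(
            DoseGrid(vals_ref, (2.0, 2.0, 2.0)), DoseGrid(vals_ev.clip(0), (2.0, 2.0, 2.0)),
            criteria,
        )
        shift = (17.0, -5.0, 11.0)
        g_b, _ = g3.gamma_map(
            DoseGrid(vals_ref, (2.0, 2.0, 2.0), origin=shift),
            DoseGrid(vals_ev.clip(0), (2.0, 2.0, 2.0), origin=shift),
            criteria,
        )
        assert np.allclose(g_a, g_b, atol=1e-12, equal_nan=True)

    def test_finer_search_step_never_increases_gamma(self):
        # the fine-step offset lattice is a superset of the coarse one
        ref, ev = rb.make_grid_pair(
            shape=(10, 12, 12), spec=rb.PerturbationSpec(dose_scale=1.06, seed=11)
        )
        coarse, _ = g3.gamma_map(ref, ev, GammaCriteria(3, 3, interp_step_mm=1.5))
        fine, _ = g3.gamma_map(ref, ev, GammaCriteria(3, 3, interp_step_mm=0.75))
        assert np.all(fine <= coarse + 1e-12)

    def test_tighter_criteria_never_lower_gamma(self):
        ref, ev = rb.make_grid_pair(
            shape=(10, 12, 12),
            spec=rb.PerturbationSpec(dose_scale=1.05, noise_sd_pct=1.0, seed=4),
        )
        loose, m1 = g3.gamma_map(ref, ev, GammaCriteria(3, 3, interp_step_mm=0.5))
        tight, m2 = g3.gamma_map(ref, ev, GammaCriteria(2, 2, interp_step_mm=0.5))
        assert np.all(tight[m2] >= loose[m1] - 1e-9)
        assert g3.pass_rate(tight, m2) <= g3.pass_rate(loose, m1)

    def test_degenerate_and_disjoint_inputs_rejected(self, flat_grid):
        zero = DoseGrid(np.zeros((5, 5, 5)), (2.0, 2.0, 2.0))
        with pytest.raises(ValidationError, match="all zero"):
            g3.gamma_map(zero, flat_grid, GammaCriteria(3, 3))
        far = DoseGrid(np.full((5, 5, 5), 10.0), (2.0, 2.0, 2.0), origin=(1e4, 1e4, 1e4))
        with pytest.raises(ValidationError, match="overlap"):
            g3.gamma_map(flat_grid, far, GammaCriteria(3, 3))

    def test_low_dose_threshold_excludes_points(self):
        vals = np.full((6, 6, 6), 1.0)
        vals[3] = 10.0
        ref = DoseGrid(vals, (3.0, 3.0, 3.0))
        _, mask = g3.gamma_map(ref, ref, GammaCriteria(3, 3, low_dose_threshold_pct=50))
        assert mask.sum() == 36  # only the high-dose slab


class TestSummaries:
    def test_pass_rate_counting(self):
        gamma = np.array([[[0.5, 0.5], [2.0, 2.0]]])
        mask = np.ones_like(gamma, dtype=bool)
        assert g3.pass_rate(gamma, mask) == 50.0
        assert g3.pass_rate(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool)) == 100.0

    def test_pass_rate_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        gamma = rng.uniform(0, 2, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.2
        expected = 100.0 * np.sum(gamma[mask] <= 1) / mask.sum()
        assert g3.pass_rate(gamma, mask) == pytest.approx(expected)

    def test_summary_hand_case(self):
        gamma = np.array([[[0.2, 0.4, 0.6]]])
        s = g3.gamma_summary(gamma, np.ones_like(gamma, dtype=bool))
        assert s.mean_gamma == pytest.approx(0.4)
        assert s.median_gamma == pytest.approx(0.4)
        assert (s.min_gamma, s.max_gamma, s.n_evaluated) == (0.2, 0.6, 3)

    def test_even_count_median_is_midpoint(self):
        gamma = np.array([[[0.2, 0.4, 0.8, 1.6]]])
        s = g3.gamma_summary(gamma, np.ones_like(gamma, dtype=bool))
        assert s.median_gamma == pytest.approx(0.6)

    def test_constant_gamma(self):
        gamma = np.full((3, 3, 3), 0.7)
        s = g3.gamma_summary(gamma, np.ones((3, 3, 3), bool))
        assert s.mean_gamma == pytest.approx(0.7)
        assert s.median_gamma == pytest.approx(0.7)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            g3.pass_rate(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValidationError, match="empty"):
            g3.gamma_summary(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestGridIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        grid = DoseGrid(rng.uniform(0, 10, (4, 5, 6)), (1.0, 2.0, 3.0), origin=(-5, 0, 5))
        path = tmp_path / "grid.csv"
        g3.save_dose_grid(grid, path)
        back = g3.load_dose_grid(path)
        assert np.allclose(back.values, grid.values)
        assert back.spacing == grid.spacing
        assert back.origin == grid.origin

    def test_npz_round_trip(self, tmp_path):
        grid = DoseGrid(np.arange(24, dtype=float).reshape(2, 3, 4), (2.0, 2.0, 2.0))
        path = tmp_path / "grid.npz"
        g3.save_dose_grid(grid, path)
        back = g3.load_dose_grid(path)
        assert np.array_equal(back.values, grid.values)

    def test_dicom_rt_dose(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        values = np.arange(2 * 3 * 4, dtype=np.uint32).reshape(2, 3, 4)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.Rows, ds.Columns, ds.NumberOfFrames = 3, 4, 2
        ds.PixelSpacing = [2.5, 2.0]  # row (y), column (x)
        ds.GridFrameOffsetVector = [0.0, 3.0]
        ds.ImagePositionPatient = [-10.0, -20.0, 5.0]
        ds.DoseGridScaling = 0.01
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = values.tobytes()
        path = tmp_path / "dose.dcm"
        ds.save_as(path, enforce_file_format=True)

        grid = g3.load_dose_grid(path)
        assert grid.shape == (2, 3, 4)
        assert np.allclose(grid.values, values * 0.01)
        assert grid.spacing == (2.0, 2.5, 3.0)
        assert grid.origin == (-10.0, -20.0, 5.0)
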