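"""Profile normalization, plane synthesis, and profile extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transitdose import beam_data as bd
from transitdose.plane_tools import (
    RelativeProfile,
    compare_relative_profiles,
    extract_profile,
    normalize_profile,
    synthesize_plane,
)


def flat_profile(value=1.0, axis="crossline", half=6.0, step=0.2,
                 depth=10.0, fs=5.0):
    pos = np.round(np.arange(-half, half + 1e-9, step), 10)
    return bd.ScanProfile(axis=axis, depth=depth, field_size=fs,
                          positions=pos, values=np.full(pos.size, value))


class TestNormalization:
    def test_divides_by_central_axis_value(self):
        p = flat_profile(50.0)
        n = normalize_profile(p)
        assert n.value_at(0.0) == pytest.approx(1.0)
        np.testing.assert_allclose(n.values, 1.0)

    def test_idempotent(self, gaussian_profiles):
        px, _ = gaussian_profiles
        once = normalize_profile(px)
        twice = normalize_profile(once)
        np.testing.assert_array_equal(once.values, twice.values)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, scale):
        pos = np.round(np.arange(-6.0, 6.01, 0.2), 10)
        px = bd.ScanProfile(axis="crossline", depth=10.0, field_size=5.0,
                            positions=pos, values=70.0 * np.exp(-(pos / 4.0) ** 2))
        scaled = bd.ScanProfile(axis=px.axis, depth=px.depth, field_size=px.field_size,
                                positions=px.positions, values=px.values * scale)
        np.testing.assert_allclose(normalize_profile(scaled).values,
                                   normalize_profile(px).values, rtol=1e-12)

    def test_symmetry_preserved(self, gaussian_profiles):
        px, _ = gaussian_profiles
        n = normalize_profile(px)
        np.testing.assert_allclose(n.values, n.values[::-1], rtol=1e-12)

    def test_nonpositive_cax_rejected(self):
        p = flat_profile(1.0)
        bad = bd.ScanProfile(axis=p.axis, depth=p.depth, field_size=p.field_size,
                             positions=p.positions, values=np.zeros(p.positions.size))
        with pytest.raises(bd.BeamDataError, match="positive"):
            normalize_profile(bad)


class TestSynthesis:
    def test_flat_unit_profiles_give_uniform_plane(self):
        plane = synthesize_plane(flat_profile(axis="crossline"),
                                 flat_profile(axis="inline"), d_cax=50.0)
        np.testing.assert_allclose(plane.dose, 50.0)
        assert plane.cax_dose == pytest.approx(50.0)

    def test_central_row_is_scaled_profile(self, gaussian_profiles):
        px, py = gaussian_profiles
        d_cax = 85.2
        plane = synthesize_plane(px, py, d_cax)
        iy = np.argmin(np.abs(plane.y_coords))
        nx = normalize_profile(px)
        expected = np.array([nx.value_at(x) for x in plane.x_coords]) * d_cax
        np.testing.assert_allclose(plane.dose[iy], expected, atol=1e-9)

    def test_matches_brute_force_outer_product(self, gaussian_profiles):
        """1000 random points vs an independent pointwise product."""
        px, py = gaussian_profiles
        d_cax = 60.0
        plane = synthesize_plane(px, py, d_cax)
        nx, ny = normalize_profile(px), normalize_profile(py)
        rng = np.random.default_rng(3)
        ix = rng.integers(0, plane.x_coords.size, 1000)
        iy = rng.integers(0, plane.y_coords.size, 1000)
        for i, j in zip(ix, iy):
            x, y = plane.x_coords[i], plane.y_coords[j]
            assert plane.dose[j, i] == pytest.approx(
                nx.value_at(x) * ny.value_at(y) * d_cax, abs=1e-12)

    def test_separability_identity(self, gaussian_profiles):
        """plane(x,y) * plane(0,0) = plane(x,0) * plane(0,y) everywhere."""
        plane = synthesize_plane(*gaussian_profiles, d_cax=70.0)
        i0 = np.argmin(np.abs(plane.x_coords))
        j0 = np.argmin(np.abs(plane.y_coords))
        lhs = plane.dose * plane.dose[j0, i0]
        rhs = np.outer(plane.dose[:, i0], plane.dose[j0, :])
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_depth_mismatch_rejected(self, gaussian_profiles):
        px, py = gaussian_profiles
        py_bad = bd.ScanProfile(axis=py.axis, depth=py.depth + 1, field_size=py.field_size,
                                positions=py.positions, values=py.values)
        with pytest.raises(bd.BeamDataError, match="depths differ"):
            synthesize_plane(px, py_bad, 50.0)


class TestExtraction:
    def test_grid_aligned_extraction_is_exact(self, gaussian_profiles):
        plane = synthesize_plane(*gaussian_profiles, d_cax=70.0)
        prof = extract_profile(plane, "crossline", spacing=plane.spacing)
        j0 = np.argmin(np.abs(plane.y_coords))
        common = np.isin(np.round(plane.x_coords, 9), np.round(prof.positions, 9))
        np.testing.assert_allclose(prof.values, plane.dose[j0, common], atol=1e-12)

    def test_round_trip_reproduces_profile(self, gaussian_profiles):
        px, py = gaussian_profiles
        d_cax = 85.0
        plane = synthesize_plane(px, py, d_cax)
        prof = extract_profile(plane, "crossline", spacing=0.2)
        nx = normalize_profile(px)
        expected = np.array([nx.value_at(s) for s in prof.positions]) * d_cax
        np.testing.assert_allclose(prof.values, expected, atol=1e-9)

    def test_diagonal_closed_form_for_separable_plane(self, gaussian_profiles):
        px, py = gaussian_profiles
        d_cax = 90.0
        plane = synthesize_plane(px, py, d_cax, spacing=0.05)
        prof = extract_profile(plane, "diagonal", spacing=0.1)
        nx, ny = normalize_profile(px), normalize_profile(py)
        expected = np.array([
            nx.value_at(s / math.sqrt(2)) * ny.value_at(s / math.sqrt(2)) * d_cax
            for s in prof.positions])
        # bilinear sampling on a fine grid vs the exact closed form
        np.testing.assert_allclose(prof.values, expected, atol=5e-3 * d_cax / 100)

    def test_uniform_plane_gives_flat_profile(self):
        plane = synthesize_plane(flat_profile(axis="crossline"),
                                 flat_profile(axis="inline"), d_cax=42.0)
        for axis in ("crossline", "inline", "diagonal"):
            prof = extract_profile(plane, axis, spacing=0.3)
            np.testing.assert_allclose(prof.values, 42.0, atol=1e-12)

    def test_nonpositive_spacing_rejected(self, gaussian_profiles):
        plane = synthesize_plane(*gaussian_profiles, d_cax=50.0)
        with pytest.raises(bd.BeamDataError, match="spacing"):
            extract_profile(plane, "crossline", spacing=0.0)


class TestProfileComparison:
    def _rel(self, values, pos, fs=10.0, depth=10.0):
        return RelativeProfile(axis="crossline", depth=depth, field_size=fs,
                               positions=pos, values=values)

    def test_identical_profiles_differ_by_zero(self, gaussian_profiles):
        n = normalize_profile(gaussian_profiles[0])
        cmp = compare_relative_profiles(n, n)
        np.testing.assert_allclose(cmp.delta, 0.0, atol=1e-15)

    def test_off_axis_scaling_shows_in_shoulder_only(self):
        pos = np.round(np.arange(-8, 8.01, 0.2), 10)
        base = np.exp(-(pos / 5.0) ** 4)
        base = base / base[np.argmin(np.abs(pos))]
        a = self._rel(base, pos)
        # scale beyond 80% of the projected half-width (10*(110)/200 = 5.5 cm)
        boost = np.where(np.abs(pos) > 0.8 * 5.5, 1.02, 1.0)
        b = self._rel(base * boost / (base * boost)[np.argmin(np.abs(pos))], pos)
        cmp = compare_relative_profiles(a, b)
        assert cmp.delta[np.argmin(np.abs(cmp.positions))] == pytest.approx(0.0, abs=1e-12)
        assert cmp.max_abs_shoulder > 0
        assert cmp.max_abs_field == pytest.approx(0.0, abs=1e-12)

    def test_shoulder_perturbation_is_located_in_shoulder(self, synthetic_beam, deficit):
        """A TPS-style shoulder boost maximizes |delta| in the shoulder band."""
        from transitdose import synthetic_data as sd
        from transitdose.plane_tools import extract_profile as ep
        fs, depth = 20.0, 31.5
        truth = sd.truth_plane(synthetic_beam, deficit, fs, depth)
        boosted = sd.emulate_tps_plane(
            synthetic_beam, deficit, sd.TPSEmulatorSpec(mode="shoulder_boost"), fs, depth)
        a = normalize_profile(ep(truth, "crossline", 0.2))
        b = normalize_profile(ep(boosted, "crossline", 0.2))
        cmp = compare_relative_profiles(a, b)
        assert cmp.max_abs_shoulder > cmp.max_abs_field
        idx = np.argmax(np.abs(cmp.delta))
        assert cmp.region[idx] == "shoulder"

    def test_no_overlap_rejected(self):
        a = self._rel(np.ones(3), np.array([-1.0, 0.0, 1.0]))
        # np.interp clamps at the edges, so a far-off flat profile still
        # satisfies the value(0) = 1 invariant while sharing no positions
        b = self._rel(np.ones(3), np.array([5.0, 6.0, 7.0]))
        with pytest.raises(bd.BeamDataError, match="overlap"):
            compare_relative_profiles(a, b)
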