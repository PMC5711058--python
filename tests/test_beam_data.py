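"""Beam-data types, invariants, file round trips, and interpolation."""

import numpy as np
import pytest

from transitdose import beam_data as bd
from transitdose.datasets import load_reference_bcf
from transitdose import synthetic_data as sd


class TestTypeInvariants:
    def test_pdd_must_be_normalized_to_100(self):
        with pytest.raises(bd.BeamDataError, match="not normalized to 100"):
            bd.PDDCurve(field_size=10, depths=[1.5, 10.0], values=[99.4, 60.0], dmax=1.5)

    def test_pdd_depths_must_increase(self):
        with pytest.raises(bd.BeamDataError, match="strictly increasing"):
            bd.PDDCurve(field_size=10, depths=[1.5, 1.5, 10.0],
                        values=[100.0, 100.0, 60.0], dmax=1.5)

    def test_of_requires_reference_field(self):
        with pytest.raises(bd.BeamDataError, match="reference field size missing"):
            bd.OutputFactorTable(field_sizes=[5.0, 15.0], factors=[0.95, 1.04])

    def test_of_must_increase_with_field_size(self):
        with pytest.raises(bd.BeamDataError, match="increase strictly"):
            bd.OutputFactorTable(field_sizes=[5.0, 10.0, 15.0], factors=[1.02, 1.0, 1.04])

    def test_profile_must_bracket_central_axis(self):
        with pytest.raises(bd.BeamDataError, match="central axis"):
            bd.ScanProfile(axis="crossline", depth=5.0, field_size=10.0,
                           positions=[1.0, 2.0], values=[1.0, 0.5])

    def test_plane_requires_uniform_spacing(self):
        with pytest.raises(bd.BeamDataError, match="uniform"):
            bd.DosePlane(depth=5.0, field_size=10.0, x_coords=[-1.0, 0.0, 1.5],
                         y_coords=[-1.0, 0.0, 1.0], dose=np.ones((3, 3)))

    def test_plane_rejects_negative_dose(self):
        with pytest.raises(bd.BeamDataError, match="non-negative"):
            bd.DosePlane(depth=5.0, field_size=10.0, x_coords=[-1.0, 0.0, 1.0],
                         y_coords=[-1.0, 0.0, 1.0], dose=-np.ones((3, 3)))

    def test_bcf_range_enforced(self):
        with pytest.raises(bd.BeamDataError, match="BCF outside"):
            bd.BCFTable(machine_id="m", tpr2010=0.67,
                        entrance_field_sizes=[10.0], entrance_thicknesses=[1.5],
                        entrance=[[0.85]], exit_field_sizes=[10.0],
                        exit_depths=[6.5], exit=[[0.98]])

    def test_bcf_marginally_above_one_accepted_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            t = bd.BCFTable(machine_id="m", tpr2010=0.67,
                            entrance_field_sizes=[10.0], entrance_thicknesses=[1.5],
                            entrance=[[1.001]], exit_field_sizes=[10.0],
                            exit_depths=[6.5], exit=[[0.98]])
        assert t.entrance[0, 0] == 1.001  # preserved, not clamped
        assert any("exceeds 1" in r.message for r in caplog.records)


class TestReferenceTables:
    """The packaged measured BCF tables load with every cell intact."""

    @pytest.mark.parametrize("machine,n_entrance,n_exit", [
        ("clinac21ex", 28, 24), ("synergy", 28, 24),
    ])
    def test_all_cells_load(self, machine, n_entrance, n_exit):
        t = load_reference_bcf(machine)
        assert t.entrance.size == n_entrance
        assert t.exit.size == n_exit
        assert np.all(t.entrance > 0.9) and np.all(t.entrance <= 1.01)
        assert np.all(t.exit > 0.9) and np.all(t.exit <= 1.01)

    def test_known_cells(self):
        clinac = load_reference_bcf("clinac21ex")
        assert clinac.entrance_bcf(20, 1.5) == pytest.approx(0.972, abs=1e-12)
        assert clinac.entrance_bcf(10, 6.5) == pytest.approx(0.994, abs=1e-12)
        assert clinac.exit_bcf(20, 31.5) == pytest.approx(0.963, abs=1e-12)
        synergy = load_reference_bcf("synergy")
        assert synergy.exit_bcf(20, 31.5) == pytest.approx(0.960, abs=1e-12)
        assert synergy.tpr2010 == pytest.approx(0.687)

    def test_exit_depth_15_maps_to_entrance_block(self):
        t = load_reference_bcf("clinac21ex")
        assert t.exit_bcf(10, 1.5) == t.entrance_bcf(10, 1.5)


class TestBCFTableIO:
    def test_round_trip_identity(self, tmp_path):
        t = load_reference_bcf("synergy")
        path = tmp_path / "bcf.csv"
        bd.write_bcf_table(t, path)
        back = bd.read_bcf_table(path)
        np.testing.assert_allclose(back.entrance, t.entrance, atol=5e-4)
        np.testing.assert_allclose(back.exit, t.exit, atol=5e-4)
        # values are stored to exactly 3 decimals, so the round trip is exact here
        np.testing.assert_array_equal(back.entrance, t.entrance)
        assert back.machine_id == t.machine_id

    def test_duplicate_field_size_rejected(self, tmp_path):
        path = tmp_path / "bcf.csv"
        path.write_text(
            "#machine,m\n#tpr2010,0.67\n#entrance\nfield_size_cm,1.5\n"
            "10,0.99\n10,0.98\n#exit\nfield_size_cm,6.5\n10,0.98\n")
        with pytest.raises(bd.BeamDataError, match="duplicate"):
            bd.read_bcf_table(path)


class TestBeamDatasetIO:
    def test_round_trip_counts(self, tmp_path, synthetic_beam):
        bd.write_beam_dataset(synthetic_beam, tmp_path / "beam")
        back = bd.read_beam_dataset(tmp_path / "beam")
        assert len(back.pdd) == 4
        assert back.machine_id == synthetic_beam.machine_id
        assert back.d_dmax == synthetic_beam.d_dmax
        assert len(back.profiles) == len(synthetic_beam.profiles)
        # PDD percent stored to 1 decimal
        np.testing.assert_allclose(back.pdd[10.0].values,
                                   synthetic_beam.pdd[10.0].values, atol=0.05 + 1e-9)

    def test_missing_of_file_errors(self, tmp_path, synthetic_beam):
        bd.write_beam_dataset(synthetic_beam, tmp_path / "beam")
        (tmp_path / "beam" / "of.csv").unlink()
        with pytest.raises(bd.BeamDataError, match="of.csv"):
            bd.read_beam_dataset(tmp_path / "beam")

    def test_non_monotone_depth_names_file_and_row(self, tmp_path):
        p = tmp_path / "pdd_10.csv"
        p.write_text("depth_cm,pdd_percent\n1.5,100\n1.0,90\n")
        with pytest.raises(bd.BeamDataError, match="row 3"):
            bd.read_pdd(p, 10.0)

    def test_measurements_round_trip(self, tmp_path):
        ms = [bd.DoseMeasurement(machine_id="m", field_size=10, depth=1.5,
                                 backscatter_thickness=6.5, dose=98.7, mu=100)]
        bd.write_measurements(ms, tmp_path / "m.csv")
        back = bd.read_measurements(tmp_path / "m.csv")
        assert back[0].dose == pytest.approx(98.7)
        assert back[0].backscatter_thickness == 6.5

    def test_plane_round_trip(self, tmp_path, gaussian_profiles):
        from transitdose.plane_tools import synthesize_plane
        plane = synthesize_plane(*gaussian_profiles, d_cax=75.0)
        bd.write_dose_plane(plane, tmp_path / "p.csv")
        back = bd.read_dose_plane(tmp_path / "p.csv")
        np.testing.assert_allclose(back.dose, plane.dose, atol=1e-5)
        assert back.depth == plane.depth


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        t = load_reference_bcf("clinac21ex")
        assert t.entrance_bcf(10, 6.5) == 0.994

    def test_midpoint_is_mean_of_nodes(self):
        t = load_reference_bcf("clinac21ex")
        expected = 0.5 * (t.entrance_bcf(10, 6.5) + t.entrance_bcf(10, 11.5))
        assert t.entrance_bcf(10, 9.0) == pytest.approx(expected, abs=1e-12)

    def test_no_silent_extrapolation(self):
        t = load_reference_bcf("clinac21ex")
        with pytest.raises(bd.ExtrapolationError):
            t.entrance_bcf(25, 6.5)
        with pytest.raises(bd.ExtrapolationError):
            t.exit_bcf(10, 40.0)

    def test_matches_independent_piecewise_linear_oracle(self):
        """Dense random queries vs a handwritten piecewise-linear evaluation."""
        t = load_reference_bcf("synergy")
        rng = np.random.default_rng(42)
        fss = t.entrance_field_sizes
        ths = t.entrance_thicknesses

        def oracle(fs, th):
            i = np.searchsorted(fss, fs, side="right") - 1
            i = min(max(i, 0), fss.size - 2)
            j = np.searchsorted(ths, th, side="right") - 1
            j = min(max(j, 0), ths.size - 2)
            wf = (fs - fss[i]) / (fss[i + 1] - fss[i])
            wt = (th - ths[j]) / (ths[j + 1] - ths[j])
            v = t.entrance
            return ((1 - wf) * (1 - wt) * v[i, j] + (1 - wf) * wt * v[i, j + 1]
                    + wf * (1 - wt) * v[i + 1, j] + wf * wt * v[i + 1, j + 1])

        for _ in range(100):
            fs = rng.uniform(fss[0], fss[-1])
            th = rng.uniform(ths[0], ths[-1])
            assert t.entrance_bcf(fs, th) == pytest.approx(oracle(fs, th), abs=1e-12)

    def test_bounded_by_neighbouring_nodes(self):
        t = load_reference_bcf("clinac21ex")
        lo = min(t.exit_bcf(10, 21.5), t.exit_bcf(10, 26.5))
        hi = max(t.exit_bcf(10, 21.5), t.exit_bcf(10, 26.5))
        mid = t.exit_bcf(10, 24.0)
        assert lo - 1e-12 <= mid <= hi + 1e-12


def test_tpr20_10_of_synthetic_presets():
    """Both presets land in the 6 MV beam-quality window."""
    for spec in (sd.CLINAC_LIKE, sd.SYNERGY_LIKE):
        pdd = sd.generate_pdd(spec, 10.0)
        assert 0.65 < bd.tpr20_10(pdd) < 0.70
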