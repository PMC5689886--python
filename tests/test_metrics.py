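"""Mean dose difference and gamma-index computation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qadb.metrics import (
    DoseGrid,
    GammaCriteria,
    MeanDoseInputs,
    gamma_map,
    gamma_pass_rate,
    load_dose_grid,
    mean_dose_difference,
    save_dose_grid,
)

from conftest import brute_force_gamma


def uniform_grid(value=2.0, shape=(5, 5, 5), spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(values=np.full(shape, value), spacing=spacing)


class TestMeanDoseDifference:
    @pytest.mark.parametrize(
        "d_m3d,d_tps,d_ref,expected",
        [
            (50.0, 50.0, 60.0, 0.0),
            (51.0, 50.0, 60.0, 1.6667),  # 100/60
            (47.5, 50.0, 62.5, -4.0),
        ],
    )
    def test_hand_arithmetic(self, d_m3d, d_tps, d_ref, expected):
        got = mean_dose_difference(MeanDoseInputs(d_m3d, d_tps, d_ref))
        assert got == pytest.approx(expected, abs=5e-5)

    def test_zero_reference_dose_rejected(self):
        with pytest.raises(ValueError):
            MeanDoseInputs(50.0, 50.0, 0.0)

    @given(
        d_m3d=st.floats(0.1, 100),
        d_tps=st.floats(0.1, 100),
        d_ref=st.floats(1.0, 100),
        scale=st.floats(0.01, 50),
    )
    def test_scale_invariance_and_antisymmetry(self, d_m3d, d_tps, d_ref, scale):
        base = mean_dose_difference(MeanDoseInputs(d_m3d, d_tps, d_ref))
        scaled = mean_dose_difference(
            MeanDoseInputs(d_m3d * scale, d_tps * scale, d_ref * scale)
        )
        swapped = mean_dose_difference(MeanDoseInputs(d_tps, d_m3d, d_ref))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert swapped == pytest.approx(-base, rel=1e-9, abs=1e-12)


def random_grid(seed, shape=(9, 9, 9), spacing=(2.0, 2.0, 2.0), lo=0.0, hi=2.0):
    rng = np.random.default_rng(seed)
    return DoseGrid(values=rng.uniform(lo, hi, size=shape), spacing=spacing)


class TestGamma:
    def test_identity_gives_zero_gamma_and_full_pass(self):
        ref = random_grid(0)
        crit = GammaCriteria()
        gm = gamma_map(ref, ref, crit)
        finite = np.isfinite(gm)
        assert finite.any()
        assert np.allclose(gm[finite], 0.0)
        assert gamma_pass_rate(ref, ref, crit) == 100.0

    def test_uniform_scaling_five_percent_fails_everywhere(self):
        # uniform 5% excess against a 3% global criterion: gamma = 5/3 at
        # every voxel, since spatial search cannot reduce a uniform offset
        ref = uniform_grid(2.0)
        ev = uniform_grid(2.0 * 1.05)
        crit = GammaCriteria(dose_pct=3.0, dta_mm=3.0)
        gm = gamma_map(ref, ev, crit)
        assert np.allclose(gm[np.isfinite(gm)], 5.0 / 3.0)
        assert gamma_pass_rate(ref, ev, crit) == 0.0

    def test_uniform_scaling_two_percent_passes_everywhere(self):
        ref = random_grid(3)
        ev = DoseGrid(values=ref.values * 1.02, spacing=ref.spacing)
        assert gamma_pass_rate(ref, ev, GammaCriteria(dose_pct=3.0)) == 100.0

    @pytest.mark.parametrize("normalization", ["global", "local"])
    def test_matches_brute_force_oracle(self, normalization):
        ref = random_grid(11)
        rng = np.random.default_rng(12)
        ev = DoseGrid(
            values=np.clip(ref.values + rng.normal(0, 0.08, ref.shape), 0, None),
            spacing=ref.spacing,
        )
        crit = GammaCriteria(normalization=normalization)
        got = gamma_map(ref, ev, crit)
        want = brute_force_gamma(ref, ev, crit)
        assert np.array_equal(np.isnan(got), np.isnan(want))
        m = np.isfinite(want)
        np.testing.assert_allclose(got[m], want[m], rtol=0, atol=1e-12)

    def test_pass_rate_monotone_in_criteria(self):
        ref = random_grid(21)
        rng = np.random.default_rng(22)
        ev = DoseGrid(
            values=np.clip(ref.values * (1 + rng.normal(0, 0.04, ref.shape)), 0, None),
            spacing=ref.spacing,
        )
        rates_dose = [
            gamma_pass_rate(ref, ev, GammaCriteria(dose_pct=p)) for p in (1, 2, 3, 5)
        ]
        assert rates_dose == sorted(rates_dose)
        rates_dta = [
            gamma_pass_rate(ref, ev, GammaCriteria(dta_mm=d)) for d in (1, 2, 3, 5)
        ]
        assert rates_dta == sorted(rates_dta)

    def test_geometry_mismatch_rejected(self):
        ref = uniform_grid(shape=(5, 5, 5))
        ev = uniform_grid(shape=(5, 5, 6))
        with pytest.raises(ValueError, match="geometry"):
            gamma_map(ref, ev, GammaCriteria())

    def test_all_zero_reference_rejected(self):
        z = DoseGrid(values=np.zeros((3, 3, 3)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="zero"):
            gamma_map(z, z, GammaCriteria())

    def test_threshold_excludes_low_dose_voxels(self):
        values = np.full((3, 3, 3), 0.05)
        values[1, 1, 1] = 2.0
        ref = DoseGrid(values=values, spacing=(2, 2, 2))
        gm = gamma_map(ref, ref, GammaCriteria(threshold_pct=10.0))
        assert np.isfinite(gm).sum() == 1
        assert gamma_pass_rate(ref, ref, GammaCriteria(threshold_pct=10.0)) == 100.0

    def test_criteria_validation(self):
        for kwargs in (
            {"dose_pct": 0},
            {"dta_mm": -1},
            {"threshold_pct": 100},
            {"normalization": "weird"},
        ):
            with pytest.raises(ValueError):
                GammaCriteria(**kwargs)


class TestGridIO:
    def test_flat_binary_round_trip(self, tmp_path):
        grid = random_grid(5, shape=(4, 5, 6), spacing=(2.5, 2.0, 2.0))
        save_dose_grid(grid, tmp_path / "ref")
        back = load_dose_grid(tmp_path / "ref")
        assert back.shape == grid.shape
        assert back.spacing == grid.spacing
        np.testing.assert_allclose(back.values, grid.values, rtol=1e-6)

    def test_rtdose_ingestion(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        rng = np.random.default_rng(7)
        dose = rng.uniform(0, 2.0, size=(4, 5, 6))
        scaling = 1e-4
        pixels = np.round(dose / scaling).astype("<u4")

        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.2"  # RT Dose Storage
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "RTDOSE"
        ds.Rows, ds.Columns = 5, 6
        ds.NumberOfFrames = 4
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.DoseGridScaling = scaling
        ds.PixelSpacing = [2.0, 2.5]
        ds.GridFrameOffsetVector = [0.0, 3.0, 6.0, 9.0]
        ds.ImagePositionPatient = [-10.0, -20.0, -30.0]
        ds.PixelData = pixels.tobytes()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        path = tmp_path / "dose.dcm"
        ds.save_as(path, enforce_file_format=True)

        grid = load_dose_grid(path)
        assert grid.shape == (4, 5, 6)
        assert grid.spacing == (3.0, 2.0, 2.5)
        assert grid.origin == (-30.0, -20.0, -10.0)
        np.testing.assert_allclose(grid.values, pixels.astype(float) * scaling)
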