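"""Band localization, defect runs/areas, thresholds and lesion volumes."""

import math

import numpy as np
import pytest

from mcoct import (
    BandSegmentation,
    IntensityVolume,
    band_from_truth_or_heuristic,
    build_phantom,
    compose_standard_oct,
    defect_area,
    defect_runs,
    hrf_volume,
    ped_volume,
    shanbhag_threshold,
)
from mcoct.rpe_contrast import MelaninMask


def _band(nb, nx, center, half=2):
    return BandSegmentation(
        center=np.full((nb, nx), float(center)),
        half_thickness=half,
        present=np.ones((nb, nx), bool),
        source="provided",
    )


def _mask_from_defect_columns(nb, nz, nx, center, defect_cols_by_scan):
    vals = np.zeros((nb, nz, nx), bool)
    vals[:, center, :] = True
    for b, cols in defect_cols_by_scan.items():
        vals[b, :, cols] = False
    return MelaninMask(values=vals, threshold=0.15)


class TestBand:
    def test_ground_truth_passthrough(self, defect_phantom):
        _vol, truth, _spec = defect_phantom
        band = band_from_truth_or_heuristic(truth=truth)
        np.testing.assert_array_equal(band.center, truth.band_center)
        assert band.source == "ground_truth"
        assert band.half_thickness == truth.band_half_thickness

    def test_heuristic_close_to_truth_on_phantom(self, healthy_phantom):
        vol, truth, _spec = healthy_phantom
        intensity = compose_standard_oct(vol)
        band = band_from_truth_or_heuristic(intensity=intensity)
        err = np.abs(band.center - truth.band_center)[band.present]
        assert (err <= 1.0).mean() >= 0.99

    def test_all_zero_volume_all_absent(self):
        iv = IntensityVolume(linear=np.zeros((2, 16, 8)), dz=0.006)
        band = band_from_truth_or_heuristic(intensity=iv)
        assert not band.present.any()

    def test_requires_some_input(self):
        with pytest.raises(ValueError):
            band_from_truth_or_heuristic()


class TestDefectRuns:
    def test_intact_band_no_runs(self):
        mel = _mask_from_defect_columns(2, 16, 20, 8, {})
        runs = defect_runs(mel, _band(2, 20, 8))
        assert all(r == [] for r in runs)

    def test_contiguous_defect_single_run(self):
        mel = _mask_from_defect_columns(1, 16, 32, 8, {0: slice(5, 15)})
        runs = defect_runs(mel, _band(1, 32, 8))
        assert runs[0] == [(5, 10)]

    def test_gap_tolerance_merging(self):
        cols = list(range(4, 8)) + list(range(9, 12))  # gap of one intact column
        mel = _mask_from_defect_columns(1, 16, 32, 8, {0: cols})
        band = _band(1, 32, 8)
        assert defect_runs(mel, band, gap_tolerance=0)[0] == [(4, 4), (9, 3)]
        assert defect_runs(mel, band, gap_tolerance=1)[0] == [(4, 8)]

    def test_absent_band_columns_excluded(self):
        mel = _mask_from_defect_columns(1, 16, 10, 8, {0: slice(0, 10)})
        band = _band(1, 10, 8)
        band.present[0, :5] = False
        runs = defect_runs(mel, band)
        assert runs[0] == [(5, 5)]

    def test_positive_voxel_anywhere_in_window_counts(self):
        mel = _mask_from_defect_columns(1, 16, 10, 8, {0: slice(0, 10)})
        mel.values[0, 6, 3] = True  # inside window center±2
        runs = defect_runs(mel, _band(1, 10, 8))
        assert runs[0] == [(0, 3), (4, 6)]


class TestDefectArea:
    def test_hand_arithmetic_10px_3_scans(self):
        dx, dy = 6.0 / 512, 6.0 / 256
        runs = [[(4, 10)], [(4, 10)], [(4, 10)]]
        recs = defect_area(runs, dx, dy)
        assert len(recs) == 1
        assert recs[0].area_mm2 == pytest.approx(3 * 10 * dx * dy)
        assert recs[0].area_mm2 == pytest.approx(0.00824, abs=5e-5)

    def test_empty_runs_empty_records(self):
        assert defect_area([[], []], 0.01, 0.02) == []

    def test_lateral_overlap_links_disjoint_does_not(self):
        runs = [[(0, 4), (20, 4)], [(2, 4)], [], [(10, 3)]]
        recs = defect_area(runs, 0.01, 0.01)
        areas = sorted(r.area_mm2 for r in recs)
        # three defects: {scan0 cols0-3 + scan1 cols2-5}, {scan0 cols20-23}, {scan3}
        assert len(recs) == 3
        assert areas == pytest.approx(sorted([8 * 1e-4, 4 * 1e-4, 3 * 1e-4]))

    def test_additivity_of_disjoint_defects(self):
        runs_a = [[(0, 5)], []]
        runs_b = [[], [(10, 7)]]
        both = [[(0, 5)], [(10, 7)]]
        total = sum(r.area_mm2 for r in defect_area(both, 0.01, 0.02))
        parts = sum(r.area_mm2 for r in defect_area(runs_a, 0.01, 0.02)) + sum(
            r.area_mm2 for r in defect_area(runs_b, 0.01, 0.02)
        )
        assert total == pytest.approx(parts)

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValueError):
            defect_area([[(0, 1)]], 0.0, 0.01)


def _shanbhag_bruteforce(values, n_bins):
    """Independent plain-Python evaluation of the fuzzy information criterion."""
    counts, edges = np.histogram(np.asarray(values, float).ravel(), bins=n_bins)
    p = counts / counts.sum()
    c1 = np.cumsum(p)
    c2 = np.cumsum(p[::-1])[::-1]
    best_t, best = None, math.inf
    for t in range(n_bins - 1):
        pb, po = c1[t], c2[t + 1]
        if pb <= 0 or po <= 0:
            continue
        term_b = 0.5 / pb
        ent_b = 0.0
        for i in range(t + 1):
            prev = c1[i - 1] if i > 0 else 0.0
            ent_b -= p[i] * math.log(1.0 - term_b * prev)
        ent_b *= term_b
        term_o = 0.5 / po
        ent_o = 0.0
        for i in range(t + 1, n_bins):
            nxt = c2[i + 1] if i + 1 < n_bins else 0.0
            ent_o -= p[i] * math.log(1.0 - term_o * nxt)
        ent_o *= term_o
        crit = abs(ent_b - ent_o)
        if crit < best:
            best, best_t = crit, t
    return float(edges[best_t + 1])


class TestShanbhag:
    def test_toy_histogram_matches_bruteforce(self):
        vals = np.repeat(np.arange(8), [10, 30, 5, 1, 1, 4, 25, 9])
        assert shanbhag_threshold(vals, n_bins=8) == pytest.approx(
            _shanbhag_bruteforce(vals, 8)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_inputs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.normal(0, 1, 200), rng.normal(rng.uniform(3, 7), 1.5, 150)]
        )
        assert shanbhag_threshold(vals, n_bins=32) == pytest.approx(
            _shanbhag_bruteforce(vals, 32)
        )

    def test_symmetric_bimodal_threshold_in_valley(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(-4, 1, 4000), rng.normal(4, 1, 4000)])
        t = shanbhag_threshold(vals, n_bins=64)
        assert abs(t) < (8.0 / 64) * 2 + 1.0  # central valley ± a bin or so

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            shanbhag_threshold(np.full(10, 2.0))


class TestVolumes:
    def test_single_rectangle_section(self):
        dx, dy, dz = 0.01, 0.02, 0.005
        mask = np.zeros((1, 20, 30), bool)
        mask[0, 2:8, 4:14] = True  # 6 x 10 pixels
        assert ped_volume(mask, dx, dy, dz) == pytest.approx(60 * dx * dz * dy)

    def test_cavalieri_hemisphere_2_percent(self):
        R, step = 1.0, 0.005
        coords = np.arange(-1.1, 1.1, step)
        y = coords[np.abs(coords) <= R + step]
        zz, xx = np.meshgrid(coords, coords, indexing="ij")
        masks = np.stack(
            [(zz**2 + xx**2 + yi**2 <= R**2) & (zz >= 0) for yi in y]
        )
        vol = ped_volume(masks, step, step, step)
        assert vol == pytest.approx((2.0 / 3.0) * math.pi * R**3, rel=0.02)

    def test_empty_masks_zero(self):
        assert ped_volume(np.zeros((3, 4, 5), bool), 0.1, 0.1, 0.1) == 0.0

    def _blob_volume(self):
        rng = np.random.default_rng(0)
        nb, nz, nx = 12, 60, 60
        lin = rng.uniform(0.8, 1.2, (nb, nz, nx)) * 1e-3  # dim background
        zb, zz, zx = np.indices((nb, nz, nx))
        blob = ((zb - 6) / 4.0) ** 2 + ((zz - 30) / 9.0) ** 2 + ((zx - 30) / 9.0) ** 2 <= 1
        lin[blob] *= 1e3  # 30 dB contrast
        ped = np.ones((nb, nz, nx), bool)
        return IntensityVolume(linear=lin, dz=0.005), ped, blob

    def test_hrf_blob_within_15_percent(self):
        iv, ped, blob = self._blob_volume()
        dx = dy = dz = 0.01
        est = hrf_volume(iv, ped, blob, dx, dy, dz)
        truth = blob.sum() * dx * dy * dz
        assert est == pytest.approx(truth, rel=0.15)

    def test_empty_roi_zero(self):
        iv, ped, _ = self._blob_volume()
        assert hrf_volume(iv, ped, np.zeros_like(ped), 0.01, 0.01, 0.01) == 0.0

    def test_roi_outside_ped_zero(self):
        iv, _, blob = self._blob_volume()
        assert hrf_volume(iv, np.zeros_like(blob), blob, 0.01, 0.01, 0.01) == 0.0

    def test_resolution_consistency(self):
        # halving dx with a correspondingly refined mask barely changes the area
        nb, nz = 3, 10
        coarse = [[(10, 8)]] * nb
        fine = [[(20, 16)]] * nb
        a1 = sum(r.area_mm2 for r in defect_area(coarse, 0.02, 0.01))
        a2 = sum(r.area_mm2 for r in defect_area(fine, 0.01, 0.01))
        assert a1 == pytest.approx(a2)
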