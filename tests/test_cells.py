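"""Segmentation, tracking, dry mass, per-cell totals, debris flags, SNR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qdf.cells import (
    DebrisThresholds,
    SegmentationConfig,
    compute_dry_mass,
    compute_snr,
    filter_debris,
    per_cell_signals,
    segment_cells,
    track_cells,
)
from qdf.config import OpticalConfig
from qdf.errors import DataError
from qdf.phantom import CircleBoundary, Punctum, Scene, ground_truth, render_phase


def _gaussian_blob(shape, cy, cx, sigma, peak):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return peak * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2))


class TestSegmentation:
    def test_all_zero_phase(self):
        labels = segment_cells(np.zeros((32, 32)))
        assert labels.max() == 0

    def test_single_blob_single_label(self):
        phase = _gaussian_blob((64, 64), 32, 32, 8, 2.0)
        labels = segment_cells(phase)
        assert labels.max() == 1
        assert labels[32, 32] == 1

    def test_touching_cells_separated(self):
        # two-cell phantom, centres 1.5 blob-widths apart, must split into two
        scene = Scene(
            canvas_shape=(128, 128),
            boundaries=[
                CircleBoundary((64, 48), 16, 5.0, phase_total=2000.0),
                CircleBoundary((64, 88), 16, 5.0, phase_total=2000.0),
            ],
            puncta=[
                Punctum((64, 48), 10.0, phase_total=0.5),
                Punctum((64, 88), 10.0, phase_total=0.5),
            ],
        )
        phase = render_phase(scene)
        labels = segment_cells(phase)
        truth = ground_truth(scene)
        assert labels.max() == 2
        # each segmented cell contains its ground-truth punctum centre, and
        # majority-overlaps the matching truth label
        assert labels[64, 48] != 0 and labels[64, 88] != 0
        assert labels[64, 48] != labels[64, 88]
        for lbl in (1, 2):
            truth_px = truth.cell_label_image == lbl
            seg_lbl = labels[64, 48] if lbl == 1 else labels[64, 88]
            overlap = (labels[truth_px] == seg_lbl).mean()
            assert overlap > 0.5

    def test_labels_partition_foreground(self):
        phase = _gaussian_blob((64, 64), 20, 20, 6, 2.0) + _gaussian_blob(
            (64, 64), 44, 44, 6, 2.0
        )
        labels = segment_cells(phase)
        assert set(np.unique(labels)) == {0, 1, 2}


def _track_table(positions_by_frame):
    rows = []
    for f, pts in enumerate(positions_by_frame):
        for i, (r, c) in enumerate(pts):
            rows.append(
                {"frame": f, "label": i + 1, "centroid_row": r, "centroid_col": c}
            )
    return pd.DataFrame(rows)


class TestTracking:
    def test_stationary_cells_keep_ids(self):
        pts = [(10.0, 10.0), (40.0, 40.0), (10.0, 50.0)]
        table = track_cells(_track_table([pts] * 5))
        assert table.groupby("track_id")["frame"].count().tolist() == [5, 5, 5]
        # identity conserved: as many tracks as cells
        assert table["track_id"].nunique() == 3

    def test_moving_cell_full_track(self):
        frames = [[(10.0 + 3 * f, 20.0)] for f in range(6)]
        table = track_cells(_track_table(frames), max_disp_px=10)
        assert table["track_id"].nunique() == 1

    def test_gap_memory(self):
        frames = [[(10.0, 10.0)], [], [(10.0, 10.0)]]
        with_memory = track_cells(_track_table(frames), memory=1)
        assert with_memory["track_id"].nunique() == 1
        without = track_cells(_track_table(frames), memory=0)
        assert without["track_id"].nunique() == 2

    def test_crossing_matches_brute_force(self):
        # two cells pass within the gate; linking must pick the assignment a
        # brute-force enumeration of permutations would
        prev = [(10.0, 10.0), (10.0, 16.0)]
        curr = [(10.0, 13.5), (10.0, 11.5)]
        table = track_cells(_track_table([prev, curr]), max_disp_px=8)
        f0 = table[table.frame == 0].set_index("label")["track_id"]
        f1 = table[table.frame == 1].set_index("label")["track_id"]
        got = {lbl: int(f1[lbl]) for lbl in f1.index}

        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(2)):
            cost = sum(
                (prev[j][0] - curr[i][0]) ** 2 + (prev[j][1] - curr[i][1]) ** 2
                for i, j in enumerate(perm)
            )
            if cost < best_cost:
                best, best_cost = perm, cost
        expected = {i + 1: int(f0[best[i] + 1]) for i in range(2)}
        assert got == expected

    def test_far_cell_starts_new_track(self):
        frames = [[(10.0, 10.0)], [(60.0, 60.0)]]
        table = track_cells(_track_table(frames), max_disp_px=5)
        assert table["track_id"].nunique() == 2


class TestDryMass:
    def test_zero_phase_zero_mass(self):
        labels = np.ones((10, 10), dtype=int)
        masses = compute_dry_mass(np.zeros((10, 10)), labels, OpticalConfig())
        assert masses.loc[1] == 0.0

    def test_unit_analysis_oracle(self):
        # phi = 1 rad over 100 px of 0.5 um pixels at 525 nm, alpha = 1.8e-4:
        # mass = 100 * (lambda/2pi) * A_px / alpha, tracked by hand in SI
        phase = np.zeros((20, 20))
        labels = np.zeros((20, 20), dtype=int)
        phase[:10, :10] = 1.0
        labels[:10, :10] = 1
        optics = OpticalConfig(wavelength_nm=525, pixel_size_um=0.5)
        expected_kg = 100 * (525e-9 / (2 * np.pi)) * (0.5e-6) ** 2 / 1.8e-4
        got = compute_dry_mass(phase, labels, optics).loc[1]
        assert got == pytest.approx(expected_kg * 1e15, rel=1e-12)

    def test_linearity_in_pixel_area(self):
        phase = np.full((8, 8), 0.7)
        labels = np.ones((8, 8), dtype=int)
        m1 = compute_dry_mass(phase, labels, OpticalConfig(pixel_size_um=0.5)).loc[1]
        m2 = compute_dry_mass(
            phase, labels, OpticalConfig(pixel_size_um=0.5 * np.sqrt(2))
        ).loc[1]
        assert m2 == pytest.approx(2 * m1, rel=1e-12)


class TestPerCellSignals:
    def test_zero_qdf(self):
        labels = np.ones((8, 8), dtype=int)
        table = per_cell_signals(labels, np.ones((8, 8)), np.zeros((8, 8)))
        assert table.loc[0, "total_qdf"] == 0.0

    def test_negative_qdf_clipped_in_totals(self):
        labels = np.ones((4, 4), dtype=int)
        qdf = np.full((4, 4), -5.0)
        qdf[0, 0] = 3.0
        table = per_cell_signals(labels, np.ones((4, 4)), qdf)
        assert table.loc[0, "total_qdf"] == 3.0

    def test_additivity_over_label_merge(self, rng):
        labels = np.zeros((16, 16), dtype=int)
        labels[:8] = 1
        labels[8:] = 2
        df = rng.uniform(0, 10, (16, 16))
        qdf = rng.uniform(0, 5, (16, 16))
        split = per_cell_signals(labels, df, qdf)
        merged = per_cell_signals(np.ones_like(labels), df, qdf)
        assert merged.loc[0, "total_df"] == pytest.approx(split["total_df"].sum())
        assert merged.loc[0, "total_qdf"] == pytest.approx(split["total_qdf"].sum())


class TestDebrisFilter:
    def _table(self):
        return pd.DataFrame(
            {
                "frame": [0] * 5,
                "label": range(1, 6),
                "track_id": range(5),
                "area_px": [100, 5, 100, 100, 100],
                "mean_phase": [1.0, 1.0, 0.01, 1.0, 1.0],
                "mean_df": [50, 50, 50, 0.5, 50],
                "mean_qdf": [20, 20, 20, 20, 0.1],
            }
        )

    def test_open_thresholds_flag_nothing(self):
        out = filter_debris(self._table(), DebrisThresholds())
        assert not out["debris"].any()

    def test_each_rule_flags_its_violator(self):
        thresholds = DebrisThresholds(
            min_area_px=10, min_mean_phase=0.1, min_mean_df=1.0, min_mean_qdf=1.0
        )
        out = filter_debris(self._table(), thresholds)
        # rule-by-rule oracle: rows 2-5 each violate exactly one criterion
        assert out["debris"].tolist() == [False, True, True, True, True]

    def test_track_length_rule(self):
        t = pd.DataFrame(
            {
                "frame": [0, 1, 2, 0],
                "label": [1, 1, 1, 2],
                "track_id": [0, 0, 0, 1],
                "area_px": [100] * 4,
            }
        )
        out = filter_debris(t, DebrisThresholds(min_track_length=2))
        assert out["debris"].tolist() == [False, False, False, True]


class TestSnr:
    def test_background_quantile_threshold(self, rng):
        # pure standard-normal background, no cells: the threshold estimates
        # 4x the 99th percentile of N(0,1) = 4 * 2.326
        qdf = rng.normal(0, 1, (400, 400))
        rep = compute_snr(qdf, np.zeros((400, 400), dtype=int))
        assert rep.threshold == pytest.approx(4 * 2.3263, rel=0.05)
        assert rep.per_cell_snr == {}
        assert rep.noise_sigma == pytest.approx(1.0, rel=0.05)

    def test_constructed_phantom_snr(self, rng):
        sigma = 2.0
        qdf = rng.normal(0, sigma, (128, 128))
        labels = np.zeros((128, 128), dtype=int)
        rows, cols = np.mgrid[0:128, 0:128]
        cell = (rows - 64) ** 2 + (cols - 64) ** 2 <= 30**2
        labels[cell] = 1
        punc = (rows - 60) ** 2 + (cols - 60) ** 2 <= 4**2
        qdf[punc] += 30 * sigma
        rep = compute_snr(qdf, labels)
        assert rep.per_cell_snr[1] == pytest.approx(30.0, rel=0.15)

    def test_zero_variance_background_rejected(self):
        qdf = np.full((64, 64), 7.0)
        labels = np.zeros((64, 64), dtype=int)
        labels[20:40, 20:40] = 1
        with pytest.raises(DataError):
            compute_snr(qdf, labels)
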