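"""Forward-model invariants: conservation, isotropy/directionality limits,
determinism, geometry of the quarter-arc deposits, and scene plumbing."""

import numpy as np
import pytest

from qdf.config import OpticalConfig
from qdf.core import compute_darkfield
from qdf.errors import ConfigError
from qdf.phantom import (
    CircleBoundary,
    Punctum,
    Scene,
    SegmentBoundary,
    bead_scene,
    cell_scene,
    ground_truth,
    make_population,
    make_shape_sequence,
    render_phase,
    render_quadrants,
)


def _render_float(scene):
    return render_quadrants(scene, quantize=False)


class TestQuadrantRendering:
    def test_isotropic_punctum_splits_equally(self):
        scene = Scene(
            canvas_shape=(64, 64),
            puncta=[Punctum(center=(32, 32), amplitude=100.0, anisotropy=0.0)],
        )
        stack, _ = _render_float(scene)
        for im in stack.images[1:]:
            np.testing.assert_allclose(im, stack.images[0], atol=1e-12)
        for im in stack.images:
            assert im.sum() == pytest.approx(25.0, rel=1e-12)

    def test_directional_segment_single_quadrant(self):
        # vertical boundary, outward normal toward top-left -> all signal in
        # the bottom-right illumination image
        scene = Scene(
            canvas_shape=(64, 64),
            boundaries=[
                SegmentBoundary(
                    p0=(16, 32), p1=(48, 32), normal=(-1.0, -1.0),
                    amplitude=50.0, anisotropy=1.0,
                )
            ],
        )
        stack, _ = _render_float(scene)
        assert stack.br.sum() > 0
        assert stack.tl.sum() == 0
        assert stack.tr.sum() == 0
        assert stack.bl.sum() == 0

    def test_bead_quarter_arc_centroids(self):
        # with g=1 each quadrant image holds one quarter-arc of the rim; the
        # analytic centroid of a quarter arc of radius R sits 2R/pi off-centre
        # along both axes, on the side opposite the illumination quadrant
        radius = 20.0
        scene = bead_scene(radius=radius, noise_sigma=0.0)
        stack, _ = _render_float(scene)
        cy = cx = scene.canvas_shape[0] / 2.0
        off = 2.0 * radius / np.pi
        expected = {
            "tl": (cy + off, cx + off),  # TL illumination <- BR-pointing arc
            "tr": (cy + off, cx - off),
            "bl": (cy - off, cx + off),
            "br": (cy - off, cx - off),
        }
        for name, (er, ec) in expected.items():
            im = getattr(stack, name)
            total = im.sum()
            rows, cols = np.mgrid[0 : im.shape[0], 0 : im.shape[1]]
            assert (rows * im).sum() / total == pytest.approx(er, abs=1.0)
            assert (cols * im).sum() / total == pytest.approx(ec, abs=1.0)
        # union of the four arcs covers the full rim
        df = compute_darkfield(stack)
        truth = ground_truth(scene)
        ring = truth.edge_mask
        assert np.all(df[ring] > 0)

    @pytest.mark.parametrize("g", [0.0, 0.3, 0.7, 1.0])
    def test_photon_conservation(self, g):
        # g redistributes light across quadrants, never creates or destroys it
        scene = Scene(
            canvas_shape=(96, 96),
            boundaries=[
                CircleBoundary(center=(48, 48), radius=20, amplitude=100.0,
                               anisotropy=g, edge_leak=0.1)
            ],
            puncta=[Punctum(center=(48, 48), amplitude=77.0)],
            background_level=3.0,
        )
        stack, truth = _render_float(scene)
        total = sum(im.sum() for im in stack.images)
        expected = truth.deposited_total + 4 * 3.0 * 96 * 96
        assert total == pytest.approx(expected, rel=1e-6)

    def test_determinism(self):
        scene = bead_scene(noise_sigma=2.0, background_level=5.0, seed=42)
        a, _ = render_quadrants(scene)
        b, _ = render_quadrants(scene)
        for x, y in zip(a.images, b.images):
            np.testing.assert_array_equal(x, y)

    def test_quantization_respects_bit_depth(self):
        scene = bead_scene(amplitude=10000.0)  # over 12-bit range
        stack, _ = render_quadrants(scene, OpticalConfig(bit_depth=12))
        for im in stack.images:
            assert im.dtype.kind == "i"
            assert im.max() <= 4095 and im.min() >= 0

    def test_out_of_canvas_rejected(self):
        scene = Scene(
            canvas_shape=(32, 32),
            boundaries=[CircleBoundary(center=(16, 16), radius=20, amplitude=1.0)],
        )
        with pytest.raises(ConfigError):
            render_quadrants(scene)

    def test_negative_amplitude_rejected(self):
        scene = Scene(canvas_shape=(32, 32), puncta=[Punctum((16, 16), amplitude=-1.0)])
        with pytest.raises(ConfigError):
            render_quadrants(scene)


class TestGroundTruth:
    def test_masks_disjoint_and_puncta_owned(self):
        scene = cell_scene(seed=5)
        truth = ground_truth(scene)
        assert not (truth.edge_mask & truth.puncta_mask).any()
        assert set(truth.per_cell_puncta_total) == {1}
        assert truth.per_cell_puncta_total[1] == pytest.approx(
            sum(p.amplitude for p in scene.puncta)
        )


class TestPhaseRendering:
    def test_empty_scene_zero_phase(self):
        assert np.all(render_phase(Scene(canvas_shape=(32, 32))) == 0)

    def test_rounding_conserves_integrated_phase(self):
        # same integrated phase at half the radius: sharper, smaller, equal sum
        flat = Scene(
            canvas_shape=(128, 128),
            boundaries=[CircleBoundary((64, 64), 30, 10.0, phase_total=500.0)],
        )
        round_ = Scene(
            canvas_shape=(128, 128),
            boundaries=[CircleBoundary((64, 64), 15, 10.0, phase_total=500.0)],
        )
        pf = render_phase(flat)
        pr = render_phase(round_)
        assert pf.sum() == pytest.approx(pr.sum(), rel=1e-6)
        assert pr.max() > pf.max()
        assert (pr > 0.2).sum() < (pf > 0.2).sum()

    def test_two_cell_integrated_phase_matches_truth(self):
        # cells far enough apart that Gaussian cross-talk is below 1e-6
        scene = Scene(
            canvas_shape=(256, 256),
            boundaries=[
                CircleBoundary((64, 64), 20, 5.0, phase_total=300.0),
                CircleBoundary((192, 192), 20, 5.0, phase_total=450.0),
            ],
        )
        phase = render_phase(scene)
        truth = ground_truth(scene)
        # direct summation oracle over generous disks around each cell
        rows, cols = np.mgrid[0:256, 0:256]
        for lbl, (cy, cx) in ((1, (64, 64)), (2, (192, 192))):
            disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= 60**2
            assert phase[disk].sum() == pytest.approx(
                truth.per_cell_phase_total[lbl], rel=1e-6
            )


class TestShapeSequence:
    def test_constant_range_identical_frames(self):
        base = cell_scene(seed=1)
        seq = make_shape_sequence(base, 3, (0.2, 0.2), seed=7)
        ref = None
        for fr in seq.frames:
            # identical up to the per-frame noise seed, so equalise the seeds
            got, _ = render_quadrants(Scene.from_dict({**fr.to_dict(), "seed": 0}))
            if ref is None:
                ref = got
                continue
            for a, b in zip(ref.images, got.images):
                np.testing.assert_array_equal(a, b)

    def test_monotone_edge_constant_puncta(self):
        base = cell_scene(seed=2)
        seq = make_shape_sequence(base, 3, (0.1, 0.9), seed=8)
        edge_amps = [fr.boundaries[0].amplitude for fr in seq.frames]
        assert np.all(np.diff(edge_amps) > 0)
        puncta_sums = [sum(p.amplitude for p in fr.puncta) for fr in seq.frames]
        assert np.allclose(puncta_sums, puncta_sums[0])

    def test_ground_truth_conserves_puncta_total(self):
        base = cell_scene(seed=3)
        seq = make_shape_sequence(base, 4, (0.0, 1.0), seed=9)
        for fr in seq.frames:
            _, truth = render_quadrants(fr)
            assert truth.puncta_total == pytest.approx(seq.conserved_puncta_total)

    def test_bad_range_rejected(self):
        with pytest.raises(ConfigError):
            make_shape_sequence(cell_scene(), 3, (0.0, 1.5))
        with pytest.raises(ConfigError):
            make_shape_sequence(cell_scene(), 1, (0.0, 1.0))


class TestPopulation:
    def test_zero_density_zero_puncta(self):
        scenes = make_population(5, 0.0, seed=0)
        assert all(len(s.puncta) == 0 for s in scenes)

    def test_seed_reproducibility(self):
        a = make_population(5, 0.01, seed=3)
        b = make_population(5, 0.01, seed=3)
        assert [s.to_dict() for s in a] == [s.to_dict() for s in b]

    def test_poisson_mean_counts(self):
        # empirical mean count within 3 standard errors of density x mean area
        density = 0.008
        scenes = make_population(500, density, seed=4)
        counts = np.array([len(s.puncta) for s in scenes])
        areas = np.array([np.pi * s.boundaries[0].radius ** 2 for s in scenes])
        expected = density * areas.mean()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se


def test_scene_json_roundtrip(tmp_path):
    scene = cell_scene(seed=6)
    scene.polynomial_background = np.arange(6, dtype=float)
    p = tmp_path / "scene.json"
    scene.to_json(p)
    back = Scene.from_json(p)
    assert back.to_dict() == scene.to_dict()
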