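"""Occlusion relevance: score arithmetic, patch sampling, map oracle, ROIs."""

import numpy as np
import pytest

import neurocausal as nc
from neurocausal.relevance import ROISet, select_top_regions
from neurocausal.synthetic import ValidationError


class TestRelevanceScore:
    def test_equal_odds_is_zero(self):
        assert nc.relevance_score(0.5, 0.5) == 0.0

    def test_closed_form_log_odds(self):
        assert nc.relevance_score(0.9, 0.5) == pytest.approx(np.log(9), abs=1e-12)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        p0, p1 = rng.uniform(0.01, 0.99, size=(2, 50))
        assert np.allclose(nc.relevance_score(p0, p1), -nc.relevance_score(p1, p0))

    def test_saturated_probabilities_stay_finite(self):
        assert np.isfinite(nc.relevance_score(1.0, 0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            nc.relevance_score(1.2, 0.5)


class TestOcclusion:
    def test_voxels_outside_patch_unchanged(self):
        rng = np.random.default_rng(1)
        vols = rng.standard_normal((5, 8, 8, 8))
        sampler = nc.PatchSampler(vols, n_draws=3)
        out = nc.occlude_patch(vols[0], (2, 3, 4), sampler, seed=0)
        assert out.shape == (3, 8, 8, 8)
        mask = np.ones((8, 8, 8), bool)
        mask[2:5, 3:6, 4:7] = False
        for draw in out:
            assert np.array_equal(draw[mask], vols[0][mask])

    def test_degenerate_sampler_reproduces_input(self):
        rng = np.random.default_rng(2)
        vols = rng.standard_normal((3, 6, 6, 6))
        sampler = nc.PatchSampler(vols, n_draws=2)
        sampler.fixed_mean = vols[0][1:4, 1:4, 1:4].copy()
        sampler.fixed_chol = np.zeros((27, 27))
        out = nc.occlude_patch(vols[0], (1, 1, 1), sampler, seed=0)
        assert np.allclose(out[0], vols[0])

    def test_draw_mean_matches_sampler_mean(self):
        rng = np.random.default_rng(3)
        vols = rng.standard_normal((40, 6, 6, 6))
        sampler = nc.PatchSampler(vols, n_draws=1)
        mean, chol = sampler.stats((0, 0, 0))
        draws = sampler.draw((0, 0, 0), 10000, np.random.default_rng(0))
        sd = np.sqrt(np.diag(chol @ chol.T))
        se = sd / np.sqrt(10000)
        assert np.all(np.abs(draws.reshape(10000, -1).mean(0) - mean) < 4 * se)

    def test_out_of_bounds_location_rejected(self):
        sampler = nc.PatchSampler(np.zeros((2, 6, 6, 6)), n_draws=1)
        with pytest.raises(ValidationError):
            nc.occlude_patch(np.zeros((6, 6, 6)), (5, 0, 0), sampler)


def _brute_force_map(model, volumes, sampler, stride, seed):
    """Independent per-window loop (no chunking, no shared accumulators)."""
    from neurocausal.relevance import _volume_seed, _window_starts, relevance_score
    volumes = np.asarray(volumes, float)
    grid = volumes.shape[1:]
    k = sampler.patch_shape
    p0 = model.predict_disease_probability(volumes)
    rngs = [np.random.default_rng(_volume_seed(seed, v)) for v in volumes]
    total = np.zeros(grid)
    cover = np.zeros(grid)
    for a in _window_starts(grid[0], k[0], stride):
        for b in _window_starts(grid[1], k[1], stride):
            for c in _window_starts(grid[2], k[2], stride):
                sl = (slice(a, a + k[0]), slice(b, b + k[1]), slice(c, c + k[2]))
                ds = []
                for i, vol in enumerate(volumes):
                    reps = np.repeat(vol[None], sampler.n_draws, 0)
                    reps[(slice(None),) + sl] = sampler.draw((a, b, c), sampler.n_draws, rngs[i])
                    p1 = model.predict_disease_probability(reps).mean()
                    ds.append(relevance_score(p0[i], p1))
                total[sl] += np.mean(ds)
                cover[sl] += 1
    return np.divide(total, cover, out=np.zeros(grid), where=cover > 0)


class TestRelevanceMap:
    @pytest.fixture
    def toy_setup(self, function_predictor):
        rng = np.random.default_rng(4)
        train = rng.standard_normal((10, 8, 8, 8))
        subjects = rng.standard_normal((3, 8, 8, 8))
        w = rng.standard_normal((8, 8, 8))
        model = function_predictor(
            lambda v: 1.0 / (1.0 + np.exp(-(v * w).sum() / 10)))
        sampler = nc.PatchSampler(train, n_draws=3)
        return model, subjects, sampler

    def test_constant_model_gives_zero_map(self, function_predictor):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((5, 8, 8, 8))
        model = function_predictor(lambda v: 0.7)
        sampler = nc.PatchSampler(train, n_draws=2)
        rmap = nc.compute_relevance_map(model, train[:2], sampler, stride=3, seed=0)
        assert np.allclose(rmap.W, 0.0)

    @pytest.mark.parametrize("stride", [3, 2])
    def test_matches_brute_force_window_loop(self, toy_setup, stride):
        model, subjects, sampler = toy_setup
        rmap = nc.compute_relevance_map(model, subjects, sampler, stride=stride, seed=9)
        expected = _brute_force_map(model, subjects, sampler, stride, seed=9)
        assert np.allclose(rmap.W, expected, atol=1e-12)

    def test_invariant_to_subject_ordering(self, toy_setup):
        model, subjects, sampler = toy_setup
        w1 = nc.compute_relevance_map(model, subjects, sampler, stride=3, seed=1).W
        w2 = nc.compute_relevance_map(model, subjects[::-1], sampler, stride=3, seed=1).W
        assert np.allclose(w1, w2)

    def test_increasing_draws_converges(self, function_predictor):
        # Monte-Carlo convergence: the map movement when going from few to
        # many replacement draws shrinks as the draw count grows
        rng = np.random.default_rng(6)
        train = rng.standard_normal((10, 8, 8, 8))
        w = rng.standard_normal((8, 8, 8))
        model = function_predictor(
            lambda v: 1.0 / (1.0 + np.exp(-(v * w).sum() / 20)))
        maps = {}
        for nd in (2, 8, 64):
            maps[nd] = nc.compute_relevance_map(
                model, train[:2], nc.PatchSampler(train, n_draws=nd),
                stride=3, seed=2).W
        coarse = np.abs(maps[2] - maps[64]).mean()
        fine = np.abs(maps[8] - maps[64]).mean()
        assert fine < coarse
        assert np.abs(maps[8] - maps[64]).max() < 4 * np.abs(maps[64]).max() / np.sqrt(8)


def _brute_force_components(mask, connectivity):
    """Union-find flood fill, independent of scipy.ndimage."""
    coords = list(map(tuple, np.argwhere(mask)))
    index = {c: i for i, c in enumerate(coords)}
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    for c in coords:
        for o in offsets:
            nb = tuple(np.add(c, o))
            if nb in index:
                ra, rb = find(index[c]), find(index[nb])
                parent[ra] = rb
    return len({find(i) for i in range(len(coords))})


class TestRegionSelection:
    def test_single_cube_is_one_roi(self):
        # background strictly below the cube; the 93.6th percentile puts the
        # threshold between background and cube, so exactly the 64 cube
        # voxels (6.4% of 1000) survive
        rng = np.random.default_rng(10)
        W = rng.uniform(0.0, 0.1, size=(10, 10, 10))
        W[2:6, 2:6, 2:6] = 1.0
        rois = select_top_regions(nc.RelevanceMap(W), percentile=93.6)
        assert len(rois) == 1
        assert rois.rois[0].size == 64
        assert rois.rois[0].bbox == ((2, 6), (2, 6), (2, 6))

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_axial_gap_separates_two_cubes(self, connectivity):
        rng = np.random.default_rng(11)
        W = rng.uniform(0.0, 0.1, size=(12, 8, 8))
        W[1:4, 1:4, 1:4] = 1.0
        W[5:8, 1:4, 1:4] = 1.0  # one sub-threshold plane between the cubes
        rois = select_top_regions(nc.RelevanceMap(W), percentile=93.5,
                                  connectivity=connectivity)
        assert len(rois) == 2
        assert sum(r.size for r in rois.rois) == 54

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_component_count_matches_union_find_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((9, 9, 9))
        rois = select_top_regions(nc.RelevanceMap(W), percentile=85,
                                  connectivity=connectivity)
        mask = W >= np.percentile(W, 85)
        assert len(rois) == _brute_force_components(mask, connectivity)
        assert rois.mask(W.shape).sum() == mask.sum()

    def test_percentile_retains_exact_count_without_ties(self):
        W = np.random.default_rng(8).permutation(1000.0 * np.arange(1, 1001)).reshape(10, 10, 10)
        rois = select_top_regions(nc.RelevanceMap(W), percentile=90)
        assert rois.mask(W.shape).sum() == 100

    def test_constant_map_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            rois = select_top_regions(nc.RelevanceMap(np.ones((4, 4, 4))))
        assert len(rois) == 0

    def test_rois_are_disjoint_and_ordered_by_size(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((12, 12, 12))
        rois = select_top_regions(nc.RelevanceMap(W), percentile=80)
        seen = set()
        sizes = [r.size for r in rois.rois]
        for roi in rois.rois:
            vox = set(map(tuple, roi.voxels))
            assert not vox & seen
            seen |= vox
        assert sizes == sorted(sizes, reverse=True)


def test_dice_coefficient_known_values():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a[:2], b[1:3] = True, True
    assert nc.dice_coefficient(a, a) == 1.0
    assert nc.dice_coefficient(a, ~a) == 0.0
    assert nc.dice_coefficient(a, b) == pytest.approx(0.5)
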