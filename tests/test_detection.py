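"""Detection stage: response computation, kurtosis thresholding,
component extraction and the self-tuning invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beliefspot import SpotDetector, detect_objects
from beliefspot.detection import (
    ComponentSet,
    ImageGrid,
    ResponseMap,
    adaptive_threshold,
    binarize_and_label,
    compute_response,
    excess_kurtosis,
    prune_by_local_maxima,
)
from beliefspot.exceptions import (
    DegenerateDistributionError,
    InvalidImageError,
    NegativeKurtosisError,
)


# ---------------------------------------------------------------- response


class TestComputeResponse:
    def test_constant_image_gives_zero_response(self):
        resp = compute_response(np.full((32, 32), 7.0), post_sigma=1.0)
        assert np.all(resp.values == 0)

    def test_linear_ramp_zero_on_interior(self):
        ramp = np.tile(np.arange(64, dtype=float), (64, 1))
        resp = compute_response(ramp, post_sigma=1.0)
        # second derivative of a linear function vanishes away from the
        # reflect-padded border (smoothing spreads the edge effect ~4 sigma)
        assert np.allclose(resp.values[6:-6, 6:-6], 0.0, atol=1e-9)

    def test_gaussian_spot_peak_at_center(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = 100.0 * np.exp(-((rr - 30.0) ** 2 + (cc - 33.0) ** 2) / (2 * 3.0**2))
        resp = compute_response(img, pre_sigma=0.0, post_sigma=1.0)
        peak = np.unravel_index(np.argmax(resp.values), resp.values.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 33) <= 1
        # positive response forms a disk covering the spot core
        assert resp.values[30, 33] > 0
        assert np.all(resp.values >= 0)

    def test_rejects_non_finite(self):
        bad = np.ones((8, 8))
        bad[3, 3] = np.nan
        with pytest.raises(InvalidImageError):
            compute_response(bad)

    def test_rejects_tiny_image(self):
        with pytest.raises(InvalidImageError):
            ImageGrid(np.ones((2, 5)))


# ---------------------------------------------------------------- kurtosis


class TestExcessKurtosis:
    def test_standard_normal_is_zero(self):
        draws = np.random.default_rng(0).standard_normal(10**6)
        assert abs(excess_kurtosis(draws)) < 0.05

    def test_symmetric_two_point_is_minus_two(self):
        values = np.array([0.0, 1.0] * 500)
        assert excess_kurtosis(values) == pytest.approx(-2.0, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDistributionError):
            excess_kurtosis(np.full(100, 3.14))
        with pytest.raises(DegenerateDistributionError):
            excess_kurtosis([1.0])


# ---------------------------------------------------------------- threshold


def _manual_threshold(values, prc):
    """Independent arithmetic re-evaluation of the closed form."""
    flat = [float(v) for v in np.ravel(values)]
    n = len(flat)
    mu = sum(flat) / n
    var = sum((v - mu) ** 2 for v in flat) / n
    k = sum(((v - mu) / math.sqrt(var)) ** 4 for v in flat) / n - 3.0
    z = k ** 0.25
    pos = [v for v in flat if v > 0]
    logs = [math.log(v) for v in pos]
    lmu = sum(logs) / len(logs)
    lsd = math.sqrt(sum((l - lmu) ** 2 for l in logs) / len(logs))
    return math.exp(lmu) * math.exp(lsd) ** (z / prc)


class TestAdaptiveThreshold:
    def test_matches_independent_closed_form(self, rng):
        # lognormal positive pixels with a zero background block
        values = np.zeros(5000)
        values[:2000] = rng.lognormal(mean=-1.0, sigma=1.5, size=2000)
        resp = ResponseMap(values=values.reshape(50, 100))
        t = adaptive_threshold(resp, prc=2.0)
        expected = _manual_threshold(values, 2.0)
        assert t == pytest.approx(expected, rel=1e-9)
        assert resp.threshold == t and resp.z_score is not None

    def test_large_prc_limit_is_geometric_mean(self, rng):
        values = np.zeros(4000)
        values[:1500] = rng.lognormal(size=1500)
        resp = ResponseMap(values=values.reshape(40, 100))
        t = adaptive_threshold(resp, prc=1e12)
        pos = values[values > 0]
        assert t == pytest.approx(np.exp(np.mean(np.log(pos))), rel=1e-6)

    def test_negative_kurtosis_error_and_clamp(self, rng):
        # uniform positives: platykurtic, excess kurtosis ~ -1.2
        values = rng.uniform(0.5, 1.5, size=4096)
        resp = ResponseMap(values=values.reshape(64, 64))
        with pytest.raises(NegativeKurtosisError, match="domain error"):
            adaptive_threshold(resp, prc=2.0, kurtosis_fallback="error")
        with pytest.warns(UserWarning, match="clamped"):
            t = adaptive_threshold(resp, prc=2.0, kurtosis_fallback="clamp")
        assert t == pytest.approx(np.exp(np.mean(np.log(values))), rel=1e-9)

    def test_empty_positive_support_raises(self):
        with pytest.raises(DegenerateDistributionError):
            adaptive_threshold(ResponseMap(values=np.zeros((16, 16))), prc=2.0)

    def test_prc_monotonicity_of_threshold(self, rng):
        values = np.zeros(4000)
        values[:1500] = rng.lognormal(sigma=1.2, size=1500)
        thresholds = [
            adaptive_threshold(ResponseMap(values=values.reshape(40, 100)), prc=p)
            for p in (0.5, 1.0, 2.0, 4.0)
        ]
        assert thresholds == sorted(thresholds, reverse=True)


# ---------------------------------------------------------------- components


def _flood_fill_components(mask, connectivity):
    """Brute-force oracle: BFS flood fill in raster-scan order."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    h, w = mask.shape
    label_map = np.zeros((h, w), dtype=int)
    components = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and label_map[r, c] == 0:
                comp_id = len(components) + 1
                stack, pixels = [(r, c)], []
                label_map[r, c] = comp_id
                while stack:
                    pr, pc = stack.pop()
                    pixels.append((pr, pc))
                    for dr, dc in offsets:
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and label_map[nr, nc] == 0:
                            label_map[nr, nc] = comp_id
                            stack.append((nr, nc))
                components.append(sorted(pixels))
    return label_map, components


class TestBinarizeAndLabel:
    def test_single_square(self):
        values = np.zeros((32, 32))
        values[10:15, 20:25] = 5.0
        comps = binarize_and_label(values, 1.0)
        assert len(comps) == 1
        assert comps.components[0].shape[0] == 25

    def test_checkerboard_connectivity_4(self):
        mask = np.indices((16, 16)).sum(axis=0) % 2 == 0
        comps = binarize_and_label(mask.astype(float), 0.5, connectivity=4)
        assert len(comps) == int(mask.sum())

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            mask = rng.random((64, 64)) < 0.35
            comps = binarize_and_label(mask.astype(float), 0.5, connectivity=connectivity)
            _, oracle = _flood_fill_components(mask, connectivity)
            assert len(comps) == len(oracle)
            got = [sorted(map(tuple, c)) for c in comps.components]
            assert got == oracle

    def test_min_area_filter(self):
        values = np.zeros((16, 16))
        values[2, 2] = 5.0
        values[8:11, 8:11] = 5.0
        comps = binarize_and_label(values, 1.0, min_area=4)
        assert len(comps) == 1
        assert comps.components[0].shape[0] == 9


class TestPruneByLocalMaxima:
    def test_gaussian_peak_retained_ramp_removed(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = 50.0 * np.exp(-((rr - 16.0) ** 2 + (cc - 16.0) ** 2) / 18.0)
        img += 0.1 * cc  # strict ramp elsewhere
        label_map = np.zeros((64, 64), dtype=int)
        peak_coords = np.argwhere((np.abs(rr - 16) <= 3) & (np.abs(cc - 16) <= 3))
        label_map[peak_coords[:, 0], peak_coords[:, 1]] = 1
        ramp_coords = np.argwhere((rr >= 40) & (rr <= 44) & (cc >= 30) & (cc <= 40))
        label_map[ramp_coords[:, 0], ramp_coords[:, 1]] = 2
        comps = ComponentSet(label_map=label_map, components=[peak_coords, ramp_coords])
        pruned = prune_by_local_maxima(comps, img)
        assert len(pruned) == 1
        assert np.array_equal(
            np.sort(pruned.components[0], axis=0), np.sort(peak_coords, axis=0)
        )


# ---------------------------------------------------------------- pipeline


class TestDetectObjects:
    def test_blank_image_raises_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            detect_objects(np.zeros((64, 64)))

    def test_deterministic(self, noisy_field):
        image, _ = noisy_field
        det = SpotDetector(post_sigma=3.0)
        a = det.detect(image)
        b = det.detect(image)
        assert np.array_equal(a.label_map, b.label_map)

    def test_multiplicative_intensity_invariance(self, noisy_field):
        image, _ = noisy_field
        det = SpotDetector(post_sigma=3.0, prc=2.0)
        base = det.detect(image)
        for c in (2.0, 3.7, 0.25):
            scaled = det.detect(image * c)
            assert np.array_equal(base.label_map, scaled.label_map)

    def test_prc_monotonicity_of_foreground(self, noisy_field):
        image, _ = noisy_field
        resp = compute_response(image, 0.0, 3.0)
        t_lo = adaptive_threshold(
            ResponseMap(values=resp.values.copy()), prc=1.5
        )
        t_hi = adaptive_threshold(
            ResponseMap(values=resp.values.copy()), prc=3.0
        )
        assert t_hi <= t_lo
        fg_precise = resp.values > t_lo
        fg_recall = resp.values > t_hi
        assert np.all(fg_recall[fg_precise])  # superset

    def test_label_ids_in_raster_order(self):
        values = np.zeros((32, 32))
        values[20:23, 2:5] = 5.0   # later in raster order
        values[2:5, 25:28] = 5.0   # first pixel earlier
        comps = binarize_and_label(values, 1.0)
        firsts = [tuple(c[0]) for c in comps.components]
        assert firsts == sorted(firsts)

    def test_sklearn_params_round_trip(self):
        det = SpotDetector(prc=4.25, min_area=9)
        params = det.get_params()
        clone = SpotDetector(**params)
        assert clone.get_params() == params


@settings(deadline=None, max_examples=25)
@given(
    prc=st.floats(min_value=0.5, max_value=8.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_threshold_scale_equivariance_property(prc, seed):
    """T(c*V) = c*T(V): the self-tuning threshold is scale-equivariant."""
    rng = np.random.default_rng(seed)
    values = np.zeros(2500)
    values[:900] = rng.lognormal(sigma=1.0, size=900)
    t1 = adaptive_threshold(ResponseMap(values=values.reshape(50, 50)), prc=prc)
    t2 = adaptive_threshold(ResponseMap(values=(values * 5.5).reshape(50, 50)), prc=prc)
    assert t2 == pytest.approx(5.5 * t1, rel=1e-9)
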