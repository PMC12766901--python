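"""ReHo / DC against independent brute-force implementations, plus map ops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from limbiccog.imaging_io import BoldSeries, BrainMask, MetricMap
from limbiccog.regional_metrics import (
    DcParams,
    RehoParams,
    compute_dc,
    compute_reho,
    neighborhood_offsets,
    normalize_map,
    smooth_map,
)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def kendalls_w_bruteforce(series_list):
    """Tie-corrected Kendall's W computed directly from its definition."""
    K = len(series_list)
    n = len(series_list[0])
    if K <= 1:
        return 0.0
    rank_sum = np.zeros(n)
    tie_term = 0.0
    for s in series_list:
        rank_sum += rankdata(s)
        _, counts = np.unique(s, return_counts=True)
        tie_term += float(np.sum(counts.astype(float) ** 3 - counts))
    s_stat = float(np.sum((rank_sum - K * (n + 1) / 2.0) ** 2))
    denom = K**2 * (n**3 - n) - K * tie_term
    return 12.0 * s_stat / denom if denom > 0 else 0.0


def reho_bruteforce(bold, mask, neighborhood=27):
    """Per-voxel W via an explicit neighbour loop (no vectorisation shared
    with the implementation under test)."""
    offsets = neighborhood_offsets(neighborhood)
    out = np.zeros(mask.data.shape)
    for x, y, z in np.argwhere(mask.data):
        series = []
        for dx, dy, dz in offsets:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < mask.data.shape[0] and 0 <= v < mask.data.shape[1] \
                    and 0 <= w < mask.data.shape[2] and mask.data[u, v, w]:
                series.append(bold.data[u, v, w].astype(float))
        out[x, y, z] = kendalls_w_bruteforce(series)
    return out


def dc_bruteforce(bold, mask, r_threshold=0.25):
    """O(V^2) double loop over in-mask voxel pairs."""
    coords = np.argwhere(mask.data)
    V = len(coords)
    out = np.zeros(mask.data.shape)
    for a in range(V):
        total = 0.0
        sa = bold.data[tuple(coords[a])].astype(float)
        for b in range(V):
            if a == b:
                continue
            sb = bold.data[tuple(coords[b])].astype(float)
            if sa.std() == 0 or sb.std() == 0:
                continue
            r = np.corrcoef(sa, sb)[0, 1]
            if r > r_threshold:
                total += r
        out[tuple(coords[a])] = total
    return out


# --------------------------------------------------------------------------
# ReHo
# --------------------------------------------------------------------------

class TestReho:
    def test_identical_monotone_series_give_w_of_one(self, full_mask):
        base = np.linspace(0.0, 1.0, 20)
        data = np.tile(base, (4, 4, 4, 1))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        reho = compute_reho(bold, full_mask)
        assert np.allclose(reho.data, 1.0, atol=1e-12)

    def test_antithetic_pair_gives_zero(self):
        # K=2 exactly reversed rank orders force every rank sum to K(n+1)/2
        mask = BrainMask(np.array([[[True, True]]]))
        up = np.arange(10.0)
        data = np.stack([up, up[::-1]]).reshape(1, 1, 2, 10)
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        reho = compute_reho(bold, mask, RehoParams(neighborhood=27))
        assert np.allclose(reho.data, 0.0, atol=1e-12)

    def test_matches_bruteforce_on_random_block(self, rng):
        data = rng.standard_normal((3, 3, 3, 20))
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        got = compute_reho(bold, mask).data
        want = reho_bruteforce(bold, mask)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_bruteforce_with_ties_and_partial_mask(self, rng):
        # heavy quantisation produces ties; irregular mask shrinks K
        data = np.round(rng.standard_normal((4, 3, 3, 15)) * 2) / 2
        mask = BrainMask(rng.random((4, 3, 3)) > 0.3)
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        got = compute_reho(bold, mask).data
        want = reho_bruteforce(bold, mask)
        np.testing.assert_allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("neighborhood", [7, 19, 27])
    def test_neighborhood_variants_match_bruteforce(self, rng, neighborhood):
        data = rng.standard_normal((3, 3, 3, 12))
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        got = compute_reho(bold, mask, RehoParams(neighborhood)).data
        want = reho_bruteforce(bold, mask, neighborhood)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_w_bounded_and_rank_invariant(self, rng):
        data = rng.standard_normal((4, 4, 4, 25))
        mask = BrainMask(np.ones((4, 4, 4), dtype=bool))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        w1 = compute_reho(bold, mask).data
        assert np.all((w1 >= 0) & (w1 <= 1))
        # strictly monotone transform of every series leaves ranks unchanged
        transformed = BoldSeries("s", np.exp(data / 2), [3, 3, 3], 2.0)
        w2 = compute_reho(transformed, mask).data
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_constant_series_neighbourhood_gets_zero(self, full_mask):
        data = np.ones((4, 4, 4, 10))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        reho = compute_reho(bold, full_mask)
        assert np.allclose(reho.data, 0.0)

    def test_single_voxel_mask_gets_zero(self, rng):
        mask_arr = np.zeros((3, 3, 3), dtype=bool)
        mask_arr[1, 1, 1] = True
        bold = BoldSeries("s", rng.standard_normal((3, 3, 3, 10)), [3, 3, 3], 2.0)
        reho = compute_reho(bold, BrainMask(mask_arr))
        assert reho.data[1, 1, 1] == 0.0


# --------------------------------------------------------------------------
# Normalisation and smoothing
# --------------------------------------------------------------------------

class TestNormalizeSmooth:
    def test_constant_map_normalizes_to_ones(self, full_mask):
        m = MetricMap(np.full((4, 4, 4), 3.5), "reho", full_mask)
        out = normalize_map(m)
        assert np.allclose(out.in_mask_values(), 1.0)
        assert out.metric_kind == "reho_normalized"

    def test_output_mean_is_one_and_scale_invariant(self, rng, full_mask):
        data = rng.random((4, 4, 4)) + 0.1
        a = normalize_map(MetricMap(data, "reho", full_mask))
        b = normalize_map(MetricMap(2 * data, "reho", full_mask))
        assert a.in_mask_values().mean() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_zero_mean_map_rejected(self, full_mask):
        m = MetricMap(np.zeros((4, 4, 4)), "reho", full_mask)
        with pytest.raises(ValueError, match="mean is zero"):
            normalize_map(m)

    def test_fwhm_zero_is_identity(self, rng, full_mask):
        m = MetricMap(rng.random((4, 4, 4)), "reho", full_mask)
        out = smooth_map(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_constant_in_mask_map_unchanged(self, rng):
        mask = BrainMask(rng.random((6, 6, 6)) > 0.4)
        m = MetricMap(np.where(mask.data, 2.0, 0.0), "reho", mask)
        out = smooth_map(m, 6.0)
        np.testing.assert_allclose(out.in_mask_values(), 2.0, atol=1e-10)

    def test_impulse_mass_preserved_in_interior(self):
        # away from mask edges, plain Gaussian smoothing conserves total mass
        mask = BrainMask(np.ones((15, 15, 15), dtype=bool))
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 5.0
        out = smooth_map(MetricMap(data, "reho", mask), 4.0, (3.0, 3.0, 3.0))
        assert out.data.sum() == pytest.approx(5.0, rel=1e-6)


# --------------------------------------------------------------------------
# Degree centrality
# --------------------------------------------------------------------------

class TestDc:
    def test_two_identical_voxels_have_unit_dc(self):
        mask_arr = np.zeros((1, 1, 3), dtype=bool)
        mask_arr[0, 0, 0] = mask_arr[0, 0, 2] = True
        base = np.sin(np.arange(20.0))
        data = np.zeros((1, 1, 3, 20))
        data[0, 0, 0] = base
        data[0, 0, 2] = base
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        dc = compute_dc(bold, BrainMask(mask_arr), standardize=False)
        assert dc.data[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert dc.data[0, 0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_series_give_zero(self):
        # sinusoids at distinct integer frequencies are exactly orthogonal
        t = np.arange(32.0)
        mask_arr = np.ones((2, 2, 1), dtype=bool)
        data = np.zeros((2, 2, 1, 32))
        for k, (i, j) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            data[i, j, 0] = np.sin(2 * np.pi * (k + 1) * t / 32)
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        dc = compute_dc(bold, BrainMask(mask_arr), standardize=False)
        assert np.allclose(dc.data, 0.0, atol=1e-10)

    def test_matches_bruteforce(self, random_bold, full_mask):
        got = compute_dc(random_bold, full_mask, standardize=False).data
        want = dc_bruteforce(random_bold, full_mask)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_monotone_nonincreasing_in_threshold(self, random_bold, full_mask):
        prev = None
        for thr in (0.1, 0.25, 0.5, 0.75):
            dc = compute_dc(random_bold, full_mask, DcParams(r_threshold=thr),
                            standardize=False).data
            assert np.all(dc >= 0)
            if prev is not None:
                assert np.all(dc <= prev + 1e-12)
            prev = dc

    def test_binary_count_weighting(self, random_bold, full_mask):
        w = compute_dc(random_bold, full_mask,
                       DcParams(weighting="weighted_sum"), standardize=False).data
        c = compute_dc(random_bold, full_mask,
                       DcParams(weighting="binary_count"), standardize=False).data
        # every counted edge contributes r in (0.25, 1], so sum < count and
        # sum > 0.25 * count
        assert np.all(w <= c + 1e-12)
        assert np.all(w >= 0.25 * c - 1e-12)

    def test_zscore_standardization(self, random_bold, full_mask):
        dc = compute_dc(random_bold, full_mask)
        vals = dc.in_mask_values()
        assert vals.mean() == pytest.approx(0.0, abs=1e-6)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-4)

    def test_zero_variance_series_contributes_nothing(self, rng):
        data = rng.standard_normal((2, 2, 1, 30))
        data[0, 0, 0] = 7.0  # constant series
        mask = BrainMask(np.ones((2, 2, 1), dtype=bool))
        bold = BoldSeries("s", data, [3, 3, 3], 2.0)
        dc = compute_dc(bold, mask, standardize=False)
        assert dc.data[0, 0, 0] == 0.0


# --------------------------------------------------------------------------
# Property tests
# --------------------------------------------------------------------------

@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(5, 30))
def test_kendalls_w_bounds_hold_for_any_series(seed, n):
    rng = np.random.default_rng(seed)
    series = [rng.standard_normal(n) for _ in range(5)]
    w = kendalls_w_bruteforce(series)
    assert 0.0 <= w <= 1.0 + 1e-12
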