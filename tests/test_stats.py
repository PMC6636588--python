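"""Detection engine: smoothing, z-scores, thresholding, clustering, filters."""

import numpy as np
import pytest
from scipy.stats import norm

from qmlm.image import VolumetricImage
from qmlm.stats import (ControlCohort, DetectionParams, detect, fdr_threshold,
                        parenchyma_filter, smooth_map, threshold_map,
                        zscore_map)

from conftest import toy_atlas, vol


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def flood_fill_clusters(sig, connectivity=26):
    """Cluster partition of a boolean volume by breadth-first search."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(sig.shape, dtype=bool)
    clusters = []
    for start in map(tuple, np.argwhere(sig)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, sig.shape)) \
                        and sig[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        clusters.append(frozenset(comp))
    return clusters


def brute_force_bh(p, q):
    """Largest p(i) with p(i) <= i*q/m, by explicit enumeration."""
    ps = sorted(p)
    m = len(ps)
    best = 0.0
    for i, pv in enumerate(ps, start=1):
        if pv <= i * q / m:
            best = pv
    return best


# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        x = vol(rng.normal(size=(8, 8, 8)))
        np.testing.assert_array_equal(smooth_map(x, 0.0).data, x.data)

    def test_constant_preserved_under_mask(self):
        """Renormalized masked smoothing keeps a constant map constant inside
        the mask, even at mask edges."""
        shape = (10, 10, 10)
        mask = np.zeros(shape); mask[2:8, 2:8, 2:8] = 1
        x = np.where(mask > 0, 7.5, 0.0)
        out = smooth_map(vol(x), 6.0, vol(mask))
        np.testing.assert_allclose(out.data[mask > 0], 7.5, atol=1e-10)
        np.testing.assert_allclose(out.data[mask == 0], 0.0)

    def test_delta_matches_closed_form_gaussian(self):
        """Unmasked smoothing of a delta equals the normalized sampled
        Gaussian (truncated at 4 sigma), computed in closed form."""
        n, fwhm, voxel = 21, 6.0, 1.0
        x = np.zeros((n, n, n)); c = n // 2
        x[c, c, c] = 1.0
        out = smooth_map(vol(x, voxel), fwhm).data
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        r = int(4 * sigma + 0.5)
        d = np.arange(-r, r + 1)
        g1 = np.exp(-d ** 2 / (2 * sigma ** 2))
        g1 /= g1.sum()
        kern = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        expected = np.zeros_like(x)
        expected[c - r:c + r + 1, c - r:c + r + 1, c - r:c + r + 1] = kern
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_negative_fwhm_errors(self):
        with pytest.raises(ValueError):
            smooth_map(vol(np.zeros((4, 4, 4))), -1.0)


class TestZScore:
    def _cohort(self):
        rng = np.random.default_rng(1)
        return ControlCohort([vol(rng.normal(size=(6, 6, 6))) for _ in range(8)])

    def test_mean_map_gives_zero(self):
        cohort = self._cohort()
        z = zscore_map(cohort.mean_map, cohort)
        np.testing.assert_allclose(z.data[np.isfinite(z.data)], 0.0, atol=1e-12)

    def test_two_sd_offset_gives_two(self):
        cohort = self._cohort()
        x = cohort.mean_map.with_data(
            cohort.mean_map.data + 2 * cohort.sd_map.data)
        z = zscore_map(x, cohort)
        np.testing.assert_allclose(z.data, 2.0, atol=1e-10)

    def test_zero_sd_is_undefined(self):
        maps = [vol(np.full((4, 4, 4), 3.0)) for _ in range(4)]
        z = zscore_map(vol(np.ones((4, 4, 4))), ControlCohort(maps))
        assert np.isnan(z.data).all()

    def test_loo_self_consistency(self, small_cohort):
        """Each control's z against the rest is centered near zero:
        |mean z| < 3/sqrt(n) on average over defined brain voxels."""
        from qmlm.measures import compute_measure_map
        maps = [compute_measure_map(s, "MD") for s in small_cohort]
        n = len(maps)
        brain = small_cohort[0].brain_mask.data > 0
        for j in range(3):
            rest = ControlCohort([m for i, m in enumerate(maps) if i != j])
            z = zscore_map(maps[j], rest).data[brain]
            assert abs(np.nanmean(z)) < 3 / np.sqrt(n)


class TestFDR:
    def test_all_rejected(self):
        assert fdr_threshold([0.001, 0.01, 0.02, 0.05], 0.05) == 0.05

    def test_none_rejected(self):
        assert fdr_threshold([1.0, 1.0], 0.05) == 0.0

    def test_single_p_reduces_to_raw(self):
        assert fdr_threshold([0.04], 0.05) == 0.04

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=200) ** 2
        cutoff = fdr_threshold(p, 0.05)
        assert cutoff == brute_force_bh(p, 0.05)
        from statsmodels.stats.multitest import multipletests
        reject, *_ = multipletests(p, 0.05, method="fdr_bh")
        np.testing.assert_array_equal(p <= cutoff, reject)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fdr_threshold([], 0.05)


class TestThreshold:
    def _params(self, **kw):
        base = dict(smoothing_fwhm_mm=0.0, p_mode="uncorrected",
                    p_value=0.001, cluster_k=30)
        base.update(kw)
        return DetectionParams(**base)

    def test_cluster_extent_boundary(self):
        """A 29-voxel blob dies at k=30; a 30-voxel blob survives."""
        shape = (12, 12, 12)
        mask = vol(np.ones(shape))
        for n_vox, expected in ((29, 0), (30, 1)):
            z = np.zeros(shape)
            flat = np.zeros(z.size, dtype=bool)
            flat[:n_vox] = True  # contiguous raster prefix is 26-connected
            z[flat.reshape(shape)] = 5.0
            cs = threshold_map(vol(z), self._params(), mask)
            assert len(cs) == expected

    def test_null_map_empty(self):
        cs = threshold_map(vol(np.zeros((8, 8, 8))), self._params(cluster_k=1),
                           vol(np.ones((8, 8, 8))))
        assert len(cs) == 0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        """Suprathreshold voxel set and cluster partition match a per-voxel
        p test plus BFS flood fill, bit-exactly."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(12, 12, 12)) * 2.0
        params = self._params(p_value=0.01, cluster_k=2,
                              connectivity=connectivity)
        cs = threshold_map(vol(z), params, vol(np.ones(z.shape)))
        sig = 2 * norm.sf(np.abs(z)) <= 0.01
        expected = [c for c in flood_fill_clusters(sig, connectivity)
                    if len(c) >= 2]
        got = [frozenset(map(tuple, c.voxels)) for c in cs.clusters]
        assert sorted(got, key=sorted) == sorted(expected, key=sorted)

    def test_peak_is_max_abs_z(self):
        z = np.zeros((8, 8, 8))
        z[2:5, 2:5, 2:5] = 4.0
        z[3, 3, 3] = -6.0
        cs = threshold_map(vol(z), self._params(cluster_k=1),
                           vol(np.ones(z.shape)))
        assert cs.clusters[0].peak_voxel == (3, 3, 3)
        assert cs.clusters[0].peak_z == -6.0

    def test_fwe_is_bonferroni(self):
        shape = (10, 10, 10)
        n = 1000
        zcrit = norm.isf(0.05 / n / 2)
        z = np.zeros(shape)
        z[0, 0, 0] = zcrit + 0.01
        z[5, 5, 5] = zcrit - 0.01
        cs = threshold_map(vol(z), self._params(p_mode="fwe", p_value=0.05,
                                                cluster_k=1),
                           vol(np.ones(shape)))
        assert len(cs) == 1 and cs.clusters[0].peak_voxel == (0, 0, 0)

    def test_undefined_voxels_not_tested(self):
        z = np.full((6, 6, 6), np.nan)
        z[0, 0, 0] = 9.0
        cs = threshold_map(vol(z), self._params(cluster_k=1),
                           vol(np.ones(z.shape)))
        assert cs.n_tests == 1 and len(cs) == 1

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_map(vol(np.zeros((4, 4, 4))), self._params(),
                          vol(np.zeros((4, 4, 4))))


class TestInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_monotonicity(self, seed):
        """Tightening thresholds never creates detections: suprathreshold
        voxel sets are nested under decreasing p, the largest surviving
        cluster never grows, and raising cluster_k never increases the
        cluster count."""
        rng = np.random.default_rng(seed)
        z = vol(rng.normal(size=(12, 12, 12)) * 1.8)
        mask = vol(np.ones((12, 12, 12)))

        def clusters(p_value, k):
            return threshold_map(
                z, DetectionParams(0.0, "uncorrected", p_value, k), mask)

        def voxset(cs):
            out = set()
            for c in cs.clusters:
                out.update(map(tuple, c.voxels))
            return out

        prev = None
        for p in (0.05, 0.01, 0.001):
            cs = clusters(p, 1)
            vs = voxset(cs)
            if prev is not None:
                assert vs <= prev  # nesting of suprathreshold sets
                # largest surviving extent shrinks with p
                assert (max((c.size for c in cs.clusters), default=0)
                        <= max((c.size for c in prev_cs.clusters), default=0))
            prev, prev_cs = vs, cs
        for k_lo, k_hi in ((1, 3), (3, 8)):
            assert len(clusters(0.05, k_hi)) <= len(clusters(0.05, k_lo))

    @pytest.mark.parametrize("seed", range(4))
    def test_fdr_nested_in_uncorrected(self, seed):
        """Every voxel significant under FDR at q is significant under the
        uncorrected test at the returned cutoff."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(10, 10, 10)) * 1.5
        mask = vol(np.ones(z.shape))
        q = 0.05
        fdr = threshold_map(vol(z), DetectionParams(0.0, "fdr", q, 1), mask)
        p = 2 * norm.sf(np.abs(z))
        cutoff = fdr_threshold(p.ravel(), q)
        fdr_vox = set()
        for c in fdr.clusters:
            fdr_vox.update(map(tuple, c.voxels))
        unc_vox = set(map(tuple, np.argwhere(p <= max(cutoff, 1e-300))))
        assert fdr_vox <= unc_vox


class TestParenchymaFilter:
    def _clusters(self, atlas, *peaks):
        from qmlm.stats import Cluster, ClusterSet
        cl = [Cluster(np.array([p]), 1, p, 5.0) for p in peaks]
        return ClusterSet(cl, DetectionParams(), 100, atlas.labels.affine,
                          atlas.labels.shape)

    def test_ventricle_peak_removed_cortex_kept(self, flat_atlas):
        vent = (6, 6, 6)       # ventricle label
        cortex = (3, 3, 10)    # left frontal, inside the GM slab
        cs = parenchyma_filter(self._clusters(flat_atlas, vent, cortex),
                               flat_atlas, cortex_distance_mm=5.0)
        assert [c.peak_voxel for c in cs.clusters] == [cortex]

    @pytest.mark.parametrize("seed", range(4))
    def test_distance_rule_matches_brute_force(self, flat_atlas, seed):
        """Deep clusters survive iff their peak is within the configured
        distance of cortical GM, per an explicit Euclidean oracle."""
        rng = np.random.default_rng(seed)
        gm = flat_atlas.gm_mask.data > 0
        gm_pts = np.argwhere(gm) * flat_atlas.labels.voxel_size
        labels = flat_atlas.labels.data
        peaks = [tuple(p) for p in rng.integers(0, 12, size=(20, 3))
                 if labels[tuple(p)] in (1, 2)]
        cs = parenchyma_filter(self._clusters(flat_atlas, *peaks),
                               flat_atlas, cortex_distance_mm=5.0)
        kept = {c.peak_voxel for c in cs.clusters}
        for p in peaks:
            d = np.linalg.norm(
                gm_pts - np.array(p) * flat_atlas.labels.voxel_size,
                axis=1).min()
            assert (p in kept) == (d <= 5.0)

    def test_no_gm_mask_skips_distance_rule(self, flat_atlas):
        import dataclasses
        atlas = dataclasses.replace(flat_atlas, gm_mask=None)
        deep = (3, 3, 0)  # far from the GM slab but labeled parenchyma
        cs = parenchyma_filter(self._clusters(atlas, deep), atlas, 5.0)
        assert len(cs) == 1

    def test_atlas_without_lobes_errors(self, flat_atlas):
        import pandas as pd
        bad = flat_atlas
        bad_table = pd.DataFrame(
            [{"label": 0, "lobe": "background", "side": "none"}])
        from qmlm.image import Atlas
        with pytest.raises(ValueError, match="lobe"):
            parenchyma_filter(self._clusters(bad, (1, 1, 1)),
                              Atlas(bad.labels, bad_table), 5.0)
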