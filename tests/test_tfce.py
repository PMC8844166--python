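import numpy as np
import pytest

from hemiclass import TFCEParams, one_sample_tstat, sign_flip_test, tfce_transform


def flood_fill_tfce(stat, E=0.5, H=2.0, n_steps=100, connectivity=26):
    """Independent brute-force oracle: relabels connected components with a
    hand-rolled flood fill at every midpoint height step."""
    stat = np.asarray(stat, float)
    sx, sy, sz = stat.shape
    vmax = stat.max()
    out = np.zeros_like(stat)
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    if connectivity == 26:
        offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    else:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
    for k in range(1, n_steps + 1):
        h = (k - 0.5) * dh
        supra = stat >= h
        visited = np.zeros_like(supra)
        for start in zip(*np.nonzero(supra)):
            if visited[start]:
                continue
            comp = [start]
            visited[start] = True
            frontier = [start]
            while frontier:
                x, y, z = frontier.pop()
                for dx, dy, dz in offs:
                    p = (x + dx, y + dy, z + dz)
                    if (0 <= p[0] < sx and 0 <= p[1] < sy and 0 <= p[2] < sz
                            and supra[p] and not visited[p]):
                        visited[p] = True
                        comp.append(p)
                        frontier.append(p)
            contrib = len(comp) ** E * h ** H * dh
            for p in comp:
                out[p] += contrib
    return out


class TestTFCETransform:
    def test_single_voxel_closed_form(self):
        """An isolated peak of height v integrates to v^3/3 at E=0.5, H=2."""
        m = np.zeros((5, 5, 5)); m[2, 2, 2] = 3.0
        out = tfce_transform(m)
        assert abs(out[2, 2, 2] - 9.0) / 9.0 < 0.01

    def test_uniform_cluster_closed_form(self):
        """n voxels at height v give sqrt(n) * v^3/3."""
        m = np.zeros((6, 6, 6)); m[2:4, 2:4, 2:4] = 2.0   # n=8, v=2
        out = tfce_transform(m)
        expected = 8 ** 0.5 * 8 / 3
        np.testing.assert_allclose(out[2:4, 2:4, 2:4], out[2, 2, 2])
        assert abs(out[2, 2, 2] - expected) / expected < 0.01

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        stat = rng.normal(size=(8, 8, 8))
        ours = tfce_transform(stat)
        oracle = flood_fill_tfce(stat)
        scale = oracle.max()
        np.testing.assert_allclose(ours, oracle, atol=1e-6 * scale)

    def test_engines_agree(self):
        rng = np.random.default_rng(42)
        stat = rng.normal(size=(7, 7, 7))
        a = tfce_transform(stat, engine="fast")
        b = tfce_transform(stat, engine="ndimage")
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)

    def test_monotone_in_stat_map(self):
        rng = np.random.default_rng(1)
        stat = rng.normal(size=(6, 6, 6))
        bigger = stat + np.abs(rng.normal(size=stat.shape)) * 0.5
        a = tfce_transform(stat)
        b = tfce_transform(bigger)
        assert np.all(b >= a - 1e-12)

    def test_identity_limit_e0_h0(self):
        rng = np.random.default_rng(2)
        stat = rng.normal(size=(5, 5, 5))
        out = tfce_transform(stat, params=TFCEParams(E=0.0, H=0.0, n_steps=4000))
        np.testing.assert_allclose(out, np.clip(stat, 0, None), atol=2e-3)

    def test_connectivity_changes_clustering(self):
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = m[1, 1, 1] = 2.0   # corner-adjacent only
        full = tfce_transform(m, params=TFCEParams(connectivity=26))
        faces = tfce_transform(m, params=TFCEParams(connectivity=6))
        assert full[0, 0, 0] > faces[0, 0, 0]   # 26-conn merges the pair

    def test_nonfinite_rejected(self):
        m = np.zeros((3, 3, 3)); m[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            tfce_transform(m)


class TestTStat:
    def test_closed_form(self):
        t = one_sample_tstat(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(t, [2 * np.sqrt(3)], rtol=1e-12)

    def test_symmetry_and_zero_sd(self):
        stack = np.array([[-1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        t = one_sample_tstat(stack, mu0=0.0)
        assert t[0] == 0.0
        assert np.isnan(t[1])   # zero-sd voxel flagged undefined

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            one_sample_tstat(np.ones((1, 3)))


class TestSignFlip:
    def small_mask(self, V=50):
        m = np.zeros((5, 5, 2), dtype=bool)
        m.ravel()[:V] = True
        return m

    def test_all_zero_stack_gives_p_one(self):
        m = self.small_mask()
        res = sign_flip_test(np.zeros((5, 50)), m, n_perm=64, seed=0)
        assert np.all(res.p_fwe_map[m] == 1.0)

    def test_exhaustive_enumeration_n3(self):
        rng = np.random.default_rng(0)
        m = self.small_mask(20)
        res = sign_flip_test(rng.normal(size=(3, 20)), m, n_perm=500, seed=0)
        assert res.exhaustive and res.n_permutations == 8
        p = res.p_fwe_map[m]
        # tail p-values are multiples of 1/8 before the two-sided doubling
        np.testing.assert_allclose((p / 2) * 8, np.round(p / 2 * 8), atol=1e-12)

    def test_p_floor_and_range(self):
        rng = np.random.default_rng(3)
        m = self.small_mask(30)
        stack = rng.normal(size=(10, 30)) + 2.0   # strong positive effect
        res = sign_flip_test(stack, m, n_perm=199, seed=1)
        p = res.p_fwe_map[m]
        assert np.all(p >= 1.0 / res.n_permutations)
        assert np.all(p <= 1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        stack = rng.normal(size=(12, 50))
        m = self.small_mask()
        a = sign_flip_test(stack, m, n_perm=100, seed=9)
        b = sign_flip_test(stack, m, n_perm=100, seed=9)
        np.testing.assert_array_equal(a.p_fwe_map, b.p_fwe_map)

    def test_detects_planted_signal(self):
        rng = np.random.default_rng(5)
        m = self.small_mask()
        stack = rng.normal(size=(16, 50)) * 0.3
        stack[:, :8] += 1.0   # strong consistent effect in 8 voxels
        res = sign_flip_test(stack, m, n_perm=300, seed=2)
        sig = res.significant()
        assert sig[m][:8].all()
        assert not sig[m][20:].any()
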