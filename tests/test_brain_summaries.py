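"""Summary derivatives against independent oracles and invariants."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from scipy.stats import rankdata

from popgraph.brain_summaries import (
    SummaryConfig,
    alff,
    compute_all,
    degree_centrality,
    dual_regression,
    eigenvector_centrality,
    falff,
    lfcd,
    reho,
    vmhc,
)
from popgraph.errors import ConfigurationError, ValidationError
from popgraph.fixtures import FixtureConfig, make_rsfmri, make_templates
from popgraph.volume_io import Volume4D

CFG = SummaryConfig()


def _full_mask_vol(data, tr=2.0):
    vol = Volume4D(data, tr_seconds=tr)
    vol.mask = np.ones(vol.spatial_shape, dtype=bool)
    return vol


def kendall_w_oracle(series: np.ndarray) -> float:
    """Direct tie-corrected Kendall's W from mid-ranks (K series x n)."""
    k, n = series.shape
    ranks = rankdata(series, axis=1)
    s = ((ranks.sum(axis=0) - k * (n + 1) / 2) ** 2).sum()
    tie = 0.0
    for row in series:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts**3 - counts).sum())
    return 12.0 * s / (k**2 * (n**3 - n) - k * tie)


class TestReho:
    def test_identical_neighbourhood_series_give_w_of_one(self):
        cfg = FixtureConfig(
            grid_shape=(8, 8, 8), n_timepoints=30, noise_sd=0.0,
            n_regions_per_hemisphere=1, seed=3,
        )
        vol, truth = make_rsfmri(cfg, "locally_homogeneous", return_truth=True)
        w = reho(vol, CFG)
        block = truth["block_map"].data == 1
        interior = binary_erosion(block, np.ones((3, 3, 3)))
        assert np.allclose(w[interior], 1.0)

    def test_matches_tie_corrected_oracle_with_constant_series(self, rng):
        data = rng.standard_normal((5, 5, 5, 20))
        data[2, 2, 2, :] = 1.0  # constant neighbour forces tie handling
        vol = _full_mask_vol(data)
        w = reho(vol, CFG)
        for voxel in [(2, 2, 1), (1, 2, 2), (3, 3, 3)]:
            series = np.array([
                data[voxel[0] + dx, voxel[1] + dy, voxel[2] + dz]
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if 0 <= voxel[0] + dx < 5
                and 0 <= voxel[1] + dy < 5
                and 0 <= voxel[2] + dz < 5
            ])
            assert w[voxel] == pytest.approx(kendall_w_oracle(series), abs=1e-12)

    def test_independent_series_give_low_concordance(self, rng):
        vol = _full_mask_vol(rng.standard_normal((5, 5, 5, 400)))
        w = reho(vol, CFG)
        assert w[2, 2, 2] < 0.15  # ~1/K for K=27 independent series

    def test_values_in_unit_interval(self, rng):
        w = reho(_full_mask_vol(rng.standard_normal((4, 4, 4, 12))), CFG)
        assert w.min() >= 0 and w.max() <= 1

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValidationError):
            reho(_full_mask_vol(rng.standard_normal((4, 4, 4, 2))), CFG)


class TestSpectral:
    @pytest.fixture(scope="class")
    def tone(self):
        cfg = FixtureConfig(
            grid_shape=(6, 6, 6), n_timepoints=200, tr_seconds=2.0,
            planted_freq_hz=0.05, noise_sd=0.0, n_regions_per_hemisphere=1,
            seed=4,
        )
        return make_rsfmri(cfg, "pure_tone", return_truth=True)

    def test_alff_matches_direct_dft_oracle(self, tone):
        vol, _ = tone
        got = alff(vol, CFG)
        t = np.arange(200)
        for voxel in [(0, 0, 0), (3, 4, 5)]:
            x = vol.data[voxel]
            x = x - np.polyval(np.polyfit(t, x, 1), t)
            amps = np.abs(np.fft.rfft(x)) * 2 / 200
            freqs = np.fft.rfftfreq(200, 2.0)
            sel = (freqs >= 0.01) & (freqs <= 0.08)
            sel[0] = False
            assert got[voxel] == pytest.approx(amps[sel].mean(), rel=1e-10)

    def test_alff_zero_signal_gives_zero(self):
        vol = Volume4D(np.zeros((4, 4, 4, 20)))
        assert np.all(alff(vol, CFG) == 0)

    def test_alff_scales_linearly_with_amplitude(self, tone):
        vol, _ = tone
        scaled = Volume4D(3.0 * vol.data, tr_seconds=vol.tr_seconds)
        assert np.allclose(alff(scaled, CFG), 3.0 * alff(vol, CFG))

    def test_falff_near_one_for_in_band_tone(self, tone):
        vol, _ = tone
        cfg = SummaryConfig(detrend=False)
        f = falff(vol, cfg)
        assert f[vol.get_mask()].min() >= 0.99

    def test_falff_near_zero_for_out_of_band_tone(self):
        cfg = FixtureConfig(
            grid_shape=(5, 5, 5), n_timepoints=200, tr_seconds=2.0,
            planted_freq_hz=0.2, noise_sd=0.0, n_regions_per_hemisphere=1,
        )
        vol = make_rsfmri(cfg, "pure_tone")
        f = falff(vol, SummaryConfig(detrend=False))
        assert f[vol.get_mask()].max() <= 0.01

    def test_constant_signal_hits_zero_denominator_rule(self):
        vol = _full_mask_vol(np.ones((4, 4, 4, 20)))
        assert np.all(falff(vol, CFG) == 0)

    def test_unresolvable_band_raises(self, rng):
        vol = _full_mask_vol(rng.standard_normal((3, 3, 3, 10)), tr=0.1)
        with pytest.raises(ConfigurationError, match="resolvable"):
            alff(vol, CFG)  # bins at multiples of 1 Hz, band is 0.01-0.08


class TestCentrality:
    def test_homogeneous_block_degree_is_block_size_minus_one(self):
        cfg = FixtureConfig(
            grid_shape=(6, 6, 6), n_timepoints=100, noise_sd=0.0,
            n_regions_per_hemisphere=1, seed=5,
        )
        vol, truth = make_rsfmri(cfg, "locally_homogeneous", return_truth=True)
        block = truth["block_map"].data == 1
        dc = degree_centrality(vol, CFG)
        assert np.all(dc[block] == block.sum() - 1)

    def test_counts_and_sums_match_all_pairs_oracle(self, rng):
        data = rng.standard_normal((4, 1, 1, 30))
        vol = _full_mask_vol(data)
        series = data.reshape(4, 30)
        r = np.corrcoef(series)
        for weighted in (False, True):
            got = degree_centrality(vol, CFG, weighted=weighted).ravel()
            for i in range(4):
                vals = [r[i, j] for j in range(4) if j != i and r[i, j] >= 0.25]
                expect = sum(vals) if weighted else len(vals)
                assert got[i] == pytest.approx(expect, abs=1e-12)

    def test_impossible_threshold_gives_zero_map(self, rng):
        vol = _full_mask_vol(rng.standard_normal((3, 3, 3, 20)))
        cfg = SummaryConfig(corr_threshold=0.999)
        assert degree_centrality(vol, cfg).sum() == 0

    def test_eigenvector_uniform_for_identical_series(self):
        base = np.sin(np.arange(30))
        data = np.tile(base, (3, 3, 3, 1))
        vol = _full_mask_vol(data)
        ec = eigenvector_centrality(vol, CFG)
        assert np.allclose(ec, 1 / np.sqrt(27), atol=1e-8)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_dense_eigendecomposition_oracle(self, rng, weighted):
        data = rng.standard_normal((3, 3, 3, 40))
        vol = _full_mask_vol(data)
        ec = eigenvector_centrality(vol, CFG, weighted=weighted)
        r = np.corrcoef(data.reshape(27, 40))
        above = r >= 0.25
        np.fill_diagonal(above, True)
        m = np.where(above, (1 + r) / 2, 0.0) if weighted else above.astype(float)
        if weighted:
            np.fill_diagonal(m, 1.0)
        _, vecs = np.linalg.eigh(m)
        lead = np.abs(vecs[:, -1])
        assert np.allclose(ec.ravel(), lead, atol=1e-8)
        assert np.linalg.norm(ec) == pytest.approx(1.0)


class TestLfcd:
    def test_isolated_seed_scores_one(self, rng):
        vol = _full_mask_vol(rng.standard_normal((3, 3, 3, 20)))
        cfg = SummaryConfig(corr_threshold=0.9999)
        assert np.all(lfcd(vol, cfg) == 1)

    def test_homogeneous_block_reports_block_size(self):
        cfg = FixtureConfig(
            grid_shape=(6, 6, 6), n_timepoints=100, noise_sd=0.0,
            n_regions_per_hemisphere=1, seed=5,
        )
        vol, truth = make_rsfmri(cfg, "locally_homogeneous", return_truth=True)
        block = truth["block_map"].data == 1
        got = lfcd(vol, CFG)
        assert np.all(got[block] == block.sum())

    def test_matches_flood_fill_oracle(self, rng):
        from collections import deque

        data = rng.standard_normal((4, 4, 2, 30))
        vol = _full_mask_vol(data)
        got = lfcd(vol, CFG)
        z = (data - data.mean(-1, keepdims=True)) / data.std(-1, keepdims=True)
        shape = data.shape[:3]
        for seed_vox in [(0, 0, 0), (2, 1, 1), (3, 3, 1)]:
            visited = {seed_vox}
            q = deque([seed_vox])
            size = 1
            while q:
                cur = q.popleft()
                for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                            (0, 0, 1), (0, 0, -1)]:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if not all(0 <= nb[i] < shape[i] for i in range(3)):
                        continue
                    if nb in visited:
                        continue
                    visited.add(nb)
                    if (z[seed_vox] @ z[nb]) / 30 >= 0.25:
                        q.append(nb)
                        size += 1
            assert got[seed_vox] == size


class TestVmhc:
    def test_mirror_symmetric_data_correlates_perfectly(self):
        cfg = FixtureConfig(
            grid_shape=(8, 8, 8), n_timepoints=30, noise_sd=0.0,
            n_regions_per_hemisphere=2,
        )
        vol = make_rsfmri(cfg, "mirror_symmetric")
        h = vmhc(vol, CFG)
        assert np.allclose(h[vol.get_mask()], 1.0)

    def test_negated_mirror_gives_minus_one(self, rng):
        data = rng.standard_normal((6, 4, 4, 20))
        data[3:] = -data[:3][::-1]
        vol = _full_mask_vol(data)
        assert np.allclose(vmhc(vol, CFG)[vol.get_mask()], -1.0)

    def test_matches_flip_and_correlate_oracle(self, rng):
        data = rng.standard_normal((6, 4, 4, 25))
        vol = _full_mask_vol(data)
        got = vmhc(vol, CFG)
        for voxel in [(0, 0, 0), (2, 3, 1), (5, 2, 2)]:
            mirror = (5 - voxel[0],) + voxel[1:]
            expect = np.corrcoef(data[voxel], data[mirror])[0, 1]
            assert got[voxel] == pytest.approx(expect, abs=1e-12)


class TestDualRegression:
    def test_exact_recovery_with_orthogonal_templates(self):
        cfg = FixtureConfig(
            grid_shape=(8, 8, 8), n_timepoints=50, noise_sd=0.0,
            n_templates=3, n_regions_per_hemisphere=1, seed=9,
        )
        vol, truth = make_rsfmri(cfg, "template_mixture", return_truth=True)
        vol.mask = np.ones(vol.spatial_shape, dtype=bool)
        out = dual_regression(vol, truth["templates"])
        for j, planted in enumerate(truth["templates"]):
            assert np.allclose(out.data[..., j], planted, atol=1e-10)

    def test_matches_per_voxel_least_squares_oracle(self, rng):
        cfg = FixtureConfig(
            grid_shape=(6, 6, 6), n_timepoints=40, noise_sd=0.5,
            n_templates=3, n_regions_per_hemisphere=1, seed=2,
        )
        vol, truth = make_rsfmri(cfg, "template_mixture", return_truth=True)
        vol.mask = np.ones(vol.spatial_shape, dtype=bool)
        out = dual_regression(vol, truth["templates"])
        # stage-1 time courses by normal equations
        p = np.stack([m.ravel() for m in truth["templates"]], axis=1)
        x = vol.data.reshape(-1, 40)
        tcs = np.linalg.solve(p.T @ p, p.T @ x).T
        for voxel in [(0, 0, 0), (3, 2, 4)]:
            beta = np.linalg.solve(
                tcs.T @ tcs, tcs.T @ vol.data[voxel]
            )
            assert np.allclose(out.data[voxel], beta, atol=1e-8)

    def test_ten_templates_give_ten_channels(self):
        cfg = FixtureConfig(
            grid_shape=(10, 10, 10), n_timepoints=30, n_templates=10,
            n_regions_per_hemisphere=1, seed=1,
        )
        vol, truth = make_rsfmri(cfg, "template_mixture", return_truth=True)
        out = dual_regression(vol, truth["templates"])
        assert out.n_channels == 10


class TestComputeAll:
    @pytest.fixture(scope="class")
    def stack_and_templates(self):
        cfg = FixtureConfig(
            grid_shape=(8, 8, 8), n_timepoints=40, noise_sd=0.5,
            n_templates=10, n_regions_per_hemisphere=1, seed=6,
        )
        vol = make_rsfmri(cfg, "template_mixture")
        templates = make_templates(cfg)
        return compute_all(vol, templates), vol, templates

    def test_nineteen_channels_with_documented_names(self, stack_and_templates):
        stack, _, _ = stack_and_templates
        assert stack.n_channels == 19
        assert stack.channel_names[:9] == [
            "reho", "alff", "falff", "dc_bin", "dc_weighted",
            "ec_bin", "ec_weighted", "lfcd", "vmhc",
        ]
        assert stack.channel_names[9:] == [f"dr_{j:02d}" for j in range(1, 11)]

    def test_zero_templates_give_nine_channels(self, stack_and_templates):
        _, vol, _ = stack_and_templates
        assert compute_all(vol, []).n_channels == 9

    def test_channel_order_stable_across_runs(self, stack_and_templates):
        stack, vol, templates = stack_and_templates
        again = compute_all(vol, templates)
        assert np.array_equal(stack.data, again.data)
        assert stack.channel_names == again.channel_names


class TestInvariances:
    def test_spatial_permutation_equivariance(self, rng):
        """Permuting voxels along an axis permutes every map identically."""
        data = rng.standard_normal((4, 4, 4, 30))
        vol = _full_mask_vol(data)
        perm = rng.permutation(4)
        pvol = _full_mask_vol(data[:, perm])  # permute an axis not used by
        # neighbourhood-based maps' structure only for the global measures
        for fn in (alff, falff):
            assert np.allclose(fn(pvol, CFG), fn(vol, CFG)[:, perm])
        dc, pdc = (degree_centrality(v, CFG) for v in (vol, pvol))
        assert np.allclose(pdc, dc[:, perm])

    def test_correlation_maps_invariant_to_affine_rescale(self, rng):
        data = rng.standard_normal((4, 4, 4, 30))
        vol = _full_mask_vol(data)
        scaled = _full_mask_vol(2.5 * data + 7.0)
        for fn in (degree_centrality, vmhc, reho):
            assert np.allclose(fn(vol, CFG), fn(scaled, CFG), atol=1e-10)
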