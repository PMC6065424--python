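"""Tests for vessel-center extraction, diffusion maps and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sff.downstream import (
    compare_groups,
    diffusion_map,
    extract_vessel_centers,
    temperature_experiment,
)
from sff.errors import DegenerateInputError, ParameterError


def bfs_components(mask):
    """Brute-force 8-connected component labeling with centroids."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pix = []
            while stack:
                r, c = stack.pop()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            pix = np.array(pix, float)
            comps.append((pix.mean(axis=0), len(pix)))
    return comps


def disc_map(shape, center, radius, value=1.0):
    gr, gc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return np.where(np.hypot(gr - center[0], gc - center[1]) <= radius, value, 0.0)


class TestExtractVesselCenters:
    def test_single_disc_centroid(self):
        vmap = disc_map((40, 40), (17.0, 23.0), 5.0)
        mask = np.ones((40, 40), bool)
        found = extract_vessel_centers(vmap, mask, threshold=0.5)
        assert len(found) == 1
        assert np.hypot(found.centers[0][0] - 17.0, found.centers[0][1] - 23.0) <= 0.5

    def test_all_subthreshold_is_empty(self):
        found = extract_vessel_centers(
            np.full((20, 20), 0.1), np.ones((20, 20), bool), threshold=0.5
        )
        assert len(found) == 0

    def test_two_discs_merge_when_close(self):
        far = disc_map((50, 50), (15.0, 15.0), 4.0) + disc_map((50, 50), (35.0, 35.0), 4.0)
        near = disc_map((50, 50), (24.0, 22.0), 4.0) + disc_map((50, 50), (24.0, 30.0), 4.0)
        mask = np.ones((50, 50), bool)
        assert len(extract_vessel_centers(far, mask, threshold=0.5)) == 2
        # separation below the structuring-element scale: closing fuses them
        assert len(extract_vessel_centers(near, mask, threshold=0.5)) == 1

    def test_centroids_match_bfs_oracle(self, rng):
        """With no-op morphology the centroids equal a brute-force labeling."""
        for _ in range(50):
            binary = rng.random((24, 24)) < 0.12
            found = extract_vessel_centers(
                binary.astype(float),
                np.ones((24, 24), bool),
                threshold=0.5,
                min_patch_px=1,
                morph_size=1,
            )
            oracle = bfs_components(binary)
            assert len(found) == len(oracle)
            got = sorted(found.centers)
            exp = sorted((tuple(c), n) for c, n in oracle)
            for (gr, gc), (ec, _) in zip(got, exp):
                assert gr == pytest.approx(ec[0], abs=1e-9)
                assert gc == pytest.approx(ec[1], abs=1e-9)

    def test_min_patch_filter_and_default_threshold(self, rng):
        vmap = disc_map((40, 40), (20.0, 20.0), 6.0, value=2.0)
        vmap[5, 5] = 3.0  # isolated bright pixel, below min_patch_px
        found = extract_vessel_centers(vmap, np.ones((40, 40), bool), threshold=1.0)
        assert len(found) == 1 and found.patch_sizes[0] > 5


class TestDiffusionMap:
    def test_peak_at_center_is_one(self):
        mask = np.ones((31, 31), bool)
        est = diffusion_map([(15.0, 15.0)], None, d_t=10.0, mask=mask)
        assert est.values[15, 15] == pytest.approx(1.0)
        assert est.values.max() == pytest.approx(1.0)
        assert est.values.min() >= 0.0

    def test_half_width_matches_analytic_form(self):
        """Before masking/normalization the profile halves where
        d^2 = 4 D_t ln 2."""
        d_t = 9.0
        mask = np.ones((61, 61), bool)
        est = diffusion_map([(30.0, 30.0)], [1.0], d_t=d_t, mask=mask)
        d_half = np.sqrt(4 * d_t * np.log(2))
        gr, gc = np.mgrid[0:61, 0:61].astype(float)
        dist = np.hypot(gr - 30, gc - 30)
        # min-max normalization leaves ratios to the peak nearly intact
        ring = np.abs(dist - d_half) < 0.05
        assert np.allclose(est.values[ring] / est.values[30, 30], 0.5, atol=0.02)

    def test_symmetry_under_center_swap(self):
        mask = np.ones((41, 41), bool)
        a = diffusion_map([(10.0, 12.0), (30.0, 28.0)], [1.0, 1.0], 16.0, mask)
        b = diffusion_map([(30.0, 28.0), (10.0, 12.0)], [1.0, 1.0], 16.0, mask)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rotation_equivariance(self):
        """Rotating the sources by 90 deg about the grid center rotates the map."""
        mask = np.ones((41, 41), bool)
        centers = [(12.0, 16.0), (28.0, 22.0)]
        rot_centers = [(c, 40 - r) for r, c in centers]
        a = diffusion_map(centers, [1.0, 0.7], 12.0, mask)
        b = diffusion_map(rot_centers, [1.0, 0.7], 12.0, mask)
        np.testing.assert_allclose(np.rot90(a.values, k=-1), b.values, atol=1e-10)

    def test_masking_zeroes_outside(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        est = diffusion_map([(10.0, 10.0)], None, 4.0, mask)
        assert np.all(est.values[~mask] == 0.0)

    def test_errors(self):
        mask = np.ones((10, 10), bool)
        with pytest.raises(DegenerateInputError):
            diffusion_map([], None, 4.0, mask)
        with pytest.raises(ParameterError):
            diffusion_map([(5.0, 5.0)], None, 0.0, mask)


def pooled_t_oracle(a, b):
    """Hand-coded pooled-variance two-sample t statistic and p-value."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_separated_groups_reach_tiny_p(self, rng):
        a = 0.0 + 1e-6 * rng.standard_normal(3)
        b = 1.0 + 1e-6 * rng.standard_normal(3)
        assert compare_groups(a, b).p_value < 1e-6

    def test_matches_textbook_formula(self, rng):
        for _ in range(20):
            a = rng.standard_normal(int(rng.integers(2, 9)))
            b = 0.3 + rng.standard_normal(int(rng.integers(2, 9)))
            res = compare_groups(a, b)
            t, p = pooled_t_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_group_size_precondition(self):
        with pytest.raises(DegenerateInputError):
            compare_groups([1.0], [1.0, 2.0])


def _animal_df(n_frames, endpoint_sff, endpoint_conv, rng):
    t = np.arange(n_frames)
    return pd.DataFrame(
        {
            "frame_index": t,
            "time_s": t / 20.0,
            "sff_percent": endpoint_sff * t / (n_frames - 1)
            + 0.1 * rng.standard_normal(n_frames),
            "conventional_percent": endpoint_conv * t / (n_frames - 1)
            + 0.1 * rng.standard_normal(n_frames),
        }
    )


class TestTemperatureExperiment:
    def test_ordered_rates_give_ordered_endpoints(self, rng):
        runs = {
            "37C": [_animal_df(10, 10 + rng.normal(), 5, rng) for _ in range(5)],
            "39C": [_animal_df(10, 20 + rng.normal(), 10, rng) for _ in range(5)],
            "42C": [_animal_df(10, 40 + rng.normal(), 20, rng) for _ in range(6)],
        }
        summary = temperature_experiment(runs)
        ends = summary.endpoints.query("method == 'sff'").set_index("group")["mean"]
        assert ends["42C"] > ends["39C"] > ends["37C"]
        assert sorted(summary.endpoints["n"].unique()) == [5, 6]
        assert len(summary.tests) == 6  # 3 pairs x 2 methods
        assert set(summary.tests["pair"]) == {
            "37C vs 39C",
            "37C vs 42C",
            "39C vs 42C",
        }

    def test_identical_groups_behave_as_null(self, rng):
        runs = {
            "a": [_animal_df(8, 10, 10, rng) for _ in range(5)],
            "b": [_animal_df(8, 10, 10, rng) for _ in range(5)],
        }
        summary = temperature_experiment(runs)
        assert (summary.tests["p"] > 0.01).all()
        means = summary.endpoints.set_index(["group", "method"])["mean"]
        assert means["a", "sff"] == pytest.approx(means["b", "sff"], abs=0.5)

    def test_small_group_excluded_with_warning(self, rng):
        runs = {
            "a": [_animal_df(8, 10, 10, rng) for _ in range(4)],
            "b": [_animal_df(8, 20, 20, rng)],
        }
        with pytest.warns(RuntimeWarning):
            summary = temperature_experiment(runs)
        assert set(summary.endpoints["group"]) == {"a"}
        assert summary.tests.empty
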