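import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foragebold.neural import GeometrySpec, VoxelDataset, synthesize_voxel_data
from foragebold.rsa import (PatternSet, estimate_patterns,
                            matched_block_distances, pattern_distance,
                            rsa_brain_behaviour, rsa_scores, summaries_frame)


class TestPatternDistance:
    def test_identical_vectors_have_zero_distance(self):
        v = np.array([1.0, 2.0, 3.0])
        assert pattern_distance(v, v, "cosine") == pytest.approx(0.0)
        assert pattern_distance(v, v, "pearson") == pytest.approx(0.0)

    def test_orthogonal_vectors_have_cosine_distance_one(self):
        assert pattern_distance([1, 0], [0, 1], "cosine") == pytest.approx(1.0)

    def test_worked_cosine_example(self):
        d = pattern_distance([1, 2, 2], [2, 1, 2], "cosine")
        assert d == pytest.approx(1 - 8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pattern_distance([0, 0], [1, 1], "cosine")
        with pytest.raises(ValueError, match="constant"):
            pattern_distance([2, 2], [1, 3], "pearson")

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10 ** 9), scale=st.floats(0.01, 100.0),
           shift=st.floats(-50.0, 50.0))
    def test_metric_invariances(self, seed, scale, shift):
        """Cosine ignores positive rescaling; Pearson also ignores shifts."""
        rng = np.random.default_rng(seed)
        u, v = rng.standard_normal((2, 12))
        assert pattern_distance(scale * u, v, "cosine") == pytest.approx(
            pattern_distance(u, v, "cosine"), abs=1e-9)
        assert pattern_distance(scale * u + shift, v, "pearson") == pytest.approx(
            pattern_distance(u, v, "pearson"), abs=1e-9)


def brute_force_matched(patterns, pair, env, metric="cosine"):
    """Independent all-pairs enumeration of the block-space estimator."""
    a, b = pair

    def levels(e):
        out = {}
        for i, j in itertools.combinations(patterns.blocks(e), 2):
            if j - i < 2:
                continue
            lvl = j - i - 1
            for u, v in ((patterns.get(a, i), patterns.get(b, j)),
                         (patterns.get(a, j), patterns.get(b, i))):
                if u is not None and v is not None:
                    out.setdefault(lvl, []).append(pattern_distance(u, v, metric))
        return out

    mine, other = levels(env), levels("rich" if env == "poor" else "poor")
    shared = sorted(set(mine) & set(other))
    return float(np.mean([np.mean(mine[lvl]) for lvl in shared])), tuple(shared)


def random_pattern_set(seed, n_vox=8):
    rng = np.random.default_rng(seed)
    envs = ["rich"] * 5 + ["poor"] * 5
    rng.shuffle(envs)
    block_env = {b + 1: envs[b] for b in range(10)}
    patterns = {}
    for b in block_env:
        for opt in ("low", "mid", "high"):
            if rng.random() < 0.9:  # occasional missing cells
                patterns[(opt, b)] = rng.standard_normal(n_vox)
    return PatternSet("roi", "s", patterns, block_env)


class TestMatchedBlockDistances:
    def test_identical_patterns_give_zero(self):
        v = np.arange(1.0, 7.0)
        patterns = {(o, b): v for o in ("low", "mid", "high")
                    for b in range(1, 11)}
        block_env = {b: ("rich" if b % 2 else "poor") for b in range(1, 11)}
        ps = PatternSet("roi", "s", patterns, block_env)
        d, _ = matched_block_distances(ps, ("low", "mid"), "poor")
        assert d == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10 ** 9))
    def test_matches_brute_force_oracle_on_random_layouts(self, seed):
        ps = random_pattern_set(seed)
        for pair in (("low", "mid"), ("mid", "high")):
            for env in ("rich", "poor"):
                try:
                    got, lv = matched_block_distances(ps, pair, env)
                except ValueError:
                    with pytest.raises(Exception):
                        d, shared = brute_force_matched(ps, pair, env)
                        if not shared:
                            raise ValueError
                    continue
                want, lv2 = brute_force_matched(ps, pair, env)
                assert lv == lv2
                assert got == pytest.approx(want)

    def test_contiguous_blocks_are_excluded(self):
        # two adjacent same-env blocks only: no non-contiguous pair exists
        patterns = {(o, b): np.arange(3.0) + b for o in ("low", "mid")
                    for b in (1, 2, 5, 6)}
        block_env = {1: "poor", 2: "poor", 5: "rich", 6: "rich"}
        ps = PatternSet("roi", "s", patterns, block_env)
        with pytest.raises(ValueError, match="block-space"):
            matched_block_distances(ps, ("low", "mid"), "poor")


class TestRsaScores:
    def test_noise_free_warp_closed_form(self, one_subject_events):
        """kappa=0.6 with orthonormal bases: d2=1-0.6/sqrt(0.52), d4=1."""
        geom = GeometrySpec(n_voxels=24, kappa=0.6, pattern_noise_sd=0.0)
        vox = synthesize_voxel_data(one_subject_events, geom,
                                    np.random.default_rng(0))
        sc = rsa_scores(estimate_patterns(vox, one_subject_events), "cosine")
        assert sc.d4 == pytest.approx(1.0, abs=1e-6)
        assert sc.d2 == pytest.approx(1 - 0.6 / np.sqrt(0.52), abs=1e-6)
        assert sc.h2 == pytest.approx(0.83205, abs=1e-4)
        assert sc.h1 == pytest.approx(0.0, abs=1e-6)

    def test_no_warp_means_no_contrast(self, one_subject_events):
        geom = GeometrySpec(n_voxels=24, kappa=0.0, pattern_noise_sd=0.0)
        vox = synthesize_voxel_data(one_subject_events, geom,
                                    np.random.default_rng(1))
        sc = rsa_scores(estimate_patterns(vox, one_subject_events), "cosine")
        assert sc.h1 == pytest.approx(0.0, abs=1e-9)
        assert sc.h2 == pytest.approx(0.0, abs=1e-9)

    def test_metric_swap_invariant_to_scale_inflation(self, one_subject_events):
        geom = GeometrySpec(n_voxels=24, kappa=0.4, pattern_noise_sd=0.0)
        vox = synthesize_voxel_data(one_subject_events, geom,
                                    np.random.default_rng(2))
        inflated = VoxelDataset(vox.roi, vox.tr, 5.0 * vox.data)
        a = rsa_scores(estimate_patterns(vox, one_subject_events), "cosine")
        b = rsa_scores(estimate_patterns(inflated, one_subject_events), "cosine")
        assert a.h2 == pytest.approx(b.h2, abs=1e-9)

    def test_univariate_offset_immunity_of_pearson(self):
        """A common scalar added to one environment leaves Pearson-H2 alone."""
        ps = random_pattern_set(123)
        base = rsa_scores(ps, "pearson")
        shifted = {k: (v + 7.5 if ps.block_env[k[1]] == "poor" else v)
                   for k, v in ps.patterns.items()}
        ps2 = PatternSet("roi", "s", shifted, ps.block_env)
        out = rsa_scores(ps2, "pearson")
        assert out.h2 == pytest.approx(base.h2, abs=1e-9)


class TestBrainBehaviour:
    def _summaries(self, h2, subjects):
        return pd.DataFrame({
            "subject": subjects, "roi": "dACC", "metric": "cosine",
            "d1": 1.0, "d2": 1.0 - h2, "d3": 1.0, "d4": 1.0,
            "H1": 0.0, "H2": h2})

    def test_planted_linkage_detected(self):
        rng = np.random.default_rng(0)
        n = 24
        subjects = [f"s{i:02d}" for i in range(n)]
        delta = pd.Series(rng.uniform(-0.1, 0.4, n), index=subjects)
        h2 = 0.8 * delta.to_numpy() + 0.02 * rng.standard_normal(n)
        out = rsa_brain_behaviour(self._summaries(h2, subjects), delta)
        assert out.loc[0, "r_H2"] > 0.8
        assert out.loc[0, "p_H2"] < 1e-4
        assert out.loc[0, "t_group"] > 0

    def test_broken_linkage_is_null(self):
        rng = np.random.default_rng(1)
        n = 24
        subjects = [f"s{i:02d}" for i in range(n)]
        delta = pd.Series(rng.uniform(-0.1, 0.4, n), index=subjects)
        h2 = rng.standard_normal(n)
        out = rsa_brain_behaviour(self._summaries(h2, subjects), delta)
        assert abs(out.loc[0, "r_H2"]) < 0.45

    def test_zero_variance_is_diagnosed(self):
        subjects = [f"s{i}" for i in range(8)]
        delta = pd.Series(np.linspace(-0.1, 0.3, 8), index=subjects)
        with pytest.raises(ValueError, match="zero variance"):
            rsa_brain_behaviour(self._summaries(np.zeros(8), subjects), delta)

    def test_too_few_subjects_rejected(self):
        subjects = [f"s{i}" for i in range(3)]
        delta = pd.Series([0.1, 0.2, 0.3], index=subjects)
        with pytest.raises(ValueError, match=">= 5"):
            rsa_brain_behaviour(self._summaries(np.array([0.1, 0.2, 0.3]),
                                                subjects), delta)
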