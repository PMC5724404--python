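import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ygate.simulate import SimulationConfig, generate
from ygate.threshold import (
    compute_threshold,
    count_significant_genes,
    mann_whitney,
    ranges_overlap,
    select_threshold_probes,
)

Z95_ONE_SIDED = 1.6448536269514722


def permutation_mann_whitney(a, b):
    """Exhaustive label-permutation oracle for the two-sided exact p.

    Enumerates every assignment of the pooled values to groups of the
    observed sizes, builds the permutation distribution of U, and returns
    2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = sum(x > y for x in a for y in b)
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        dist.append(sum(x > y for x in ga for y in gb))
    dist = np.array(dist)
    lo = np.mean(dist <= u_obs)
    hi = np.mean(dist >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], "two_sided")
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of the C(6,3)=20 assignments

    def test_identical_constant_groups_give_p_one(self):
        u, p = mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=4, max_size=10, unique=True
        ),
        split=st.integers(2, 8),
    )
    def test_exact_p_matches_permutation_oracle(self, data, split):
        """For tie-free inputs with n <= 10 the p-value equals exhaustive
        enumeration of all label assignments."""
        split = min(split, len(data) - 2)
        a, b = data[:split], data[split:]
        _, p = mann_whitney(a, b, "two_sided")
        assert p == pytest.approx(permutation_mann_whitney(a, b), abs=1e-12)

    def test_asymptotic_close_to_large_resample_oracle(self, rng):
        a = rng.normal(1.0, 1.0, 9)
        b = rng.normal(0.0, 1.0, 7)
        _, p = mann_whitney(a, b)
        # independent oracle: Monte-Carlo permutation at large resample
        pooled = np.concatenate([a, b])
        u_obs = (a[:, None] > b[None, :]).sum()
        mean_u = len(a) * len(b) / 2
        hits = 0
        n_resample = 20000
        r = np.random.default_rng(1)
        for _ in range(n_resample):
            perm = r.permutation(pooled)
            u = (perm[:9, None] > perm[None, 9:]).sum()
            hits += abs(u - mean_u) >= abs(u_obs - mean_u)
        assert p == pytest.approx(hits / n_resample, abs=0.02)


class TestRangesOverlap:
    @pytest.mark.parametrize(
        "m, f, expected_overlap",
        [
            ([6, 7], [2, 3], False),  # disjoint, male high
            ([6, 7], [2, 6.5], True),
            ([2, 3], [6, 7], True),  # disjoint but female high: still overlap
        ],
    )
    def test_male_high_orientation(self, m, f, expected_overlap):
        assert ranges_overlap(m, f) is expected_overlap

    def test_sign_agnostic_mode_accepts_female_high(self):
        assert ranges_overlap([2, 3], [6, 7], sign_agnostic=True) is False


class TestSelectThresholdProbes:
    def test_planted_male_specific_probe_is_the_only_selection(self):
        config = SimulationConfig(
            seed=11, n_probes=51, n_y_specific=1, n_y_neutral=50,
            n_low=0, n_medium=0, n_high=0, male_effect=6.0, bg_sd=0.2,
        )
        matrix, meta, annot, truth = generate(config)
        res = select_threshold_probes(matrix, meta, annot)
        selected = res.index[res["significant"] & res["nonoverlapping"]]
        assert list(selected) == list(truth.index[truth["is_y_specific"]])

    def test_all_female_cohort_is_error(self):
        config = SimulationConfig(seed=3, n_male=0, n_female=6, n_y_specific=0)
        matrix, meta, annot, _ = generate(config)
        with pytest.raises(ValueError, match="each sex"):
            select_threshold_probes(matrix, meta, annot)

    def test_no_y_probes_is_error(self):
        config = SimulationConfig(
            seed=3, n_probes=10, n_y_specific=0, n_y_neutral=0,
            n_low=0, n_medium=0, n_high=0,
        )
        matrix, meta, annot, _ = generate(config)
        with pytest.raises(ValueError, match="chromosome Y"):
            select_threshold_probes(matrix, meta, annot)

    def test_invariant_to_row_and_column_permutation(self, rng):
        config = SimulationConfig(seed=5, n_probes=60, n_y_specific=2,
                                  n_y_neutral=30, n_low=0, n_medium=0, n_high=0)
        matrix, meta, annot, _ = generate(config)
        res = select_threshold_probes(matrix, meta, annot)
        shuffled = matrix.sample(frac=1, axis=0, random_state=7).sample(
            frac=1, axis=1, random_state=8
        )
        res2 = select_threshold_probes(shuffled, meta, annot)
        pd.testing.assert_frame_equal(res, res2)

    def test_gene_aggregation_rules(self, paper_fixture):
        res = select_threshold_probes(
            paper_fixture.matrix, paper_fixture.meta, paper_fixture.annot
        )
        assert count_significant_genes(res, "any_probe") >= count_significant_genes(
            res, "all_probes"
        )


class TestComputeThreshold:
    def _selected_frame(self, probes, genes):
        return pd.DataFrame(
            {
                "gene_symbol": genes,
                "significant": True,
                "nonoverlapping": True,
            },
            index=pd.Index(probes, name="probe_id"),
        )

    def test_constant_female_values_give_threshold_equal_to_constant(self):
        matrix = pd.DataFrame(
            [[8.0, 8.0, 3.0, 3.0]],
            index=pd.Index(["p1"], name="probe_id"),
            columns=["m1", "m2", "f1", "f2"],
        )
        meta = pd.Series(
            ["male", "male", "female", "female"],
            index=["m1", "m2", "f1", "f2"],
        )
        model = compute_threshold(self._selected_frame(["p1"], ["G"]), matrix, meta)
        assert model.threshold == pytest.approx(3.0)
        assert model.female_sd == 0.0

    def test_large_sample_converges_to_normal_upper_limit(self, rng):
        mu, sigma, n = 3.0, 0.5, 1000
        values = rng.normal(mu, sigma, n)
        matrix = pd.DataFrame(
            np.concatenate([[mu + 8, mu + 8], values])[None, :],
            index=pd.Index(["p1"], name="probe_id"),
            columns=["m1", "m2"] + [f"f{i}" for i in range(n)],
        )
        meta = pd.Series(
            ["male", "male"] + ["female"] * n, index=matrix.columns
        )
        model = compute_threshold(self._selected_frame(["p1"], ["G"]), matrix, meta)
        se = sigma * np.sqrt(1 / n + Z95_ONE_SIDED**2 / (2 * n))
        assert model.threshold == pytest.approx(mu + Z95_ONE_SIDED * sigma, abs=4 * se)

    def test_threshold_monotone_in_confidence(self, paper_fixture):
        res = select_threshold_probes(
            paper_fixture.matrix, paper_fixture.meta, paper_fixture.annot
        )
        thresholds = [
            compute_threshold(
                res, paper_fixture.matrix, paper_fixture.meta, confidence=c
            ).threshold
            for c in (0.80, 0.90, 0.95, 0.99)
        ]
        assert thresholds == sorted(thresholds)

    def test_two_sided_mode_uses_wider_quantile(self, paper_fixture):
        res = select_threshold_probes(
            paper_fixture.matrix, paper_fixture.meta, paper_fixture.annot
        )
        one = compute_threshold(res, paper_fixture.matrix, paper_fixture.meta)
        two = compute_threshold(
            res, paper_fixture.matrix, paper_fixture.meta, sided="two"
        )
        assert two.z == pytest.approx(1.959963984540054)
        assert two.threshold > one.threshold

    def test_no_selected_probes_is_error(self, paper_fixture):
        res = select_threshold_probes(
            paper_fixture.matrix, paper_fixture.meta, paper_fixture.annot
        )
        res = res.assign(significant=False)
        with pytest.raises(ValueError, match="no selected probes"):
            compute_threshold(res, paper_fixture.matrix, paper_fixture.meta)
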