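import itertools
import math

import numpy as np
import pytest

from capnoshape import (
    bonferroni_adjust,
    cohens_d,
    correlate_with_clinical,
    effect_category,
    feature_screen,
    mann_whitney_u,
    pearson_r,
)


def enumeration_oracle(x, y):
    """Independent exact two-sided Mann-Whitney p by direct pair counting
    over every labeling of the pooled sample (midrank-equivalent)."""
    pooled = list(x) + list(y)
    nx = len(x)
    n = len(pooled)
    mu = nx * (n - nx) / 2.0

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return u

    u_obs = u_of(tuple(range(nx)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_groups_fixture(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3], mode="exact")
        assert p == 1.0

    def test_degenerate_constant_data(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5], mode="auto")
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 5))
        ny = int(rng.integers(2, 5))
        # integer draws force ties, exercising the midrank path
        x = rng.integers(0, 4, nx).astype(float)
        y = rng.integers(0, 4, ny).astype(float)
        _, p = mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(enumeration_oracle(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_n6(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.3, 1.0, size=6)
            _, p_exact = mann_whitney_u(x, y, mode="exact")
            _, p_norm = mann_whitney_u(x, y, mode="normal_approx")
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBonferroni:
    def test_cap_and_arithmetic(self):
        assert bonferroni_adjust([0.01], m=159) == [1.0]
        assert bonferroni_adjust([0.0], m=1000) == [0.0]
        assert bonferroni_adjust([0.0001], m=100) == [pytest.approx(0.01)]

    def test_monotone_and_bounded(self):
        ps = [0.001, 0.2, 0.9]
        out = bonferroni_adjust(ps, m=5)
        assert all(o >= p for o, p in zip(out, ps))
        assert all(o <= 1.0 for o in out)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_evaluated_fixture(self):
        d = cohens_d([0, 0, 1, 1], [1, 1, 2, 2])
        assert d == pytest.approx(-math.sqrt(3.0), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1.0, 2.0, size=5)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x), abs=1e-12)

    def test_zero_pooled_sd(self):
        assert cohens_d([2.0, 2.0], [2.0, 2.0]) == 0.0
        assert math.isinf(cohens_d([3.0, 3.0], [2.0, 2.0]))

    def test_categories_match_bins(self):
        assert effect_category(1.16) == "large"
        assert effect_category(-1.14) == "large"
        assert effect_category(0.55) == "medium"
        assert effect_category(0.49) == "small"
        assert effect_category(0.8) == "large"
        assert effect_category(0.5) == "medium"


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(4.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_evaluated_fixture(self):
        res = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson_r(x, y).r
        r1 = pearson_r(3.0 * x + 7.0, 0.5 * y - 2.0).r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


class TestFeatureScreen:
    def test_self_comparison_is_null(self, registry):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {n: rng.normal(size=10) for n in registry.vector_names})
        comps, summary = feature_screen(df, df.copy(), registry)
        assert all(c.d == 0.0 for c in comps)
        assert all(c.category == "small" for c in comps)
        assert all(c.p_adj == 1.0 for c in comps)
        # conservation: region counts sum to the registry's feature counts
        total = int(summary.table["n_features"].sum())
        assert total == len(comps) == 159

    def test_region_counts_conserved(self, registry):
        import pandas as pd

        rng = np.random.default_rng(1)
        a = pd.DataFrame({n: rng.normal(size=8)
                          for n in registry.vector_names})
        b = pd.DataFrame({n: rng.normal(0.5, 1, size=8)
                          for n in registry.vector_names})
        comps, summary = feature_screen(a, b, registry)
        per_region = {}
        for name in registry.vector_names:
            per_region[registry.region_of(name)] = \
                per_region.get(registry.region_of(name), 0) + 1
        for _, row in summary.table.iterrows():
            assert row["n_features"] == per_region[row["region"]]
            assert row[["n_small", "n_medium", "n_large"]].sum() == \
                row["n_features"]


class TestClinicalCorrelation:
    def test_exact_linear_covariate(self):
        import pandas as pd

        feats = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(6)],
            "median_alpha_deg": np.linspace(100, 120, 6),
        })
        cov = pd.DataFrame({
            "subject_id": feats.subject_id,
            "fev1_fvc_pct": 150 - feats.median_alpha_deg,
        })
        res = correlate_with_clinical(
            feats, cov, [("median_alpha_deg", "fev1_fvc_pct")])[0]
        assert res.r == pytest.approx(-1.0)
        assert res.n == 6

    def test_too_few_pairs_is_an_error(self):
        import pandas as pd

        feats = pd.DataFrame({"subject_id": ["a", "b"],
                              "f": [1.0, 2.0]})
        cov = pd.DataFrame({"subject_id": ["a", "b"], "c": [1.0, np.nan]})
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_with_clinical(feats, cov, [("f", "c")])

    def test_missing_column_is_an_error(self):
        import pandas as pd

        df = pd.DataFrame({"subject_id": ["a"], "f": [1.0]})
        with pytest.raises(KeyError):
            correlate_with_clinical(df, df, [("nope", "f")])
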