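"""Tertile assignment, missing-indicator handling and design construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sepsisthresh.data import (FormulaSpec, add_missing_dummies, assign_tertiles,
                               build_design, drop_missing_exposure, hinge)


def brute_force_tertiles(values):
    """Independent oracle: apply the stated rank-cut rule literally.

    Sort, cut after ranks n//3 and 2n//3, and send every observation tied
    with a cut value to the lower group.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    s = np.sort(v)
    c1, c2 = s[n // 3 - 1], s[2 * n // 3 - 1]
    labels = np.where(v <= c1, 1, np.where(v <= c2, 2, 3))
    return labels, tuple(int((labels == k).sum()) for k in (1, 2, 3))


class TestAssignTertiles:
    def test_exact_thirds(self):
        t = assign_tertiles(np.arange(1.0, 10.0))
        assert t.counts == (3, 3, 3)
        assert list(t.labels) == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        assert t.boundaries == (3.0, 6.0)

    def test_n724_distinct_values_matches_published_split(self, rng):
        values = rng.normal(size=724)
        assert assign_tertiles(values).counts == (241, 241, 242)

    def test_ties_match_brute_force_rule(self):
        values = [1, 1, 1, 2, 2, 2, 3, 3, 3, 3]
        t = assign_tertiles(values)
        labels, counts = brute_force_tertiles(values)
        assert t.counts == counts == (3, 3, 4)
        assert list(t.labels) == list(labels)

    @given(hst.lists(hst.integers(min_value=0, max_value=5), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_oracle_on_tied_vectors(self, values):
        if len(set(values)) < 2:
            return
        t = assign_tertiles(values)
        labels, counts = brute_force_tertiles(values)
        assert t.counts == counts
        assert list(t.labels) == list(labels)

    def test_permutation_equivariance(self, rng):
        values = rng.normal(size=101)
        perm = rng.permutation(101)
        base = assign_tertiles(values).labels.to_numpy()
        shuffled = assign_tertiles(values[perm]).labels.to_numpy()
        assert (shuffled == base[perm]).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            assign_tertiles([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            assign_tertiles([2.0] * 10)


class TestMissingDummies:
    def make_table(self, n=1000, frac_missing=0.283, seed=0):
        rng = np.random.default_rng(seed)
        lactate = rng.lognormal(0.6, 0.6, n)
        miss = rng.random(n) < frac_missing
        lactate[miss] = np.nan
        return pd.DataFrame({"death28": rng.integers(0, 2, n),
                             "ratio": rng.uniform(0.3, 10, n),
                             "lactate": lactate,
                             "age": rng.normal(65, 10, n)})

    def test_indicator_added_above_threshold(self):
        table = self.make_table()
        out = add_missing_dummies(table, ["lactate", "age"])
        assert "lactate_missing" in out.columns
        assert "age_missing" not in out.columns
        assert out["lactate"].notna().all()
        # indicator marks exactly the rows that were missing
        assert (out["lactate_missing"] == table["lactate"].isna().astype(int)).all()

    def test_observed_mean_preserved_exactly(self):
        table = self.make_table()
        out = add_missing_dummies(table, ["lactate"])
        assert out["lactate"].mean() == pytest.approx(table["lactate"].mean(), abs=1e-12)

    def test_exactly_one_percent_is_not_flagged(self):
        # strictly-greater rule: 1.0% missing gets mean-filled, no indicator
        n = 1000
        table = self.make_table(n=n, frac_missing=0.0)
        table.loc[:9, "lactate"] = np.nan
        assert table["lactate"].isna().sum() == 10  # independent direct count
        out = add_missing_dummies(table, ["lactate"])
        assert "lactate_missing" not in out.columns
        assert out["lactate"].notna().all()

    def test_fully_missing_covariate_errors(self):
        table = self.make_table(n=20, frac_missing=0.0)
        table["lactate"] = np.nan
        with pytest.raises(ValueError, match="100% missing"):
            add_missing_dummies(table, ["lactate"])

    def test_outcome_exposure_protected(self):
        table = self.make_table()
        with pytest.raises(ValueError):
            add_missing_dummies(table, ["ratio"])


class TestBuildDesign:
    def toy_table(self):
        return pd.DataFrame({
            "death28": [0, 1, 0],
            "ratio": [1.0, 3.5, 6.0],
            "age": [50.0, 60.0, 70.0],
            "sex": ["male", "female", "male"],
            "infection_site": ["pulmonary", "GI", "other"],
        })

    def test_k_minus_1_coding(self, small_cohort):
        _, table = small_cohort
        d = build_design(table, FormulaSpec(categorical={"infection_site": "pulmonary"}))
        site_cols = [c for c in d.X.columns if c.startswith("infection_site[")]
        assert len(site_cols) == 5
        assert "infection_site[pulmonary]" not in d.X.columns
        assert set(np.unique(d.X[site_cols].to_numpy())) <= {0.0, 1.0}

    def test_hinge_column(self):
        table = self.toy_table()
        d = build_design(table, FormulaSpec(hinge_terms={"ratio": 3.3}))
        expected = np.maximum(table["ratio"].to_numpy() - 3.3, 0.0)
        np.testing.assert_allclose(d.X["ratio_hinge"], expected)
        np.testing.assert_allclose(hinge([1.0, 3.5, 6.0], 3.3), expected)

    def test_column_count_by_hand(self):
        # intercept + ratio + hinge + age + sex(1) + site(2 of 3 observed...
        # levels come from the declared vocabulary: 6 levels -> 5 indicators)
        table = self.toy_table()
        spec = FormulaSpec(continuous=["age"], categorical={"sex": "male",
                                                            "infection_site": "pulmonary"},
                           hinge_terms={"ratio": 3.3})
        d = build_design(table, spec)
        assert d.X.shape[1] == 1 + 2 + 1 + 1 + 5
        assert d.reference_levels == {"sex": "male", "infection_site": "pulmonary"}

    def test_no_missing_values_by_construction(self, small_cohort):
        _, table = small_cohort
        assert table["lactate"].isna().any()
        d = build_design(table, FormulaSpec(continuous=["lactate", "age"]))
        assert not d.X.isna().any().any()
        assert "lactate_missing" in d.X.columns
        assert len(d.X) == len(table)  # no silently dropped rows

    def test_unknown_column_and_level_errors(self):
        table = self.toy_table()
        with pytest.raises(KeyError, match="nope"):
            build_design(table, FormulaSpec(continuous=["nope"]))
        with pytest.raises(ValueError, match="reference level"):
            build_design(table, FormulaSpec(categorical={"sex": "unknown_level"}))


def test_drop_missing_exposure_counts():
    table = pd.DataFrame({"ratio": [1.0, np.nan, 2.0], "death28": [0, 1, 0]})
    out, dropped = drop_missing_exposure(table)
    assert dropped == 1 and len(out) == 2 and out["ratio"].notna().all()
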