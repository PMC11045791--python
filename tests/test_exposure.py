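"""Exposure averaging, clustering and weighted-score contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exogene import ClusterDefinition, ExposureWindow
from exogene.exposure import (
    correlation_cluster,
    longterm_average,
    weighted_cluster_score,
)


def _subjects(diag_years: dict[str, int | float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"subject_id": list(diag_years), "diagnosis_year": list(diag_years.values())}
    )


def _records(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "location_type", "year", "pesticide", "lbs_per_acre"]
    )


class TestLongTermAverage:
    def test_absent_years_count_as_zero(self):
        # 1974-1983 at 2.0 lbs/acre, diagnosis 1995, 10-year lag
        # => window 1974-1985 (12 years), mean = 20/12
        rows = [("A", "residential", y, "phorate", 2.0) for y in range(1974, 1984)]
        lt = longterm_average(_records(rows), _subjects({"A": 1995}))
        val = lt.loc[
            (lt["pesticide"] == "phorate") & (lt["location_type"] == "residential"),
            "mean_lbs_per_acre",
        ].iloc[0]
        assert val == pytest.approx(20 / 12)

    def test_single_year_divided_by_window_length(self):
        rows = [("A", "workplace", 1980, "aldicarb", 6.0)]
        lt = longterm_average(_records(rows), _subjects({"A": 1995}))
        val = lt.loc[
            (lt["location_type"] == "workplace"), "mean_lbs_per_acre"
        ].iloc[0]
        assert val == pytest.approx(6.0 / 12)

    def test_no_records_gives_zero_row(self):
        rows = [("A", "residential", 1980, "phorate", 1.0)]
        lt = longterm_average(_records(rows), _subjects({"A": 1995, "B": 2000}))
        b = lt[(lt["subject_id"] == "B")]
        assert len(b) == 2  # both locations gridded
        assert (b["mean_lbs_per_acre"] == 0).all()

    def test_out_of_window_records_ignored(self):
        rows = [
            ("A", "residential", 1990, "phorate", 99.0),  # after 1985 end
            ("A", "residential", 1980, "phorate", 1.2),
        ]
        lt = longterm_average(_records(rows), _subjects({"A": 1995}))
        val = lt.loc[lt["location_type"] == "residential", "mean_lbs_per_acre"].iloc[0]
        assert val == pytest.approx(1.2 / 12)

    def test_missing_or_early_diagnosis_flagged_unexposable(self):
        rows = [("A", "residential", 1980, "phorate", 1.0)]
        lt = longterm_average(
            _records(rows), _subjects({"A": 1995, "B": np.nan, "C": 1980})
        )
        assert lt.attrs["unexposable"] == ["B", "C"]
        assert set(lt["subject_id"]) == {"A"}


class TestCorrelationCluster:
    @staticmethod
    def _longterm_from_matrix(mat: np.ndarray, names: list[str]) -> pd.DataFrame:
        rows = []
        for i in range(mat.shape[0]):
            for j, p in enumerate(names):
                rows.append((f"S{i}", p, "residential", mat[i, j]))
        return pd.DataFrame(
            rows, columns=["subject_id", "pesticide", "location_type", "mean_lbs_per_acre"]
        )

    def test_identical_columns_cluster_together(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2, 1, 30)
        mat = np.column_stack([x, x, rng.gamma(2, 1, 30)])
        lt = self._longterm_from_matrix(mat, ["a", "b", "c"])
        clusters = correlation_cluster(lt, cutpoint=0.45)
        grouping = {frozenset(c.members) for c in clusters}
        assert frozenset({"a", "b"}) in grouping

    def test_planted_two_cluster_structure_recovered(self):
        rng = np.random.default_rng(1)
        n = 400
        g1, g2 = rng.standard_normal((2, n))
        mat = np.column_stack(
            [np.sqrt(0.6) * g1 + np.sqrt(0.4) * rng.standard_normal(n) for _ in range(4)]
            + [np.sqrt(0.6) * g2 + np.sqrt(0.4) * rng.standard_normal(n) for _ in range(4)]
        )
        names = [f"p{i}" for i in range(8)]
        lt = self._longterm_from_matrix(mat - mat.min() + 0.1, names)
        clusters = correlation_cluster(lt, cutpoint=0.45)
        grouping = {frozenset(c.members) for c in clusters}
        assert grouping == {
            frozenset(names[:4]),
            frozenset(names[4:]),
        }

    def test_cutpoint_one_gives_singletons(self):
        rng = np.random.default_rng(2)
        lt = self._longterm_from_matrix(rng.gamma(2, 1, (20, 4)), list("abcd"))
        clusters = correlation_cluster(lt, cutpoint=1.0)
        assert all(len(c.members) == 1 for c in clusters)

    def test_zero_variance_pesticide_excluded(self):
        rng = np.random.default_rng(3)
        mat = np.column_stack([rng.gamma(2, 1, 20), np.zeros(20), rng.gamma(2, 1, 20)])
        lt = self._longterm_from_matrix(mat, ["a", "const", "c"])
        clusters = correlation_cluster(lt)
        members = {m for c in clusters for m in c.members}
        assert "const" not in members


class TestWeightedClusterScore:
    @staticmethod
    def _longterm(values: dict[str, dict[tuple[str, str], float]]) -> pd.DataFrame:
        rows = []
        for s, d in values.items():
            for (p, loc), v in d.items():
                rows.append((s, p, loc, v))
        return pd.DataFrame(
            rows, columns=["subject_id", "pesticide", "location_type", "mean_lbs_per_acre"]
        )

    cluster = ClusterDefinition("c", ["x", "y"], {"x": 1.0, "y": 1.0})

    def test_all_zero_cohort_guarded(self):
        lt = self._longterm(
            {s: {("x", "residential"): 0.0, ("y", "residential"): 0.0} for s in "ABC"}
        )
        scores = weighted_cluster_score(lt, self.cluster)
        assert (scores["scaled_score"] == 0).all()
        assert (scores["display_score"] == 1).all()

    def test_single_exposed_subject_has_maximum(self):
        lt = self._longterm(
            {
                "A": {("x", "residential"): 5.0},
                "B": {("x", "residential"): 0.0},
                "C": {("x", "residential"): 0.0},
            }
        )
        scores = weighted_cluster_score(lt, self.cluster).set_index("subject_id")
        assert scores["raw_weighted_sum"].idxmax() == "A"
        assert scores["display_score"].idxmax() == "A"

    def test_dual_location_scores_strictly_higher(self):
        lt = self._longterm(
            {
                "both": {("x", "residential"): 2.0, ("x", "workplace"): 2.0},
                "one": {("x", "residential"): 2.0},
                "none": {("x", "residential"): 0.0},
                "other": {("x", "residential"): 1.0},
            }
        )
        s = weighted_cluster_score(lt, self.cluster).set_index("subject_id")
        assert s.loc["both", "raw_weighted_sum"] > s.loc["one", "raw_weighted_sum"]
        assert s.loc["one", "raw_weighted_sum"] > s.loc["none", "raw_weighted_sum"]

    def test_scaled_score_has_unit_sd_and_display_mean_one(self):
        rng = np.random.default_rng(4)
        lt = self._longterm(
            {
                f"S{i}": {
                    ("x", "residential"): float(rng.gamma(2, 1)),
                    ("y", "workplace"): float(rng.gamma(2, 1)),
                }
                for i in range(40)
            }
        )
        s = weighted_cluster_score(lt, self.cluster)
        assert s["scaled_score"].std(ddof=1) == pytest.approx(1.0)
        assert s["display_score"].mean() == pytest.approx(1.0)
        assert s["display_score"].std(ddof=1) == pytest.approx(1.0)

    def test_doubling_matches_direct_recomputation(self):
        """The score after doubling all exposures must equal a from-scratch
        recomputation (log1p is nonlinear, so no shortcut exists)."""
        rng = np.random.default_rng(5)
        base = {
            f"S{i}": {("x", "residential"): float(rng.gamma(2, 1))} for i in range(20)
        }
        doubled = {
            s: {k: 2 * v for k, v in d.items()} for s, d in base.items()
        }
        got = weighted_cluster_score(
            self._longterm(doubled), self.cluster
        ).set_index("subject_id")

        # independent recomputation of the doubled cohort
        ids = [f"S{i}" for i in range(20)]
        vals = np.array([doubled[s][("x", "residential")] for s in ids])
        t = np.log1p(vals)
        z = t / t.std(ddof=1)
        raw = 1.0 * z  # beta_x = 1, single location; y column all zero
        expect = raw / raw.std(ddof=1)
        np.testing.assert_allclose(
            got.loc[ids, "scaled_score"].to_numpy(), expect, atol=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        add=st.floats(min_value=0.01, max_value=50),
        which=st.integers(min_value=0, max_value=9),
    )
    def test_monotonicity_adding_exposure(self, add, which):
        """With nonnegative betas, adding exposure to one subject never
        decreases that subject's raw weighted sum."""
        rng = np.random.default_rng(6)
        vals = rng.gamma(2, 1, 10)
        lt = self._longterm(
            {f"S{i}": {("x", "residential"): float(v)} for i, v in enumerate(vals)}
        )
        before = weighted_cluster_score(lt, self.cluster).set_index("subject_id")
        vals2 = vals.copy()
        vals2[which] += add
        lt2 = self._longterm(
            {f"S{i}": {("x", "residential"): float(v)} for i, v in enumerate(vals2)}
        )
        after = weighted_cluster_score(lt2, self.cluster).set_index("subject_id")
        sid = f"S{which}"
        assert after.loc[sid, "raw_weighted_sum"] >= before.loc[sid, "raw_weighted_sum"] - 1e-12

    def test_missing_beta_raises(self):
        lt = self._longterm({"A": {("x", "residential"): 1.0}})
        with pytest.raises(Exception):
            weighted_cluster_score(
                lt, ClusterDefinition("c", ["x", "y"], {"x": 1.0})
            )
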