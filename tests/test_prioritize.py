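"""Carrier averaging, thresholding, composite ranking, gene rollup,
CADD binning, the additivity check and report consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_panel
from exogene.prioritize import (
    additivity_check,
    build_report,
    cadd_bin,
    carrier_averages,
    composite_score,
    gene_rollup,
    threshold_prioritize,
)


def _scores(d: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"subject_id": list(d), "display_score": list(d.values())}
    )


def _enrichment_row(vid, subpop="European"):
    return {
        "variant_id": vid,
        "subpopulation": subpop,
        "p_value": 1e-5,
        "enriched": True,
        "reference_absent": False,
    }


class TestCarrierAverages:
    def test_single_carrier_averages_equal_carrier_scores(self):
        panel = make_panel(n_variants=1)
        panel.genotypes.iloc[0, :] = [1, 0, 0, 0, 0]
        enr = pd.DataFrame([_enrichment_row(panel.variant_ids[0])])
        expo = _scores({"P1": 1.7, "P2": 0.5, "P3": 0.9})
        prog = _scores({"P1": 2.1, "P2": 0.4, "P3": 1.0})
        out = carrier_averages(
            enr, panel, expo, prog, {"European": panel.samples}
        )
        assert out.iloc[0]["avg_exposure"] == pytest.approx(1.7)
        assert out.iloc[0]["avg_progression"] == pytest.approx(2.1)
        assert out.iloc[0]["carrier_count"] == 1

    def test_two_carrier_mean(self):
        panel = make_panel(n_variants=1)
        panel.genotypes.iloc[0, :] = [1, 1, 0, 0, 0]
        enr = pd.DataFrame([_enrichment_row(panel.variant_ids[0])])
        expo = _scores({"P1": 0.5, "P2": 1.5, "P3": 9.0})
        prog = _scores({"P1": 1.0, "P2": 3.0, "P3": 9.0})
        out = carrier_averages(enr, panel, expo, prog, {"European": panel.samples})
        assert out.iloc[0]["avg_exposure"] == pytest.approx(1.0)
        assert out.iloc[0]["avg_progression"] == pytest.approx(2.0)

    def test_carrier_without_progression_score_excluded(self):
        """Counting oracle: P2 lacks a progression score, so both
        averages use P1 only."""
        panel = make_panel(n_variants=1)
        panel.genotypes.iloc[0, :] = [1, 1, 0, 0, 0]
        enr = pd.DataFrame([_enrichment_row(panel.variant_ids[0])])
        expo = _scores({"P1": 2.0, "P2": 8.0})
        prog = _scores({"P1": 1.2})
        out = carrier_averages(enr, panel, expo, prog, {"European": panel.samples})
        assert out.iloc[0]["carrier_count"] == 1
        assert out.iloc[0]["avg_exposure"] == pytest.approx(2.0)

    def test_no_in_cohort_carrier_dropped_with_log(self):
        panel = make_panel(n_variants=1)
        panel.genotypes.iloc[0, :] = [0, 0, 0, 0, 1]  # only P5 carries
        enr = pd.DataFrame([_enrichment_row(panel.variant_ids[0])])
        expo = _scores({"P1": 1.0})
        prog = _scores({"P1": 1.0})
        out = carrier_averages(enr, panel, expo, prog, {"European": panel.samples})
        assert len(out) == 0
        assert out.attrs["n_no_carrier"] == 1


class TestThresholdAndComposite:
    def _averaged(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "gene", "group", "cadd", "subpopulation",
                     "p_value", "carriers", "carrier_count", "avg_exposure",
                     "avg_progression"],
        )

    def test_inclusive_boundary(self):
        df = self._averaged([
            ("v1", "A", 1, 15, "European", 0.01, "s1", 1, 1.0, 1.0),
            ("v2", "B", 1, 15, "European", 0.01, "s2", 1, 0.999, 2.0),
            ("v3", "C", 1, 15, "European", 0.01, "s3", 1, 2.0, 0.999),
        ])
        kept = threshold_prioritize(df)
        assert list(kept["variant_id"]) == ["v1"]

    def test_composite_normalization_and_ties(self):
        df = self._averaged([
            ("v1", "A", 1, 15, "European", 0.01, "s1", 1, 1.0, 2.0),
            ("v2", "B", 1, 15, "European", 0.01, "s2", 1, 2.0, 1.0),
        ])
        scored = composite_score(threshold_prioritize(df))
        # hand computation: norm by per-column max 2.0 => both 0.5
        assert scored["composite_score"].tolist() == pytest.approx([0.5, 0.5])
        # lexicographic gene tie-break
        assert scored["gene"].tolist() == ["A", "B"]

    def test_variant_holding_both_maxima_scores_one(self):
        df = self._averaged([
            ("v1", "A", 1, 15, "European", 0.01, "s1", 1, 3.0, 4.0),
            ("v2", "B", 1, 15, "European", 0.01, "s2", 1, 1.5, 2.0),
        ])
        scored = composite_score(df)
        assert scored.iloc[0]["composite_score"] == pytest.approx(1.0)
        assert scored.iloc[1]["composite_score"] < 1.0

    def test_no_variant_attains_both_maxima_all_below_one(self):
        df = self._averaged([
            ("v1", "A", 1, 15, "European", 0.01, "s1", 1, 3.0, 1.0),
            ("v2", "B", 1, 15, "European", 0.01, "s2", 1, 1.0, 4.0),
        ])
        scored = composite_score(df)
        assert (scored["composite_score"] < 1.0).all()
        assert (scored["composite_score"] > 0.0).all()

    def test_rescaling_invariance_of_ranking(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"v{i}", f"G{i}", 1, 15, "European", 0.01, f"s{i}", 1,
             float(rng.uniform(1, 3)), float(rng.uniform(1, 3)))
            for i in range(10)
        ]
        df = self._averaged(rows)
        base = composite_score(df)
        scaled = df.assign(
            avg_exposure=df["avg_exposure"] * 7.3,
            avg_progression=df["avg_progression"] * 7.3,
        )
        again = composite_score(scaled)
        assert base["variant_id"].tolist() == again["variant_id"].tolist()
        np.testing.assert_allclose(
            base["composite_score"], again["composite_score"], atol=1e-12
        )


class TestCaddBin:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (24.4, ">20"),
            (10.0, "10-20"),
            (20.0, "10-20"),
            (9.99, "<10"),
            (0.0, "<10"),
            (float("nan"), "unscored"),
            (None, "unscored"),
        ],
    )
    def test_bins(self, score, expected):
        assert cadd_bin(score) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cadd_bin(-1.0)


class TestGeneRollup:
    def _prioritized(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "gene", "subpopulation", "carriers",
                     "carrier_count", "composite_score"],
        )

    def test_mean_composite_and_flags(self):
        df = self._prioritized([
            ("v1", "A", "European", "s1", 1, 0.4),
            ("v2", "A", "European", "s2;s3", 2, 0.6),
            ("v3", "B", "European", "s4", 1, 0.2),
        ])
        genes = gene_rollup(df).set_index("gene")
        assert genes.loc["A", "gene_composite"] == pytest.approx(0.5)
        assert bool(genes.loc["A", "multi_variant"])
        assert bool(genes.loc["A", "multi_carrier"])
        assert not bool(genes.loc["B", "multi_variant"])

    def test_dual_subpopulation_variant_counts_as_two_entries(self):
        df = self._prioritized([
            ("v1", "A", "European", "s1", 1, 0.4),
            ("v1", "A", "Hispanic", "s2", 1, 0.8),
        ])
        genes = gene_rollup(df).set_index("gene")
        assert genes.loc["A", "n_entries"] == 2
        assert genes.loc["A", "n_variants"] == 1
        assert genes.loc["A", "gene_composite"] == pytest.approx(0.6)

    def test_constraint_flags(self):
        df = self._prioritized([
            ("v1", "A", "European", "s1", 1, 0.4),
            ("v2", "B", "European", "s2", 1, 0.3),
        ])
        constraints = pd.DataFrame(
            {"gene": ["A"], "pli": [0.95], "mis_z": [2.5]}
        )
        genes = gene_rollup(df, constraints).set_index("gene")
        assert bool(genes.loc["A", "lof_constrained"])
        assert bool(genes.loc["A", "missense_constrained"])
        assert genes.loc["B", "lof_constrained"] is None


class TestAdditivity:
    @staticmethod
    def _prioritized_with_carriers(rng, shift=0.0):
        rows = []
        subjects = [f"s{i}" for i in range(40)]
        # 10 multi-variant carriers, 30 single
        for i, s in enumerate(subjects):
            n_var = 2 if i < 10 else 1
            for k in range(n_var):
                rows.append(
                    {
                        "variant_id": f"v{i}_{k}",
                        "gene": "G",
                        "carriers": s,
                        "composite_score": float(
                            np.clip(rng.normal(0.5 + (shift if i < 10 else 0), 0.1),
                                    0.01, 1.0)
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_calibration_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = [
            additivity_check(self._prioritized_with_carriers(rng))["p_value"]
            for _ in range(200)
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        hits = sum(
            additivity_check(self._prioritized_with_carriers(rng, shift=0.3))[
                "p_value"
            ] < 0.01
            for _ in range(20)
        )
        assert hits >= 18

    def test_small_group_skipped(self):
        df = pd.DataFrame(
            [{"variant_id": "v", "gene": "G", "carriers": "s1",
              "composite_score": 0.5}]
        )
        out = additivity_check(df)
        assert not out["tested"] and np.isnan(out["p_value"])


class TestReport:
    def test_empty_prioritized_set_well_formed(self):
        empty = pd.DataFrame(
            columns=["variant_id", "gene", "group", "cadd", "subpopulation",
                     "carriers", "carrier_count", "avg_exposure",
                     "avg_progression", "composite_score", "cadd_bin"]
        )
        rep = build_report(composite_score(empty))
        assert rep.n_variants == 0 and rep.n_genes == 0
        assert "Prioritized variants: 0" in rep.to_markdown()

    def test_pipeline_conservation(self, pipeline_result):
        """Every enriched test lands in exactly one bucket: prioritized,
        below-threshold, or no-in-cohort-carrier."""
        res = pipeline_result
        n_enriched = int(
            (res.enrichment["enriched"] & ~res.enrichment["reference_absent"]).sum()
        )
        n_no_carrier = res.averaged.attrs["n_no_carrier"]
        n_below = len(res.averaged) - len(res.prioritized)
        assert n_enriched == len(res.prioritized) + n_below + n_no_carrier

    def test_report_counts_recompute_from_tables(self, pipeline_result):
        res = pipeline_result
        rep = res.report
        assert rep.n_entries == len(res.prioritized)
        assert rep.n_variants == res.prioritized["variant_id"].nunique()
        assert rep.n_genes == len(res.genes)
        assert rep.n_multi_variant_genes == int(res.genes["multi_variant"].sum())
        assert sum(rep.cadd_bin_counts.values()) == rep.n_variants
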