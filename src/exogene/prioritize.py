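"""Variant prioritization, composite ranking, gene rollup and reporting.

Enriched variants are scored by the mean display-scale pesticide-exposure
and disease-progression scores of their carriers within the analysis
cohort (subjects holding both scores).  Variants with both carrier
averages >= 1 (inclusive) are prioritized, then ranked by a composite
disease-severity x pesticide-exposure score: each carrier average is
normalized by its maximum over the prioritized set and the two
normalized values multiplied, giving scores in (0, 1].  Genes roll up
the mean of member composites (a variant enriched in both
subpopulations contributes one entry per subpopulation), with gnomAD
constraint flags (pLI > 0.9, missense Z > 2) attached when provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "carrier_averages",
    "threshold_prioritize",
    "composite_score",
    "gene_rollup",
    "cadd_bin",
    "additivity_check",
    "SummaryReport",
    "build_report",
    "plot_prioritization",
]

logger = logging.getLogger(__name__)

CADD_BINS = ("<10", "10-20", ">20", "unscored")


def carrier_averages(
    enrichment: pd.DataFrame,
    panel,
    exposure_scores: pd.DataFrame,
    progression_scores: pd.DataFrame,
    subpopulations: dict[str, list[str]],
) -> pd.DataFrame:
    """Carrier-mean display scores per enriched (variant, subpopulation).

    The analysis cohort contains only subjects with both an exposure and
    a progression score; carriers outside it are ignored, and variants
    with no in-cohort carrier are dropped with a log entry.
    """
    expo = exposure_scores.set_index("subject_id")["display_score"]
    prog = progression_scores.set_index("subject_id")["display_score"]
    cohort = expo.index.intersection(prog.index)

    enriched = enrichment[
        enrichment["enriched"] & ~enrichment["reference_absent"]
    ]
    rows, dropped = [], 0
    for _, erow in enriched.iterrows():
        vid, label = erow["variant_id"], erow["subpopulation"]
        members = pd.Index(subpopulations.get(label, [])).intersection(cohort)
        gt = panel.genotypes.loc[vid, members]
        carriers = list(gt.index[gt > 0])
        if not carriers:
            dropped += 1
            logger.info("variant %s (%s): no carrier in analysis cohort",
                        vid, label)
            continue
        vinfo = panel.variants.loc[vid]
        rows.append(
            {
                "variant_id": vid,
                "gene": vinfo["gene"],
                "group": int(vinfo["group"]),
                "cadd": vinfo["cadd"],
                "subpopulation": label,
                "p_value": erow["p_value"],
                "carriers": ";".join(carriers),
                "carrier_count": len(carriers),
                "avg_exposure": float(expo.loc[carriers].mean()),
                "avg_progression": float(prog.loc[carriers].mean()),
            }
        )
    if dropped:
        logger.info("%d enriched variant tests dropped: no in-cohort carrier",
                    dropped)
    out = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gene", "group", "cadd", "subpopulation",
            "p_value", "carriers", "carrier_count", "avg_exposure",
            "avg_progression",
        ],
    )
    out.attrs["n_no_carrier"] = dropped
    return out


def threshold_prioritize(
    averaged: pd.DataFrame,
    exposure_min: float = 1.0,
    progression_min: float = 1.0,
) -> pd.DataFrame:
    """Keep variants with both carrier averages at/above threshold
    (inclusive: "1 or greater")."""
    keep = (averaged["avg_exposure"] >= exposure_min) & (
        averaged["avg_progression"] >= progression_min
    )
    return averaged[keep].reset_index(drop=True)


def composite_score(prioritized: pd.DataFrame) -> pd.DataFrame:
    """Composite = norm(avg progression) x norm(avg exposure), each factor
    divided by its maximum over the prioritized set; descending rank with
    lexicographic gene/variant tie-breaks."""
    if len(prioritized) == 0:
        out = prioritized.copy()
        out["composite_score"] = pd.Series(dtype=float)
        out["cadd_bin"] = pd.Series(dtype=str)
        return out
    out = prioritized.copy()
    max_e = out["avg_exposure"].max()
    max_p = out["avg_progression"].max()
    out["composite_score"] = (out["avg_progression"] / max_p) * (
        out["avg_exposure"] / max_e
    )
    out["cadd_bin"] = [cadd_bin(c) for c in out["cadd"]]
    out = out.sort_values(
        ["composite_score", "gene", "variant_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cadd_bin(score) -> str:
    """Bin a scaled CADD score: [0,10) -> '<10', [10,20] -> '10-20',
    (20,inf) -> '>20', missing -> 'unscored'."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "unscored"
    score = float(score)
    if score < 0:
        raise ValueError("CADD scaled scores are nonnegative")
    if score < 10:
        return "<10"
    if score <= 20:
        return "10-20"
    return ">20"


def gene_rollup(
    prioritized: pd.DataFrame,
    constraints: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene summary: mean composite over member entries (an entry per
    enriched subpopulation), multi-variant / multi-carrier flags, and
    constraint annotations (pLI > 0.9, missense Z > 2) when provided."""
    if len(prioritized) == 0:
        return pd.DataFrame(
            columns=[
                "gene", "n_variants", "n_entries", "gene_composite",
                "multi_variant", "multi_carrier", "pli", "mis_z",
                "lof_constrained", "missense_constrained",
            ]
        )
    grp = prioritized.groupby("gene")
    out = pd.DataFrame(
        {
            "gene": list(grp.groups),
            "n_variants": grp["variant_id"].nunique().to_numpy(),
            "n_entries": grp.size().to_numpy(),
            "gene_composite": grp["composite_score"].mean().to_numpy(),
            "multi_variant": (grp["variant_id"].nunique() >= 2).to_numpy(),
            "multi_carrier": (grp["carrier_count"].max() >= 2).to_numpy(),
        }
    )
    if constraints is not None:
        c = constraints.set_index("gene")
        out["pli"] = out["gene"].map(c["pli"]) if "pli" in c else np.nan
        out["mis_z"] = out["gene"].map(c["mis_z"]) if "mis_z" in c else np.nan
    else:
        out["pli"] = np.nan
        out["mis_z"] = np.nan
    out["lof_constrained"] = np.where(
        out["pli"].isna(), None, out["pli"] > 0.9
    )
    out["missense_constrained"] = np.where(
        out["mis_z"].isna(), None, out["mis_z"] > 2
    )
    return out.sort_values(
        "gene_composite", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def additivity_check(prioritized: pd.DataFrame) -> dict:
    """Welch t-test of per-subject mean composite: carriers of >= 2
    prioritized variants vs single-variant carriers."""
    per_subject: dict[str, list[float]] = {}
    for _, row in prioritized.iterrows():
        for s in str(row["carriers"]).split(";"):
            if s:
                per_subject.setdefault(s, []).append(row["composite_score"])
    multi = [np.mean(v) for v in per_subject.values() if len(v) >= 2]
    single = [np.mean(v) for v in per_subject.values() if len(v) == 1]
    if len(multi) < 2 or len(single) < 2:
        logger.warning("additivity check skipped: group too small "
                       "(%d multi, %d single)", len(multi), len(single))
        return {"p_value": np.nan, "n_multi": len(multi),
                "n_single": len(single), "tested": False}
    t, p = stats.ttest_ind(multi, single, equal_var=False)
    return {"p_value": float(p), "t": float(t), "n_multi": len(multi),
            "n_single": len(single), "tested": True}


# ---------------------------------------------------------------------------
# reporting


@dataclass
class SummaryReport:
    """Counts and fractions of the prioritized set, recomputed from the
    tables they describe."""

    n_variants: int
    n_entries: int
    n_genes: int
    n_multi_variant_genes: int
    n_multi_carrier_genes: int
    cadd_bin_counts: dict[str, int]
    group_counts: dict[int, int]
    composite_max: float
    composite_min: float
    replication_counts: dict[str, int] = field(default_factory=dict)
    additivity: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# Prioritized variant summary", ""]
        lines.append(
            f"- Prioritized variants: {self.n_variants} "
            f"({self.n_entries} subpopulation entries) in "
            f"{self.n_genes} genes"
        )
        if self.n_genes:
            lines.append(
                f"- Multi-variant genes: {self.n_multi_variant_genes}/"
                f"{self.n_genes} "
                f"({100 * self.n_multi_variant_genes / self.n_genes:.0f}%)"
            )
            lines.append(
                f"- Multi-carrier genes: {self.n_multi_carrier_genes}/"
                f"{self.n_genes} "
                f"({100 * self.n_multi_carrier_genes / self.n_genes:.0f}%)"
            )
        if self.n_variants:
            for b, c in self.cadd_bin_counts.items():
                lines.append(
                    f"- CADD {b}: {c}/{self.n_variants} "
                    f"({100 * c / self.n_variants:.0f}%)"
                )
            for g, c in sorted(self.group_counts.items()):
                lines.append(
                    f"- Gene group {g}: {c}/{self.n_variants} "
                    f"({100 * c / self.n_variants:.0f}%)"
                )
            lines.append(
                f"- Composite score range: {self.composite_min:.3f} - "
                f"{self.composite_max:.3f}"
            )
        for status, c in self.replication_counts.items():
            lines.append(f"- Replication {status}: {c}")
        if self.additivity.get("tested"):
            lines.append(
                f"- Multi- vs single-variant carrier composite: "
                f"p = {self.additivity['p_value']:.2f} "
                f"({self.additivity['n_multi']} vs "
                f"{self.additivity['n_single']} subjects)"
            )
        return "\n".join(lines) + "\n"


def build_report(
    prioritized: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    replication: pd.DataFrame | None = None,
    additivity: dict | None = None,
) -> SummaryReport:
    """Summarize a scored prioritized table (well-formed when empty)."""
    genes = gene_rollup(prioritized) if genes is None else genes
    n_variants = prioritized["variant_id"].nunique() if len(prioritized) else 0
    per_variant = (
        prioritized.drop_duplicates("variant_id") if len(prioritized) else prioritized
    )
    cadd_counts = {b: 0 for b in CADD_BINS}
    group_counts: dict[int, int] = {}
    if n_variants:
        for b in per_variant["cadd_bin"] if "cadd_bin" in per_variant else []:
            cadd_counts[b] += 1
        group_counts = (
            per_variant.groupby("group").size().astype(int).to_dict()
            if "group" in per_variant
            else {}
        )
    repl_counts = (
        replication.groupby("status").size().astype(int).to_dict()
        if replication is not None and len(replication)
        else {}
    )
    composite = (
        genes["gene_composite"] if len(genes) else pd.Series(dtype=float)
    )
    return SummaryReport(
        n_variants=int(n_variants),
        n_entries=int(len(prioritized)),
        n_genes=int(len(genes)),
        n_multi_variant_genes=int(genes["multi_variant"].sum()) if len(genes) else 0,
        n_multi_carrier_genes=int(genes["multi_carrier"].sum()) if len(genes) else 0,
        cadd_bin_counts=cadd_counts,
        group_counts={int(k): int(v) for k, v in group_counts.items()},
        composite_max=float(composite.max()) if len(composite) else float("nan"),
        composite_min=float(composite.min()) if len(composite) else float("nan"),
        replication_counts=repl_counts,
        additivity=additivity or {},
    )


def plot_prioritization(averaged: pd.DataFrame, path=None):
    """Scatter of carrier-average exposure vs progression with the
    >=1 / >=1 prioritization quadrant highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = averaged["subpopulation"].map(
        {"European": "tab:blue", "Hispanic": "tab:red"}
    ).fillna("tab:gray")
    ax.scatter(
        averaged["avg_exposure"], averaged["avg_progression"],
        c=colors, s=18, alpha=0.8,
    )
    ax.axvline(1.0, color="gray", lw=0.8, ls="--")
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    xmax = max(1.5, averaged["avg_exposure"].max() * 1.05) if len(averaged) else 2
    ymax = max(1.5, averaged["avg_progression"].max() * 1.05) if len(averaged) else 2
    ax.axvspan(1.0, xmax, ymin=0, ymax=1, color="gold", alpha=0.08)
    ax.set_xlabel("carrier-average pesticide exposure score")
    ax.set_ylabel("carrier-average disease progression score")
    ax.set_title("Enriched variants by exposure and progression")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
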