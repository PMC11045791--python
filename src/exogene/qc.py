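"""Variant call filtering, relatedness estimation and cohort splitting.

Call filters follow the amplicon-panel rules: caller PASS, site Phred
quality >= 30, and >= 10x depth in >= 90% of samples within each
subpopulation (evaluated per subpopulation: a variant may survive in one
subpopulation only and is then tested only there).  Region filters keep
exonic/splice-site calls on the canonical transcript; gene-specific
rules drop low-complexity HTT calls and HLA-DRB5 calls with phase or
low-quality warnings.  Relatedness uses the PLINK-style method-of-moments
IBS->IBD decomposition (PI_HAT = P(IBD=2) + P(IBD=1)/2); samples in a
pair with PI_HAT > 0.05 are excluded greedily, dropping the sample in
the most flagged pairs first.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .vcfio import PanelData

__all__ = [
    "apply_call_filters",
    "restrict_exonic_canonical",
    "apply_special_gene_rules",
    "estimate_pihat",
    "exclude_related",
    "split_subpopulations",
]

logger = logging.getLogger(__name__)

ANALYSIS_SUBPOPULATIONS = ("European", "Hispanic")


def _log(exclusions: list, vid: str, reason: str) -> None:
    exclusions.append({"variant_id": vid, "reason": reason})


def apply_call_filters(
    panel: PanelData,
    subpopulations: dict[str, list[str]],
    min_quality: float = 30.0,
    min_depth: int = 10,
    min_depth_fraction: float = 0.9,
) -> tuple[PanelData, pd.DataFrame, pd.DataFrame]:
    """PASS / Phred>=30 / 10x-in-90%-per-subpopulation call filters.

    Returns (filtered panel, eligibility, exclusion log).  ``eligibility``
    is a variant x subpopulation boolean frame; a variant is kept if it is
    eligible in at least one subpopulation.  Both quality bounds are
    inclusive ("30 or higher", ">= 90%").
    """
    v = panel.variants
    exclusions: list[dict] = []
    pass_filter = v["filter"].eq("PASS")
    qual_ok = v["qual"] >= min_quality

    elig = {}
    dp = panel.depth
    for label, members in subpopulations.items():
        members = [m for m in members if m in dp.columns]
        if not members:
            elig[label] = pd.Series(False, index=v.index)
            continue
        frac = (dp[members] >= min_depth).sum(axis=1) / len(members)
        elig[label] = frac >= min_depth_fraction
    eligibility = pd.DataFrame(elig)
    depth_ok = eligibility.any(axis=1)

    keep = pass_filter & qual_ok & depth_ok
    for vid in v.index[~keep]:
        if not pass_filter.loc[vid]:
            reason = "fail_caller_filter"
        elif not qual_ok.loc[vid]:
            reason = "site_quality_below_30"
        else:
            reason = "depth_below_10x_in_90pct_all_subpops"
        _log(exclusions, vid, reason)
    kept = panel.subset(v.index[keep])
    return kept, eligibility.loc[keep], _exclusion_frame(exclusions)


def restrict_exonic_canonical(
    panel: PanelData,
) -> tuple[PanelData, pd.DataFrame]:
    """Keep exonic or splice-site variants on the canonical transcript."""
    v = panel.variants
    region_ok = v["region"].isin(["exonic", "splice"])
    keep = region_ok & v["canonical"].astype(bool)
    exclusions = [
        {
            "variant_id": vid,
            "reason": "non_canonical_transcript"
            if region_ok.loc[vid]
            else "non_exonic_region",
        }
        for vid in v.index[~keep]
    ]
    return panel.subset(v.index[keep]), _exclusion_frame(exclusions)


def apply_special_gene_rules(panel: PanelData) -> tuple[PanelData, pd.DataFrame]:
    """Gene-specific exclusions: HTT low-complexity calls and HLA-DRB5
    calls with a low-quality warning or in phase with other variants."""
    v = panel.variants
    htt_drop = v["gene"].eq("HTT") & v["low_complexity"].astype(bool)
    hla_drop = v["gene"].eq("HLA-DRB5") & (
        v["phase_warning"].astype(bool) | v["lowqual_warning"].astype(bool)
    )
    exclusions = [
        {"variant_id": vid, "reason": "HTT_low_complexity"}
        for vid in v.index[htt_drop]
    ] + [
        {"variant_id": vid, "reason": "HLA-DRB5_phase_or_quality_warning"}
        for vid in v.index[hla_drop]
    ]
    keep = ~(htt_drop | hla_drop)
    return panel.subset(v.index[keep]), _exclusion_frame(exclusions)


def _exclusion_frame(exclusions: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(exclusions, columns=["variant_id", "reason"])


# ---------------------------------------------------------------------------
# relatedness


def estimate_pihat(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Method-of-moments PI_HAT for every sample pair.

    ``genotypes`` holds biallelic dosages 0/1/2 with sites as rows and
    samples as columns.  Monomorphic sites are skipped.  For each pair,
    observed genome-wide IBS0/1/2 proportions are decomposed into
    IBD-state probabilities using their expectations given allele
    frequencies (the classical PLINK estimator); PI_HAT = P(IBD=2) +
    P(IBD=1)/2, clamped to [0, 1].
    """
    g = genotypes.to_numpy(dtype=np.int8)
    samples = list(genotypes.columns)
    p = g.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 100:
        logger.warning(
            "only %d informative sites; PI_HAT estimates are low-confidence",
            int(poly.sum()),
        )
    g = g[poly]
    p = p[poly]
    q = 1.0 - p
    m = len(p)
    if m == 0:
        raise ValueError("no polymorphic sites for IBD estimation")

    # expected IBS-state probabilities given IBD state, summed over sites
    e_ibs0_z0 = float(np.sum(2 * p**2 * q**2))
    e_ibs1_z0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e_ibs1_z1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e_ibs2_z0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e_ibs2_z1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    # indicator matrices for fast pairwise IBS counting
    ind = [(g == k).astype(np.float32) for k in (0, 1, 2)]
    n_ibs0 = ind[0].T @ ind[2] + ind[2].T @ ind[0]
    n_ibs2 = sum(a.T @ a for a in ind)

    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        c0 = float(n_ibs0[i, j])
        c2 = float(n_ibs2[i, j])
        c1 = m - c0 - c2
        z0 = c0 / e_ibs0_z0 if e_ibs0_z0 > 0 else 0.0
        z1 = (c1 - z0 * e_ibs1_z0) / e_ibs1_z1 if e_ibs1_z1 > 0 else 0.0
        z2 = (c2 - z0 * e_ibs2_z0 - z1 * e_ibs2_z1) / m
        pihat = z2 + 0.5 * z1
        rows.append((samples[i], samples[j], float(np.clip(pihat, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["sample1", "sample2", "pi_hat"])


def exclude_related(
    subjects: pd.DataFrame | list[str],
    kinship: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Greedy removal of one member of each pair with PI_HAT > threshold.

    Strictly-greater comparison; the sample participating in the most
    flagged pairs is dropped first, ties broken by subject id.  Returns
    (retained ids, removed ids).
    """
    if isinstance(subjects, pd.DataFrame):
        ids = list(subjects["subject_id"])
    else:
        ids = list(subjects)
    idset = set(ids)
    flagged = kinship[
        (kinship["pi_hat"] > threshold)
        & kinship["sample1"].isin(idset)
        & kinship["sample2"].isin(idset)
    ]
    edges = {
        frozenset((a, b))
        for a, b in zip(flagged["sample1"], flagged["sample2"])
        if a != b
    }
    removed: list[str] = []
    edges = set(edges)
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        worst = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        removed.append(worst)
        edges = {e for e in edges if worst not in e}
    retained = [s for s in ids if s not in set(removed)]
    return retained, sorted(removed)


def split_subpopulations(
    subjects: pd.DataFrame,
    labels: tuple[str, ...] = ANALYSIS_SUBPOPULATIONS,
) -> dict[str, list[str]]:
    """Partition subjects by self-reported ancestry into the analysis
    subpopulations; other labels are set aside (not analyzed)."""
    out: dict[str, list[str]] = {}
    for label in labels:
        out[label] = list(
            subjects.loc[subjects["ancestry"] == label, "subject_id"]
        )
    n_aside = len(subjects) - sum(len(v) for v in out.values())
    if n_aside:
        logger.info("%d subjects outside analysis subpopulations set aside",
                    n_aside)
    return out
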