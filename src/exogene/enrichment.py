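"""Allele-frequency enrichment against a matched reference population.

Each QC-surviving variant with at least one carrier in a subpopulation is
tested with a pooled-variance two-proportion z-test of the cohort allele
frequency against the matched reference (gnomAD-style) AC/AN entry
(European -> non-Finnish European, Hispanic -> Latino/Admixed American).
"Enriched" requires both a two-sided p below alpha and cohort frequency
above the reference frequency.  No allele-frequency floor or multiple-
testing correction is applied; variants absent from the reference table
are excluded (no enrichment score can be computed).  The same test
compares a replication PD cohort against its healthy controls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .vcfio import PanelData

__all__ = ["two_proportion_test", "enrich_all", "replication_test"]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def two_proportion_test(ac1, an1, ac2, an2):
    """Pooled-variance two-proportion z-test (vectorized).

    Returns ``(z, p)`` with a two-sided p from the normal tail, clamped
    to (1e-300, 1].  A pooled proportion of exactly 0 or 1 carries no
    evidence and yields z = 0, p = 1.
    """
    ac1 = np.asarray(ac1, dtype=float)
    an1 = np.asarray(an1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    an2 = np.asarray(an2, dtype=float)
    if np.any(an1 <= 0) or np.any(an2 <= 0):
        raise ValueError("allele numbers must be positive")
    if np.any(ac1 < 0) or np.any(ac1 > an1) or np.any(ac2 < 0) or np.any(ac2 > an2):
        raise ValueError("allele counts must satisfy 0 <= AC <= AN")
    p1 = ac1 / an1
    p2 = ac2 / an2
    pooled = (ac1 + ac2) / (an1 + an2)
    var = pooled * (1.0 - pooled) * (1.0 / an1 + 1.0 / an2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    p = np.where(var > 0, p, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def cohort_allele_counts(
    panel: PanelData,
    members: list[str],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Per-variant AC/AN over ``members``: AN = 2 x samples passing depth
    at the site, AC = alt-allele dosage summed over those samples."""
    members = [m for m in members if m in panel.genotypes.columns]
    gt = panel.genotypes[members].to_numpy()
    dp = panel.depth[members].to_numpy()
    ok = dp >= min_depth
    ac = np.where(ok, gt, 0).sum(axis=1)
    an = 2 * ok.sum(axis=1)
    return pd.DataFrame(
        {"cohort_ac": ac, "cohort_an": an}, index=panel.variant_ids
    )


def enrich_all(
    panel: PanelData,
    reference: pd.DataFrame,
    subpopulations: dict[str, list[str]],
    eligibility: pd.DataFrame | None = None,
    population_map: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Two-proportion enrichment of every variant x subpopulation.

    Only variants eligible in a subpopulation (per-subpopulation depth
    rule, if ``eligibility`` given) and with >= 1 carrier there are
    tested.  Returns one row per tested (variant, subpopulation) plus
    flagged-excluded rows for reference-absent variants.
    """
    population_map = population_map or {"European": "nfe", "Hispanic": "amr"}
    unknown = set(subpopulations) - set(population_map)
    if unknown:
        raise ValueError(f"no reference population mapped for {sorted(unknown)}")
    ref = reference.set_index(["variant_id", "population"])

    rows = []
    for label, members in subpopulations.items():
        if not members:
            logger.info("subpopulation %s empty; enrichment skipped", label)
            continue
        pop = population_map[label]
        counts = cohort_allele_counts(panel, members, min_depth=min_depth)
        for vid, row in counts.iterrows():
            if eligibility is not None and not bool(
                eligibility.loc[vid, label]
            ):
                continue
            ac, an = int(row["cohort_ac"]), int(row["cohort_an"])
            if ac == 0 or an == 0:
                continue
            key = (vid, pop)
            if key not in ref.index:
                rows.append(
                    {
                        "variant_id": vid,
                        "subpopulation": label,
                        "cohort_ac": ac,
                        "cohort_an": an,
                        "ref_ac": np.nan,
                        "ref_an": np.nan,
                        "cohort_freq": ac / an,
                        "ref_freq": np.nan,
                        "z": np.nan,
                        "p_value": np.nan,
                        "enriched": False,
                        "reference_absent": True,
                    }
                )
                continue
            rac, ran = (int(ref.loc[key, "AC"]), int(ref.loc[key, "AN"]))
            z, p = two_proportion_test(ac, an, rac, ran)
            cohort_freq = ac / an
            ref_freq = rac / ran
            rows.append(
                {
                    "variant_id": vid,
                    "subpopulation": label,
                    "cohort_ac": ac,
                    "cohort_an": an,
                    "ref_ac": rac,
                    "ref_an": ran,
                    "cohort_freq": cohort_freq,
                    "ref_freq": ref_freq,
                    "z": z,
                    "p_value": p,
                    "enriched": bool(p < alpha and cohort_freq > ref_freq),
                    "reference_absent": False,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "subpopulation", "cohort_ac", "cohort_an",
            "ref_ac", "ref_an", "cohort_freq", "ref_freq", "z", "p_value",
            "enriched", "reference_absent",
        ],
    )
    n_absent = int(out["reference_absent"].sum()) if len(out) else 0
    if n_absent:
        logger.info("%d variant tests skipped: absent from reference table",
                    n_absent)
    return out


def replication_test(
    variant_ids: list[str],
    pd_panel: PanelData,
    hc_panel: PanelData,
    alpha: float = 0.05,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Replicate prioritized variants in an independent case/control cohort.

    Variants absent from the replication call set are 'absent'
    (unevaluable); otherwise a pooled two-proportion test of PD vs HC
    allele frequency with the same alpha and direction rule yields
    'enriched' or 'not_enriched'.
    """
    pd_counts = cohort_allele_counts(pd_panel, pd_panel.samples, min_depth)
    hc_counts = cohort_allele_counts(hc_panel, hc_panel.samples, min_depth)
    rows = []
    for vid in variant_ids:
        present = (
            vid in pd_counts.index and int(pd_counts.loc[vid, "cohort_ac"]) > 0
        )
        if not present:
            rows.append({"variant_id": vid, "status": "absent",
                         "p_value": np.nan})
            continue
        ac1 = int(pd_counts.loc[vid, "cohort_ac"])
        an1 = int(pd_counts.loc[vid, "cohort_an"])
        if vid in hc_counts.index:
            ac2 = int(hc_counts.loc[vid, "cohort_ac"])
            an2 = int(hc_counts.loc[vid, "cohort_an"])
        else:
            ac2, an2 = 0, 2 * len(hc_panel.samples)
        z, p = two_proportion_test(ac1, an1, ac2, max(an2, 1))
        enriched = p < alpha and (ac1 / an1) > (ac2 / max(an2, 1))
        rows.append(
            {
                "variant_id": vid,
                "status": "enriched" if enriched else "not_enriched",
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "status", "p_value"])
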