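"""Calibration and recovery experiments over the synthetic pipeline.

These drive the generator + analysis chain under controlled conditions:
the null enrichment simulation (no planted variants, fold 1) for type-I
error, slope-recovery correlation for the progression score, and
planted-variant recovery through the full pipeline.
"""

from __future__ import annotations

import numpy as np

from . import enrichment as enr
from . import qc
from .config import SimulationConfig
from .pipeline import PipelineResult, run_all
from .progression import progression_scores
from .simulate import generate_panel, generate_subjects

__all__ = [
    "null_enrichment_rate",
    "slope_recovery_correlation",
    "planted_recovery",
]


def null_enrichment_rate(
    n_reps: int = 200,
    n_subjects: int = 320,
    n_variants: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[int, int]:
    """Fraction of variants flagged enriched under the null.

    Simulates ``n_reps`` panels with enrichment_fold = 1 (nothing
    planted; cohort genotypes drawn at the matched reference frequency)
    and counts enrichment flags.  Returns (n_flagged, n_tested).
    """
    base = SimulationConfig(
        n_subjects=n_subjects,
        subpop_fractions={"European": 1.0},
        n_background_variants=n_variants,
        n_planted_variants=0,
        enrichment_fold=1.0,
        reference_absent_fraction=0.0,
        low_depth_fraction=0.0,
        fail_filter_fraction=0.0,
        low_qual_fraction=0.0,
        n_related_pairs=0,
        n_relatedness_sites=50,
        seed=seed,
    )
    flagged = tested = 0
    for r in range(n_reps):
        cfg = base.replace(seed=seed + 10_000 + r)
        subjects, _, truth = generate_subjects(cfg)
        panel, reference, _, _ = generate_panel(cfg, subjects, truth)
        subpops = qc.split_subpopulations(subjects)
        table = enr.enrich_all(panel, reference, subpops, alpha=alpha)
        table = table[~table["reference_absent"]]
        flagged += int(table["enriched"].sum())
        tested += len(table)
    return flagged, tested


def slope_recovery_correlation(
    n_subjects: int = 400, seed: int = 0, config: SimulationConfig | None = None
) -> float:
    """Correlation between true random slopes and the progression display
    score at default generator settings."""
    cfg = config or SimulationConfig(n_subjects=n_subjects, seed=seed)
    subjects, visits, truth = generate_subjects(cfg)
    scores, _ = progression_scores(visits, subjects)
    scored = scores.set_index("subject_id")["display_score"]
    true = np.array([truth.true_slopes[s] for s in scored.index])
    return float(np.corrcoef(true, scored.to_numpy())[0, 1])


def planted_recovery(result: PipelineResult) -> dict:
    """Recovery summary for a finished pipeline run.

    Planted variants absent from the reference table are unevaluable by
    design (no enrichment score exists) and are excluded from the
    denominator.  Also reports PI_HAT for the planted related pairs and
    whether the relatedness filter removed them, and the rate at which
    background variants leak into the prioritized set.
    """
    truth = result.cohort.truth
    evaluable = [
        v
        for v in truth.planted_variant_ids
        if v not in set(truth.planted_reference_absent)
    ]
    got = set(result.prioritized["variant_id"])
    n_recovered = sum(v in got for v in evaluable)

    kin = result.kinship.set_index(["sample1", "sample2"])["pi_hat"]
    pairs = []
    for a, b, expected in truth.related_pairs:
        pihat = kin.get((a, b), kin.get((b, a), np.nan))
        removed = a in result.related_removed or b in result.related_removed
        pairs.append(
            {"expected": expected, "pi_hat": float(pihat), "removed": removed}
        )

    background = set(result.cohort.panel.variant_ids) - set(
        truth.planted_variant_ids
    )
    n_background_prioritized = len(got & background)
    return {
        "n_planted": len(truth.planted_variant_ids),
        "n_evaluable": len(evaluable),
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / len(evaluable) if evaluable else np.nan,
        "pairs": pairs,
        "n_background_prioritized": n_background_prioritized,
        "n_background": len(background),
    }
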