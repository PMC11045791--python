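"""Long-term pesticide exposure averaging, co-exposure clustering and the
SD-scaled weighted cluster exposure score.

The exposure window runs from 1974 to ten years before PD diagnosis
(prodromal lag).  Annual lbs/acre records are averaged over the whole
window, counting years without an application as zero, separately for
residential and workplace locations.  Co-application clusters are found
by average-linkage hierarchical clustering on 1 - Pearson r of the
per-subject long-term averages, cut so merged groups correlate above the
cut-point (default R > 0.45).  The cluster score is the sum over member
pesticides and both locations of beta x log(1 + mean lbs/acre)/SD, then
itself scaled to cohort SD; the display scale anchors the cohort mean
at 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import ClusterDefinition, ExposureWindow

__all__ = [
    "longterm_average",
    "correlation_cluster",
    "weighted_cluster_score",
]

logger = logging.getLogger(__name__)


def longterm_average(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    window: ExposureWindow | None = None,
) -> pd.DataFrame:
    """Average annual lbs/acre over each subject's exposure window.

    One row per subject x pesticide x location over the full grid;
    absent years count as zero, so the mean is (sum over in-window
    records) / (window length in years).  Subjects whose window is
    empty (diagnosis too early, or missing diagnosis year) are flagged
    ``unexposable`` and carry no rows.

    Returns a DataFrame with columns subject_id, pesticide,
    location_type, mean_lbs_per_acre and attrs["unexposable"] listing
    excluded subjects.
    """
    window = window or ExposureWindow()
    diag = subjects.set_index("subject_id")["diagnosis_year"]
    end = (diag - window.lag_years).astype("float")
    length = end - window.start_year + 1
    unexposable = sorted(
        diag.index[(length < 1) | diag.isna()].tolist()
    )
    if unexposable:
        logger.warning("%d subjects with empty exposure window excluded",
                       len(unexposable))
    ok_subjects = [s for s in diag.index if s not in set(unexposable)]

    pesticides = sorted(records["pesticide"].unique()) if len(records) else []
    locations = ["residential", "workplace"]

    rec = records.merge(
        end.rename("end_year"), left_on="subject_id", right_index=True
    )
    rec = rec[
        (rec["year"] >= window.start_year) & (rec["year"] <= rec["end_year"])
    ]
    sums = (
        rec.groupby(["subject_id", "pesticide", "location_type"])["lbs_per_acre"]
        .sum()
    )

    grid = pd.MultiIndex.from_product(
        [ok_subjects, pesticides, locations],
        names=["subject_id", "pesticide", "location_type"],
    )
    total = sums.reindex(grid, fill_value=0.0)
    out = total.reset_index(name="total")
    out["mean_lbs_per_acre"] = out["total"] / out["subject_id"].map(length)
    out = out.drop(columns="total")
    out.attrs["unexposable"] = unexposable
    return out


def _wide_averages(longterm: pd.DataFrame) -> pd.DataFrame:
    """Subject x pesticide matrix of long-term averages, locations summed."""
    return (
        longterm.groupby(["subject_id", "pesticide"])["mean_lbs_per_acre"]
        .sum()
        .unstack(fill_value=0.0)
    )


def correlation_cluster(
    longterm: pd.DataFrame, cutpoint: float = 0.45
) -> list[ClusterDefinition]:
    """Co-exposure clusters by average-linkage correlation clustering.

    Distance is 1 - Pearson r between per-subject long-term averages
    (residential + workplace summed); the tree is cut so that merged
    groups have linkage correlation strictly above ``cutpoint``.
    Zero-variance pesticides are excluded with a warning.  Singletons
    are allowed.
    """
    wide = _wide_averages(longterm)
    if wide.shape[1] < 2 or wide.shape[0] < 3:
        raise ValueError("need >= 2 pesticides and >= 3 subjects")
    sd = wide.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("excluding zero-variance pesticides: %s", dropped)
    wide = wide.drop(columns=dropped)
    names = list(wide.columns)
    if len(names) < 2:
        return [ClusterDefinition(f"cluster_{i + 1}", [n])
                for i, n in enumerate(names)]

    corr = np.corrcoef(wide.to_numpy(), rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry
    z = linkage(squareform(dist, checks=False), method="average")
    # merge only while linkage correlation > cutpoint, i.e. height < 1-cutpoint
    height = (1.0 - cutpoint) * (1.0 - 1e-12)
    labels = fcluster(z, t=height, criterion="distance")

    clusters: list[ClusterDefinition] = []
    for k, lab in enumerate(sorted(set(labels))):
        members = [names[i] for i in range(len(names)) if labels[i] == lab]
        clusters.append(ClusterDefinition(f"cluster_{k + 1}", sorted(members)))
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    for i, c in enumerate(clusters):
        c.cluster_id = f"cluster_{i + 1}"
    return clusters


def weighted_cluster_score(
    longterm: pd.DataFrame,
    cluster: ClusterDefinition,
    cohort: list[str] | pd.Index | None = None,
) -> pd.DataFrame:
    """Toxicity-weighted, SD-scaled cluster exposure score per subject.

    For each member pesticide and each location: t = log(1 + mean
    lbs/acre); z = t / SD(t over the cohort) (uncentered, preserving the
    natural zero of "no exposure"); the raw weighted sum is sum of
    beta * z, entering residential and workplace separately so dual-site
    exposure scores highest.  ``scaled_score`` divides by the cohort SD
    of the raw sum; ``display_score`` = 1 + (scaled - cohort mean of
    scaled), so 1 is the cohort reference level.
    """
    betas = cluster.require_betas()
    df = longterm[longterm["pesticide"].isin(cluster.members)]
    wide = df.pivot_table(
        index="subject_id",
        columns=["pesticide", "location_type"],
        values="mean_lbs_per_acre",
        fill_value=0.0,
    )
    if cohort is not None:
        cohort_idx = pd.Index(cohort).intersection(wide.index)
        wide = wide.loc[cohort_idx]
    t = np.log1p(wide.to_numpy(dtype=float))
    sd = t.std(axis=0, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        logger.warning(
            "%d pesticide-location terms with zero cohort SD contribute 0",
            int(degenerate.sum()),
        )
    z = np.zeros_like(t)
    z[:, ~degenerate] = t[:, ~degenerate] / sd[~degenerate]
    w = np.array([betas[p] for p, _loc in wide.columns])
    raw = z @ w

    raw_sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    if raw_sd > 0:
        scaled = raw / raw_sd
        display = 1.0 + (scaled - scaled.mean())
    else:
        logger.warning("degenerate exposure distribution; scores set to 0")
        scaled = np.zeros_like(raw)
        display = np.ones_like(raw)
    return pd.DataFrame(
        {
            "subject_id": wide.index,
            "raw_weighted_sum": raw,
            "scaled_score": scaled,
            "display_score": display,
        }
    ).reset_index(drop=True)
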