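"""Synthetic case-only cohort generator.

Emulates the inputs of the gene-environment pipeline with known ground
truth: a two-ancestry PD cohort with longitudinal UPDRS-III visits driven
by true random intercepts/slopes, ambient pesticide application records
with correlated co-application clusters (a 10-member "cotton" cluster),
a panel variant call set in which a configurable number of variants are
planted at an allele frequency inflated over a gnomAD-style reference
table with carriers biased toward high exposure and fast progression, and
a biallelic SNP matrix carrying planted related pairs for the IBD filter.

Every stage derives its random stream from ``config.seed`` through
independent spawned generators, so outputs are reproducible and
stage-order independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ClusterDefinition, InvalidConfigError, SimulationConfig
from .vcfio import PanelData

__all__ = [
    "TruthBundle",
    "SyntheticCohort",
    "generate_subjects",
    "generate_applications",
    "generate_panel",
    "generate_cohort",
]

# Named members of the co-applied cotton-crop pesticide cluster; extended
# with generated names if the configured cluster is larger.
COTTON_PESTICIDES = [
    "trifluralin", "tribufos", "sodium_cacodylate", "prometryn", "phorate",
    "aldicarb", "methyl_parathion", "dicrotophos", "cyanazine", "naled",
]

# Gene pools per selection group: known PD risk genes (1), strict lysosomal
# function (2), lysosomal PD-interactors (3), high nigral expression (4),
# other lysosomal storage disorder genes (5).
_GENE_POOLS = {
    1: ["HTT", "HLA-DRB5", "SNCA", "LRRK2", "PRKN", "PINK1", "PARK7",
        "VPS35", "GBA1", "MAPT", "GAK", "HIP1R", "ACMSD", "MCCC1"],
    2: ["CTSD", "LAMP1", "LAMP3", "SMPD1", "MCOLN1", "NPC1", "ACP2",
        "BLOC1S1", "ATG4C", "TSC1", "ASAH1", "CTSB", "ATP13A2"],
    3: ["EP300", "HDAC6", "APP", "BAG6", "FBXO7", "NPC2", "SQSTM1",
        "VPS13C", "TFEB", "RAB7A", "DNAJC6", "SYNJ1", "ATG5", "ATG7",
        "ULK1", "BECN1", "WIPI2", "PLA2G6"],
    4: [f"NIG{i:02d}" for i in range(1, 37)],
    5: ["GALC", "GNPTAB", "SLC17A5", "GUSB"],
}

_BASES = np.array(list("ACGT"))


@dataclass
class TruthBundle:
    """Ground truth recorded by the generator for recovery testing."""

    true_slopes: dict[str, float] = field(default_factory=dict)
    true_intercepts: dict[str, float] = field(default_factory=dict)
    true_exposure_sums: dict[str, float] = field(default_factory=dict)
    planted_variant_ids: list[str] = field(default_factory=list)
    planted_carrier_sets: dict[str, list[str]] = field(default_factory=dict)
    planted_reference_absent: list[str] = field(default_factory=list)
    related_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_clusters: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "true_slopes": self.true_slopes,
            "true_intercepts": self.true_intercepts,
            "true_exposure_sums": self.true_exposure_sums,
            "planted_variant_ids": self.planted_variant_ids,
            "planted_carrier_sets": self.planted_carrier_sets,
            "planted_reference_absent": self.planted_reference_absent,
            "related_pairs": [list(p) for p in self.related_pairs],
            "true_clusters": self.true_clusters,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    def validate(self) -> None:
        for vid in self.planted_variant_ids:
            if not self.planted_carrier_sets.get(vid):
                raise AssertionError(f"planted variant {vid} has no carrier")
        for _, _, pihat in self.related_pairs:
            if pihat not in (0.5, 1.0):
                raise AssertionError("expected_pihat must be 0.5 or 1.0")


@dataclass
class SyntheticCohort:
    """All generated pipeline inputs plus ground truth."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    applications: pd.DataFrame
    panel: PanelData
    reference: pd.DataFrame
    gene_panel: pd.DataFrame
    relatedness_genotypes: pd.DataFrame
    cluster_spec: ClusterDefinition
    truth: TruthBundle


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(8)[stage]
    )


def _pesticide_names(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Pesticide names partitioned into clusters; cluster 'cotton' first."""
    cotton = [
        COTTON_PESTICIDES[i] if i < len(COTTON_PESTICIDES) else f"cotton_x{i:02d}"
        for i in range(config.cotton_cluster_size)
    ]
    n_other = config.n_pesticides - config.cotton_cluster_size
    others = [f"pest_{i:02d}" for i in range(1, n_other + 1)]
    clusters: dict[str, list[str]] = {"cotton": cotton}
    n_other_clusters = max(config.n_clusters - 1, 1)
    for k in range(n_other_clusters):
        clusters[f"cluster_{k + 1}"] = []
    for i, p in enumerate(others):
        clusters[f"cluster_{(i % n_other_clusters) + 1}"].append(p)
    clusters = {k: v for k, v in clusters.items() if v}
    return cotton + others, clusters


# ---------------------------------------------------------------------------
# subjects & visits


def generate_subjects(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Draw demographics, true random effects and longitudinal visits.

    UPDRS-III at visit t is the fixed-effect linear predictor plus
    ``b0_i + b1_i * t`` plus residual noise; the true slopes go into the
    returned :class:`TruthBundle`.
    """
    if config.n_subjects <= 0:  # defensive; config validates too
        raise InvalidConfigError("n_subjects must be positive")
    rng = _rng(config, 0)
    n = config.n_subjects
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    labels = list(config.subpop_fractions)
    probs = np.array([config.subpop_fractions[l] for l in labels])
    ancestry = rng.choice(labels, size=n, p=probs / probs.sum())
    sex = np.where(rng.random(n) < 0.62, "M", "F")
    age_dx = np.clip(rng.normal(67.7, 10.6, n), 23, 89).round(1)
    wave = np.where(rng.random(n) < 0.6, 1, 2)
    enroll = np.where(
        wave == 1, rng.integers(2001, 2008, n), rng.integers(2010, 2015, n)
    )
    duration = np.clip(rng.normal(2.9, 2.5, n), 0.0, 15.0).round(1)
    diagnosis_year = enroll - np.round(duration).astype(int)
    education = np.clip(rng.normal(12, 4, n), 0, 20).round().astype(int)
    family_history = (rng.random(n) < 0.15).astype(int)
    zero_exposure = rng.random(n) < config.zero_exposure_fraction
    workplace_zero = rng.random(n) < config.workplace_zero_fraction

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "ancestry": ancestry,
            "sex": sex,
            "age_at_diagnosis": age_dx,
            "diagnosis_year": diagnosis_year,
            "pd_duration_baseline": duration,
            "education_years": education,
            "family_history": family_history,
            "study_wave": wave,
            "zero_exposure": zero_exposure.astype(int),
            "workplace_zero": workplace_zero.astype(int),
        }
    )

    b0 = rng.normal(0.0, config.intercept_sd, n)
    b1 = rng.normal(0.0, config.slope_sd, n)
    fe = config.fixed_effects
    linpred = (
        fe.get("intercept", 0.0)
        + fe.get("age_at_diagnosis", 0.0) * age_dx
        + fe.get("male", 0.0) * (sex == "M")
        + fe.get("hispanic", 0.0) * (ancestry == "Hispanic")
        + fe.get("pd_duration_baseline", 0.0) * duration
        + fe.get("family_history", 0.0) * family_history
        + fe.get("education_years", 0.0) * education
        + fe.get("study_wave", 0.0) * wave
    )

    retain = rng.random((n, max(config.n_visits_max - 1, 0)))
    rows = []
    for i in range(n):
        visits_i = [0] + [
            t
            for t in range(1, config.n_visits_max)
            if retain[i, t - 1] < config.dropout_retain_prob
        ]
        for t in visits_i:
            y = (
                linpred[i]
                + fe.get("visit", 0.0) * t
                + b0[i]
                + b1[i] * t
                + rng.normal(0.0, config.resid_sd)
            )
            rows.append((ids[i], t, round(float(y), 3)))
    visits = pd.DataFrame(rows, columns=["subject_id", "visit", "updrs3"])

    truth = TruthBundle(
        true_slopes=dict(zip(ids, b1.round(6))),
        true_intercepts=dict(zip(ids, b0.round(6))),
    )
    return subjects, visits, truth


# ---------------------------------------------------------------------------
# pesticide applications


def _log_scale_corr(target: float, sigma: float) -> float:
    """Log-scale latent loading whose lognormal exp-scale correlation is
    ``target`` (inverts the standard lognormal correlation attenuation)."""
    if target <= 0:
        return 0.0
    return float(np.log1p(target * np.expm1(sigma**2)) / sigma**2)


def generate_applications(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    truth: TruthBundle | None = None,
    start_year: int = 1974,
) -> pd.DataFrame:
    """Per-subject, per-location, per-year pesticide poundage records.

    Pesticides in the same cluster load on a shared subject-level latent
    factor so that long-term-average correlations within a cluster reach
    ``within_cluster_corr`` while cross-cluster correlations are near
    zero.  Only nonzero records are emitted (years with no application
    are implicitly zero).  The subject's cotton-cluster latent factor is
    recorded in ``truth.true_exposure_sums``.
    """
    rng = _rng(config, 1)
    names, clusters = _pesticide_names(config)
    n = len(subjects)
    sigma = 0.5
    rho_log = _log_scale_corr(config.within_cluster_corr, sigma)

    # subject x cluster latent factors
    cluster_names = list(clusters)
    g = rng.standard_normal((n, len(cluster_names)))
    pesticide_cluster = {
        p: ci for ci, cname in enumerate(cluster_names) for p in clusters[cname]
    }
    # per-pesticide intensity scale (lbs/acre magnitude differs by product)
    scale = np.exp(rng.normal(0.0, 0.7, len(names))) * 1.5

    # long-term mean intensity per subject x pesticide
    e = rng.standard_normal((n, len(names)))
    base = np.empty((n, len(names)))
    for j, p in enumerate(names):
        ci = pesticide_cluster[p]
        base[:, j] = np.sqrt(rho_log) * g[:, ci] + np.sqrt(1 - rho_log) * e[:, j]
    mean_intensity = np.exp(sigma * base) * scale

    zero_mask = subjects["zero_exposure"].to_numpy().astype(bool)
    wz = subjects["workplace_zero"].to_numpy().astype(bool)
    diag = subjects["diagnosis_year"].to_numpy()
    ids = subjects["subject_id"].to_numpy()

    frames = []
    for i in range(n):
        if zero_mask[i]:
            continue
        years = np.arange(start_year, diag[i] + 1)
        if len(years) == 0:
            continue
        for loc, amp in (("residential", 1.0), ("workplace", 0.5)):
            if loc == "workplace" and wz[i]:
                continue
            loc_noise = np.exp(rng.normal(0.0, 0.1, len(names)))
            applied = rng.random((len(years), len(names))) < config.application_prob
            amounts = (
                mean_intensity[i][None, :]
                * amp
                * loc_noise[None, :]
                * rng.gamma(8.0, 1.0 / 8.0, size=(len(years), len(names)))
            )
            amounts = np.where(applied, amounts, 0.0)
            yy, jj = np.nonzero(amounts)
            if len(yy) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": ids[i],
                        "location_type": loc,
                        "year": years[yy],
                        "pesticide": np.asarray(names)[jj],
                        "lbs_per_acre": amounts[yy, jj].round(5),
                    }
                )
            )
    if frames:
        applications = pd.concat(frames, ignore_index=True)
    else:
        applications = pd.DataFrame(
            columns=["subject_id", "location_type", "year", "pesticide", "lbs_per_acre"]
        )

    if truth is not None:
        cotton_idx = cluster_names.index("cotton")
        latent = np.where(zero_mask, -3.0, g[:, cotton_idx])
        truth.true_exposure_sums = dict(zip(ids, np.round(latent, 6)))
        truth.true_clusters = {k: list(v) for k, v in clusters.items()}
    return applications


def default_cluster_spec(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ClusterDefinition:
    """Cotton cluster with synthetic PD log-odds beta weights."""
    rng = rng or _rng(config, 5)
    members, _ = _pesticide_names(config)
    cotton = members[: config.cotton_cluster_size]
    betas = {p: round(float(b), 4) for p, b in zip(cotton, rng.uniform(0.1, 0.5, len(cotton)))}
    return ClusterDefinition("cotton", cotton, betas)


# ---------------------------------------------------------------------------
# variant panel, reference table, relatedness matrix


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    genes, groups = [], []
    for gi, size in enumerate(config.group_sizes, start=1):
        pool = _GENE_POOLS.get(gi, [])
        for k in range(size):
            name = pool[k] if k < len(pool) else f"G{gi}X{k + 1:02d}"
            genes.append(name)
            groups.append(gi)
    return pd.DataFrame({"gene": genes, "group": groups})


def generate_panel(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    truth: TruthBundle,
) -> tuple[PanelData, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Panel call set, reference AC/AN table, gene panel and SNP matrix.

    Background variants carry cohort allele frequencies equal to their
    reference frequency; planted variants are ``enrichment_fold`` times
    more frequent in their designated subpopulation, with carriers drawn
    with weight ``exp(bias * (exposure_z + slope_z))``.  Related pairs are
    planted in the separate biallelic SNP matrix used for kinship
    estimation (duplicate => expected PI_HAT 1.0, parent-offspring
    mixing => 0.5).

    Returns ``(panel, reference, gene_panel, relatedness_genotypes)``.
    """
    if config.enrichment_fold <= 1.0 and config.n_planted_variants > 0:
        raise InvalidConfigError(
            "enrichment_fold must exceed 1 when planting enriched variants"
        )
    rng = _rng(config, 2)
    gene_panel = _gene_table(config)
    ids = subjects["subject_id"].to_numpy()
    n = len(ids)
    n_bg = config.n_background_variants
    n_pl = config.n_planted_variants
    n_var = n_bg + n_pl

    # gene assignment; planted variants avoid HTT/HLA-DRB5 (special rules)
    safe_genes = gene_panel[~gene_panel["gene"].isin(["HTT", "HLA-DRB5"])]
    gene_idx_bg = rng.integers(0, len(gene_panel), n_bg)
    gene_idx_pl = rng.integers(0, len(safe_genes), n_pl)
    gene_bg = gene_panel.iloc[gene_idx_bg]
    gene_pl = safe_genes.iloc[gene_idx_pl]
    gene = np.concatenate([gene_bg["gene"].to_numpy(), gene_pl["gene"].to_numpy()])
    group = np.concatenate([gene_bg["group"].to_numpy(), gene_pl["group"].to_numpy()])

    pos = (np.arange(n_var) + 1) * 1000 + rng.integers(0, 999, n_var)
    ref_base = _BASES[rng.integers(0, 4, n_var)]
    alt_base = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref_base]
    )
    chrom = np.full(n_var, "1")
    vids = np.array(
        [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref_base, alt_base)]
    )

    # reference frequencies (per matched population)
    # background reference frequencies: log-uniform over MAF 1e-3 .. 0.2.
    # Rarer variants are below what a ~640-allele cohort can measure, and
    # the pooled z-test is anti-conservative for singleton observations of
    # ultra-rare alleles (see docs/methods.md).
    freq_bg = 10 ** rng.uniform(-3.0, -0.7, n_bg)
    freq_pl = rng.uniform(0.003, 0.01, n_pl)
    base_freq = np.concatenate([freq_bg, freq_pl])
    pop_an = {"nfe": 113000, "amr": 35000}
    absent = rng.random(n_var) < config.reference_absent_fraction
    # per-population reference frequencies (mild divergence between pops);
    # the written AC/AN and the cohort genotype draws use the SAME values,
    # so background variants are exactly null against their matched pop
    pop_freq: dict[str, np.ndarray] = {}
    ref_rows = []
    for pop, an in pop_an.items():
        pf = base_freq * np.exp(rng.normal(0.0, 0.2, n_var))
        ac = np.maximum(np.round(pf * an), 1).astype(int)
        pop_freq[pop] = ac / an  # frequency as actually recorded
        for k in range(n_var):
            if absent[k]:
                continue
            ref_rows.append((vids[k], pop, int(ac[k]), an))
    reference = pd.DataFrame(ref_rows, columns=["variant_id", "population", "AC", "AN"])

    # genotypes: background at matched-population reference frequency (HWE)
    pop_of_subject = np.where(subjects["ancestry"].to_numpy() == "Hispanic", "amr", "nfe")
    geno = np.zeros((n_var, n), dtype=np.int8)
    for pop in ("nfe", "amr"):
        mask = pop_of_subject == pop
        if mask.sum() == 0:
            continue
        pf = pop_freq[pop][:n_bg]
        geno[:n_bg, mask] = rng.binomial(
            2, np.tile(pf[:, None], (1, mask.sum()))
        ).astype(np.int8)

    # planted variants: tilted carrier sampling within a designated subpop
    slope_z = _standardize(
        np.array([truth.true_slopes[s] for s in ids], dtype=float)
    )
    expo_z = _standardize(
        np.array(
            [truth.true_exposure_sums.get(s, 0.0) for s in ids], dtype=float
        )
    )
    tilt = np.exp(
        config.exposure_progression_bias * (expo_z + slope_z)
    )
    subpops = subjects["ancestry"].to_numpy()
    labels = list(config.subpop_fractions)
    label_probs = np.array([config.subpop_fractions[l] for l in labels])
    planted_ids, carrier_sets = [], {}
    for k in range(n_pl):
        vrow = n_bg + k
        label = rng.choice(labels, p=label_probs / label_probs.sum())
        members = np.where(subpops == label)[0]
        matched_pop = "amr" if label == "Hispanic" else "nfe"
        # het carriers: allele freq f => AC = m over AN = 2N, so m = 2Nf
        f_cohort = min(
            config.enrichment_fold * pop_freq[matched_pop][vrow], 0.25
        )
        m = max(1, min(int(round(f_cohort * 2 * len(members))), len(members)))
        w = tilt[members]
        carriers = rng.choice(members, size=m, replace=False, p=w / w.sum())
        geno[vrow, carriers] = 1
        planted_ids.append(vids[vrow])
        carrier_sets[vids[vrow]] = [ids[c] for c in sorted(carriers)]
    truth.planted_variant_ids = planted_ids
    truth.planted_carrier_sets = carrier_sets
    truth.planted_reference_absent = [
        vids[n_bg + k] for k in range(n_pl) if absent[n_bg + k]
    ]

    # annotations
    region = rng.choice(
        ["exonic", "splice", "intronic"], size=n_var, p=[0.7, 0.1, 0.2]
    )
    canonical = rng.random(n_var) < 0.9
    region[n_bg:] = rng.choice(["exonic", "splice"], size=n_pl, p=[0.9, 0.1])
    canonical[n_bg:] = True

    cadd = _cadd_mixture(rng, n_bg, probs=(0.6, 0.3, 0.1))
    cadd_pl = _cadd_mixture(rng, n_pl, probs=(5 / 36, 11 / 36, 20 / 36))
    cadd = np.concatenate([cadd, cadd_pl])
    cadd[rng.random(n_var) < 0.05] = np.nan

    qual = rng.uniform(100, 3000, n_var)
    lowq = rng.random(n_var) < config.low_qual_fraction
    qual[lowq] = rng.uniform(5, 29.9, lowq.sum())
    filt = np.where(rng.random(n_var) < config.fail_filter_fraction, "LowQ", "PASS")
    qual[n_bg:] = rng.uniform(500, 3000, n_pl)
    filt[n_bg:] = "PASS"

    mean_depth = np.maximum(rng.normal(config.mean_depth, 15, n_var), 20)
    low_dp = rng.random(n_var) < config.low_depth_fraction
    mean_depth[low_dp] = 8.0
    mean_depth[n_bg:] = np.maximum(mean_depth[n_bg:], 40)
    depth = rng.poisson(np.tile(mean_depth[:, None], (1, n))).astype(np.int32)

    is_htt = gene == "HTT"
    is_hla = gene == "HLA-DRB5"
    low_complexity = rng.random(n_var) < np.where(is_htt, 0.3, 0.02)
    phase_warning = rng.random(n_var) < np.where(is_hla, 0.2, 0.02)
    lowqual_warning = rng.random(n_var) < np.where(is_hla, 0.2, 0.02)
    low_complexity[n_bg:] = False
    phase_warning[n_bg:] = False
    lowqual_warning[n_bg:] = False

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref_base,
            "alt": alt_base,
            "gene": gene,
            "group": group,
            "region": region,
            "canonical": canonical,
            "cadd": np.round(cadd, 2),
            "qual": np.round(qual, 1),
            "filter": filt,
            "low_complexity": low_complexity,
            "phase_warning": phase_warning,
            "lowqual_warning": lowqual_warning,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    panel = PanelData(
        variants,
        pd.DataFrame(geno, index=variants.index, columns=ids),
        pd.DataFrame(depth, index=variants.index, columns=ids),
    )

    relatedness = _relatedness_matrix(config, rng, ids, truth)
    truth.validate()
    return panel, reference, gene_panel, relatedness


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _cadd_mixture(rng, n, probs) -> np.ndarray:
    """CADD scores from a 3-bin mixture: [0,10), [10,20], (20,35]."""
    bins = rng.choice(3, size=n, p=list(probs))
    out = np.empty(n)
    out[bins == 0] = rng.uniform(0, 9.99, (bins == 0).sum())
    out[bins == 1] = rng.uniform(10, 20, (bins == 1).sum())
    out[bins == 2] = rng.uniform(20.01, 35, (bins == 2).sum())
    return out


def _relatedness_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    ids: np.ndarray,
    truth: TruthBundle,
) -> pd.DataFrame:
    """Biallelic SNP dosage matrix (sites x samples) with planted pairs."""
    m = config.n_relatedness_sites
    n = len(ids)
    p = rng.uniform(0.05, 0.5, m)
    geno = rng.binomial(2, np.tile(p[:, None], (1, n))).astype(np.int8)

    pairs = []
    n_pairs = min(config.n_related_pairs, n // 2)
    chosen = rng.choice(n, size=2 * n_pairs, replace=False)
    for k in range(n_pairs):
        a, b = chosen[2 * k], chosen[2 * k + 1]
        if k % 2 == 0:
            geno[:, b] = geno[:, a]  # duplicate / MZ twin
            expected = 1.0
        else:
            transmitted = rng.binomial(1, geno[:, a] / 2.0)
            untransmitted = rng.binomial(1, p)
            geno[:, b] = (transmitted + untransmitted).astype(np.int8)
            expected = 0.5
        pairs.append((str(ids[a]), str(ids[b]), expected))
    truth.related_pairs = pairs

    site_ids = [f"rs{100000 + i}" for i in range(m)]
    return pd.DataFrame(geno, index=pd.Index(site_ids, name="site_id"), columns=ids)


def generate_replication(
    config: SimulationConfig,
    panel: PanelData,
    reference: pd.DataFrame,
    truth: TruthBundle,
    n_pd: int = 496,
    n_hc: int = 192,
    presence_prob: float = 0.4,
) -> tuple[PanelData, PanelData]:
    """Independent case/control replication cohort over the same variants.

    Each panel variant is present in the replication data with
    probability ``presence_prob`` (absent variants are unevaluable
    downstream).  Present background variants are drawn at reference
    frequency in both arms; present planted variants keep their
    enrichment fold in the PD arm only.
    """
    rng = _rng(config, 3)
    vids = panel.variant_ids
    ref_freq = (
        reference[reference["population"] == "nfe"]
        .set_index("variant_id")
        .assign(freq=lambda d: d["AC"] / d["AN"])["freq"]
        .reindex(vids)
    )
    # reference-absent variants still exist; give them a rare frequency
    ref_freq = ref_freq.fillna(0.001).to_numpy()
    present = rng.random(len(vids)) < presence_prob
    planted = vids.isin(truth.planted_variant_ids)
    f_pd = np.where(
        planted, np.minimum(config.enrichment_fold * ref_freq, 0.25), ref_freq
    )
    f_hc = ref_freq
    f_pd = np.where(present, f_pd, 0.0)
    f_hc = np.where(present, f_hc, 0.0)

    def _arm(freqs: np.ndarray, n: int, prefix: str) -> PanelData:
        geno = rng.binomial(2, np.tile(freqs[:, None], (1, n))).astype(np.int8)
        samples = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
        depth = np.full_like(geno, 50, dtype=np.int32)
        return PanelData(
            panel.variants.copy(),
            pd.DataFrame(geno, index=vids, columns=samples),
            pd.DataFrame(depth, index=vids, columns=samples),
        )

    return _arm(f_pd, n_pd, "RPD"), _arm(f_hc, n_hc, "RHC")


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run all generator stages and bundle the outputs."""
    subjects, visits, truth = generate_subjects(config)
    applications = generate_applications(config, subjects, truth)
    panel, reference, gene_panel, relatedness = generate_panel(
        config, subjects, truth
    )
    cluster_spec = default_cluster_spec(config)
    return SyntheticCohort(
        subjects=subjects,
        visits=visits,
        applications=applications,
        panel=panel,
        reference=reference,
        gene_panel=gene_panel,
        relatedness_genotypes=relatedness,
        cluster_spec=cluster_spec,
        truth=truth,
    )
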