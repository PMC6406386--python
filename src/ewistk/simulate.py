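"""Synthetic methylation cohorts with planted BMI x methylation interactions.

Emulates a nested case-control methylome study: a 450K-style CpG manifest
with clustered probe positions, non-overlapping gene models tiling the CpG
clusters, mutually exclusive pathway gene sets, beta values built from a
cell-mixture mean plus shared latent batch factors (which also drive the 220
control probes) plus individual noise, and disease status drawn from a
logistic model containing planted gamma_i * exposure * beta_i interaction
terms. Cases and controls are then subsampled to exact target counts, so the
planted log-odds interactions are recoverable by downstream case-control
fits.

Everything is driven by one `numpy.random.Generator` seeded from
`SimDesign.seed`; a fixed seed reproduces the full bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

CELL_TYPES = ("Bcell", "CD4T", "CD8T", "NK", "Mono", "Eos", "Neu")
# typical whole-blood leukocyte composition used as the Dirichlet mean
_CELL_MEANS = np.array([0.05, 0.15, 0.10, 0.06, 0.08, 0.03, 0.53])
_CELL_CONCENTRATION = 120.0

EDUCATION_LEVELS = ("low", "middle", "high")
PHYS_ACT_LEVELS = ("insufficient", "sufficient", "NA")


@dataclass
class SimDesign:
    """Parameters of one synthetic cohort.

    Defaults mirror the study design this generator emulates: 61 adult-onset
    non-atopic asthma cases and 146 non-atopic controls, BMI medians near
    25.7 (cases) vs 24.5 (controls) arising from a modest BMI main effect on
    disease, seven Houseman-style cell fractions, and a natural-log hs-CRP
    slope of 0.1 per BMI unit.
    """

    n_cases: int = 61
    n_controls: int = 146
    n_cpgs: int | None = None  # informational; the manifest is authoritative
    n_genes: int | None = None
    n_pathways: int | None = None
    gamma: dict[str, float] = field(default_factory=dict)  # CpG -> log-odds per beta-unit per BMI-unit
    gamma_change: dict[str, float] = field(default_factory=dict)  # same, for 10-year BMI change
    batch_dim: int = 5
    batch_sd: float = 0.4  # SD of target-probe loadings on each latent batch factor (logit scale)
    cell_profile_shift: dict[str, float] = field(
        default_factory=lambda: {"Neu": 1.5, "CD4T": 0.8, "Bcell": 0.5}
    )
    noise_sd: float = 0.5  # individual logit-scale noise
    missing_rate: float = 0.01
    hs_crp_missing: float = 0.005
    crp_slope: float = 0.1  # ln(hs-CRP) per BMI unit
    main_effects: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.06, "female": 0.6, "age": 0.018}
    )
    target_prevalence: float = 0.33
    oversample: int = 12
    seed: int = 0
    # when set, CpG-level parameters (baseline methylation, cell and batch
    # loadings) are drawn from this separate seed, so one fixed "array" can
    # be reused across many simulated cohorts
    probe_seed: int | None = None

    def validate(self, manifest: pd.DataFrame) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        probes = set(manifest["probe_id"])
        unknown = (set(self.gamma) | set(self.gamma_change)) - probes
        if unknown:
            raise ValueError(f"gamma refers to probes absent from manifest: {sorted(unknown)[:5]}")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for recovery checks."""

    causal_cpgs: set[str]
    causal_pathways: set[str]
    planted_dmr_intervals: list[tuple[str, int, int]]
    batch_loadings: np.ndarray  # n_cpgs x batch_dim, logit scale
    batch_factors: np.ndarray  # batch_dim x n_samples (selected samples)
    true_gamma: dict[str, float]
    true_gamma_change: dict[str, float] = field(default_factory=dict)


def generate_manifest(
    n_cpgs: int,
    n_chroms: int = 5,
    cluster_size: int = 10,
    cluster_spacing: int = 20_000,
    intra_spacing: int = 80,
    sex_chrom_frac: float = 0.04,
    masked_frac: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out `n_cpgs` probes in islands of `cluster_size` probes.

    Intra-island gaps are uniform on [30, intra_spacing] bp (well under the
    1000 bp smoothing bandwidth); islands are separated by at least
    `cluster_spacing` bp. A fraction of islands is placed on chrX and
    flagged `is_sex_chrom`; a fraction of probes is flagged `is_masked`
    (multi-mapping / SNP-overlap surrogate).
    """
    if n_cpgs <= 0 or n_chroms <= 0 or cluster_size < 1:
        raise ValueError("n_cpgs, n_chroms and cluster_size must be positive")
    if n_cpgs < n_chroms:
        raise ValueError("need at least one CpG per chromosome")
    rng = np.random.default_rng(seed)

    n_clusters = -(-n_cpgs // cluster_size)
    n_sex_clusters = int(round(sex_chrom_frac * n_clusters))
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    # round-robin autosomal clusters; sex clusters go to chrX
    cluster_chroms = [chrom_names[i % n_chroms] for i in range(n_clusters - n_sex_clusters)]
    cluster_chroms += ["chrX"] * n_sex_clusters

    sizes = np.full(n_clusters, cluster_size)
    sizes[-1] = n_cpgs - cluster_size * (n_clusters - 1)

    rows = []
    next_pos: dict[str, int] = {}
    for csize, chrom in zip(sizes, cluster_chroms):
        start = next_pos.get(chrom, 1000) + int(rng.integers(0, cluster_spacing))
        gaps = rng.integers(30, max(intra_spacing, 31), size=csize - 1) if csize > 1 else []
        pos = start + np.concatenate([[0], np.cumsum(gaps)]).astype(int) if csize > 1 else np.array([start])
        for p in pos:
            rows.append((chrom, int(p)))
        next_pos[chrom] = int(pos[-1]) + cluster_spacing

    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["probe_id"] = [f"cg{i:08d}" for i in range(len(df))]
    df["is_sex_chrom"] = df["chrom"] == "chrX"
    df["is_masked"] = rng.random(len(df)) < masked_frac
    order = {c: i for i, c in enumerate(chrom_names + ["chrX"])}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    df = df.reset_index(drop=True)
    return df[["probe_id", "chrom", "pos", "is_sex_chrom", "is_masked"]]


def _clusters(manifest: pd.DataFrame, max_gap: int = 1500) -> list[pd.DataFrame]:
    """Group consecutive same-chromosome probes with gaps <= max_gap bp."""
    out = []
    for _, sub in manifest.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        brk = sub["pos"].diff().fillna(0) > max_gap
        for _, grp in sub.groupby(brk.cumsum()):
            out.append(grp)
    return out


def generate_genes_and_pathways(
    manifest: pd.DataFrame,
    n_genes: int,
    n_pathways: int,
    genes_per_pathway: int,
    seed: int = 0,
    overlapping: bool = False,
    extension: int = 1500,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Tile CpG islands with non-overlapping genes and partition them into
    mutually exclusive pathway gene sets (plus a "global" union set).

    Each gene's TSS sits at the midpoint of one CpG island — mirroring the
    promoter-centric probe placement of real arrays — with the body
    extending `extension` bp beyond the island. Half of an island's CpGs
    therefore fall in the gene body (assigned to pathways under the
    +/-200 bp rule) and half in the upstream promoter window (picked up by
    DMR annotation). With `overlapping=True` each pathway additionally
    receives a 10% sprinkle of genes drawn from the whole pool, producing
    overlapping sets.
    """
    if n_genes < n_pathways * genes_per_pathway:
        raise ValueError("n_genes must cover n_pathways * genes_per_pathway disjoint sets")
    rng = np.random.default_rng(seed)
    islands = [c for c in _clusters(manifest) if not c["is_sex_chrom"].any()]
    if n_genes > len(islands):
        raise ValueError(
            f"cannot tile {n_genes} non-overlapping genes on {len(islands)} CpG islands"
        )
    chosen = sorted(rng.choice(len(islands), size=n_genes, replace=False))
    rows = []
    for gi, idx in enumerate(chosen):
        isl = islands[idx]
        s, e = int(isl["pos"].min()), int(isl["pos"].max())
        mid = (s + e) // 2
        if rng.random() < 0.5:  # '+': TSS = start = island midpoint
            rows.append((f"G{gi:04d}", isl["chrom"].iloc[0], mid, e + extension, "+"))
        else:  # '-': TSS = end = island midpoint
            rows.append((f"G{gi:04d}", isl["chrom"].iloc[0], max(1, s - extension), mid, "-"))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    perm = rng.permutation(n_genes)
    db: dict[str, set[str]] = {}
    for p in range(n_pathways):
        ids = perm[p * genes_per_pathway : (p + 1) * genes_per_pathway]
        db[f"pathway_{p + 1:02d}"] = {genes["gene_id"].iloc[i] for i in ids}
    if overlapping:
        n_extra = max(1, genes_per_pathway // 10)
        for name in list(db):
            extra = rng.choice(n_genes, size=n_extra, replace=False)
            db[name] |= {genes["gene_id"].iloc[i] for i in extra}
    db["global"] = set().union(*db.values())
    return genes, db


def plant_effects(
    manifest: pd.DataFrame,
    genes: pd.DataFrame,
    pathway_db: dict[str, set[str]],
    n_causal_pathways: int = 2,
    gamma_pathway: float = 1.0,
    n_dmr_blocks: int = 3,
    dmr_block_size: int = 10,
    gamma_dmr: float = 2.0,
    flank: int = 200,
    seed: int = 0,
) -> tuple[dict[str, float], set[str], list[tuple[str, int, int]]]:
    """Choose causal pathways and contiguous DMR blocks and return a gamma map.

    Pathway CpGs receive random-sign interactions of magnitude
    `gamma_pathway` (enrichment on |Z| is sign-agnostic); each DMR block is a
    run of `dmr_block_size` consecutive island CpGs sharing one sign with
    magnitude `gamma_dmr`, so region recovery is well defined.
    """
    from .pathways import assign_cpgs_to_genes

    rng = np.random.default_rng(seed)
    usable = manifest[~manifest["is_sex_chrom"] & ~manifest["is_masked"]]
    pairs = assign_cpgs_to_genes(usable, genes, flank=flank)
    gene_to_cpgs = pairs.groupby("gene_id")["probe_id"].agg(set)

    names = [n for n in pathway_db if n != "global"]
    causal = set(rng.choice(names, size=min(n_causal_pathways, len(names)), replace=False))
    gamma: dict[str, float] = {}
    for name in causal:
        cpgs = set().union(*(gene_to_cpgs.get(g, set()) for g in pathway_db[name]))
        for cg in sorted(cpgs):
            gamma[cg] = float(gamma_pathway * rng.choice([-1.0, 1.0]))

    intervals = []
    blocks = [
        c
        for c in _clusters(usable)
        if len(c) >= dmr_block_size and not set(c["probe_id"]) & set(gamma)
    ]
    rng.shuffle(blocks)
    for blk in blocks[:n_dmr_blocks]:
        sign = float(rng.choice([-1.0, 1.0]))
        members = blk.iloc[:dmr_block_size]
        for cg in members["probe_id"]:
            gamma[cg] = sign * gamma_dmr
        intervals.append(
            (members["chrom"].iloc[0], int(members["pos"].min()), int(members["pos"].max()))
        )
    return gamma, causal, intervals


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    bmi_s2 = np.clip(rng.normal(24.4, 3.8, n), 16, 45)
    bmi_change = np.clip(rng.normal(0.45, 1.5, n), -8, 8)
    cov = pd.DataFrame(
        {
            "bmi_s2": bmi_s2,
            "bmi_change": bmi_change,
            "bmi_s3": bmi_s2 + bmi_change,
            "age": np.clip(rng.normal(58, 11, n), 30, 80),
            "sex": np.where(rng.random(n) < 0.58, "F", "M"),
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=[0.01, 0.66, 0.33]),
            "area": rng.choice([f"area{i + 1}" for i in range(8)], size=n),
            "packyears": np.where(
                rng.random(n) < 0.62, 0.0, np.clip(rng.gamma(1.3, 8.0, n), 0, 60)
            ),
            "benchtime": np.clip(rng.normal(81, 25, n), 10, 180),
            "phys_act": rng.choice(PHYS_ACT_LEVELS, size=n, p=[0.23, 0.75, 0.02]),
        }
    )
    cells = rng.dirichlet(_CELL_CONCENTRATION * _CELL_MEANS, size=n)
    for j, ct in enumerate(CELL_TYPES):
        cov[ct] = cells[:, j]
    return cov


def simulate_cohort(
    design: SimDesign,
    manifest: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    pathway_db: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate one cohort bundle.

    Returns (beta, detection_p, control_probes, covariates, truth). Disease
    is generated forward — covariates and methylation first, then logistic
    sampling of status with the planted interaction terms, then subsampling
    to exactly `n_cases` / `n_controls` — so case-control odds ratios are
    recoverable.
    """
    design.validate(manifest)
    rng = np.random.default_rng(design.seed)
    n_cpgs = len(manifest)
    n_target = design.n_cases + design.n_controls
    n_pool = design.oversample * n_target

    cov = _draw_covariates(rng, n_pool)

    # CpG-level parameters (a fixed probe_seed freezes the "array" across cohorts)
    rng_probe = rng if design.probe_seed is None else np.random.default_rng(design.probe_seed)
    comp = rng_probe.choice(3, size=n_cpgs, p=[0.35, 0.35, 0.30])
    mu = np.where(
        comp == 0,
        rng_probe.normal(-2.8, 0.6, n_cpgs),
        np.where(comp == 1, rng_probe.normal(2.8, 0.6, n_cpgs), rng_probe.normal(0.0, 1.2, n_cpgs)),
    )
    cell_load = np.zeros((n_cpgs, len(CELL_TYPES)))
    for j, ct in enumerate(CELL_TYPES):
        scale = design.cell_profile_shift.get(ct, 0.0)
        if scale > 0:
            hit = rng_probe.random(n_cpgs) < 0.25
            cell_load[hit, j] = rng_probe.normal(0.0, scale, hit.sum())
    batch_load = rng_probe.normal(0.0, design.batch_sd, (n_cpgs, design.batch_dim))
    factors = rng.standard_normal((design.batch_dim, n_pool))
    cells_pool = cov[list(CELL_TYPES)].to_numpy()
    cells_centered = cells_pool - _CELL_MEANS

    probe_ids = manifest["probe_id"].to_numpy()
    probe_idx = {p: i for i, p in enumerate(probe_ids)}
    gamma_idx = np.array([probe_idx[p] for p in design.gamma], dtype=int)
    gamma_val = np.array(list(design.gamma.values()))
    gammac_idx = np.array([probe_idx[p] for p in design.gamma_change], dtype=int)
    gammac_val = np.array(list(design.gamma_change.values()))
    causal_idx = np.unique(np.concatenate([gamma_idx, gammac_idx])).astype(int)

    # beta for causal CpGs across the whole pool (these enter the disease model)
    def _logit_beta(rows: np.ndarray, factors_sub, cells_sub, noise):
        return (
            mu[rows][:, None]
            + cell_load[rows] @ cells_sub.T
            + batch_load[rows] @ factors_sub
            + noise
        )

    noise_causal = rng.normal(0.0, design.noise_sd, (len(causal_idx), n_pool))
    beta_causal = expit(_logit_beta(causal_idx, factors, cells_centered, noise_causal))

    # disease model
    lin = (
        design.main_effects.get("bmi", 0.0) * cov["bmi_s3"].to_numpy()
        + design.main_effects.get("female", 0.0) * (cov["sex"] == "F").to_numpy()
        + design.main_effects.get("age", 0.0) * cov["age"].to_numpy()
    )
    # The planted product uses centered exposure and centered beta: the
    # interaction log-odds per beta-unit per exposure-unit is unchanged by
    # centering (the differences are main effects), while the latent scale
    # stays bounded even with many causal CpGs.
    causal_row = {i: r for r, i in enumerate(causal_idx)}
    beta_c = beta_causal - beta_causal.mean(axis=1, keepdims=True)
    if len(gamma_idx):
        rows = [causal_row[i] for i in gamma_idx]
        bmi_c = cov["bmi_s3"].to_numpy() - cov["bmi_s3"].mean()
        lin = lin + gamma_val @ (beta_c[rows] * bmi_c)
    if len(gammac_idx):
        rows = [causal_row[i] for i in gammac_idx]
        chg_c = cov["bmi_change"].to_numpy() - cov["bmi_change"].mean()
        lin = lin + gammac_val @ (beta_c[rows] * chg_c)

    lo, hi = -200.0, 200.0  # bisect intercept for the target marginal prevalence
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + lin).mean() < design.target_prevalence:
            lo = mid
        else:
            hi = mid
    status = rng.random(n_pool) < expit(0.5 * (lo + hi) + lin)

    case_pool = np.flatnonzero(status)
    ctrl_pool = np.flatnonzero(~status)
    if len(case_pool) < design.n_cases or len(ctrl_pool) < design.n_controls:
        raise RuntimeError(
            f"oversampled pool of {n_pool} yielded {len(case_pool)} cases / "
            f"{len(ctrl_pool)} controls; need {design.n_cases}/{design.n_controls} — "
            "increase design.oversample or target_prevalence"
        )
    sel = np.concatenate(
        [
            rng.choice(case_pool, design.n_cases, replace=False),
            rng.choice(ctrl_pool, design.n_controls, replace=False),
        ]
    )
    sel.sort()

    sample_ids = [f"S{i + 1:04d}" for i in range(n_target)]
    covariates = cov.iloc[sel].reset_index(drop=True)
    covariates.insert(0, "sample_id", sample_ids)
    covariates.insert(1, "asthma", status[sel].astype(int))
    ln_crp = -2.44 + design.crp_slope * covariates["bmi_s2"] + rng.normal(0, 0.75, n_target)
    hs_crp = np.exp(ln_crp)
    hs_crp[rng.random(n_target) < design.hs_crp_missing] = np.nan
    covariates["hs_crp"] = hs_crp

    # full beta matrix for the selected samples; causal rows reuse pool values
    noise_sel = rng.normal(0.0, design.noise_sd, (n_cpgs, n_target))
    logit_all = _logit_beta(np.arange(n_cpgs), factors[:, sel], cells_centered[sel], noise_sel)
    beta = expit(logit_all)
    beta[causal_idx] = beta_causal[:, sel]
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    beta_df.index.name = "probe_id"

    # detection p-values: missing entries exceed the 1e-16 threshold
    miss = rng.random((n_cpgs, n_target)) < design.missing_rate
    detp = 10.0 ** -rng.uniform(16.0, 30.0, (n_cpgs, n_target))
    detp[miss] = 10.0 ** -rng.uniform(0.0, 15.5, int(miss.sum()))
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    detp_df.index.name = "probe_id"

    # 220 control probes driven by the same latent batch factors
    ctrl_load = rng.normal(0.0, 1.0, (220, design.batch_dim))
    controls = 2000.0 + 250.0 * (ctrl_load @ factors[:, sel]) + rng.normal(0, 80.0, (220, n_target))
    controls_df = pd.DataFrame(
        controls, index=[f"ctrl{i + 1:03d}" for i in range(220)], columns=sample_ids
    )
    controls_df.index.name = "probe_id"

    causal_cpgs = set(design.gamma) | set(design.gamma_change)
    causal_pathways: set[str] = set()
    if pathway_db and genes is not None and causal_cpgs:
        from .pathways import assign_cpgs_to_genes

        pairs = assign_cpgs_to_genes(manifest, genes, flank=200)
        hit_genes = set(pairs[pairs["probe_id"].isin(causal_cpgs)]["gene_id"])
        causal_pathways = {
            n for n, gs in pathway_db.items() if n != "global" and gs & hit_genes
        }

    truth = TruthRecord(
        causal_cpgs=causal_cpgs,
        causal_pathways=causal_pathways,
        planted_dmr_intervals=_derive_dmr_intervals(manifest, design),
        batch_loadings=batch_load,
        batch_factors=factors[:, sel],
        true_gamma=dict(design.gamma),
        true_gamma_change=dict(design.gamma_change),
    )
    return beta_df, detp_df, controls_df, covariates, truth


def _derive_dmr_intervals(
    manifest: pd.DataFrame, design: SimDesign, min_run: int = 5
) -> list[tuple[str, int, int]]:
    """Contiguous same-sign gamma runs of length >= min_run within islands."""
    gamma = {**design.gamma_change, **design.gamma}
    if not gamma:
        return []
    intervals = []
    for cl in _clusters(manifest):
        g = cl["probe_id"].map(gamma)
        sign = np.sign(g.fillna(0.0).to_numpy())
        run_id = np.cumsum(np.concatenate([[1], np.diff(sign) != 0]))
        for rid in np.unique(run_id):
            m = run_id == rid
            if sign[m][0] != 0 and m.sum() >= min_run:
                pos = cl["pos"].to_numpy()[m]
                intervals.append((cl["chrom"].iloc[0], int(pos.min()), int(pos.max())))
    return intervals


def design_to_dict(design: SimDesign) -> dict:
    return dataclasses.asdict(design)
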