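"""Pathway-level enrichment of epigenome-wide interaction statistics.

CpGs are attached to genes when they lie within the gene body or within a
200 bp flank on either side; a pathway's CpG set is the union over its
member genes, intersected with the analyzed probes (a CpG may belong to
several pathways even when the gene sets are disjoint, via shared flanks).

Enrichment compares the absolute interaction Z statistics of a pathway's
CpGs against the empirical distribution of all analyzed CpGs using a
one-sided Kolmogorov-Smirnov distance,

    D+ = sup_x [ F_all(x) - F_pathway(x) ],

positive when the pathway's |Z| are stochastically larger. The null is
Monte-Carlo: size-matched CpG sets drawn uniformly WITHOUT replacement from
the analyzed universe (null pathways are subsets of the real array), with
mc_p = (1 + #{D+_b >= D+_obs}) / (B + 1) and a Westfall-Young min-p
adjustment across pathways sharing the replicate ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .ewis import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_FLANK = 200
DEFAULT_B = 10_000


def assign_cpgs_to_genes(
    manifest: pd.DataFrame, genes: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> pd.DataFrame:
    """Many-to-many CpG/gene assignment: probe at `pos` maps to gene g iff
    pos in [start - flank, end + flank] (gene body included, strand-agnostic).

    Returns a (probe_id, gene_id) pair frame. Gene chromosomes must be known
    to the manifest.
    """
    known = set(manifest["chrom"])
    unknown = set(genes["chrom"]) - known
    if unknown:
        raise ValueError(f"gene chromosomes absent from manifest: {sorted(unknown)}")
    pairs = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in manifest.groupby("chrom")}
    for _, g in genes.iterrows():
        sub = by_chrom.get(g["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, g["start"] - flank, side="left")
        hi = np.searchsorted(pos, g["end"] + flank, side="right")
        for pid in sub["probe_id"].iloc[lo:hi]:
            pairs.append((pid, g["gene_id"]))
    return pd.DataFrame(pairs, columns=["probe_id", "gene_id"])


@dataclass
class PathwayCpGSets:
    """Per-pathway CpG index sets over the analyzed probes."""

    sets: dict[str, np.ndarray]  # name -> array of probe_ids
    n_genes: dict[str, int]
    n_cpgs: dict[str, int]


def build_pathway_cpg_sets(
    cpg_gene_pairs: pd.DataFrame,
    pathway_db: dict[str, set[str]],
    ewis_table: pd.DataFrame,
) -> PathwayCpGSets:
    """Union of CpGs of each pathway's member genes, restricted to analyzed
    probes. Pathways with zero CpGs are retained (n_cpgs=0) but flagged; the
    enrichment test skips them.
    """
    analyzed = set(ewis_table["probe_id"])
    gene_to_cpgs = cpg_gene_pairs.groupby("gene_id")["probe_id"].agg(set)
    sets, n_genes, n_cpgs = {}, {}, {}
    for name, gs in pathway_db.items():
        cpgs = set().union(*(gene_to_cpgs.get(g, set()) for g in gs)) & analyzed
        sets[name] = np.array(sorted(cpgs))
        n_genes[name] = len(gs)
        n_cpgs[name] = len(cpgs)
        if not cpgs:
            log.warning("pathway %r has no CpGs among analyzed probes; untested", name)
    return PathwayCpGSets(sets=sets, n_genes=n_genes, n_cpgs=n_cpgs)


def wks_statistic(pathway_abs_z, all_abs_z) -> float:
    """One-sided KS distance D+ = sup_x [F_all(x) - F_pathway(x)].

    Both ECDFs are right-continuous; ties are handled exactly. `all_abs_z`
    is the full universe (the pathway compared against everything, itself
    included), so a pathway equal to the universe gives D+ = 0.
    """
    v = np.sort(np.asarray(pathway_abs_z, dtype=float))
    allv = np.sort(np.asarray(all_abs_z, dtype=float))
    m, N = len(v), len(allv)
    if m == 0:
        raise ValueError("pathway |Z| set is empty")
    if not (np.isfinite(v).all() and np.isfinite(allv).all()):
        raise ValueError("|Z| values must be finite")
    left = np.searchsorted(allv, v, side="left")
    return float(np.maximum(left / N - np.arange(m) / m, 0.0).max())


def _sample_wor(rng: np.random.Generator, N: int, m: int, B: int) -> np.ndarray:
    """B uniform draws of m distinct integers from range(N), exactly.

    Rejection on whole rows (sampling with replacement conditioned on
    distinctness) when collisions are rare; Gumbel top-m (argpartition of
    iid keys) when m is a large fraction of N.
    """
    if m > N:
        raise ValueError(f"cannot draw {m} distinct items from universe of {N}")
    if m == N:
        return np.tile(np.arange(N), (B, 1))
    if m * (m - 1) > 1.4 * N:  # collision-heavy regime
        out = np.empty((B, m), dtype=np.int64)
        step = max(1, int(2e7) // N)
        for s in range(0, B, step):
            keys = rng.random((min(step, B - s), N))
            out[s : s + keys.shape[0]] = np.argpartition(keys, m - 1, axis=1)[:, :m]
        return out
    out = rng.integers(0, N, size=(B, m), dtype=np.int64)
    for _ in range(10_000):
        srt = np.sort(out, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, N, size=(int(bad.sum()), m), dtype=np.int64)
    raise RuntimeError("rejection sampling failed to terminate")


def _running_sum_max(desc_positions: np.ndarray, member_values: np.ndarray,
                     N: int, weight: float = 1.0) -> np.ndarray:
    """Maximum of the GSEA-style running sum, vectorized over draws.

    `desc_positions`: (B, m) ascending 0-based positions of the members in
    the descending-|Z| ordering of the universe; `member_values`: matching
    |Z| values. The path steps up by |Z|^weight at members and down by a
    constant elsewhere; its maximum is attained just after a member step.
    """
    m = desc_positions.shape[-1]
    w = np.abs(member_values) ** weight
    up = np.cumsum(w, axis=-1) / np.maximum(w.sum(axis=-1, keepdims=True), 1e-300)
    down = (desc_positions + 1 - np.arange(1, m + 1)) / max(N - m, 1)
    return np.maximum((up - down).max(axis=-1), 0.0)


def wks_enrichment(
    ewis_table: pd.DataFrame,
    cpg_sets: PathwayCpGSets,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "ks",
    weight: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo WKS enrichment of every non-empty pathway CpG set.

    The universe is the converged probes of `ewis_table`. Per pathway of
    size m, B null statistics are computed from size-m draws without
    replacement; `mc_p` uses the add-one convention and is never exactly 0.
    `adj_p` is the Westfall-Young min-p adjustment over the shared replicate
    ensemble, made monotone in mc_p. `enriched` flags mc_p < alpha.

    `statistic="ks"` (default) uses the one-sided KS distance D+;
    `statistic="running_sum"` uses the GSEA-style weighted running-sum
    maximum with exponent `weight` on |Z|.
    """
    if statistic not in ("ks", "running_sum"):
        raise ValueError("statistic must be 'ks' or 'running_sum'")
    ok = ewis_table["converged"] & np.isfinite(ewis_table["z"])
    n_dropped = int((~ok).sum())
    universe = ewis_table.loc[ok, "probe_id"].to_numpy()
    abs_z = np.abs(ewis_table.loc[ok, "z"].to_numpy(float))
    N = len(universe)
    order = np.argsort(abs_z, kind="stable")
    sorted_z = abs_z[order]
    # left-rank of each sorted value (ties collapse to the first index)
    lrank = np.searchsorted(sorted_z, sorted_z, side="left")
    desc_vals = sorted_z[::-1]
    desc_pos_of = np.empty(N, dtype=np.int64)  # probe row -> descending rank
    desc_pos_of[order[::-1]] = np.arange(N)
    probe_pos = {p: i for i, p in enumerate(universe)}

    rng = np.random.default_rng(seed)
    tested = [n for n, m in cpg_sets.n_cpgs.items() if m > 0]
    rows, null_p = [], []
    for name in tested:
        members = cpg_sets.sets[name]
        idx = np.array([probe_pos[p] for p in members if p in probe_pos])
        m = len(idx)
        if m == 0:
            continue
        draws = _sample_wor(rng, N, m, B)
        draws.sort(axis=1)
        if statistic == "ks":
            obs = wks_statistic(abs_z[idx], abs_z)
            d_null = (lrank[draws] / N - np.arange(m) / m).max(axis=1)
            d_null = np.maximum(d_null, 0.0)
        else:
            pos = np.sort(desc_pos_of[idx])
            obs = float(_running_sum_max(pos[None, :], desc_vals[pos][None, :],
                                         N, weight)[0])
            # a uniform draw of sorted indices is a uniform draw of
            # descending-rank positions
            d_null = _running_sum_max(draws, desc_vals[draws], N, weight)
        mc_p = (1 + int((d_null >= obs).sum())) / (B + 1)
        rows.append((name, cpg_sets.n_genes[name], m, obs, mc_p))
        null_p.append(rankdata(-d_null, method="max") / (B + 1))

    res = pd.DataFrame(rows, columns=["pathway", "n_genes", "n_cpgs", "observed_stat", "mc_p"])
    if len(res):
        q_b = np.vstack(null_p).min(axis=0)  # per-replicate minimum p across pathways
        adj = np.array([(1 + int((q_b <= p).sum())) / (B + 1) for p in res["mc_p"]])
        adj = np.maximum(adj, res["mc_p"].to_numpy())
        # enforce monotonicity of the adjustment in mc_p
        o = np.argsort(res["mc_p"].to_numpy(), kind="stable")
        adj[o] = np.maximum.accumulate(adj[o])
        res["adj_p"] = np.minimum(adj, 1.0)
    else:
        res["adj_p"] = []
    res["enriched"] = res["mc_p"] < alpha
    skipped = [n for n, m in cpg_sets.n_cpgs.items() if m == 0]
    for name in skipped:
        res = pd.concat(
            [res, pd.DataFrame([{
                "pathway": name, "n_genes": cpg_sets.n_genes[name], "n_cpgs": 0,
                "observed_stat": np.nan, "mc_p": np.nan, "adj_p": np.nan, "enriched": False,
            }])],
            ignore_index=True,
        )
    res.attrs.update({"B": B, "seed": seed, "n_universe": N, "n_probes_dropped": n_dropped,
                      "alpha": alpha, "statistic": statistic})
    return res


def gsea_running_sum_statistic(pathway_abs_z, all_abs_z, weight: float = 1.0) -> float:
    """Weighted running-sum enrichment score (GSEA-style) as an alternative
    statistic: walk the universe ranked by decreasing |Z|, stepping up by
    |Z|^weight at pathway members and down by a constant elsewhere; the
    score is the maximum positive deviation. Pathway values must occur in
    the universe; tied values consume successive ranks.
    """
    allv = np.asarray(all_abs_z, dtype=float)
    v = np.sort(np.asarray(pathway_abs_z, dtype=float))[::-1]
    N = len(allv)
    desc = np.sort(allv)[::-1]
    positions, j = [], 0
    for x in v:  # members descending; scan the descending universe once
        j = max(j, int(np.searchsorted(-desc, -x, side="left")))
        if j >= N or desc[j] != x:
            raise ValueError("pathway value not found in universe")
        positions.append(j)
        j += 1
    pos = np.array(positions)
    return float(_running_sum_max(pos[None, :], desc[pos][None, :], N, weight)[0])


def ora_fisher(
    gene_list, gene_universe, pathway_db: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact over-representation of `gene_list`
    in each pathway, against `gene_universe`, with BH across pathways.
    """
    universe = set(gene_universe)
    if not universe:
        raise ValueError("gene universe is empty")
    hits = set(gene_list)
    if not hits <= universe:
        raise ValueError("gene_list must be a subset of gene_universe")
    rows = []
    for name, gs in pathway_db.items():
        pw = gs & universe
        a = len(hits & pw)
        b = len(hits - pw)
        c = len(pw - hits)
        d = len(universe) - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, len(pw), a, odds, p))
    res = pd.DataFrame(rows, columns=["pathway", "n_pathway_genes", "overlap", "odds_ratio", "p"])
    res["bh_q"] = bh_adjust(res["p"])
    return res
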