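"""Pathway erosion statistics over COG functional categories.

For every genome the proportion of genes in each COG category
(p = genes carrying the category / total genes) and the corresponding
pseudogene-proportion profile (q = pseudogenes carrying the category /
total pseudogenes) are computed; a gene carrying several category letters
counts once in every carried category and once in the denominator.

A category's erosion trend is the Spearman correlation between its gene
proportion and genome size across genomes: a significantly *positive*
correlation marks an eroded pathway (small genomes have proportionally
fewer of its genes), a significantly negative one a preserved pathway.
An ordinary least-squares fit of proportion on genome size is reported
alongside. The module also builds per-pathway gene/pseudogene/absent
state matrices with hierarchical clustering of rows, and a Wilcoxon
rank-sum comparison of genome sizes between phenotype groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .orthology import OrthoGroup

logger = logging.getLogger(__name__)

STATE_CODES = {"gene": 2, "pseudogene": 1, "absent": 0}
#: largest sample for the exact Spearman permutation null
SPEARMAN_EXACT_N = 9
#: largest combined sample for the exact Wilcoxon enumeration
WILCOXON_EXACT_N = 12


@dataclass
class ErosionTable:
    genomes: list[str]
    genome_size: pd.Series  # bp per genome
    gene_prop: pd.DataFrame  # genome x category
    pseudo_prop: pd.DataFrame  # genome x category; NaN rows when no pseudogenes
    categories: list[str]


@dataclass
class TrendResult:
    category: str
    spearman_rho: float
    spearman_p: float
    ols_slope: float
    ols_intercept: float
    verdict: str  # eroded | preserved | none


def assign_cog(gene_ids, cog_map) -> dict[str, frozenset]:
    """Per-gene COG category sets from a gene -> letters mapping.

    ``cog_map`` is a DataFrame/TSV path with columns gene_id, categories;
    a multi-letter string like ``KL`` assigns the gene to every letter.
    Rows with malformed letters are rejected (logged); unmapped genes get
    the empty set.
    """
    if isinstance(cog_map, (str, Path)):
        cog_map = pd.read_csv(cog_map, sep="\t", dtype=str)
    mapping: dict[str, frozenset] = {}
    for row in cog_map.itertuples(index=False):
        letters = str(row.categories).strip()
        if not letters or not all("A" <= c <= "Z" for c in letters):
            logger.warning("malformed COG category %r for gene %s; row rejected", letters, row.gene_id)
            continue
        mapping[str(row.gene_id)] = frozenset(letters)
    return {g: mapping.get(g, frozenset()) for g in gene_ids}


def build_erosion_table(
    calls: pd.DataFrame,
    cog: dict[str, frozenset],
    genome_size: pd.Series,
    include_unmapped: bool = True,
    categories: list[str] | None = None,
) -> ErosionTable:
    """Per-genome COG proportions for genes and pseudogenes.

    ``calls`` needs columns genome_id, gene_id, is_pseudogene. The
    denominator of the gene proportions is the total gene count of the
    genome (unmapped genes included unless ``include_unmapped=False``);
    pseudogene proportions use the genome's pseudogene count and are NaN
    for genomes without pseudogenes. ``categories`` fixes the category
    universe explicitly — a category whose genes were all lost then keeps
    an all-zero column instead of vanishing from the table.
    """
    if calls.empty:
        raise ValueError("no genes in the calls table")
    genomes = sorted(calls["genome_id"].unique())
    if categories is None:
        categories = sorted({c for cats in cog.values() for c in cats})
    else:
        categories = sorted(categories)
    gene_prop = pd.DataFrame(0.0, index=genomes, columns=categories)
    pseudo_prop = pd.DataFrame(np.nan, index=genomes, columns=categories)
    for genome, sub in calls.groupby("genome_id"):
        gene_cats = [cog.get(g, frozenset()) for g in sub["gene_id"]]
        pseudo_cats = [
            cog.get(g, frozenset())
            for g, is_p in zip(sub["gene_id"], sub["is_pseudogene"])
            if is_p
        ]
        n_genes = len(gene_cats) if include_unmapped else sum(1 for c in gene_cats if c)
        n_pseudo = len(pseudo_cats) if include_unmapped else sum(1 for c in pseudo_cats if c)
        if n_genes == 0:
            raise ValueError(f"genome {genome} has zero genes")
        for cat in categories:
            gene_prop.at[genome, cat] = sum(1 for c in gene_cats if cat in c) / n_genes
            if n_pseudo > 0:
                pseudo_prop.at[genome, cat] = sum(1 for c in pseudo_cats if cat in c) / n_pseudo
    return ErosionTable(
        genomes=genomes,
        genome_size=genome_size.reindex(genomes).astype(float),
        gene_prop=gene_prop,
        pseudo_prop=pseudo_prop,
        categories=categories,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman rho (all n! permutations)."""
    n = len(x)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    yp = yr[perms]  # (n!, n)
    xc = xr - xr.mean()
    yc = yp - yp.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=1))
    rho_perm = (yc @ xc) / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def erosion_trend(table: ErosionTable, category: str, alpha: float = 0.05) -> TrendResult:
    """Spearman + OLS trend of a category's gene proportion vs genome size.

    Exact permutation p for n <= 9 genomes, t-approximation otherwise.
    Verdict: ``eroded`` iff p < alpha and rho > 0; ``preserved`` iff
    p < alpha and rho < 0; ``none`` otherwise (including zero variance).
    """
    y = table.gene_prop[category].to_numpy(dtype=float)
    x = table.genome_size.to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need >= 4 genomes with defined proportions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendResult(category, float("nan"), float("nan"), float("nan"), float("nan"), "none")
    rho, p_approx = stats.spearmanr(x, y)
    if len(x) <= SPEARMAN_EXACT_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(p_approx)
    ols = stats.linregress(x, y)
    if p < alpha and rho > 0:
        verdict = "eroded"
    elif p < alpha and rho < 0:
        verdict = "preserved"
    else:
        verdict = "none"
    return TrendResult(category, float(rho), p, float(ols.slope), float(ols.intercept), verdict)


def erosion_trends(table: ErosionTable, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for cat in table.categories:
        t = erosion_trend(table, cat, alpha=alpha)
        rows.append((t.category, t.spearman_rho, t.spearman_p, t.ols_slope, t.ols_intercept, t.verdict))
    return pd.DataFrame(rows, columns=["category", "rho", "p", "slope", "intercept", "verdict"])


def state_matrix(
    groups: list[OrthoGroup],
    pseudo_status: dict[str, bool],
    genome_ids: list[str],
    categories: set[str] = frozenset({"K", "L", "N"}),
) -> pd.DataFrame:
    """Per-orthogroup gene/pseudogene/absent state matrix.

    One row per group carrying any of the requested categories. The state
    of a genome is ``pseudogene`` if *any* of its members in the group is
    a pseudogene (erosion evidence takes precedence over intact paralogs),
    ``gene`` if it contributes members but none degraded, else ``absent``.
    """
    rows = {}
    for group in sorted(groups, key=lambda g: g.group_id):
        if not (group.cog_categories & set(categories)):
            continue
        states = []
        for genome in genome_ids:
            members = [m for m in group.members if m.genome_id == genome]
            if not members:
                states.append("absent")
            elif any(pseudo_status.get(m.gene_id, False) for m in members):
                states.append("pseudogene")
            else:
                states.append("gene")
        rows[group.group_id] = states
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(genome_ids))


def encode_states(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.replace(STATE_CODES).astype(float)


@dataclass
class Dendrogram:
    labels: list[str]  # input row labels, in clustering input order
    merges: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]


def hcluster_rows(matrix: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of state-matrix rows.

    States are encoded gene=2, pseudogene=1, absent=0; distances are
    Euclidean. Rows are sorted by label before clustering so that merge
    ties resolve deterministically by row label. A single row yields a
    trivial single-leaf dendrogram.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    data = matrix.sort_index()
    if data.select_dtypes(exclude="number").shape[1]:
        data = encode_states(data)
    labels = list(data.index)
    if len(labels) == 1:
        return Dendrogram(labels=labels, merges=np.empty((0, 4)), leaf_order=labels)
    z = hierarchy.linkage(data.to_numpy(dtype=float), method=linkage, metric="euclidean")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return Dendrogram(labels=labels, merges=z, leaf_order=order)


def dendrogram_newick(dend: Dendrogram) -> str:
    """Newick rendering of the row dendrogram (merge heights as depths)."""
    n = len(dend.labels)
    if n == 1:
        return f"{dend.labels[0]};"
    height = {i: 0.0 for i in range(n)}
    newick = {i: dend.labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(dend.merges):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node = n + k
        newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
        height[node] = h
    return newick[n + len(dend.merges) - 1] + ";"


def wilcoxon_ranksum(sizes_a, sizes_b) -> tuple[float, float]:
    """Wilcoxon rank-sum test on two genome-size samples.

    Returns (W, two-sided p) where W is the rank sum of the first sample
    (mid-ranks for ties). The null distribution is enumerated exactly
    (conditional on the observed ties) when the combined sample has at
    most 12 observations; otherwise the normal approximation with
    continuity and tie correction is used.
    """
    a = np.asarray(list(sizes_a), dtype=float)
    b = np.asarray(list(sizes_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[: a.size].sum())
    n = a.size + b.size
    if n <= WILCOXON_EXACT_N:
        sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), a.size)]
        sums = np.asarray(sums)
        p_le = np.mean(sums <= w + 1e-12)
        p_ge = np.mean(sums >= w - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return w, float(p)


def wilcoxon_by_phenotype(meta: pd.DataFrame, group_a: str = "motile", group_b: str = "immobile") -> tuple[float, float]:
    """Genome-size Wilcoxon between two phenotype groups of a metadata table."""
    a = meta.loc[meta["phenotype"] == group_a, "genome_size_bp"]
    b = meta.loc[meta["phenotype"] == group_b, "genome_size_bp"]
    return wilcoxon_ranksum(a, b)


def assign_group_categories(groups: list[OrthoGroup], cog: dict[str, frozenset]) -> None:
    """Set each group's COG categories to the union over its members."""
    for group in groups:
        cats: set[str] = set()
        for m in group.members:
            cats |= cog.get(m.gene_id, frozenset())
        group.cog_categories = cats
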