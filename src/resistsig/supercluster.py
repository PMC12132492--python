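"""Cross-cell-line grouping of RACs into superclusters.

Clusters from different cell lines are matched on their differential
mean-expression vectors: for each cluster, the per-gene difference between
its mean log-normalized expression and that of all other cells of the same
line, restricted to the genes that are highly variable in every line.  The
all-by-all Spearman correlation of these vectors is hierarchically clustered
(average linkage on 1 - rho) and the tree cut at a fixed height; a group
qualifies as a supercluster when it contains RACs from at least
``min_lines`` distinct cell lines.

Supercluster consensus signatures re-use the RRA machinery on the component
RACs' differential-expression lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_prep import ExpressionMatrix, LOGNORM
from .signatures import (
    GeneSignature,
    RankedGeneList,
    filter_down,
    filter_up,
    rra_aggregate,
)


@dataclass
class SuperclusterGrouping:
    shared_genes: list[str]
    vectors: pd.DataFrame  # clusters x shared_genes
    corr: pd.DataFrame  # clusters x clusters Spearman rho
    assignment: dict[str, str | None]  # cluster -> supercluster id or None
    linkage_record: np.ndarray

    def members(self, supercluster: str) -> list[str]:
        return sorted(c for c, s in self.assignment.items() if s == supercluster)

    @property
    def supercluster_ids(self) -> list[str]:
        return sorted({s for s in self.assignment.values() if s is not None})


def variable_genes(m: ExpressionMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by standardized-variance dispersion.

    Variance of clipped standardized values after a quadratic mean-variance
    trend fit in log10 space: genes whose variance exceeds the trend for
    their mean expression rank highest.  Deterministic; ties broken by gene
    id.
    """
    if m.layer_tag != LOGNORM:
        raise ValueError("variable_genes expects the lognorm layer")
    X = m.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    n_cells = X.shape[0]
    disp = np.zeros(m.n_genes)
    ok = (var > 0) & (mean > 0)
    if ok.any():
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        deg = 2 if ok.sum() > 2 else 1
        coef = np.polyfit(lm, lv, deg)
        expected_sd = np.sqrt(10 ** np.polyval(coef, lm))
        z = (X[:, ok] - mean[ok]) / expected_sd
        clip = np.sqrt(n_cells)
        z = np.clip(z, -clip, clip)
        disp[ok] = z.var(axis=0, ddof=1)
    if n > m.n_genes:
        warnings.warn("n exceeds the gene count; returning all genes")
        n = m.n_genes
    order = sorted(range(m.n_genes), key=lambda i: (-disp[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n]]


def shared_variable_genes(per_line_lists: Sequence[Sequence[str]]) -> list[str]:
    """Intersection of per-line variable-gene lists, sorted for determinism."""
    if len(per_line_lists) < 2:
        raise ValueError("need >= 2 lists")
    shared = set(per_line_lists[0])
    for lst in per_line_lists[1:]:
        shared &= set(lst)
    if not shared:
        raise ValueError("no genes shared across all cell lines")
    return sorted(shared)


def differential_mean_vector(
    m: ExpressionMatrix, cluster: str, genes: Sequence[str]
) -> np.ndarray:
    """mean(expr | cluster) - mean(expr | same-line complement) over ``genes``."""
    labels = m.cell_meta["cluster"].astype(str)
    in_cluster = (labels == str(cluster)).to_numpy()
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster!r} is empty")
    if in_cluster.all():
        raise ValueError(f"cluster {cluster!r} has no complement")
    gi = {g: i for i, g in enumerate(m.gene_ids)}
    cols = [gi[g] for g in genes]
    X = m.dense()[:, cols]
    return X[in_cluster].mean(axis=0) - X[~in_cluster].mean(axis=0)


def correlation_matrix(vectors: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """All-by-all Spearman rho of differential-expression vectors."""
    names = sorted(vectors)
    if len(names) < 2:
        raise ValueError("need >= 2 vectors")
    lengths = {len(vectors[n]) for n in names}
    if len(lengths) != 1 or lengths.pop() < 3:
        raise ValueError("vectors must share a common length >= 3")
    for nm in names:
        v = np.asarray(vectors[nm], dtype=float)
        if np.all(v == v[0]):
            raise ValueError(f"constant vector for cluster {nm!r}: Spearman undefined")
    mat = np.column_stack([np.asarray(vectors[nm], dtype=float) for nm in names])
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)  # midranks per vector
    rho = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


def group_superclusters(
    corr: pd.DataFrame,
    rac_flags: Mapping[str, bool],
    cluster_lines: Mapping[str, str],
    min_lines: int = 2,
    cut: float = 0.7,
) -> SuperclusterGrouping:
    """Cut the average-linkage tree on 1 - rho and retain qualifying groups.

    A group becomes a supercluster iff it contains RACs from >= min_lines
    distinct cell lines; its RAC members are assigned to it (non-RAC members
    stay unassigned, since only RACs are supercluster components).
    Supercluster ids SC1, SC2, ... are numbered by first member in sorted
    cluster order, so the labelling is input-order invariant.
    """
    names = sorted(corr.index)
    corr = corr.loc[names, names]
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    assignment: dict[str, str | None] = {c: None for c in names}
    qualifying = []
    for g in np.unique(flat):
        members = [names[i] for i in np.flatnonzero(flat == g)]
        rac_members = [c for c in members if rac_flags.get(c, False)]
        lines = {str(cluster_lines[c]) for c in rac_members}
        if len(lines) >= min_lines:
            qualifying.append((min(members), rac_members))
    if not qualifying:
        warnings.warn("no group qualifies as a supercluster at this cut")
    for k, (_, rac_members) in enumerate(sorted(qualifying), start=1):
        for c in rac_members:
            assignment[c] = f"SC{k}"
    vectors = pd.DataFrame(index=names)
    return SuperclusterGrouping(
        shared_genes=[],
        vectors=vectors,
        corr=corr,
        assignment=assignment,
        linkage_record=Z,
    )


def build_grouping(
    m: ExpressionMatrix,
    rac_table: pd.DataFrame,
    n_variable: int = 2000,
    min_lines: int = 2,
    cut: float = 0.7,
) -> SuperclusterGrouping:
    """Full supercluster stage on a multi-line lognorm matrix.

    Per line: top-n variable genes; across lines: their intersection; per
    cluster (RAC or not — all clusters participate in the correlation):
    differential mean vector over the shared genes; then Spearman,
    average-linkage grouping, and supercluster retention by RAC flags.
    """
    lines = m.cell_lines()
    if len(lines) < 2:
        raise ValueError("supercluster grouping needs >= 2 cell lines")
    per_line = []
    line_mats = {}
    for line in lines:
        sub = m.subset_cells((m.cell_meta["cell_line"].astype(str) == line).to_numpy())
        line_mats[line] = sub
        per_line.append(variable_genes(sub, n_variable))
    shared = shared_variable_genes(per_line)
    vectors: dict[str, np.ndarray] = {}
    cluster_lines: dict[str, str] = {}
    for line in lines:
        sub = line_mats[line]
        for cl in sorted(sub.cell_meta["cluster"].astype(str).unique()):
            vectors[cl] = differential_mean_vector(sub, cl, shared)
            cluster_lines[cl] = line
    corr = correlation_matrix(vectors)
    rac_flags = {
        str(r["cluster_id"]): bool(r["is_rac"]) for _, r in rac_table.iterrows()
    }
    grouping = group_superclusters(corr, rac_flags, cluster_lines,
                                   min_lines=min_lines, cut=cut)
    grouping.shared_genes = shared
    grouping.vectors = pd.DataFrame(
        {c: vectors[c] for c in sorted(vectors)}, index=shared
    ).T
    return grouping


def supercluster_signature(
    component_de: Sequence[RankedGeneList],
    direction: str = "up",
    max_padj: float = 0.05,
    max_rank_p: float = 0.05,
    name: str = "supercluster",
    universe_size: int | None = None,
) -> GeneSignature:
    """Consensus signature of a supercluster from its component RACs' DE lists.

    Each component list is filtered to strictly up- (or down-) regulated
    significant genes, sorted by |log2fc|, and the filtered lists are
    aggregated with RRA at the adjusted rank-p threshold.  ``universe_size``
    defaults to the length of the unfiltered component lists, so filtered
    positions keep their genome-wide meaning.
    """
    if len(component_de) < 2:
        raise ValueError("need >= 2 component DE lists")
    if universe_size is None:
        universe_size = max(len(rl) for rl in component_de)
    filtered = []
    for rl in component_de:
        f = filter_up(rl, 0.0, max_padj) if direction == "up" else filter_down(rl, 0.0, max_padj)
        if direction == "down" and len(f):
            # rank by magnitude so the strongest downregulation leads the list
            df = f.entries.copy()
            df["log2fc"] = -df["log2fc"]
            f = RankedGeneList(df, name=f.name)
        filtered.append(f)
    if any(len(f) == 0 for f in filtered):
        warnings.warn("a component list is empty after filtering")
    nonempty = [f for f in filtered if len(f)]
    if len(nonempty) < 2:
        warnings.warn("fewer than 2 non-empty component lists; empty signature")
        from .signatures import _empty_ok

        return _empty_ok(name, direction)
    sig = rra_aggregate(nonempty, max_rank_p=max_rank_p, name=name,
                        direction=direction, universe_size=universe_size)
    return sig
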