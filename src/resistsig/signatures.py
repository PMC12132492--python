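"""Consensus resistance signatures.

Builds a resistance gene signature the way consensus signatures are built
from multiple independent drug-treatment experiments: per-dataset
differential expression (Wilcoxon rank-sum on log-normalized values),
filtering to significantly upregulated genes, and Robust Rank Aggregation
(RRA) of the per-dataset ranked lists into a single consensus set.

RRA scores each gene by rho = min_j P(Binomial(m, r_(j)) >= j), the smallest
tail probability that its j-th best normalized rank r_(j) across m lists
would be that extreme under uniform ranks.  The rho score is converted to a
rank p-value by a Bonferroni factor m over the order statistics, then
Benjamini-Hochberg across genes ("adjusted rank p-value"); both correction
stages are explicit and configurable.

Also provides the simpler cross-species route: majority-vote consensus over
upregulated gene lists and ortholog table mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from .io_prep import ExpressionMatrix

UP = "up"
DOWN = "down"
UNSIGNED = "unsigned"


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally directional."""

    name: str
    genes: frozenset[str]
    direction: str = UNSIGNED

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.direction not in (UP, DOWN, UNSIGNED):
            raise ValueError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RankedGeneList:
    """Genes ordered by descending log2 fold change with p-values.

    ``entries`` holds columns gene_id, log2fc, p, p_adj.  Construction sorts
    by descending log2fc, breaking ties by ascending p then gene id, so list
    order is deterministic.
    """

    entries: pd.DataFrame
    name: str = ""

    def __post_init__(self):
        df = self.entries
        required = ["gene_id", "log2fc", "p", "p_adj"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"ranked list missing columns {missing}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in ranked list")
        if ((df["p"] < 0) | (df["p"] > 1)).any():
            raise ValueError("p outside [0,1]")
        df = df.sort_values(
            ["log2fc", "p", "gene_id"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        self.entries = df[required]

    @property
    def genes(self) -> list[str]:
        return self.entries["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str = "") -> "RankedGeneList":
        return cls(pd.read_csv(path, sep="\t"), name=name or Path(path).stem)


# -- differential expression ----------------------------------------------

def differential_expression(
    m: "ExpressionMatrix",
    group_a: Iterable[str],
    group_b: Iterable[str],
    pseudocount: float = 1.0,
    adjust: str = "bonferroni",
) -> RankedGeneList:
    """Per-gene Wilcoxon rank-sum of group A vs group B on lognorm values.

    log2fc is computed on de-logged (expm1) group means with a pseudocount;
    p-values are two-sided rank-sum, Bonferroni-adjusted over tested genes
    by default (``adjust="bh"`` for Benjamini-Hochberg).
    """
    from .io_prep import LOGNORM

    if m.layer_tag != LOGNORM:
        raise ValueError("differential_expression expects the lognorm layer")
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups overlap")
    if len(ga) < 3 or len(gb) < 3:
        raise ValueError("each group needs >= 3 cells")
    idx = {c: i for i, c in enumerate(m.cell_ids)}
    X = m.dense()
    A = X[[idx[c] for c in ga]]  # n_a x genes
    B = X[[idx[c] for c in gb]]

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    combined = np.vstack([A, B])
    degenerate = combined.max(axis=0) == combined.min(axis=0)
    pvals = np.ones(m.n_genes)
    if (~degenerate).any():
        res = stats.mannwhitneyu(
            A[:, ~degenerate], B[:, ~degenerate], axis=0, alternative="two-sided"
        )
        pvals[~degenerate] = np.minimum(res.pvalue, 1.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes constant across both groups; p set to 1"
        )
    if adjust == "bonferroni":
        p_adj = np.minimum(pvals * m.n_genes, 1.0)
    elif adjust == "bh":
        p_adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return RankedGeneList(
        pd.DataFrame(
            {"gene_id": m.gene_ids, "log2fc": log2fc, "p": pvals, "p_adj": p_adj}
        )
    )


def filter_up(
    ranked: RankedGeneList, min_lfc: float = 0.0, max_padj: float = 0.05
) -> RankedGeneList:
    """Keep entries with log2fc strictly above min_lfc and p_adj strictly below max_padj."""
    df = ranked.entries
    keep = (df["log2fc"] > min_lfc) & (df["p_adj"] < max_padj)
    return RankedGeneList(df[keep].reset_index(drop=True), name=ranked.name)


def filter_down(
    ranked: RankedGeneList, max_lfc: float = 0.0, max_padj: float = 0.05
) -> RankedGeneList:
    """Downregulated counterpart: log2fc strictly below max_lfc."""
    df = ranked.entries
    keep = (df["log2fc"] < max_lfc) & (df["p_adj"] < max_padj)
    return RankedGeneList(df[keep].reset_index(drop=True), name=ranked.name)


# -- robust rank aggregation ----------------------------------------------

def rra_rho(normalized_ranks: Sequence[float], m: int) -> float:
    """RRA rho score for one gene's normalized ranks across m lists.

    ``normalized_ranks`` holds rank/list_length for the lists where the gene
    appears (length k <= m).  rho = min over j of the binomial tail
    P(Binomial(m, r_(j)) >= j) with ranks sorted ascending.
    """
    r = np.asarray(sorted(normalized_ranks), dtype=float)
    if r.size == 0:
        return 1.0
    if r.size > m:
        raise ValueError("more ranks than lists")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, r.size + 1)
    betas = stats.binom.sf(j - 1, m, r)
    return float(betas.min())


def rra_score_p(rho: float, m: int) -> float:
    """Bonferroni correction of rho over the m order statistics."""
    return min(rho * m, 1.0)


def rra_aggregate(
    lists: Sequence[RankedGeneList],
    max_rank_p: float = 0.05,
    across_gene_adjust: str = "bh",
    name: str = "rra_consensus",
    direction: str = UP,
    universe_size: int | None = None,
) -> GeneSignature:
    """Aggregate ranked lists with RRA and keep genes with adjusted rank p < threshold.

    Genes absent from a list contribute no rank there but m stays the total
    number of lists.  Per-gene rho scores are Bonferroni-corrected over order
    statistics (rho*m) and then, by default, Benjamini-Hochberg corrected
    across genes; pass ``across_gene_adjust="none"`` to skip the second stage.

    When the input lists are pre-filtered (e.g. to significantly upregulated
    genes), pass ``universe_size`` = the number of genes originally tested so
    that a position-k entry gets normalized rank k/universe_size rather than
    k/len(filtered list); otherwise ranks carry no information beyond
    membership.
    """
    df = rra_table(lists, universe_size=universe_size)
    col = "p_adj" if across_gene_adjust == "bh" else "rank_p"
    keep = df[df[col] < max_rank_p]
    if keep.empty:
        warnings.warn("RRA retained no genes at the requested threshold")
        return _empty_ok(name, direction)
    return GeneSignature(name=name, genes=frozenset(keep["gene_id"]), direction=direction)


class EmptySignature(GeneSignature):
    """Sentinel for an aggregation that retained nothing; len() == 0."""

    def __init__(self, name: str, direction: str):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset())
        object.__setattr__(self, "direction", direction)

    def __post_init__(self):  # pragma: no cover
        pass


def _empty_ok(name: str, direction: str) -> EmptySignature:
    return EmptySignature(name, direction)


def rra_table(
    lists: Sequence[RankedGeneList], universe_size: int | None = None
) -> pd.DataFrame:
    """Per-gene RRA scores over the union of list members.

    Returns a DataFrame (gene_id, rho, rank_p, p_adj) sorted by rho then
    gene id.  rank_p = min(rho*m, 1); p_adj = BH of rank_p across genes.
    Positions are normalized by ``universe_size`` when given (for
    pre-filtered lists), else by each list's own length.
    """
    if len(lists) < 2:
        raise ValueError("need >= 2 ranked lists")
    m = len(lists)
    ranks: dict[str, list[float]] = {}
    for rl in lists:
        genes = rl.genes
        n = universe_size if universe_size is not None else len(genes)
        if len(genes) == 0:
            continue
        if len(genes) > n:
            raise ValueError("list longer than the stated universe")
        for pos, g in enumerate(genes, start=1):
            ranks.setdefault(g, []).append(pos / n)
    if not ranks:
        raise ValueError("empty union of gene lists")
    gene_ids = sorted(ranks)
    rho = np.array([rra_rho(ranks[g], m) for g in gene_ids])
    rank_p = np.minimum(rho * m, 1.0)
    p_adj = multipletests(rank_p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"gene_id": gene_ids, "rho": rho, "rank_p": rank_p, "p_adj": p_adj}
    )
    return df.sort_values(["rho", "gene_id"], kind="mergesort").reset_index(drop=True)


# -- consensus / top-N / orthologs ----------------------------------------

def consensus_majority(
    lists: Sequence[GeneSignature], min_support: int = 5, name: str = "consensus"
) -> GeneSignature:
    """Genes present in at least ``min_support`` of the input signatures."""
    if not lists:
        raise ValueError("need >= 1 signature")
    if min_support > len(lists):
        warnings.warn("min_support exceeds number of lists; result is empty")
        return _empty_ok(name, lists[0].direction)
    counts: dict[str, int] = {}
    for sig in lists:
        for g in sig.genes:
            counts[g] = counts.get(g, 0) + 1
    genes = frozenset(g for g, c in counts.items() if c >= min_support)
    if not genes:
        return _empty_ok(name, lists[0].direction)
    return GeneSignature(name=name, genes=genes, direction=lists[0].direction)


def top_n_signature(ranked: RankedGeneList, n: int = 200, name: str = "") -> GeneSignature:
    """First min(n, len) genes of a descending-log2fc list."""
    if n <= 0:
        warnings.warn("top_n_signature with n <= 0 yields an empty signature")
        return _empty_ok(name or ranked.name, UP)
    genes = ranked.genes[: min(n, len(ranked))]
    return GeneSignature(name=name or ranked.name, genes=frozenset(genes), direction=UP)


@dataclass
class OrthologReport:
    n_input: int
    n_mapped: int
    unmapped: list[str]

    @property
    def unmapped_fraction(self) -> float:
        return len(self.unmapped) / self.n_input if self.n_input else 0.0


def read_ortholog_table(path) -> dict[str, set[str]]:
    """Two-column TSV (source gene, target gene) -> source -> target set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for src, tgt in zip(df["source"], df["target"]):
        mapping.setdefault(src, set()).add(tgt)
    return mapping


def map_orthologs(
    sig: GeneSignature, ortho: Mapping[str, set[str]], name: str = ""
) -> tuple[GeneSignature, OrthologReport]:
    """Map a signature across species via an ortholog table.

    One-to-many mappings contribute all targets; unmapped members are dropped
    and counted in the returned report.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in sorted(sig.genes):
        targets = ortho.get(g)
        if targets:
            mapped |= set(targets)
        else:
            unmapped.append(g)
    report = OrthologReport(len(sig.genes), len(sig.genes) - len(unmapped), unmapped)
    if not mapped:
        raise ValueError(
            f"no ortholog targets: {report.unmapped_fraction:.0%} of genes unmapped"
        )
    return (
        GeneSignature(name=name or f"{sig.name}_ortholog", genes=frozenset(mapped),
                      direction=sig.direction),
        report,
    )
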