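"""Gene-set activity scoring.

Per-cell activity of a gene signature is measured with an AUCell-style
statistic: genes are ranked by descending expression within each cell
(expression ties broken by a seeded random permutation) and the score is the
area under the recovery curve of signature genes among the top ranks,
normalized by the area of the ideal curve in which all signature genes sit
at the very top.  A cell is called "active" when its score exceeds a null
threshold built from expression-matched control gene sets: signature genes
are matched by mean-expression decile, a random control set is drawn and
scored, the 95th percentile of control scores is one putative threshold, and
the final threshold is the maximum over 100 such draws.  The max-of-repeats
construction makes the call deliberately conservative.

The module also carries the rest of the scoring toolbox used downstream:
bin-matched module scores and cell-cycle phase assignment, single-sample
GSEA for bulk cohorts, ranked-list GSEA with a gene-permutation null, and
the two-group effect statistics (Cohen's d, Wilcoxon rank-sum).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature, RankedGeneList

if TYPE_CHECKING:  # pragma: no cover
    from .io_prep import ExpressionMatrix

PHASE_PRIORITY = ("G0", "G1", "S", "G2M")


@dataclass
class ActivityResult:
    """Per-cell signature scores with the activity threshold and calls."""

    scores: pd.Series  # indexed by cell id
    threshold: float
    signature_name: str
    max_rank_fraction: float
    seed: int

    @property
    def active(self) -> pd.Series:
        return self.scores > self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.scores.index,
                "signature": self.signature_name,
                "score": self.scores.to_numpy(),
                "active": self.active.to_numpy(),
            }
        )


class CellRankings:
    """Per-cell gene rankings by descending expression, seeded tie-break.

    Computed once per (matrix, seed) so that scoring many gene sets (e.g.
    100 control sets for the threshold) reuses the same ranking.
    ``ranks[c, g]`` is the 1-based rank of gene g in cell c.
    """

    def __init__(self, m: "ExpressionMatrix", seed: int):
        X = m.dense()
        n_cells, n_genes = X.shape
        rng = np.random.default_rng(seed)
        ranks = np.empty((n_cells, n_genes), dtype=np.int32)
        positions = np.arange(1, n_genes + 1, dtype=np.int32)
        for c in range(n_cells):
            perm = rng.permutation(n_genes)
            order = perm[np.argsort(-X[c, perm], kind="stable")]
            ranks[c, order] = positions
        self.ranks = ranks
        self.gene_index = {g: i for i, g in enumerate(m.gene_ids)}
        self.cell_ids = list(m.cell_ids)
        self.n_genes = n_genes
        self.seed = seed

    def score_gene_set(self, genes: Sequence[str], max_rank_fraction: float) -> np.ndarray:
        """AUCell score of a gene set for every cell.

        Only the curve up to R = ceil(fraction * n_genes) ranks contributes;
        area = sum over signature genes of max(0, R - rank + 1), ideal area =
        sum_{x=1..R} min(x, s) with s = min(|set|, R).
        """
        if not 0 < max_rank_fraction <= 1:
            raise ValueError("max_rank_fraction must lie in (0, 1]")
        cols = [self.gene_index[g] for g in genes if g in self.gene_index]
        if not cols:
            raise ValueError("no signature gene present in the matrix")
        R = math.ceil(max_rank_fraction * self.n_genes)
        s = min(len(cols), R)
        ideal = s * (s + 1) // 2 + s * (R - s)
        r = self.ranks[:, cols]
        area = np.maximum(R + 1 - r, 0).sum(axis=1)
        return area / ideal


def aucell_score(
    m: "ExpressionMatrix",
    sig: GeneSignature,
    max_rank_fraction: float = 0.05,
    seed: int = 0,
    rankings: CellRankings | None = None,
) -> pd.Series:
    """Per-cell AUCell score of ``sig`` in ``m``; values in [0, 1].

    Warns when fewer than 80% of signature genes are present in the matrix.
    """
    if rankings is None:
        rankings = CellRankings(m, seed)
    present = sum(g in rankings.gene_index for g in sig.genes)
    if present == 0:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    if present < 0.8 * len(sig.genes):
        warnings.warn(
            f"only {present}/{len(sig.genes)} genes of {sig.name!r} present"
        )
    scores = rankings.score_gene_set(sorted(sig.genes), max_rank_fraction)
    return pd.Series(scores, index=rankings.cell_ids, name=sig.name)


# -- expression bins and control gene sets ---------------------------------

def _expression_bins(m: "ExpressionMatrix", n_bins: int) -> pd.Series:
    """Equal-frequency bins of expressed genes by mean normalized expression."""
    mean_expr = pd.Series(m.dense().mean(axis=0), index=m.gene_ids)
    expressed = mean_expr[mean_expr > 0]
    if expressed.empty:
        raise ValueError("no expressed genes")
    n_bins = min(n_bins, expressed.size)
    codes = pd.qcut(expressed.rank(method="first"), n_bins, labels=False)
    return codes.astype(int)


def _control_candidates(
    bins: pd.Series, sig_genes: set[str]
) -> dict[int, np.ndarray]:
    out = {}
    for b in sorted(bins.unique()):
        members = bins.index[bins == b]
        cands = np.array([g for g in members if g not in sig_genes])
        out[int(b)] = cands
    return out


def _draw_control_set(
    sig_bins: list[int],
    candidates: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> list[str]:
    """One bin-matched random gene per signature gene; nearest non-empty bin fallback."""
    control = []
    bin_ids = sorted(candidates)
    for b in sig_bins:
        cands = candidates.get(b)
        if cands is None or cands.size == 0:
            nearest = min(
                (bb for bb in bin_ids if candidates[bb].size > 0),
                key=lambda bb: abs(bb - b),
                default=None,
            )
            if nearest is None:
                raise ValueError("no control candidates in any bin")
            warnings.warn(f"bin {b} has no control candidates; using bin {nearest}")
            cands = candidates[nearest]
        control.append(str(rng.choice(cands)))
    return control


def activity_threshold(
    m: "ExpressionMatrix",
    sig: GeneSignature,
    n_bins: int = 10,
    pct: float = 95.0,
    n_repeats: int = 100,
    max_rank_fraction: float = 0.05,
    seed: int = 0,
    rankings: CellRankings | None = None,
) -> float:
    """Activity threshold from expression-matched control gene sets.

    One repeat draws, for each signature gene, a random gene from the same
    mean-expression bin, scores all cells on that control set, and records
    the ``pct``-th percentile of the control scores; the final threshold is
    the maximum over ``n_repeats`` repeats.
    """
    from .io_prep import LOGNORM

    if m.layer_tag != LOGNORM:
        raise ValueError("activity_threshold expects the lognorm layer")
    if rankings is None:
        rankings = CellRankings(m, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0_FFEE]))
    bins = _expression_bins(m, n_bins)
    sig_present = sorted(g for g in sig.genes if g in bins.index)
    if not sig_present:
        raise ValueError("no signature gene among expressed genes")
    sig_bins = [int(bins[g]) for g in sig_present]
    candidates = _control_candidates(bins, set(sig.genes))
    putative = np.empty(n_repeats)
    for rep in range(n_repeats):
        control = _draw_control_set(sig_bins, candidates, rng)
        scores = rankings.score_gene_set(sorted(set(control)), max_rank_fraction)
        putative[rep] = np.percentile(scores, pct)
    return float(putative.max())


def score_activity(
    m: "ExpressionMatrix",
    sig: GeneSignature,
    max_rank_fraction: float = 0.05,
    n_bins: int = 10,
    pct: float = 95.0,
    n_repeats: int = 100,
    seed: int = 0,
) -> ActivityResult:
    """AUCell scores plus the control-set threshold, as an ActivityResult."""
    rankings = CellRankings(m, seed)
    scores = aucell_score(m, sig, max_rank_fraction, rankings=rankings)
    thr = activity_threshold(
        m, sig, n_bins=n_bins, pct=pct, n_repeats=n_repeats,
        max_rank_fraction=max_rank_fraction, seed=seed, rankings=rankings,
    )
    return ActivityResult(
        scores=scores,
        threshold=thr,
        signature_name=sig.name,
        max_rank_fraction=max_rank_fraction,
        seed=seed,
    )


def module_score(
    m: "ExpressionMatrix",
    sig: GeneSignature,
    n_bins: int = 10,
    ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean signature expression minus mean of a bin-matched control pool."""
    from .io_prep import LOGNORM

    if m.layer_tag != LOGNORM:
        raise ValueError("module_score expects the lognorm layer")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C02E]))
    bins = _expression_bins(m, n_bins)
    sig_present = sorted(g for g in sig.genes if g in bins.index)
    if not sig_present:
        raise ValueError("no signature gene among expressed genes")
    candidates = _control_candidates(bins, set(sig.genes))
    pool: set[str] = set()
    for g in sig_present:
        b = int(bins[g])
        chosen = _draw_control_set([b] * ctrl_per_gene, candidates, rng)
        pool |= set(chosen)
    X = m.dense()
    gi = {g: i for i, g in enumerate(m.gene_ids)}
    sig_idx = [gi[g] for g in sig_present]
    pool_idx = [gi[g] for g in sorted(pool)]
    score = X[:, sig_idx].mean(axis=1) - X[:, pool_idx].mean(axis=1)
    return pd.Series(score, index=m.cell_ids, name=sig.name)


def assign_cell_cycle(
    m: "ExpressionMatrix",
    phase_sigs: Mapping[str, GeneSignature],
    seed: int = 0,
    n_bins: int = 10,
    ctrl_per_gene: int = 100,
) -> pd.Series:
    """Per-cell phase = argmax module score; ties broken by fixed priority.

    Requires at least the phases G0, G1, G2M, S; tie priority is the order
    G0 < G1 < S < G2M (earlier wins).
    """
    required = {"G0", "G1", "G2M", "S"}
    missing = required - set(phase_sigs)
    if missing:
        raise ValueError(f"missing phase signatures: {sorted(missing)}")
    ordered = [p for p in PHASE_PRIORITY if p in phase_sigs] + sorted(
        set(phase_sigs) - set(PHASE_PRIORITY)
    )
    score_mat = np.column_stack(
        [
            module_score(m, phase_sigs[p], n_bins=n_bins,
                         ctrl_per_gene=ctrl_per_gene, seed=seed).to_numpy()
            for p in ordered
        ]
    )
    best = np.argmax(score_mat, axis=1)  # first max wins -> priority order
    labels = pd.Series([ordered[i] for i in best], index=m.cell_ids, name="phase")
    labels.attrs["tie_priority"] = ordered
    return labels


# -- enrichment scores -----------------------------------------------------

def ssgsea(
    sample_values: pd.Series, sig: GeneSignature, alpha: float = 0.25
) -> float:
    """Single-sample GSEA enrichment score of ``sig`` in one sample.

    Genes are ranked by descending value; walking down the ranking, set
    members accumulate weight (N - position + 1)^alpha normalized over set
    members, non-members accumulate 1/(N - |set|); the score is the sum over
    positions of (cumulative in-set - cumulative out-set).  Positive scores
    mean the set concentrates at the top of the sample's ranking.
    """
    genes = sample_values.index
    in_set = np.asarray(genes.isin(sorted(sig.genes)))
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == len(genes):
        raise ValueError("signature must be a proper non-empty subset of genes")
    order = np.argsort(-sample_values.to_numpy(), kind="stable")
    hit = in_set[order]
    N = len(genes)
    rank_weight = (N - np.arange(N)).astype(float) ** alpha
    w_in = np.where(hit, rank_weight, 0.0)
    w_in /= w_in.sum()
    w_out = np.where(hit, 0.0, 1.0 / (N - n_in))
    return float(np.sum(np.cumsum(w_in) - np.cumsum(w_out)))


def ssgsea_matrix(
    values: pd.DataFrame, sigs: Sequence[GeneSignature], alpha: float = 0.25,
    rescale: bool = False,
) -> pd.DataFrame:
    """ssGSEA of several signatures over a samples x genes frame.

    Optional min-max rescaling across samples per signature.
    """
    out = pd.DataFrame(
        {
            sig.name: [ssgsea(values.loc[s], sig, alpha) for s in values.index]
            for sig in sigs
        },
        index=values.index,
    )
    if rescale:
        rng_ = out.max() - out.min()
        out = (out - out.min()) / rng_.replace(0, np.nan)
    return out


def _gsea_es(hit: np.ndarray, weight: np.ndarray) -> float:
    """Weighted KS running-sum enrichment score for a boolean hit vector."""
    w_hit = np.where(hit, weight, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = np.where(hit, 1.0, 0.0)
        total = w_hit.sum()
    n_miss = (~hit).sum()
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~hit) / n_miss if n_miss else np.zeros_like(p_hit)
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked: RankedGeneList, sig: GeneSignature, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Classic weighted-KS GSEA with a gene-permutation null.

    Weight is |log2fc|; ES is the extreme of the running sum; the null
    permutes gene-set membership; NES = ES / mean(|ES_perm| of the same
    sign); p is the same-sign permutation tail fraction with a +1
    pseudo-count.  Returns (es, nes, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = np.array(ranked.genes)
    weight = np.abs(ranked.entries["log2fc"].to_numpy())
    hit = np.isin(genes, sorted(sig.genes))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("signature does not intersect the ranked list")
    es = _gsea_es(hit, weight)
    rng = np.random.default_rng(seed)
    n = len(genes)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        ph = np.zeros(n, dtype=bool)
        ph[rng.choice(n, size=k, replace=False)] = True
        perm_es[i] = _gsea_es(ph, weight)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        nes = float("nan")
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
    return float(es), float(nes), float(p)


# -- two-group statistics --------------------------------------------------

def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with an (n-1)-weighted pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Rank-sum test with midranks; exact by enumeration for n <= 20.

    Returns (rank-sum statistic of x, p).  For combined n <= 20 the null
    distribution of the rank sum is enumerated over all C(n, n_x) group
    assignments (valid under ties); larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    allranks = _midranks(np.concatenate([x, y]))
    w = float(allranks[:nx].sum())
    if n <= 20:
        sums = np.array(
            [allranks[list(c)].sum() for c in combinations(range(n), nx)]
        )
        ge = np.mean(sums >= w - 1e-12)
        le = np.mean(sums <= w + 1e-12)
        if alternative == "greater":
            p = ge
        elif alternative == "less":
            p = le
        else:
            p = min(1.0, 2 * min(ge, le))
        return w, float(p)
    mean_w = nx * (n + 1) / 2
    _, tie_counts = np.unique(allranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_w = nx * ny / 12 * ((n + 1) - tie_term)
    if var_w == 0:
        return w, 1.0
    z_g = (w - mean_w - 0.5) / math.sqrt(var_w)
    z_l = (w - mean_w + 0.5) / math.sqrt(var_w)
    if alternative == "greater":
        p = stats.norm.sf(z_g)
    elif alternative == "less":
        p = stats.norm.cdf(z_l)
    else:
        p = min(1.0, 2 * min(stats.norm.sf(z_g), stats.norm.cdf(z_l)))
    return w, float(p)
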