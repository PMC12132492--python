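"""Resistance-Activated Cluster (RAC) calling.

A cluster is a RAC when the odds of a cell being signature-active inside the
cluster exceed the odds outside it (odds ratio > 1) with a
Benjamini-Hochberg-adjusted Fisher exact p below 0.05.  Tests run within
each cell line: every cluster is compared against all other clusters of the
same line in a 2x2 active/inactive table.

A RAC is further classified as "pre-existing" when calling RACs on the
untreated cells alone also flags it, "emergent" otherwise; non-RACs carry
status "none".

The same machinery measures drug-class concentration: for a group of member
clusters (e.g. a supercluster's components), the odds that a treated cell
carrying a given drug class sits inside the member clusters rather than
outside them.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ActivityResult

PRE_EXISTING = "pre_existing"
EMERGENT = "emergent"
NONE = "none"


def cluster_odds_ratio(a_in: int, i_in: int, a_out: int, i_out: int) -> float:
    """(active/inactive in cluster) / (active/inactive outside).

    Returns +inf for a zero inactive count inside (or zero active outside)
    with activity present, 0.0 when the cluster has no active cells.
    """
    if min(a_in, i_in, a_out, i_out) < 0:
        raise ValueError("counts must be non-negative")
    if a_in + i_in == 0 or a_out + i_out == 0:
        raise ValueError("cluster and background must both be non-empty")
    if a_in == 0:
        if a_out == 0:
            raise ValueError("odds ratio undefined: no active cells anywhere")
        return 0.0
    if i_in == 0 or a_out == 0:
        return float("inf")
    return (a_in / i_in) / (a_out / i_out)


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided p sums the probabilities of tables at most as likely as the
    observed one (the R-style definition, as implemented by scipy).
    """
    if min(a, b, c, d) < 0 or a + b + c + d < 1:
        raise ValueError("invalid 2x2 table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_racs(
    activity: ActivityResult,
    clusters: pd.Series,
    cell_lines: pd.Series | None = None,
    or_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster RAC table: odds ratio, Fisher p, BH-adjusted p, is_rac.

    ``clusters`` (and optionally ``cell_lines``) are per-cell labels indexed
    by cell id; they must cover exactly the scored cells.  The 2x2 test and
    BH correction run within each cell line.  is_rac requires strictly
    odds_ratio > or_min and p_adj < padj_max.
    """
    active = activity.active
    if set(clusters.index) != set(active.index):
        raise ValueError("cluster labels and activity cover different cells")
    clusters = clusters.reindex(active.index)
    if cell_lines is None:
        cell_lines = pd.Series("all", index=active.index)
    else:
        cell_lines = cell_lines.reindex(active.index)
    rows = []
    for line in sorted(cell_lines.astype(str).unique()):
        in_line = cell_lines.astype(str) == line
        line_active = active[in_line]
        line_clusters = clusters[in_line].astype(str)
        uniq = sorted(line_clusters.unique())
        if len(uniq) < 2:
            raise ValueError(f"cell line {line!r} has a single cluster; no background")
        n_active_total = int(line_active.sum())
        n_total = int(in_line.sum())
        line_rows = []
        for cl in uniq:
            mask = line_clusters == cl
            a_in = int(line_active[mask].sum())
            i_in = int(mask.sum()) - a_in
            a_out = n_active_total - a_in
            i_out = (n_total - int(mask.sum())) - a_out
            try:
                oratio = cluster_odds_ratio(a_in, i_in, a_out, i_out)
            except ValueError:
                oratio = float("nan")
            p = fisher_exact(a_in, i_in, a_out, i_out)
            line_rows.append(
                dict(cell_line=line, cluster_id=cl, n_active=a_in, n_inactive=i_in,
                     odds_ratio=oratio, p=p)
            )
        padj = bh_adjust([r["p"] for r in line_rows])
        for r, q in zip(line_rows, padj):
            r["p_adj"] = float(q)
            r["is_rac"] = bool(r["odds_ratio"] > or_min and q < padj_max)
        rows.extend(line_rows)
    return pd.DataFrame(rows)


def classify_rac_status(
    rac_table: pd.DataFrame,
    activity: ActivityResult,
    clusters: pd.Series,
    treated: pd.Series,
    cell_lines: pd.Series | None = None,
    or_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Add a status column: pre_existing / emergent / none.

    A RAC is pre-existing when restricting the same test to untreated cells
    also flags the cluster; emergent otherwise.  Lines without untreated
    cells leave their RACs classified emergent with a warning.
    """
    out = rac_table.copy()
    out["status"] = NONE
    untreated = ~treated.astype(bool)
    if untreated.sum() == 0:
        warnings.warn("no untreated cells; every RAC is classified emergent")
        out.loc[out["is_rac"], "status"] = EMERGENT
        return out
    sub_scores = activity.scores[untreated.reindex(activity.scores.index).to_numpy()]
    sub_activity = ActivityResult(
        scores=sub_scores,
        threshold=activity.threshold,
        signature_name=activity.signature_name,
        max_rank_fraction=activity.max_rank_fraction,
        seed=activity.seed,
    )
    try:
        base = call_racs(
            sub_activity,
            clusters.reindex(sub_scores.index),
            cell_lines.reindex(sub_scores.index) if cell_lines is not None else None,
            or_min=or_min,
            padj_max=padj_max,
        )
        base_rac = set(base.loc[base["is_rac"], "cluster_id"])
    except ValueError:
        base_rac = set()
    for i, row in out.iterrows():
        if row["is_rac"]:
            out.at[i, "status"] = (
                PRE_EXISTING if row["cluster_id"] in base_rac else EMERGENT
            )
    return out


def drug_class_enrichment(
    cell_meta: pd.DataFrame,
    member_clusters: Iterable[str],
    drug_classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Odds of a treated cell's drug class falling inside member clusters.

    Only treated cells are considered.  The 2x2 tables (in members vs not) x
    (this class vs other classes) are built within each cell line and summed
    across lines; Fisher p per class, BH across classes.  Classes absent
    from the data are skipped with a warning.
    """
    members = set(str(c) for c in member_clusters)
    treated = cell_meta[cell_meta["treated"].astype(bool)].copy()
    if treated.empty:
        raise ValueError("no treated cells")
    treated["in_members"] = treated["cluster"].astype(str).isin(members)
    present = sorted(treated["drug_class"].astype(str).unique())
    if drug_classes is None:
        drug_classes = present
    rows = []
    for cls in drug_classes:
        if cls not in present:
            warnings.warn(f"drug class {cls!r} absent; row skipped")
            continue
        a = b = c = d = 0
        for _, grp in treated.groupby("cell_line", observed=True):
            is_cls = grp["drug_class"].astype(str) == cls
            inm = grp["in_members"]
            a += int((is_cls & inm).sum())
            b += int((is_cls & ~inm).sum())
            c += int((~is_cls & inm).sum())
            d += int((~is_cls & ~inm).sum())
        try:
            oratio = cluster_odds_ratio(a, b, c, d)
        except ValueError:
            oratio = float("nan")
        rows.append(dict(drug_class=cls, n_in=a, n_out=b, odds_ratio=oratio,
                         p=fisher_exact(a, b, c, d)))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"])
    return df
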