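"""Synthetic inputs with recorded ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_cell_lines` — multi-cell-line single-cell count matrices
  with pre-assigned clusters.  Counts are negative-binomial with log-normal
  gene baseline means; in designated "active" clusters the means of a
  planted gene program are multiplied by a fold factor.  Two independent
  programs shared across lines are planted by default, so that downstream
  supercluster grouping has a known two-block answer.  Drug-class labels are
  assigned so one class concentrates (>= 80%) in the active clusters.

* :func:`simulate_ranked_lists` — ranked differential-expression lists over
  a shared gene universe, with a consensus gene subset planted uniformly
  within the top fraction of every list (fixture for rank aggregation).

* :func:`simulate_survival_cohort` — bulk expression plus survival times
  whose hazard is exponential in a planted signature-activity score, with
  hazard-independent age/sex/purity covariates (fixture for Cox recovery).

All generators are pure functions of (parameters, seed); the ground truth
is returned alongside (and serializable as a JSON sidecar) so expected RAC
calls, supercluster membership and hazard ratios can be computed in tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .io_prep import COUNTS, LOGNORM, ExpressionMatrix
from .signatures import GeneSignature, RankedGeneList

DRUG_CLASSES = ("hdac_inhibitor", "kinase_inhibitor", "alkylating_agent", "antimetabolite")
CONCENTRATED_CLASS = DRUG_CLASSES[0]
DRUGS_PER_CLASS = 2


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated dataset."""

    seed: int
    active_clusters: set[str] = field(default_factory=set)
    program_genes: set[str] = field(default_factory=set)
    fold: float = 1.0
    consensus_genes: set[str] = field(default_factory=set)
    survival_beta: float = 0.0
    programs: dict[str, list[str]] = field(default_factory=dict)
    cluster_programs: dict[str, str] = field(default_factory=dict)
    concentrated_class: str = ""
    sample_activity: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("active_clusters", "program_genes", "consensus_genes"):
            d[key] = sorted(d[key])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_cell_lines(
    n_lines: int = 3,
    clusters_per_line: int = 8,
    cells_per_cluster: int = 200,
    n_genes: int = 2000,
    program_size: int = 100,
    fold: float = 4.0,
    dispersion: float = 0.3,
    seed: int = 0,
    n_programs: int = 2,
    treated_frac: float = 0.8,
    cluster_jitter_sd: float = 0.1,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Multi-line clustered scRNA-seq counts with planted active programs.

    Each line carries ``n_programs`` active clusters, one per planted
    program; program-gene means are multiplied by ``fold`` there.  Every
    cluster additionally receives a small gene-wise log-normal jitter
    (``cluster_jitter_sd``) so clusters are distinguishable but only the
    planted programs correlate across lines.  Negative-binomial dispersion
    is ``dispersion`` (variance = mu + dispersion * mu^2).
    """
    if min(n_lines, clusters_per_line, cells_per_cluster, n_genes, program_size) < 1:
        raise ValueError("all sizes must be >= 1")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if n_programs * program_size > n_genes:
        raise ValueError("programs exceed the gene universe")
    if n_programs > clusters_per_line:
        raise ValueError("more programs than clusters per line")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    baseline = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes)

    program_idx = rng.choice(n_genes, size=n_programs * program_size, replace=False)
    programs = {
        f"P{p + 1}": sorted(genes[i] for i in program_idx[p * program_size:(p + 1) * program_size])
        for p in range(n_programs)
    }
    gene_pos = {g: i for i, g in enumerate(genes)}

    truth = SimTruth(seed=seed, fold=fold, concentrated_class=CONCENTRATED_CLASS,
                     programs=programs)
    size = 1.0 / dispersion if dispersion > 0 else np.inf

    blocks, obs_rows, cell_counter = [], [], 0
    for li in range(n_lines):
        line = f"LINE{li + 1}"
        active = rng.choice(clusters_per_line, size=n_programs, replace=False)
        cluster_program = {int(active[p]): f"P{p + 1}" for p in range(n_programs)}
        for ci in range(clusters_per_line):
            cluster = f"{line}_c{ci}"
            mu = baseline * rng.lognormal(0.0, cluster_jitter_sd, size=n_genes)
            prog = cluster_program.get(ci)
            if prog is not None:
                truth.active_clusters.add(cluster)
                truth.cluster_programs[cluster] = prog
                cols = [gene_pos[g] for g in programs[prog]]
                mu = mu.copy()
                mu[cols] *= fold
            shape = (cells_per_cluster, n_genes)
            if np.isinf(size):
                counts = rng.poisson(mu, size=shape)
            else:
                p_nb = size / (size + mu)
                counts = rng.negative_binomial(size, p_nb, size=shape)
            blocks.append(counts.astype(np.int32))
            treated = rng.random(cells_per_cluster) < treated_frac
            is_active = prog is not None
            for t in treated:
                cell_id = f"cell{cell_counter:06d}"
                cell_counter += 1
                if t:
                    if is_active:
                        cls = CONCENTRATED_CLASS if rng.random() < 0.9 else str(
                            rng.choice(DRUG_CLASSES[1:]))
                    else:
                        cls = CONCENTRATED_CLASS if rng.random() < 0.05 else str(
                            rng.choice(DRUG_CLASSES[1:]))
                    drug = f"{cls}_{int(rng.integers(DRUGS_PER_CLASS)) + 1}"
                else:
                    cls, drug = "", ""
                obs_rows.append(dict(cell_id=cell_id, cell_line=line, cluster=cluster,
                                     treated=bool(t), drug=drug, drug_class=cls))
    X = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(X, obs=obs, var=pd.DataFrame(index=genes))
    truth.program_genes = set().union(*programs.values())
    return ExpressionMatrix(adata, COUNTS), truth


def program_signature(truth: SimTruth, program: str = "P1") -> GeneSignature:
    """The planted program as a GeneSignature (for scoring stages)."""
    return GeneSignature(name=program, genes=frozenset(truth.programs[program]),
                         direction="up")


def simulate_ranked_lists(
    n_lists: int = 6,
    list_len: int = 1000,
    n_consensus: int = 50,
    consensus_top_frac: float = 0.05,
    seed: int = 0,
) -> tuple[list[RankedGeneList], SimTruth]:
    """Ranked lists over a shared universe with a planted consensus subset.

    Consensus genes land uniformly within the top ``consensus_top_frac`` of
    every list; the rest of the universe fills the remaining positions
    uniformly.  log2FC decreases strictly with rank; p/p_adj increase.
    """
    top_k = int(np.floor(consensus_top_frac * list_len))
    if n_consensus > top_k:
        raise ValueError("n_consensus exceeds the top window")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_ids(list_len))
    consensus = sorted(rng.choice(genes, size=n_consensus, replace=False))
    rest = np.array(sorted(set(genes) - set(consensus)))
    lfc = np.linspace(6.0, 0.5, list_len)
    p = np.linspace(1e-8, 0.9, list_len)
    p_adj = np.minimum(p * list_len, 1.0)
    lists = []
    for k in range(n_lists):
        order = np.empty(list_len, dtype=object)
        top_pos = rng.choice(top_k, size=n_consensus, replace=False)
        order[top_pos] = rng.permutation(consensus)
        fill = rng.permutation(rest)
        order[[i for i in range(list_len) if order[i] is None]] = fill
        lists.append(
            RankedGeneList(
                pd.DataFrame({"gene_id": order.astype(str), "log2fc": lfc,
                              "p": p, "p_adj": p_adj}),
                name=f"experiment_{k + 1}",
            )
        )
    truth = SimTruth(seed=seed, consensus_genes=set(consensus))
    return lists, truth


def simulate_survival_cohort(
    n_samples: int = 500,
    n_genes: int = 1000,
    signature: GeneSignature | None = None,
    beta: float = 1.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Bulk cohort whose hazard is exponential in a planted signature score.

    Per-sample activity a_s ~ N(0,1) shifts the expression of signature
    genes; the planted score is the z-scored mean signature-gene
    expression; event times are exponential with hazard
    h0 * exp(beta * score).  Age, sex and purity are generated independently
    of the hazard.  An all-censored draw is regenerated (up to 10 retries).
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if signature is None:
        sig_genes = _gene_ids(n_genes)[:50]
        signature = GeneSignature("planted_signature", frozenset(sig_genes), "up")
    sig_genes = sorted(signature.genes)
    filler = [g for g in _gene_ids(n_genes + len(sig_genes)) if g not in signature.genes]
    genes = sig_genes + filler[: n_genes - len(sig_genes)]
    samples = [f"sample{i:04d}" for i in range(n_samples)]

    for attempt in range(10):
        activity = rng.normal(0.0, 1.0, size=n_samples)
        base = rng.uniform(3.0, 8.0, size=len(genes))
        X = base[None, :] + rng.normal(0.0, 1.0, size=(n_samples, len(genes)))
        sig_cols = np.arange(len(sig_genes))
        X[:, sig_cols] += activity[:, None]
        X = np.clip(X, 0.0, None)
        raw = X[:, sig_cols].mean(axis=1)
        score = (raw - raw.mean()) / raw.std()
        hazard = baseline_hazard * np.exp(beta * score)
        t_event = rng.exponential(1.0 / hazard)
        censored = rng.random(n_samples) < censor_rate
        time = np.where(censored, t_event * rng.random(n_samples), t_event)
        time = np.maximum(time, 1e-6)
        event = ~censored
        if event.any():
            break
        warnings.warn("all samples censored; regenerating")
    else:
        raise RuntimeError("could not draw a cohort with at least one event")

    surv = pd.DataFrame(
        {
            "sample_id": samples,
            "time": time,
            "event": event,
            "age": rng.uniform(40, 80, n_samples).round(1),
            "sex": rng.integers(0, 2, n_samples),
            "purity": rng.beta(5, 2, n_samples).round(3),
        }
    )
    obs = pd.DataFrame(
        {"cell_line": "bulk", "cluster": "bulk", "treated": False,
         "drug": "", "drug_class": ""},
        index=samples,
    )
    adata = ad.AnnData(X, obs=obs, var=pd.DataFrame(index=genes))
    m = ExpressionMatrix(adata, LOGNORM)
    truth = SimTruth(
        seed=seed,
        survival_beta=beta,
        program_genes=set(sig_genes),
        sample_activity=dict(zip(samples, map(float, score))),
    )
    return m, surv, truth


def planted_score(m: ExpressionMatrix, signature: GeneSignature) -> pd.Series:
    """Mean signature-gene expression z-scored across samples (the planted activity)."""
    gi = {g: i for i, g in enumerate(m.gene_ids)}
    cols = [gi[g] for g in sorted(signature.genes) if g in gi]
    raw = m.dense()[:, cols].mean(axis=1)
    return pd.Series((raw - raw.mean()) / raw.std(), index=m.cell_ids, name="score")
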