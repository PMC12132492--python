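"""End-to-end orchestration of the resistance-state analysis.

``run_pipeline`` executes the stages in dependency order on a run
directory, caching each stage's outputs so a rerun regenerates only what is
missing:

  01_simulate   synthetic inputs + ground truth (or load user inputs)
  02_prep       QC filters + log-normalization
  03_signature  RRA consensus signature from the ranked DE lists
  04_score      per-line AUCell scores + control-set activity thresholds
  05_rac        RAC tables per cell line, drug-class enrichment
  06_supercluster  cross-line grouping + consensus signatures
  07_enrichment hypergeometric ORA of the supercluster signatures
  08_clinical   survival-cohort scoring, Cox fit, median split, group test

One global seed is expanded into per-stage seeds through a fixed
derivation, so any stage is independently reproducible.
"""

from __future__ import annotations

import json
import sys
import zlib
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, enrichment, io_prep, rac, scoring, signatures, supercluster, synthetic_data
from .io_prep import ExpressionMatrix
from .signatures import GeneSignature


@dataclass
class RunConfig:
    """All pipeline tunables with their protocol defaults."""

    seed: int = 0
    out_dir: str = "run"
    # optional external inputs; empty string -> simulate
    counts_dir: str = ""
    # simulation scale
    n_lines: int = 3
    clusters_per_line: int = 8
    cells_per_cluster: int = 200
    n_genes: int = 2000
    program_size: int = 100
    fold: float = 4.0
    dispersion: float = 0.3
    n_ranked_lists: int = 6
    ranked_list_len: int = 1000
    n_consensus: int = 50
    consensus_top_frac: float = 0.05
    survival_n: int = 500
    survival_beta: float = 1.0
    censor_rate: float = 0.3
    # QC / normalization
    min_features: int = 200
    max_features: int = 2500
    min_cells: int = 100
    scale: float = 1e4
    # scoring
    max_rank_fraction: float = 0.05
    n_bins: int = 10
    pct: float = 95.0
    n_repeats: int = 100
    # RAC
    or_min: float = 1.0
    padj_max: float = 0.05
    # supercluster: top-variable-gene count scaled to the default simulated
    # universe (500 of 2000 genes ~ the selectivity of 2000 on genome-scale data)
    n_variable: int = 500
    cut: float = 0.7
    min_lines: int = 2
    # ssGSEA
    alpha: float = 0.25

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in asdict(self).items()) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


def _log(run_dir: Path, msg: str) -> None:
    line = f"[resistsig] {msg}"
    print(line, file=sys.stderr)
    with open(run_dir / "run.log", "a") as fh:
        fh.write(line + "\n")


def _done(stage_dir: Path) -> bool:
    return (stage_dir / "_done").exists()


def _mark(stage_dir: Path) -> None:
    (stage_dir / "_done").write_text("ok\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.txt").write_text(config.to_text())

    # -- 01 simulate / load ------------------------------------------------
    sim_dir = run_dir / "01_simulate"
    if not _done(sim_dir):
        sim_dir.mkdir(exist_ok=True)
        if config.counts_dir:
            m = io_prep.read_matrix_dir(config.counts_dir)
            io_prep.write_matrix_dir(m, sim_dir / "cells")
            truth = None
        else:
            m, truth = synthetic_data.simulate_cell_lines(
                n_lines=config.n_lines,
                clusters_per_line=config.clusters_per_line,
                cells_per_cluster=config.cells_per_cluster,
                n_genes=config.n_genes,
                program_size=config.program_size,
                fold=config.fold,
                dispersion=config.dispersion,
                seed=stage_seed(config.seed, "cells"),
            )
            io_prep.write_matrix_dir(m, sim_dir / "cells")
            truth.to_json(sim_dir / "cells_truth.json")
        lists, list_truth = synthetic_data.simulate_ranked_lists(
            n_lists=config.n_ranked_lists,
            list_len=config.ranked_list_len,
            n_consensus=config.n_consensus,
            consensus_top_frac=config.consensus_top_frac,
            seed=stage_seed(config.seed, "lists"),
        )
        for rl in lists:
            rl.to_tsv(sim_dir / f"ranked_{rl.name}.tsv")
        list_truth.to_json(sim_dir / "lists_truth.json")
        bulk, surv, surv_truth = synthetic_data.simulate_survival_cohort(
            n_samples=config.survival_n,
            beta=config.survival_beta,
            censor_rate=config.censor_rate,
            seed=stage_seed(config.seed, "survival"),
        )
        io_prep.write_matrix_dir(bulk, sim_dir / "bulk")
        surv.to_csv(sim_dir / "survival.tsv", sep="\t", index=False)
        surv_truth.to_json(sim_dir / "survival_truth.json")
        _mark(sim_dir)
        _log(run_dir, f"01_simulate: {m.n_cells} cells x {m.n_genes} genes, "
                      f"{len(lists)} ranked lists, {len(surv)} survival samples")

    # -- 02 prep -----------------------------------------------------------
    prep_dir = run_dir / "02_prep"
    if not _done(prep_dir):
        prep_dir.mkdir(exist_ok=True)
        m = io_prep.read_matrix_dir(sim_dir / "cells")
        m = io_prep.prep(
            m,
            min_features=config.min_features,
            max_features=config.max_features,
            min_cells=config.min_cells,
            scale=config.scale,
        )
        io_prep.write_matrix_dir(m, prep_dir / "lognorm")
        _mark(prep_dir)
        _log(run_dir, f"02_prep: {m.n_cells} cells x {m.n_genes} genes after QC")

    # -- 03 signature --------------------------------------------------------
    sig_dir = run_dir / "03_signature"
    if not _done(sig_dir):
        sig_dir.mkdir(exist_ok=True)
        lists = [
            signatures.RankedGeneList.from_tsv(p)
            for p in sorted(sim_dir.glob("ranked_*.tsv"))
        ]
        table = signatures.rra_table(lists)
        table.to_csv(sig_dir / "rra_table.tsv", sep="\t", index=False)
        consensus = signatures.rra_aggregate(lists, name="rra_consensus")
        io_prep.write_gmt([consensus], sig_dir / "consensus.gmt")
        _mark(sig_dir)
        _log(run_dir, f"03_signature: consensus of {len(consensus)} genes")

    # -- 04 score ------------------------------------------------------------
    score_dir = run_dir / "04_score"
    if not _done(score_dir):
        score_dir.mkdir(exist_ok=True)
        m = io_prep.read_matrix_dir(prep_dir / "lognorm")
        sig = _resistance_signature(sim_dir, m)
        frames, thresholds = [], {}
        for line in m.cell_lines():
            sub = m.subset_cells((m.cell_meta["cell_line"].astype(str) == line).to_numpy())
            res = scoring.score_activity(
                sub, sig,
                max_rank_fraction=config.max_rank_fraction,
                n_bins=config.n_bins, pct=config.pct, n_repeats=config.n_repeats,
                seed=stage_seed(config.seed, f"score_{line}"),
            )
            thresholds[line] = res.threshold
            frames.append(res.to_frame().assign(cell_line=line))
        pd.concat(frames).to_csv(score_dir / "activity.tsv", sep="\t", index=False)
        (score_dir / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
        _mark(score_dir)
        _log(run_dir, f"04_score: thresholds {thresholds}")

    # -- 05 rac --------------------------------------------------------------
    rac_dir = run_dir / "05_rac"
    if not _done(rac_dir):
        rac_dir.mkdir(exist_ok=True)
        m = io_prep.read_matrix_dir(prep_dir / "lognorm")
        act = pd.read_csv(score_dir / "activity.tsv", sep="\t")
        thresholds = json.loads((score_dir / "thresholds.json").read_text())
        tables = []
        meta = m.cell_meta
        for line, thr in thresholds.items():
            sub = act[act["cell_line"] == line]
            res = scoring.ActivityResult(
                scores=pd.Series(sub["score"].to_numpy(), index=sub["cell_id"]),
                threshold=float(thr), signature_name="resistance",
                max_rank_fraction=config.max_rank_fraction,
                seed=stage_seed(config.seed, f"score_{line}"),
            )
            line_cells = meta.index[meta["cell_line"].astype(str) == line]
            clusters = meta.loc[line_cells, "cluster"].astype(str)
            table = rac.call_racs(res, clusters, or_min=config.or_min,
                                  padj_max=config.padj_max)
            table["cell_line"] = line
            table = rac.classify_rac_status(
                table, res, clusters, meta.loc[line_cells, "treated"],
                or_min=config.or_min, padj_max=config.padj_max,
            )
            tables.append(table)
        rac_table = pd.concat(tables, ignore_index=True)
        rac_table.to_csv(rac_dir / "rac_table.tsv", sep="\t", index=False)
        racs = rac_table.loc[rac_table["is_rac"], "cluster_id"]
        dce = rac.drug_class_enrichment(meta, set(racs))
        dce.to_csv(rac_dir / "drug_class_enrichment.tsv", sep="\t", index=False)
        _mark(rac_dir)
        _log(run_dir, f"05_rac: {int(rac_table['is_rac'].sum())} RACs "
                      f"of {len(rac_table)} clusters")

    # -- 06 supercluster -------------------------------------------------------
    sc_dir = run_dir / "06_supercluster"
    if not _done(sc_dir):
        sc_dir.mkdir(exist_ok=True)
        m = io_prep.read_matrix_dir(prep_dir / "lognorm")
        rac_table = pd.read_csv(rac_dir / "rac_table.tsv", sep="\t")
        grouping = supercluster.build_grouping(
            m, rac_table, n_variable=config.n_variable,
            min_lines=config.min_lines, cut=config.cut,
        )
        grouping.corr.to_csv(sc_dir / "correlation.tsv", sep="\t")
        assign = pd.DataFrame(
            {
                "cluster_id": list(grouping.assignment),
                "supercluster": [grouping.assignment[c] or "" for c in grouping.assignment],
            }
        )
        assign.to_csv(sc_dir / "assignment.tsv", sep="\t", index=False)
        np.savetxt(sc_dir / "linkage.tsv", grouping.linkage_record, delimiter="\t")
        sigs = []
        meta = m.cell_meta
        non_rac = set(rac_table.loc[~rac_table["is_rac"], "cluster_id"].astype(str))
        for sc in grouping.supercluster_ids:
            comp_lists = []
            for cl in grouping.members(sc):
                line = meta.loc[meta["cluster"].astype(str) == cl, "cell_line"].iloc[0]
                line_meta = meta[meta["cell_line"] == line]
                in_cl = line_meta.index[line_meta["cluster"].astype(str) == cl]
                background = line_meta.index[line_meta["cluster"].astype(str).isin(non_rac)]
                sub = m.subset_cells(line_meta.index.to_numpy())
                comp_lists.append(
                    signatures.differential_expression(sub, in_cl, background)
                )
            sig = supercluster.supercluster_signature(comp_lists, name=f"{sc}_up")
            if len(sig):
                sigs.append(sig)
        if sigs:
            io_prep.write_gmt(sigs, sc_dir / "supercluster_signatures.gmt")
        _mark(sc_dir)
        _log(run_dir, f"06_supercluster: {len(grouping.supercluster_ids)} superclusters")

    # -- 07 enrichment --------------------------------------------------------
    enr_dir = run_dir / "07_enrichment"
    if not _done(enr_dir):
        enr_dir.mkdir(exist_ok=True)
        m = io_prep.read_matrix_dir(prep_dir / "lognorm")
        truth = json.loads((sim_dir / "cells_truth.json").read_text()) if (
            sim_dir / "cells_truth.json").exists() else None
        collection = _reference_collection(m, truth, stage_seed(config.seed, "enrich"))
        gmt = sc_dir / "supercluster_signatures.gmt"
        if gmt.exists():
            for sig in io_prep.read_gmt(gmt):
                res = enrichment.overrepresentation(sig, collection, m.gene_ids)
                res.to_csv(enr_dir / f"ora_{sig.name}.tsv", sep="\t", index=False)
        _mark(enr_dir)
        _log(run_dir, "07_enrichment: done")

    # -- 08 clinical ----------------------------------------------------------
    clin_dir = run_dir / "08_clinical"
    if not _done(clin_dir):
        clin_dir.mkdir(exist_ok=True)
        bulk = io_prep.read_matrix_dir(sim_dir / "bulk")
        surv = clinical.read_survival_tsv(sim_dir / "survival.tsv")
        truth = json.loads((sim_dir / "survival_truth.json").read_text())
        sig = GeneSignature("planted_signature", frozenset(truth["program_genes"]), "up")
        values = pd.DataFrame(bulk.dense(), index=bulk.cell_ids, columns=bulk.gene_ids)
        scores = scoring.ssgsea_matrix(values, [sig], alpha=config.alpha)[sig.name]
        z = (scores - scores.mean()) / scores.std()
        surv = surv.set_index("sample_id")
        surv["score"] = z
        fit = clinical.cox_fit(surv, ["score", "age", "sex", "purity"])
        fit.summary().to_csv(clin_dir / "cox.tsv", sep="\t", index=False)
        groups = clinical.km_median_split(surv["score"])
        logrank_p = clinical.km_logrank(surv["time"], surv["event"], groups)
        direction, wp, d = clinical.compare_outcome_groups(surv["score"], surv["event"])
        pd.DataFrame(
            [dict(logrank_p=logrank_p, direction=direction, wilcoxon_p=wp, cohens_d=d,
                  n_high=groups.attrs["n_high"], n_low=groups.attrs["n_low"])]
        ).to_csv(clin_dir / "km_compare.tsv", sep="\t", index=False)
        surv.reset_index().to_csv(clin_dir / "scored_survival.tsv", sep="\t", index=False)
        _mark(clin_dir)
        _log(run_dir, f"08_clinical: hr(score) = {fit.hr[0]:.3f}")

    return run_dir


def _resistance_signature(sim_dir: Path, m: ExpressionMatrix) -> GeneSignature:
    """Signature used for activity scoring: planted programs when simulating."""
    truth_file = sim_dir / "cells_truth.json"
    if truth_file.exists():
        truth = json.loads(truth_file.read_text())
        genes = frozenset(g for g in truth["program_genes"] if g in set(m.gene_ids))
        return GeneSignature("resistance", genes, "up")
    consensus = io_prep.read_gmt(sim_dir.parent / "03_signature" / "consensus.gmt")[0]
    return consensus


def _reference_collection(m, truth, seed: int) -> list[GeneSignature]:
    """Collection for ORA: planted programs plus random background sets."""
    rng = np.random.default_rng(seed)
    genes = np.array(m.gene_ids)
    collection = []
    if truth:
        for name, members in truth["programs"].items():
            present = frozenset(g for g in members if g in set(m.gene_ids))
            if present:
                collection.append(GeneSignature(f"planted_{name}", present, "up"))
    for i in range(20):
        size = int(rng.integers(30, 120))
        collection.append(
            GeneSignature(f"random_{i:02d}",
                          frozenset(rng.choice(genes, size=size, replace=False)), "unsigned")
        )
    return collection
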