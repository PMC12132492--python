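"""Cross-cell-line supercluster grouping and consensus signatures.

Groups the called RACs across cell lines on Spearman-correlated
differential-expression vectors and measures whether the two planted
programs come back as two superclusters with the right members, and how
much of each program the consensus signatures recover.
"""

import shutil

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from common import TABLES, ensure_run, load_truth

run_dir = ensure_run()
truth = load_truth(run_dir)

assign = pd.read_csv(run_dir / "06_supercluster" / "assignment.tsv", sep="\t",
                     keep_default_na=False)
assign.to_csv(TABLES / "06_assignment.tsv", sep="\t", index=False)
shutil.copy(run_dir / "06_supercluster" / "correlation.tsv",
            TABLES / "06_correlation.tsv")

amap = dict(zip(assign["cluster_id"], assign["supercluster"]))
planted = [truth["cluster_programs"][c] for c in sorted(truth["active_clusters"])]
pred = [amap.get(c, "") for c in sorted(truth["active_clusters"])]
ari = adjusted_rand_score(planted, pred)
n_sc = len({s for s in assign["supercluster"] if s})
print(f"superclusters found: {n_sc}; ARI vs planted programs: {ari:.2f}")

import resistsig.io_prep as io_prep  # noqa: E402

gmt = run_dir / "06_supercluster" / "supercluster_signatures.gmt"
if gmt.exists():
    shutil.copy(gmt, TABLES / "06_supercluster_signatures.gmt")
    for sig in io_prep.read_gmt(gmt):
        sc = sig.name.split("_")[0]
        members = [c for c, s in amap.items() if s == sc]
        progs = {truth["cluster_programs"][c] for c in members
                 if c in truth["cluster_programs"]}
        for p in progs:
            prog_genes = set(truth["programs"][p])
            recall = len(sig.genes & prog_genes) / len(prog_genes)
            print(f"{sig.name}: {len(sig.genes)} genes; recall of planted "
                  f"{p}: {100 * recall:.1f}%")
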