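"""AUCell activity scores and control-set thresholds per cell line.

Scores every cell for the planted resistance programs and reports, per cell
line, the activity threshold and the fraction of active cells inside vs
outside the planted clusters.
"""

import json

import pandas as pd

from common import TABLES, ensure_run, load_truth

run_dir = ensure_run()
truth = load_truth(run_dir)
active_clusters = set(truth["active_clusters"])

act = pd.read_csv(run_dir / "04_score" / "activity.tsv", sep="\t")
thresholds = json.loads((run_dir / "04_score" / "thresholds.json").read_text())

import resistsig.io_prep as io_prep  # noqa: E402

m = io_prep.read_matrix_dir(run_dir / "02_prep" / "lognorm")
clusters = m.cell_meta["cluster"].astype(str)
act["cluster"] = clusters.reindex(act["cell_id"]).to_numpy()
act["in_planted"] = act["cluster"].isin(active_clusters)
summary = (
    act.groupby(["cell_line", "cluster", "in_planted"], observed=True)
    .agg(n_cells=("cell_id", "size"), mean_score=("score", "mean"),
         active_fraction=("active", "mean"))
    .reset_index()
)
summary.to_csv(TABLES / "04_activity_by_cluster.tsv", sep="\t", index=False)

for line, thr in thresholds.items():
    sub = act[act["cell_line"] == line]
    inp = sub[sub["in_planted"]]["active"].mean()
    outp = sub[~sub["in_planted"]]["active"].mean()
    print(f"{line}: threshold {thr:.3f}; active fraction "
          f"{100 * inp:.1f}% in planted clusters, {100 * outp:.1f}% elsewhere")
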