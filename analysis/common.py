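"""Shared setup for the numbered analysis scripts.

All scripts drive one cached pipeline run under results/run (seed 1, the
default synthetic study design: 3 cell lines x 8 clusters x 200 cells,
2000 genes, two 100-gene programs at fold 4).  The first script executed
materializes the run; the rest read their stage's cached outputs.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
TABLES = RESULTS / "tables"


def ensure_run(seed: int = 1):
    from resistsig.pipeline import RunConfig, run_pipeline

    TABLES.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=seed, out_dir=str(RESULTS / "run"))
    return run_pipeline(cfg)


def load_truth(run_dir, name="cells_truth.json"):
    return json.loads((Path(run_dir) / "01_simulate" / name).read_text())
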