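"""QC filtering and log-normalization of the simulated counts.

Reports how many cells and genes survive the feature-count and
detected-cell filters, per cell line.
"""

from common import ensure_run

run_dir = ensure_run()

import resistsig.io_prep as io_prep  # noqa: E402

raw = io_prep.read_matrix_dir(run_dir / "01_simulate" / "cells")
prepped = io_prep.read_matrix_dir(run_dir / "02_prep" / "lognorm")

print(f"before QC: {raw.n_cells} cells x {raw.n_genes} genes")
print(f"after  QC: {prepped.n_cells} cells x {prepped.n_genes} genes "
      f"(layer: {prepped.layer_tag})")
for line in prepped.cell_lines():
    n = int((prepped.cell_meta["cell_line"] == line).sum())
    print(f"  {line}: {n} cells")
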