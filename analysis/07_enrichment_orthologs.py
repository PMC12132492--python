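"""Functional enrichment of the supercluster signatures, plus the
cross-species ortholog route.

Runs hypergeometric over-representation of each supercluster consensus
signature against a collection containing the planted programs and random
decoy sets, then demonstrates ortholog mapping of a signature through a
synthetic two-column ortholog table.
"""

import pandas as pd

from common import TABLES, ensure_run, load_truth

run_dir = ensure_run()
truth = load_truth(run_dir)

import resistsig.io_prep as io_prep  # noqa: E402
from resistsig.signatures import map_orthologs  # noqa: E402

enr_dir = run_dir / "07_enrichment"
for path in sorted(enr_dir.glob("ora_*.tsv")):
    res = pd.read_csv(path, sep="\t")
    res.to_csv(TABLES / f"07_{path.name}", sep="\t", index=False)
    top = res.iloc[0]
    print(f"{path.stem}: top set {top['collection_set']} "
          f"(k={top['k']}/{top['K']}, adj p {top['p_adj']:.2e})")

# ortholog mapping demo: synthetic table mapping planted program genes
gmt = run_dir / "06_supercluster" / "supercluster_signatures.gmt"
if gmt.exists():
    sig = io_prep.read_gmt(gmt)[0]
    genes = sorted(sig.genes)
    # synthetic ortholog table: 70% of genes map 1:1 into an "HS_" namespace
    ortho = {g: {f"HS_{g}"} for g in genes[: int(0.7 * len(genes))]}
    mapped, report = map_orthologs(sig, ortho)
    print(f"ortholog mapping of {sig.name}: {report.n_mapped}/{report.n_input} "
          f"mapped ({100 * report.unmapped_fraction:.0f}% unmapped), "
          f"{len(mapped.genes)} target genes")
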