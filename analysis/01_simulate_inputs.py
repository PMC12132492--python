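"""Simulate every input of the study and record its ground truth.

Generates the multi-cell-line clustered count matrix with two planted
resistance programs, the six ranked DE lists with a planted consensus set,
and the survival cohort with a planted hazard coefficient of 1.
"""

from common import ensure_run, load_truth

run_dir = ensure_run()
truth = load_truth(run_dir)
lists_truth = load_truth(run_dir, "lists_truth.json")
surv_truth = load_truth(run_dir, "survival_truth.json")

print(f"run directory: {run_dir}")
print(f"planted active clusters: {sorted(truth['active_clusters'])}")
print(f"program sizes: { {k: len(v) for k, v in truth['programs'].items()} }")
print(f"concentrated drug class: {truth['concentrated_class']}")
print(f"ranked-list consensus genes: {len(lists_truth['consensus_genes'])}")
print(f"planted survival log-hazard coefficient: {surv_truth['survival_beta']}")
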