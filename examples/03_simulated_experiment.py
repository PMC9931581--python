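"""Run a complete in-silico experiment: scene -> 16 rounds -> decoding.

A 200-cell scene with 20 genes is imaged over 16 rounds with 5% bit
dropout and per-round stage drift; fiducial beads register the rounds,
spots are aggregated into molecules and decoded against the codebook.
The decode recall should match the binomial prediction
(1-p)^6 + 6 p (1-p)^5 for dropout probability p.
"""

from eelkit.workflows import simulated_experiment

res = simulated_experiment(n_cells=200, n_genes=20, p_dropout=0.05, seed=1)

print(f"true molecules        : {len(res['scene'].molecules)}")
print(f"decoded molecules     : {res['decode_stats']['n_decoded']}")
print(f"decode recall         : {res['recall']:.4f}")
print(f"binomial prediction   : {res['pred_recall']:.4f}")
print(f"per-gene count corr r : {res['gene_count_r']:.4f}")
print(f"blank FPR             : {100 * res['blank_fpr']['mean']:.4f}% "
      f"± {100 * res['blank_fpr']['sd']:.4f}% per blank code")
print(f"registration error    : {res['max_registration_translation_error_um']:.4f} um "
      "(max translation error across rounds)")
# recall ~0.96 vs prediction 0.967: the small gap is molecules lost to
# optical merging when two molecules sit closer than the match radius
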