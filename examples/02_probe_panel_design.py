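"""Design a tiled encoding-probe panel for a synthetic transcript.

Each probe binds a 26-32 nt window passing composition (40-60% G+C),
affinity (duplex dG <= -28 kcal/mol at 37 C), structure (no hairpin or
homodimer below -9 kcal/mol) and specificity filters, then carries the
six 20-nt readout sequences of its gene's barcode bits.
"""

import numpy as np

from eelkit import probe_design as pdgn
from eelkit.codebook import assign_genes, generate_codebook

rng = np.random.default_rng(42)
transcript = pdgn.TranscriptRecord("GeneA", "".join(rng.choice(list("ACGT"), 3000)))
assignments, book = assign_genes(generate_codebook(16, 6, 4, size=448), ["GeneA"])
library = pdgn.default_readout_library()

panel = pdgn.design_panel([transcript], assignments, library, seed=7)
probes = panel.probes["GeneA"]
print(f"{len(probes)} probes tiled on a 3 kb transcript "
      "(the design caps panels at 28 probes per gene)")
p = probes[0]
print(f"first probe: {p.start}-{p.end}, GC {p.gc_percent:.1f}%, "
      f"dG {p.dg_bind:.1f} kcal/mol, structure dG {p.dg_structure:.1f}")
print(f"full oligo ({len(p.full_sequence)} nt = binding + 6 x (2-nt spacer + 20-nt readout)):")
print(p.full_sequence)
print("readout tail order (randomized per probe):", p.tail_ids)
# genes whose transcript supports fewer than 10 probes are reported dropped
print("dropped genes:", panel.dropped_genes or "none")
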