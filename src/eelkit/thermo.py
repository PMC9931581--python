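"""Nearest-neighbor DNA duplex thermodynamics at 37 °C.

Unified DNA/DNA nearest-neighbor free-energy parameters (kcal/mol, 1 M
NaCl, 37 °C).  ``NN_DG37`` maps the 5'→3' dinucleotide of the top strand
(paired with its Watson–Crick complement) to the stack free energy;
``INIT_DG37`` holds the per-terminus initiation penalty keyed by the
terminal base.  Values for complementary dinucleotides (e.g. TT vs AA)
are equal by strand symmetry and are stored explicitly so lookups never
need reverse-complementation.

Probes here bind RNA, but no DNA/RNA hybrid table is shipped; the DNA/DNA
unified set is the default scoring model and an alternative table of the
same shape can be passed to the scoring functions.
"""

from __future__ import annotations

NN_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

# initiation penalty per duplex terminus, keyed by the terminal base pair
INIT_DG37: dict[str, float] = {
    "G": 0.98, "C": 0.98,
    "A": 1.03, "T": 1.03,
}

COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def duplex_delta_g(seq: str, temp_c: float = 37.0, table: dict[str, float] | None = None) -> float:
    """Free energy of the perfect duplex of ``seq`` with its complement.

    ΔG°37 = initiation (both termini) + sum of nearest-neighbor stack
    terms.  More negative means stronger binding.  Only the 37 °C
    parameter set is shipped; ``temp_c`` other than 37 raises.
    """
    if table is None:
        if abs(temp_c - 37.0) > 1e-9:
            raise ValueError("only the 37 °C parameter table is available")
        table = NN_DG37
    seq = seq.upper().replace("U", "T")
    if len(seq) < 2:
        raise ValueError("duplex requires at least 2 nucleotides")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    dg = INIT_DG37[seq[0]] + INIT_DG37[seq[-1]]
    for i in range(len(seq) - 1):
        dg += table[seq[i : i + 2]]
    return dg
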