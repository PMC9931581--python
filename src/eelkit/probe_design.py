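"""Encoding-probe panel design for barcoded smFISH.

Each encoding probe carries a 26–32 nt transcript-binding region (the
reverse complement of a target window) and an overhanging tail with the
six 20-nt readout sequences of the gene's barcode bits, in randomized
order, separated by 2-nt spacers cycling TT, AT, TA, AA.

Candidate binding regions are filtered on four rules before tiling:

- duplex free energy at 37 °C of −28 kcal/mol or less (strong binding);
- G+C content between 40 and 60%;
- no predicted hairpin or homodimer stronger than −9.0 kcal/mol;
- fewer than five off-target transcripts with >60% ungapped identity
  (a 12-mer seed-and-extend screen standing in for a full BLAST search).

Surviving candidates are tiled left-to-right with a minimum 2-bp gap, at
most 28 probes per gene; genes left with fewer than 10 probes are dropped
from the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eelkit.codebook import GeneAssignment
from eelkit.thermo import INIT_DG37, NN_DG37, duplex_delta_g, reverse_complement

__all__ = [
    "TranscriptRecord",
    "CandidateProbe",
    "ReadoutProbe",
    "ReadoutLibrary",
    "EncodingProbe",
    "PanelDesign",
    "gc_content",
    "duplex_delta_g",
    "self_structure_delta_g",
    "offtarget_screen",
    "tile_transcript",
    "design_panel",
    "default_readout_library",
    "read_fasta",
    "write_panel_tsv",
]

SPACERS = ("TT", "AT", "TA", "AA")
MIN_PROBE_LEN = 26
MAX_PROBE_LEN = 32
DG_BIND_MAX = -28.0     # candidates must bind at least this strongly
GC_RANGE = (40.0, 60.0)
DG_STRUCTURE_MIN = -9.0  # structures stronger (more negative) are disallowed
SEED_KMER = 12


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"transcript {self.id} is empty")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"transcript {self.id} has invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class CandidateProbe:
    """A candidate binding region: [start, end) on the transcript."""

    gene: str
    start: int
    end: int
    binding_seq: str  # reverse complement of the target window
    dg_bind: float
    gc_percent: float
    dg_structure: float

    def __post_init__(self) -> None:
        if not (MIN_PROBE_LEN <= self.end - self.start <= MAX_PROBE_LEN):
            raise ValueError("probe length must be 26–32 nt")
        if len(self.binding_seq) != self.end - self.start:
            raise ValueError("binding_seq length mismatch")


@dataclass(frozen=True)
class ReadoutProbe:
    id: str
    sequence: str
    channel: str = "A647"


@dataclass(frozen=True)
class ReadoutLibrary:
    """One 20-nt detection sequence per readout bit."""

    probes: tuple[ReadoutProbe, ...]

    def __post_init__(self) -> None:
        seqs = [p.sequence for p in self.probes]
        if any(len(s) != 20 for s in seqs):
            raise ValueError("readout sequences must be 20 nt")
        if len(set(seqs)) != len(seqs) or len({p.id for p in self.probes}) != len(self.probes):
            raise ValueError("readout ids and sequences must be distinct")

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, bit: int) -> ReadoutProbe:
        return self.probes[bit]


@dataclass(frozen=True)
class EncodingProbe:
    gene: str
    start: int
    end: int
    binding_seq: str
    tail_bits: tuple[int, ...]  # readout bit order as assembled, 5'->3'
    tail_ids: tuple[str, ...]
    full_sequence: str
    dg_bind: float
    gc_percent: float
    dg_structure: float


@dataclass
class PanelDesign:
    """Result of designing a full panel: probes per gene plus dropped genes."""

    probes: dict[str, list[EncodingProbe]] = field(default_factory=dict)
    dropped_genes: dict[str, int] = field(default_factory=dict)  # gene -> surviving probe count
    metadata: dict = field(default_factory=dict)


def gc_content(seq: str) -> float:
    """G+C percentage of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def _complementary(a: str, b: str) -> bool:
    return (a, b) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def self_structure_delta_g(seq: str, min_stem: int = 3, min_loop: int = 3) -> float:
    """Minimum ΔG over predicted hairpins and homodimers; 0 if none form.

    Hairpins: every ungapped stem of >= ``min_stem`` base pairs enclosing a
    loop of >= ``min_loop`` nt, scored as the duplex free energy of the stem.
    Homodimers: every ungapped antiparallel self-alignment run of >= 2
    complementary pairs, scored the same way.  The returned value is the
    most stable (most negative) structure, or 0.0 when no structure with
    negative free energy exists.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    if n < 6:
        raise ValueError("sequence too short for structure prediction")
    best = 0.0

    # hairpins: pair (i + t, j - t); stem k requires loop j - i - 2k + 1 >= min_loop
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            k = 0
            while (
                i + k < j - k
                and (j - k) - (i + k) - 1 >= min_loop
                and _complementary(seq[i + k], seq[j - k])
            ):
                k += 1
            if k >= min_stem:
                dg = duplex_delta_g(seq[i : i + k])
                if dg < best:
                    best = dg

    # homodimers: antiparallel alignment of the sequence with itself;
    # copy-1 position i pairs with copy-2 position c - i, c = alignment offset
    for c in range(1, 2 * n - 2):  # overlap of >= 2 positions
        run_start = None
        lo = max(0, c - n + 1)
        hi = min(n - 1, c)
        for i in range(lo, hi + 2):
            paired = i <= hi and _complementary(seq[i], seq[c - i])
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                if i - run_start >= 2:
                    dg = duplex_delta_g(seq[run_start:i])
                    if dg < best:
                        best = dg
                run_start = None
    return best


def _kmer_index(transcriptome: list[TranscriptRecord], k: int = SEED_KMER) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for rec in transcriptome:
        seq = rec.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((rec.id, pos))
    return index


def offtarget_screen(
    binding_seq: str,
    gene: str,
    transcriptome: list[TranscriptRecord],
    identity_frac: float = 0.60,
    max_offtargets: int = 5,
    kmer_index: dict[str, list[tuple[str, int]]] | None = None,
) -> tuple[bool, list[str]]:
    """Specificity screen: seed-and-extend against non-target transcripts.

    A probe fails when at least ``max_offtargets`` distinct non-target
    transcripts contain an ungapped window whose identity to the probe
    exceeds ``identity_frac``.  Seeding uses exact 12-mers, so hits with
    no shared 12-mer are invisible — the screen is a fast proxy for a
    full alignment search.

    Returns (passes, sorted list of off-target transcript ids).
    """
    if len(binding_seq) < MIN_PROBE_LEN:
        raise ValueError("probe too short to screen")
    probe = binding_seq.upper()
    if kmer_index is None:
        kmer_index = _kmer_index(transcriptome)
    seqs = {rec.id: rec.sequence for rec in transcriptome}
    hits: set[str] = set()
    checked: set[tuple[str, int]] = set()
    for off in range(len(probe) - SEED_KMER + 1):
        for tid, pos in kmer_index.get(probe[off : off + SEED_KMER], ()):
            if tid == gene:
                continue
            anchor = pos - off  # probe position 0 aligns here
            if (tid, anchor) in checked or tid in hits:
                continue
            checked.add((tid, anchor))
            target = seqs[tid]
            matches = 0
            for i, base in enumerate(probe):
                j = anchor + i
                if 0 <= j < len(target) and target[j] == base:
                    matches += 1
            if matches / len(probe) > identity_frac:
                hits.add(tid)
    passes = len(hits) < max_offtargets
    return passes, sorted(hits)


def tile_transcript(
    candidates: list[CandidateProbe], min_gap: int = 2, max_probes: int = 28
) -> list[CandidateProbe]:
    """Greedy left-to-right tiling of non-overlapping candidates.

    Repeatedly takes the first candidate (in input order, which is
    (start, length)-sorted for panel design) starting at least ``min_gap``
    past the previous probe's end, until ``max_probes`` are selected.
    """
    selected: list[CandidateProbe] = []
    next_start = 0
    for cand in candidates:
        if len(selected) >= max_probes:
            break
        if cand.start >= next_start:
            selected.append(cand)
            next_start = cand.end + min_gap
    return selected


def _windows_passing_cheap_filters(seq: str) -> list[tuple[int, int, float, float]]:
    """Vectorized GC and duplex-ΔG evaluation of all 26–32 nt windows.

    Returns (start, end, dg_bind, gc_percent) for windows passing the GC
    and binding-energy filters, ordered by start then length ascending.
    """
    n = len(seq)
    if n < MIN_PROBE_LEN:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.float64)
    gc_cum = np.concatenate([[0.0], np.cumsum(is_gc)])
    stack = np.array([NN_DG37[seq[i : i + 2]] for i in range(n - 1)])
    stack_cum = np.concatenate([[0.0], np.cumsum(stack)])
    init = np.array([INIT_DG37[b] for b in seq])
    out = []
    for start in range(n - MIN_PROBE_LEN + 1):
        for length in range(MIN_PROBE_LEN, MAX_PROBE_LEN + 1):
            end = start + length
            if end > n:
                break
            gc = 100.0 * (gc_cum[end] - gc_cum[start]) / length
            if not (GC_RANGE[0] <= gc <= GC_RANGE[1]):
                continue
            dg = init[start] + init[end - 1] + (stack_cum[end - 1] - stack_cum[start])
            if dg > DG_BIND_MAX:
                continue
            out.append((start, end, float(dg), float(gc)))
    return out


def enumerate_candidates(
    transcript: TranscriptRecord,
    transcriptome: list[TranscriptRecord] | None = None,
    kmer_index: dict[str, list[tuple[str, int]]] | None = None,
) -> list[CandidateProbe]:
    """All filtered binding-region candidates for one transcript.

    Windows are enumerated at every offset and length 26–32, by start then
    length ascending; cheap composition/energy filters run vectorized first,
    the structure and specificity screens on the survivors.
    """
    seq = transcript.sequence
    cands: list[CandidateProbe] = []
    for start, end, dg_bind, gc in _windows_passing_cheap_filters(seq):
        window = seq[start:end]
        binding = reverse_complement(window)
        dg_struct = self_structure_delta_g(binding)
        if dg_struct < DG_STRUCTURE_MIN:
            continue
        if transcriptome is not None:
            ok, _ = offtarget_screen(
                binding, transcript.id, transcriptome, kmer_index=kmer_index
            )
            if not ok:
                continue
        cands.append(
            CandidateProbe(transcript.id, start, end, binding, dg_bind, gc, dg_struct)
        )
    return cands


def default_readout_library(n_bits: int = 16, seed: int = 2023) -> ReadoutLibrary:
    """Deterministic library of distinct 20-nt detection sequences.

    Sequences are sampled with 40–60% G+C and no run longer than 4;
    one per readout bit, ids ``R00..R15``.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: list[str] = []
    while len(seqs) < n_bits:
        s = "".join(rng.choice(bases, size=20))
        if not (40.0 <= gc_content(s) <= 60.0):
            continue
        if any(b * 5 in s for b in "ACGT"):
            continue
        if s in seqs:
            continue
        seqs.append(s)
    return ReadoutLibrary(tuple(ReadoutProbe(f"R{i:02d}", s) for i, s in enumerate(seqs)))


def _assemble(binding_seq: str, bits: tuple[int, ...], library: ReadoutLibrary) -> str:
    """Binding region 5' of the tail; a 2-nt spacer precedes every readout
    sequence, including the first (cycling TT, AT, TA, AA)."""
    parts = [binding_seq]
    for k, bit in enumerate(bits):
        parts.append(SPACERS[k % 4])
        parts.append(library[bit].sequence)
    return "".join(parts)


def design_panel(
    transcripts: list[TranscriptRecord],
    assignments: list[GeneAssignment],
    readout_library: ReadoutLibrary,
    seed: int = 0,
    min_probes: int = 10,
    max_probes: int = 28,
    min_gap: int = 2,
    screen_offtargets: bool = True,
) -> PanelDesign:
    """Design the encoding-probe panel for an assigned gene set.

    Per gene: enumerate and filter candidates, tile, drop genes with fewer
    than ``min_probes`` survivors, then assemble full oligos.  Each probe's
    six readout tails are the "on" bits of the gene's codeword in an order
    randomized per probe (seeded), so the panel is reproducible.
    """
    by_id = {t.id: t for t in transcripts}
    missing = [a.gene for a in assignments if a.gene not in by_id]
    if missing:
        raise ValueError(f"no transcript for assigned genes: {missing}")
    rng = np.random.default_rng(seed)
    kmer_index = _kmer_index(transcripts) if screen_offtargets else None
    design = PanelDesign(
        metadata={
            "spacer_convention": "2-nt spacer before every readout tail, "
            "including the first; cycle TT,AT,TA,AA",
            "thermo_table": "unified DNA/DNA nearest-neighbor, 37C",
            "seed": seed,
        }
    )
    for a in assignments:
        transcript = by_id[a.gene]
        if len(transcript.sequence) < MIN_PROBE_LEN:
            design.dropped_genes[a.gene] = 0
            continue
        cands = enumerate_candidates(
            transcript,
            transcripts if screen_offtargets else None,
            kmer_index=kmer_index,
        )
        tiled = tile_transcript(cands, min_gap=min_gap, max_probes=max_probes)
        if len(tiled) < min_probes:
            design.dropped_genes[a.gene] = len(tiled)
            continue
        on_bits = a.codeword.on_bits
        probes = []
        for cand in tiled:
            order = tuple(int(b) for b in rng.permutation(on_bits))
            probes.append(
                EncodingProbe(
                    gene=a.gene,
                    start=cand.start,
                    end=cand.end,
                    binding_seq=cand.binding_seq,
                    tail_bits=order,
                    tail_ids=tuple(readout_library[b].id for b in order),
                    full_sequence=_assemble(cand.binding_seq, order, readout_library),
                    dg_bind=cand.dg_bind,
                    gc_percent=cand.gc_percent,
                    dg_structure=cand.dg_structure,
                )
            )
        design.probes[a.gene] = probes
    return design


def read_fasta(path) -> list[TranscriptRecord]:
    from Bio import SeqIO

    return [TranscriptRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_panel_tsv(design: PanelDesign, path) -> None:
    import pandas as pd

    rows = [
        {
            "gene": p.gene,
            "start": p.start,
            "end": p.end,
            "binding_seq": p.binding_seq,
            "tail_order": ",".join(p.tail_ids),
            "full_sequence": p.full_sequence,
            "dg_bind": p.dg_bind,
            "gc_percent": p.gc_percent,
            "dg_structure": p.dg_structure,
        }
        for probes in design.probes.values()
        for p in probes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
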