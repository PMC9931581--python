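"""Constant-weight error-correcting barcode codebooks.

Genes are encoded as binary words over imaging rounds: a gene's molecules
fluoresce only in the rounds where its codeword bit is 1.  The default
scheme uses words of length 16 with exactly 6 positive bits and a minimum
pairwise Hamming distance of 4, which supports correcting any single bit
error while detecting double errors, and leaves room for "blank" codewords
assigned to no gene whose decoded counts estimate the false-positive rate.

Construction for distance 4 uses a checksum residue class: among all
weight-w words of length n, keep those with ``sum(i * x_i) % n`` equal to
a fixed residue.  Two distinct equal-weight words differ in an even number
of bits; if they differed in exactly two, the checksum would differ by the
(nonzero) gap between the two positions, so words sharing a residue class
are at distance >= 4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Codeword",
    "Codebook",
    "GeneAssignment",
    "DecodeResult",
    "generate_codebook",
    "validate_codebook",
    "assign_genes",
    "decode_word",
    "read_codebook_csv",
    "write_codebook_csv",
]


@dataclass(frozen=True)
class Codeword:
    """An immutable binary barcode; bit index = readout round index."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("codeword bits must be 0 or 1")

    @property
    def weight(self) -> int:
        return sum(self.bits)

    @property
    def on_bits(self) -> tuple[int, ...]:
        """Indices of the rounds in which this barcode lights up."""
        return tuple(i for i, b in enumerate(self.bits) if b)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "Codeword":
        return cls(tuple(int(c) for c in s))

    @classmethod
    def from_on_bits(cls, on: tuple[int, ...], n_bits: int) -> "Codeword":
        bits = [0] * n_bits
        for i in on:
            bits[i] = 1
        return cls(tuple(bits))


def _hamming(a: Codeword, b: Codeword) -> int:
    return sum(x != y for x, y in zip(a.bits, b.bits))


@dataclass
class Codebook:
    """A set of labelled constant-weight codewords with distance guarantees.

    ``entries`` maps labels (gene symbols or ``Blank-k``) to codewords.
    All codewords are distinct, have Hamming weight ``weight`` and every
    pair is at Hamming distance >= ``min_distance``.
    """

    n_bits: int
    weight: int
    min_distance: int
    entries: dict[str, Codeword] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> Codeword:
        return self.entries[label]

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    @property
    def blank_labels(self) -> list[str]:
        return [lab for lab in self.entries if lab.startswith("Blank-")]

    @property
    def gene_labels(self) -> list[str]:
        return [lab for lab in self.entries if not lab.startswith("Blank-")]

    def to_matrix(self) -> np.ndarray:
        """(n_entries, n_bits) uint8 matrix in label order."""
        return np.array([cw.bits for cw in self.entries.values()], dtype=np.uint8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.entries), "code": [str(cw) for cw in self.entries.values()]}
        )


@dataclass(frozen=True)
class GeneAssignment:
    gene: str
    codeword: Codeword
    coexpression_group: str | None = None


def _checksum_class_words(n_bits: int, weight: int) -> list[tuple[int, ...]]:
    """All weight-w words (as on-bit tuples) of the largest checksum class.

    Checksum s(x) = sum of on-bit positions mod n_bits (0-based). Ties
    between equally large residue classes break to the smallest residue,
    so construction is deterministic without a seed.
    """
    classes: dict[int, list[tuple[int, ...]]] = {r: [] for r in range(n_bits)}
    for comb in itertools.combinations(range(n_bits), weight):
        classes[sum(comb) % n_bits].append(comb)
    best = max(classes, key=lambda r: (len(classes[r]), -r))
    return classes[best]


def _greedy_lexicode(n_bits: int, weight: int, min_distance: int) -> list[tuple[int, ...]]:
    """Greedy lexicographic accept/reject over all weight-w words."""
    accepted: list[np.ndarray] = []
    out: list[tuple[int, ...]] = []
    for comb in itertools.combinations(range(n_bits), weight):
        v = np.zeros(n_bits, dtype=np.uint8)
        v[list(comb)] = 1
        if accepted:
            dists = (np.vstack(accepted) != v).sum(axis=1)
            if dists.min() < min_distance:
                continue
        accepted.append(v)
        out.append(comb)
    return out


def generate_codebook(n_bits: int, weight: int, min_distance: int, size: int | None = None) -> Codebook:
    """Construct a constant-weight codebook with guaranteed pairwise distance.

    For ``min_distance == 4`` the checksum-class construction is used
    (deterministic, size >= C(n,w)/n by pigeonhole); for other distances a
    greedy lexicographic accept/reject scan is used.  Entries are labelled
    ``Blank-1..Blank-N`` until genes are assigned.  ``size`` optionally
    truncates to the lexicographically first ``size`` codewords (e.g. the
    448 codes actually used per color channel in a 16-round experiment).

    Raises
    ------
    ValueError
        If ``weight >= n_bits``, ``weight <= 0``, or ``min_distance`` is
        odd or < 2 (equal-weight words always differ in an even number of
        bits, so odd distances are unattainable guarantees).
    """
    if not (0 < weight < n_bits):
        raise ValueError(f"need 0 < weight < n_bits, got weight={weight}, n_bits={n_bits}")
    if min_distance < 2 or min_distance % 2 != 0:
        raise ValueError(f"min_distance must be even and >= 2, got {min_distance}")
    if min_distance == 2:
        # distinct equal-weight words always differ in >= 2 bits
        combs = list(itertools.combinations(range(n_bits), weight))
    elif min_distance == 4:
        combs = _checksum_class_words(n_bits, weight)
    else:
        combs = _greedy_lexicode(n_bits, weight, min_distance)
    combs = sorted(combs)
    if size is not None:
        if size > len(combs):
            raise ValueError(f"requested size {size} exceeds construction size {len(combs)}")
        combs = combs[:size]
    entries = {
        f"Blank-{k + 1}": Codeword.from_on_bits(comb, n_bits)
        for k, comb in enumerate(sorted(combs))
    }
    return Codebook(n_bits=n_bits, weight=weight, min_distance=min_distance, entries=entries)


def validate_codebook(cb: Codebook) -> dict:
    """Exhaustive validation report: min pairwise distance, weight histogram,
    duplicate count, and whether the codebook's stated guarantees hold."""
    if len(cb) == 0:
        raise ValueError("empty codebook")
    mat = cb.to_matrix().astype(np.int16)
    n = mat.shape[0]
    weights = mat.sum(axis=1)
    weight_hist = {int(w): int(c) for w, c in zip(*np.unique(weights, return_counts=True))}
    if n > 1:
        # pairwise Hamming distances via dot products on +-1 is overkill;
        # direct block comparison is fine at n <= ~8008
        gram = mat @ mat.T
        dists = weights[:, None] + weights[None, :] - 2 * gram
        iu = np.triu_indices(n, k=1)
        min_dist = int(dists[iu].min())
        duplicates = int((dists[iu] == 0).sum())
    else:
        min_dist = cb.n_bits
        duplicates = 0
    return {
        "n_entries": n,
        "min_pairwise_distance": min_dist,
        "weight_histogram": weight_hist,
        "duplicate_count": duplicates,
        "distance_ok": min_dist >= cb.min_distance and duplicates == 0,
        "weight_ok": set(weight_hist) == {cb.weight},
    }


def _round_collision_score(
    assigned: dict[str, Codeword], groups: dict[str, str], n_bits: int
) -> int:
    """Sum over rounds of same-group gene pairs both 'on' in that round."""
    score = 0
    for r in range(n_bits):
        on_by_group: dict[str, int] = {}
        for gene, cw in assigned.items():
            g = groups.get(gene)
            if g is not None and cw.bits[r]:
                on_by_group[g] = on_by_group.get(g, 0) + 1
        for cnt in on_by_group.values():
            score += cnt * (cnt - 1) // 2
    return score


def assign_genes(
    cb: Codebook,
    genes: list[str],
    coexpression_groups: dict[str, str] | None = None,
    seed: int = 0,
    n_sweeps: int = 20,
) -> tuple[list[GeneAssignment], Codebook]:
    """Assign genes to codewords; leftover codewords become blanks.

    Without coexpression groups the assignment is deterministic in input
    order (i-th gene gets the i-th codeword).  With groups, co-expressed
    genes are kept out of shared decoding rounds as far as possible:
    greedy assignment (each gene takes the codeword minimizing the
    incremental same-group same-round pair count) followed by seeded
    pairwise-swap hill climbing.

    Returns the assignments and a relabelled codebook whose entries carry
    gene symbols, with remaining codewords labelled ``Blank-1..Blank-k``
    in lexicographic codeword order.
    """
    if len(genes) > len(cb):
        raise ValueError(f"{len(genes)} genes exceed codebook capacity {len(cb)}")
    if len(set(genes)) != len(genes):
        raise ValueError("gene list contains duplicates")
    words = list(cb.entries.values())

    if not coexpression_groups:
        assigned = {g: words[i] for i, g in enumerate(genes)}
    else:
        rng = np.random.default_rng(seed)
        groups = dict(coexpression_groups)
        assigned = {}
        free = list(words)
        # genes with group constraints first, then the rest
        order = sorted(genes, key=lambda g: (groups.get(g) is None, genes.index(g)))
        for gene in order:
            if groups.get(gene) is None:
                assigned[gene] = free.pop(0)
                continue
            best_i, best_s = 0, None
            for i, cand in enumerate(free):
                trial = dict(assigned)
                trial[gene] = cand
                s = _round_collision_score(trial, groups, cb.n_bits)
                if best_s is None or s < best_s:
                    best_i, best_s = i, s
                    if s == 0:
                        break
            assigned[gene] = free.pop(best_i)
        # pairwise-swap hill climbing over gene/gene and gene/free swaps
        cur = _round_collision_score(assigned, groups, cb.n_bits)
        gene_list = list(assigned)
        for _ in range(n_sweeps):
            if cur == 0:
                break
            improved = False
            idx = rng.permutation(len(gene_list))
            for a in idx:
                for b in range(len(gene_list)):
                    if a == b:
                        continue
                    ga, gb = gene_list[a], gene_list[b]
                    assigned[ga], assigned[gb] = assigned[gb], assigned[ga]
                    s = _round_collision_score(assigned, groups, cb.n_bits)
                    if s < cur:
                        cur = s
                        improved = True
                    else:
                        assigned[ga], assigned[gb] = assigned[gb], assigned[ga]
            if not improved:
                break

    used = set(assigned.values())
    blanks = sorted((cw for cw in words if cw not in used), key=lambda cw: cw.bits)
    entries: dict[str, Codeword] = {g: assigned[g] for g in genes}
    for k, cw in enumerate(blanks):
        entries[f"Blank-{k + 1}"] = cw
    out_cb = Codebook(cb.n_bits, cb.weight, cb.min_distance, entries)
    assignments = [
        GeneAssignment(g, assigned[g], (coexpression_groups or {}).get(g)) for g in genes
    ]
    return assignments, out_cb


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of decoding one observed bit word.

    ``label`` is None for a no-call; ``reason`` is then "distance" (no
    codeword within ``max_correct``) or "tie" (two codewords equally near).
    """

    label: str | None
    bit_errors: int | None
    reason: str | None = None

    @property
    def is_call(self) -> bool:
        return self.label is not None


def decode_word(observed, cb: Codebook, max_correct: int = 1) -> DecodeResult:
    """Nearest-neighbor decode of an observed bit vector.

    Returns the unique codebook entry within Hamming distance
    ``max_correct``; ambiguity (a distance tie at the minimum) or distance
    beyond ``max_correct`` yields a no-call, never an arbitrary pick —
    silent mis-calls would bias the blank-based false-positive rate.
    """
    obs = np.asarray(observed, dtype=np.uint8)
    if obs.shape != (cb.n_bits,):
        raise ValueError(f"observed word must have {cb.n_bits} bits")
    mat = cb.to_matrix()
    dists = np.abs(mat.astype(np.int16) - obs.astype(np.int16)).sum(axis=1)
    order = np.argsort(dists, kind="stable")
    best = int(dists[order[0]])
    if best > max_correct:
        return DecodeResult(None, None, "distance")
    if len(order) > 1 and int(dists[order[1]]) == best:
        return DecodeResult(None, None, "tie")
    return DecodeResult(list(cb.entries)[order[0]], best)


def write_codebook_csv(cb: Codebook, path) -> None:
    """Write `label,code` CSV; code is the bit string, bit 0 leftmost."""
    cb.to_frame().to_csv(path, index=False)


def read_codebook_csv(path, min_distance: int = 4) -> Codebook:
    df = pd.read_csv(path, dtype={"label": str, "code": str})
    entries = {row.label: Codeword.from_string(row.code) for row in df.itertuples()}
    first = next(iter(entries.values()))
    return Codebook(len(first.bits), first.weight, min_distance, entries)
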