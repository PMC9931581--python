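"""Spot aggregation, barcode decoding, blank FPR, mask expansion and
molecule-to-cell assignment.

Registered spots from all rounds are joined into candidate molecules by
connected components of a cross-round proximity graph; each candidate's
observed bit word has bit r set iff the component contains a spot from
round r.  Words are decoded against the codebook with single-bit error
correction; codewords assigned to no gene ("blanks") provide an internal
false-positive rate estimate.  Nucleus segmentation masks are expanded a
fixed distance without overlap and molecules are assigned to the cell
whose expanded mask they fall in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from eelkit.codebook import Codebook, decode_word
from eelkit.transforms import SimilarityTransform

__all__ = [
    "CellMatrix",
    "aggregate_rounds",
    "decode_molecules",
    "blank_fpr",
    "expand_masks",
    "assign_to_cells",
    "qc_cells",
]


def aggregate_rounds(spots: pd.DataFrame, match_radius_um: float = 0.75) -> pd.DataFrame:
    """Group registered spots across rounds into candidate molecules.

    ``spots`` must hold all rounds in one reference frame (columns
    spot_id, round, x_um, y_um; beads should be excluded beforehand).
    Spots from *different* rounds within ``match_radius_um`` are joined;
    connected components become candidates.  Within a component, rounds
    represented by several spots are deduplicated by keeping the spot
    closest to the component centroid, so no candidate spans more spots
    than rounds.

    Returns one row per candidate: word (bit string), n_on_bits,
    x_um/y_um (centroid of kept member spots), spot_ids.
    """
    df = spots.reset_index(drop=True)
    xy = df[["x_um", "y_um"]].to_numpy()
    rounds = df["round"].to_numpy()
    n_bits = int(rounds.max()) + 1 if len(df) else 0
    g = nx.Graph()
    g.add_nodes_from(range(len(df)))
    if len(df):
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(match_radius_um):
            if rounds[i] != rounds[j]:
                g.add_edge(i, j)

    rows = []
    for comp in nx.connected_components(g):
        idx = np.fromiter(comp, dtype=int)
        centroid = xy[idx].mean(axis=0)
        # keep one spot per round: the one nearest the component centroid
        keep: dict[int, int] = {}
        for i in idx:
            r = int(rounds[i])
            if r not in keep or (
                np.hypot(*(xy[i] - centroid)) < np.hypot(*(xy[keep[r]] - centroid))
            ):
                keep[r] = i
        kept = np.array(sorted(keep.values()))
        word = np.zeros(n_bits, dtype=np.uint8)
        word[sorted(keep)] = 1
        pos = xy[kept].mean(axis=0)
        rows.append(
            (
                "".join(map(str, word)),
                int(word.sum()),
                float(pos[0]),
                float(pos[1]),
                tuple(int(df["spot_id"].iloc[k]) for k in kept),
            )
        )
    return pd.DataFrame(rows, columns=["word", "n_on_bits", "x_um", "y_um", "spot_ids"])


def decode_molecules(
    candidates: pd.DataFrame, codebook: Codebook, max_correct: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Decode candidate bit words against the codebook.

    No-calls (no codeword within ``max_correct`` or a distance tie) are
    dropped from the table but counted in the returned stats, which also
    carry per-label totals.  Decoding is vectorized: one Hamming-distance
    matrix between candidate words and codebook rows.
    """
    stats = {"n_candidates": len(candidates), "n_nocall_distance": 0, "n_nocall_tie": 0}
    if len(candidates) == 0:
        empty = pd.DataFrame(
            columns=["label", "x_um", "y_um", "n_on_bits", "bit_errors", "spot_ids"]
        )
        stats["per_label"] = {}
        return empty, stats

    words = np.array(
        [[int(c) for c in w] for w in candidates["word"]], dtype=np.int16
    )
    mat = codebook.to_matrix().astype(np.int16)
    labels = list(codebook.entries)
    # Hamming distance via weights and overlap
    dists = words.sum(1)[:, None] + mat.sum(1)[None, :] - 2 * (words @ mat.T)
    best_idx = np.argmin(dists, axis=1)
    best = dists[np.arange(len(words)), best_idx]
    sorted_d = np.sort(dists, axis=1)
    tie = (sorted_d[:, 0] == sorted_d[:, 1]) if dists.shape[1] > 1 else np.zeros(len(words), bool)
    callable_ = best <= max_correct
    stats["n_nocall_distance"] = int((~callable_).sum())
    stats["n_nocall_tie"] = int((callable_ & tie).sum())
    ok = callable_ & ~tie

    out = candidates.loc[ok, ["x_um", "y_um", "n_on_bits", "spot_ids"]].copy()
    out.insert(0, "label", [labels[i] for i in best_idx[ok]])
    out["bit_errors"] = best[ok].astype(int)
    out = out[["label", "x_um", "y_um", "n_on_bits", "bit_errors", "spot_ids"]].reset_index(
        drop=True
    )
    stats["per_label"] = out["label"].value_counts().to_dict()
    stats["n_decoded"] = len(out)
    return out, stats


def blank_fpr(decoded: pd.DataFrame, codebook: Codebook) -> dict:
    """Blank-based false-positive rate.

    For each blank codeword b: count(b) / total decoded molecules; the
    report carries every per-blank fraction plus their mean and sd (ddof=0).
    The denominator convention (all decoded molecules, genes + blanks) is
    recorded in the result under ``definition``.
    """
    blanks = codebook.blank_labels
    if not blanks:
        raise ValueError("codebook contains no blank codewords")
    total = len(decoded)
    counts = decoded["label"].value_counts()
    fracs = np.array([counts.get(b, 0) / total if total else 0.0 for b in blanks])
    return {
        "per_blank": dict(zip(blanks, fracs)),
        "mean": float(fracs.mean()),
        "sd": float(fracs.std()),
        "n_decoded": total,
        "definition": "per-blank decoded count / total decoded molecules",
    }


def expand_masks(
    label_image: np.ndarray, pixel_size_um: float, distance_um: float = 8.0
) -> np.ndarray:
    """Expand integer segmentation labels outward without overlap.

    Every background pixel within ``distance_um`` of a labeled pixel takes
    the label of its nearest seed pixel (Euclidean distance between pixel
    centers); exact distance ties go to the smaller label id, and original
    labeled pixels are never reassigned.  Pixels must be isotropic.

    Implemented as one distance transform per label restricted to the
    label's expanded bounding box, which makes the tie rule exact.
    """
    if label_image.ndim != 2:
        raise ValueError("expected a 2D label image (isotropic pixels)")
    if np.issubdtype(label_image.dtype, np.floating):
        raise ValueError("label image must be integer")
    if (label_image < 0).any():
        raise ValueError("labels must be non-negative (0 = background)")
    if distance_um <= 0:
        return label_image.copy()
    r_px = distance_um / pixel_size_um
    pad = int(np.ceil(r_px)) + 1
    h, w = label_image.shape
    best_dist = np.full(label_image.shape, np.inf)
    out = label_image.copy()
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    for lab in labels:  # increasing order: strict '<' keeps smaller label on ties
        ys, xs = np.nonzero(label_image == lab)
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, h)
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, w)
        window = label_image[y0:y1, x0:x1]
        dist = distance_transform_edt(window != lab)
        grow = (dist <= r_px) & (window == 0)
        sub_best = best_dist[y0:y1, x0:x1]
        sub_out = out[y0:y1, x0:x1]
        take = grow & (dist < sub_best)
        sub_out[take] = lab
        sub_best[take] = dist[take]
    return out


@dataclass
class CellMatrix:
    """Cells x genes count matrix with bookkeeping for unassigned and
    blank-labelled molecules (blanks are excluded from the matrix)."""

    counts: pd.DataFrame       # index cell_id, columns genes
    cell_meta: pd.DataFrame    # cell_id, x_um, y_um (centroid), area_px
    n_unassigned: int
    blank_counts: dict[str, int] = field(default_factory=dict)
    n_dropped_cells: int = 0

    @property
    def n_assigned(self) -> int:
        return int(self.counts.to_numpy().sum())


def assign_to_cells(
    molecules: pd.DataFrame,
    expanded_labels: np.ndarray,
    pixel_size_um: float,
    stain_to_mol: SimilarityTransform | None = None,
) -> tuple[CellMatrix, pd.DataFrame]:
    """Assign decoded molecules to expanded segmentation labels.

    Molecule positions are mapped into the stain-image frame with the
    inverse of ``stain_to_mol`` (identity if None) and looked up in the
    label image; label 0 or out-of-bounds positions leave the molecule
    unassigned.  Returns the cells x genes :class:`CellMatrix` (blanks
    excluded from the matrix, reported separately) and a copy of the
    molecule table with a ``cell_id`` column (0 = unassigned).
    """
    mol = molecules.copy()
    xy = mol[["x_um", "y_um"]].to_numpy(dtype=float)
    if stain_to_mol is not None:
        xy = stain_to_mol.inverse().apply(xy)
    cols = np.floor(xy[:, 0] / pixel_size_um).astype(int)
    rows = np.floor(xy[:, 1] / pixel_size_um).astype(int)
    h, w = expanded_labels.shape
    inside = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    cell_id = np.zeros(len(mol), dtype=int)
    cell_id[inside] = expanded_labels[rows[inside], cols[inside]]
    mol["cell_id"] = cell_id

    is_blank = mol["label"].str.startswith("Blank-")
    blank_counts = mol.loc[is_blank, "label"].value_counts().to_dict()
    gene_mol = mol[~is_blank]
    assigned = gene_mol[gene_mol["cell_id"] > 0]
    counts = (
        assigned.groupby(["cell_id", "label"]).size().unstack(fill_value=0)
        if len(assigned)
        else pd.DataFrame()
    )
    counts.index.name = "cell_id"
    counts.columns.name = "gene"

    labs, areas = np.unique(expanded_labels[expanded_labels > 0], return_counts=True)
    centroids = []
    for lab in labs:
        ys, xs = np.nonzero(expanded_labels == lab)
        centroids.append(
            ((xs.mean() + 0.5) * pixel_size_um, (ys.mean() + 0.5) * pixel_size_um)
        )
    cell_meta = pd.DataFrame(
        {
            "cell_id": labs,
            "x_um": [c[0] for c in centroids],
            "y_um": [c[1] for c in centroids],
            "area_px": areas,
        }
    )
    # unassigned counts gene molecules outside any mask; blanks tracked separately
    n_unassigned = int((gene_mol["cell_id"] == 0).sum())
    matrix = CellMatrix(
        counts=counts,
        cell_meta=cell_meta,
        n_unassigned=n_unassigned,
        blank_counts=blank_counts,
    )
    return matrix, mol


def qc_cells(matrix: CellMatrix, min_counts: int = 0, min_genes: int = 0) -> CellMatrix:
    """Drop cells below total-count or detected-gene thresholds."""
    if min_counts < 0 or min_genes < 0:
        raise ValueError("thresholds must be >= 0")
    counts = matrix.counts
    if len(counts) == 0:
        return matrix
    totals = counts.sum(axis=1)
    n_genes = (counts > 0).sum(axis=1)
    keep = (totals >= min_counts) & (n_genes >= min_genes)
    return CellMatrix(
        counts=counts.loc[keep],
        cell_meta=matrix.cell_meta[matrix.cell_meta["cell_id"].isin(counts.index[keep])],
        n_unassigned=matrix.n_unassigned,
        blank_counts=matrix.blank_counts,
        n_dropped_cells=int((~keep).sum()),
    )
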