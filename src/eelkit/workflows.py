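"""End-to-end workflow compositions used by the examples and benchmarks.

These glue functions chain the library stages (scene simulation, readout,
bead registration, spot aggregation, decoding, scoring against ground
truth) with no logic of their own beyond bookkeeping, so that a full
in-silico experiment is one call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from eelkit import decode_assign as da
from eelkit import spot_pipeline as sp
from eelkit import synthetic_scene as scn
from eelkit.codebook import Codebook, assign_genes, generate_codebook
from eelkit.transforms import SimilarityTransform

__all__ = ["default_gene_rates", "simulated_experiment", "random_drift"]


def default_gene_rates(n_genes: int = 20, lo: float = 0.02, hi: float = 1.0) -> pd.DataFrame:
    """One-cell-type expression profile with log-spaced per-gene rates.

    Rates are expected molecules per cell per gene; the log spacing gives
    the wide dynamic range of real panels (abundant markers to rare
    transcripts) so that per-gene count recovery is a meaningful check.
    """
    genes = [f"Gene{i:03d}" for i in range(n_genes)]
    rates = np.geomspace(lo, hi, n_genes)
    return pd.DataFrame([rates], index=["type0"], columns=genes)


def random_drift(n_rounds: int, seed: int, scale_jitter: float = 0.01,
                 max_rot_deg: float = 2.0, max_shift_um: float = 5.0) -> list[SimilarityTransform]:
    """Per-round stage drift: round 0 is the identity reference."""
    rng = np.random.default_rng(seed)
    out = [SimilarityTransform()]
    for _ in range(n_rounds - 1):
        out.append(
            SimilarityTransform(
                float(rng.uniform(1 - scale_jitter, 1 + scale_jitter)),
                float(np.radians(rng.uniform(-max_rot_deg, max_rot_deg))),
                tuple(rng.uniform(-max_shift_um, max_shift_um, 2)),
            )
        )
    return out


def simulated_experiment(
    n_cells: int = 200,
    n_genes: int = 20,
    extent: tuple[float, float] = (2000.0, 2000.0),
    cell_radius_um: float = 20.0,
    p_dropout: float = 0.05,
    p_gain: float = 0.0,
    seed: int = 0,
    codebook: Codebook | None = None,
    drift: list[SimilarityTransform] | None = None,
    match_radius_um: float = 0.75,
    bead_density: float = 5e-5,
    rates: pd.DataFrame | None = None,
) -> dict:
    """Simulate, register, aggregate and decode one experiment; score it.

    Returns a dict with the scene, decoded table, and summary metrics:
    ``recall`` (decoded gene calls / true molecules), ``pred_recall``
    (binomial prediction for the dropout rate), ``gene_count_r`` (Pearson r
    of per-gene decoded vs true counts), ``blank_fpr`` and registration
    translation error.
    """
    if codebook is None:
        book = generate_codebook(16, 6, 4, size=448)
        genes = [f"Gene{i:03d}" for i in range(n_genes)]
        _, codebook = assign_genes(book, genes)
    genes = codebook.gene_labels
    if rates is None:
        rates = default_gene_rates(len(genes))
        rates.columns = genes
    if drift is None:
        drift = random_drift(codebook.n_bits, seed=seed + 1)

    scene = scn.simulate_scene(
        rates, n_cells, extent, cell_radius_um=cell_radius_um,
        bead_density=bead_density, seed=seed,
    )
    config = scn.AcquisitionConfig(p_dropout=p_dropout, p_gain=p_gain, drift=drift, seed=seed)
    sim = scn.simulate_readout(scene, codebook, config)

    beads = {r: sim.beads_for_round(r) for r in range(codebook.n_bits)}
    transforms = sp.register_rounds(beads, reference_round=0, match_radius=2.0)
    reg_err = 0.0
    for rnd in range(1, codebook.n_bits):
        inv = drift[rnd].inverse()
        est = transforms[rnd]
        reg_err = max(
            reg_err,
            float(np.hypot(est.translation[0] - inv.translation[0],
                           est.translation[1] - inv.translation[1])),
        )

    parts = []
    for rnd in range(codebook.n_bits):
        s = sim.spots_for_round(rnd)
        s = s[~s["is_bead"]]
        parts.append(sp.apply_transform_to_spots(s, transforms[rnd]))
    registered = pd.concat(parts, ignore_index=True)

    candidates = da.aggregate_rounds(registered, match_radius_um)
    decoded, stats = da.decode_molecules(candidates, codebook)
    fpr = da.blank_fpr(decoded, codebook) if codebook.blank_labels else None

    n_true = len(scene.molecules)
    gene_calls = decoded[decoded["label"].isin(genes)]
    recall = len(gene_calls) / n_true if n_true else np.nan
    k = codebook.weight
    pred = (1 - p_dropout) ** k + k * p_dropout * (1 - p_dropout) ** (k - 1)

    truth_counts = scene.molecules["gene"].value_counts()
    dec_counts = gene_calls["label"].value_counts()
    both = pd.DataFrame({"truth": truth_counts, "decoded": dec_counts}).fillna(0.0)
    gene_count_r = float(both["truth"].corr(both["decoded"])) if len(both) > 1 else np.nan

    return {
        "scene": scene,
        "sim": sim,
        "transforms": transforms,
        "decoded": decoded,
        "decode_stats": stats,
        "recall": float(recall),
        "pred_recall": float(pred),
        "gene_count_r": gene_count_r,
        "blank_fpr": fpr,
        "max_registration_translation_error_um": reg_err,
    }
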