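"""Ground-truth tissue scenes and simulated multi-round acquisitions.

A :class:`Scene` holds cells (disks), single RNA molecules with known
source cells, and fiducial beads on a flat capture surface.  The readout
simulator turns a scene plus a codebook assignment into per-round spot
tables with configurable bit errors (dropped "on" bits, spurious "off"
bits), localization jitter and per-round stage drift, together with a
ground-truth link table so every downstream stage can be scored exactly.
Images can also be rendered (Gaussian point-spread, background, shot and
read noise) to exercise the detection pipeline.

Coordinate convention (repo-wide): microns, origin at the image top-left,
y increasing downward; pixel index = floor(coord / pixel_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eelkit.codebook import Codebook
from eelkit.transforms import SimilarityTransform

__all__ = [
    "Scene",
    "AcquisitionConfig",
    "ReadoutSim",
    "simulate_scene",
    "apply_lateral_diffusion",
    "simulate_readout",
    "render_round_image",
]


@dataclass
class Scene:
    """Ground truth: cells, molecules and beads within a rectangular extent."""

    extent: tuple[float, float]  # (width, height) in microns
    cells: pd.DataFrame      # cell_id, x_um, y_um, radius_um, cell_type
    molecules: pd.DataFrame  # molecule_id, gene, x_um, y_um, cell_id (-1 = ambient)
    beads: pd.DataFrame      # x_um, y_um

    def __post_init__(self) -> None:
        w, h = self.extent
        for df, cols in ((self.molecules, ("x_um", "y_um")), (self.beads, ("x_um", "y_um"))):
            if len(df) and (
                (df[cols[0]] < 0).any()
                or (df[cols[0]] > w).any()
                or (df[cols[1]] < 0).any()
                or (df[cols[1]] > h).any()
            ):
                raise ValueError("coordinates outside scene extent")
        if len(self.molecules):
            valid = set(self.cells["cell_id"]) | {-1}
            if not set(self.molecules["cell_id"]).issubset(valid):
                raise ValueError("molecule references unknown cell")


@dataclass
class AcquisitionConfig:
    """Imaging and error model for a simulated multi-round acquisition.

    Defaults reflect a 60x objective with an 11-um camera pixel
    (0.18 um/px) and a diffraction-limited PSF of ~1.2 px sigma.
    ``p_dropout`` is the probability that an "on" bit yields no spot in its
    round; ``p_gain`` the per-round probability of a spurious spot on the
    molecule in an "off" round (models probe cross-talk, hence colocated).
    """

    pixel_size_um: float = 0.18
    psf_sigma_px: float = 1.2
    drift: list[SimilarityTransform] = field(default_factory=list)  # per round; empty = identity
    p_dropout: float = 0.0
    p_gain: float = 0.0
    sigma_loc_um: float = 0.05
    spot_amplitude: float = 800.0
    bead_amplitude: float = 8000.0
    background: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for p in (self.p_dropout, self.p_gain):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def round_transform(self, rnd: int) -> SimilarityTransform:
        if not self.drift:
            return SimilarityTransform()
        return self.drift[rnd]


def simulate_scene(
    profiles: pd.DataFrame,
    n_cells: int,
    extent: tuple[float, float] = (1000.0, 1000.0),
    ambient_rate: float = 0.0,
    bead_density: float = 5e-4,
    cell_radius_um: float = 5.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> Scene:
    """Sample a ground-truth scene.

    ``profiles``: cell types x genes table of expected molecule counts per
    cell (Poisson means).  Cell centroids are uniform with disk-overlap
    rejection; molecule positions uniform within the cell disk.  Ambient
    molecules arrive as a Poisson process of ``ambient_rate`` per um^2 with
    uniform gene identity; beads as a Poisson process of ``bead_density``.
    """
    if (profiles.values < 0).any():
        raise ValueError("expression rates must be non-negative")
    rng = np.random.default_rng(seed)
    w, h = extent
    genes = list(profiles.columns)
    types = list(profiles.index)

    # non-overlapping cell placement by rejection
    centers: list[tuple[float, float]] = []
    margin = cell_radius_um
    tries = 0
    while len(centers) < n_cells:
        if tries > max_tries * max(n_cells, 1):
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {extent} "
                f"after {tries} attempts"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= (2 * cell_radius_um) ** 2 for cx, cy in centers):
            centers.append((x, y))

    cell_types = [types[i] for i in rng.integers(0, len(types), size=n_cells)]
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "x_um": [c[0] for c in centers],
            "y_um": [c[1] for c in centers],
            "radius_um": cell_radius_um,
            "cell_type": cell_types,
        }
    )

    rows: list[tuple] = []
    for cid, (cx, cy), ctype in zip(cells["cell_id"], centers, cell_types):
        rates = profiles.loc[ctype]
        for gene in genes:
            k = rng.poisson(rates[gene])
            if k == 0:
                continue
            r = cell_radius_um * np.sqrt(rng.uniform(size=k))
            theta = rng.uniform(0, 2 * np.pi, size=k)
            for xi, yi in zip(cx + r * np.cos(theta), cy + r * np.sin(theta)):
                rows.append((gene, float(np.clip(xi, 0, w)), float(np.clip(yi, 0, h)), cid))

    n_ambient = rng.poisson(ambient_rate * w * h)
    if n_ambient and genes:
        ax = rng.uniform(0, w, size=n_ambient)
        ay = rng.uniform(0, h, size=n_ambient)
        ag = rng.integers(0, len(genes), size=n_ambient)
        rows.extend((genes[g], float(x), float(y), -1) for g, x, y in zip(ag, ax, ay))

    molecules = pd.DataFrame(rows, columns=["gene", "x_um", "y_um", "cell_id"])
    molecules.insert(0, "molecule_id", np.arange(len(molecules)))

    n_beads = rng.poisson(bead_density * w * h)
    beads = pd.DataFrame(
        {"x_um": rng.uniform(0, w, size=n_beads), "y_um": rng.uniform(0, h, size=n_beads)}
    )
    return Scene(extent=extent, cells=cells, molecules=molecules, beads=beads)


def apply_lateral_diffusion(scene: Scene, sigma_um: float, seed: int = 0) -> Scene:
    """Displace every molecule by an isotropic 2D Gaussian N(0, sigma^2 I).

    Models lateral dispersion of captured RNA away from its source; the
    pre-diffusion position is retained in ``x_orig_um``/``y_orig_um`` so
    displacement statistics (the radial displacement is Rayleigh with
    median sigma*sqrt(2 ln 2)) can be recovered exactly.
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    rng = np.random.default_rng(seed)
    mol = scene.molecules.copy()
    mol["x_orig_um"] = mol["x_um"]
    mol["y_orig_um"] = mol["y_um"]
    if sigma_um > 0 and len(mol):
        w, h = scene.extent
        mol["x_um"] = np.clip(mol["x_um"] + rng.normal(0, sigma_um, len(mol)), 0, w)
        mol["y_um"] = np.clip(mol["y_um"] + rng.normal(0, sigma_um, len(mol)), 0, h)
    return Scene(scene.extent, scene.cells.copy(), mol, scene.beads.copy())


@dataclass
class ReadoutSim:
    """Simulated acquisition: one tidy spot table covering all rounds plus
    the ground-truth link table (spot_id -> molecule_id, round, bit truth)."""

    spots: pd.DataFrame  # spot_id, round, x_um, y_um, intensity, is_bead, fov
    truth: pd.DataFrame  # spot_id, molecule_id, round, spurious
    n_rounds: int

    def spots_for_round(self, rnd: int) -> pd.DataFrame:
        return self.spots[self.spots["round"] == rnd].reset_index(drop=True)

    def beads_for_round(self, rnd: int) -> pd.DataFrame:
        s = self.spots
        return s[(s["round"] == rnd) & s["is_bead"]].reset_index(drop=True)


def simulate_readout(scene: Scene, codebook: Codebook, config: AcquisitionConfig) -> ReadoutSim:
    """Simulate the cyclic fluorescent readout of a scene.

    Each molecule emits a spot in every "on" round of its gene's codeword
    with probability ``1 - p_dropout`` and a spurious colocated spot in
    each "off" round with probability ``p_gain``.  Spot positions carry
    N(0, sigma_loc^2) localization jitter; each round's spots and beads are
    then mapped through that round's drift transform.
    """
    missing = set(scene.molecules["gene"]) - set(codebook.entries)
    if missing:
        raise ValueError(f"scene genes not in codebook: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    n_rounds = codebook.n_bits
    code_of = {g: np.array(codebook[g].bits, dtype=bool) for g in set(scene.molecules["gene"])}

    mol = scene.molecules
    n_mol = len(mol)
    if n_mol:
        bits = np.vstack([code_of[g] for g in mol["gene"]])  # (n_mol, n_rounds)
        u = rng.uniform(size=(n_mol, n_rounds))
        emit = np.where(bits, u >= config.p_dropout, u < config.p_gain)
    else:
        bits = np.zeros((0, n_rounds), dtype=bool)
        emit = bits

    spot_rows = []
    truth_rows = []
    spot_id = 0
    mol_x = mol["x_um"].to_numpy() if n_mol else np.empty(0)
    mol_y = mol["y_um"].to_numpy() if n_mol else np.empty(0)
    mol_ids = mol["molecule_id"].to_numpy() if n_mol else np.empty(0, dtype=int)
    bead_xy = scene.beads[["x_um", "y_um"]].to_numpy()

    for rnd in range(n_rounds):
        tf = config.round_transform(rnd)
        idx = np.flatnonzero(emit[:, rnd])
        if len(idx):
            jitter = rng.normal(0, config.sigma_loc_um, size=(len(idx), 2))
            xy = np.column_stack([mol_x[idx], mol_y[idx]]) + jitter
            xy = tf.apply(xy)
            inten = config.spot_amplitude * rng.lognormal(0.0, 0.2, size=len(idx))
            for k, i in enumerate(idx):
                spot_rows.append(
                    (spot_id, rnd, xy[k, 0], xy[k, 1], inten[k], False, 0)
                )
                truth_rows.append((spot_id, int(mol_ids[i]), rnd, not bits[i, rnd]))
                spot_id += 1
        if len(bead_xy):
            bj = rng.normal(0, config.sigma_loc_um, size=bead_xy.shape)
            bxy = tf.apply(bead_xy + bj)
            for k in range(len(bxy)):
                spot_rows.append(
                    (spot_id, rnd, bxy[k, 0], bxy[k, 1], config.bead_amplitude, True, 0)
                )
                truth_rows.append((spot_id, -1, rnd, False))
                spot_id += 1

    spots = pd.DataFrame(
        spot_rows, columns=["spot_id", "round", "x_um", "y_um", "intensity", "is_bead", "fov"]
    )
    truth = pd.DataFrame(truth_rows, columns=["spot_id", "molecule_id", "round", "spurious"])
    return ReadoutSim(spots=spots, truth=truth, n_rounds=n_rounds)


def render_round_image(
    spots: pd.DataFrame,
    beads: pd.DataFrame | None,
    config: AcquisitionConfig,
    fov_um: tuple[float, float] = (92.16, 92.16),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one round as a 16-bit image.

    Sum of 2D Gaussian kernels (sigma = ``psf_sigma_px``) at spot and bead
    positions, over a constant background, with optional Poisson shot
    noise and Gaussian read noise.  Default FOV is 512 px at 0.18 um/px.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ps = config.pixel_size_um
    width_px = int(round(fov_um[0] / ps))
    height_px = int(round(fov_um[1] / ps))
    img = np.full((height_px, width_px), float(config.background))

    def add_points(df: pd.DataFrame, default_amp: float) -> None:
        if df is None or len(df) == 0:
            return
        amps = df["intensity"].to_numpy() if "intensity" in df else np.full(len(df), default_amp)
        sig = config.psf_sigma_px
        r = int(np.ceil(4 * sig))
        for x_um, y_um, amp in zip(df["x_um"].to_numpy(), df["y_um"].to_numpy(), amps):
            # pixel-center coordinates of the subpixel spot position
            cx = x_um / ps - 0.5
            cy = y_um / ps - 0.5
            x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
            y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
            x0c, x1c = max(x0, 0), min(x1, width_px)
            y0c, y1c = max(y0, 0), min(y1, height_px)
            if x0c >= x1c or y0c >= y1c:
                continue
            xs = np.arange(x0c, x1c)
            ys = np.arange(y0c, y1c)
            gx = np.exp(-((xs - cx) ** 2) / (2 * sig**2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sig**2))
            img[y0c:y1c, x0c:x1c] += amp * np.outer(gy, gx)

    add_points(spots, config.spot_amplitude)
    if beads is not None:
        add_points(beads, config.bead_amplitude)

    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0, config.read_noise_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)
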