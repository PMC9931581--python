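"""Point-cloud spatial statistics for surface-captured transcriptomics.

Molecules (gene, x, y) are aggregated into a pointy-top hexagonal lattice
for region-level analysis: connectivity-constrained Ward clustering turns
hexagons into spatially contiguous expression regions; a random-forest
classifier's label probabilities mix region colors to display gradients;
a border field quantifies local expression heterogeneity as the maximal
Euclidean distance between per-gene count vectors of two half-disks over
a set of split angles.  Point-pattern tools include Ripley's L with
isotropic rectangle edge correction, a DBSCAN-based radial diffusion
profile around putative cell centroids, and an optical-crowding
simulation against the Abbe diffraction limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "HexGrid",
    "hexbin",
    "regionalize",
    "mix_region_colors",
    "border_field",
    "ripley_l",
    "diffusion_profile",
    "optical_crowding",
    "link_regions",
    "region_mean_expression",
]

_AXIAL_NEIGHBORS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


@dataclass
class HexGrid:
    """Hexagonally binned molecule counts.

    ``centers`` holds axial coordinates (q, r) and micron centers of the
    occupied hexes; ``counts`` is hexes x genes (row i of ``counts``
    corresponds to row i of ``centers``); ``adjacency`` is the symmetric
    neighbor matrix of the occupied hexes (<= 6 neighbors each).
    Pointy-top orientation: ``spacing_um`` is the center-to-center
    distance of adjacent hexes.
    """

    spacing_um: float
    centers: pd.DataFrame            # q, r, x_um, y_um
    counts: pd.DataFrame             # index aligned with centers, columns = genes
    adjacency: sparse.csr_matrix
    region_labels: np.ndarray | None = None
    region_colors: dict[int, tuple[float, float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_hexes(self) -> int:
        return len(self.centers)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def hex_area_um2(self) -> float:
        # regular hexagon with center spacing s has area sqrt(3)/2 * s^2
        return float(np.sqrt(3) / 2 * self.spacing_um**2)


def _xy_to_axial(x: np.ndarray, y: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest pointy-top hex (axial q, r) for micron coordinates."""
    size = spacing / np.sqrt(3.0)
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def _axial_to_xy(q: np.ndarray, r: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    size = spacing / np.sqrt(3.0)
    x = size * np.sqrt(3.0) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def hexbin(molecules: pd.DataFrame, spacing_um: float) -> HexGrid:
    """Bin molecules (gene, x_um, y_um) into a pointy-top hex lattice.

    Every molecule is assigned to the nearest hex center; hexes with no
    molecules are not represented.  Total counts are conserved exactly.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    q, r = _xy_to_axial(
        molecules["x_um"].to_numpy(float), molecules["y_um"].to_numpy(float), spacing_um
    )
    df = pd.DataFrame({"q": q, "r": r, "gene": molecules["gene"].to_numpy()})
    counts = df.groupby(["q", "r", "gene"]).size().unstack(fill_value=0)
    centers_idx = counts.index.to_frame(index=False)
    cx, cy = _axial_to_xy(
        centers_idx["q"].to_numpy(), centers_idx["r"].to_numpy(), spacing_um
    )
    centers = pd.DataFrame(
        {"q": centers_idx["q"], "r": centers_idx["r"], "x_um": cx, "y_um": cy}
    )
    counts = counts.reset_index(drop=True)
    counts.columns.name = "gene"

    index_of = {(qq, rr): i for i, (qq, rr) in enumerate(zip(centers["q"], centers["r"]))}
    rows, cols = [], []
    for (qq, rr), i in index_of.items():
        for dq, dr in _AXIAL_NEIGHBORS:
            j = index_of.get((qq + dq, rr + dr))
            if j is not None:
                rows.append(i)
                cols.append(j)
    adjacency = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(centers), len(centers))
    )
    return HexGrid(
        spacing_um=spacing_um,
        centers=centers,
        counts=counts,
        adjacency=adjacency,
        metadata={"orientation": "pointy-top axial"},
    )


def _normalize_counts(counts: pd.DataFrame) -> np.ndarray:
    """Median-total scaling followed by log1p (recorded in grid metadata)."""
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scaled = np.divide(x * med, totals[:, None], out=np.zeros_like(x), where=totals[:, None] > 0)
    return np.log1p(scaled)


def _order_regions_spectrally(means: np.ndarray) -> np.ndarray:
    """1D spectral-embedding order of regions by expression similarity."""
    k = len(means)
    if k <= 2:
        return np.arange(k)
    from sklearn.manifold import spectral_embedding

    z = means / np.maximum(np.linalg.norm(means, axis=1, keepdims=True), 1e-12)
    affinity = np.clip(z @ z.T, 0, None) + 1e-6  # cosine similarity, connected
    np.fill_diagonal(affinity, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = spectral_embedding(affinity, n_components=1, random_state=0)
    return np.argsort(emb[:, 0])


def regionalize(
    grid: HexGrid,
    n_regions: int,
    n_components: int = 10,
    reduction: str = "pca",
    seed: int = 0,
) -> HexGrid:
    """Cluster hexes into spatially contiguous expression regions.

    Counts are normalized per hex (scaled to the median hex total, then
    log1p), reduced by PCA or latent Dirichlet allocation, and clustered
    with Ward agglomeration constrained by the hex adjacency graph, so
    every region is a connected patch of tissue.  Region colors are
    assigned along a 1D spectral embedding of the region-mean expression
    similarity so transcriptionally similar regions get similar hues.

    Returns a new HexGrid with ``region_labels`` and ``region_colors``.
    """
    if n_regions > grid.n_hexes:
        raise ValueError(f"n_regions={n_regions} exceeds {grid.n_hexes} hexes")
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.decomposition import PCA, LatentDirichletAllocation

    norm = _normalize_counts(grid.counts)
    k = min(n_components, norm.shape[1], max(grid.n_hexes - 1, 1))
    if n_regions == 1:
        labels = np.zeros(grid.n_hexes, dtype=int)
    else:
        if reduction.lower() == "pca":
            reduced = PCA(n_components=k, random_state=seed).fit_transform(norm)
        elif reduction.lower() == "lda":
            lda = LatentDirichletAllocation(n_components=k, random_state=seed)
            reduced = lda.fit_transform(grid.counts.to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown reduction {reduction!r} (pca or lda)")
        model = AgglomerativeClustering(
            n_clusters=n_regions, linkage="ward", connectivity=grid.adjacency
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns when it must reconnect
            labels = model.fit_predict(reduced)

    means = np.vstack(
        [norm[labels == lab].mean(axis=0) for lab in range(n_regions)]
    )
    order = _order_regions_spectrally(means)
    import matplotlib

    cmap = matplotlib.colormaps["hsv"]
    colors: dict[int, tuple[float, float, float]] = {}
    for rank, lab in enumerate(order):
        rgba = cmap(0.85 * rank / max(n_regions - 1, 1))
        colors[int(lab)] = (float(rgba[0]), float(rgba[1]), float(rgba[2]))

    meta = dict(grid.metadata)
    meta.update(
        {
            "normalization": "median-total scaling + log1p",
            "reduction": reduction.lower(),
            "n_components": k,
            "color_order": "1D spectral embedding of region mean expression",
        }
    )
    return HexGrid(
        grid.spacing_um,
        grid.centers,
        grid.counts,
        grid.adjacency,
        region_labels=labels,
        region_colors=colors,
        metadata=meta,
    )


def mix_region_colors(
    grid: HexGrid, seed: int = 0, n_trees: int = 100
) -> np.ndarray:
    """Per-hex RGB mixing region colors by classifier probability.

    A random forest is trained on normalized hex expression against the
    region labels; each hex's color is sum_r P(region r | hex) * color_r,
    which renders gradual transitions between regions as blended hues.
    """
    if grid.region_labels is None or grid.region_colors is None:
        raise ValueError("grid has no region labels; run regionalize first")
    labels = grid.region_labels
    color_mat = np.array([grid.region_colors[lab] for lab in sorted(grid.region_colors)])
    if len(np.unique(labels)) == 1:
        warnings.warn("single region: returning its flat color", stacklevel=2)
        return np.tile(color_mat[0], (grid.n_hexes, 1))
    from sklearn.ensemble import RandomForestClassifier

    x = _normalize_counts(grid.counts)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(x, labels)
    proba = clf.predict_proba(x)  # columns follow clf.classes_ (sorted labels)
    return proba @ color_mat[clf.classes_]


def border_field(
    molecules: pd.DataFrame,
    grid_spacing_um: float,
    radius_um: float = 200.0,
    n_angles: int = 12,
    min_molecules: int = 10,
) -> pd.DataFrame:
    """Expression border strength and angle on a regular grid.

    At each grid point, molecules within ``radius_um`` are split in half by
    ``n_angles`` equally spaced lines through the point; for each split the
    Euclidean distance between the per-gene count vectors of the two
    half-disks is computed.  Strength is the maximum over angles and the
    reported angle is the split-line orientation (degrees in [0, 180)).
    Disks with fewer than ``min_molecules`` molecules get strength 0 and
    are flagged ``low_support``.
    """
    genes, gene_codes = np.unique(molecules["gene"].to_numpy(), return_inverse=True)
    if len(genes) < 2:
        raise ValueError("border field requires at least 2 genes")
    xy = molecules[["x_um", "y_um"]].to_numpy(float)
    n_genes = len(genes)
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    gx = np.arange(x0, x1 + grid_spacing_um, grid_spacing_um)
    gy = np.arange(y0, y1 + grid_spacing_um, grid_spacing_um)
    points = np.array([(px, py) for py in gy for px in gx])
    tree = cKDTree(xy)
    angles = np.arange(n_angles) * np.pi / n_angles  # split-line orientations
    normals = np.column_stack([-np.sin(angles), np.cos(angles)])

    rows = []
    for px, py in points:
        idx = tree.query_ball_point((px, py), radius_um)
        if len(idx) < min_molecules:
            rows.append((px, py, 0.0, 0.0, len(idx), True))
            continue
        rel = xy[idx] - (px, py)
        codes = gene_codes[idx]
        side = rel @ normals.T >= 0  # (n_mol, n_angles)
        best_s, best_a = 0.0, 0.0
        for a in range(n_angles):
            up = np.bincount(codes[side[:, a]], minlength=n_genes)
            down = np.bincount(codes[~side[:, a]], minlength=n_genes)
            s = float(np.linalg.norm(up - down))
            if s > best_s:
                best_s, best_a = s, np.degrees(angles[a])
        rows.append((px, py, best_s, best_a, len(idx), False))
    return pd.DataFrame(
        rows, columns=["x_um", "y_um", "strength", "angle_deg", "n_molecules", "low_support"]
    )


def _isotropic_weights(centers: np.ndarray, d: np.ndarray, extent: tuple[float, float]) -> np.ndarray:
    """Fraction of each circle (center, radius d) inside the rectangle.

    Valid for d < min(extent)/2 (a circle can cross at most two adjacent
    edges).  Exterior arc = sum over crossed edges of 2*arccos(dist/d)
    minus, for each corner closer than d, the double-counted overlap
    pi/2 - arcsin(d_e/d) - arcsin(d_f/d).
    """
    w, h = extent
    x, y = centers[:, 0], centers[:, 1]
    dists = np.column_stack([x, w - x, y, h - y])  # left, right, bottom, top
    with np.errstate(invalid="ignore"):
        ratios = np.clip(dists / d[:, None], 0, 1)
    exterior = np.where(dists < d[:, None], 2 * np.arccos(ratios), 0.0).sum(axis=1)
    for e, f in ((0, 2), (0, 3), (1, 2), (1, 3)):  # adjacent edge pairs (corners)
        inside = dists[:, e] ** 2 + dists[:, f] ** 2 < d**2
        if inside.any():
            overlap = (
                np.pi / 2
                - np.arcsin(ratios[inside, e])
                - np.arcsin(ratios[inside, f])
            )
            exterior[inside] -= overlap
    return 1.0 - exterior / (2 * np.pi)


def ripley_l(
    points: np.ndarray,
    radii: np.ndarray,
    extent: tuple[float, float],
    correction: str = "isotropic",
) -> pd.DataFrame:
    """Ripley's K and L functions on a rectangular window.

    K(r) = area * sum over ordered pairs within r of the edge-correction
    weight / n^2; L(r) = sqrt(K/pi).  Under complete spatial randomness
    L(r) - r = 0; positive values indicate clustering at scale r.
    Corrections: ``isotropic`` (Ripley circle-arc weights), ``toroidal``
    (periodic distances), ``none``.
    """
    pts = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    w, h = extent
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if radii.max() >= min(w, h) / 2:
        raise ValueError("radii must be < half the shorter window side")
    n = len(pts)
    area = w * h
    r_max = float(radii.max())

    if correction == "toroidal":
        tree = cKDTree(np.mod(pts, (w, h)), boxsize=(w, h))
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        diff = np.abs(pts[pairs[:, 0]] - pts[pairs[:, 1]])
        diff = np.minimum(diff, (w, h) - diff)
        d = np.hypot(diff[:, 0], diff[:, 1])
        weights = np.ones(len(d))
        d_all, w_all = np.concatenate([d, d]), np.concatenate([weights, weights])
    else:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        d = np.hypot(*(pts[pairs[:, 0]] - pts[pairs[:, 1]]).T)
        if correction == "isotropic":
            w_i = 1.0 / _isotropic_weights(pts[pairs[:, 0]], d, extent)
            w_j = 1.0 / _isotropic_weights(pts[pairs[:, 1]], d, extent)
        elif correction == "none":
            w_i = w_j = np.ones(len(d))
        else:
            raise ValueError(f"unknown correction {correction!r}")
        d_all = np.concatenate([d, d])
        w_all = np.concatenate([w_i, w_j])

    order = np.argsort(d_all)
    d_sorted = d_all[order]
    cum = np.concatenate([[0.0], np.cumsum(w_all[order])])
    k_vals = area / n**2 * cum[np.searchsorted(d_sorted, radii, side="right")]
    l_vals = np.sqrt(k_vals / np.pi)
    return pd.DataFrame({"r": radii, "K": k_vals, "L": l_vals, "L_minus_r": l_vals - radii})


def diffusion_profile(
    molecules: pd.DataFrame,
    marker_gene: str,
    dbscan_eps: float = 10.0,
    dbscan_min_samples: int = 5,
) -> dict:
    """Radial spread of a marker gene's molecules around putative cells.

    DBSCAN clusters of the marker's molecules stand in for cells; for each
    cluster the centroid is computed and molecule-centroid distances are
    pooled.  Reports the pooled radial CDF and the radius containing 50%
    of molecules (for Gaussian scatter of sd sigma this median is
    sigma * sqrt(2 ln 2)).
    """
    from sklearn.cluster import DBSCAN

    sub = molecules[molecules["gene"] == marker_gene]
    if len(sub) == 0:
        raise ValueError(f"marker gene {marker_gene!r} not present")
    xy = sub[["x_um", "y_um"]].to_numpy(float)
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit_predict(xy)
    cluster_ids = np.unique(labels[labels >= 0])
    if len(cluster_ids) == 0:
        warnings.warn("DBSCAN found no clusters", stacklevel=2)
        return {"n_cells": 0, "median_radius_um": np.nan, "distances_um": np.array([])}
    dists = []
    for cid in cluster_ids:
        pts = xy[labels == cid]
        centroid = pts.mean(axis=0)
        dists.append(np.hypot(*(pts - centroid).T))
    pooled = np.concatenate(dists)
    pooled_sorted = np.sort(pooled)
    cdf = np.arange(1, len(pooled_sorted) + 1) / len(pooled_sorted)
    return {
        "n_cells": int(len(cluster_ids)),
        "median_radius_um": float(np.quantile(pooled, 0.5)),
        "distances_um": pooled,
        "radial_cdf": pd.DataFrame({"radius_um": pooled_sorted, "cdf": cdf}),
    }


def optical_crowding(
    n_points_grid: np.ndarray,
    wavelength_nm: float = 660.0,
    numerical_aperture: float = 1.4,
    area_um: tuple[float, float] = (10.0, 10.0),
    n_rep: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of randomly placed points resolvable at the Abbe limit.

    Points are scattered uniformly in ``area_um``; a point is resolvable
    iff its nearest neighbor is at least lambda/(2 NA) away.  In the sparse
    limit the expected fraction approaches the Poisson void probability
    exp(-n pi d^2 / A).
    """
    if numerical_aperture <= 0:
        raise ValueError("numerical aperture must be positive")
    rng = np.random.default_rng(seed)
    d_min = wavelength_nm / (2 * numerical_aperture) / 1000.0  # um
    w, h = area_um
    rows = []
    for n in np.asarray(n_points_grid, dtype=int):
        fracs = np.empty(n_rep)
        for rep in range(n_rep):
            if n == 1:
                fracs[rep] = 1.0
                continue
            pts = rng.uniform((0, 0), (w, h), size=(n, 2))
            nn_d, _ = cKDTree(pts).query(pts, k=2)
            fracs[rep] = float((nn_d[:, 1] >= d_min).mean())
        rows.append((int(n), float(fracs.mean()), float(fracs.std())))
    return pd.DataFrame(rows, columns=["n_points", "fraction_resolvable", "sd"])


def region_mean_expression(grid: HexGrid) -> pd.DataFrame:
    """Mean raw counts per region (regions x genes, gene-named columns)."""
    if grid.region_labels is None:
        raise ValueError("grid has no region labels")
    df = grid.counts.copy()
    df["__region"] = grid.region_labels
    return df.groupby("__region").mean()


def link_regions(grid_a: HexGrid, grid_b: HexGrid, threshold: float = 0.7) -> pd.DataFrame:
    """Match regions across two sections by expression correlation.

    Pearson correlation between region-mean expression vectors over the
    shared gene panel (joined by gene name); greedy best-match: repeatedly
    pair the globally most correlated unmatched regions with r above
    ``threshold``.  Returns matched pairs (region_a, region_b, r).
    """
    means_a = region_mean_expression(grid_a)
    means_b = region_mean_expression(grid_b)
    shared = [g for g in means_a.columns if g in set(means_b.columns)]
    if not shared:
        raise ValueError("no shared genes between the two grids")
    a = means_a[shared].to_numpy(float)
    b = means_b[shared].to_numpy(float)
    az = (a - a.mean(1, keepdims=True)) / np.maximum(a.std(1, keepdims=True), 1e-12)
    bz = (b - b.mean(1, keepdims=True)) / np.maximum(b.std(1, keepdims=True), 1e-12)
    corr = az @ bz.T / len(shared)
    pairs = []
    free_a = set(range(len(a)))
    free_b = set(range(len(b)))
    while free_a and free_b:
        best = max(
            ((i, j) for i in free_a for j in free_b), key=lambda ij: corr[ij[0], ij[1]]
        )
        r = corr[best]
        if r < threshold:
            break
        pairs.append((means_a.index[best[0]], means_b.index[best[1]], float(r)))
        free_a.discard(best[0])
        free_b.discard(best[1])
    return pd.DataFrame(pairs, columns=["region_a", "region_b", "r"])
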