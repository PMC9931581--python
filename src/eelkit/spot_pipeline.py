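"""Spot detection, SNR measurement and fiducial-bead registration.

Diffraction-limited spots are isolated with a difference-of-Gaussians
band-pass, detected as local maxima above a robust threshold
(median + k * 1.4826 * MAD) and localized to subpixel precision by an
intensity-weighted 3x3 centroid.  Per-spot SNR is the peak signal over
the standard deviation of an annulus of background pixels (radii 3 and
9 px by default), with pixels belonging to other detected spots excluded.

Registration between hybridization rounds, and between low- and
high-magnification acquisitions, uses the fiducial beads: an iterative
closest-point loop alternating mutual nearest-neighbor matching with a
closed-form least-squares similarity fit, seeded from a moment-based
initialization (centroid shift plus RMS-radius scale ratio) so that both
small drifts and large magnification ratios converge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from eelkit.transforms import SimilarityTransform

__all__ = [
    "SimilarityTransform",
    "filter_image",
    "detect_spots",
    "compute_snr",
    "estimate_similarity",
    "register_rounds",
    "register_magnifications",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    """Raised when point-set registration cannot find enough matches."""


def filter_image(img: np.ndarray, low_sigma: float = 1.0, high_sigma: float = 5.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass; negative response clipped to 0.

    ``low_sigma`` should match the PSF scale, ``high_sigma`` the background
    scale; the filter suppresses both pixel noise and smooth background.
    """
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if low_sigma >= high_sigma:
        raise ValueError("low_sigma must be < high_sigma")
    x = img.astype(np.float64)
    dog = gaussian_filter(x, low_sigma) - gaussian_filter(x, high_sigma)
    return np.clip(dog, 0, None)


def detect_spots(
    filtered: np.ndarray,
    pixel_size_um: float,
    threshold_sd: float = 5.0,
    min_separation_px: int = 3,
    round_index: int = 0,
    fov: int = 0,
) -> pd.DataFrame:
    """Detect local maxima above a robust threshold; subpixel centroids.

    Threshold = median + threshold_sd * robust sd of the filtered image,
    where the robust sd is the larger of 1.4826 * MAD and the 84.13th
    percentile above the median (both equal the Gaussian sd on symmetric
    noise, but the MAD collapses on zero-clipped band-passed images where
    more than half the pixels are exactly 0; the one-sided quantile does
    not).  Non-maximum suppression keeps one peak per ``min_separation_px``
    neighborhood; each peak is refined by an intensity-weighted centroid
    over its 3x3 window and converted to microns (pixel center
    (i + 0.5) * pixel_size).
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    med = float(np.median(filtered))
    mad = float(np.median(np.abs(filtered - med)))
    upper = float(np.quantile(filtered, 0.8413)) - med
    robust_sd = max(1.4826 * mad, upper)
    thr = med + threshold_sd * robust_sd
    peaks = peak_local_max(
        filtered, min_distance=min_separation_px, threshold_abs=thr, exclude_border=1
    )
    rows = []
    h, w = filtered.shape
    for py, px in peaks:
        win = filtered[py - 1 : py + 2, px - 1 : px + 2].astype(float)
        win = win - win.min()  # local background removal sharpens the centroid
        total = win.sum()
        if total <= 0:
            cx, cy = float(px), float(py)
        else:
            dy, dx = np.mgrid[-1:2, -1:2]
            cy = py + float((win * dy).sum() / total)
            cx = px + float((win * dx).sum() / total)
        rows.append(
            (
                round_index,
                (cx + 0.5) * pixel_size_um,
                (cy + 0.5) * pixel_size_um,
                float(filtered[py, px]),
                fov,
                False,
            )
        )
    return pd.DataFrame(rows, columns=["round", "x_um", "y_um", "intensity", "fov", "is_bead"])


def compute_snr(
    img: np.ndarray,
    spots: pd.DataFrame,
    pixel_size_um: float,
    r_in: int = 3,
    r_out: int = 9,
) -> pd.Series:
    """Per-spot SNR: peak signal over the sd of annulus background pixels.

    The annulus spans radii ``r_in``..``r_out`` pixels around each spot;
    pixels within ``r_in`` of any *other* detected spot are excluded from
    the background so neighboring signals do not inflate the noise
    estimate.  A zero background sd yields +inf.
    """
    h, w = img.shape
    px = (spots["x_um"].to_numpy() / pixel_size_um - 0.5).round().astype(int)
    py = (spots["y_um"].to_numpy() / pixel_size_um - 0.5).round().astype(int)
    yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    rr = np.hypot(xx, yy)
    annulus = (rr >= r_in) & (rr <= r_out)
    core = rr < r_in

    # mask of pixels claimed by any spot core
    claimed = np.zeros_like(img, dtype=bool)
    for x, y in zip(px, py):
        y0, y1 = max(y - r_in + 1, 0), min(y + r_in, h)
        x0, x1 = max(x - r_in + 1, 0), min(x + r_in, w)
        sub = core[
            r_out - (y - y0) : r_out + (y1 - y), r_out - (x - x0) : r_out + (x1 - x)
        ]
        claimed[y0:y1, x0:x1] |= sub

    out = np.empty(len(spots))
    img_f = img.astype(float)
    for i, (x, y) in enumerate(zip(px, py)):
        if y - r_out < 0 or y + r_out >= h or x - r_out < 0 or x + r_out >= w:
            out[i] = np.nan
            continue
        patch = img_f[y - r_out : y + r_out + 1, x - r_out : x + r_out + 1]
        claimed_patch = claimed[y - r_out : y + r_out + 1, x - r_out : x + r_out + 1]
        bg = patch[annulus & ~claimed_patch]
        sd = bg.std()
        # signal strength = peak above the local background level
        peak = patch[r_out, r_out] - bg.mean()
        out[i] = np.inf if sd == 0 else peak / sd
    return pd.Series(out, index=spots.index, name="snr")


def _similarity_lsq(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity fit (Umeyama/Procrustes)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    s_c, d_c = src - mu_s, dst - mu_d
    cov = d_c.T @ s_c / len(src)
    u, d, vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(u @ vt))
    S = np.diag([1.0, sgn])
    rot_mat = u @ S @ vt
    var_s = (s_c**2).sum() / len(src)
    scale = float(np.trace(np.diag(d) @ S) / var_s)
    rotation = float(np.arctan2(rot_mat[1, 0], rot_mat[0, 0]))
    t = mu_d - scale * (rot_mat @ mu_s)
    return SimilarityTransform(scale, rotation, (float(t[0]), float(t[1])))


def _mutual_matches(a: np.ndarray, b: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, k=1, distance_upper_bound=radius)
    d_ba, j_ba = ta.query(b, k=1, distance_upper_bound=radius)
    ia = np.arange(len(a))
    ok = np.isfinite(d_ab) & (j_ab < len(b))
    mutual = ok & (j_ba[np.where(ok, j_ab, 0)] == ia)
    return ia[mutual], j_ab[mutual]


def estimate_similarity(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    max_iter: int = 50,
    match_radius: float = 2.0,
    tol: float = 1e-6,
) -> tuple[SimilarityTransform, float]:
    """Estimate the similarity transform mapping src onto dst.

    Iterates mutual nearest-neighbor matching (in the dst frame) against a
    closed-form least-squares similarity fit on the matched pairs, until
    the transform parameters change by less than ``tol``.  Initialization
    aligns centroids and RMS radii; the match radius then anneals from a
    coarse value (a fraction of the point-cloud extent) down to
    ``match_radius``, so multi-micron drifts, degree-scale rotations and
    magnification-scale differences converge from the same code path while
    the final fit only trusts tight mutual matches.
    Returns (transform, RMS residual of the final matches).
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if len(src) < 3 or len(dst) < 3:
        raise RegistrationError("need at least 3 points in each set")

    # moment initialization: centroids + RMS-radius scale ratio
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    r_s = np.sqrt(((src - mu_s) ** 2).sum(axis=1).mean())
    r_d = np.sqrt(((dst - mu_d) ** 2).sum(axis=1).mean())
    s0 = r_d / r_s if r_s > 0 else 1.0
    t0 = mu_d - s0 * mu_s
    tf = SimilarityTransform(s0, 0.0, (float(t0[0]), float(t0[1])))

    # coarse-to-fine radius schedule; at each level iterate the ICP loop to
    # stability before tightening, so large initial rotations cannot strand
    # the matcher at a fine radius with a half-converged transform
    coarse = max(match_radius, 0.3 * r_d)
    levels = (
        list(np.geomspace(coarse, match_radius, 6))
        if coarse > match_radius
        else [match_radius]
    )
    rms = np.inf
    for level, radius in enumerate(levels):
        prev = np.array([tf.scale, tf.rotation, *tf.translation])
        last_level = level == len(levels) - 1
        for _ in range(max_iter):
            moved = tf.apply(src)
            i_s, i_d = _mutual_matches(moved, dst, radius)
            if len(i_s) < 3:
                raise RegistrationError(
                    f"only {len(i_s)} mutual matches within radius {radius:g}"
                )
            tf = _similarity_lsq(src[i_s], dst[i_d])
            resid = tf.apply(src[i_s]) - dst[i_d]
            rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
            cur = np.array([tf.scale, tf.rotation, *tf.translation])
            if np.abs(cur - prev).max() < (tol if last_level else 1e-3):
                break
            prev = cur
    return tf, rms


def register_rounds(
    bead_tables: dict[int, pd.DataFrame] | list[pd.DataFrame],
    reference_round: int = 0,
    match_radius: float = 2.0,
    max_iter: int = 50,
) -> dict[int, SimilarityTransform]:
    """Per-round similarity transforms into the reference round's frame.

    ``bead_tables`` maps round index to a table with x_um/y_um columns (a
    list is treated as rounds 0..n-1).  The returned transform for round r
    maps round-r coordinates into the reference frame.
    """
    if isinstance(bead_tables, list):
        bead_tables = dict(enumerate(bead_tables))
    if reference_round not in bead_tables:
        raise RegistrationError(f"reference round {reference_round} missing")
    ref = bead_tables[reference_round][["x_um", "y_um"]].to_numpy()
    out: dict[int, SimilarityTransform] = {}
    for rnd, table in sorted(bead_tables.items()):
        if len(table) < 3:
            raise RegistrationError(f"round {rnd}: fewer than 3 beads")
        if rnd == reference_round:
            out[rnd] = SimilarityTransform()
            continue
        pts = table[["x_um", "y_um"]].to_numpy()
        try:
            tf, _ = estimate_similarity(
                pts, ref, max_iter=max_iter, match_radius=match_radius
            )
        except RegistrationError as err:
            raise RegistrationError(f"round {rnd}: {err}") from err
        out[rnd] = tf
    return out


def register_magnifications(
    beads_lowmag: pd.DataFrame,
    beads_highmag: pd.DataFrame,
    match_radius: float = 2.0,
    max_iter: int = 50,
) -> tuple[SimilarityTransform, float]:
    """Transform mapping low-magnification bead coordinates onto the
    high-magnification frame; expected scale ~= the magnification ratio."""
    return estimate_similarity(
        beads_lowmag[["x_um", "y_um"]].to_numpy(),
        beads_highmag[["x_um", "y_um"]].to_numpy(),
        max_iter=max_iter,
        match_radius=match_radius,
    )


def apply_transform_to_spots(spots: pd.DataFrame, tf: SimilarityTransform) -> pd.DataFrame:
    """Return a copy of a spot table with coordinates mapped through ``tf``."""
    out = spots.copy()
    xy = tf.apply(out[["x_um", "y_um"]].to_numpy())
    out["x_um"] = xy[:, 0]
    out["y_um"] = xy[:, 1]
    return out
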