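"""3D COLLAGE: co-occurrence of local anisotropic gradient orientations.

COLLAGE quantifies local textural heterogeneity inside tumor compartments.
For every voxel the intensity gradient is computed along x, y, z; the
gradient vectors of a small window around the voxel are stacked into a
matrix F (one row per window voxel) and the dominant local gradient
direction psi = (psiX, psiY, psiZ) is obtained as the first right-singular
vector of F (equivalently the top eigenvector of F^T F). Two orientation
angles follow:

    theta = arctan(psiY / psiX)                       in-plane orientation
    phi   = arctan(psiZ / sqrt(psiX^2 + psiY^2))      out-of-plane elevation

Both angles are axial (psi and -psi describe the same orientation) and live
in (-pi/2, pi/2]. Each angle map is uniformly quantized; around every
compartment voxel a local co-occurrence matrix of quantized orientations is
accumulated over a set of symmetric 3D offsets, and 13 classical Haralick
statistics are evaluated per voxel, giving 26 feature maps (13 per angle).
Aggregating each map over the compartment with five first-order statistics
yields 13 x 5 x 2 = 130 features per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .deformation import STAT_NAMES, EmptyRegionError, first_order_stats
from .io import VolumeGrid

__all__ = [
    "CollageConfig",
    "GradientVolumes",
    "OrientationMaps",
    "HARALICK_NAMES",
    "DEFAULT_OFFSETS",
    "compute_gradients",
    "dominant_orientations",
    "quantize_orientations",
    "local_cooccurrence",
    "haralick_13",
    "collage_descriptor",
    "collage_feature_names",
]

#: the 13 Haralick statistics, in the fixed order used everywhere
HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

#: the 13 unique 3D direction offsets at Chebyshev distance 1 (26-neighbour
#: shell modulo central symmetry); symmetric counting covers both signs
DEFAULT_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_LOG_EPS = 1e-12  # epsilon guarding logarithms in entropy-like statistics
_DEGENERATE_TOL = 1e-20


@dataclass(frozen=True)
class CollageConfig:
    """Window sizes, quantization and offsets of the COLLAGE computation.

    window_radius r gives the (2r+1)^3 gradient window entering the SVD
    (default 3x3x3); cooccur_window_radius gives the local neighbourhood
    over which orientation pairs are counted (default 5x5x5).
    """

    window_radius: int = 1
    n_orientation_bins: int = 64
    cooccur_window_radius: int = 2
    cooccur_offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS
    haralick_names: tuple[str, ...] = HARALICK_NAMES

    def __post_init__(self) -> None:
        if self.window_radius < 1 or self.cooccur_window_radius < 1:
            raise ValueError("window radii must give odd windows >= 3")
        if self.n_orientation_bins < 2:
            raise ValueError("need at least 2 orientation bins")
        if len(self.haralick_names) != 13:
            raise ValueError("exactly 13 Haralick statistics required")


@dataclass
class GradientVolumes:
    """Intensity gradients along the three axes, in intensity units per mm."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.x.shape


@dataclass
class OrientationMaps:
    """Per-voxel dominant-orientation angles and a degeneracy mask.

    theta/phi lie in (-pi/2, pi/2]; voxels whose local gradient window is
    all-zero are flagged invalid and carry theta = phi = 0.
    """

    theta: np.ndarray
    phi: np.ndarray
    valid: np.ndarray


def compute_gradients(volume: VolumeGrid) -> GradientVolumes:
    """Central differences in the interior, one-sided at borders, per mm."""
    if min(volume.shape) < 2:
        raise ValueError("each axis needs length >= 2 to form gradients")
    sx, sy, sz = volume.spacing
    gx, gy, gz = np.gradient(volume.data.astype(float), sx, sy, sz)
    return GradientVolumes(x=gx, y=gy, z=gz)


def _window_sums(arr: np.ndarray, w: int) -> np.ndarray:
    # zero-padded box sum == sum over the window clipped at image borders
    return ndimage.uniform_filter(arr, size=w, mode="constant") * float(w**3)


def dominant_orientations(
    grads: GradientVolumes, cfg: CollageConfig = CollageConfig()
) -> OrientationMaps:
    """Dominant local gradient direction per voxel via the window SVD.

    The first right-singular vector of the stacked window gradients equals
    the top eigenvector of the 3x3 matrix F^T F, whose entries are window
    sums of gradient products; windows are clipped at image borders. The
    eigenvector sign is canonicalized so its largest-magnitude component is
    positive (orientations are axial).
    """
    w = 2 * cfg.window_radius + 1
    gx, gy, gz = grads.x, grads.y, grads.z
    s = np.empty(gx.shape + (3, 3), dtype=float)
    s[..., 0, 0] = _window_sums(gx * gx, w)
    s[..., 1, 1] = _window_sums(gy * gy, w)
    s[..., 2, 2] = _window_sums(gz * gz, w)
    s[..., 0, 1] = s[..., 1, 0] = _window_sums(gx * gy, w)
    s[..., 0, 2] = s[..., 2, 0] = _window_sums(gx * gz, w)
    s[..., 1, 2] = s[..., 2, 1] = _window_sums(gy * gz, w)

    valid = (s[..., 0, 0] + s[..., 1, 1] + s[..., 2, 2]) > _DEGENERATE_TOL
    _, vecs = np.linalg.eigh(s)
    psi = vecs[..., :, 2]  # eigenvector of the largest eigenvalue

    # axial sign canonicalization: largest-|component| positive
    flat = psi.reshape(-1, 3)
    lead = flat[np.arange(flat.shape[0]), np.argmax(np.abs(flat), axis=1)]
    flat *= np.where(lead < 0, -1.0, 1.0)[:, None]
    psi = flat.reshape(psi.shape)

    px, py, pz = psi[..., 0], psi[..., 1], psi[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(px != 0, np.arctan(np.divide(
            py, px, out=np.zeros_like(py), where=px != 0)), np.pi / 2)
        rho = np.hypot(px, py)
        phi = np.where(rho != 0, np.arctan(np.divide(
            pz, rho, out=np.zeros_like(pz), where=rho != 0)), np.pi / 2)
    theta = np.where(valid, theta, 0.0)
    phi = np.where(valid, phi, 0.0)
    return OrientationMaps(theta=theta, phi=phi, valid=valid)


def quantize_orientations(angles: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniformly bin angles in (-pi/2, pi/2] into left-open intervals.

    Bin k covers (-pi/2 + k*h, -pi/2 + (k+1)*h], h = pi/n_bins, so the
    right edge pi/2 falls in bin n_bins - 1.
    """
    a = np.asarray(angles, dtype=float)
    if np.any(a <= -np.pi / 2 - 1e-12) or np.any(a > np.pi / 2 + 1e-12):
        raise ValueError("orientation angles must lie in (-pi/2, pi/2]")
    h = np.pi / n_bins
    idx = np.ceil((a + np.pi / 2) / h).astype(np.int64) - 1
    return np.clip(idx, 0, n_bins - 1)


def _offset_slices(off: tuple[int, int, int]) -> tuple[tuple, tuple]:
    sa, sb = [], []
    for o in off:
        if o >= 0:
            sa.append(slice(0, None if o == 0 else -o))
            sb.append(slice(o, None))
        else:
            sa.append(slice(-o, None))
            sb.append(slice(0, o))
    return tuple(sa), tuple(sb)


def _batch_cooccurrence(
    windows: np.ndarray, center_bins: np.ndarray, cfg: CollageConfig
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrices for a batch of windows.

    `windows` is (M, W, W, W) of bin indices with -1 marking out-of-image
    voxels. Ordered pairs are counted per offset, symmetrized by adding the
    transpose, and normalized to sum 1. A window yielding no valid pair
    degenerates to a delta at the center voxel's bin.
    """
    nb = cfg.n_orientation_bins
    m = windows.shape[0]
    counts = np.zeros(m * nb * nb, dtype=np.int64)
    row = np.arange(m, dtype=np.int64) * (nb * nb)
    for off in cfg.cooccur_offsets:
        sa, sb = _offset_slices(off)
        a = windows[(slice(None),) + sa].reshape(m, -1)
        b = windows[(slice(None),) + sb].reshape(m, -1)
        ok = (a >= 0) & (b >= 0)
        flat = row[:, None] + a * nb + b
        counts += np.bincount(flat[ok], minlength=counts.size)
    mats = counts.reshape(m, nb, nb).astype(float)
    mats += mats.transpose(0, 2, 1)
    totals = mats.sum(axis=(1, 2))
    empty = totals == 0
    if np.any(empty):
        idx = np.nonzero(empty)[0]
        mats[idx, center_bins[idx], center_bins[idx]] = 1.0
        totals[idx] = 1.0
    return mats / totals[:, None, None]


def local_cooccurrence(
    quantized: np.ndarray,
    center: tuple[int, int, int],
    cfg: CollageConfig = CollageConfig(),
) -> np.ndarray:
    """Normalized symmetric orientation co-occurrence around one voxel.

    Pairs (b_i, b_j) are counted for every configured offset with both
    endpoints inside the (2R+1)^3 window around `center`, clipped at image
    borders; the matrix is symmetrized and normalized to sum 1.
    """
    q = np.asarray(quantized)
    r = cfg.cooccur_window_radius
    lo = [c - r for c in center]
    hi = [c + r + 1 for c in center]
    if all(h <= 0 for h in hi) or all(l >= n for l, n in zip(lo, q.shape)):
        raise ValueError("co-occurrence window lies entirely outside image")
    w = 2 * r + 1
    win = np.full((w, w, w), -1, dtype=np.int64)
    src = tuple(slice(max(l, 0), min(h, n))
                for l, h, n in zip(lo, hi, q.shape))
    dst = tuple(slice(max(l, 0) - l, (min(h, n) - l))
                for l, h, n in zip(lo, hi, q.shape))
    win[dst] = q[src]
    cbin = np.asarray([q[center]], dtype=np.int64)
    return _batch_cooccurrence(win[None], cbin, cfg)[0]


@lru_cache(maxsize=8)
def _sum_diff_onehots(n: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n)
    plus = (i[:, None] + i[None, :]).reshape(-1)
    minus = np.abs(i[:, None] - i[None, :]).reshape(-1)
    s_plus = np.zeros((n * n, 2 * n - 1))
    s_plus[np.arange(n * n), plus] = 1.0
    s_minus = np.zeros((n * n, n))
    s_minus[np.arange(n * n), minus] = 1.0
    return s_plus, s_minus


def _haralick_batch(mats: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics for a batch of normalized matrices.

    Returns (M, 13) in HARALICK_NAMES order; 0-based gray (bin) indices are
    used throughout, logarithms are eps-guarded, and correlation of a
    zero-variance marginal is defined as 0.
    """
    p = np.asarray(mats, dtype=float)
    if p.ndim == 2:
        p = p[None]
    m, n, _ = p.shape
    i = np.arange(n, dtype=float)
    px = p.sum(axis=2)
    py = p.sum(axis=1)
    mu_x = px @ i
    mu_y = py @ i
    var_x = ((i[None, :] - mu_x[:, None]) ** 2 * px).sum(axis=1)
    var_y = ((i[None, :] - mu_y[:, None]) ** 2 * py).sum(axis=1)

    s_plus, s_minus = _sum_diff_onehots(n)
    flat = p.reshape(m, n * n)
    p_plus = flat @ s_plus            # (m, 2n-1)
    p_minus = flat @ s_minus          # (m, n)
    k_plus = np.arange(2 * n - 1, dtype=float)
    k_minus = i

    energy = (flat ** 2).sum(axis=1)
    contrast = p_minus @ (k_minus ** 2)
    ij = i[:, None] * i[None, :]
    cross = (p * ij[None]).sum(axis=(1, 2))
    sig = np.sqrt(var_x * var_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(sig > _LOG_EPS,
                               (cross - mu_x * mu_y) / np.where(sig > 0, sig, 1.0),
                               0.0)
    sum_of_squares = var_x
    idm = p_minus @ (1.0 / (1.0 + k_minus ** 2))
    sum_average = p_plus @ k_plus
    sum_variance = ((k_plus[None, :] - sum_average[:, None]) ** 2
                    * p_plus).sum(axis=1)
    sum_entropy = -(p_plus * np.log(p_plus + _LOG_EPS)).sum(axis=1)
    entropy = -(flat * np.log(flat + _LOG_EPS)).sum(axis=1)
    mu_minus = p_minus @ k_minus
    difference_variance = ((k_minus[None, :] - mu_minus[:, None]) ** 2
                           * p_minus).sum(axis=1)
    difference_entropy = -(p_minus * np.log(p_minus + _LOG_EPS)).sum(axis=1)

    hx = -(px * np.log(px + _LOG_EPS)).sum(axis=1)
    hy = -(py * np.log(py + _LOG_EPS)).sum(axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    log_pxpy = np.log(pxpy + _LOG_EPS)
    hxy1 = -(p * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
    hmax = np.maximum(hx, hy)
    with np.errstate(divide="ignore", invalid="ignore"):
        imc1 = np.where(hmax > _LOG_EPS,
                        (entropy - hxy1) / np.where(hmax > 0, hmax, 1.0),
                        0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None))

    return np.stack([
        energy, contrast, correlation, sum_of_squares, idm, sum_average,
        sum_variance, sum_entropy, entropy, difference_variance,
        difference_entropy, imc1, imc2,
    ], axis=1)


def haralick_13(mat: np.ndarray) -> np.ndarray:
    """13 Haralick statistics of one normalized co-occurrence matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if abs(mat.sum() - 1.0) > 1e-8:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    return _haralick_batch(mat)[0]


def collage_feature_names(
    compartment: str, cfg: CollageConfig = CollageConfig()
) -> list[str]:
    """``collage_{comp}_{theta|phi}_{haralick}_{stat}``, angle-major."""
    return [
        f"collage_{compartment}_{angle}_{h}_{stat}"
        for angle in ("theta", "phi")
        for h in cfg.haralick_names
        for stat in STAT_NAMES
    ]


def _crop_with_margin(mask: np.ndarray, margin: int,
                      shape: tuple[int, ...]) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(ax.min()) - margin, 0),
              min(int(ax.max()) + margin + 1, n))
        for ax, n in zip(idx, shape)
    )


def collage_descriptor(
    volume: VolumeGrid,
    compartment_mask: np.ndarray,
    cfg: CollageConfig = CollageConfig(),
    compartment: str = "T",
    return_maps: bool = False,
    _chunk: int = 1024,
):
    """130 COLLAGE features of one tumor compartment.

    For every compartment voxel the local theta/phi co-occurrence matrices
    are formed and their 13 Haralick statistics evaluated, giving 26
    per-voxel feature maps; each map is aggregated over the compartment with
    the five first-order statistics (26 x 5 = 130 values). The computation
    is restricted to a bounding box chosen large enough that results are
    identical to a whole-volume evaluation.

    Returns the feature vector, and with ``return_maps=True`` also a dict of
    the 26 per-voxel maps (values at compartment voxels, in flat order).
    """
    mask = np.asarray(compartment_mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError(f"compartment {compartment!r} is empty")
    margin = cfg.cooccur_window_radius + cfg.window_radius + 1
    box = _crop_with_margin(mask, margin, volume.shape)
    sub = VolumeGrid(data=np.ascontiguousarray(volume.data[box]),
                     affine=volume.affine)
    submask = mask[box]

    grads = compute_gradients(sub)
    orient = dominant_orientations(grads, cfg)
    r = cfg.cooccur_window_radius
    w = 2 * r + 1
    feats = {}
    centers = np.nonzero(submask)
    for angle, amap in (("theta", orient.theta), ("phi", orient.phi)):
        q = quantize_orientations(amap, cfg.n_orientation_bins)
        qpad = np.pad(q, r, mode="constant", constant_values=-1)
        wins = sliding_window_view(qpad, (w, w, w))[centers]
        cbins = q[centers].astype(np.int64)
        hvals = np.empty((wins.shape[0], 13))
        for start in range(0, wins.shape[0], _chunk):
            sl = slice(start, start + _chunk)
            mats = _batch_cooccurrence(np.ascontiguousarray(wins[sl]),
                                       cbins[sl], cfg)
            hvals[sl] = _haralick_batch(mats)
        for hi, hname in enumerate(cfg.haralick_names):
            feats[(angle, hname)] = hvals[:, hi]

    out = np.empty(130)
    pos = 0
    for angle in ("theta", "phi"):
        for hname in cfg.haralick_names:
            out[pos:pos + 5] = first_order_stats(feats[(angle, hname)])
            pos += 5
    if return_maps:
        return out, feats
    return out
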