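"""Affine co-registration of secondary volumes onto the primary (T2W) grid.

The secondary (DWI or DCE) volume is aligned to the primary by maximizing
mutual information (MI) over a 9-DoF affine transform — three translations
(mm), three rotations (degrees) and three scales — with a nonlinear
Polak-Ribiere conjugate-gradient ascent.  Gradients are central finite
differences; a per-parameter scaling (1 mm = 1 deg = 0.01 scale) puts all
nine parameters on a common step size.

MI is the plug-in estimate from a joint histogram with 32 equal-width bins
spanning each image's 1st-99th percentile range, computed over the voxels
where the transformed secondary actually overlaps the primary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .transforms import AffineTransform9
from .volume import VolumeImage

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "initial_transform_from_metadata",
    "resample_volume",
    "mutual_information",
    "register_affine",
]


def initial_transform_from_metadata(
    primary: VolumeImage, secondary: VolumeImage
) -> AffineTransform9:
    """Initial guess aligning the secondary's world frame onto the primary's.

    Uses only the scanner geometry (origin and orientation): identity
    rotations and scales, translation equal to the world origin offset —
    the translation part of composing the secondary's voxel-to-world map
    with the primary's world-to-voxel map when the two frames share an
    orientation.  Raises if either volume lacks geometry rather than
    silently returning identity.
    """
    for name, vol in (("primary", primary), ("secondary", secondary)):
        if vol.affine is None or not np.all(np.isfinite(vol.affine)):
            raise ValueError(f"{name} volume carries no usable geometry metadata")
    t = secondary.origin - primary.origin
    center = primary.voxel_to_world((np.asarray(primary.shape, dtype=float) - 1) / 2.0)
    return AffineTransform9(translation=t, center=center)


def resample_volume(
    secondary: VolumeImage,
    target: VolumeImage,
    transform: AffineTransform9,
    fill_value: float = 0.0,
) -> VolumeImage:
    """Resample the secondary onto the target grid under the transform.

    For each target voxel, the world point is mapped through the transform
    into the secondary's world frame and interpolated trilinearly; points
    falling outside the secondary get ``fill_value``.  Output geometry is
    exactly the target's.
    """
    if np.any(np.abs(transform.scale) < 1e-12):
        raise ValueError("degenerate transform: zero scale")
    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    world = target.voxel_to_world(idx)
    moving_world = transform.apply(world)
    moving_vox = secondary.world_to_voxel(moving_world)
    values = map_coordinates(
        secondary.data,
        moving_vox.T,
        order=1,
        mode="constant",
        cval=fill_value,
    )
    out = values.reshape(target.shape)
    return VolumeImage(out, target.affine.copy(), modality=secondary.modality,
                       allow_nan=not np.isfinite(fill_value))


def _overlap_mask(
    secondary: VolumeImage, target: VolumeImage, transform: AffineTransform9
) -> np.ndarray:
    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    vox = secondary.world_to_voxel(transform.apply(target.voxel_to_world(idx)))
    shape = np.asarray(secondary.shape, dtype=float)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    return inside.reshape(target.shape)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Plug-in mutual information (nats) of two paired intensity samples.

    Joint histogram over equal-width bins spanning each sample's 1st-99th
    percentile range; MI = sum p(i,j) ln[p(i,j) / (p(i) p(j))] >= 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("sample sets must have equal size")
    if a.size == 0:
        raise ValueError("empty overlap region: no samples for MI")
    if bins < 2:
        raise ValueError("bins must be >= 2")

    def _edges(x: np.ndarray) -> np.ndarray:
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)

    joint, _, _ = np.histogram2d(a, b, bins=[_edges(a), _edges(b)])
    n = joint.sum()
    if n == 0:
        raise ValueError("no samples fall inside the histogram range")
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    mi = float(np.sum(pj[nz] * np.log(pj[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


@dataclass
class RegistrationOptions:
    bins: int = 32
    max_iter: int = 200
    mi_tol: float = 1e-5          # stop when MI gain falls below this (nats)
    fd_step: float = 0.05         # finite-difference step in scaled units
    # per-parameter scaling: one scaled unit is 1 mm, 1 degree, 0.01 scale
    param_scale: np.ndarray = field(
        default_factory=lambda: np.array([1, 1, 1, 1, 1, 1, 0.01, 0.01, 0.01], float)
    )
    initial_step: float = 1.0
    divergence_patience: int = 10


@dataclass
class RegistrationResult:
    transform: AffineTransform9
    mi: float
    n_iter: int
    converged: bool
    status: str = "ok"
    mi_initial: float = np.nan


def register_affine(
    primary: VolumeImage,
    secondary: VolumeImage,
    options: RegistrationOptions | None = None,
    initial: AffineTransform9 | None = None,
) -> RegistrationResult:
    """Maximize MI over the 9 affine parameters; deterministic.

    Polak-Ribiere conjugate gradient with restart and a backtracking line
    search; an iterate is accepted only if it increases MI, so MI is
    non-decreasing along accepted iterates.  If no uphill step can be
    found the best-so-far transform is returned.
    """
    opts = options or RegistrationOptions()
    t0 = initial or initial_transform_from_metadata(primary, secondary)
    center = t0.center

    # precompute fixed quantities: primary voxel world coordinates and
    # per-image histogram edges (1st-99th percentile, frozen so the MI
    # objective is comparable across candidate transforms)
    idx = np.indices(primary.shape, dtype=float).reshape(3, -1).T
    world = primary.voxel_to_world(idx)
    prim_flat = primary.data.ravel()
    sec_inv = np.linalg.inv(secondary.affine)

    def _fixed_edges(x: np.ndarray) -> np.ndarray:
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = float(np.min(x)), float(np.max(x)) or 1.0
        return np.linspace(lo, hi, opts.bins + 1)

    edges_p = _fixed_edges(prim_flat)
    edges_s = _fixed_edges(secondary.data.ravel())

    def mi_of(params_scaled: np.ndarray) -> float:
        tr = AffineTransform9.from_params(params_scaled * opts.param_scale, center)
        if np.any(tr.scale <= 0.1):
            return -np.inf
        M = sec_inv[:3, :3] @ tr.as_matrix()[:3, :3]
        off = sec_inv[:3, :3] @ tr.as_matrix()[:3, 3] + sec_inv[:3, 3]
        moving_vox = world @ M.T + off
        vals = map_coordinates(
            secondary.data, moving_vox.T, order=1, mode="constant", cval=np.nan
        )
        ok = np.isfinite(vals)
        if ok.sum() < 64:
            return -np.inf
        joint, _, _ = np.histogram2d(prim_flat[ok], vals[ok], bins=[edges_p, edges_s])
        n = joint.sum()
        if n < 64:
            return -np.inf
        pj = joint / n
        px = pj.sum(axis=1, keepdims=True)
        py = pj.sum(axis=0, keepdims=True)
        nzm = pj > 0
        return float(np.sum(pj[nzm] * np.log(pj[nzm] / (px @ py)[nzm])))

    def grad_of(x: np.ndarray, fx: float) -> np.ndarray:
        g = np.zeros(9)
        for k in range(9):
            e = np.zeros(9)
            e[k] = opts.fd_step
            fp, fm = mi_of(x + e), mi_of(x - e)
            if not np.isfinite(fp):
                fp = fx
            if not np.isfinite(fm):
                fm = fx
            g[k] = (fp - fm) / (2 * opts.fd_step)
        return g

    x = t0.to_params() / opts.param_scale
    f = mi_of(x)
    if not np.isfinite(f):
        raise ValueError("volumes do not overlap under the initial transform")
    f_init = f

    g = grad_of(x, f)
    d = g.copy()
    step = opts.initial_step
    n_bad = 0
    converged = False
    status = "ok"
    it = 0
    for it in range(1, opts.max_iter + 1):
        if np.linalg.norm(d) < 1e-12:
            converged = True
            break
        # backtracking line search along d (ascent)
        dn = d / max(np.linalg.norm(d), 1e-12)
        alpha = step
        accepted = False
        for _ in range(12):
            f_new = mi_of(x + alpha * dn)
            if np.isfinite(f_new) and f_new > f:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if step <= 1e-3:
                # no uphill step at a tiny trust region: we are at an optimum
                converged = True
                break
            n_bad += 1
            if n_bad >= opts.divergence_patience:
                status = "stalled"
                break
            # restart along steepest ascent with a smaller step
            g = grad_of(x, f)
            d = g.copy()
            step *= 0.5
            if step < 1e-6:
                converged = True
                break
            continue
        n_bad = 0
        gain = f_new - f
        x = x + alpha * dn
        f = f_new
        step = max(alpha * 2.0, 1e-6)
        if gain < opts.mi_tol:
            converged = True
            break
        g_new = grad_of(x, f)
        beta = float(np.dot(g_new, g_new - g) / max(np.dot(g, g), 1e-30))
        beta = max(beta, 0.0)  # Polak-Ribiere+ restart
        d = g_new + beta * d
        if np.dot(d, g_new) <= 0:  # not an ascent direction: restart
            d = g_new.copy()
        g = g_new

    if status != "ok":
        warnings.warn(
            "registration stalled before meeting the MI tolerance; "
            "returning best-so-far transform",
            RuntimeWarning,
            stacklevel=2,
        )
    best = AffineTransform9.from_params(x * opts.param_scale, center)
    return RegistrationResult(
        transform=best, mi=f, n_iter=it, converged=converged, status=status,
        mi_initial=f_init,
    )
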