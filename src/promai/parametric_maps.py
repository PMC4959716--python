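"""Per-voxel functional parameters: ADC, Tofts pharmacokinetics, normalized T2W.

All maps live on the primary (T2W) grid; the registration stage is
responsible for resampling DWI and DCE there first.  Fit-quality flags are
a per-voxel integer bitfield (see ``FLAG_*`` constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tofts import tofts_forward
from .volume import VolumeImage

__all__ = [
    "ParametricMaps",
    "FLAG_ADC",
    "FLAG_TOFTS",
    "FLAG_T2W",
    "fit_adc",
    "fit_tofts",
    "fit_tofts_volume",
    "tofts_forward",
    "normalize_t2w",
    "dce_signal_to_concentration",
    "compute_parametric_maps",
]

FLAG_ADC = 1      # ADC fit degraded (non-positive signals) or impossible
FLAG_TOFTS = 2    # Tofts fit failed / did not converge
FLAG_T2W = 4      # T2W normalization degenerate (constant VOI)

_SEC_PER_MIN = 60.0


@dataclass
class ParametricMaps:
    """The five per-voxel parameters feeding the malignancy model.

    ``kep = ktrans / ve`` holds wherever ``ve > 0``; all arrays share the
    T2W grid geometry given by ``affine``.
    """

    adc: np.ndarray        # mm^2/s
    s0: np.ndarray         # a.u.
    ktrans: np.ndarray     # 1/min
    ve: np.ndarray         # fraction
    kep: np.ndarray        # 1/min
    t2w_norm: np.ndarray   # robust z-score, unitless
    flags: np.ndarray      # integer bitfield
    affine: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (self.adc, self.s0, self.ktrans, self.ve, self.kep,
                      self.t2w_norm, self.flags)
        }
        if len(shapes) != 1:
            raise ValueError("all parameter maps must share one shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.adc.shape


# ---------------------------------------------------------------------------
# ADC
# ---------------------------------------------------------------------------

def fit_adc(
    signals: np.ndarray, b_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mono-exponential ADC fit: OLS of ln S on b, per voxel.

    Parameters
    ----------
    signals
        Array (..., B) of DWI signals, one per b-value; must be >= 0.
    b_values
        B distinct diffusion weightings in s/mm^2.

    Returns
    -------
    adc, s0, flags
        ``adc = -slope`` clamped at zero (mm^2/s), ``s0 = exp(intercept)``.
        Voxels with any non-positive signal are fitted on the positive
        samples only and flagged; with fewer than 2 usable samples the
        voxel gets adc = 0 and the flag.
    """
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    if np.any(b < 0):
        raise ValueError("b-values must be >= 0")
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != b.size:
        raise ValueError("signals last axis must match the number of b-values")
    if np.any(s < 0):
        raise ValueError("signals must be >= 0")

    flat = s.reshape(-1, b.size)
    usable = flat > 0
    n_use = usable.sum(axis=1)
    flags = np.where(np.all(usable, axis=1), 0, FLAG_ADC)

    # weighted (0/1 mask) OLS of ln S on b, vectorized over voxels
    logs = np.where(usable, np.log(np.where(usable, flat, 1.0)), 0.0)
    w = usable.astype(float)
    sw = w.sum(axis=1)
    ok = n_use >= 2
    sw_safe = np.where(sw > 0, sw, 1.0)
    mb = (w * b).sum(axis=1) / sw_safe
    my = logs.sum(axis=1) / sw_safe
    cov = (w * (b - mb[:, None]) * (logs - my[:, None])).sum(axis=1)
    var = (w * (b - mb[:, None]) ** 2).sum(axis=1)
    # a voxel whose usable b-values are all equal cannot constrain a slope
    degenerate = var <= 0
    ok &= ~degenerate
    slope = np.where(ok, cov / np.where(var > 0, var, 1.0), 0.0)
    intercept = np.where(ok, my - slope * mb, 0.0)
    adc = np.clip(-slope, 0.0, None)
    s0 = np.where(ok, np.exp(intercept), 0.0)
    flags = np.where(ok, flags, FLAG_ADC)
    shape = s.shape[:-1]
    return adc.reshape(shape), s0.reshape(shape), flags.reshape(shape)


# ---------------------------------------------------------------------------
# Tofts
# ---------------------------------------------------------------------------

_MULTISTART = [
    (kt, ve) for kt in (0.05, 0.3, 1.0) for ve in (0.2, 0.5, 0.9)
]  # fixed 3x3 grid


def fit_tofts(
    curve: np.ndarray,
    aif,
    times_s: np.ndarray,
    ktrans_bounds: tuple[float, float] = (0.0, 5.0),
) -> tuple[float, float, float, int]:
    """Nonlinear least-squares Tofts fit of one concentration curve.

    Multi-start from a fixed 3x3 (Ktrans, Ve) grid; the start with the
    lowest forward-model SSE is refined first and the rest only if the
    refined cost remains poor, so the procedure is deterministic.

    Returns ``(ktrans, ve, kep, flag)`` with ``flag`` = ``FLAG_TOFTS`` on
    failure (zeros returned).
    """
    curve = np.asarray(curve, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if curve.size != times_s.size or curve.size < 5:
        raise ValueError("need >= 5 frames and matching curve/times lengths")
    scale = float(np.max(np.abs(curve)))
    if scale == 0.0:
        return 0.0, 0.0, 0.0, FLAG_TOFTS  # identically zero curve

    def residual(p: np.ndarray) -> np.ndarray:
        return tofts_forward(p[0], p[1], aif, times_s) - curve

    starts = sorted(
        _MULTISTART,
        key=lambda p: float(np.sum(residual(np.asarray(p)) ** 2)),
    )
    lo = [ktrans_bounds[0], 1e-6]
    hi = [ktrans_bounds[1], 1.0]
    best = None
    for i, p0 in enumerate(starts):
        try:
            sol = least_squares(residual, np.asarray(p0), bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        # good-enough fit from the best-SSE start: stop early
        if best.cost <= (1e-6 * scale) ** 2 * curve.size:
            break
        if i >= 2 and best is not None:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        return 0.0, 0.0, 0.0, FLAG_TOFTS
    kt, ve = float(best.x[0]), float(best.x[1])
    kep = kt / ve if ve > 0 else 0.0
    return kt, ve, kep, 0


def _tofts_forward_batch(
    ktrans: np.ndarray, ve: np.ndarray, cp: np.ndarray, t_min: np.ndarray
) -> np.ndarray:
    """Forward model for V parameter pairs at once -> (V, T)."""
    kt = np.clip(np.asarray(ktrans, dtype=float), 0.0, None)
    ve = np.clip(np.asarray(ve, dtype=float), 1e-6, 1.0)
    kep = kt / ve
    V, T = kt.size, t_min.size
    ct = np.zeros((V, T))
    for n in range(1, T):
        dt = t_min[n] - t_min[n - 1]
        kdt = kep * dt
        e = np.exp(-kdt)
        a = np.where(kdt > 1e-8, -np.expm1(-kdt) / np.where(kep > 0, kep, 1.0), dt)
        b = np.where(kdt > 1e-8, (dt - a) / np.where(kep > 0, kep, 1.0), dt * dt / 2)
        ct[:, n] = e * ct[:, n - 1] + kt * (cp[n - 1] * a + (cp[n] - cp[n - 1]) * b / dt)
    return ct


def fit_tofts_volume(
    curves: np.ndarray,
    aif,
    times_s: np.ndarray,
    n_refine: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Tofts fit for many voxels: linearized init + Gauss-Newton.

    Initialization solves the linear-least-squares form of the Tofts
    equation (Ct regressed on the running integrals of Cp and Ct), then a
    damped Gauss-Newton refinement with finite-difference Jacobians runs
    simultaneously for all voxels against the exact recursion forward
    model.  Deterministic; voxels whose curves are identically zero are
    flagged and returned as zeros.

    Returns ``(ktrans, ve, kep, flags)`` shaped like ``curves[..., 0]``.
    """
    curves = np.asarray(curves, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    shape = curves.shape[:-1]
    C = curves.reshape(-1, times_s.size)
    t_min = times_s / _SEC_PER_MIN
    cp = np.asarray(aif(times_s), dtype=float)

    nz = np.ptp(C, axis=1) > 0
    flags = np.where(nz, 0, FLAG_TOFTS)

    # Murase-style linearization: Ct = Ktrans*int(Cp) - kep*int(Ct)
    int_cp = np.concatenate(
        [[0.0], np.cumsum((cp[1:] + cp[:-1]) / 2 * np.diff(t_min))]
    )
    int_ct = np.concatenate(
        [np.zeros((C.shape[0], 1)),
         np.cumsum((C[:, 1:] + C[:, :-1]) / 2 * np.diff(t_min), axis=1)],
        axis=1,
    )
    a11 = float(np.dot(int_cp, int_cp))
    a12 = -(int_ct @ int_cp)
    a22 = np.sum(int_ct * int_ct, axis=1)
    b1 = C @ int_cp
    b2 = -np.sum(C * int_ct, axis=1)
    det = a11 * a22 - a12 * a12
    det_safe = np.where(np.abs(det) > 1e-30, det, 1.0)
    kt = (b1 * a22 - b2 * a12) / det_safe
    kep = (a11 * b2 - a12 * b1) / det_safe
    kt = np.clip(kt, 1e-4, 5.0)
    kep = np.clip(kep, kt, kt / 1e-3)  # keeps ve = kt/kep within (1e-3, 1]
    ve = np.clip(kt / kep, 1e-3, 1.0)

    lam = np.full(C.shape[0], 1e-3)
    resid = _tofts_forward_batch(kt, ve, cp, t_min) - C
    cost = np.sum(resid**2, axis=1)
    for _ in range(n_refine):
        d_kt = np.maximum(1e-7, 1e-7 + 1e-4 * kt)
        d_ve = np.maximum(1e-7, 1e-7 + 1e-4 * ve)
        j_kt = (_tofts_forward_batch(kt + d_kt, ve, cp, t_min)
                - _tofts_forward_batch(kt - d_kt, ve, cp, t_min)) / (2 * d_kt[:, None])
        j_ve = (_tofts_forward_batch(kt, ve + d_ve, cp, t_min)
                - _tofts_forward_batch(kt, ve - d_ve, cp, t_min)) / (2 * d_ve[:, None])
        g11 = np.sum(j_kt * j_kt, axis=1) + lam
        g12 = np.sum(j_kt * j_ve, axis=1)
        g22 = np.sum(j_ve * j_ve, axis=1) + lam
        r1 = -np.sum(j_kt * resid, axis=1)
        r2 = -np.sum(j_ve * resid, axis=1)
        det = g11 * g22 - g12 * g12
        det = np.where(np.abs(det) > 1e-30, det, 1.0)
        step_kt = (r1 * g22 - r2 * g12) / det
        step_ve = (g11 * r2 - g12 * r1) / det
        kt_new = np.clip(kt + step_kt, 0.0, 5.0)
        ve_new = np.clip(ve + step_ve, 1e-3, 1.0)
        resid_new = _tofts_forward_batch(kt_new, ve_new, cp, t_min) - C
        cost_new = np.sum(resid_new**2, axis=1)
        better = cost_new < cost
        kt = np.where(better, kt_new, kt)
        ve = np.where(better, ve_new, ve)
        resid = np.where(better[:, None], resid_new, resid)
        cost = np.where(better, cost_new, cost)
        lam = np.where(better, lam * 0.3, lam * 5.0)

    kt = np.where(nz, kt, 0.0)
    ve = np.where(nz, ve, 0.0)
    kep = np.where(ve > 0, kt / np.where(ve > 0, ve, 1.0), 0.0)
    return (kt.reshape(shape), ve.reshape(shape), kep.reshape(shape),
            flags.reshape(shape))


# ---------------------------------------------------------------------------
# T2W normalization & DCE conversion
# ---------------------------------------------------------------------------

def normalize_t2w(
    t2w: VolumeImage, voi: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Robust z-score of T2W intensities over a rectangular VOI.

    The VOI is an axis-aligned voxel-index box ``[x0,x1) x [y0,y1) x [z0,z1)``
    (0-based, half-open) enclosing the prostate.  Location is the VOI
    median, scale 1.4826 x MAD, which makes the output invariant to any
    positive affine rescaling of the input.  A constant VOI yields zeros
    with the T2W flag set everywhere.
    """
    (x0, x1), (y0, y1), (z0, z1) = voi
    shape = t2w.shape
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
            and 0 <= z0 < z1 <= shape[2]):
        raise ValueError(f"VOI {voi} is empty or outside the volume {shape}")
    roi = t2w.data[x0:x1, y0:y1, z0:z1]
    med = float(np.median(roi))
    mad = float(np.median(np.abs(roi - med)))
    scale = 1.4826 * mad
    if scale == 0.0:
        return np.zeros(shape), np.full(shape, FLAG_T2W, dtype=int)
    return (t2w.data - med) / scale, np.zeros(shape, dtype=int)


def dce_signal_to_concentration(
    frames: np.ndarray,
    times_s: np.ndarray,
    gain: float,
    baseline_end_s: float,
) -> np.ndarray:
    """Convert DCE signal frames (..., T) to contrast concentration.

    Enhancement over the pre-bolus baseline divided by a configured
    relaxivity-proportionality constant ``gain`` (a.u. per mM); baseline =
    mean over frames acquired before ``baseline_end_s`` (the AIF onset).
    """
    frames = np.asarray(frames, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    pre = times_s < baseline_end_s
    if not np.any(pre):
        raise ValueError("no pre-enhancement frames before the AIF onset")
    if gain <= 0:
        raise ValueError("conversion gain must be positive")
    baseline = frames[..., pre].mean(axis=-1, keepdims=True)
    return (frames - baseline) / gain


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def compute_parametric_maps(
    t2w: VolumeImage,
    dwi_aligned: list[VolumeImage],
    b_values: np.ndarray,
    dce_aligned: list[VolumeImage],
    dce_times_s: np.ndarray,
    aif,
    voi: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
    dce_gain: float = 1.0,
    mask: np.ndarray | None = None,
) -> ParametricMaps:
    """All five parameter maps on the T2W grid.

    DWI and DCE volumes must already be resampled to the T2W grid (the
    registration stage's job); geometry equality is asserted.  ``mask``
    restricts the expensive Tofts fits to the voxels of interest (the
    prostate); outside it the pharmacokinetic maps are zero.
    """
    for v in [*dwi_aligned, *dce_aligned]:
        if not v.same_geometry(t2w, tol=1e-6):
            raise ValueError(
                f"volume {v.modality!r} is not on the T2W grid; register first"
            )
    dwi_stack = np.stack([v.data for v in dwi_aligned], axis=-1)
    adc, s0, adc_flags = fit_adc(dwi_stack, b_values)

    dce_stack = np.stack([v.data for v in dce_aligned], axis=-1)
    conc = dce_signal_to_concentration(dce_stack, dce_times_s, dce_gain,
                                       baseline_end_s=aif.onset_s)
    shape = t2w.shape
    ktrans = np.zeros(shape)
    ve = np.zeros(shape)
    kep = np.zeros(shape)
    tofts_flags = np.zeros(shape, dtype=int)
    sel = np.ones(shape, bool) if mask is None else mask.astype(bool)
    kt_m, ve_m, kep_m, fl_m = fit_tofts_volume(conc[sel], aif, dce_times_s)
    ktrans[sel] = kt_m
    ve[sel] = ve_m
    kep[sel] = kep_m
    tofts_flags[sel] = fl_m

    t2w_norm, t2w_flags = normalize_t2w(t2w, voi)
    flags = adc_flags.astype(int) | tofts_flags | t2w_flags
    return ParametricMaps(
        adc=adc, s0=s0, ktrans=ktrans, ve=ve, kep=kep,
        t2w_norm=t2w_norm, flags=flags, affine=t2w.affine.copy(),
    )
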