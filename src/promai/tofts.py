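"""Two-compartment Tofts pharmacokinetic forward model and AIF.

Tissue contrast concentration under the standard Tofts model:

    Ct(t) = Ktrans * integral_0^t Cp(tau) exp(-kep (t - tau)) dtau,
    kep = Ktrans / Ve

with Ktrans (1/min) the transfer constant, Ve the extravascular
extracellular volume fraction and Cp the arterial plasma concentration
(the AIF).  Times are in seconds throughout the package (DCE frames are
seconds apart); rate constants stay in 1/min, the field's convention.

The convolution is evaluated with an exponential-kernel recursion that
is exact when the AIF is piecewise linear between frames, so the forward
model and any fit against it are mutually consistent to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BiexponentialAif", "tofts_forward"]

_SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class BiexponentialAif:
    """Population arterial input function: a delayed biexponential decay.

    Cp(t) = a1 * exp(-m1 * t') + a2 * exp(-m2 * t') for t' = t - onset > 0,
    zero before the bolus onset.  Amplitudes in mM, decay rates in 1/min,
    onset in seconds.  Defaults follow the classic biexponential
    population parameterisation for a standard 0.1 mmol/kg bolus.
    """

    a1_mm: float = 3.99
    m1_per_min: float = 0.144
    a2_mm: float = 4.78
    m2_per_min: float = 0.0111
    onset_s: float = 30.0

    def __call__(self, t_s: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        dt_min = (t - self.onset_s) / _SEC_PER_MIN
        cp = np.where(
            dt_min > 0,
            self.a1_mm * np.exp(-self.m1_per_min * np.clip(dt_min, 0, None))
            + self.a2_mm * np.exp(-self.m2_per_min * np.clip(dt_min, 0, None)),
            0.0,
        )
        return cp


def tofts_forward(
    ktrans: float,
    ve: float,
    aif,
    times_s: np.ndarray,
) -> np.ndarray:
    """Tissue concentration series Ct at the frame times.

    Parameters
    ----------
    ktrans
        Transfer constant, 1/min, >= 0.
    ve
        Extravascular extracellular volume fraction, in (0, 1].
    aif
        Callable Cp(t_seconds) -> plasma concentration.
    times_s
        Strictly increasing frame times in seconds.
    """
    if ktrans < 0:
        raise ValueError(f"ktrans must be >= 0, got {ktrans}")
    if not 0 < ve <= 1:
        raise ValueError(f"ve must lie in (0, 1], got {ve}")
    times_s = np.asarray(times_s, dtype=float)
    if times_s.ndim != 1 or times_s.size < 1:
        raise ValueError("times_s must be a 1D array of frame times")
    if times_s.size > 1 and np.any(np.diff(times_s) <= 0):
        raise ValueError("times_s must be strictly increasing")

    ct = np.zeros_like(times_s)
    if ktrans == 0.0:
        return ct

    kep = ktrans / ve  # 1/min
    t_min = times_s / _SEC_PER_MIN
    cp = np.asarray(aif(times_s), dtype=float)

    for n in range(1, t_min.size):
        dt = t_min[n] - t_min[n - 1]
        kdt = kep * dt
        e = np.exp(-kdt)
        # integral of exp(-kep (dt - u)) over [0, dt] and its first moment;
        # series fallback avoids cancellation at tiny kep*dt
        a = -np.expm1(-kdt) / kep
        b = dt * dt / 2.0 if kdt < 1e-8 else (dt - a) / kep
        c0, c1 = cp[n - 1], cp[n]
        ct[n] = e * ct[n - 1] + ktrans * (c0 * a + (c1 - c0) * b / dt)
    return ct
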