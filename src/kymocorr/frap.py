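"""Mobile-fraction estimation from fluorescence recovery after photobleaching.

A bleached spot recovers as unbleached molecules exchange in.  The rapidly
recovering component reflects freely diffusing monomer; the component that
never recovers on the experimental time scale reflects network-bound
(filamentous) probe.  Recovery is modelled as a single exponential

    F(t) = F0 + (F_inf - F0) * (1 - exp(-t / tau))

and the mobile fraction is M = (F_inf - F0) / (F_pre - F0), with F_pre the
mean pre-bleach intensity.  Curves are assumed corrected for acquisition
bleaching upstream; M is invariant to affine intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapCurve", "FrapResult", "fit_recovery"]


@dataclass
class FrapCurve:
    """A photobleaching recovery time series.

    ``post_bleach_index`` marks the first sample after the bleach event;
    everything before it is pre-bleach.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    post_bleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.post_bleach_index < 3:
            raise ValueError("need at least 3 pre-bleach samples")
        if t.size - self.post_bleach_index < 5:
            raise ValueError("need at least 5 post-bleach samples")
        self.times_s, self.intensities = t, f


@dataclass
class FrapResult:
    f_pre: float
    f0: float
    f_inf: float
    tau_s: float
    mobile_fraction: float
    rms_residual: float


def _model(t, f0, f_inf, tau):
    return f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau))


def fit_recovery(curve: FrapCurve) -> FrapResult:
    """Fit the single-exponential recovery and report the mobile fraction.

    Initialization: F0 = first post-bleach sample, F_inf = mean of the last
    10% of samples, tau = time to half recovery.  The fit is bounded so
    F_inf stays within [F0, 1.2 * F_pre].  M is clamped to [0, 1].
    """
    i0 = curve.post_bleach_index
    f_pre = float(curve.intensities[:i0].mean())
    t_post = curve.times_s[i0:] - curve.times_s[i0]
    f_post = curve.intensities[i0:]
    f0_init = float(f_post[0])
    if f_pre - f0_init <= 0:
        raise ValueError(
            f"no bleach depth: pre-bleach mean {f_pre:.3g} does not exceed "
            f"first post-bleach sample {f0_init:.3g}"
        )
    n_tail = max(1, f_post.size // 10)
    finf_init = float(f_post[-n_tail:].mean())
    half = f0_init + 0.5 * (finf_init - f0_init)
    above = np.flatnonzero(f_post >= half)
    tau_init = float(t_post[above[0]]) if above.size and t_post[above[0]] > 0 else (
        t_post[-1] / 4 or 1.0
    )
    finf_init = min(max(finf_init, f0_init + 1e-9), 1.2 * f_pre)
    f0_lo, f0_hi = f0_init - 0.5 * (f_pre - f0_init), f_pre
    try:
        popt, _ = curve_fit(
            _model,
            t_post,
            f_post,
            p0=(f0_init, finf_init, max(tau_init, 1e-3)),
            bounds=([f0_lo, f0_lo, 1e-6], [f0_hi, 1.2 * f_pre, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise ValueError(f"recovery fit did not converge: {exc}") from exc
    f0, f_inf, tau = (float(v) for v in popt)
    mobile = (f_inf - f0) / (f_pre - f0)
    mobile = float(min(max(mobile, 0.0), 1.0))
    resid = float(np.sqrt(np.mean((_model(t_post, *popt) - f_post) ** 2)))
    return FrapResult(
        f_pre=f_pre, f0=f0, f_inf=f_inf, tau_s=tau,
        mobile_fraction=mobile, rms_residual=resid,
    )
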