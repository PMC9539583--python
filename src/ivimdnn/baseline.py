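"""Conventional least-squares IVIM fitting.

Serves three roles: the in-repo comparison method for the network, the
noiseless-recovery oracle used in validation, and a reference for how
external fitters plug into the evaluation (any method producing parameter
maps can be fed to :func:`ivimdnn.metrics.build_report`).

The segmented fit exploits the fact that at high b the pseudo-diffusion
compartment has fully decayed: a log-linear regression on b >= threshold
gives D and the intercept 1-f, after which f and D* are refined on all
b-values with D fixed.  The full fit is bounded nonlinear least squares on
the biexponential, initialized from the segmented result, so its residual
can never exceed the initializer's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import AcquisitionScheme, ParamRanges

__all__ = ["FitOptions", "fit_voxel_lsq", "fit_volume"]

#: default split between perfusion-sensitive and diffusion-only b-values;
#: the standard 9-point scheme jumps from 300 to 800 s/mm^2, so 300 is the
#: natural threshold.
DEFAULT_B_THRESHOLD = 300.0


@dataclass(frozen=True)
class FitOptions:
    """Mode, segmentation threshold and box constraints for the LSQ fit.

    ``bounds`` is a (3, 2) array ordered (D, f, Dstar) x (lo, hi); by
    default the sampling ranges expanded by 2x either way (f capped to
    [0, 1]) so estimates near a range edge are not artificially pinned.
    """

    mode: str = "full_biexp"
    b_threshold: float = DEFAULT_B_THRESHOLD
    bounds: np.ndarray = field(default_factory=lambda: FitOptions.default_bounds())
    max_evals: int = 200
    tolerance: float = 1e-10

    @staticmethod
    def default_bounds(ranges: ParamRanges | None = None, expand: float = 2.0) -> np.ndarray:
        ranges = ranges or ParamRanges()
        arr = ranges.as_array()
        lo = arr[:, 0] / expand
        hi = arr[:, 1] * expand
        lo[1] = 0.0
        hi[1] = min(hi[1], 1.0)
        return np.column_stack([lo, hi])

    def __post_init__(self) -> None:
        if self.mode not in ("full_biexp", "segmented"):
            raise ValueError("mode must be 'full_biexp' or 'segmented'")
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float))


def _biexp(theta: np.ndarray, b: np.ndarray) -> np.ndarray:
    D, f, Dstar = theta
    return (1.0 - f) * np.exp(-b * D) + f * np.exp(-b * Dstar)


def _clip_to_bounds(theta: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    # strict interior so trf has room to move off the start point
    span = bounds[:, 1] - bounds[:, 0]
    return np.clip(theta, bounds[:, 0] + 1e-12 * span, bounds[:, 1] - 1e-12 * span)


def _segmented_fit(s: np.ndarray, b: np.ndarray, options: FitOptions):
    high = b >= options.b_threshold
    if high.sum() < 2:
        raise ValueError("b_threshold leaves fewer than 2 high-b points")
    # log-linear regression on the mono-exponential tail
    y = np.log(np.maximum(s[high], 1e-12))
    slope, intercept = np.polyfit(b[high], y, 1)
    D = -slope
    f = 1.0 - np.exp(intercept)
    bounds = options.bounds
    D = float(np.clip(D, bounds[0, 0], bounds[0, 1]))
    f = float(np.clip(f, bounds[1, 0], bounds[1, 1]))

    # refine f and D* on all b with D fixed
    def resid(x):
        return (1.0 - x[0]) * np.exp(-b * D) + x[0] * np.exp(-b * x[1]) - s

    x0 = _clip_to_bounds(np.array([f, 10.0 * max(D, bounds[2, 0] / 10.0)]),
                         bounds[1:])
    res = least_squares(resid, x0, bounds=(bounds[1:, 0], bounds[1:, 1]),
                        method="trf", max_nfev=options.max_evals,
                        xtol=options.tolerance, ftol=options.tolerance,
                        gtol=options.tolerance)
    return np.array([D, res.x[0], res.x[1]]), bool(res.status > 0)


def fit_voxel_lsq(signal: np.ndarray, scheme: AcquisitionScheme,
                  options: FitOptions | None = None):
    """Fit one voxel's signal vector; returns ((D, f, Dstar), converged).

    The signal is normalized to its first (b0) sample internally.  On
    non-convergence of the full fit the segmented estimate is returned with
    the flag set False.
    """
    options = options or FitOptions()
    b = scheme.as_array()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != b.shape:
        raise ValueError("signal length does not match the scheme")
    if signal[0] <= 0:
        raise ValueError("Sb0 must be positive")
    s = signal / signal[0]

    theta_seg, seg_ok = _segmented_fit(s, b, options)
    if options.mode == "segmented":
        return theta_seg, seg_ok

    bounds = options.bounds

    def resid(x):
        return _biexp(x, b) - s

    res = least_squares(resid, _clip_to_bounds(theta_seg, bounds),
                        bounds=(bounds[:, 0], bounds[:, 1]), method="trf",
                        max_nfev=options.max_evals, xtol=options.tolerance,
                        ftol=options.tolerance, gtol=options.tolerance)
    if res.status <= 0:
        return theta_seg, False
    return res.x, True


def fit_volume(dw_volume: np.ndarray, mask: np.ndarray | None,
               scheme: AcquisitionScheme, options: FitOptions | None = None,
               fill_value: float = np.nan):
    """Voxel-wise LSQ over a volume (b-axis last).

    Results are independent of traversal order (each voxel is fit in
    isolation).  Returns (D_map, f_map, Dstar_map, converged_map); masked-out
    voxels hold ``fill_value`` (converged_map False).
    """
    options = options or FitOptions()
    dw_volume = np.asarray(dw_volume, dtype=float)
    spatial = dw_volume.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    maps = np.full((3,) + spatial, fill_value, dtype=float)
    conv = np.zeros(spatial, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        theta, ok = fit_voxel_lsq(dw_volume[idx], scheme, options)
        maps[(slice(None),) + idx] = theta
        conv[idx] = ok
    return maps[0], maps[1], maps[2], conv
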