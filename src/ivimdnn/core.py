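"""IVIM signal model and shared parameter types.

The intravoxel incoherent motion (IVIM) model describes diffusion-weighted
MRI signal decay as a mixture of two exponentials: a slow tissue-diffusion
component with coefficient ``D`` and a fast pseudo-diffusion component with
coefficient ``D*`` carrying a fraction ``f`` of the signal::

    S(b) = S0 * [ (1 - f) * exp(-b * D) + f * exp(-b * Dstar) ]

All diffusion coefficients are expressed in mm^2/s and b-values in s/mm^2;
``f`` is a dimensionless fraction in [0, 1].  No rescaling happens in this
module — network-facing scaling lives in :mod:`ivimdnn.features`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "IVIMParams",
    "ParamRanges",
    "AcquisitionScheme",
    "ivim_signal",
    "signal_vector",
]

#: Nine-point diffusion-weighting scheme (s/mm^2) used throughout:
#: dense low-b sampling for the perfusion component, two high b-values for D.
DEFAULT_B_VALUES: tuple[float, ...] = (0, 25, 50, 75, 100, 150, 300, 800, 1000)


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class IVIMParams:
    """A (D, f, D*) triplet — scalar or voxel-wise arrays.

    Invariants: ``D > 0``, ``0 <= f <= 1``, ``Dstar > 0``.  Physically
    meaningful fits additionally have ``Dstar > D`` (pseudo-diffusion is the
    fast compartment); that is not enforced here because raw estimator
    output may violate it and the metrics must see it.
    """

    D: np.ndarray | float
    f: np.ndarray | float
    Dstar: np.ndarray | float

    def __post_init__(self) -> None:
        D, f, Dstar = _asarray(self.D), _asarray(self.f), _asarray(self.Dstar)
        if np.any(D <= 0):
            raise ValueError("D must be positive")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("f must lie in [0, 1]")
        if np.any(Dstar <= 0):
            raise ValueError("Dstar must be positive")

    def as_array(self) -> np.ndarray:
        """Stack into an array of shape ``(..., 3)`` ordered (D, f, Dstar)."""
        return np.stack(np.broadcast_arrays(
            _asarray(self.D), _asarray(self.f), _asarray(self.Dstar)), axis=-1)


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling bounds for each IVIM parameter.

    Defaults are wide literature-based ranges covering both healthy and
    lesioned tissue: D in [5e-4, 2e-3] mm^2/s, f in [0.025, 0.4],
    D* in [5e-3, 1e-1] mm^2/s.
    """

    D: tuple[float, float] = (0.0005, 0.002)
    f: tuple[float, float] = (0.025, 0.4)
    Dstar: tuple[float, float] = (0.005, 0.1)

    def __post_init__(self) -> None:
        for name in ("D", "f", "Dstar"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
        if self.D[0] <= 0 or self.Dstar[0] <= 0 or self.f[0] < 0 or self.f[1] > 1:
            raise ValueError("bounds must respect IVIMParams invariants")

    def contains(self, params: IVIMParams) -> bool:
        arr = params.as_array().reshape(-1, 3)
        bounds = np.array([self.D, self.f, self.Dstar])
        return bool(np.all((arr >= bounds[:, 0]) & (arr <= bounds[:, 1])))

    def as_array(self) -> np.ndarray:
        """Bounds as a ``(3, 2)`` array ordered (D, f, Dstar) x (lo, hi)."""
        return np.array([self.D, self.f, self.Dstar], dtype=float)


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered list of b-values; the first entry is the reference b0."""

    b_values: tuple[float, ...] = DEFAULT_B_VALUES

    def __post_init__(self) -> None:
        b = _asarray(self.b_values)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def b0(self) -> float:
        return self.b_values[0]

    def as_array(self) -> np.ndarray:
        return _asarray(self.b_values)


def ivim_signal(params: IVIMParams, b, S0=1.0) -> np.ndarray | float:
    """Noiseless biexponential IVIM signal at diffusion weighting ``b``.

    Broadcasts over array-valued parameters, ``b`` and ``S0``.  Raises for
    negative ``b`` or non-positive ``S0``.
    """
    b = _asarray(b)
    S0 = _asarray(S0)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(S0 <= 0):
        raise ValueError("S0 must be positive")
    D, f, Dstar = _asarray(params.D), _asarray(params.f), _asarray(params.Dstar)
    out = S0 * ((1.0 - f) * np.exp(-b * D) + f * np.exp(-b * Dstar))
    return out if out.ndim else float(out)


def signal_vector(params: IVIMParams, scheme: AcquisitionScheme, S0=1.0) -> np.ndarray:
    """Noiseless signal sampled at every b-value of ``scheme``.

    Returns an array of shape ``(..., n_b)``; leading dimensions broadcast
    from the parameter arrays and ``S0``.
    """
    b = scheme.as_array()
    D = _asarray(params.D)[..., None]
    f = _asarray(params.f)[..., None]
    Dstar = _asarray(params.Dstar)[..., None]
    S0 = _asarray(S0)[..., None]
    return S0 * ((1.0 - f) * np.exp(-b * D) + f * np.exp(-b * Dstar))
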