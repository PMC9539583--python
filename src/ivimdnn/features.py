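"""Network input construction and target standardization.

Inputs: per-voxel signals are normalized to the measured b0 (Sb/Sb0), the
natural log of the normalized signals is optionally appended (9 -> 18
features for the default scheme), and each feature is affinely mapped to
[-1, 1] using per-feature min/max recorded on the training set.  Targets:
(D, f, D*) are z-scored against training-set ground truth so their very
different magnitudes contribute comparably to the MSE loss.

All scaling constants live here and travel with the trained model, so a
model file is self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FeatureConfig",
    "TargetStandardizer",
    "raw_features",
    "build_features",
    "fit_feature_scaling",
    "standardize_targets",
    "destandardize_outputs",
]

logger = logging.getLogger(__name__)

#: floor applied to normalized signals before taking the log; Rician
#: magnitudes are non-negative but can be arbitrarily close to zero.
LOG_FLOOR = 1e-6

PARAM_NAMES = ("D", "f", "Dstar")


@dataclass(frozen=True)
class FeatureConfig:
    """What the network sees per voxel and how it is scaled.

    ``n_features`` is ``n_b`` (normalized signals only) or ``2 * n_b``
    (log-augmented).  ``feature_min``/``feature_max`` are fitted on the
    training set by :func:`fit_feature_scaling`; until then they are None
    and only unscaled features can be produced.
    """

    n_b: int = 9
    log_features: bool = True
    normalize_to_b0: bool = True
    log_floor: float = LOG_FLOOR
    feature_min: tuple[float, ...] | None = None
    feature_max: tuple[float, ...] | None = None

    @property
    def n_features(self) -> int:
        return 2 * self.n_b if self.log_features else self.n_b

    @property
    def structurally_constant(self) -> frozenset[int]:
        """Feature indices that are constant by construction: with b0
        normalization the b0 ratio is identically 1 (and its log 0)."""
        if not self.normalize_to_b0:
            return frozenset()
        idx = {0}
        if self.log_features:
            idx.add(self.n_b)
        return frozenset(idx)

    @property
    def is_fitted(self) -> bool:
        return self.feature_min is not None

    def to_dict(self) -> dict:
        return {
            "n_b": self.n_b,
            "log_features": self.log_features,
            "normalize_to_b0": self.normalize_to_b0,
            "log_floor": self.log_floor,
            "feature_min": None if self.feature_min is None else list(self.feature_min),
            "feature_max": None if self.feature_max is None else list(self.feature_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        for key in ("feature_min", "feature_max"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def raw_features(signals: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Unscaled features: Sb/Sb0 per b-value, plus ln of those if enabled.

    ``signals`` has shape ``(n_voxels, n_b)``; Sb0 must be positive where
    normalization is requested.  Non-positive normalized values are clamped
    to ``config.log_floor`` before the log; the clamp count is logged.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != config.n_b:
        raise ValueError(f"expected (n_voxels, {config.n_b}) signals, got {signals.shape}")
    if config.normalize_to_b0:
        s0 = signals[:, :1]
        if np.any(s0 <= 0):
            raise ValueError("Sb0 must be positive for b0 normalization")
        ratios = signals / s0
    else:
        ratios = signals
    if not config.log_features:
        return ratios
    n_clamped = int(np.count_nonzero(ratios < config.log_floor))
    if n_clamped:
        logger.warning("log features: clamped %d non-positive values to %g",
                       n_clamped, config.log_floor)
    return np.concatenate([ratios, np.log(np.maximum(ratios, config.log_floor))], axis=1)


def fit_feature_scaling(training_signals: np.ndarray,
                        config: FeatureConfig) -> FeatureConfig:
    """Record per-feature min/max over the training set for the [-1, 1] map.

    The returned config is frozen and serialized with the model; applying it
    to data outside the training range produces values outside [-1, 1]
    (deliberately not clipped).
    """
    feats = raw_features(training_signals, config)
    if feats.shape[0] == 0:
        raise ValueError("empty training matrix")
    fmin = feats.min(axis=0)
    fmax = feats.max(axis=0)
    constant = set(np.flatnonzero(fmin == fmax).tolist())
    unexpected = constant - set(config.structurally_constant)
    if unexpected:
        raise ValueError(f"constant feature(s) {sorted(unexpected)}: min == max, "
                         "cannot map to [-1, 1]")
    # structurally constant features (b0 ratio == 1) map to the midpoint 0
    for i in constant:
        fmin[i] -= 1.0
        fmax[i] += 1.0
    return replace(config, feature_min=tuple(fmin), feature_max=tuple(fmax))


def build_features(signals: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Per-voxel network inputs, affinely mapped to [-1, 1].

    Requires a fitted config (stored min/max).  A raw value equal to the
    stored min maps to -1, the stored max to +1; out-of-range values are
    not clipped.
    """
    if not config.is_fitted:
        raise ValueError("FeatureConfig has no scaling constants; "
                         "call fit_feature_scaling on training data first")
    feats = raw_features(signals, config)
    fmin = np.asarray(config.feature_min)
    fmax = np.asarray(config.feature_max)
    return 2.0 * (feats - fmin) / (fmax - fmin) - 1.0


@dataclass(frozen=True)
class TargetStandardizer:
    """z-scoring of (D, f, D*) targets, fitted on training ground truth.

    With ``enabled=False`` both transforms are identity maps (the
    no-standardization ablation arm).
    """

    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    std: tuple[float, float, float] = (1.0, 1.0, 1.0)
    enabled: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise ValueError("standardizer std must be positive")

    @classmethod
    def fit(cls, targets: np.ndarray, enabled: bool = True) -> "TargetStandardizer":
        targets = np.asarray(targets, dtype=float)
        if targets.ndim != 2 or targets.shape[1] != 3:
            raise ValueError("targets must have shape (n, 3)")
        if not enabled:
            return cls(enabled=False)
        return cls(mean=tuple(targets.mean(axis=0)),
                   std=tuple(targets.std(axis=0)), enabled=True)

    def standardize(self, params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        if not self.enabled:
            return params.copy()
        return (params - np.asarray(self.mean)) / np.asarray(self.std)

    def destandardize(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if not self.enabled:
            return z.copy()
        return z * np.asarray(self.std) + np.asarray(self.mean)

    def to_dict(self) -> dict:
        return {"mean": list(self.mean), "std": list(self.std), "enabled": self.enabled}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetStandardizer":
        return cls(mean=tuple(d["mean"]), std=tuple(d["std"]), enabled=d["enabled"])


def standardize_targets(params: np.ndarray, std: TargetStandardizer) -> np.ndarray:
    """z = (p - mean) / std per parameter (identity when disabled)."""
    return std.standardize(params)


def destandardize_outputs(outputs: np.ndarray, std: TargetStandardizer,
                          clip_to=None) -> np.ndarray:
    """p = z * std + mean; optionally clip to a ``ParamRanges`` box.

    Clipping is off by default so metrics see raw estimator behaviour
    (failure-rate analysis depends on it); pass a ``ParamRanges`` for map
    rendering.
    """
    p = std.destandardize(outputs)
    if clip_to is not None:
        bounds = clip_to.as_array()
        p = np.clip(p, bounds[:, 0], bounds[:, 1])
    return p
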