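"""Supervised fully connected network for voxel-wise IVIM regression.

A small multilayer perceptron (tanh hidden layers, linear output) maps the
per-voxel feature vector (9 or 18 inputs, see :mod:`ivimdnn.features`) to
the three standardized IVIM targets under an MSE loss.  One network is
trained jointly on voxels pooled across all SNR levels — the whole point of
the approach is a single model for the full SNR range.

Two optimizers share the same stopping criteria (gradient floor, iteration
cap, validation patience):

* ``"lm"`` — damped Gauss–Newton / Levenberg–Marquardt with the classic
  damping schedule (initial 1e-3, x0.1 on an accepted step, x10 on a
  rejected one).  Exact but builds the full Jacobian; intended for runs up
  to a few thousand voxels.
* ``"adam"`` — mini-batch first-order fallback for large pooled training
  sets, with a per-epoch validation check mirroring LM's per-iteration one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ParamRanges
from .features import (FeatureConfig, TargetStandardizer, build_features,
                       fit_feature_scaling)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "TrainedModel",
    "MLP",
    "EarlyStopping",
    "train",
    "train_on_phantoms",
    "predict",
    "run_ablation_grid",
    "ABLATION_ARMS",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture: n_inputs -> hidden_width x hidden_layers (tanh) -> 3 (linear)."""

    n_inputs: int = 18
    hidden_layers: int = 3
    hidden_width: int = 32
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.hidden_layers, self.hidden_width, self.n_outputs) < 1:
            raise ValueError("network dimensions must be positive")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs,) + (self.hidden_width,) * self.hidden_layers + (self.n_outputs,)


@dataclass(frozen=True)
class TrainingConfig:
    """Loss is MSE; stopping criteria are shared by both optimizers.

    ``initial_lr`` plays the role of the LM damping parameter (for
    ``optimizer="lm"``) or the Adam step size (for ``"adam"``);
    ``lr_decrease``/``lr_increase`` drive the LM damping schedule.
    ``max_iterations`` counts LM iterations or Adam epochs.
    """

    optimizer: str = "lm"
    initial_lr: float = 1e-3
    lr_decrease: float = 0.1
    lr_increase: float = 10.0
    max_iterations: int = 5000
    min_gradient: float = 1e-7
    validation_patience: int = 6
    validation_fraction: float = 0.2
    batch_size: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("lm", "adam"):
            raise ValueError("optimizer must be 'lm' or 'adam'")
        if self.lr_decrease <= 0 or self.lr_increase <= 0 or self.initial_lr <= 0:
            raise ValueError("learning-rate factors must be positive")
        if self.validation_patience < 1:
            raise ValueError("validation_patience must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


class MLP:
    """Feedforward net with tanh hidden activations and linear outputs."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        sizes = config.layer_sizes
        self.weights: list[np.ndarray] = [np.zeros((sizes[i], sizes[i + 1]))
                                          for i in range(len(sizes) - 1)]
        self.biases: list[np.ndarray] = [np.zeros(sizes[i + 1])
                                         for i in range(len(sizes) - 1)]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def init_weights(self, rng: np.random.Generator) -> None:
        """Symmetric uniform init scaled by fan-in (U[-1/sqrt(fan_in), +])."""
        for i, w in enumerate(self.weights):
            bound = 1.0 / np.sqrt(w.shape[0])
            self.weights[i] = rng.uniform(-bound, bound, size=w.shape)
            self.biases[i] = rng.uniform(-bound, bound, size=self.biases[i].shape)

    def forward(self, X: np.ndarray, keep: bool = False):
        """Forward pass; with ``keep`` returns the per-layer activations too."""
        a = np.asarray(X, dtype=float)
        acts = [a]
        last = self.n_layers - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = z if i == last else np.tanh(z)
            if keep:
                acts.append(a)
        return (a, acts) if keep else a

    # flat parameter vector <-> weight list, used by the LM solver
    def get_flat(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b.ravel()])
                               for w, b in zip(self.weights, self.biases)])

    def set_flat(self, theta: np.ndarray) -> None:
        k = 0
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[k:k + w.size].reshape(w.shape).copy()
            k += w.size
            self.biases[i] = theta[k:k + b.size].copy()
            k += b.size

    def gradient(self, X: np.ndarray, Y: np.ndarray):
        """MSE loss and its flat gradient (backprop), averaged over samples."""
        out, acts = self.forward(X, keep=True)
        n = X.shape[0]
        err = out - Y
        loss = float(np.mean(err ** 2))
        # d(mean sq err)/d out; MSE averages over samples AND outputs
        delta = 2.0 * err / err.size
        grads_w, grads_b = [], []
        for i in range(self.n_layers - 1, -1, -1):
            grads_w.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1.0 - acts[i] ** 2)
        grads_w.reverse()
        grads_b.reverse()
        flat = np.concatenate([np.concatenate([gw.ravel(), gb.ravel()])
                               for gw, gb in zip(grads_w, grads_b)])
        return loss, flat

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """Per-sample Jacobian of outputs w.r.t. parameters: (n, n_out, n_params).

        Dense — memory scales as n * n_outputs * n_params, so this is only
        for LM-scale problems.
        """
        out, acts = self.forward(X, keep=True)
        n, n_out = out.shape
        J = np.empty((n, n_out, self.n_params))
        for k in range(n_out):
            delta = np.zeros_like(out)
            delta[:, k] = 1.0
            col = 0
            pieces = []
            for i in range(self.n_layers - 1, -1, -1):
                gw = np.einsum("ni,nj->nij", acts[i], delta)
                gb = delta
                pieces.append((i, gw, gb))
                if i > 0:
                    delta = (delta @ self.weights[i].T) * (1.0 - acts[i] ** 2)
            pieces.sort(key=lambda p: p[0])
            for _, gw, gb in pieces:
                J[:, k, col:col + gw.shape[1] * gw.shape[2]] = gw.reshape(n, -1)
                col += gw.shape[1] * gw.shape[2]
                J[:, k, col:col + gb.shape[1]] = gb
                col += gb.shape[1]
        return J


class EarlyStopping:
    """Validation patience: stop after ``patience`` consecutive checks that
    fail to improve on the best validation loss seen; remembers the best
    parameter vector."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_theta: np.ndarray | None = None
        self.fails = 0

    def check(self, loss: float, theta: np.ndarray) -> bool:
        """Record one validation check; True means training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_theta = theta.copy()
            self.fails = 0
            return False
        self.fails += 1
        return self.fails >= self.patience


def _split_train_val(n: int, fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * fraction)))
    return perm[n_val:], perm[:n_val]


def _train_lm(net: MLP, Xtr, Ytr, Xval, Yval, tr: TrainingConfig, history: dict):
    theta = net.get_flat()
    mu = tr.initial_lr
    stopper = EarlyStopping(tr.validation_patience)
    out = net.forward(Xtr)
    loss = float(np.mean((out - Ytr) ** 2))
    stop_reason = "max_iterations"
    n_iter = 0
    eye = np.eye(net.n_params)
    for n_iter in range(1, tr.max_iterations + 1):
        J = net.jacobian(Xtr).reshape(-1, net.n_params)
        r = (net.forward(Xtr) - Ytr).ravel()
        g = 2.0 * (J.T @ r) / r.size           # gradient of the MSE
        if np.max(np.abs(g)) < tr.min_gradient:
            stop_reason = "min_gradient"
            break
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        while mu < 1e10:
            try:
                step = np.linalg.solve(JtJ + mu * eye, -Jtr)
            except np.linalg.LinAlgError:
                mu *= tr.lr_increase
                continue
            net.set_flat(theta + step)
            new_loss = float(np.mean((net.forward(Xtr) - Ytr) ** 2))
            if np.isnan(new_loss):
                raise RuntimeError("NaN training loss in LM step")
            if new_loss < loss:                # accept only improving steps
                theta = theta + step
                loss = new_loss
                mu = max(mu * tr.lr_decrease, 1e-20)
                accepted = True
                break
            mu *= tr.lr_increase
        if not accepted:
            net.set_flat(theta)
            stop_reason = "min_gradient"       # damping exhausted: stationary
            break
        val_loss = float(np.mean((net.forward(Xval) - Yval) ** 2))
        history["train_loss"].append(loss)
        history["val_loss"].append(val_loss)
        if stopper.check(val_loss, theta):
            stop_reason = "patience_exhausted"
            break
    if stopper.best_theta is not None:
        net.set_flat(stopper.best_theta)
    else:
        net.set_flat(theta)
    return stop_reason, n_iter


#: number of validation-plateau rate decreases the first-order fallback
#: performs before declaring the patience exhausted.
ADAM_LR_DECAYS = 3


def _train_adam(net: MLP, Xtr, Ytr, Xval, Yval, tr: TrainingConfig,
                rng: np.random.Generator, history: dict):
    """Mini-batch Adam with the adaptive-rate schedule applied globally:
    when validation fails to improve for ``validation_patience`` consecutive
    epochs the best weights are restored and the step size is multiplied by
    ``lr_decrease``; after ``ADAM_LR_DECAYS`` such plateaus training stops."""
    theta = net.get_flat()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    lr = tr.initial_lr
    decays_left = ADAM_LR_DECAYS
    stopper = EarlyStopping(tr.validation_patience)
    stop_reason = "max_iterations"
    n = Xtr.shape[0]
    n_epoch = 0
    for n_epoch in range(1, tr.max_iterations + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        grad_inf = 0.0
        for start in range(0, n, tr.batch_size):
            idx = perm[start:start + tr.batch_size]
            net.set_flat(theta)
            loss, g = net.gradient(Xtr[idx], Ytr[idx])
            if np.isnan(loss):
                raise RuntimeError("NaN training loss in Adam step")
            t += 1
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            theta = theta - lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
            grad_inf = max(grad_inf, float(np.max(np.abs(g))))
        net.set_flat(theta)
        val_loss = float(np.mean((net.forward(Xval) - Yval) ** 2))
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if stopper.check(val_loss, theta):
            if decays_left > 0:
                decays_left -= 1
                lr *= tr.lr_decrease
                theta = stopper.best_theta.copy()
                m[:] = 0.0
                v[:] = 0.0
                t = 0
                stopper.fails = 0
            else:
                stop_reason = "patience_exhausted"
                break
        if grad_inf < tr.min_gradient:
            stop_reason = "min_gradient"
            break
    if stopper.best_theta is not None:
        net.set_flat(stopper.best_theta)
    return stop_reason, n_epoch


@dataclass
class TrainedModel:
    """Network weights plus everything needed to apply them.

    Feature scaling and target standardization constants travel with the
    weights; :func:`predict` refuses to run without them.
    """

    network: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_config: FeatureConfig
    standardizer: TargetStandardizer
    metadata: dict = field(default_factory=dict)

    def _mlp(self) -> MLP:
        net = MLP(self.network)
        net.weights = [w.copy() for w in self.weights]
        net.biases = [b.copy() for b in self.biases]
        return net

    def predict_signals(self, signals: np.ndarray,
                        clip_to: ParamRanges | None = None) -> np.ndarray:
        """(n_voxels, n_b) signals -> (n_voxels, 3) destandardized (D, f, D*)."""
        if self.feature_config is None or self.standardizer is None:
            raise ValueError("model is missing scaling constants; cannot predict")
        if signals.shape[1] != self.feature_config.n_b:
            raise ValueError(
                f"b-value count {signals.shape[1]} does not match the "
                f"{self.feature_config.n_b} the model was trained on; a different "
                "b-value set requires retraining the network")
        X = build_features(signals, self.feature_config)
        z = self._mlp().forward(X)
        out = self.standardizer.destandardize(z)
        if clip_to is not None:
            bounds = clip_to.as_array()
            out = np.clip(out, bounds[:, 0], bounds[:, 1])
        return out

    def save(self, path) -> Path:
        """Single JSON archive: version header, configs, scaling constants,
        weight arrays (nested lists), training metadata."""
        path = Path(path)
        doc = {
            "format": "ivimdnn-model",
            "version": MODEL_FORMAT_VERSION,
            "network": asdict(self.network),
            "feature_config": self.feature_config.to_dict(),
            "standardizer": self.standardizer.to_dict(),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "metadata": self.metadata,
        }
        path.write_text(json.dumps(doc, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "TrainedModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "ivimdnn-model":
            raise ValueError(f"{path} is not an ivimdnn model file")
        if doc["version"] > MODEL_FORMAT_VERSION:
            raise ValueError(f"model format version {doc['version']} is newer "
                             f"than supported ({MODEL_FORMAT_VERSION})")
        return cls(
            network=NetworkConfig(**doc["network"]),
            weights=[np.array(w) for w in doc["weights"]],
            biases=[np.array(b) for b in doc["biases"]],
            feature_config=FeatureConfig.from_dict(doc["feature_config"]),
            standardizer=TargetStandardizer.from_dict(doc["standardizer"]),
            metadata=doc["metadata"],
        )


def train(signals: np.ndarray, targets: np.ndarray,
          network: NetworkConfig | None = None,
          training: TrainingConfig | None = None,
          feature_config: FeatureConfig | None = None,
          standardize: bool = True) -> TrainedModel:
    """Fit the network on pooled per-voxel (signal, ground-truth) pairs.

    ``signals`` is ``(n_voxels, n_b)`` (background already excluded),
    ``targets`` is ``(n_voxels, 3)`` in physical units.  Feature scaling and
    target standardization are fitted here on the training voxels and frozen
    into the returned model.  Deterministic given ``training.seed``.
    """
    network = network or NetworkConfig()
    training = training or TrainingConfig()
    signals = np.asarray(signals, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if signals.shape[0] == 0:
        raise ValueError("empty training dataset")
    if signals.shape[0] != targets.shape[0]:
        raise ValueError("signals and targets disagree on voxel count")

    feature_config = feature_config or FeatureConfig(
        n_b=signals.shape[1], log_features=(network.n_inputs == 2 * signals.shape[1]))
    feature_config = fit_feature_scaling(signals, feature_config)
    if feature_config.n_features != network.n_inputs:
        raise ValueError(f"feature config produces {feature_config.n_features} "
                         f"inputs but the network expects {network.n_inputs}")
    X = build_features(signals, feature_config)
    standardizer = TargetStandardizer.fit(targets, enabled=standardize)
    Y = standardizer.standardize(targets)

    rng = np.random.default_rng(training.seed)
    tr_idx, val_idx = _split_train_val(X.shape[0], training.validation_fraction, rng)
    net = MLP(network)
    net.init_weights(rng)
    history: dict = {"train_loss": [], "val_loss": []}
    if training.optimizer == "lm":
        stop_reason, n_iter = _train_lm(net, X[tr_idx], Y[tr_idx],
                                        X[val_idx], Y[val_idx], training, history)
    else:
        stop_reason, n_iter = _train_adam(net, X[tr_idx], Y[tr_idx],
                                          X[val_idx], Y[val_idx], training, rng, history)
    val_mse = float(np.mean((net.forward(X[val_idx]) - Y[val_idx]) ** 2))
    if not np.isfinite(val_mse):
        raise RuntimeError("training produced a non-finite validation loss")
    return TrainedModel(
        network=network, weights=net.weights, biases=net.biases,
        feature_config=feature_config, standardizer=standardizer,
        metadata={
            "optimizer": training.optimizer,
            "stop_reason": stop_reason,
            "n_iterations": n_iter,
            "seed": training.seed,
            "n_training_voxels": int(len(tr_idx)),
            "n_validation_voxels": int(len(val_idx)),
            "final_val_mse": val_mse,
            "train_loss": history["train_loss"],
            "val_loss": history["val_loss"],
        })


def extract_training_voxels(phantoms, rng: np.random.Generator | None = None,
                            max_voxels: int | None = None):
    """Pool foreground voxels (noisy signals + ground truth) from phantoms.

    Optionally subsamples to ``max_voxels`` without replacement.  Phantoms
    should span every SNR level the model is meant to serve.
    """
    sig_blocks, tgt_blocks = [], []
    for inst in phantoms:
        fg = inst.foreground
        sig_blocks.append(inst.noisy[fg])
        tgt_blocks.append(inst.truth_array()[fg])
    signals = np.concatenate(sig_blocks, axis=0)
    targets = np.concatenate(tgt_blocks, axis=0)
    if max_voxels is not None and signals.shape[0] > max_voxels:
        if rng is None:
            raise ValueError("subsampling requires an rng")
        keep = rng.choice(signals.shape[0], size=max_voxels, replace=False)
        signals, targets = signals[keep], targets[keep]
    return signals, targets


def train_on_phantoms(phantoms, network: NetworkConfig | None = None,
                      training: TrainingConfig | None = None,
                      standardize: bool = True,
                      max_voxels: int | None = None) -> TrainedModel:
    """Convenience wrapper: pool phantom foreground voxels and train."""
    training = training or TrainingConfig()
    rng = np.random.default_rng(np.random.SeedSequence((training.seed, 0xF00D)))
    signals, targets = extract_training_voxels(phantoms, rng, max_voxels)
    return train(signals, targets, network=network, training=training,
                 standardize=standardize)


def predict(model: TrainedModel, dw_volume: np.ndarray,
            mask: np.ndarray | None = None, fill_value: float = np.nan,
            clip_to: ParamRanges | None = None):
    """Apply a trained model voxel-wise to a DW volume.

    ``dw_volume`` has the b-axis last (any leading spatial shape); ``mask``
    selects voxels to fit, everything else is filled with ``fill_value``.
    Returns three maps (D, f, Dstar) with the volume's spatial shape.
    """
    dw_volume = np.asarray(dw_volume, dtype=float)
    spatial = dw_volume.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match volume spatial shape")
    maps = np.full((3,) + spatial, fill_value, dtype=float)
    if mask.any():
        out = model.predict_signals(dw_volume[mask], clip_to=clip_to)
        for k in range(3):
            maps[k][mask] = out[:, k]
    return maps[0], maps[1], maps[2]


#: The five architecture/ablation arms of the tuning study, by name:
#: 2/3/4 hidden layers with 9 standardized inputs, the 3-layer 9-input arm
#: without target standardization, and the final 3-layer 18-input arm.
ABLATION_ARMS: dict[str, dict] = {
    "h2-9in-std": {"hidden_layers": 2, "log_features": False, "standardize": True},
    "h3-9in-std": {"hidden_layers": 3, "log_features": False, "standardize": True},
    "h4-9in-std": {"hidden_layers": 4, "log_features": False, "standardize": True},
    "h3-9in-raw": {"hidden_layers": 3, "log_features": False, "standardize": False},
    "h3-18in-std": {"hidden_layers": 3, "log_features": True, "standardize": True},
}


def run_ablation_grid(arms: dict[str, dict], train_phantoms, test_phantoms,
                      training: TrainingConfig | None = None,
                      hidden_width: int = 32,
                      max_voxels: int | None = None) -> dict:
    """Train one model per arm on identical data and evaluate each.

    Every arm shares the same pooled voxel sample, the same train/validation
    split seed and the same held-out phantoms, so differences between arms
    reflect architecture/standardization choices only.  Returns
    ``{name: {"model": TrainedModel, "report": DataFrame}}``.
    """
    from .metrics import build_report

    training = training or TrainingConfig(optimizer="adam", max_iterations=60)
    train_phantoms = list(train_phantoms)
    test_phantoms = list(test_phantoms)
    rng = np.random.default_rng(np.random.SeedSequence((training.seed, 0xF00D)))
    signals, targets = extract_training_voxels(train_phantoms, rng, max_voxels)

    results = {}
    for name, arm in arms.items():
        n_b = signals.shape[1]
        n_inputs = 2 * n_b if arm.get("log_features", True) else n_b
        net_cfg = NetworkConfig(n_inputs=n_inputs,
                                hidden_layers=arm.get("hidden_layers", 3),
                                hidden_width=hidden_width)
        feat_cfg = FeatureConfig(n_b=n_b, log_features=arm.get("log_features", True))
        model = train(signals, targets, network=net_cfg, training=training,
                      feature_config=feat_cfg,
                      standardize=arm.get("standardize", True))
        records = []
        for inst in test_phantoms:
            d_map, f_map, ds_map = predict(model, inst.noisy, inst.foreground)
            records.append({
                "method": name, "snr": inst.snr,
                "est": np.stack([d_map, f_map, ds_map]),
                "truth": np.moveaxis(inst.truth_array(), -1, 0),
                "roi_labels": inst.roi_labels,
            })
        results[name] = {"model": model, "report": build_report(records)}
    return results
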