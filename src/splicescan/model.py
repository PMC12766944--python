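"""The splice-site classifier: a two-layer 1D-CNN with 7026 parameters.

Layer stack (default 202 bp window, one-hot input 4 x 202)::

    conv1d(4 -> 16, k=5, no bias)   320 parameters, out 16 x 198
    ReLU
    max-pool(3, ceil)                        out 16 x 66
    conv1d(16 -> 16, k=5, no bias) 1280 parameters, out 16 x 62
    ReLU
    max-pool(3, ceil)                        out 16 x 21
    flatten                                  out 336
    dense(336 -> 16) + bias        5392 parameters
    ReLU
    dense(16 -> 2) + bias            34 parameters
    softmax

for 7026 trainable parameters in total.  The same stack on a 302 bp window
puts 16 x 32 cells at the last max-pool layer.  Both counts are enforced
at build time so any change to the shapes fails fast.  Donors and
acceptors share one joint model: the central GT/AG of the input window
identifies the site type, and the two-way softmax separates site from
non-site.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import nn
from .dataset import SiteExample, codes_to_onehot, examples_to_arrays, windows_to_codes

EXPECTED_PARAMS_202 = 7026
EXPECTED_LAST_POOL_302 = (16, 32)


class ModelBuildError(ValueError):
    pass


@dataclass
class ModelConfig:
    window_len: int = 202
    conv_features: int = 16
    kernel_size: int = 5
    n_conv_layers: int = 2
    pool_size: int = 3
    dense_hidden: int = 16
    n_outputs: int = 2

    def is_canonical_family(self) -> bool:
        """Whether this config claims the published two-conv-layer model
        (16 features, kernel 5); such configs must hit the architecture
        checksums at build time."""
        return (
            self.conv_features == 16
            and self.kernel_size == 5
            and self.n_conv_layers == 2
            and self.n_outputs == 2
        )


@dataclass
class FitResult:
    """Training outcome: per-epoch costs, the best epoch and final weights."""

    train_cost: list[float] = field(default_factory=list)
    val_cost: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 1-based
    stopped_epoch: int = -1
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "SpliceCNN training",
            f"  epochs run   : {self.stopped_epoch}",
            f"  best epoch   : {self.best_epoch}",
            f"  best val cost: {min(self.val_cost):.4f}" if self.val_cost else "",
            "  epoch  train_cost  val_cost",
        ]
        for i, (tc, vc) in enumerate(zip(self.train_cost, self.val_cost), 1):
            mark = " *" if i == self.best_epoch else ""
            lines.append(f"  {i:5d}  {tc:10.4f}  {vc:8.4f}{mark}")
        return "\n".join(line for line in lines if line)


class SpliceCNN:
    """Splice-site model object; :meth:`fit` returns a :class:`FitResult`."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        self.net, self._last_pool_index, self.last_pool_shape = _build_net(
            self.config, seed
        )
        self.fit_result: FitResult | None = None
        self.calibration = None  # CalibrationTable, attached after calibrate

    # -- scoring ----------------------------------------------------------

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Raw scores t in [0,1] (softmax site probability) per window.

        ``batch`` is (B, 4, L) one-hot; order is preserved.
        """
        if batch.ndim != 3 or batch.shape[1] != 4 or batch.shape[2] != self.config.window_len:
            raise ValueError(
                f"expected batch of one-hot windows (B, 4, {self.config.window_len}), "
                f"got {batch.shape}"
            )
        logits = self.net.forward(batch.astype(nn.DTYPE))
        return nn.softmax(logits)[:, 1]

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        logits = self.net.forward(batch.astype(nn.DTYPE))
        return nn.softmax(logits)

    def score_windows(self, windows: Sequence[str], batch_size: int = 1024) -> np.ndarray:
        """Raw scores for string windows, computed in batches."""
        codes = windows_to_codes(list(windows))
        return self.score_codes(codes, batch_size)

    def score_codes(self, codes: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = np.empty(len(codes), dtype=np.float64)
        for i in range(0, len(codes), batch_size):
            out[i : i + batch_size] = self.forward(codes_to_onehot(codes[i : i + batch_size]))
        return out

    def count_parameters(self) -> int:
        return self.net.n_params()

    # -- training ---------------------------------------------------------

    def fit(
        self,
        train_examples: Sequence[SiteExample],
        val_examples: Sequence[SiteExample],
        max_epochs: int = 20,
        patience: int = 3,
        lr: float = 3e-3,
        batch_size: int = 64,
        weight_decay: float = 0.3,
        seed: int = 0,
        val_cost_fn: Callable[["SpliceCNN", int], float] | None = None,
    ) -> FitResult:
        """Minimize cross-entropy with Adam; early-stop on validation cost.

        Training stops when the validation cost has not improved for
        ``patience`` consecutive epochs (or at ``max_epochs``) and the
        weights of the best-validation epoch are restored.  ``val_cost_fn``
        overrides the validation-cost computation (used to test the
        early-stopping state machine in isolation).
        """
        if not train_examples or not val_examples:
            raise ValueError("train and validation sets must be non-empty")
        xc, y = examples_to_arrays(train_examples)
        if len(set(y.tolist())) < 2:
            raise ValueError("training set must contain both labels")
        vxc, vy = examples_to_arrays(val_examples)

        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.net.params(), lr=lr, weight_decay=weight_decay)
        result = FitResult(config={
            "max_epochs": max_epochs, "patience": patience, "lr": lr,
            "batch_size": batch_size, "weight_decay": weight_decay, "seed": seed,
            "optimizer": "adamw", "n_train": len(y), "n_val": len(vy),
        })
        best_cost = np.inf
        best_weights = self.net.get_weights()
        best_epoch = 0
        stale = 0
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(len(y))
            costs = []
            for i in range(0, len(order), batch_size):
                idx = order[i : i + batch_size]
                x = codes_to_onehot(xc[idx])
                logits = self.net.forward(x, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
                self.net.backward(dlogits)
                opt.step(self.net.grads())
                costs.append(loss)
            if val_cost_fn is not None:
                vcost = float(val_cost_fn(self, epoch))
            else:
                vcost = self._cost(vxc, vy, batch_size)
            result.train_cost.append(float(np.mean(costs)))
            result.val_cost.append(vcost)
            if vcost < best_cost:
                best_cost = vcost
                best_weights = self.net.get_weights()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
            if stale >= patience:
                break
        self.net.set_weights(best_weights)
        result.best_epoch = best_epoch
        result.stopped_epoch = len(result.val_cost)
        self.fit_result = result
        return result

    def _cost(self, codes: np.ndarray, labels: np.ndarray, batch_size: int = 1024) -> float:
        total = 0.0
        for i in range(0, len(codes), batch_size):
            x = codes_to_onehot(codes[i : i + batch_size])
            logits = self.net.forward(x)
            loss, _ = nn.softmax_cross_entropy(logits, labels[i : i + batch_size])
            total += loss * len(logits)
        return total / len(codes)

    # -- inspection -------------------------------------------------------

    def activation_rates(self, batch: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Fraction of inputs activating (value > 0) each last-max-pool cell.

        Returns a matrix with the last pool layer's shape; all entries lie
        in [0, 1] because the preceding ReLU makes activations non-negative.
        """
        if len(batch) == 0:
            raise ValueError("need at least one window")
        counts = np.zeros(self.last_pool_shape, dtype=np.int64)
        for i in range(0, len(batch), batch_size):
            _, act = self.net.forward(
                batch[i : i + batch_size].astype(nn.DTYPE),
                capture=self._last_pool_index,
            )
            counts += (act > 0).sum(axis=0)
        return counts / len(batch)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            f"w{i}": w for i, w in enumerate(self.net.get_weights())
        }
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        if self.fit_result is not None:
            payload["train_cost"] = np.array(self.fit_result.train_cost)
            payload["val_cost"] = np.array(self.fit_result.val_cost)
            payload["fit_meta"] = np.array(
                [self.fit_result.best_epoch, self.fit_result.stopped_epoch]
            )
        if self.calibration is not None:
            payload["calib_P"] = self.calibration.P_i
            payload["calib_N"] = self.calibration.N_i
            payload["calib_s"] = self.calibration.s_i
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "SpliceCNN":
        from .calibrate import CalibrationTable

        data = np.load(path)
        config = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = cls(config)
        weights = [data[f"w{i}"] for i in range(len(model.net.params()))]
        model.net.set_weights(weights)
        if "train_cost" in data:
            best, stopped = (int(v) for v in data["fit_meta"])
            model.fit_result = FitResult(
                train_cost=list(data["train_cost"]),
                val_cost=list(data["val_cost"]),
                best_epoch=best,
                stopped_epoch=stopped,
            )
        if "calib_P" in data:
            model.calibration = CalibrationTable.from_counts(
                data["calib_P"].astype(np.int64), data["calib_N"].astype(np.int64)
            )
        return model

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(json.dumps(asdict(self.config)).encode()).hexdigest()[:12]


def _build_net(config: ModelConfig, seed: int) -> tuple[nn.Sequential, int, tuple[int, int]]:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    shape = (4, config.window_len)
    last_pool_index = -1
    in_ch = 4
    for _ in range(config.n_conv_layers):
        conv = nn.Conv1D(in_ch, config.conv_features, config.kernel_size,
                         bias=False, rng=rng)
        layers.append(conv)
        shape = conv.out_shape(shape)
        relu = nn.ReLU()
        layers.append(relu)
        pool = nn.MaxPool1D(config.pool_size)
        layers.append(pool)
        shape = pool.out_shape(shape)
        last_pool_index = len(layers) - 1
        in_ch = config.conv_features
    if shape[1] < 1:
        raise ModelBuildError(f"window_len {config.window_len} too small: last pool empty")
    last_pool_shape = shape
    layers.append(nn.Flatten())
    flat = shape[0] * shape[1]
    layers.append(nn.Dense(flat, config.dense_hidden, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.dense_hidden, config.n_outputs, rng=rng))
    net = nn.Sequential(layers)

    n_params = net.n_params()
    if config.is_canonical_family():
        if config.window_len == 202 and n_params != EXPECTED_PARAMS_202:
            raise ModelBuildError(
                f"default 202bp stack must have {EXPECTED_PARAMS_202} parameters; "
                f"built {n_params} with last pool {last_pool_shape}"
            )
        if config.window_len == 302 and last_pool_shape != EXPECTED_LAST_POOL_302:
            raise ModelBuildError(
                f"302bp stack must have last pool {EXPECTED_LAST_POOL_302}; "
                f"built {last_pool_shape} with {n_params} parameters"
            )
    return net, last_pool_index, last_pool_shape


# -- spec-facing functional wrappers ---------------------------------------


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SpliceCNN:
    return SpliceCNN(config, seed)


def count_parameters(model: SpliceCNN) -> int:
    return model.count_parameters()


def forward(model: SpliceCNN, batch: np.ndarray) -> np.ndarray:
    return model.forward(batch)


def train(model: SpliceCNN, train_examples, val_examples, max_epochs: int = 20,
          patience: int = 3, seed: int = 0, **kwargs) -> SpliceCNN:
    model.fit(train_examples, val_examples, max_epochs=max_epochs,
              patience=patience, seed=seed, **kwargs)
    return model


def activation_rates(model: SpliceCNN, batch: np.ndarray) -> np.ndarray:
    return model.activation_rates(batch)
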