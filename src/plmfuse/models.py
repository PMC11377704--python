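"""Per-residue convolutional predictors in three input-fusion variants.

``base`` consumes one feature matrix per chain (embeddings, any width);
``concat`` consumes embeddings with PSSM columns appended; ``split`` routes
embeddings and PSSM through separate convolutional branches whose learned
per-residue features are concatenated before a final convolutional head.
All variants share the fit/predict contract, so comparisons between
workflows differ only in their inputs, not in model capacity.

The estimator follows the scikit-learn conventions: constructor arguments
are stored verbatim, ``fit`` returns ``self``, and fitted state lives in
trailing-underscore attributes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import Adam, ConvStack, masked_mse, masked_softmax_xent, softmax
from .types import SS3_ALPHABET, LabelTrack

VARIANTS = ("base", "concat", "split")


@dataclass
class ModelConfig:
    """Bundle of architecture and training settings (checkpointable)."""

    variant: str = "base"
    input_width: int = 1024
    pssm_width: int = 20
    hidden_widths: tuple[int, ...] = (32, 16, 8)
    n_classes: int = 3
    kernel_size: int = 7
    task: str = "classification"
    classes: tuple[str, ...] = SS3_ALPHABET
    leaky_slope: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    class_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if len(self.hidden_widths) < 1:
            raise ValueError("need at least one hidden width")
        if self.task == "classification" and self.n_classes < 2:
            raise ValueError("need n_classes >= 2")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


class ResidueConvNet(BaseEstimator):
    """Per-residue 1-D CNN over fixed embeddings (transfer learning head).

    Parameters mirror :class:`ModelConfig`. ``X`` is a list of per-chain
    feature matrices: ``(L, input_width)`` for ``base``,
    ``(L, input_width + pssm_width)`` for ``concat`` and ``split`` (the
    last ``pssm_width`` columns are the PSSM block; ``split`` slices them
    into its second branch). ``y`` is a list of per-chain label strings,
    integer arrays or :class:`LabelTrack` objects (float arrays for the
    regression task).

    The architecture is a stack of same-padding 1-D convolutions with
    leaky-ReLU activations and channel widths ``input -> hidden_widths ->
    n_classes`` with a per-residue softmax head (linear head for
    regression). The ``split`` variant runs two branches through the first
    two hidden widths and merges them by channel concatenation before the
    remaining widths.

    Attributes
    ----------
    stacks_ : dict of ConvStack
        Learned weights ("main" or "branch_emb"/"branch_pssm"/"trunk").
    history_ : pandas.DataFrame
        Per-epoch loss and validation metric.
    n_epochs_ : int
        Epochs actually run.
    best_val_metric_ : float
        Monitor value of the returned weights.
    """

    def __init__(self, variant="base", input_width=1024, pssm_width=20,
                 hidden_widths=(32, 16, 8), n_classes=3, kernel_size=7,
                 task="classification", classes=SS3_ALPHABET, leaky_slope=0.01,
                 learning_rate=1e-3, batch_size=32, max_epochs=200, patience=10,
                 class_weights=None, seed=0):
        self.variant = variant
        self.input_width = input_width
        self.pssm_width = pssm_width
        self.hidden_widths = hidden_widths
        self.n_classes = n_classes
        self.kernel_size = kernel_size
        self.task = task
        self.classes = classes
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weights = class_weights
        self.seed = seed

    # -- configuration ----------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant, input_width=self.input_width,
            pssm_width=self.pssm_width, hidden_widths=tuple(self.hidden_widths),
            n_classes=self.n_classes, kernel_size=self.kernel_size,
            task=self.task, classes=tuple(self.classes),
            leaky_slope=self.leaky_slope, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience,
            class_weights=None if self.class_weights is None else tuple(self.class_weights),
            seed=self.seed,
        )

    @property
    def feature_width(self) -> int:
        """Width of the per-residue feature rows ``fit``/``predict`` expect."""
        if self.variant == "base":
            return self.input_width
        return self.input_width + self.pssm_width

    @property
    def out_width(self) -> int:
        return self.n_classes if self.task == "classification" else 1

    def _init_stacks(self, rng) -> dict[str, ConvStack]:
        hw = list(self.hidden_widths)
        k, sl = self.kernel_size, self.leaky_slope
        if self.variant in ("base", "concat"):
            widths = [self.feature_width] + hw + [self.out_width]
            return {"main": ConvStack(widths, k, sl, activate_last=False, rng=rng)}
        if len(hw) < 2:
            raise ValueError("split variant needs at least two hidden widths")
        branch = hw[:2]
        trunk = [2 * branch[-1]] + hw[2:] + [self.out_width]
        return {
            "branch_emb": ConvStack([self.input_width] + branch, k, sl, True, rng),
            "branch_pssm": ConvStack([self.pssm_width] + branch, k, sl, True, rng),
            "trunk": ConvStack(trunk, k, sl, False, rng),
        }

    def n_parameters(self) -> int:
        rng = np.random.default_rng(0)
        stacks = self.stacks_ if hasattr(self, "stacks_") else self._init_stacks(rng)
        return sum(s.n_parameters() for s in stacks.values())

    # -- data packing -----------------------------------------------------

    def _check_features(self, X) -> list[np.ndarray]:
        mats = []
        for i, x in enumerate(X):
            if isinstance(x, tuple):
                x = np.concatenate([np.asarray(p) for p in x], axis=1)
            x = np.asarray(x, dtype=np.float32)
            if x.ndim != 2 or x.shape[1] != self.feature_width:
                raise ValueError(
                    f"chain {i}: feature width {x.shape[1] if x.ndim == 2 else '?'} "
                    f"!= expected {self.feature_width} for variant {self.variant!r}"
                )
            mats.append(x)
        return mats

    def _encode_targets(self, y) -> list[np.ndarray]:
        out = []
        if self.task == "classification":
            index = {c: k for k, c in enumerate(self.classes)}
            for t in y:
                if isinstance(t, LabelTrack):
                    t = t.labels
                if isinstance(t, str):
                    t = np.array([index[c] for c in t])
                out.append(np.asarray(t, dtype=np.int64))
        else:
            for t in y:
                if isinstance(t, LabelTrack):
                    t = t.scores
                out.append(np.asarray(t, dtype=np.float64))
        return out

    @staticmethod
    def _pack(mats, targets=None):
        B = len(mats)
        Lmax = max(m.shape[0] for m in mats)
        X = np.zeros((B, Lmax, mats[0].shape[1]), dtype=np.float64)
        mask = np.zeros((B, Lmax), dtype=bool)
        for i, m in enumerate(mats):
            X[i, :m.shape[0]] = m
            mask[i, :m.shape[0]] = True
        if targets is None:
            return X, mask, None
        tdtype = targets[0].dtype
        T = np.zeros((B, Lmax), dtype=tdtype)
        for i, t in enumerate(targets):
            T[i, :t.shape[0]] = t
        return X, mask, T

    # -- forward / backward ------------------------------------------------

    def _forward(self, X, mask3):
        if self.variant in ("base", "concat"):
            out, cache = self.stacks_["main"].forward(X, mask3)
            return out, {"main": cache}
        D = self.input_width
        he, ce = self.stacks_["branch_emb"].forward(X[..., :D], mask3)
        hp, cp = self.stacks_["branch_pssm"].forward(X[..., D:], mask3)
        merged = np.concatenate([he, hp], axis=2)
        out, ct = self.stacks_["trunk"].forward(merged, mask3)
        return out, {"branch_emb": ce, "branch_pssm": cp, "trunk": ct,
                     "merge_width": he.shape[2]}

    def _backward(self, dout, mask3, caches):
        if self.variant in ("base", "concat"):
            _, g = self.stacks_["main"].backward(dout, mask3, caches["main"])
            return {"main": g}
        dmerged, gt = self.stacks_["trunk"].backward(dout, mask3, caches["trunk"])
        w = caches["merge_width"]
        _, ge = self.stacks_["branch_emb"].backward(dmerged[..., :w], mask3,
                                                    caches["branch_emb"])
        _, gp = self.stacks_["branch_pssm"].backward(dmerged[..., w:], mask3,
                                                     caches["branch_pssm"])
        return {"branch_emb": ge, "branch_pssm": gp, "trunk": gt}

    def _parameters(self):
        params = []
        for name in sorted(self.stacks_):
            params.extend(self.stacks_[name].parameters())
        return params

    def _gradients(self, grads_by_stack):
        grads = []
        for name in sorted(self.stacks_):
            grads.extend(grads_by_stack[name])
        return grads

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam and early stopping on the validation monitor.

        The monitor is per-residue accuracy (Q on the declared classes) for
        classification and negative squared error for regression; without a
        validation set, negative training loss is monitored. Weights of the
        best-monitor epoch are restored. Deterministic under ``seed``.
        """
        self._config()  # validates
        mats = self._check_features(X)
        if len(mats) == 0:
            raise ValueError("empty training set")
        targets = self._encode_targets(y)
        for i, (m, t) in enumerate(zip(mats, targets)):
            if m.shape[0] != t.shape[0]:
                raise ValueError(f"chain {i}: feature/label length mismatch")
        rng = np.random.default_rng(self.seed)
        self.stacks_ = self._init_stacks(rng)
        self.classes_ = tuple(self.classes)
        opt = Adam(self._parameters(), lr=self.learning_rate)

        have_val = X_val is not None
        if have_val:
            val_mats = self._check_features(X_val)
            val_targets = self._encode_targets(y_val)

        cw = None
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, dtype=float)

        history = []
        best_monitor = -np.inf
        best_epoch = 0
        best_params = [p.copy() for p in self._parameters()]
        n = len(mats)
        bs = max(1, self.batch_size)
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            total_loss, total_w = 0.0, 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                Xb, maskb, Tb = self._pack([mats[i] for i in idx],
                                           [targets[i] for i in idx])
                mask3 = maskb[..., None].astype(np.float64)
                out, caches = self._forward(Xb, mask3)
                if self.task == "classification":
                    loss, dout = masked_softmax_xent(out, Tb, maskb, cw)
                else:
                    loss, dout = masked_mse(out, Tb, maskb)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                grads = self._gradients(self._backward(dout, mask3, caches))
                opt.step(grads)
                w = maskb.sum()
                total_loss += loss * w
                total_w += w
            epoch_loss = total_loss / total_w

            if have_val:
                monitor = self._monitor(val_mats, val_targets)
            else:
                monitor = -epoch_loss
            history.append((epoch, epoch_loss, monitor))
            if monitor > best_monitor:
                best_monitor = monitor
                best_epoch = epoch
                best_params = [p.copy() for p in self._parameters()]
            if epoch - best_epoch >= self.patience:
                break

        for p, bp in zip(self._parameters(), best_params):
            p[...] = bp
        self.history_ = pd.DataFrame(history, columns=["epoch", "loss", "val_metric"])
        self.n_epochs_ = len(history)
        self.best_epoch_ = best_epoch
        self.best_val_metric_ = best_monitor
        return self

    def _monitor(self, mats, targets) -> float:
        correct, total, sq = 0.0, 0.0, 0.0
        for m, t in zip(mats, targets):
            out = self._forward_single(m)
            if self.task == "classification":
                correct += (out.argmax(axis=1) == t).sum()
                total += t.shape[0]
            else:
                sq += ((out[:, 0] - t) ** 2).sum()
                total += t.shape[0]
        if self.task == "classification":
            return 100.0 * correct / total
        return -sq / total

    def _forward_single(self, mat: np.ndarray) -> np.ndarray:
        X = mat[None, ...].astype(np.float64)
        mask3 = np.ones((1, mat.shape[0], 1))
        out, _ = self._forward(X, mask3)
        return out[0]

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-chain (L, K) class-probability matrices (classification only)."""
        if self.task != "classification":
            raise ValueError("predict_proba is only defined for classification")
        self._require_fitted()
        return [softmax(self._forward_single(m)) for m in self._check_features(X)]

    def predict_scores(self, X) -> list[np.ndarray]:
        """Per-chain (L,) continuous scores (regression task)."""
        if self.task != "regression":
            raise ValueError("predict_scores is only defined for regression")
        self._require_fitted()
        return [self._forward_single(m)[:, 0] for m in self._check_features(X)]

    def predict(self, X) -> list:
        """Argmax labels per chain (ties break to the lowest class index),
        or raw scores for regression."""
        if self.task == "regression":
            return self.predict_scores(X)
        out = []
        for probs in self.predict_proba(X):
            out.append("".join(self.classes_[k] for k in probs.argmax(axis=1)))
        return out

    def _require_fitted(self) -> None:
        if not hasattr(self, "stacks_"):
            raise RuntimeError("model is not fitted; call fit() or load a checkpoint")

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights plus config into a single .npz container."""
        self._require_fitted()
        arrays = {}
        for name, stack in self.stacks_.items():
            for i, w in enumerate(stack.W):
                arrays[f"{name}/W{i}"] = w
            for i, b in enumerate(stack.b):
                arrays[f"{name}/b{i}"] = b
        cfg = asdict(self._config())
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ResidueConvNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            for key in ("hidden_widths", "classes"):
                cfg[key] = tuple(cfg[key])
            if cfg.get("class_weights") is not None:
                cfg["class_weights"] = tuple(cfg["class_weights"])
            model = cls(**cfg)
            model.stacks_ = model._init_stacks(np.random.default_rng(0))
            model.classes_ = tuple(model.classes)
            for name, stack in model.stacks_.items():
                for i in range(len(stack.W)):
                    stack.W[i] = data[f"{name}/W{i}"]
                    stack.b[i] = data[f"{name}/b{i}"]
        return model


@dataclass
class TrainedModel:
    """Spec-surface bundle: config, fitted estimator, training history."""

    config: ModelConfig
    estimator: ResidueConvNet
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_model(config: ModelConfig) -> ResidueConvNet:
    """Instantiate an untrained :class:`ResidueConvNet` from a config."""
    return ResidueConvNet(**asdict(config))


def train(model: ResidueConvNet, X, y, X_val=None, y_val=None) -> TrainedModel:
    """Fit ``model`` and wrap it with its config and history."""
    model.fit(X, y, X_val=X_val, y_val=y_val)
    return TrainedModel(config=model._config(), estimator=model,
                        history=model.history_)


def predict(model, X):
    """Per-chain (L, K) probabilities (or (L,) scores for regression)."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    if est.task == "regression":
        return est.predict_scores(X)
    return est.predict_proba(X)
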