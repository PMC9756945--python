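"""Three-class CNV image classifier: build, train, predict.

The classifier maps a 224x224x3 depth-profile image to probabilities over
(rare deletion, rare duplication, artifact).  Two backbones are provided on
the bundled NumPy backend:

* ``generic_cnn`` — six 3x3 convolutional layers with stride-2 downsampling,
  then global average pooling and a 3-unit softmax head;
* ``mobilenet_v1`` — the MobileNet-v1 layer pattern (stride-2 stem followed
  by depthwise-separable blocks), with a width multiplier ``alpha`` (default
  0.25) so it trains in reasonable time on a CPU.

Training follows the transfer-learning protocol: phase 1 trains only the
head with every base weight frozen; phase 2 fine-tunes the whole network
with Adam at a very low learning rate (1e-5), batches of 32, up to 20
epochs, early-stopped after 3 epochs without loss improvement.  The final
model is the epoch checkpoint with the highest selection accuracy
(validation by default; ``select_on="test"`` reproduces selection on the
held-out test split).  No pretrained weights are bundled, so models start
from seeded random initialization and :func:`train_from_scratch` offers the
matching single-phase end-to-end protocol.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import _nn
from .errors import CnvConfirmError, ConfigurationError, ValidationError
from .trio_labeling import CLASS_ORDER

INPUT_SHAPE = (224, 224, 3)


@dataclass
class ClassifierSpec:
    base_architecture: str = "mobilenet_v1"
    class_order: tuple[str, str, str] = CLASS_ORDER
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if len(self.class_order) != 3:
            raise ValidationError("class_order must have exactly 3 classes")


@dataclass
class TrainingConfig:
    batch_size: int = 32
    max_epochs: int = 20
    head_learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-5
    optimizer: str = "adam"
    early_stop_metric: str = "loss"
    early_stop_patience: int = 3
    seed: int = 0
    select_on: str = "validation"

    def __post_init__(self) -> None:
        if self.head_learning_rate <= 0 or self.finetune_learning_rate <= 0:
            raise ValidationError("learning rates must be > 0")
        if self.early_stop_patience < 1:
            raise ValidationError("patience must be >= 1")


@dataclass
class PredictionRecord:
    cnv_ref: str
    probabilities: tuple[float, float, float]
    predicted_label: str
    max_probability: float


_MOBILENET_BLOCKS = [
    # (pointwise output channels at alpha=1, stride of the depthwise conv)
    (64, 1),
    (128, 2),
    (128, 1),
    (256, 2),
    (256, 1),
    (512, 2),
    (512, 1),
    (512, 1),
    (512, 1),
    (512, 1),
    (512, 1),
    (1024, 2),
    (1024, 1),
]


class ImageClassifier:
    """A built network plus its preprocessing and class metadata."""

    def __init__(
        self,
        spec: ClassifierSpec,
        base: list[_nn.Layer],
        head: list[_nn.Layer],
        seed: int,
        pretrained: bool = False,
    ) -> None:
        self.spec = spec
        self.base = _nn.Sequential(base)
        self.head = _nn.Sequential(head)
        self.seed = seed
        self.pretrained = pretrained

    # --- parameters -----------------------------------------------------
    def base_params(self) -> list[_nn.Param]:
        return self.base.params()

    def head_params(self) -> list[_nn.Param]:
        return self.head.params()

    def params(self) -> list[_nn.Param]:
        return self.base_params() + self.head_params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    # --- compute --------------------------------------------------------
    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """8-bit RGB -> float32 in [-1, 1] (recorded in the manifest)."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValidationError(
                f"images shape {x.shape[1:]} != expected {self.spec.input_shape}"
            )
        return (x.astype(np.float32) / 127.5) - 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.base.forward(x))

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    # --- persistence ----------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(os.path.join(directory, "weights.npz"), **arrays)
        manifest = {
            "base_architecture": self.spec.base_architecture,
            "alpha": self.spec.alpha,
            "class_order": list(self.spec.class_order),
            "input_shape": list(self.spec.input_shape),
            "preprocessing": "rgb8 / 127.5 - 1 (range [-1, 1])",
            "seed": self.seed,
            "pretrained": self.pretrained,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "ImageClassifier":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        spec = ClassifierSpec(
            base_architecture=manifest["base_architecture"],
            class_order=tuple(manifest["class_order"]),
            input_shape=tuple(manifest["input_shape"]),
            alpha=manifest["alpha"],
        )
        model = build_classifier(spec, pretrained=False, seed=manifest["seed"])
        data = np.load(os.path.join(directory, "weights.npz"))
        model.set_weights([data[f"p{i}"] for i in range(len(model.params()))])
        return model


def _ch(alpha: float, c: int) -> int:
    return max(8, int(round(c * alpha)))


def build_classifier(
    spec: ClassifierSpec, pretrained: bool = False, seed: int = 0
) -> ImageClassifier:
    """Instantiate a classifier with seeded random initialization.

    ``pretrained=True`` is rejected: no pretrained weight archive is bundled
    with the package and none can be fetched at build time.
    """
    if pretrained:
        raise ConfigurationError(
            "no pretrained weights are bundled with this backend; "
            "build with pretrained=False and train with the provided protocols"
        )
    rng = np.random.default_rng(seed)
    arch = spec.base_architecture
    if arch == "generic_cnn":
        chans = [16, 32, 64, 64, 128, 128]
        strides = [2, 2, 2, 2, 2, 1]
        layers: list[_nn.Layer] = []
        c_in = 3
        for i, (c_out, s) in enumerate(zip(chans, strides)):
            layers.append(_nn.Conv2D(rng, c_in, c_out, 3, s, name=f"conv{i}"))
            layers.append(_nn.ReLU())
            c_in = c_out
        head: list[_nn.Layer] = [_nn.GlobalAvgPool(), _nn.Dense(rng, c_in, 3, "head")]
        return ImageClassifier(spec, layers, head, seed)
    if arch == "mobilenet_v1":
        a = spec.alpha
        layers = [_nn.Conv2D(rng, 3, _ch(a, 32), 3, 2, name="stem"), _nn.ReLU()]
        c_in = _ch(a, 32)
        for i, (c_out, s) in enumerate(_MOBILENET_BLOCKS):
            layers.append(_nn.DepthwiseConv2D(rng, c_in, 3, s, name=f"dw{i}"))
            layers.append(_nn.ReLU())
            layers.append(_nn.Conv2D(rng, c_in, _ch(a, c_out), 1, 1, name=f"pw{i}"))
            layers.append(_nn.ReLU())
            c_in = _ch(a, c_out)
        head = [_nn.GlobalAvgPool(), _nn.Dense(rng, c_in, 3, "head")]
        return ImageClassifier(spec, layers, head, seed)
    if arch == "resnet50":
        raise ConfigurationError(
            "the resnet50 backbone is not implemented on the bundled NumPy "
            "backend; use mobilenet_v1 or generic_cnn"
        )
    raise ConfigurationError(f"unknown architecture id {spec.base_architecture!r}")


def labels_to_indices(labels, class_order=CLASS_ORDER) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc} not in class_order") from exc


def _run_epoch(
    model: ImageClassifier,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int,
    optimizer: _nn.Adam | None,
    rng: np.random.Generator | None,
    train_base: bool,
) -> tuple[float, float]:
    """One pass over (x, y); updates weights when an optimizer is given."""
    n = x.shape[0]
    order = rng.permutation(n) if rng is not None else np.arange(n)
    total_loss, correct = 0.0, 0
    for lo in range(0, n, batch_size):
        idx = order[lo : lo + batch_size]
        xb = model.preprocess(x[idx])
        feats = model.base.forward(xb)
        logits = model.head.forward(feats)
        loss, dlogits = _nn.softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise CnvConfirmError(f"training diverged: non-finite loss {loss}")
        total_loss += loss * len(idx)
        correct += int((logits.argmax(axis=1) == y[idx]).sum())
        if optimizer is not None:
            optimizer.zero_grad()
            dfeats = model.head.backward(dlogits)
            if train_base:
                model.base.backward(dfeats)
            optimizer.step()
    return total_loss / n, correct / n


def _evaluate(model, x, y, batch_size=32) -> tuple[float, float]:
    return _run_epoch(model, x, y, batch_size, None, None, False)


def _check_classes(y: np.ndarray, class_order) -> None:
    present = set(np.unique(y).tolist())
    missing = [c for i, c in enumerate(class_order) if i not in present]
    if missing:
        raise ValidationError(f"training data missing class(es): {missing}")


def _train_phase(
    model: ImageClassifier,
    train_x,
    train_y,
    val_x,
    val_y,
    config: TrainingConfig,
    lr: float,
    train_base: bool,
    rng: np.random.Generator,
    select_x,
    select_y,
    best: dict,
    phase_name: str,
) -> list[dict]:
    params = model.params() if train_base else model.head_params()
    optimizer = _nn.Adam(params, lr=lr)
    history: list[dict] = []
    best_loss, stale = np.inf, 0
    for epoch in range(config.max_epochs):
        loss, acc = _run_epoch(
            model, train_x, train_y, config.batch_size, optimizer, rng, train_base
        )
        record = {"phase": phase_name, "epoch": epoch, "loss": loss, "accuracy": acc}
        if val_x is not None and len(val_x):
            val_loss, val_acc = _evaluate(model, val_x, val_y, config.batch_size)
            record.update(val_loss=val_loss, val_accuracy=val_acc)
        # "loss" monitors the training loss (the conventional Keras meaning);
        # "val_loss" switches early stopping to the validation loss
        monitored = record.get(config.early_stop_metric, loss)
        if select_x is not None and len(select_x):
            sel_loss, sel_acc = (
                (record["val_loss"], record["val_accuracy"])
                if select_x is val_x
                else _evaluate(model, select_x, select_y, config.batch_size)
            )
        else:
            sel_loss, sel_acc = loss, acc
        if sel_acc > best["accuracy"]:
            best.update(accuracy=sel_acc, weights=model.get_weights())
        history.append(record)
        if monitored < best_loss - 1e-9:
            best_loss, stale = monitored, 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    return history


def _train(
    model: ImageClassifier,
    train_x,
    train_y,
    val_x,
    val_y,
    config: TrainingConfig,
    phases: list[tuple[str, float, bool]],
    test_x=None,
    test_y=None,
) -> dict:
    train_y = np.asarray(train_y)
    _check_classes(train_y, model.spec.class_order)
    rng = np.random.default_rng(config.seed)
    if config.select_on == "test":
        if test_x is None:
            raise ValidationError('select_on="test" requires test data')
        select_x, select_y = test_x, np.asarray(test_y)
    elif val_x is not None and len(val_x):
        select_x, select_y = val_x, np.asarray(val_y)
    else:
        select_x = select_y = None
    best = {"accuracy": -1.0, "weights": model.get_weights()}
    history: dict = {}
    for name, lr, train_base in phases:
        history[name] = _train_phase(
            model,
            train_x,
            train_y,
            val_x,
            np.asarray(val_y) if val_y is not None else None,
            config,
            lr,
            train_base,
            rng,
            select_x,
            select_y,
            best,
            name,
        )
    model.set_weights(best["weights"])
    return history


def train_transfer(
    model: ImageClassifier,
    train_x,
    train_y,
    val_x=None,
    val_y=None,
    config: TrainingConfig | None = None,
    test_x=None,
    test_y=None,
    run_phases: tuple[str, ...] = ("phase1", "phase2"),
) -> dict:
    """Two-phase transfer protocol.

    Phase 1 trains the head only (base frozen, ``head_learning_rate``);
    phase 2 fine-tunes everything at ``finetune_learning_rate`` with a fresh
    Adam optimizer.  Each phase early-stops on the monitored loss with the
    configured patience.  Returns ``{"phase1": [...], "phase2": [...]}`` with
    per-epoch loss/accuracy records; the model is left at the checkpoint with
    the best selection accuracy.  ``run_phases`` restricts the protocol, e.g.
    to head-only training.
    """
    config = config or TrainingConfig()
    all_phases = [
        ("phase1", config.head_learning_rate, False),
        ("phase2", config.finetune_learning_rate, True),
    ]
    phases = [p for p in all_phases if p[0] in run_phases]
    return _train(model, train_x, train_y, val_x, val_y, config, phases, test_x, test_y)


def train_from_scratch(
    model: ImageClassifier,
    train_x,
    train_y,
    val_x=None,
    val_y=None,
    config: TrainingConfig | None = None,
    test_x=None,
    test_y=None,
) -> dict:
    """Single-phase end-to-end training for randomly initialized networks.

    With no pretrained base there is nothing to protect with a frozen phase
    or a reduced fine-tuning rate; the whole network trains at
    ``head_learning_rate`` under the same batch size, epoch budget, early
    stopping and checkpoint selection as the transfer protocol.
    """
    config = config or TrainingConfig()
    phases = [("phase1", config.head_learning_rate, True)]
    return _train(model, train_x, train_y, val_x, val_y, config, phases, test_x, test_y)


def predict_proba(model: ImageClassifier, images, cnv_refs=None) -> list[PredictionRecord]:
    """Softmax probabilities and argmax labels, one record per image in order.

    Ties take the earliest class in ``class_order`` (argmax returns the first
    maximum).
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != model.spec.input_shape:
        raise ValidationError(f"images shape {x.shape[1:]} != {model.spec.input_shape}")
    refs = list(cnv_refs) if cnv_refs is not None else [str(i) for i in range(len(x))]
    if len(refs) != len(x):
        raise ValidationError("cnv_refs length mismatch")
    records: list[PredictionRecord] = []
    for lo in range(0, len(x), 32):
        logits = model.forward(model.preprocess(x[lo : lo + 32]))
        probs = _nn.softmax(logits.astype(np.float64))
        for ref, p in zip(refs[lo : lo + 32], probs):
            j = int(np.argmax(p))
            records.append(
                PredictionRecord(
                    cnv_ref=ref,
                    probabilities=tuple(float(v) for v in p),
                    predicted_label=model.spec.class_order[j],
                    max_probability=float(p[j]),
                )
            )
    return records
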