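"""BiLSTM sequence regression of GRF curves from pressure-region inputs.

The network maps, for every stance, a [101 x C] input sequence to the
[101 x 2] GRF output (vertical and A/P, in BW).  The reference
architecture is a sequence input over eight predictors (five pressure
regions, body mass, speed, slope), a 400-node BiLSTM, 30 % dropout, a
200-node BiLSTM, 20 % dropout, fully connected layers of 300 and 150
nodes with hyperbolic-tangent activations, and a linear 2-node output.
A 6-channel variant omits the speed and slope predictors.  A reduced
(32/16 BiLSTM, 48/24 FC) spec is provided for CPU-scale experiments.

Inputs are Z-score normalized with statistics computed on the training
split only; training uses Adam on the mean squared error, with shuffled
sequences, an internal validation split and early stopping.  Subject-
specific fine-tuning continues training a generic model on a small
fraction of the target subject's steps at a reduced learning rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import N_NODES, StepDataset
from .nn import Adam, BiLSTMLayer, DenseLayer, DropoutLayer, Network, mse_loss

__all__ = [
    "RNNSpec",
    "NormStats",
    "TrainOptions",
    "GRFNet",
    "build_rnn",
    "features_from_steps",
    "targets_from_steps",
    "compute_norm_stats",
    "apply_norm",
    "train_rnn",
    "predict_rnn",
    "finetune_subject",
]

FEATURE_NAMES_8 = ["pr1", "pr2", "pr3", "pr4", "pr5", "mass", "speed", "slope"]
FEATURE_NAMES_6 = FEATURE_NAMES_8[:6]


@dataclass(frozen=True)
class RNNSpec:
    """Architecture hyperparameters."""

    input_channels: int = 8
    bilstm_nodes: tuple[int, int] = (400, 200)
    dropout: tuple[float, float] = (0.30, 0.20)
    fc_nodes: tuple[int, int] = (300, 150)
    output_nodes: int = 2

    def __post_init__(self) -> None:
        if self.input_channels not in (6, 8):
            raise ValueError("input_channels must be 6 or 8")
        if any(n < 1 for n in self.bilstm_nodes + self.fc_nodes) or self.output_nodes < 1:
            raise ValueError("node counts must be positive")
        if any(not 0.0 <= p < 1.0 for p in self.dropout):
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def reduced(
        cls, input_channels: int = 8, dropout: tuple[float, float] = (0.10, 0.10)
    ) -> "RNNSpec":
        """Desk-scale spec for CPU experiments.

        Node counts are scaled down ~12x; dropout is lightened accordingly
        (small networks on desk-scale cohorts need less regularization).
        """
        return cls(
            input_channels=input_channels,
            bilstm_nodes=(32, 16),
            dropout=dropout,
            fc_nodes=(48, 24),
        )


@dataclass
class NormStats:
    """Per-channel Z-score statistics, training split only."""

    mean: np.ndarray
    std: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.mean)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float))


@dataclass(frozen=True)
class TrainOptions:
    """Optimization settings (Adam throughout)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    shuffle_seed: int = 0
    patience: int = 5
    val_fraction: float = 0.1
    finetune_lr: float = 3e-4
    finetune_epochs: int = 30
    init_output_bias: bool = True  # start the linear head at the target mean

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class GRFNet:
    """A built (possibly trained) sequence regressor plus its spec."""

    def __init__(self, spec: RNNSpec, net: Network, seed: int):
        self.spec = spec
        self.net = net
        self.seed = seed

    def clone(self) -> "GRFNet":
        fresh = build_rnn(self.spec, self.seed)
        fresh.net.set_weights(self.net.get_weights())
        return fresh

    def forward(
        self, x: np.ndarray, train: bool = False, rng=None
    ) -> np.ndarray:
        """x: [N x T x C] -> [N x T x 2]."""
        y = self.net.forward(x.transpose(1, 0, 2), train=train, rng=rng)
        return y.transpose(1, 0, 2)

    def save(self, path_prefix: str) -> None:
        """Weights as .npz plus a JSON sidecar with the spec and seed."""
        np.savez(
            path_prefix + ".npz",
            **{f"w{i}": w for i, w in enumerate(self.net.get_weights())},
        )
        with open(path_prefix + ".json", "w") as fh:
            json.dump(
                {
                    "input_channels": self.spec.input_channels,
                    "bilstm_nodes": list(self.spec.bilstm_nodes),
                    "dropout": list(self.spec.dropout),
                    "fc_nodes": list(self.spec.fc_nodes),
                    "output_nodes": self.spec.output_nodes,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path_prefix: str) -> "GRFNet":
        with open(path_prefix + ".json") as fh:
            d = json.load(fh)
        spec = RNNSpec(
            input_channels=d["input_channels"],
            bilstm_nodes=tuple(d["bilstm_nodes"]),
            dropout=tuple(d["dropout"]),
            fc_nodes=tuple(d["fc_nodes"]),
            output_nodes=d["output_nodes"],
        )
        model = build_rnn(spec, d["seed"])
        data = np.load(path_prefix + ".npz")
        model.net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return model


def build_rnn(spec: RNNSpec, seed: int = 0) -> GRFNet:
    """Assemble an untrained network; identical seeds give identical weights."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    h1, h2 = spec.bilstm_nodes
    f1, f2 = spec.fc_nodes
    layers = [
        BiLSTMLayer(spec.input_channels, h1, rng),
        DropoutLayer(spec.dropout[0]),
        BiLSTMLayer(2 * h1, h2, rng),
        DropoutLayer(spec.dropout[1]),
        DenseLayer(2 * h2, f1, rng, tanh=True),
        DenseLayer(f1, f2, rng, tanh=True),
        DenseLayer(f2, spec.output_nodes, rng, tanh=False),
    ]
    return GRFNet(spec, Network(layers), seed)


# ---------------------------------------------------------------------------
# features and normalization


def features_from_steps(
    dataset: StepDataset, include_speed_slope: bool = True
) -> np.ndarray:
    """Input sequences [N x 101 x C]; mass/speed/slope replicated per node."""
    n = len(dataset)
    c = 8 if include_speed_slope else 6
    X = np.empty((n, N_NODES, c))
    for i, s in enumerate(dataset):
        if s.mass is None:
            raise ValueError(f"step {i} has no subject mass; cannot build features")
        X[i, :, :5] = s.pr.T
        X[i, :, 5] = s.mass
        if include_speed_slope:
            X[i, :, 6] = s.condition.speed
            X[i, :, 7] = s.condition.slope
    return X


def targets_from_steps(dataset: StepDataset) -> np.ndarray:
    """Target sequences [N x 101 x 2] in BW."""
    n = len(dataset)
    Y = np.empty((n, N_NODES, 2))
    for i, s in enumerate(dataset):
        Y[i, :, 0] = s.grf_vert
        Y[i, :, 1] = s.grf_ap
    return Y


def compute_norm_stats(X: np.ndarray) -> NormStats:
    """Channel means and SDs over all nodes of all training sequences.

    Constant channels get unit SD with a warning rather than dividing by
    zero (a mass channel is constant whenever training data hold a single
    subject).
    """
    if X.size == 0:
        raise ValueError("empty training set")
    mean = X.mean(axis=(0, 1))
    std = X.std(axis=(0, 1))
    if np.any(std < 1e-12):
        warnings.warn(
            "constant input channel(s); using unit SD for Z-scoring",
            RuntimeWarning,
            stacklevel=2,
        )
        std = np.where(std < 1e-12, 1.0, std)
    return NormStats(mean=mean, std=std)


def apply_norm(stats: NormStats, X: np.ndarray) -> np.ndarray:
    if X.shape[-1] != stats.n_channels:
        raise ValueError(
            f"channel mismatch: data has {X.shape[-1]}, stats have {stats.n_channels}"
        )
    return (X - stats.mean) / stats.std


# ---------------------------------------------------------------------------
# training


def train_rnn(
    model: GRFNet,
    X: np.ndarray,
    Y: np.ndarray,
    stats: NormStats,
    options: TrainOptions = TrainOptions(),
) -> dict:
    """Train in place on normalized sequences; returns the loss history.

    ``X`` is raw [N x T x C] (normalization is applied here with the
    supplied training-split stats), ``Y`` the BW targets [N x T x 2].
    Minimizes MSE over both components and all nodes.  Sequences are
    shuffled each epoch; an internal validation split drives early
    stopping; the best-validation weights are restored.  Divergence
    (non-finite loss) aborts with diagnostics.
    """
    if X.shape[-1] != model.spec.input_channels:
        raise ValueError(
            f"network expects {model.spec.input_channels} channels, got {X.shape[-1]}"
        )
    Xn = apply_norm(stats, X)
    if options.init_output_bias and not np.any(model.net.layers[-1].b):
        # initializing the output bias at the training-target mean removes
        # the epochs Adam would spend learning the DC level of the curves
        model.net.layers[-1].b[:] = Y.mean(axis=(0, 1))
    rng = np.random.default_rng(np.random.SeedSequence([options.shuffle_seed, 0x7E]))
    n = Xn.shape[0]
    n_val = int(round(options.val_fraction * n)) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = Xn[train_idx], Y[train_idx]
    Xv, Yv = Xn[val_idx], Y[val_idx]

    opt = Adam(model.net, lr=options.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = model.net.get_weights()
    bad_epochs = 0
    for epoch in range(options.max_epochs):
        order = rng.permutation(len(Xt))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(Xt), options.batch_size):
            idx = order[start : start + options.batch_size]
            xb = Xt[idx].transpose(1, 0, 2)
            yb = Yt[idx].transpose(1, 0, 2)
            model.net.zero_grad()
            pred = model.net.forward(xb, train=True, rng=rng)
            loss, grad = mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}, "
                    f"lr={options.learning_rate}"
                )
            model.net.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if n_val:
            pred_v = model.forward(Xv, train=False)
            val_loss, _ = mse_loss(pred_v, Yv)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = model.net.get_weights()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > options.patience:
                    break
    if n_val and best_val < np.inf:
        model.net.set_weights(best_weights)
    return history


def predict_rnn(model: GRFNet, stats: NormStats, X: np.ndarray) -> np.ndarray:
    """Deterministic inference (dropout inactive) -> [N x 2 x 101] in BW."""
    if X.shape[-1] != model.spec.input_channels:
        raise ValueError(
            f"network expects {model.spec.input_channels} channels, got {X.shape[-1]}"
        )
    pred = model.forward(apply_norm(stats, X), train=False)
    return pred.transpose(0, 2, 1)


def finetune_subject(
    generic: GRFNet,
    stats: NormStats,
    X_subject: np.ndarray,
    Y_subject: np.ndarray,
    condition_keys: list[str],
    fraction: float = 0.10,
    options: TrainOptions = TrainOptions(),
    seed: int = 0,
) -> tuple[GRFNet, np.ndarray, np.ndarray]:
    """Subject-specific model from ~10 % of the target subject's steps.

    Samples the fine-tuning steps without replacement, stratified by
    condition, and continues training the generic network on them at the
    reduced fine-tuning learning rate.  Returns the tuned network, the
    fine-tuning indices and the disjoint held-out indices (evaluation must
    use only the latter).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = X_subject.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    keys = np.asarray(condition_keys)
    tune_idx: list[int] = []
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        k = max(1, int(round(fraction * len(idx))))
        tune_idx.extend(rng.choice(idx, size=k, replace=False).tolist())
    tune_idx = np.sort(np.asarray(tune_idx, dtype=int))
    if tune_idx.size < 1:
        raise ValueError("fraction yields no fine-tuning steps")
    holdout_idx = np.setdiff1d(np.arange(n), tune_idx)

    tuned = generic.clone()
    ft_options = replace(
        options,
        learning_rate=options.finetune_lr,
        max_epochs=options.finetune_epochs,
        val_fraction=0.0,
        shuffle_seed=seed,
    )
    train_rnn(tuned, X_subject[tune_idx], Y_subject[tune_idx], stats, ft_options)
    return tuned, tune_idx, holdout_idx
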