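"""Per-pathway multi-modal sparse denoising autoencoders.

For one pathway, k omics modalities contribute feature blocks x_1..x_k for
the same n patients.  The network encodes each modality separately into at
most floor(p_j/2) first-hidden units (no cross-modality connections), then
compresses all first-hidden units into a single shared bottleneck unit —
the per-patient pathway score — and decodes through a laterally reversed
architecture.  All activations are tanh; hidden pre-activations are batch
normalized; inputs are per-feature standardized (z-scores of the training
set), which puts modalities with different native ranges on one loss scale.

Training minimizes

    F(W) = 1/2 sigma(W) + penalty(W)

where sigma(W) is the mean over patients of the summed per-modality squared
reconstruction errors (standardized scale) and penalty(W) is a sparse group
lasso: a group term over the k modality-specific input weight blocks
(weighted by sqrt(s_l * s_lsucc)) selecting whole omics modalities, plus an
l1 term over all weight matrices selecting individual features.  Denoising
corrupts each mini-batch by dropping input features with retention
probability p (targets stay clean).  Everything — forward, backward, the
four stochastic-gradient optimizers, early stopping — is implemented
directly on numpy arrays so analytic gradients are exact and checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "AutoencoderArchitecture",
    "AutoencoderModel",
    "TrainingConfig",
    "TrainedPathwayModel",
    "PathwayScoreMatrix",
    "encode_decode",
    "reconstruction_loss",
    "sgl_penalty",
    "objective",
    "train",
    "tune",
    "score_patients",
    "assemble_score_matrix",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
OPTIMIZERS = ("momentum", "rmsprop", "adam", "nadam")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderArchitecture:
    """Layer sizes of one pathway model.

    ``input_sizes`` are the per-modality feature counts p_j; ``hidden_sizes``
    the per-modality first-hidden widths h_j with 1 <= h_j <= max(1,
    floor(p_j/2)).  The bottleneck always has exactly one unit and the
    decoder mirrors the encoder.
    """

    input_sizes: list[int]
    hidden_sizes: list[int]
    modalities: list[str] | None = None
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if len(self.input_sizes) != len(self.hidden_sizes):
            raise ValueError("input_sizes and hidden_sizes length mismatch")
        if not self.input_sizes:
            raise ValueError("need at least one modality")
        for p_j, h_j in zip(self.input_sizes, self.hidden_sizes):
            if p_j < 1:
                raise ValueError("modality with no features")
            if not 1 <= h_j <= max(1, p_j // 2):
                raise ValueError(
                    f"hidden size {h_j} outside [1, max(1, {p_j}//2)] for p_j={p_j}"
                )
        if self.modalities is None:
            self.modalities = [f"modality_{j}" for j in range(len(self.input_sizes))]

    @property
    def k(self) -> int:
        return len(self.input_sizes)

    @property
    def total_inputs(self) -> int:
        return sum(self.input_sizes)

    @property
    def total_hidden(self) -> int:
        return sum(self.hidden_sizes)

    def input_slices(self) -> list[slice]:
        out, start = [], 0
        for p in self.input_sizes:
            out.append(slice(start, start + p))
            start += p
        return out

    def hidden_slices(self) -> list[slice]:
        out, start = [], 0
        for h in self.hidden_sizes:
            out.append(slice(start, start + h))
            start += h
        return out

    @staticmethod
    def max_hidden(p_j: int) -> int:
        return max(1, p_j // 2)


@dataclass
class TrainingConfig:
    """Hyper-parameters of one training run (ranges are enforced)."""

    mini_batch_size: int = 16
    lam: float = 1e-4          # sparse-group-lasso weight decay λ
    alpha: float = 0.5         # lasso / group-lasso mix α
    learning_rate: float = 1e-2
    retention_p: float = 0.9   # input keep probability (denoising)
    optimizer: str = "adam"
    patience: int = 20
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mini_batch_size not in (4, 8, 16, 32):
            raise ValueError("mini_batch_size must be in {4, 8, 16, 32}")
        if self.lam < 0:
            # [1e-9, 1e-1] is the hyper-parameter *search* range (see tune);
            # explicit configs may use any non-negative weight decay, and
            # lam=0 switches the penalty off entirely.
            raise ValueError("lam must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 1e-5 <= self.learning_rate <= 1e-1:
            raise ValueError("learning_rate must be in [1e-5, 1e-1]")
        if not 0.5 <= self.retention_p <= 1.0:
            raise ValueError("retention_p must be in [0.5, 1]")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _init_params(arch: AutoencoderArchitecture, rng: np.random.Generator) -> dict:
    """Symmetric uniform fan-in initialization of all weights/biases/BN."""
    params: dict[str, np.ndarray] = {}

    def u(fan_in, shape):
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-bound, bound, size=shape)

    H = arch.total_hidden
    for j, (p, h) in enumerate(zip(arch.input_sizes, arch.hidden_sizes)):
        params[f"W_enc1_{j}"] = u(p, (p, h))
        params[f"b_enc1_{j}"] = np.zeros(h)
        params[f"W_dec2_{j}"] = u(h, (h, p))
        params[f"b_dec2_{j}"] = np.zeros(p)
    params["W_enc2"] = u(H, (H, 1))
    params["b_enc2"] = np.zeros(1)
    params["W_dec1"] = u(1, (1, H))
    params["b_dec1"] = np.zeros(H)
    if arch.batchnorm:
        for name, size in (("bn_enc1", H), ("bn_enc2", 1), ("bn_dec1", H)):
            params[f"{name}_gamma"] = np.ones(size)
            params[f"{name}_beta"] = np.zeros(size)
    return params


def _weight_names(arch: AutoencoderArchitecture) -> list[str]:
    names = [f"W_enc1_{j}" for j in range(arch.k)]
    names += ["W_enc2", "W_dec1"]
    names += [f"W_dec2_{j}" for j in range(arch.k)]
    return names


@dataclass
class AutoencoderModel:
    """Weights, batch-norm state and standardization statistics."""

    arch: AutoencoderArchitecture
    params: dict
    running_mean: dict = field(default_factory=dict)
    running_var: dict = field(default_factory=dict)
    feature_mean: np.ndarray | None = None  # concatenated, len = total_inputs
    feature_sd: np.ndarray | None = None
    feature_names: list[str] | None = None

    @classmethod
    def initialize(cls, arch: AutoencoderArchitecture, seed: int = 0) -> "AutoencoderModel":
        rng = np.random.default_rng(seed)
        model = cls(arch, _init_params(arch, rng))
        if arch.batchnorm:
            H = arch.total_hidden
            for name, size in (("bn_enc1", H), ("bn_enc2", 1), ("bn_dec1", H)):
                model.running_mean[name] = np.zeros(size)
                model.running_var[name] = np.ones(size)
        model.feature_mean = np.zeros(arch.total_inputs)
        model.feature_sd = np.ones(arch.total_inputs)
        return model

    # -- persistence (small models: JSON with array payloads) ---------------

    def save(self, path) -> None:
        blob = {
            "arch": {
                "input_sizes": self.arch.input_sizes,
                "hidden_sizes": self.arch.hidden_sizes,
                "modalities": self.arch.modalities,
                "batchnorm": self.arch.batchnorm,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running_mean": {k: v.tolist() for k, v in self.running_mean.items()},
            "running_var": {k: v.tolist() for k, v in self.running_var.items()},
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "feature_names": self.feature_names,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "AutoencoderModel":
        with open(path) as fh:
            blob = json.load(fh)
        arch = AutoencoderArchitecture(**blob["arch"])
        model = cls(
            arch,
            {k: np.asarray(v, dtype=float) for k, v in blob["params"].items()},
            {k: np.asarray(v, dtype=float) for k, v in blob["running_mean"].items()},
            {k: np.asarray(v, dtype=float) for k, v in blob["running_var"].items()},
            np.asarray(blob["feature_mean"], dtype=float),
            np.asarray(blob["feature_sd"], dtype=float),
            blob.get("feature_names"),
        )
        return model

    # -- standardization ----------------------------------------------------

    def fit_standardization(self, X: np.ndarray) -> None:
        self.feature_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.feature_sd = sd

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_sd

    def destandardize(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.feature_sd + self.feature_mean


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _bn_forward(z, gamma, beta, running_mean, running_var, name, training,
                update_running, cache):
    if training:
        mu = z.mean(axis=0)
        var = z.var(axis=0)
        if update_running:
            running_mean[name] = (_BN_MOMENTUM * running_mean[name]
                                  + (1 - _BN_MOMENTUM) * mu)
            running_var[name] = (_BN_MOMENTUM * running_var[name]
                                 + (1 - _BN_MOMENTUM) * var)
    else:
        mu = running_mean[name]
        var = running_var[name]
    inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
    zhat = (z - mu) * inv_sd
    cache[name] = (zhat, inv_sd, gamma, training)
    return gamma * zhat + beta


def _bn_backward(dout, name, cache):
    zhat, inv_sd, gamma, training = cache[name]
    dgamma = (dout * zhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    if not training:
        dz = dout * gamma * inv_sd
        return dz, dgamma, dbeta
    N = zhat.shape[0]
    dzh = dout * gamma
    dz = inv_sd * (dzh - dzh.mean(axis=0) - zhat * (dzh * zhat).mean(axis=0))
    if N == 1:  # degenerate batch: batch stats make the map constant
        dz = np.zeros_like(dz)
    return dz, dgamma, dbeta


def _forward(model: AutoencoderModel, Xs: np.ndarray, training: bool,
             update_running: bool = False):
    """Forward pass on standardized (and possibly corrupted) inputs.

    Returns (score column vector, standardized reconstruction, cache).
    """
    arch, P = model.arch, model.params
    cache: dict = {"X": Xs}
    bn = arch.batchnorm

    z1 = np.concatenate(
        [Xs[:, sl] @ P[f"W_enc1_{j}"] + P[f"b_enc1_{j}"]
         for j, sl in enumerate(arch.input_slices())], axis=1)
    u1 = (_bn_forward(z1, P["bn_enc1_gamma"], P["bn_enc1_beta"],
                      model.running_mean, model.running_var, "bn_enc1",
                      training, update_running, cache) if bn else z1)
    a1 = np.tanh(u1)

    z2 = a1 @ P["W_enc2"] + P["b_enc2"]
    u2 = (_bn_forward(z2, P["bn_enc2_gamma"], P["bn_enc2_beta"],
                      model.running_mean, model.running_var, "bn_enc2",
                      training, update_running, cache) if bn else z2)
    score = np.tanh(u2)

    z3 = score @ P["W_dec1"] + P["b_dec1"]
    u3 = (_bn_forward(z3, P["bn_dec1_gamma"], P["bn_dec1_beta"],
                      model.running_mean, model.running_var, "bn_dec1",
                      training, update_running, cache) if bn else z3)
    a3 = np.tanh(u3)

    hs = arch.hidden_slices()
    out = np.concatenate(
        [np.tanh(a3[:, hs[j]] @ P[f"W_dec2_{j}"] + P[f"b_dec2_{j}"])
         for j in range(arch.k)], axis=1)

    cache.update(a1=a1, score=score, a3=a3, out=out)
    return score, out, cache


def _backward(model: AutoencoderModel, cache: dict, dout: np.ndarray) -> dict:
    """Backpropagate d(loss)/d(out) to all parameters."""
    arch, P = model.arch, model.params
    bn = arch.batchnorm
    grads: dict[str, np.ndarray] = {}
    Xs, a1, score, a3, out = (cache[k] for k in ("X", "a1", "score", "a3", "out"))
    hs, isl = arch.hidden_slices(), arch.input_slices()

    da3 = np.zeros_like(a3)
    for j in range(arch.k):
        dz_out = dout[:, isl[j]] * (1 - out[:, isl[j]] ** 2)
        grads[f"W_dec2_{j}"] = a3[:, hs[j]].T @ dz_out
        grads[f"b_dec2_{j}"] = dz_out.sum(axis=0)
        da3[:, hs[j]] = dz_out @ P[f"W_dec2_{j}"].T

    du3 = da3 * (1 - a3 ** 2)
    if bn:
        dz3, grads["bn_dec1_gamma"], grads["bn_dec1_beta"] = \
            _bn_backward(du3, "bn_dec1", cache)
    else:
        dz3 = du3
    grads["W_dec1"] = score.T @ dz3
    grads["b_dec1"] = dz3.sum(axis=0)
    dscore = dz3 @ P["W_dec1"].T

    du2 = dscore * (1 - score ** 2)
    if bn:
        dz2, grads["bn_enc2_gamma"], grads["bn_enc2_beta"] = \
            _bn_backward(du2, "bn_enc2", cache)
    else:
        dz2 = du2
    grads["W_enc2"] = a1.T @ dz2
    grads["b_enc2"] = dz2.sum(axis=0)
    da1 = dz2 @ P["W_enc2"].T

    du1 = da1 * (1 - a1 ** 2)
    if bn:
        dz1, grads["bn_enc1_gamma"], grads["bn_enc1_beta"] = \
            _bn_backward(du1, "bn_enc1", cache)
    else:
        dz1 = du1
    for j, sl in enumerate(isl):
        grads[f"W_enc1_{j}"] = Xs[:, sl].T @ dz1[:, hs[j]]
        grads[f"b_enc1_{j}"] = dz1[:, hs[j]].sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def encode_decode(model: AutoencoderModel, x: np.ndarray):
    """Evaluation-mode forward pass of raw-unit input(s).

    Returns (pathway score(s) in (-1, 1), reconstruction in original units).
    Accepts a single concatenated feature vector or a patients x features
    matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.arch.total_inputs:
        raise ValueError(
            f"expected {model.arch.total_inputs} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    score, out, _ = _forward(model, model.standardize(X), training=False)
    recon = model.destandardize(out)
    if single:
        return float(score[0, 0]), recon[0]
    return score[:, 0], recon


def reconstruction_loss(model: AutoencoderModel, X: np.ndarray) -> float:
    """sigma(W): mean over patients of the total squared reconstruction
    error across modalities, on the standardized scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    Xs = model.standardize(X)
    _, out, _ = _forward(model, Xs, training=False)
    return float(((out - Xs) ** 2).sum() / X.shape[0])


def sgl_penalty(model: AutoencoderModel, lam: float, alpha: float) -> float:
    """Sparse-group-lasso penalty of the current weights.

    (lam/2) * [ (1-alpha) * sum_j sqrt(p_j*h_j) * sum (W_enc1_j)^2
                + alpha * sum over all weight matrices of |W| ].
    The group term runs over the k modality input blocks only; biases and
    batch-norm parameters are unpenalized.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    arch, P = model.arch, model.params
    group = sum(
        np.sqrt(p * h) * float((P[f"W_enc1_{j}"] ** 2).sum())
        for j, (p, h) in enumerate(zip(arch.input_sizes, arch.hidden_sizes))
    )
    l1 = sum(float(np.abs(P[name]).sum()) for name in _weight_names(arch))
    return (lam / 2.0) * ((1 - alpha) * group + alpha * l1)


def _penalty_grads(model: AutoencoderModel, lam: float, alpha: float) -> dict:
    arch, P = model.arch, model.params
    grads: dict[str, np.ndarray] = {}
    for name in _weight_names(arch):
        grads[name] = (lam / 2.0) * alpha * np.sign(P[name])
    for j, (p, h) in enumerate(zip(arch.input_sizes, arch.hidden_sizes)):
        grads[f"W_enc1_{j}"] = grads[f"W_enc1_{j}"] + \
            lam * (1 - alpha) * np.sqrt(p * h) * P[f"W_enc1_{j}"]
    return grads


def objective(model: AutoencoderModel, X: np.ndarray, lam: float,
              alpha: float, training: bool = False,
              Xs_corrupted: np.ndarray | None = None) -> float:
    """F(W) = 1/2 sigma(W) + sparse-group-lasso penalty.

    With ``training=True`` the forward pass uses batch statistics of the
    given data (deterministic, no running-stat update), which is the
    function the analytic gradients differentiate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = model.standardize(X)
    inp = Xs if Xs_corrupted is None else Xs_corrupted
    _, out, _ = _forward(model, inp, training=training)
    sigma = float(((out - Xs) ** 2).sum() / X.shape[0])
    return 0.5 * sigma + sgl_penalty(model, lam, alpha)


def objective_grads(model: AutoencoderModel, X: np.ndarray, lam: float,
                    alpha: float, training: bool = True,
                    Xs_corrupted: np.ndarray | None = None) -> dict:
    """Analytic gradients of F(W) w.r.t. every parameter."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = model.standardize(X)
    inp = Xs if Xs_corrupted is None else Xs_corrupted
    _, out, cache = _forward(model, inp, training=training)
    dout = (out - Xs) / X.shape[0]  # d(1/2 sigma)/d out
    grads = _backward(model, cache, dout)
    if lam > 0:
        for name, g in _penalty_grads(model, lam, alpha).items():
            grads[name] = grads[name] + g
    return grads


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, kind: str, lr: float):
        self.kind = kind
        self.lr = lr
        self.state: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr, t = self.lr, self.t
        for name, g in grads.items():
            st = self.state.get(name)
            if st is None:
                st = self.state[name] = {"m": np.zeros_like(g),
                                         "v": np.zeros_like(g)}
            if self.kind == "momentum":
                st["m"] = 0.9 * st["m"] - lr * g
                params[name] = params[name] + st["m"]
            elif self.kind == "rmsprop":
                st["v"] = 0.9 * st["v"] + 0.1 * g ** 2
                params[name] = params[name] - lr * g / (np.sqrt(st["v"]) + 1e-8)
            elif self.kind == "adam":
                st["m"] = 0.9 * st["m"] + 0.1 * g
                st["v"] = 0.999 * st["v"] + 0.001 * g ** 2
                mhat = st["m"] / (1 - 0.9 ** t)
                vhat = st["v"] / (1 - 0.999 ** t)
                params[name] = params[name] - lr * mhat / (np.sqrt(vhat) + 1e-8)
            elif self.kind == "nadam":
                st["m"] = 0.9 * st["m"] + 0.1 * g
                st["v"] = 0.999 * st["v"] + 0.001 * g ** 2
                mhat = st["m"] / (1 - 0.9 ** (t + 1))
                vhat = st["v"] / (1 - 0.999 ** t)
                nesterov = 0.9 * mhat + 0.1 * g / (1 - 0.9 ** t)
                params[name] = params[name] - lr * nesterov / (np.sqrt(vhat) + 1e-8)
            else:  # pragma: no cover
                raise ValueError(self.kind)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedPathwayModel:
    model: AutoencoderModel
    loss_trace: list[float]
    config: TrainingConfig
    cv_errors: list[float] | None = None
    pathway_id: str | None = None
    stopped_early: bool = False


def train(
    X: np.ndarray,
    arch: AutoencoderArchitecture,
    cfg: TrainingConfig,
    feature_names: list[str] | None = None,
) -> TrainedPathwayModel:
    """Train a multi-modal sparse denoising autoencoder on a patients x
    features matrix (columns concatenated in modality order).

    Mini-batch inputs are corrupted by independent feature dropout with
    retention probability ``cfg.retention_p`` while reconstruction targets
    stay clean.  The monitored quantity is the full-data objective F(W);
    training stops after ``cfg.patience`` epochs without a relative
    improvement of at least 1e-6, restoring the best parameters seen.
    Deterministic given ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if X.shape[1] != arch.total_inputs:
        raise ValueError("data width does not match architecture inputs")

    rng = np.random.default_rng(cfg.seed)
    model = AutoencoderModel.initialize(arch, seed=int(rng.integers(2 ** 31)))
    model.feature_names = feature_names
    model.fit_standardization(X)
    Xs = model.standardize(X)

    opt = _Optimizer(cfg.optimizer, cfg.learning_rate)
    batch = min(cfg.mini_batch_size, n)

    trace: list[float] = []
    best_obj = np.inf
    best_params: dict | None = None
    best_running: tuple | None = None
    since_improve = 0
    stopped_early = False

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb = Xs[idx]
            if cfg.retention_p < 1.0:
                mask = rng.random(Xb.shape) < cfg.retention_p
                Xin = Xb * mask
            else:
                Xin = Xb
            _, out, cache = _forward(model, Xin, training=True,
                                     update_running=True)
            dout = (out - Xb) / Xb.shape[0]
            grads = _backward(model, cache, dout)
            if cfg.lam > 0:
                for name, g in _penalty_grads(model, cfg.lam, cfg.alpha).items():
                    grads[name] = grads[name] + g
            opt.step(model.params, grads)

        obj = objective(model, X, cfg.lam, cfg.alpha, training=True)
        if not np.isfinite(obj):
            raise RuntimeError(f"training diverged at epoch {epoch} "
                               f"(non-finite objective)")
        trace.append(obj)
        if obj < best_obj * (1 - 1e-6) or not np.isfinite(best_obj):
            best_obj = obj
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_running = (
                {k: v.copy() for k, v in model.running_mean.items()},
                {k: v.copy() for k, v in model.running_var.items()},
            )
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                stopped_early = True
                break

    if best_params is not None:
        model.params = best_params
        model.running_mean, model.running_var = best_running
    return TrainedPathwayModel(model, trace, cfg, pathway_id=None,
                               stopped_early=stopped_early)


# ---------------------------------------------------------------------------
# hyper-parameter search
# ---------------------------------------------------------------------------

def _sample_config(arch_inputs: list[int], rng: np.random.Generator,
                   max_epochs: int, optimizer: str) -> tuple[TrainingConfig, list[int]]:
    cfg = TrainingConfig(
        mini_batch_size=int(rng.choice([4, 8, 16, 32])),
        lam=float(10 ** rng.uniform(-9, -1)),
        alpha=float(rng.uniform(0, 1)),
        learning_rate=float(10 ** rng.uniform(-5, -1)),
        retention_p=float(rng.uniform(0.5, 1.0)),
        optimizer=optimizer,
        max_epochs=max_epochs,
        seed=int(rng.integers(2 ** 31)),
    )
    hidden = [int(rng.integers(1, AutoencoderArchitecture.max_hidden(p) + 1))
              for p in arch_inputs]
    return cfg, hidden


def tune(
    X: np.ndarray,
    input_sizes: list[int],
    budget: int = 50,
    folds: int = 5,
    seed: int = 0,
    max_epochs: int = 500,
    optimizer: str = "adam",
    modalities: list[str] | None = None,
):
    """Randomized hyper-parameter search with k-fold cross-validation.

    Samples ``budget`` configurations (log-uniform lambda and learning rate,
    uniform alpha and retention probability, categorical batch size,
    per-modality hidden sizes in [1, floor(p_j/2)]) and scores each by the
    mean held-out reconstruction error sigma(W) over the folds.  Returns
    (best TrainingConfig, best AutoencoderArchitecture, best CV error,
    trial log).  Fold splits and sampling are deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < folds:
        raise ValueError(
            f"n={n} patients < {folds} folds; use a smaller fold count")
    if budget < 1:
        raise ValueError("budget must be >= 1")

    rng = np.random.default_rng(seed)
    splits = list(KFold(n_splits=folds, shuffle=True,
                        random_state=seed % (2 ** 31)).split(X))
    trials = []
    best = None
    for _ in range(budget):
        cfg, hidden = _sample_config(input_sizes, rng, max_epochs, optimizer)
        arch = AutoencoderArchitecture(list(input_sizes), hidden,
                                       modalities=list(modalities) if modalities else None)
        fold_errors = []
        for train_idx, test_idx in splits:
            tm = train(X[train_idx], arch, cfg)
            fold_errors.append(reconstruction_loss(tm.model, X[test_idx]))
        cv = float(np.mean(fold_errors))
        trials.append({"config": cfg, "hidden_sizes": hidden, "cv_error": cv,
                       "fold_errors": fold_errors})
        if best is None or cv < best[2]:
            best = (cfg, arch, cv)
    cfg, arch, cv = best
    return cfg, arch, cv, trials


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_patients(trained: TrainedPathwayModel, X: np.ndarray) -> np.ndarray:
    """One bottleneck activation per patient (evaluation mode, in (-1, 1))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != trained.model.arch.total_inputs:
        raise ValueError("feature mismatch between model and data")
    scores, _ = encode_decode(trained.model, X)
    return np.asarray(scores)


@dataclass
class PathwayScoreMatrix:
    """P pathways x n patients score matrix, rows min-max rescaled to [0, 1]."""

    pathway_ids: list[str]
    patients: list[str]
    values: np.ndarray  # P x n, in [0, 1]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.pathway_ids,
                            columns=self.patients)

    @classmethod
    def from_frame(cls, df) -> "PathwayScoreMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def assemble_score_matrix(
    scores_by_pathway: dict[str, np.ndarray],
    patients: list[str],
) -> PathwayScoreMatrix:
    """Stack per-pathway score vectors into the non-negative matrix the
    sparse NMF consumes.

    Each pathway row is independently min-max rescaled to [0, 1] across
    patients (tanh scores are signed; the factorization needs X >= 0);
    constant rows map to 0.5.
    """
    n = len(patients)
    ids = list(scores_by_pathway.keys())
    M = np.zeros((len(ids), n))
    for r, pid in enumerate(ids):
        v = np.asarray(scores_by_pathway[pid], dtype=float)
        if v.shape != (n,):
            raise ValueError(f"pathway '{pid}': expected {n} scores, got {v.shape}")
        lo, hi = v.min(), v.max()
        M[r] = 0.5 if hi == lo else (v - lo) / (hi - lo)
    return PathwayScoreMatrix(ids, list(patients), M)
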