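"""Multi-scale convolutional epigenetic clock.

The clock maps a vector of beta values to a predicted age in years through
four stages: a fully connected layer with sigmoid activation mixes all CpG
sites into a fixed-width hidden vector; that vector, read as a 1-D signal,
feeds parallel 1-D convolution blocks with different kernel sizes (default
1, 8, 16 and 32) so that both very local and broad patterns across the
hidden units are captured; each block applies a rectifier and global average
pooling, giving one descriptor per channel per scale; the concatenated
descriptors pass through a second fully connected layer to a single linear
output, the predicted methylation age.

Training minimizes mean absolute error by default — the same quantity (MAD,
years) used to evaluate epigenetic clocks — with Adam.  Ages are
standardized internally (the recorded mean/sd travel with the model), so the
optimizer sees unit-scale targets regardless of the cohort's age range.

The reference full-array input dimension in the literature is 25,789 CpG
sites (the Illumina 27K/450K intersection); the module itself is size
agnostic and is routinely exercised at desk scale (hundreds to thousands of
sites).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .data_io import BetaMatrix

#: CpG count shared between the Illumina 27K and 450K arrays — the
#: full-scale input dimension the architecture was designed around.
FULL_ARRAY_SITES = 25_789


@dataclass
class ClockConfig:
    n_input_sites: int
    fc1_width: int = 64
    kernel_sizes: tuple[int, ...] = (1, 8, 16, 32)
    channels_per_scale: int = 4
    fc2_width: int = 16
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    loss_name: str = "mae"   # or "mse"
    # training-loss plateau schedule (decay lr by the factor after
    # `plateau_patience` epochs without relative improvement)
    plateau_patience: int = 25
    lr_decay_factor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernel_sizes:
            raise ValueError("kernel_sizes must be non-empty")
        if any(k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be >= 1")
        if max(self.kernel_sizes) > self.fc1_width:
            raise ValueError(
                f"kernel size {max(self.kernel_sizes)} exceeds fc1_width {self.fc1_width}")
        for name in ("n_input_sites", "fc1_width", "channels_per_scale", "fc2_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.loss_name not in ("mae", "mse"):
            raise ValueError(f"loss_name must be 'mae' or 'mse', got {self.loss_name!r}")


@dataclass
class TrainedClock:
    config: ClockConfig
    params: dict[str, np.ndarray]
    history: list[float] = field(default_factory=list)  # per-epoch training loss (scaled units)
    cpg_order: list[str] | None = None
    age_mean: float = 0.0
    age_sd: float = 1.0


def parameter_count(config: ClockConfig) -> int:
    """Closed-form learnable-parameter count of the architecture."""
    f, l = config.n_input_sites, config.fc1_width
    c, s = config.channels_per_scale, len(config.kernel_sizes)
    n = f * l + l                               # fc1
    n += sum(k * c + c for k in config.kernel_sizes)  # conv blocks
    n += (c * s) * config.fc2_width + config.fc2_width  # fc2
    n += config.fc2_width + 1                   # linear output
    return n


def build_clock(config: ClockConfig) -> TrainedClock:
    """Initialize an untrained clock; parameter draw is seeded."""
    rng = np.random.default_rng([int(config.seed), 0])
    f, l = config.n_input_sites, config.fc1_width
    c = config.channels_per_scale
    params: dict[str, np.ndarray] = {
        "W1": _nn.glorot(rng, f, l),
        "b1": np.zeros(l),
    }
    for k in config.kernel_sizes:
        params[f"Wc{k}"] = _nn.glorot(rng, k, c, shape=(k, c))
        params[f"bc{k}"] = np.zeros(c)
    feat = c * len(config.kernel_sizes)
    params["W2"] = _nn.glorot(rng, feat, config.fc2_width)
    params["b2"] = np.zeros(config.fc2_width)
    params["W3"] = _nn.glorot(rng, config.fc2_width, 1)
    params["b3"] = np.zeros(1)
    return TrainedClock(config=config, params=params)


# ---------------------------------------------------------------------------
# forward / backward


def _conv_forward(h1: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 1-D convolution of a (B, L) signal with a (k, C) kernel.

    Returns pre-activation (B, L, C) and the padded signal for backprop.
    """
    k = w.shape[0]
    left, right = (k - 1) // 2, k // 2
    h1p = np.pad(h1, ((0, 0), (left, right)))
    windows = np.lib.stride_tricks.sliding_window_view(h1p, k, axis=1)
    c = np.tensordot(windows, w, axes=([2], [0])) + b[None, None, :]
    return c, h1p


def _forward(params: dict[str, np.ndarray], x: np.ndarray,
             config: ClockConfig, want_cache: bool = False):
    """Forward pass; x is (B, n_input_sites); returns scaled-age predictions."""
    z1 = x @ params["W1"] + params["b1"]
    return _tail_from_z1(params, z1, config, want_cache=want_cache, x=x)


def _tail_from_z1(params: dict[str, np.ndarray], z1: np.ndarray,
                  config: ClockConfig, want_cache: bool = False,
                  x: np.ndarray | None = None):
    """Network tail: everything after the (linear) fc1 pre-activation."""
    h1 = _nn.sigmoid(z1)
    pooled, cache_scales = [], {}
    for k in config.kernel_sizes:
        c, h1p = _conv_forward(h1, params[f"Wc{k}"], params[f"bc{k}"])
        r = _nn.relu(c)
        g = r.mean(axis=1)
        pooled.append(g)
        if want_cache:
            cache_scales[k] = (c, h1p)
    feats = np.concatenate(pooled, axis=1)
    z2 = feats @ params["W2"] + params["b2"]
    h2 = _nn.relu(z2)
    out = (h2 @ params["W3"] + params["b3"])[:, 0]
    if not want_cache:
        return out
    cache = dict(x=x, h1=h1, scales=cache_scales, feats=feats, z2=z2, h2=h2)
    return out, cache


def _backward(params: dict[str, np.ndarray], cache: dict, dout: np.ndarray,
              config: ClockConfig) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    h2, z2, feats, h1, x = (cache["h2"], cache["z2"], cache["feats"],
                            cache["h1"], cache["x"])
    L = config.fc1_width
    C = config.channels_per_scale
    grads["W3"] = h2.T @ dout[:, None]
    grads["b3"] = np.array([dout.sum()])
    dh2 = dout[:, None] @ params["W3"].T
    dz2 = dh2 * _nn.relu_grad(z2)
    grads["W2"] = feats.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dfeats = dz2 @ params["W2"].T
    dh1 = np.zeros_like(h1)
    for si, k in enumerate(config.kernel_sizes):
        c, h1p = cache["scales"][k]
        dg = dfeats[:, si * C:(si + 1) * C]
        dc = (dg[:, None, :] / L) * _nn.relu_grad(c)
        w = params[f"Wc{k}"]
        left = (k - 1) // 2
        dwk = np.empty_like(w)
        dh1p = np.zeros_like(h1p)
        for j in range(k):
            dwk[j] = np.einsum("bl,blc->c", h1p[:, j:j + L], dc)
            dh1p[:, j:j + L] += dc @ w[j]
        grads[f"Wc{k}"] = dwk
        grads[f"bc{k}"] = dc.sum(axis=(0, 1))
        dh1 += dh1p[:, left:left + L]
    dz1 = dh1 * h1 * (1.0 - h1)
    grads["W1"] = x.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return grads


# ---------------------------------------------------------------------------
# training / prediction


def train_clock(clock: TrainedClock, beta: BetaMatrix, ages: Sequence[float],
                config: ClockConfig | None = None) -> TrainedClock:
    """Train in place on a complete beta matrix; returns the same object.

    ``ages`` aligns with ``beta.sample_ids``.  The recorded ``cpg_order`` is
    ``beta.cpg_ids``; prediction later requires exactly that site set.
    """
    config = config or clock.config
    ages = np.asarray(ages, dtype=float)
    if np.isnan(ages).any():
        raise ValueError("missing age in training cohort")
    if np.isnan(beta.values).any():
        raise ValueError("beta matrix has missing values; impute first")
    if beta.n_cpgs != config.n_input_sites:
        raise ValueError(
            f"clock expects {config.n_input_sites} sites, matrix has {beta.n_cpgs}")
    if len(ages) != beta.n_samples:
        raise ValueError("ages length does not match sample count")

    x = np.ascontiguousarray(beta.values.T)
    mu, sd = float(ages.mean()), float(ages.std())
    sd = sd if sd > 0 else 1.0
    y = (ages - mu) / sd

    rng = np.random.default_rng([int(config.seed), 1])
    opt = _nn.Adam(lr=config.learning_rate)
    sched = _nn.PlateauScheduler(opt, patience=config.plateau_patience,
                                 factor=config.lr_decay_factor, rel_tol=1e-3)
    n = x.shape[0]
    bs = min(config.batch_size, n)
    clock.history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            pred, cache = _forward(clock.params, xb, config, want_cache=True)
            resid = pred - yb
            if config.loss_name == "mae":
                loss = np.abs(resid).mean()
                dout = np.sign(resid) / len(idx)
            else:
                loss = (resid ** 2).mean()
                dout = 2.0 * resid / len(idx)
            grads = _backward(clock.params, cache, dout, config)
            opt.step(clock.params, grads)
            losses.append(loss)
        clock.history.append(float(np.mean(losses)))
        sched.update(clock.history[-1])
    clock.cpg_order = list(beta.cpg_ids)
    clock.age_mean, clock.age_sd = mu, sd
    return clock


def predict_age(trained: TrainedClock, beta: BetaMatrix) -> np.ndarray:
    """Predicted ages (years), one per sample, in ``beta.sample_ids`` order.

    ``beta`` may contain extra CpGs; it must cover the clock's recorded
    site set, which is reordered internally.
    """
    if trained.cpg_order is None:
        raise ValueError("clock has no recorded cpg order; train it first")
    missing = sorted(set(trained.cpg_order) - set(beta.cpg_ids))
    if missing:
        raise ValueError(f"beta matrix lacks required CpGs: {missing[:5]}" +
                         (" ..." if len(missing) > 5 else ""))
    sub = beta.subset_cpgs(trained.cpg_order)
    if np.isnan(sub.values).any():
        raise ValueError("beta matrix has missing values; impute first")
    pred = _forward(trained.params, np.ascontiguousarray(sub.values.T),
                    trained.config)
    return trained.age_mean + trained.age_sd * pred


def mad(pred_ages: Sequence[float], true_ages: Sequence[float]) -> float:
    """Mean absolute deviation between predicted and true ages, years."""
    pred = np.asarray(pred_ages, dtype=float)
    true = np.asarray(true_ages, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError(f"length mismatch or empty: {pred.shape} vs {true.shape}")
    return float(np.abs(pred - true).mean())


def compare_subset_retrain(beta: BetaMatrix, ages: Sequence[float],
                           full_site_set: Sequence[str],
                           subset_site_set: Sequence[str],
                           config: ClockConfig, k_folds: int = 5) -> dict:
    """Retrain-on-subset comparison: per-fold held-out MAD of a clock trained
    on the full site set versus one trained on the marker subset, with
    identical seeds and fold assignments for both arms."""
    full = list(full_site_set)
    subset = list(subset_site_set)
    if not set(subset) <= set(full):
        raise ValueError("subset_site_set is not contained in full_site_set")
    ages = np.asarray(ages, dtype=float)
    n = beta.n_samples
    rng = np.random.default_rng([int(config.seed), 2])
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)

    record: dict = {"full_mad": [], "subset_mad": [], "k_folds": k_folds}
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        for label, sites in (("full", full), ("subset", subset)):
            cfg = dataclasses.replace(config, n_input_sites=len(sites))
            sub = beta.subset_cpgs(sites)
            tr = sub.subset_samples([beta.sample_ids[i] for i in train_idx])
            te = sub.subset_samples([beta.sample_ids[i] for i in test_idx])
            model = build_clock(cfg)
            train_clock(model, tr, ages[train_idx], cfg)
            record[f"{label}_mad"].append(mad(predict_age(model, te), ages[test_idx]))
    record["full_mad_mean"] = float(np.mean(record["full_mad"]))
    record["subset_mad_mean"] = float(np.mean(record["subset_mad"]))
    return record


# ---------------------------------------------------------------------------
# serialization


def save_clock(trained: TrainedClock, outdir: str | Path) -> None:
    """Model bundle: config/order/history as JSON, parameters as .npz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": dataclasses.asdict(trained.config),
        "cpg_order": trained.cpg_order,
        "history": trained.history,
        "age_mean": trained.age_mean,
        "age_sd": trained.age_sd,
    }
    (outdir / "clock.json").write_text(json.dumps(meta, indent=1) + "\n")
    # np.save of the param dict gives byte-stable output (zip containers
    # embed timestamps, which would break reproducibility audits)
    np.save(outdir / "clock_params.npy", trained.params, allow_pickle=True)


def load_clock(outdir: str | Path) -> TrainedClock:
    outdir = Path(outdir)
    meta = json.loads((outdir / "clock.json").read_text())
    cfg = meta["config"]
    cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
    config = ClockConfig(**cfg)
    params = np.load(outdir / "clock_params.npy", allow_pickle=True).item()
    return TrainedClock(config=config, params=params, history=meta["history"],
                        cpg_order=meta["cpg_order"], age_mean=meta["age_mean"],
                        age_sd=meta["age_sd"])
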