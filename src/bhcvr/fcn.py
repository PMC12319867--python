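"""1D fully-convolutional network predicting end-tidal CO2 from RVT.

The network translates a z-normalized RVT trace (plus a one-hot subject
identifier channel) into a z-normalized P_ET_CO2 trace of the same length.
The encoder half uses stride-2 convolutions, the decoder half stride-2
transposed convolutions, so an ``n_layers`` model downsamples by
``2**(n_layers/2)`` at the bottleneck.  Training uses per-segment (batch
size 1) Adam with an initial learning rate of 0.01 reduced by 10x after 4
epochs without improvement of the best training loss, and a loss that adds
``peak_weight`` times the MSE at the end-tidal peaks to the plain MSE.

Everything (forward, backward, optimizer, schedule) is implemented here in
numpy; model state is a flat list of weight arrays, so checkpoints are a
single ``.npz`` archive.

Architecture constants not fixed by the training recipe: kernel size 8
(pad 3), base width 16 doubling per encoder layer up to a cap of 64, leaky
ReLU activations (slope 0.1) everywhere except the final linear output
layer, gradient clipping at global norm 1.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

KERNEL = 8
STRIDE = 2
PAD = 3  # keeps L_out = L_in/2 (conv) and 2*L_in (transposed) exactly
BASE_WIDTH = 16
MAX_WIDTH = 64

LAYER_OPTIONS = (2, 4, 6, 8, 10, 12, 14)
EPOCH_OPTIONS = (5, 10, 15, 20, 25)
PEAK_WEIGHT_OPTIONS = (0.0, 0.5, 1.0, 1.5, 2.0)

# peak detection on z-scored target segments (loss + evaluation)
PEAK_PROMINENCE_Z = 0.5
PEAK_MIN_SEPARATION_S = 15.0
WORKING_FS = 10.0

# batch-1 training on whole segments produces occasional violent gradients;
# global-norm clipping keeps the fixed 0.01 learning rate stable, and the
# leaky activation prevents the dead-unit collapse plain ReLU shows at this
# learning rate on roughly half of initialization seeds
GRAD_CLIP_NORM = 1.0
LEAKY_SLOPE = 0.1


@dataclass
class FcnConfig:
    """Hyperparameters of the predictor and its training recipe."""

    n_layers: int = 12
    epochs: int = 20
    peak_weight: float = 0.5
    lr0: float = 0.01
    plateau_factor: float = 0.1
    plateau_patience: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers % 2 or self.n_layers < 2:
            raise ValueError("n_layers must be an even integer >= 2")
        if self.peak_weight < 0:
            raise ValueError("peak_weight must be >= 0")

    @property
    def n_down(self) -> int:
        return self.n_layers // 2

    @property
    def pad_multiple(self) -> int:
        return 2**self.n_down


@dataclass
class TrainingSegment:
    """Aligned (delay-corrected) z-normalized RVT / P_ET_CO2 pair."""

    rvt_z: np.ndarray
    petco2_z: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.rvt_z = np.asarray(self.rvt_z, dtype=float)
        self.petco2_z = np.asarray(self.petco2_z, dtype=float)
        if self.rvt_z.shape != self.petco2_z.shape:
            raise ValueError("rvt_z and petco2_z must have equal length")


def _check_znormed(x: np.ndarray, name: str) -> None:
    # segments cut from a z-normalized full trace drift from (0, 1) — a
    # segment of skipped holds can be nearly flat — so only reject inputs
    # that are clearly on a raw physical scale
    if abs(float(np.mean(x))) > 2.0 or not (1e-4 <= float(np.std(x)) <= 10.0):
        raise ValueError(f"{name} does not look z-normalized (mean {np.mean(x):.3g}, sd {np.std(x):.3g})")


def encode_input(rvt_z: np.ndarray, subject_id: str, vocabulary: list[str]) -> np.ndarray:
    """Build the N x 2 model input.

    Column 1 is ``tanh`` of the z-normalized RVT (squashed into (-1, 1));
    column 2 carries the one-hot subject code in its first ``len(vocabulary)``
    entries, zero-padded to N.  Unknown subjects get an all-zero column.
    """
    rvt_z = np.asarray(rvt_z, dtype=float)
    n = rvt_z.size
    if n < len(vocabulary):
        raise ValueError(f"input length {n} shorter than vocabulary size {len(vocabulary)}")
    out = np.zeros((n, 2))
    out[:, 0] = np.tanh(rvt_z)
    if subject_id in vocabulary:
        out[vocabulary.index(subject_id), 1] = 1.0
    return out


def detect_target_peaks(target: np.ndarray, fs: float = WORKING_FS) -> np.ndarray:
    """Indices of end-tidal maxima in a z-scored target segment."""
    idx, _ = find_peaks(
        np.asarray(target, dtype=float),
        prominence=PEAK_PROMINENCE_Z,
        distance=max(1, int(round(PEAK_MIN_SEPARATION_S * fs))),
    )
    return idx


def peak_weighted_loss(
    pred: np.ndarray, target: np.ndarray, peak_indices: np.ndarray, peak_weight: float
) -> float:
    """MSE plus ``peak_weight`` times the MSE restricted to the peaks."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    err = pred - target
    loss = float(np.mean(err**2))
    peak_indices = np.asarray(peak_indices, dtype=int)
    if peak_weight > 0:
        if peak_indices.size == 0:
            warnings.warn("no peaks in target; falling back to plain MSE")
        else:
            loss += peak_weight * float(np.mean(err[peak_indices] ** 2))
    return loss


def _loss_grad(pred, target, peak_indices, peak_weight):
    err = pred - target
    g = 2.0 * err / err.size
    if peak_weight > 0 and peak_indices.size:
        g[peak_indices] += 2.0 * peak_weight * err[peak_indices] / peak_indices.size
    return g


# --- layers ---------------------------------------------------------------


class _Conv:
    """Stride-2 1D convolution; weight (Cout, Cin, K)."""

    transposed = False

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * KERNEL))
        self.W = rng.normal(0.0, scale, size=(cout, cin, KERNEL))
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, L = x.shape
        lout = L // STRIDE
        xp = np.zeros((cin, L + 2 * PAD))
        xp[:, PAD : PAD + L] = x
        self._xp, self._L = xp, L
        y = np.repeat(self.b[:, None], lout, axis=1)
        for k in range(KERNEL):
            y += self.W[:, :, k] @ xp[:, k : k + STRIDE * lout : STRIDE]
        return y

    def backward(self, dy: np.ndarray):
        xp, L = self._xp, self._L
        lout = dy.shape[1]
        dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for k in range(KERNEL):
            sl = slice(k, k + STRIDE * lout, STRIDE)
            dW[:, :, k] = dy @ xp[:, sl].T
            dxp[:, sl] += self.W[:, :, k].T @ dy
        return dxp[:, PAD : PAD + L], dW, dy.sum(axis=1)


class _ConvTranspose:
    """Stride-2 1D transposed convolution; weight (Cin, Cout, K)."""

    transposed = True

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * KERNEL / STRIDE))
        self.W = rng.normal(0.0, scale, size=(cin, cout, KERNEL))
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, L = x.shape
        cout = self.b.size
        lout = STRIDE * L
        self._x = x
        ypad = np.zeros((cout, STRIDE * (L - 1) + KERNEL))
        for k in range(KERNEL):
            ypad[:, k : k + STRIDE * L : STRIDE] += self.W[:, :, k].T @ x
        return ypad[:, PAD : PAD + lout] + self.b[:, None]

    def backward(self, dy: np.ndarray):
        x = self._x
        L = x.shape[1]
        dypad = np.zeros((dy.shape[0], STRIDE * (L - 1) + KERNEL))
        dypad[:, PAD : PAD + dy.shape[1]] = dy
        dx = np.zeros_like(x)
        dW = np.empty_like(self.W)
        for k in range(KERNEL):
            sl = slice(k, k + STRIDE * L, STRIDE)
            dx += self.W[:, :, k] @ dypad[:, sl]
            dW[:, :, k] = x @ dypad[:, sl].T
        return dx, dW, dy.sum(axis=1)


def _widths(n_down: int) -> list[int]:
    return [min(BASE_WIDTH * 2**i, MAX_WIDTH) for i in range(n_down)]


@dataclass
class FcnModel:
    """Trained predictor: layer list, hyperparameters, subject vocabulary."""

    layers: list
    config: FcnConfig
    subject_vocabulary: list[str] = field(default_factory=list)

    def _forward(self, x: np.ndarray, record: bool = False) -> np.ndarray:
        acts = []
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            last = i == n - 1
            if not last:
                mask = np.where(x > 0, 1.0, LEAKY_SLOPE)
                x = x * mask
                if record:
                    acts.append(mask)
        self._relu_masks = acts if record else None
        return x

    def _backward(self, dy: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        grads = [None] * len(self.layers)
        masks = self._relu_masks
        for i in range(len(self.layers) - 1, -1, -1):
            dy, dW, db = self.layers[i].backward(dy)
            grads[i] = (dW, db)
            if i > 0:
                dy = dy * masks[i - 1]
        return grads

    def forward_trace(self, rvt_z: np.ndarray, subject_id: str, record: bool = False) -> np.ndarray:
        """Length-preserving prediction: pad to a stride multiple, crop back."""
        enc = encode_input(rvt_z, subject_id, self.subject_vocabulary)
        n = enc.shape[0]
        m = self.config.pad_multiple
        n_pad = (-n) % m
        x = np.zeros((2, n + n_pad))
        x[:, :n] = enc.T
        self._n_out = n
        y = self._forward(x, record=record)
        return y[0, :n]

    def predict(self, rvt_z: np.ndarray, subject_id: str = "unknown") -> np.ndarray:
        return self.forward_trace(np.asarray(rvt_z, dtype=float), subject_id)

    # --- persistence ---
    def save(self, path: str | Path) -> None:
        arrays = {}
        kinds = []
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
            kinds.append("t" if layer.transposed else "c")
        meta = {"config": asdict(self.config), "vocab": self.subject_vocabulary, "kinds": kinds}
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FcnModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            cfg = FcnConfig(**meta["config"])
            rng = np.random.default_rng(0)
            layers = []
            for i, kind in enumerate(meta["kinds"]):
                W, b = data[f"W{i}"], data[f"b{i}"]
                if kind == "t":
                    layer = _ConvTranspose(W.shape[0], W.shape[1], rng)
                else:
                    layer = _Conv(W.shape[1], W.shape[0], rng)
                layer.W, layer.b = W, b
                layers.append(layer)
        return cls(layers, cfg, meta["vocab"])


def build_model(config: FcnConfig, subject_vocabulary: list[str]) -> FcnModel:
    rng = np.random.default_rng(config.seed)
    widths = _widths(config.n_down)
    layers: list = []
    cin = 2
    for w in widths:
        layers.append(_Conv(cin, w, rng))
        cin = w
    for w in list(reversed(widths))[1:]:
        layers.append(_ConvTranspose(cin, w, rng))
        cin = w
    layers.append(_ConvTranspose(cin, 1, rng))
    return FcnModel(layers, config, list(subject_vocabulary))


class _Adam:
    def __init__(self, layers, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = [
            (np.zeros_like(l.W), np.zeros_like(l.W), np.zeros_like(l.b), np.zeros_like(l.b))
            for l in layers
        ]

    def step(self, layers, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for layer, (dW, db), st in zip(layers, grads, self.state):
            mW, vW, mb, vb = st
            mW *= b1; mW += (1 - b1) * dW
            vW *= b2; vW += (1 - b2) * dW**2
            mb *= b1; mb += (1 - b1) * db
            vb *= b2; vb += (1 - b2) * db**2
            layer.W -= self.lr * (mW / corr1) / (np.sqrt(vW / corr2) + self.eps)
            layer.b -= self.lr * (mb / corr1) / (np.sqrt(vb / corr2) + self.eps)


def train(
    segments: list[TrainingSegment], config: FcnConfig, verbose: bool = False
) -> tuple[FcnModel, pd.DataFrame]:
    """Train the predictor on aligned RVT/P_ET_CO2 segments.

    Batch size 1 (one segment per optimizer step), Adam starting at
    ``config.lr0``, reduce-on-plateau on the per-epoch mean training loss.
    Deterministic given ``config.seed``.  Returns the model and a per-epoch
    history (loss, learning rate).
    """
    if not segments:
        raise ValueError("need at least one training segment")
    for s in segments:
        _check_znormed(s.rvt_z, "rvt_z")
        _check_znormed(s.petco2_z, "petco2_z")
    vocab = sorted({s.subject_id for s in segments})
    model = build_model(config, vocab)
    opt = _Adam(model.layers, config.lr0)
    rng = np.random.default_rng(config.seed + 1)
    peaks = [detect_target_peaks(s.petco2_z) for s in segments]

    history = []
    best = np.inf
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(segments))
        losses = []
        for i in order:
            seg = segments[i]
            pred = model.forward_trace(seg.rvt_z, seg.subject_id, record=True)
            loss = peak_weighted_loss(pred, seg.petco2_z, peaks[i], config.peak_weight)
            g = _loss_grad(pred, seg.petco2_z, peaks[i], config.peak_weight)
            # route the gradient back through the pad-and-crop wrapper
            n = seg.rvt_z.size
            n_pad = (-n) % config.pad_multiple
            dy = np.zeros((1, n + n_pad))
            dy[0, :n] = g
            grads = model._backward(dy)
            gnorm = np.sqrt(sum(float(np.sum(dW**2)) + float(np.sum(db**2))
                                for dW, db in grads))
            if gnorm > GRAD_CLIP_NORM:
                scale = GRAD_CLIP_NORM / gnorm
                grads = [(dW * scale, db * scale) for dW, db in grads]
            opt.step(model.layers, grads)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                stall = 0
        history.append({"epoch": epoch, "loss": epoch_loss, "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.5f}  lr {opt.lr:g}")
    return model, pd.DataFrame(history)


def predict(model: FcnModel, rvt_z, subject_id: str = "unknown") -> np.ndarray:
    """Predict a z-scale P_ET_CO2 trace from a z-normalized RVT trace."""
    return model.predict(np.asarray(rvt_z, dtype=float), subject_id)


def _fold_assignments(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f in range(folds):
        fold_of[order[f::folds]] = f
    return fold_of


def grid_search(
    segments: list[TrainingSegment],
    layer_options=LAYER_OPTIONS,
    epoch_options=EPOCH_OPTIONS,
    peak_weight_options=PEAK_WEIGHT_OPTIONS,
    folds: int = 5,
    seed: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """K-fold hyperparameter search ranked by mean RMSE at the peaks.

    Each combination is trained on the training folds and evaluated on the
    held-out segments with Fisher-z correlation, MAE, RMSE and RMSE at the
    target's end-tidal peaks; rows are sorted ascending by mean
    rmse_at_peaks (the quantity that matters most for CVR scaling).
    """
    from .metrics import trace_metrics_arrays

    if len(segments) < folds:
        raise ValueError(f"need at least {folds} segments for {folds}-fold CV")
    fold_of = _fold_assignments(len(segments), folds, seed)
    rows = []
    for n_layers in layer_options:
        for epochs in epoch_options:
            for lam in peak_weight_options:
                per_fold = {"fisher_z": [], "mae": [], "rmse": [], "rmse_at_peaks": []}
                for f in range(folds):
                    train_segs = [s for s, g in zip(segments, fold_of) if g != f]
                    val_segs = [s for s, g in zip(segments, fold_of) if g == f]
                    cfg = FcnConfig(
                        n_layers=n_layers, epochs=epochs, peak_weight=lam, seed=seed + f
                    )
                    model, _ = train(train_segs, cfg)
                    vals = {k: [] for k in per_fold}
                    for s in val_segs:
                        pred = model.predict(s.rvt_z, s.subject_id)
                        m = trace_metrics_arrays(
                            s.petco2_z, pred, detect_target_peaks(s.petco2_z)
                        )
                        for k in vals:
                            if m[k] is not None:
                                vals[k].append(m[k])
                    for k in per_fold:
                        per_fold[k].append(float(np.mean(vals[k])) if vals[k] else np.nan)
                row = {"n_layers": n_layers, "epochs": epochs, "peak_weight": lam}
                for k, v in per_fold.items():
                    row[f"{k}_mean"] = float(np.nanmean(v))
                    row[f"{k}_sd"] = float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0
                rows.append(row)
                if verbose:
                    print(row)
    table = pd.DataFrame(rows).sort_values("rmse_at_peaks_mean", kind="stable")
    return table.reset_index(drop=True)
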