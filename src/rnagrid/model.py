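"""Dual-path multi-channel convolutional classifier, in pure NumPy.

Each RNA sample is a pair of channel stacks: the descriptor image split into
its 14 subgroup channels (28 x 27 x 14) and the gap-feature image split into
its 17 subgroup channels (27 x 27 x 17).  The two stacks are processed by
independent convolutional paths:

    initial 3x3 same-padding convolution with a single filter
    -> [2x2 stride-2 max-pool (ceil padding) -> three parallel 3x3 valid
        convolutions -> channel concatenation]
    -> [3x3 stride-1 max-pool -> three parallel 3x3 same convolutions
        (64 filters each) -> channel concatenation]

which takes both 28x27 and 27x27 inputs to exactly 192 feature maps of
spatial size 10x10.  Global max pooling per path yields a 192-vector, the
two paths concatenate to a 384-vector, and a fully connected softmax layer
produces class probabilities.  Training minimises categorical cross-entropy
with Adam.  Everything (forward, backward, optimiser) is implemented here in
NumPy; gradients are verified against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

#: Hyperparameter grid searched during model selection (selection metric: MCC).
BATCH_SIZE_GRID = (32, 64, 96)
LEARNING_RATE_GRID = (1e-5, 1e-4, 2e-4, 5e-4)


@dataclasses.dataclass
class ModelConfig:
    task: str = "binary-coding"
    n_classes: int = 2
    batch_size: int = 32
    learning_rate: float = 2e-4
    epochs: int = 30
    seed: int = 0
    # architecture block spec: filters per parallel convolution in each block
    block1_filters: int = 4
    block2_filters: int = 64
    dtype: str = "float32"      # compute precision; float64 for gradient checks

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclasses.dataclass
class MetricsReport:
    spe: float
    sen: float
    pre: float
    acc: float
    auc: float
    mcc: float
    confusion: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {"SPE": self.spe, "SEN": self.sen, "PRE": self.pre,
                "ACC": self.acc, "AUC": self.auc, "MCC": self.mcc}


# ---------------------------------------------------------------------------
# layer primitives (forward + backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: tuple[int, int, int, int]):
    """(N,H,W,C) -> (N,OH,OW,kh*kw*C) patch matrix; pad = (top,bottom,left,right)."""
    t, b, l, r = pad
    if any(pad):
        x = np.pad(x, ((0, 0), (t, b), (l, r), (0, 0)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # N,OH,OW,C,kh,kw
    win = win.transpose(0, 1, 2, 4, 5, 3)                # N,OH,OW,kh,kw,C
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, oh, ow, kh * kw * x.shape[3])


def _conv_forward(x, w, b, padding):
    """w: (kh,kw,C,F).  padding 'same' (odd kernels) or 'valid'."""
    kh, kw, _, f = w.shape
    if padding == "same":
        pad = (kh // 2, kh // 2, kw // 2, kw // 2)
    else:
        pad = (0, 0, 0, 0)
    col = _im2col(x, kh, kw, pad)
    out = col @ w.reshape(-1, f) + b
    cache = (col, x.shape, w, pad)
    return out, cache


def _conv_backward(dout, cache):
    col, x_shape, w, pad = cache
    kh, kw, c, f = w.shape
    n, oh, ow, _ = dout.shape
    dflat = dout.reshape(-1, f)
    dw = (col.reshape(-1, kh * kw * c).T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcol = (dflat @ w.reshape(-1, f).T).reshape(n, oh, ow, kh, kw, c)
    t, btm, l, r = pad
    hp, wp = x_shape[1] + t + btm, x_shape[2] + l + r
    dxp = np.zeros((n, hp, wp, c), dtype=dout.dtype)
    for di in range(kh):
        for dj in range(kw):
            dxp[:, di:di + oh, dj:dj + ow, :] += dcol[:, :, :, di, dj, :]
    return dxp[:, t:t + x_shape[1], l:l + x_shape[2], :], dw, db


def _relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def _maxpool2_forward(x):
    """2x2 stride-2 max pool with ceil (-inf) padding on odd dims."""
    n, h, w, c = x.shape
    hp, wp = h + h % 2, w + w % 2
    xp = np.full((n, hp, wp, c), -np.inf, dtype=x.dtype)
    xp[:, :h, :w, :] = x
    win = xp.reshape(n, hp // 2, 2, wp // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    flat = win.reshape(n, hp // 2, wp // 2, 4, c)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, x.shape)


def _maxpool2_backward(dout, cache):
    idx, x_shape = cache
    n, h, w, c = x_shape
    hp, wp = h + h % 2, w + w % 2
    dflat = np.zeros((n, hp // 2, wp // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dxp = dflat.reshape(n, hp // 2, wp // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    dxp = dxp.reshape(n, hp, wp, c)
    return dxp[:, :h, :w, :]


def _maxpool3s1_forward(x):
    """3x3 stride-1 valid max pool."""
    win = sliding_window_view(x, (3, 3), axis=(1, 2))  # N,OH,OW,C,3,3
    n, oh, ow, c = win.shape[:4]
    flat = np.ascontiguousarray(win).reshape(n, oh, ow, c, 9)
    idx = flat.argmax(axis=4)
    out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
    return out, (idx, x.shape)


def _maxpool3s1_backward(dout, cache):
    idx, x_shape = cache
    n, oh, ow, c = dout.shape
    dx = np.zeros(x_shape, dtype=dout.dtype)
    di, dj = np.unravel_index(idx, (3, 3))
    ii = np.arange(oh)[None, :, None, None] + di
    jj = np.arange(ow)[None, None, :, None] + dj
    nn = np.arange(n)[:, None, None, None]
    cc = np.arange(c)[None, None, None, :]
    np.add.at(dx, (nn, ii, jj, cc), dout)
    return dx


def _global_max_forward(x):
    n, h, w, c = x.shape
    flat = x.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)
    out = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
    return out, (idx, x.shape)


def _global_max_backward(dout, cache):
    idx, x_shape = cache
    n, h, w, c = x_shape
    dflat = np.zeros((n, h * w, c), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[:, None, :], dout[:, None, :], axis=1)
    return dflat.reshape(x_shape)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(proba: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy of probability rows against labels."""
    p = np.clip(proba[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.log(p).mean())


# ---------------------------------------------------------------------------
# the dual-path model
# ---------------------------------------------------------------------------

class ShapeScheduleError(ValueError):
    pass


def _check_schedule(grid: tuple[int, int], path: str) -> tuple[int, int]:
    """Spatial size after [pool2-ceil -> conv3-valid -> pool3-s1 -> conv3-same]."""
    out = []
    for dim in grid:
        d = -(-dim // 2) - 2 - 2
        if d < 1:
            raise ShapeScheduleError(
                f"{path} path: grid dimension {dim} collapses to {d} under "
                f"the pooling schedule")
        out.append(d)
    return tuple(out)


class DualPathModel:
    """Dual-path multi-channel CNN over (D, G) image channel stacks."""

    def __init__(self, config: ModelConfig, d_shape: tuple[int, int, int],
                 g_shape: tuple[int, int, int]):
        self.config = config
        self.d_shape = d_shape
        self.g_shape = g_shape
        self.d_final = _check_schedule(d_shape[:2], "D")
        self.g_final = _check_schedule(g_shape[:2], "G")
        self.n_maps = 3 * config.block2_filters        # per-path feature maps
        self.embedding_dim = 2 * self.n_maps
        self.trained = False
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for path, (_, _, ch) in (("d", d_shape), ("g", g_shape)):
            self._init_path(rng, path, ch)
        k = config.n_classes
        self.params["head_w"] = rng.normal(
            0.0, np.sqrt(2.0 / self.embedding_dim), (self.embedding_dim, k))
        self.params["head_b"] = np.zeros(k)
        dt = np.dtype(config.dtype)
        self.params = {k_: v.astype(dt) for k_, v in self.params.items()}
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    def _init_path(self, rng, path: str, channels: int) -> None:
        f1, f2 = self.config.block1_filters, self.config.block2_filters
        def he(shape):
            fan_in = shape[0] * shape[1] * shape[2]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params[f"{path}_w0"] = he((3, 3, channels, 1))
        self.params[f"{path}_b0"] = np.zeros(1)
        for blk, (cin, f) in (("1", (1, f1)), ("2", (3 * f1, f2))):
            for tap in "abc":
                self.params[f"{path}_w{blk}{tap}"] = he((3, 3, cin, f))
                self.params[f"{path}_b{blk}{tap}"] = np.zeros(f)

    # -- forward ------------------------------------------------------------

    def _path_forward(self, x: np.ndarray, path: str, want_cache: bool):
        p = self.params
        caches = {}
        x = np.ascontiguousarray(x, dtype=p[f"{path}_w0"].dtype)
        h, caches["conv0"] = _conv_forward(x, p[f"{path}_w0"], p[f"{path}_b0"], "same")
        h, caches["relu0"] = _relu_forward(h)
        h, caches["pool1"] = _maxpool2_forward(h)
        outs = []
        for tap in "abc":
            o, caches[f"conv1{tap}"] = _conv_forward(
                h, p[f"{path}_w1{tap}"], p[f"{path}_b1{tap}"], "valid")
            o, caches[f"relu1{tap}"] = _relu_forward(o)
            outs.append(o)
        h = np.concatenate(outs, axis=3)
        h, caches["pool2"] = _maxpool3s1_forward(h)
        outs = []
        for tap in "abc":
            o, caches[f"conv2{tap}"] = _conv_forward(
                h, p[f"{path}_w2{tap}"], p[f"{path}_b2{tap}"], "same")
            o, caches[f"relu2{tap}"] = _relu_forward(o)
            outs.append(o)
        maps = np.concatenate(outs, axis=3)
        emb, caches["gmax"] = _global_max_forward(maps)
        if want_cache:
            return emb, maps, caches
        return emb, maps, None

    def _path_backward(self, demb, caches, path: str, grads):
        p = self.params
        f2 = self.config.block2_filters
        dmaps = _global_max_backward(demb, caches["gmax"])
        dh = None
        for t, tap in enumerate("abc"):
            do = dmaps[..., t * f2:(t + 1) * f2] * caches[f"relu2{tap}"]
            dx, dw, db = _conv_backward(do, caches[f"conv2{tap}"])
            grads[f"{path}_w2{tap}"] = dw
            grads[f"{path}_b2{tap}"] = db
            dh = dx if dh is None else dh + dx
        dh = _maxpool3s1_backward(dh, caches["pool2"])
        f1 = self.config.block1_filters
        dpool = None
        for t, tap in enumerate("abc"):
            do = dh[..., t * f1:(t + 1) * f1] * caches[f"relu1{tap}"]
            dx, dw, db = _conv_backward(do, caches[f"conv1{tap}"])
            grads[f"{path}_w1{tap}"] = dw
            grads[f"{path}_b1{tap}"] = db
            dpool = dx if dpool is None else dpool + dx
        dh0 = _maxpool2_backward(dpool, caches["pool1"])
        dh0 = dh0 * caches["relu0"]
        _, dw, db = _conv_backward(dh0, caches["conv0"])
        grads[f"{path}_w0"] = dw
        grads[f"{path}_b0"] = db

    def path_embeddings(self, xd: np.ndarray, xg: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Per-path pooled embedding vectors (each n x 192)."""
        ed, _, _ = self._path_forward(xd, "d", False)
        eg, _, _ = self._path_forward(xg, "g", False)
        return ed, eg

    def path_embedding(self, x: np.ndarray, path: str) -> np.ndarray:
        emb, _, _ = self._path_forward(x, path, False)
        return emb

    def proba_from_embeddings(self, ed: np.ndarray, eg: np.ndarray) -> np.ndarray:
        z = np.concatenate([ed, eg], axis=1) @ self.params["head_w"] + self.params["head_b"]
        return _softmax(z)

    def forward(self, xd: np.ndarray, xg: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (rows sum to 1)."""
        ed, eg = self.path_embeddings(xd, xg)
        return self.proba_from_embeddings(ed, eg)

    def feature_maps(self, xd: np.ndarray, xg: np.ndarray):
        """Pre-pooling feature-map tensors of both paths (shape checks)."""
        _, md, _ = self._path_forward(xd, "d", False)
        _, mg, _ = self._path_forward(xg, "g", False)
        return md, mg

    def predict_proba(self, xd: np.ndarray, xg: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model is untrained; call train() first")
        return self.forward(xd, xg)

    # -- training -----------------------------------------------------------

    def _step(self, xd, xg, y) -> float:
        grads: dict[str, np.ndarray] = {}
        ed, _, cd = self._path_forward(xd, "d", True)
        eg, _, cg = self._path_forward(xg, "g", True)
        e = np.concatenate([ed, eg], axis=1)
        z = e @ self.params["head_w"] + self.params["head_b"]
        proba = _softmax(z)
        n = len(y)
        loss = cross_entropy(proba, y)
        dz = proba.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        grads["head_w"] = e.T @ dz
        grads["head_b"] = dz.sum(axis=0)
        de = dz @ self.params["head_w"].T
        m = self.n_maps
        self._path_backward(de[:, :m], cd, "d", grads)
        self._path_backward(de[:, m:], cg, "g", grads)
        self._adam(grads)
        return loss

    def _adam(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.config.learning_rate
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train(self, xd: np.ndarray, xg: np.ndarray, y: np.ndarray,
              validation: tuple | None = None) -> dict[str, list[float]]:
        """Minibatch Adam training; returns per-epoch history.

        Deterministic for a fixed config seed (epoch shuffles are drawn from
        a seeded generator).
        """
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training needs at least 2 classes present")
        if xd.shape[1:] != self.d_shape or xg.shape[1:] != self.g_shape:
            raise ValueError(
                f"input shapes {xd.shape[1:]}/{xg.shape[1:]} do not match "
                f"model shapes {self.d_shape}/{self.g_shape}")
        rng = np.random.default_rng(self.config.seed + 1)
        n = len(y)
        bs = self.config.batch_size
        hist: dict[str, list[float]] = {
            "loss": [], "acc": [], "val_loss": [], "val_acc": []}
        for _ in range(self.config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                losses.append(self._step(xd[idx], xg[idx], y[idx]))
            self.trained = True
            proba = self.forward(xd, xg)
            hist["loss"].append(cross_entropy(proba, y))
            hist["acc"].append(float((proba.argmax(1) == y).mean()))
            if validation is not None:
                vd, vg, vy = validation
                vp = self.forward(vd, vg)
                hist["val_loss"].append(cross_entropy(vp, vy))
                hist["val_acc"].append(float((vp.argmax(1) == vy).mean()))
        self.history = hist
        return hist


def save_model(model: DualPathModel, path) -> None:
    """Serialise weights plus config to an .npz checkpoint."""
    import json
    meta = dict(dataclasses.asdict(model.config),
                d_shape=list(model.d_shape), g_shape=list(model.g_shape),
                trained=model.trained)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path) -> DualPathModel:
    import json
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    d_shape = tuple(meta.pop("d_shape"))
    g_shape = tuple(meta.pop("g_shape"))
    trained = meta.pop("trained")
    model = DualPathModel(ModelConfig(**meta), d_shape, g_shape)
    model.params = params
    model.trained = trained
    return model


def build_dual_path_model(config: ModelConfig, d_channels: int = 14,
                          g_channels: int = 17,
                          d_grid: tuple[int, int] = (28, 27),
                          g_grid: tuple[int, int] = (27, 27)) -> DualPathModel:
    """Untrained dual-path model for the given template dimensions."""
    return DualPathModel(config, d_grid + (d_channels,), g_grid + (g_channels,))


def cross_validate(config: ModelConfig, xd, xg, y, n_folds: int = 5
                   ) -> list[MetricsReport]:
    """Stratified k-fold cross-validation; one MetricsReport per fold."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    reports = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        model = DualPathModel(config, xd.shape[1:], xg.shape[1:])
        model.train(xd[tr], xg[tr], y[tr])
        proba = model.predict_proba(xd[te], xg[te])
        if config.n_classes == 2:
            reports.append(compute_metrics(y[te], proba[:, 1]))
        else:
            reports.append(compute_metrics(y[te], proba))
    return reports


def grid_search(make_and_eval, batch_sizes=BATCH_SIZE_GRID,
                learning_rates=LEARNING_RATE_GRID):
    """Pick (batch_size, learning_rate) maximising MCC.

    ``make_and_eval(batch_size, lr)`` must return a MetricsReport.
    """
    best = None
    for bs in batch_sizes:
        for lr in learning_rates:
            rep = make_and_eval(bs, lr)
            if best is None or rep.mcc > best[2].mcc:
                best = (bs, lr, rep)
    return best


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator for {name}; reporting 0")
        return 0.0
    return num / den


def auc_mann_whitney(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) formulation with midranks for ties."""
    y_true = np.asarray(y_true)
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(y_score)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def compute_metrics(y_true: np.ndarray, y_score: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """SPE/SEN/PRE/ACC/AUC/MCC from scores.

    Binary: ``y_score`` is the positive-class score, thresholded at
    ``threshold``.  Multiclass: ``y_score`` is an (n, k) probability matrix;
    SPE/SEN/PRE/AUC are macro-averaged one-vs-rest and MCC is the multiclass
    generalisation computed from the k x k confusion table.  Metrics with a
    degenerate denominator are reported as 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    if y_score.ndim == 1:
        y_pred = (y_score >= threshold).astype(int)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return MetricsReport(
            spe=_safe_div(tn, tn + fp, "SPE"),
            sen=_safe_div(tp, tp + fn, "SEN"),
            pre=_safe_div(tp, tp + fp, "PRE"),
            acc=(tp + tn) / len(y_true),
            auc=auc_mann_whitney(y_true, y_score),
            mcc=_safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
            confusion=np.array([[tn, fp], [fn, tp]]),
        )
    k = y_score.shape[1]
    y_pred = y_score.argmax(axis=1)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    spe = sen = pre = auc = 0.0
    for c in range(k):
        yt = (y_true == c).astype(int)
        yp = (y_pred == c).astype(int)
        tp = int(((yt == 1) & (yp == 1)).sum())
        tn = int(((yt == 0) & (yp == 0)).sum())
        fp = int(((yt == 0) & (yp == 1)).sum())
        fn = int(((yt == 1) & (yp == 0)).sum())
        spe += _safe_div(tn, tn + fp, "SPE")
        sen += _safe_div(tp, tp + fn, "SEN")
        pre += _safe_div(tp, tp + fp, "PRE")
        auc += auc_mann_whitney(yt, y_score[:, c])
    s = conf.sum()
    c_trace = np.trace(conf)
    t_k = conf.sum(axis=1).astype(float)
    p_k = conf.sum(axis=0).astype(float)
    num = c_trace * s - (t_k * p_k).sum()
    den = np.sqrt((s ** 2 - (p_k ** 2).sum()) * (s ** 2 - (t_k ** 2).sum()))
    return MetricsReport(
        spe=spe / k, sen=sen / k, pre=pre / k, acc=c_trace / s,
        auc=auc / k, mcc=_safe_div(num, den, "MCC"), confusion=conf)
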