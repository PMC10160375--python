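"""The PCA-fused convolutional classifier.

A small CNN for the stacked band-ratio score maps: two blocks of
(valid 5×5 convolution -> ReLU -> 3×3 max pooling at stride 1 with same
padding -> PCA fusion), a fully connected layer and a two-unit softmax
head trained with cross-entropy and plain SGD (weight decay 1e-4).

PCA fusion is the structural modification: after each convolution the
activated feature map is flattened, projected onto a low-rank basis fitted
once by (uncentered) PCA on a warm-up batch of activations, reconstructed,
reshaped and added point by point to the pooled map before it enters the
next layer.  With zero fusion bases the network reduces exactly to the
plain CNN, which the test suite uses as an ablation oracle.

The learning-rate schedule follows a loss-triggered rule: whenever the
epoch-mean training loss rises by more than 25 % over the previous epoch,
the learning rate is halved before the next update.

Everything is numpy; gradients are hand-derived and validated against
central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# Elementary operations (functional forms)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | float = 0.0) -> np.ndarray:
    """Valid 2-D convolution, stride 1: x (B,C,H,W), w (F,C,kh,kw), b (F,).

    2-D ``x`` and ``w`` are promoted to single-image/single-filter form and
    the result squeezed back, so hand-sized examples stay hand-sized.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, None]
    if w.ndim == 2:
        w = w[None, None]
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if b.size == 1 and w.shape[0] > 1:
        b = np.repeat(b, w.shape[0])
    kh, kw = w.shape[-2:]
    if kh > x.shape[-2] or kw > x.shape[-1]:
        raise ValueError("kernel larger than input")
    patches = sliding_window_view(x, (kh, kw), axis=(-2, -1))
    out = np.einsum("bchwij,fcij->bfhw", patches, w) + b[None, :, None, None]
    return out[0, 0] if squeeze else out


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def conv_block(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Convolution followed by ReLU: g = max(Σ a·w + b, 0)."""
    return relu(conv2d(x, w, b))


def max_pool(
    x: np.ndarray, pool: int = 3, stride: int = 1, same: bool = True
) -> np.ndarray:
    """Max pooling.  ``same=True`` pads with −inf so the output keeps the
    input's spatial shape (stride must be 1); ``same=False`` is the plain
    valid pooling with the given stride.  2-D inputs are handled directly."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, None]
    out, _ = _max_pool_forward(x, pool, stride, same)
    return out[0, 0] if squeeze else out


def _max_pool_forward(
    x: np.ndarray, pool: int, stride: int, same: bool
) -> tuple[np.ndarray, np.ndarray]:
    if same:
        if stride != 1:
            raise ValueError("same-padding pooling requires stride 1")
        p = pool // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, pool - 1 - p), (p, pool - 1 - p)),
                    constant_values=-np.inf)
    else:
        xp = x
        if pool > x.shape[-2] or pool > x.shape[-1]:
            raise ValueError("pool window larger than map")
    win = sliding_window_view(xp, (pool, pool), axis=(-2, -1))[:, :, ::stride, ::stride]
    flat = win.reshape(*win.shape[:4], pool * pool)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _max_pool_backward(
    grad: np.ndarray, x_shape: tuple, arg: np.ndarray, pool: int, same: bool
) -> np.ndarray:
    """Route pooled gradients back to each window's argmax position."""
    B, C, H, W = x_shape
    p = pool // 2 if same else 0
    dxp = np.zeros((B, C, H + (pool - 1 if same else 0), W + (pool - 1 if same else 0)))
    bi, ci, oi, oj = np.indices(grad.shape)
    di, dj = arg // pool, arg % pool
    rows = oi + di  # stride 1 windows start at the output index
    cols = oj + dj
    np.add.at(dxp, (bi, ci, rows, cols), grad)
    if same:
        return dxp[:, :, p : p + H, p : p + W]
    return dxp[:, :, :H, :W]


def pca_fuse(conv_map: np.ndarray, pooled_map: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """fused = pooled + reshape(V Vᵀ · flatten(conv)) — point-by-point fusion.

    ``basis`` V has shape (d, m) with d = conv map size per sample; a zero
    basis returns the pooled map unchanged.
    """
    conv_map = np.asarray(conv_map, dtype=float)
    pooled_map = np.asarray(pooled_map, dtype=float)
    if conv_map.shape != pooled_map.shape:
        raise ValueError("conv and pooled maps must share a shape")
    squeeze = conv_map.ndim == 2
    if squeeze:
        conv_map = conv_map[None, None]
        pooled_map = pooled_map[None, None]
    B = conv_map.shape[0]
    flat = conv_map.reshape(B, -1)
    if basis.shape[0] != flat.shape[1]:
        raise ValueError(
            f"fusion basis expects dim {basis.shape[0]}, got {flat.shape[1]}"
        )
    recon = (flat @ basis) @ basis.T
    fused = pooled_map + recon.reshape(conv_map.shape)
    return fused[0, 0] if squeeze else fused


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax y'_i = e^{y_i} / Σ_j e^{y_j}."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """H(p, q) = −Σ p(x)·ln q(x) for two distributions (natural log)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    terms = np.where(p > 0, p * logq, 0.0)
    return float(-terms.sum())


def sgd_step(
    w: np.ndarray, grad: np.ndarray, learning_rate: float, weight_decay: float = 0.0
) -> np.ndarray:
    """w ← w − ε·(∂J/∂w + decay·w)."""
    return w - learning_rate * (grad + weight_decay * w)


def update_learning_rate(
    lr: float, prev_loss: float, new_loss: float,
    increase_threshold: float = 0.25, cut: float = 0.5,
) -> float:
    """Halve the rate when the loss rose by more than the threshold."""
    if prev_loss > 0 and (new_loss - prev_loss) / prev_loss > increase_threshold:
        return lr * cut
    return lr


# ---------------------------------------------------------------------------
# Model


@dataclass
class CNNConfig:
    input_shape: tuple[int, int] = (13, 20)
    n_filters: tuple[int, int] = (4, 4)
    kernel: int = 5
    pool: int = 3
    batch_size: int = 20
    learning_rate: float = 0.1
    weight_decay: float = 1e-4
    max_iterations: int = 600
    loss_increase_threshold: float = 0.25
    lr_cut: float = 0.5
    fusion_components: int = 2
    warmup_batch: int = 64
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_shape) < self.kernel:
            raise ValueError("kernel must fit the input shape")
        for v in (self.batch_size, self.max_iterations, self.kernel, self.pool):
            if v < 1:
                raise ValueError("structural parameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class PCAFusedCNN:
    """Two-block PCA-fused CNN with a softmax head (binary output)."""

    def __init__(self, config: CNNConfig):
        self.config = config
        h, w = config.input_shape
        f1, f2 = config.n_filters
        k = config.kernel
        self.shape1 = (f1, h - k + 1, w - k + 1)
        self.shape2 = (f2, self.shape1[1] - k + 1, self.shape1[2] - k + 1)
        if min(self.shape2[1:]) < 1:
            raise ValueError("input too small for two convolution blocks")
        self.d1 = int(np.prod(self.shape1))
        self.d2 = int(np.prod(self.shape2))
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0, np.sqrt(2.0 / (k * k)), (f1, 1, k, k)),
            "b1": np.zeros(f1),
            "W2": rng.normal(0, np.sqrt(2.0 / (f1 * k * k)), (f2, f1, k, k)),
            "b2": np.zeros(f2),
            "Wfc": rng.normal(0, np.sqrt(2.0 / self.d2), (2, self.d2)),
            "bfc": np.zeros(2),
        }
        # fusion bases start at zero: the network is a plain CNN until
        # fit_fusion() is called (and stays plain if fusion_components == 0)
        self.V1 = np.zeros((self.d1, max(config.fusion_components, 1)))
        self.V2 = np.zeros((self.d2, max(config.fusion_components, 1)))
        self.fusion_frozen = False

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        x4 = x[:, None, :, :] if x.ndim == 3 else x
        z1 = conv2d(x4, self.params["W1"], self.params["b1"])
        a1 = relu(z1)
        p1, arg1 = _max_pool_forward(a1, cfg.pool, 1, True)
        f1 = pca_fuse(a1, p1, self.V1)
        z2 = conv2d(f1, self.params["W2"], self.params["b2"])
        a2 = relu(z2)
        p2, arg2 = _max_pool_forward(a2, cfg.pool, 1, True)
        f2 = pca_fuse(a2, p2, self.V2)
        flat = f2.reshape(f2.shape[0], -1)
        logits = flat @ self.params["Wfc"].T + self.params["bfc"]
        probs = softmax(logits)
        return {
            "x": x4, "z1": z1, "a1": a1, "arg1": arg1, "f1": f1,
            "z2": z2, "a2": a2, "arg2": arg2, "f2": f2,
            "flat": flat, "logits": logits, "probs": probs,
        }

    def _loss_from_probs(self, probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy of a batch (no decay term)."""
        return self._loss_from_probs(self._forward(x)["probs"], np.asarray(y))

    def _backward(
        self, cache: dict[str, np.ndarray], y: np.ndarray
    ) -> dict[str, np.ndarray]:
        cfg = self.config
        B = len(y)
        probs = cache["probs"].copy()
        probs[np.arange(B), y] -= 1.0
        dlogits = probs / B
        grads: dict[str, np.ndarray] = {}
        grads["Wfc"] = dlogits.T @ cache["flat"]
        grads["bfc"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["Wfc"]
        df2 = dflat.reshape(cache["f2"].shape)
        # fusion 2: f2 = p2 + reshape(P2 · flat(a2)), P2 symmetric
        dp2 = df2
        da2_fuse = ((df2.reshape(B, -1) @ self.V2) @ self.V2.T).reshape(cache["a2"].shape)
        da2 = _max_pool_backward(dp2, cache["a2"].shape, cache["arg2"], cfg.pool, True)
        da2 += da2_fuse
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"], grads["b2"], df1 = _conv_backward(
            cache["f1"], self.params["W2"], dz2
        )
        dp1 = df1
        da1_fuse = ((df1.reshape(B, -1) @ self.V1) @ self.V1.T).reshape(cache["a1"].shape)
        da1 = _max_pool_backward(dp1, cache["a1"].shape, cache["arg1"], cfg.pool, True)
        da1 += da1_fuse
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"], grads["b1"], _ = _conv_backward(cache["x"], self.params["W1"], dz1)
        return grads

    # -- fusion bases -------------------------------------------------------

    def fit_fusion(self, x_warmup: np.ndarray) -> None:
        """Fit the per-layer fusion bases on a warm-up batch, then freeze.

        Bases are the top principal directions (uncentered SVD) of the
        flattened post-ReLU convolution activations.  With
        ``fusion_components == 0`` the bases stay zero (plain CNN).
        """
        m = self.config.fusion_components
        if m == 0:
            self.fusion_frozen = True
            return
        x4 = x_warmup[:, None, :, :] if x_warmup.ndim == 3 else x_warmup
        a1 = conv_block(x4, self.params["W1"], self.params["b1"])
        self.V1 = _top_components(a1.reshape(a1.shape[0], -1), m)
        p1, _ = _max_pool_forward(a1, self.config.pool, 1, True)
        f1 = pca_fuse(a1, p1, self.V1)
        a2 = conv_block(f1, self.params["W2"], self.params["b2"])
        self.V2 = _top_components(a2.reshape(a2.shape[0], -1), m)
        self.fusion_frozen = True

    # -- training -----------------------------------------------------------

    def train(
        self,
        inputs: np.ndarray,
        labels: np.ndarray,
        test_mask: np.ndarray | None = None,
    ) -> "TrainingResult":
        """Mini-batch SGD training with the loss-triggered LR halving rule.

        A stratified 75/25 train/test split is drawn from the config seed
        unless ``test_mask`` supplies one.  Trajectories (per-iteration
        loss, train-batch accuracy, test accuracy) are recorded; the run is
        deterministic for a fixed config seed.
        """
        cfg = self.config
        x = np.asarray(inputs, dtype=float)
        y = np.asarray(labels, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training needs both classes present")
        rng = np.random.default_rng(cfg.seed + 1)
        if test_mask is None:
            test_mask = _stratified_test_mask(y, cfg.test_fraction, rng)
        tr = np.where(~test_mask)[0]
        te = np.where(test_mask)[0]
        if cfg.batch_size > tr.size:
            raise ValueError("batch size exceeds the training set")
        warm = tr[: min(cfg.warmup_batch, tr.size)]
        if not self.fusion_frozen:
            self.fit_fusion(x[warm])

        lr = cfg.learning_rate
        prev_epoch_loss: float | None = None
        hist = {"iteration": [], "loss": [], "train_acc": [], "test_acc": [], "lr": []}
        it = 0
        while it < cfg.max_iterations:
            order = rng.permutation(tr)
            epoch_losses: list[float] = []
            for start in range(0, len(order), cfg.batch_size):
                if it >= cfg.max_iterations:
                    break
                batch = order[start : start + cfg.batch_size]
                cache = self._forward(x[batch])
                loss = self._loss_from_probs(cache["probs"], y[batch])
                grads = self._backward(cache, y[batch])
                for name in self.params:
                    self.params[name] = sgd_step(
                        self.params[name], grads[name], lr, cfg.weight_decay
                    )
                pred = cache["probs"].argmax(axis=1)
                test_acc = (
                    float(np.mean(self.predict(x[te])[0] == y[te])) if te.size else np.nan
                )
                hist["iteration"].append(it)
                hist["loss"].append(loss)
                hist["train_acc"].append(float(np.mean(pred == y[batch])))
                hist["test_acc"].append(test_acc)
                hist["lr"].append(lr)
                epoch_losses.append(loss)
                it += 1
            if epoch_losses:
                epoch_loss = float(np.mean(epoch_losses))
                if prev_epoch_loss is not None:
                    lr = update_learning_rate(
                        lr, prev_epoch_loss, epoch_loss,
                        cfg.loss_increase_threshold, cfg.lr_cut,
                    )
                prev_epoch_loss = epoch_loss
        return TrainingResult(
            model=self,
            history=pd.DataFrame(hist),
            train_indices=tr,
            test_indices=te,
        )

    def predict(self, inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores): score = probability of the positive (low-SA)
        class 1; label = argmax."""
        x = np.asarray(inputs, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected input shape {self.config.input_shape}, got {x.shape[-2:]}"
            )
        probs = self._forward(x)["probs"]
        return probs.argmax(axis=1), probs[:, 1]

    # -- parameter vector utilities (for gradient checking) -----------------

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat_params(self, vec: np.ndarray) -> None:
        pos = 0
        for k in sorted(self.params):
            n = self.params[k].size
            self.params[k] = vec[pos : pos + n].reshape(self.params[k].shape).copy()
            pos += n

    def flat_gradients(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cache = self._forward(np.asarray(x, dtype=float))
        grads = self._backward(cache, np.asarray(y, dtype=int))
        return np.concatenate([grads[k].ravel() for k in sorted(grads)])


@dataclass
class TrainingResult:
    model: PCAFusedCNN
    history: pd.DataFrame
    train_indices: np.ndarray
    test_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# ---------------------------------------------------------------------------
# helpers


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid stride-1 convolution: (dW, db, dx)."""
    kh, kw = w.shape[-2:]
    patches = sliding_window_view(x, (kh, kw), axis=(-2, -1))
    dw = np.einsum("bchwij,bfhw->fcij", patches, dz)
    db = dz.sum(axis=(0, 2, 3))
    dz_pad = np.pad(dz, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    dz_patches = sliding_window_view(dz_pad, (kh, kw), axis=(-2, -1))
    w_flip = w[:, :, ::-1, ::-1]
    dx = np.einsum("bfhwij,fcij->bchw", dz_patches, w_flip)
    return dw, db, dx


def _top_components(A: np.ndarray, m: int) -> np.ndarray:
    """Top-m right singular vectors of an (n, d) activation matrix."""
    m = min(m, min(A.shape))
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    V = vt[:m].T  # (d, m)
    # sign convention: largest-magnitude entry of each direction positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] *= -1
    return V


def gradient_check(
    model: PCAFusedCNN,
    x: np.ndarray,
    y: np.ndarray,
    n_coords: int = 40,
    eps: float = 1e-5,
    seed: int = 0,
) -> tuple[float, int]:
    """Max relative error of backprop vs central finite differences.

    The loss surface has kinks (ReLU, max pooling); a coordinate whose
    finite-difference estimate changes materially between step sizes eps
    and 3·eps straddles a kink, where no derivative comparison is
    meaningful, and is skipped.  Returns (max relative error, number of
    coordinates actually compared).  Model parameters are restored.
    """
    g = model.flat_gradients(x, y)
    p0 = model.get_flat_params()
    rng = np.random.default_rng(seed)
    idx = rng.choice(p0.size, min(n_coords, p0.size), replace=False)

    def fd(i: int, e: float) -> float:
        p = p0.copy(); p[i] += e
        model.set_flat_params(p)
        lp = model.loss(x, y)
        p = p0.copy(); p[i] -= e
        model.set_flat_params(p)
        lm = model.loss(x, y)
        return (lp - lm) / (2 * e)

    worst, checked = 0.0, 0
    for i in idx:
        n1, n2 = fd(i, eps), fd(i, 3 * eps)
        if abs(n1 - n2) > 1e-6 + 1e-4 * abs(n1):
            continue  # kink between the two stencils
        checked += 1
        rel = abs(n1 - g[i]) / max(1e-8, abs(n1) + abs(g[i]))
        worst = max(worst, rel)
    model.set_flat_params(p0)
    return worst, checked


def _stratified_test_mask(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        n_test = max(1, int(round(fraction * idx.size)))
        mask[rng.permutation(idx)[:n_test]] = True
    return mask
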