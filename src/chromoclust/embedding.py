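"""Two-step dimension reduction: convolutional autoencoder, then t-SNE.

Every (resized, max-normalized) surface-distance matrix is treated as a
single-channel image.  An autoencoder with three conv+maxpool stages
(16/8/4 filters, 10x10 kernels, pool windows 5,5,2) compresses it to a latent
matrix whose flattened, z-scored vector feeds a 2D t-SNE (perplexity 200,
learning rate 1000).  The latent matrix has (side/50)^2 * 4 entries, i.e.,
625x fewer than the input image.

The autoencoder is implemented natively on NumPy/SciPy: convolutions run as
FFT products (same padding, stride 1), training uses Adadelta (no learning
rate to tune) on the summed-square reconstruction loss.  All randomness
(weight init, dataset shuffle) is driven by one seed, so the full embedding
is deterministic given (seed, spec, input order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from sklearn.manifold import (
    MDS,
    TSNE,
    Isomap,
    LocallyLinearEmbedding,
    SpectralEmbedding,
)
from sklearn.decomposition import PCA


@dataclass
class AutoencoderSpec:
    """Architecture and training constants (all overridable)."""

    encoder_filters: tuple[int, ...] = (16, 8, 4)
    decoder_filters: tuple[int, ...] = (4, 8, 16)
    kernel: int = 10
    pool: tuple[int, ...] = (5, 5, 2)
    upsample: tuple[int, ...] = (2, 5, 5)
    epochs: int = 15
    batch_size: int = 200
    rho: float = 0.95  # Adadelta decay
    eps: float = 1e-6


@dataclass
class LatentVectors:
    values: np.ndarray  # (n, d)
    standardized: bool = False


@dataclass
class Embedding2D:
    points: np.ndarray  # (n, 2)
    method: str
    seed: int | None = None


# ---------------------------------------------------------------------------
# FFT convolution primitives (same padding, stride 1, NCHW, kernel K x K)
# ---------------------------------------------------------------------------


def _fft2(x, p):
    return sfft.rfft2(x, s=(p, p))


def _conv_same_forward(x, w, b, p):
    """Cross-correlation with 'same' output (pad (K-1)//2 left, K//2 right)."""
    k = w.shape[-1]
    h = x.shape[-1]
    xf = _fft2(x, p)
    kf = _fft2(w[..., ::-1, ::-1], p)
    yf = np.einsum("ncij,fcij->nfij", xf, kf)
    y = sfft.irfft2(yf, s=(p, p))[..., k // 2 : k // 2 + h, k // 2 : k // 2 + h]
    return (y + b[None, :, None, None]).astype(np.float32), xf


def _conv_same_backward(dy, x, xf, w, p):
    """Gradients of the same-padding cross-correlation.

    Returns (dx, dw, db).  Index algebra: with left pad p0 = (K-1)//2,
    dx = full_conv(dy, w) sliced at offset p0, and dw[u, v] is the full
    convolution of the flipped input with dy evaluated at (H-1+p0-u),
    zero where that index is negative (taps falling entirely off the image).
    """
    k = w.shape[-1]
    h = x.shape[-1]
    p0 = (k - 1) // 2
    dyf = _fft2(dy, p)
    wf = _fft2(w, p)
    dxf = np.einsum("nfij,fcij->ncij", dyf, wf)
    dx = sfft.irfft2(dxf, s=(p, p))[..., p0 : p0 + h, p0 : p0 + h].astype(np.float32)

    xrf = _fft2(x[..., ::-1, ::-1], p)
    zf = np.einsum("ncij,nfij->fcij", xrf, dyf)
    z = sfft.irfft2(zf, s=(p, p))
    dw = np.zeros_like(w)
    for u in range(k):
        iu = h - 1 + p0 - u
        if iu < 0:
            continue
        for v in range(k):
            iv = h - 1 + p0 - v
            if iv < 0:
                continue
            dw[:, :, u, v] = z[:, :, iu, iv]
    db = dy.sum(axis=(0, 2, 3))
    return dx, dw.astype(np.float32), db.astype(np.float32)


def _maxpool_forward(x, size):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // size, size, w // size, size)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // size, w // size, size * size)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return y, arg


def _maxpool_backward(dy, arg, size, in_shape):
    n, c, h, w = in_shape
    flat = np.zeros((n, c, h // size, w // size, size * size), dtype=dy.dtype)
    np.put_along_axis(flat, arg[..., None], dy[..., None], axis=-1)
    xr = flat.reshape(n, c, h // size, w // size, size, size).transpose(0, 1, 2, 4, 3, 5)
    return xr.reshape(n, c, h, w)


def _upsample(x, size):
    return x.repeat(size, axis=2).repeat(size, axis=3)


def _upsample_backward(dy, size):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // size, size, w // size, size).sum(axis=(3, 5))


class _Adadelta:
    def __init__(self, rho, eps):
        self.rho, self.eps = rho, eps
        self.eg2 = {}
        self.ed2 = {}

    def step(self, key, param, grad):
        g2 = self.eg2.get(key, np.zeros_like(param))
        d2 = self.ed2.get(key, np.zeros_like(param))
        g2 = self.rho * g2 + (1 - self.rho) * grad * grad
        delta = -np.sqrt(d2 + self.eps) / np.sqrt(g2 + self.eps) * grad
        d2 = self.rho * d2 + (1 - self.rho) * delta * delta
        self.eg2[key], self.ed2[key] = g2, d2
        param += delta


class ConvAutoencoder:
    """Symmetric convolutional autoencoder over single-channel square images.

    Encoder: [conv(f, 10x10, same) + ReLU + maxpool] for (f, pool) in
    zip(encoder_filters, pool).  Decoder mirrors it with nearest-neighbour
    upsampling and ends in a 1-filter sigmoid conv, so outputs lie in [0, 1]
    and match the input shape.
    """

    def __init__(self, side: int, spec: AutoencoderSpec | None = None, seed: int = 0):
        if side % 50:
            raise ValueError(f"input side {side} is not a multiple of 50")
        self.side = side
        self.spec = spec or AutoencoderSpec()
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.history: list[float] = []
        self._build()

    def _glorot(self, f, c, k):
        limit = np.sqrt(6.0 / (c * k * k + f * k * k))
        return self.rng.uniform(-limit, limit, size=(f, c, k, k)).astype(np.float32)

    def _build(self):
        sp = self.spec
        k = sp.kernel
        c = 1
        for li, f in enumerate(sp.encoder_filters):
            self.params[f"enc{li}_w"] = self._glorot(f, c, k)
            self.params[f"enc{li}_b"] = np.zeros(f, dtype=np.float32)
            c = f
        dec = list(sp.decoder_filters) + [1]
        for li, f in enumerate(dec):
            self.params[f"dec{li}_w"] = self._glorot(f, c, k)
            self.params[f"dec{li}_b"] = np.zeros(f, dtype=np.float32)
            c = f

    # -- forward -----------------------------------------------------------

    def _forward(self, x, cache=None):
        sp = self.spec
        k = sp.kernel
        a = x[:, None, :, :].astype(np.float32)
        for li, pool in enumerate(sp.pool):
            p = sfft.next_fast_len(a.shape[-1] + k - 1)
            z, xf = _conv_same_forward(a, self.params[f"enc{li}_w"], self.params[f"enc{li}_b"], p)
            r = np.maximum(z, 0.0)
            y, arg = _maxpool_forward(r, pool)
            if cache is not None:
                cache.append(("enc", li, a, xf, z, r, arg, pool, p))
            a = y
        latent = a
        dec = list(sp.decoder_filters) + [1]
        ups = list(sp.upsample) + [None]
        for li, (f, up) in enumerate(zip(dec, ups)):
            p = sfft.next_fast_len(a.shape[-1] + k - 1)
            z, xf = _conv_same_forward(a, self.params[f"dec{li}_w"], self.params[f"dec{li}_b"], p)
            if li < len(dec) - 1:
                r = np.maximum(z, 0.0)
                y = _upsample(r, up)
            else:
                from scipy.special import expit

                r = expit(z)
                y = r
            if cache is not None:
                cache.append(("dec", li, a, xf, z, r, None, up, p))
            a = y
        return latent, a[:, 0]

    def reconstruct(self, x):
        return self._forward(np.asarray(x))[1]

    def encode_latent(self, x):
        """Latent feature maps (n, 4, side/50, side/50) for a stack of images."""
        x = np.asarray(x)
        if x.shape[-1] != self.side:
            raise ValueError(f"model was trained on side {self.side}, got {x.shape[-1]}")
        return self._forward(x)[0]

    # -- training ----------------------------------------------------------

    def _backward(self, dout, cache, grads):
        da = dout[:, None, :, :]
        for entry in reversed(cache):
            kind, li, a_in, xf, z, r, arg, aux, p = entry
            if kind == "dec":
                if li == len(self.spec.decoder_filters):
                    dz = da * r * (1.0 - r)  # sigmoid
                else:
                    dz = _upsample_backward(da, aux) * (z > 0)
                dx, dw, db = _conv_same_backward(dz, a_in, xf, self.params[f"dec{li}_w"], p)
                grads[f"dec{li}_w"] = grads.get(f"dec{li}_w", 0) + dw
                grads[f"dec{li}_b"] = grads.get(f"dec{li}_b", 0) + db
                da = dx
            else:
                dr = _maxpool_backward(da, arg, aux, r.shape)
                dz = dr * (z > 0)
                dx, dw, db = _conv_same_backward(dz, a_in, xf, self.params[f"enc{li}_w"], p)
                grads[f"enc{li}_w"] = grads.get(f"enc{li}_w", 0) + dw
                grads[f"enc{li}_b"] = grads.get(f"enc{li}_b", 0) + db
                da = dx

    def fit(self, matrices: np.ndarray, verbose: bool = False):
        """Train on a stack of images in [0, 1]; records per-epoch MSE."""
        x = np.asarray(matrices, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != x.shape[2]:
            raise ValueError("matrices must be a (n, side, side) stack")
        if x.shape[-1] != self.side:
            raise ValueError("matrix side does not match model")
        sp = self.spec
        order = self.rng.permutation(len(x))
        x = x[order]
        opt = _Adadelta(sp.rho, sp.eps)
        for epoch in range(sp.epochs):
            losses = []
            for start in range(0, len(x), sp.batch_size):
                xb = x[start : start + sp.batch_size]
                cache = []
                _, out = self._forward(xb, cache)
                diff = out - xb
                # loss: mean over samples of the squared Frobenius norm
                losses.append(float((diff**2).sum(axis=(1, 2)).mean()) * len(xb))
                grads: dict[str, np.ndarray] = {}
                self._backward(2.0 * diff / len(xb), cache, grads)
                for key, g in grads.items():
                    opt.step(key, self.params[key], g)
            self.history.append(sum(losses) / len(x))
            if verbose:
                print(f"epoch {epoch + 1}/{sp.epochs}  mse={self.history[-1]:.5f}")
        return self


def train_autoencoder(
    matrices: np.ndarray, spec: AutoencoderSpec | None = None, seed: int = 0,
    verbose: bool = False, max_restarts: int = 3,
) -> ConvAutoencoder:
    """Train the autoencoder on a stack of resized, normalized distance matrices.

    With a narrow bottleneck, training occasionally collapses onto the mean
    predictor (all bottleneck ReLU channels dead; the loss flatlines at the
    level of the trivial mean-image predictor).  Collapse is detected by
    comparing the final training loss with 0.9 x that baseline — the per-image
    squared deviation from the dataset mean image — and training restarts
    from a seed derived from (seed, attempt); the best attempt by final loss
    is kept.
    """
    x = np.asarray(matrices)
    if x.min() < -1e-6 or x.max() > 1 + 1e-6:
        raise ValueError("matrices must be normalized to [0, 1]")
    baseline = float(((x - x.mean(axis=0)) ** 2).sum(axis=(1, 2)).mean())
    best = None
    for attempt in range(max_restarts + 1):
        model = ConvAutoencoder(
            side=x.shape[-1], spec=spec, seed=seed if attempt == 0 else (seed, attempt)
        )
        model.fit(x, verbose=verbose)
        if best is None or model.history[-1] < best.history[-1]:
            best = model
        if model.history[-1] <= 0.9 * baseline:
            break
        warnings.warn(
            f"training attempt {attempt + 1} collapsed "
            f"(loss {model.history[-1]:.3g} vs mean-predictor {baseline:.3g}); restarting",
            stacklevel=2,
        )
    return best


def encode(model: ConvAutoencoder, matrices: np.ndarray) -> LatentVectors:
    """Flatten latent feature maps to one vector per matrix.

    Flatten order: spatial row-major, channels last, i.e., index
    (row, col, channel) — fixed so latents are reproducible.
    """
    x = np.asarray(matrices, dtype=np.float32)
    out = []
    step = 512  # bound memory for large stacks
    for start in range(0, len(x), step):
        lat = model.encode_latent(x[start : start + step])
        out.append(lat.transpose(0, 2, 3, 1).reshape(len(lat), -1))
    return LatentVectors(values=np.concatenate(out), standardized=False)


def standardize(latents: LatentVectors) -> LatentVectors:
    """Per-dimension z-scoring over the set; zero-variance dimensions go to 0."""
    v = np.asarray(latents.values, dtype=float)
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    out = np.zeros_like(v)
    nz = sd > 0
    out[:, nz] = (v[:, nz] - mu[nz]) / sd[nz]
    return LatentVectors(values=out, standardized=True)


def tsne_embed(
    latents: LatentVectors, perplexity: float = 200.0, learning_rate: float = 1000.0,
    seed: int = 0,
) -> Embedding2D:
    """2D t-SNE of the standardized latent vectors (KL-divergence embedding)."""
    v = np.asarray(latents.values, dtype=float)
    n = len(v)
    if n < 5:
        raise ValueError("need at least 5 points for t-SNE")
    if n <= 3 * perplexity:
        new = max(5.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} points; using {new:.0f}",
            stacklevel=2,
        )
        perplexity = new
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        random_state=seed,
        init="pca",
    )
    pts = ts.fit_transform(v)
    return Embedding2D(points=np.asarray(pts, dtype=float), method="tsne", seed=seed)


def alternative_embed(latents: LatentVectors, method: str, seed: int = 0) -> Embedding2D:
    """Generic 2D alternative-embedding hook (PCA/MDS/LLE/Isomap/Spectral/UMAP)."""
    v = np.asarray(latents.values, dtype=float)
    method_l = method.lower()
    if method_l == "pca":
        emb = PCA(n_components=2, random_state=seed).fit_transform(v)
    elif method_l == "mds":
        emb = MDS(n_components=2, random_state=seed, normalized_stress="auto").fit_transform(v)
    elif method_l == "lle":
        emb = LocallyLinearEmbedding(n_components=2, random_state=seed).fit_transform(v)
    elif method_l == "isomap":
        emb = Isomap(n_components=2).fit_transform(v)
    elif method_l == "spectralembedding":
        emb = SpectralEmbedding(n_components=2, random_state=seed).fit_transform(v)
    elif method_l == "umap":
        try:
            from umap import UMAP
        except ImportError as exc:  # pragma: no cover
            raise ImportError("umap-learn is required for the UMAP hook") from exc
        emb = UMAP(n_components=2, learning_rate=1.0, random_state=seed).fit_transform(v)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding2D(points=np.asarray(emb, dtype=float), method=method_l, seed=seed)
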