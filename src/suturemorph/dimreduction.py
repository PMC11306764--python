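"""Standardization, dimension reduction and the cross-validated
method comparison.

The N x 3p raw geometry matrix G0 (p semilandmarks per subject) is
column z-scored into G (population SD; the stored mean/SD pair is the
invertible standardization operator).  Reduction methods share one
interface -- ``transform`` to k scores and ``inverse_transform`` back to
the standardized space -- so reconstruction error can be measured
uniformly as the location mean deviation

    LMD(A, B) = mean_i | A_i - B_i |   (mm),

the average Euclidean distance between corresponding points after
inverse standardization.

Methods: classic PCA (SVD-based), kernel PCA with linear / cosine /
rbf / sigmoid / laplacian kernels (scikit-learn, with a kernel-ridge
pre-image map so reconstructions are computable), and a fully-connected
variational autoencoder implemented in NumPy with manual gradients and
Adam, trained full-batch with the reparameterization trick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import KernelPCA
from sklearn.metrics.pairwise import laplacian_kernel

from .types import ReducedModel, ShapeMatrix, ValidationError


# ----------------------------------------------------------- standardize

def standardize(G0: np.ndarray) -> ShapeMatrix:
    """Column z-scoring with population (divide-by-N) SD.

    Zero-variance columns pass through unscaled (SD treated as 1) and
    are flagged in ``constant_columns``.
    """
    G0 = np.asarray(G0, dtype=float)
    if G0.ndim != 2 or len(G0) < 2:
        raise ValidationError("need an (N >= 2) x 3p matrix")
    mean = G0.mean(axis=0)
    sd = G0.std(axis=0)          # population SD
    constant = sd == 0.0
    sd_safe = np.where(constant, 1.0, sd)
    G = (G0 - mean) / sd_safe
    return ShapeMatrix(G0=G0, mean=mean, sd=sd_safe, G=G, constant_columns=constant)


def shape_matrix_from_sets(shapes) -> ShapeMatrix:
    """Stack SemilandmarkSets into rows (x1, y1, z1, x2, ...) and z-score."""
    return standardize(np.stack([s.flat() for s in shapes]))


# ------------------------------------------------------------------ LMD

def lmd(A: np.ndarray, B: np.ndarray) -> float:
    """Location mean deviation between corresponding 3D point sets (mm)."""
    A = np.asarray(A, dtype=float).reshape(-1, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B, axis=1).mean())


# ------------------------------------------------------------ classic PCA

class PCAModel(ReducedModel):
    def transform(self, G: np.ndarray) -> np.ndarray:
        return np.atleast_2d(G) @ self.basis.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.basis


def fit_pca(G: np.ndarray, k: int) -> PCAModel:
    """Classic PCA of the standardized matrix via SVD.

    ``basis`` rows are the top-k orthonormal eigenvectors; ``scores``
    the N x k score matrix.  Component signs follow the convention that
    each component's largest-magnitude loading is positive.
    """
    G = np.asarray(G, dtype=float)
    N, p = G.shape
    if not 1 <= k <= min(N - 1, p):
        raise ValidationError(f"k={k} out of range [1, {min(N - 1, p)}]")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :len(s)]
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    return PCAModel(
        method="classic_pca",
        k=k,
        scores=(U[:, :k] * s[:k]),
        explained_variance_ratio=evr[:k],
        basis=Vt[:k],
    )


def components_for_variance(G: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest k whose components explain at least ``threshold`` of the
    variance of the standardized matrix."""
    full = fit_pca(G, min(len(G) - 1, G.shape[1]))
    cum = np.cumsum(full.explained_variance_ratio)
    return int(np.searchsorted(cum, threshold) + 1)


def reconstruct_subject(
    model: ReducedModel,
    Z: ShapeMatrix,
    scores_row: np.ndarray,
) -> np.ndarray:
    """Inverse-standardized geometry (p x 3) from one row of scores."""
    scores_row = np.asarray(scores_row, dtype=float).reshape(1, -1)
    if scores_row.shape[1] != model.k:
        raise ValidationError(
            f"scores length {scores_row.shape[1]} != model components {model.k}"
        )
    g = model.inverse_transform(scores_row)
    return Z.inverse(g).reshape(-1, 3)


# ------------------------------------------------------------- kernel PCA

_KPCA_KERNELS = ("linear", "cosine", "rbf", "sigmoid", "laplacian")


class KPCAModel(ReducedModel):
    def transform(self, G: np.ndarray) -> np.ndarray:
        return self.estimator.transform(np.atleast_2d(G))

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.estimator.inverse_transform(np.atleast_2d(scores))


def fit_kernel_pca(
    G: np.ndarray,
    kernel: str = "rbf",
    k: int = 10,
    gamma: float | None = None,
    coef0: float = 1.0,
    alpha: float = 1e-3,
) -> KPCAModel:
    """Kernel PCA with a learned pre-image map.

    Reconstruction goes through scikit-learn's inverse transform, a
    kernel ridge regression from feature space back to input space
    (ridge ``alpha``), so LMD is computable for every kernel.  Default
    ``gamma`` is 1/n_features for rbf/laplacian/sigmoid.
    """
    G = np.asarray(G, dtype=float)
    if kernel not in _KPCA_KERNELS:
        raise ValidationError(f"kernel must be one of {_KPCA_KERNELS}")
    if not 1 <= k < len(G):
        raise ValidationError(f"k={k} out of range [1, {len(G) - 1}]")
    if gamma is None:
        gamma = 1.0 / G.shape[1]
    if kernel == "laplacian":
        est = KernelPCA(
            n_components=k,
            kernel=lambda X, Y: laplacian_kernel(
                X.reshape(1, -1), Y.reshape(1, -1), gamma=gamma
            )[0, 0],
            fit_inverse_transform=True,
            alpha=alpha,
        )
    else:
        est = KernelPCA(
            n_components=k,
            kernel=kernel,
            gamma=None if kernel in ("linear", "cosine") else gamma,
            coef0=coef0,
            fit_inverse_transform=True,
            alpha=alpha,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # sigmoid may produce small negative eigenvalues
        scores = est.fit_transform(G)
    return KPCAModel(method=f"kernel_pca:{kernel}", k=k, scores=scores, estimator=est)


# ------------------------------------------------------------------- VAE

class _DenseVAE:
    """Fully-connected VAE trained full-batch with Adam (NumPy).

    tanh hidden layers, Gaussian reconstruction term 0.5 ||x - x^||^2
    plus the analytic KL to the unit normal, reparameterized sampling
    during training and the posterior mean at evaluation.
    """

    def __init__(self, n_in: int, latent: int, hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        def init(a, b):
            return rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))
        self.W1, self.b1 = init(hidden, n_in), np.zeros(hidden)
        self.W2, self.b2 = init(latent, hidden), np.zeros(latent)
        self.W3, self.b3 = init(latent, hidden), np.zeros(latent)
        self.W4, self.b4 = init(hidden, latent), np.zeros(hidden)
        self.W5, self.b5 = init(n_in, hidden), np.zeros(n_in)
        self.rng = rng

    def _params(self):
        return ["W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4", "W5", "b5"]

    def encode(self, X):
        h = np.tanh(X @ self.W1.T + self.b1)
        return h @ self.W2.T + self.b2, h @ self.W3.T + self.b3, h

    def decode(self, Zl):
        h2 = np.tanh(Zl @ self.W4.T + self.b4)
        return h2 @ self.W5.T + self.b5, h2

    def loss_and_grads(self, X):
        N = len(X)
        mu, logvar, h = self.encode(X)
        logvar = np.clip(logvar, -10.0, 10.0)
        eps = self.rng.standard_normal(mu.shape)
        z = mu + eps * np.exp(0.5 * logvar)
        xhat, h2 = self.decode(z)

        rec = 0.5 * ((xhat - X) ** 2).sum()
        kl = -0.5 * (1.0 + logvar - mu ** 2 - np.exp(logvar)).sum()
        loss = (rec + kl) / N

        d5 = (xhat - X) / N
        gW5, gb5 = d5.T @ h2, d5.sum(axis=0)
        da4 = (d5 @ self.W5) * (1 - h2 ** 2)
        gW4, gb4 = da4.T @ z, da4.sum(axis=0)
        dz = da4 @ self.W4
        dmu = dz + mu / N
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar) + 0.5 * (np.exp(logvar) - 1.0) / N
        gW2, gb2 = dmu.T @ h, dmu.sum(axis=0)
        gW3, gb3 = dlogvar.T @ h, dlogvar.sum(axis=0)
        da1 = (dmu @ self.W2 + dlogvar @ self.W3) * (1 - h ** 2)
        gW1, gb1 = da1.T @ X, da1.sum(axis=0)
        grads = dict(W1=gW1, b1=gb1, W2=gW2, b2=gb2, W3=gW3, b3=gb3,
                     W4=gW4, b4=gb4, W5=gW5, b5=gb5)
        return float(loss), grads


class VAEModel(ReducedModel):
    def transform(self, G: np.ndarray) -> np.ndarray:
        mu, _, _ = self.estimator.encode(np.atleast_2d(G))
        return mu

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        xhat, _ = self.estimator.decode(np.atleast_2d(scores))
        return xhat


def fit_vae(
    G: np.ndarray,
    latent_dim: int = 10,
    seed: int = 0,
    epochs: int = 300,
    hidden: int = 64,
    lr: float = 1e-2,
    arch: str = "dense",
) -> VAEModel:
    """Train the fully-connected VAE; deterministic for a fixed seed.

    Training stops early with a warning if the loss diverges.  The
    smoothed training-loss curve is stored as ``model.loss_curve``.
    """
    if arch != "dense":
        raise ValidationError(f"unsupported VAE architecture {arch!r}")
    G = np.asarray(G, dtype=float)
    net = _DenseVAE(G.shape[1], latent_dim, hidden, seed)
    m = {p: np.zeros_like(getattr(net, p)) for p in net._params()}
    v = {p: np.zeros_like(getattr(net, p)) for p in net._params()}
    b1, b2, epsilon = 0.9, 0.999, 1e-8
    curve = []
    for t in range(1, epochs + 1):
        loss, grads = net.loss_and_grads(G)
        curve.append(loss)
        if not np.isfinite(loss) or (len(curve) > 10 and loss > 100 * curve[0]):
            warnings.warn(f"VAE training diverged at epoch {t}; stopping early")
            break
        for p in net._params():
            g = grads[p]
            m[p] = b1 * m[p] + (1 - b1) * g
            v[p] = b2 * v[p] + (1 - b2) * g ** 2
            mh = m[p] / (1 - b1 ** t)
            vh = v[p] / (1 - b2 ** t)
            setattr(net, p, getattr(net, p) - lr * mh / (np.sqrt(vh) + epsilon))
    model = VAEModel(method="vae:dense", k=latent_dim,
                     scores=None, estimator=net)
    model.scores = model.transform(G)
    model.loss_curve = np.asarray(curve)
    return model


# ------------------------------------------------------ method registry

def fit_method(spec, G: np.ndarray, k: int, seed: int) -> ReducedModel:
    """Fit one reduction method from a (name, kwargs) spec."""
    name, kwargs = (spec, {}) if isinstance(spec, str) else (spec[0], dict(spec[1]))
    if name == "classic_pca":
        return fit_pca(G, k)
    if name == "kernel_pca":
        return fit_kernel_pca(G, k=k, **kwargs)
    if name == "vae":
        kwargs.setdefault("seed", seed)
        return fit_vae(G, latent_dim=k, **kwargs)
    raise ValidationError(f"unknown reduction method {name!r}")


def method_label(spec) -> str:
    name, kwargs = (spec, {}) if isinstance(spec, str) else (spec[0], dict(spec[1]))
    if name == "kernel_pca":
        return f"kernel_pca[{kwargs.get('kernel', 'rbf')}]"
    return name


DEFAULT_METHODS = (
    "classic_pca",
    ("kernel_pca", {"kernel": "linear"}),
    ("kernel_pca", {"kernel": "cosine"}),
    ("kernel_pca", {"kernel": "rbf"}),
    ("kernel_pca", {"kernel": "sigmoid"}),
    ("kernel_pca", {"kernel": "laplacian"}),
    ("vae", {}),
)


# ------------------------------------------------------------ k-fold CV

def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Random, near-equal fold partition (e.g. 9x7 + 1x6 for n=69)."""
    if n < folds:
        raise ValidationError(f"dataset size {n} < folds {folds}")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]


def kfold_compare(
    G0: np.ndarray,
    methods=DEFAULT_METHODS,
    folds: int = 10,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-method mean train/test reconstruction LMD over a k-fold split.

    Standardization is fitted on each fold's training subjects and the
    held-out subjects are projected, reconstructed and inverse
    standardized before LMD is measured in mm.  A method failure marks
    its cells NaN; the run continues.
    """
    G0 = np.asarray(G0, dtype=float)
    folds_idx = kfold_indices(len(G0), folds, seed)
    rows = []
    for spec in methods:
        train_err, test_err = [], []
        failed = False
        for f, test in enumerate(folds_idx):
            train = np.setdiff1d(np.arange(len(G0)), test)
            Z = standardize(G0[train])
            k_fold = min(k, len(train) - 1)   # per-fold feasible rank
            try:
                model = fit_method(spec, Z.G, k_fold, seed + f)
                for idx_set, sink in ((train, train_err), (test, test_err)):
                    Gs = (G0[idx_set] - Z.mean) / Z.sd
                    rec = Z.inverse(model.inverse_transform(model.transform(Gs)))
                    for i, row in enumerate(idx_set):
                        sink.append(lmd(rec[i], G0[row]))
            except Exception as exc:    # noqa: BLE001 -- per-cell failure policy
                warnings.warn(f"{method_label(spec)} failed in fold {f}: {exc}")
                failed = True
                break
        rows.append({
            "method": method_label(spec),
            "train_lmd": np.nan if failed else float(np.mean(train_err)),
            "test_lmd": np.nan if failed else float(np.mean(test_err)),
        })
    return pd.DataFrame(rows).set_index("method")
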