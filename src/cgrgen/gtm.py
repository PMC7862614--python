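"""Generative topographic mapping of the autoencoder latent space.

Standard GTM: a regular K-node 2-D grid is mapped into data space through M
Gaussian radial basis functions and a linear weight matrix W; the data
density is an equal-weight mixture of isotropic Gaussians centered on the
node images with common precision beta.  Fitting is expectation-maximization
with PCA-based initialization; the log-likelihood is asserted non-decreasing
at every iteration.

Class landscapes color each node by the responsibility-weighted label
fractions of the data; a zone is the node set exceeding purity and density
thresholds, and latent sampling draws from the zone nodes' Gaussian
components — the generative path of the reaction-generation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ArgumentError, DegenerateDataError, EmptyZoneError


@dataclass
class GTMModel:
    nodes: np.ndarray  # (K, 2) latent grid
    centers: np.ndarray  # (M, 2) RBF centers
    sigma: float  # common RBF width
    W: np.ndarray  # (M+1, D) mapping weights (bias row last)
    beta: float  # noise precision
    log_likelihoods: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.nodes)

    def phi(self, points=None) -> np.ndarray:
        pts = self.nodes if points is None else points
        d2 = cdist(pts, self.centers, "sqeuclidean")
        phi = np.exp(-d2 / (2.0 * self.sigma**2))
        return np.hstack([phi, np.ones((len(pts), 1))])

    def node_images(self) -> np.ndarray:
        """Images of the grid nodes in data space, shape (K, D)."""
        return self.phi() @ self.W

    def save(self, path) -> None:
        np.savez(
            path,
            nodes=self.nodes,
            centers=self.centers,
            sigma=np.array(self.sigma),
            W=self.W,
            beta=np.array(self.beta),
            log_likelihoods=np.array(self.log_likelihoods),
        )

    @classmethod
    def load(cls, path) -> "GTMModel":
        d = np.load(path)
        return cls(
            nodes=d["nodes"],
            centers=d["centers"],
            sigma=float(d["sigma"]),
            W=d["W"],
            beta=float(d["beta"]),
            log_likelihoods=list(d["log_likelihoods"]),
        )


def _grid(k: int) -> np.ndarray:
    axis = np.linspace(-1.0, 1.0, k)
    xx, yy = np.meshgrid(axis, axis)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _log_likelihood(Y, X, beta):
    D = X.shape[1]
    d2 = cdist(Y, X, "sqeuclidean")  # (K, N)
    logp = -0.5 * beta * d2 + 0.5 * D * np.log(beta / (2 * np.pi)) - np.log(len(Y))
    m = logp.max(axis=0)
    return float((m + np.log(np.exp(logp - m).sum(axis=0))).sum())


def _responsibilities(Y, X, beta):
    d2 = cdist(Y, X, "sqeuclidean")
    logr = -0.5 * beta * d2
    logr -= logr.max(axis=0)
    R = np.exp(logr)
    R /= R.sum(axis=0)
    return R  # (K, N)


def fit(
    vectors,
    grid_k: int = 15,
    rbf_m: int = 7,
    width_factor: float = 2.0,
    reg: float = 1e-3,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
) -> GTMModel:
    """Fit a GTM by EM over latent vectors (rows).

    ``width_factor`` scales the RBF width relative to the center spacing;
    ``reg`` sets the fixed Gaussian weight prior (alpha = reg * initial
    beta).  The per-iteration objective (log-likelihood plus weight prior)
    is recorded in ``log_likelihoods`` and asserted non-decreasing;
    all-identical data raises DegenerateDataError.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ArgumentError("need a 2-D array with at least two vectors")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateDataError("latent vectors are all identical")
    N, D = X.shape
    nodes = _grid(grid_k)
    centers = _grid(rbf_m)
    spacing = 2.0 / (rbf_m - 1) if rbf_m > 1 else 2.0
    sigma = width_factor * spacing
    model = GTMModel(nodes, centers, sigma, W=None, beta=None)
    Phi = model.phi()

    # PCA initialization: map the grid onto the first two principal axes
    mean = X.mean(axis=0)
    Xc = X - mean
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scale = s[:2] / np.sqrt(N)
    targets = nodes @ (vt[:2] * scale[:, None]) + mean
    W, *_ = np.linalg.lstsq(Phi, targets, rcond=None)
    Y = Phi @ W
    # initial beta: larger of the 3rd PCA eigenvalue and half the mean
    # squared distance between neighboring node images
    lam3 = (s[2] ** 2 / N) if len(s) > 2 else 0.0
    d_nodes = cdist(Y, Y, "sqeuclidean")
    np.fill_diagonal(d_nodes, np.inf)
    inv_beta = max(lam3, d_nodes.min(axis=1).mean() / 2.0, 1e-6)
    beta = 1.0 / inv_beta
    # fixed Gaussian weight prior; holding alpha constant (rather than
    # alpha/beta) keeps the penalized objective a single function that
    # generalized EM increases monotonically
    alpha = reg * beta

    lls = []
    for _it in range(max_iter):
        ll = _log_likelihood(Y, X, beta) - 0.5 * alpha * float((W**2).sum())
        if lls and ll < lls[-1] - 1e-9 * max(1.0, abs(lls[-1])):
            raise AssertionError("EM objective decreased")
        converged = bool(lls) and abs(ll - lls[-1]) < tol * max(1.0, abs(ll))
        lls.append(ll)
        if converged:
            break
        R = _responsibilities(Y, X, beta)
        G = R.sum(axis=1)
        A = (Phi * G[:, None]).T @ Phi + (alpha / beta) * np.eye(Phi.shape[1])
        B = Phi.T @ (R @ X)
        W = np.linalg.solve(A, B)
        Y = Phi @ W
        d2 = cdist(Y, X, "sqeuclidean")
        beta = N * D / float((R * d2).sum())
    model.W = W
    model.beta = beta
    model.log_likelihoods = lls
    return model


def responsibilities(model: GTMModel, vectors) -> np.ndarray:
    """Posterior node distribution per point, shape (N, K); rows sum to 1."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.W.shape[1]:
        raise ArgumentError(
            f"dimension mismatch: vectors have {X.shape[1]}, model {model.W.shape[1]}"
        )
    return _responsibilities(model.node_images(), X, model.beta).T


@dataclass
class ClassLandscape:
    classes: tuple
    density: np.ndarray  # (K,)
    probabilities: np.ndarray  # (K, n_classes); NaN rows where density == 0

    def to_rows(self, model: GTMModel):
        for k in range(len(self.density)):
            yield (
                k,
                float(model.nodes[k, 0]),
                float(model.nodes[k, 1]),
                float(self.density[k]),
                *(float(p) for p in self.probabilities[k]),
            )


def class_landscape(model: GTMModel, vectors, labels) -> ClassLandscape:
    """Responsibility-weighted class probabilities and density per node."""
    labels = list(labels)
    X = np.asarray(vectors, dtype=np.float64)
    if len(labels) != len(X):
        raise ArgumentError("labels and vectors must align")
    classes = tuple(sorted(set(labels)))
    R = responsibilities(model, X)  # (N, K)
    density = R.sum(axis=0)
    probs = np.full((model.K, len(classes)), np.nan)
    for ci, cls in enumerate(classes):
        mask = np.array([l == cls for l in labels], dtype=float)
        weighted = (R * mask[:, None]).sum(axis=0)
        occupied = density > 0
        probs[occupied, ci] = weighted[occupied] / density[occupied]
    return ClassLandscape(classes, density, probs)


def select_zone(
    landscape: ClassLandscape,
    cls,
    min_purity: float = 0.9,
    min_density: float = 1.0,
) -> np.ndarray:
    """Node indices whose class probability and density meet the thresholds."""
    if cls not in landscape.classes:
        raise ArgumentError(f"unknown class {cls!r}; have {landscape.classes}")
    ci = landscape.classes.index(cls)
    with np.errstate(invalid="ignore"):
        keep = (landscape.density >= min_density) & (
            landscape.probabilities[:, ci] >= min_purity
        )
    nodes = np.flatnonzero(keep)
    if len(nodes) == 0:
        raise EmptyZoneError(
            f"no node with purity >= {min_purity} and density >= {min_density}"
        )
    return nodes


def sample_latent(model: GTMModel, zone, n: int, seed: int = 0) -> np.ndarray:
    """Draw latent vectors from the zone's equal-weight Gaussian mixture.

    Each draw picks a zone node uniformly and samples N(node image,
    1/beta * I).
    """
    zone = np.asarray(zone, dtype=int)
    if n <= 0:
        raise ArgumentError("n must be positive")
    if zone.size == 0:
        raise ArgumentError("empty zone")
    rng = np.random.default_rng(seed)
    images = model.node_images()[zone]
    picks = rng.integers(0, len(zone), size=n)
    noise = rng.normal(0.0, np.sqrt(1.0 / model.beta), size=(n, images.shape[1]))
    return images[picks] + noise
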