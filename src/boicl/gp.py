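"""Gaussian-process comparison arm on reduced text embeddings.

High-dimensional text embeddings make GP training ill-conditioned in the
small-data regime, so the GP arm first reduces them with Isomap (default
32 output dimensions), then fits a stationary RBF kernel whose length
scale and amplitude are chosen by marginal-likelihood maximization. The
GP exposes the same (mu, sigma) predict contract as the ICL surrogate so
the two plug into an identical campaign loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy.sparse.csgraph import connected_components
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .errors import ConnectivityError


class ReducerConfig(BaseModel):
    """Isomap manifold reduction of embedding vectors."""

    target_dim: int = Field(default=32, ge=1)
    n_neighbors: int = Field(default=10, ge=1)


class GPConfig(BaseModel):
    """Kernel hyperparameters for the GP surrogate.

    With ``optimize=True`` (default) the amplitude and length scale are
    refit by maximizing the log marginal likelihood; with
    ``optimize=False`` the stated values are used as-is, which makes the
    posterior exactly reproducible by the closed-form GP equations.
    """

    amplitude: float = Field(default=1.0, gt=0.0)
    length_scale: float = Field(default=1.0, gt=0.0)
    noise: float = Field(default=1e-8, ge=0.0)
    optimize: bool = True
    normalize_y: bool = True


def reduce_dimensions(embeddings: np.ndarray, config: ReducerConfig) -> np.ndarray:
    """Isomap-reduce an (n, d) embedding matrix to ``target_dim`` columns.

    Deterministic given the input order and config. Inputs already at or
    below the target dimension are returned unchanged (nothing to
    reduce). A disconnected neighborhood graph raises
    :class:`~boicl.errors.ConnectivityError` advising a larger
    ``n_neighbors``.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    if X.shape[1] <= config.target_dim:
        return X.copy()
    if X.shape[0] <= config.n_neighbors:
        raise ValueError(
            f"need more points ({X.shape[0]}) than n_neighbors ({config.n_neighbors})"
        )
    graph = kneighbors_graph(X, config.n_neighbors, mode="connectivity")
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ConnectivityError(
            f"neighborhood graph has {n_comp} components; increase n_neighbors "
            f"(currently {config.n_neighbors})"
        )
    iso = Isomap(n_neighbors=config.n_neighbors, n_components=config.target_dim)
    return iso.fit_transform(X)


def _build_kernel(config: GPConfig):
    kernel = ConstantKernel(config.amplitude, constant_value_bounds=(1e-6, 1e6)) * RBF(
        config.length_scale, length_scale_bounds=(1e-4, 1e4)
    )
    if config.optimize and config.noise > 0:
        kernel = kernel + WhiteKernel(config.noise, noise_level_bounds=(1e-12, 1e2))
    return kernel


def gp_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: GPConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation at the test points.

    Ill-conditioned kernel matrices are handled by escalating jitter on
    the diagonal (1e-10 up to 1e-2) before failing.
    """
    config = config or GPConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    if X_train.ndim == 1:
        X_train = X_train[:, None]
    if X_test.ndim == 1:
        X_test = X_test[:, None]
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training points")

    jitter = max(config.noise, 1e-10)
    last_err: Exception | None = None
    while jitter <= 1e-2:
        try:
            gp = GaussianProcessRegressor(
                kernel=_build_kernel(config),
                alpha=jitter,
                optimizer="fmin_l_bfgs_b" if config.optimize else None,
                normalize_y=config.normalize_y,
                n_restarts_optimizer=2 if config.optimize else 0,
                random_state=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X_train, y_train)
                mu, sigma = gp.predict(X_test, return_std=True)
            return mu, np.maximum(sigma, 0.0)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare path
            last_err = err
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        f"kernel matrix remained ill-conditioned up to jitter 1e-2: {last_err}"
    )


@dataclass
class GPSurrogate:
    """Stateful wrapper giving the GP the surrogate predict contract.

    Holds the reduced embedding coordinates of the full pool (indexed by
    candidate id) so campaign code can train on memory and score
    unlabeled candidates without re-reducing.
    """

    coords: dict[str, np.ndarray]
    config: GPConfig

    @classmethod
    def from_pool(cls, pool, reducer: ReducerConfig | None = None,
                  gp_config: GPConfig | None = None) -> "GPSurrogate":
        reducer = reducer or ReducerConfig()
        reduced = reduce_dimensions(pool.embedding_matrix(), reducer)
        # standardize coordinates so the default length-scale prior is sane
        scale = reduced.std(axis=0)
        scale[scale == 0] = 1.0
        reduced = (reduced - reduced.mean(axis=0)) / scale
        coords = {c.id: reduced[i] for i, c in enumerate(pool)}
        return cls(coords=coords, config=gp_config or GPConfig())

    def predict(self, memory, candidates) -> tuple[np.ndarray, np.ndarray]:
        X_train = np.stack([self.coords[ex.candidate.id] for ex in memory])
        y_train = np.array([ex.label for ex in memory])
        X_test = np.stack([self.coords[c.id] for c in candidates])
        return gp_fit_predict(X_train, y_train, X_test, self.config)
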