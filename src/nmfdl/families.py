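"""Concrete model families for the DL engine.

Families here cover the generic building blocks: an isotropic Gaussian
mean model (the textbook mixture component used for oracle checks), a
uniform-amplitude clutter model and a Gaussian background model (two ways
of absorbing unstructured signal), and the Bernoulli object-presence model
used for situation learning.  The phase-cone family lives in
:mod:`nmfdl.cones` and the paired-channel family in :mod:`nmfdl.dual`.
"""

from __future__ import annotations

import numpy as np

from .core import InputError, ModelFamily

#: Bernoulli probabilities are clamped to (P_CLAMP, 1 - P_CLAMP).
P_CLAMP = 1e-6


# ---------------------------------------------------------------------------
# Shared Bernoulli primitives (reused by the dual-channel family)
# ---------------------------------------------------------------------------


def clamp_p(p: np.ndarray, eps: float = P_CLAMP) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def bernoulli_log_lik(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log prod_i p_i^x_i (1-p_i)^(1-x_i) per row of X, in log space."""
    w = np.log(p) - np.log1p(-p)
    return X @ w + np.log1p(-p).sum()


def bernoulli_update(X: np.ndarray, weights: np.ndarray, eps: float = P_CLAMP) -> np.ndarray:
    """Weighted Bernoulli MLE p_i = sum_n w_n x_ni / sum_n w_n, clamped."""
    return clamp_p((weights @ X) / weights.sum(), eps)


# ---------------------------------------------------------------------------
# Gaussian mean family
# ---------------------------------------------------------------------------


class GaussianMeanFamily(ModelFamily):
    """Isotropic Gaussian: predicted signal = mean vector, spread = variance.

    l(n|m) is the multivariate normal density of X(n) with mean S_m and
    covariance spread * I.

    The spread update is annealed: the variance may shrink by at most the
    factor ``anneal`` per iteration on its way down to the weighted MLE.
    Since the weighted likelihood is unimodal in the variance, any value
    between the old one and the MLE does not decrease it, so the engine's
    monotonicity contract is kept while the models cool down gradually from
    vague to crisp instead of jumping straight to the high-temperature
    symmetric fixed point.
    """

    name = "gaussian"

    def __init__(self, dim: int, var_floor: float = 1e-8, jitter: float = 1.0,
                 anneal: float = 0.9, init_var_frac: float = 0.5):
        self.dim = int(dim)
        self.var_floor = float(var_floor)
        self.jitter = float(jitter)
        self.anneal = float(anneal)
        # Initial vagueness sits just below the symmetry-breaking temperature
        # (for balanced well-separated clusters the critical variance is about
        # the global variance), so cooling differentiates the models instead
        # of freezing them at the high-temperature symmetric fixed point.
        self.init_var_frac = float(init_var_frac)

    @property
    def n_free_params(self) -> int:
        return self.dim + 1  # mean + shared variance

    def validate_datum(self, x: np.ndarray, params: np.ndarray) -> None:
        if x.shape[-1] != len(params):
            raise InputError(f"datum dimension {x.shape[-1]} != model dimension {len(params)}")

    def predict(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        return np.broadcast_to(params, X.shape)

    def log_cond_similarity(self, params: np.ndarray, spread: float, X: np.ndarray) -> np.ndarray:
        if spread <= 0:
            raise InputError(f"spread must be positive, got {spread}")
        d = X.shape[1]
        sq = ((X - params) ** 2).sum(axis=1)
        return -0.5 * d * np.log(2.0 * np.pi * spread) - sq / (2.0 * spread)

    def update(self, params, spread, X, weights):
        wsum = weights.sum()
        mean = weights @ X / wsum
        sq = ((X - mean) ** 2).sum(axis=1)
        var_ml = (weights @ sq) / (wsum * X.shape[1])
        var = max(var_ml, self.anneal * spread)  # cool down gradually
        return mean, float(max(var, self.var_floor))

    def spawn_vague(self, X, rng):
        mean = X.mean(axis=0)
        var = float(X.var()) or 1.0
        mean = mean + self.jitter * np.sqrt(var) * rng.standard_normal(X.shape[1])
        return mean, self.init_var_frac * var

    def merge_distance(self, pa, sa, pb, sb):
        scale = 0.5 * (np.sqrt(sa) + np.sqrt(sb)) + 1e-12
        d_centers = np.linalg.norm(pa - pb) / scale
        d_spread = abs(np.log(sa / sb)) / np.log(4.0)
        return max(2.0 * d_centers, d_spread)

    def spawn_from_datum(self, x, X, rng):
        var = float(X.var()) or 1.0
        return np.array(x, dtype=float, copy=True), 0.25 * var


# ---------------------------------------------------------------------------
# Background / clutter families
# ---------------------------------------------------------------------------


class UniformClutterFamily(ModelFamily):
    """Spatially uniform clutter with uniform amplitude density 1/(hi - lo).

    params = [lo, hi]; the density applies to the signal column
    (``value_col``, default the last column of the data field).  No free
    parameters: the range is pinned to the data at spawn time.
    """

    name = "uniform_clutter"

    def __init__(self, value_col: int = -1, lo: float | None = None, hi: float | None = None):
        self.value_col = value_col
        self.lo = lo
        self.hi = hi

    @property
    def n_free_params(self) -> int:
        return 0

    def validate_datum(self, x, params):
        pass

    def predict(self, params, X):
        return np.full(X.shape[0], 0.5 * (params[0] + params[1]))

    def log_cond_similarity(self, params, spread, X):
        lo, hi = params
        v = X[:, self.value_col]
        out = np.full(X.shape[0], -np.log(hi - lo))
        out[(v < lo) | (v > hi)] = -np.inf
        return out

    def update(self, params, spread, X, weights):
        return params, spread  # no free parameters

    def spawn_vague(self, X, rng):
        v = X[:, self.value_col]
        lo = self.lo if self.lo is not None else float(v.min())
        hi = self.hi if self.hi is not None else float(v.max())
        if hi <= lo:
            hi = lo + 1.0
        return np.array([lo, hi]), 1.0


class GaussianBackgroundFamily(ModelFamily):
    """Spatially uniform background: signal column ~ Normal(mu, spread).

    Models additive sensor noise; two free parameters (mu, variance).
    """

    name = "gaussian_background"

    def __init__(self, value_col: int = -1, var_floor: float = 1e-8):
        self.value_col = value_col
        self.var_floor = float(var_floor)

    @property
    def n_free_params(self) -> int:
        return 2

    def validate_datum(self, x, params):
        pass

    def predict(self, params, X):
        return np.full(X.shape[0], params[0])

    def log_cond_similarity(self, params, spread, X):
        if spread <= 0:
            raise InputError(f"spread must be positive, got {spread}")
        v = X[:, self.value_col]
        return -0.5 * np.log(2.0 * np.pi * spread) - (v - params[0]) ** 2 / (2.0 * spread)

    def update(self, params, spread, X, weights):
        v = X[:, self.value_col]
        wsum = weights.sum()
        mu = float(weights @ v / wsum)
        var = max(float(weights @ (v - mu) ** 2 / wsum), self.var_floor)
        return np.array([mu]), var

    def spawn_vague(self, X, rng):
        v = X[:, self.value_col]
        return np.array([float(v.mean())]), float(v.var()) or 1.0


# ---------------------------------------------------------------------------
# Bernoulli object-presence family
# ---------------------------------------------------------------------------


class BernoulliFamily(ModelFamily):
    """Binary-vector model: each object present independently with rate p_i.

    The vagueness of a component lives in p itself (p = 0.5 is maximally
    vague); the spread slot is a fixed placeholder.
    """

    name = "bernoulli"

    def __init__(self, dim: int, eps: float = P_CLAMP, jitter: float = 0.02):
        self.dim = int(dim)
        self.eps = float(eps)
        self.jitter = float(jitter)

    @property
    def n_free_params(self) -> int:
        return self.dim

    def validate_datum(self, x, params):
        if x.shape[-1] != len(params):
            raise InputError(f"datum dimension {x.shape[-1]} != model dimension {len(params)}")

    def predict(self, params, X):
        return np.broadcast_to(params, X.shape)

    def log_cond_similarity(self, params, spread, X):
        return bernoulli_log_lik(X, params)

    def update(self, params, spread, X, weights):
        return bernoulli_update(X, weights, self.eps), spread

    def spawn_vague(self, X, rng):
        p = 0.5 + self.jitter * (rng.random(X.shape[1]) - 0.5)
        return clamp_p(p, self.eps), 1.0

    def merge_distance(self, pa, sa, pb, sb):
        return float(np.max(np.abs(pa - pb))) / 0.5

    def spawn_from_datum(self, x, X, rng):
        # Neighborhood seeding: a candidate copied from one row would commit
        # to that row's incidental objects and merely memorize it.  Average
        # the rows that share unusually many objects with the anchor (above
        # the midpoint of the median and maximum overlap) — for a planted
        # type these are exactly its instances, and the incidental objects
        # wash out to their marginal rate.
        x = np.asarray(x, dtype=float)
        overlap = X @ x
        # the largest overlap is the anchor row itself; scale the cut by the
        # best genuine neighbour instead
        second = np.partition(overlap, -2)[-2] if len(overlap) > 1 else overlap.max()
        thr = 0.5 * (np.median(overlap) + second)
        sel = overlap >= thr
        if sel.sum() >= 2:
            return clamp_p(X[sel].mean(axis=0), self.eps), 1.0
        return clamp_p(0.5 + 0.7 * (x - 0.5), self.eps), 1.0
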