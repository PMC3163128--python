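"""Generic neural-modeling-fields / dynamic-logic (NMF-DL) estimation engine.

The engine fits a mixture of parametric "concept models" to a field of
bottom-up signals by an annealed, vague-to-crisp EM-style fixed-point
iteration.  The objective is the total log-similarity

    log L = sum_n log sum_m r(m) l(n|m),

where ``l(n|m)`` is the conditional similarity of datum ``n`` under model
``m`` (supplied by a pluggable :class:`ModelFamily`) and ``r(m)`` are prior
rates.  Association variables

    f(m|n) = r(m) l(n|m) / sum_m' r(m') l(n|m')

drive responsibility-weighted parameter updates (the fixed point of the
gradient-flow dynamics).  A "skeptic" complexity penalty and a store of
dormant, maximally vague models provide data-driven model activation and
pruning, so the number of concept models is itself estimated.

Monotonicity contract: between structural changes of the model roster the
recorded log-similarity trace is non-decreasing (standard EM argument; the
parameter, spread and rate updates are all exact or guarded constrained
M-steps).  Iterations at which the roster changes (merge / prune /
activate) are flagged in :attr:`FitState.structural_iterations`; there the
*penalized* similarity is guaranteed not to decrease instead, because a
removal is only accepted when its exact log-likelihood cost is covered by
the parameter-count penalty it releases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger("nmfdl")

# ---------------------------------------------------------------------------
# Constants (engine-wide numerical policy)
# ---------------------------------------------------------------------------

#: Floor rate pinned on dormant models so they stay in the competition and
#: can re-emerge; kept tiny so the active mixture is essentially unaffected.
EPS_R = 1e-6

#: A model whose total association weight falls below this floor is left
#: unchanged by the parameter update and flagged for deactivation review.
EPS_W = 1e-8

#: Relative tolerance for the per-iteration monotonicity assertion.
MONO_RTOL = 1e-8

ACTIVE = "active"
DORMANT = "dormant"


class NMFDLError(Exception):
    """Base class for engine errors."""


class InputError(NMFDLError):
    """Invalid data or argument shapes/values."""


class StateError(NMFDLError):
    """Operation called on an invalid model-set state."""


class MonotonicityError(NMFDLError):
    """The log-similarity decreased at a fixed-roster iteration."""


# ---------------------------------------------------------------------------
# Data field
# ---------------------------------------------------------------------------


class DataField:
    """An ordered collection of N bottom-up signal vectors X(n) of dimension D."""

    def __init__(self, X: np.ndarray, binary: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise InputError(f"data must be a non-empty (N, D) array, got shape {X.shape}")
        if binary:
            finite = X[np.isfinite(X)]
            if not np.all((finite == 0.0) | (finite == 1.0)):
                raise InputError("binary data field requires all entries in {0, 1}")
        self.X = X
        self.binary = binary

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.n_samples


# ---------------------------------------------------------------------------
# Model family contract
# ---------------------------------------------------------------------------


class ModelFamily(ABC):
    """Contract a concrete concept-model class fulfils.

    A family defines the predicted signal, the conditional similarity
    l(n|m), the responsibility-weighted parameter update (the fixed point of
    the NMF dynamics for this family), and how to spawn a maximally vague
    component.
    """

    name: str = "family"

    @property
    @abstractmethod
    def n_free_params(self) -> int:
        """Number of free parameters per component (for the skeptic penalty)."""

    @abstractmethod
    def predict(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Expected signal M_m(S_m, n) for every sample in X."""

    @abstractmethod
    def log_cond_similarity(self, params: np.ndarray, spread: float, X: np.ndarray) -> np.ndarray:
        """log l(n|m) for every sample; shape (N,)."""

    @abstractmethod
    def update(
        self, params: np.ndarray, spread: float, X: np.ndarray, weights: np.ndarray
    ) -> tuple[np.ndarray, float]:
        """Weighted maximum-similarity update of (params, spread).

        Implementations must not decrease the weighted conditional
        log-similarity sum(w * log l); closed forms satisfy this exactly,
        iterative updates must guard it.
        """

    @abstractmethod
    def spawn_vague(self, X: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        """A maximally vague (params, spread) pair for this data field."""

    def merge_distance(
        self,
        params_a: np.ndarray,
        spread_a: float,
        params_b: np.ndarray,
        spread_b: float,
    ) -> float:
        """Normalized distance between two components; < 1 means duplicates.

        Default: never merge.
        """
        return np.inf

    def spawn_from_datum(
        self, x: np.ndarray, X: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, float]:
        """A candidate component seeded at a poorly-explained datum.

        Used by the admission test for dormant models: a fully vague
        candidate has exponentially small density against adapted models in
        high dimension, so candidates are anchored at data the current
        mixture explains worst.  Default falls back to a vague spawn.
        """
        return self.spawn_vague(X, rng)

    def adapt_candidate(
        self,
        params: np.ndarray,
        spread: float,
        X: np.ndarray,
        log_mix: np.ndarray,
        pi: float,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, float]:
        """Privately adapt an admission candidate against the active mixture.

        Runs a few EM steps on the candidate's responsibilities under an
        admission prior ``pi``; families may override to localize the
        adaptation.  The engine then decides admission by the penalized
        insertion gain, not by these responsibilities.
        """
        for _ in range(8):
            logl_c = self.log_cond_similarity(params, spread, X)
            with np.errstate(over="ignore"):
                ratio = np.exp(np.minimum(log_mix - logl_c, 700.0))
            resp = 1.0 / (1.0 + ((1.0 - pi) / pi) * ratio)
            if resp.sum() <= 0.0:
                break
            params, spread = self.update(params, spread, X, resp)
        return params, spread

    def validate_datum(self, x: np.ndarray, params: np.ndarray) -> None:
        """Hook for dimension checks in the scalar similarity wrapper."""


@dataclass
class ModelComponent:
    """One top-down concept model: parameters, prior rate, vagueness, status."""

    index: int
    family: ModelFamily
    params: np.ndarray
    spread: float
    r: float
    status: str = ACTIVE
    is_background: bool = False
    flagged: bool = False  # starved during the last parameter update

    def copy(self) -> "ModelComponent":
        return ModelComponent(
            index=self.index,
            family=self.family,
            params=np.array(self.params, copy=True),
            spread=float(self.spread),
            r=float(self.r),
            status=self.status,
            is_background=self.is_background,
            flagged=self.flagged,
        )


def active_models(models: Sequence[ModelComponent]) -> list[ModelComponent]:
    return [m for m in models if m.status == ACTIVE]


def dormant_models(models: Sequence[ModelComponent]) -> list[ModelComponent]:
    return [m for m in models if m.status == DORMANT]


# ---------------------------------------------------------------------------
# Similarity (Eq. 1) and the skeptic penalty
# ---------------------------------------------------------------------------


def conditional_similarity(family: ModelFamily, model: ModelComponent, datum: np.ndarray) -> float:
    """l(n|m) for a single datum (scalar convenience wrapper)."""
    x = np.atleast_1d(np.asarray(datum, dtype=float))
    if model.spread <= 0:
        raise InputError(f"spread must be positive, got {model.spread}")
    family.validate_datum(x, model.params)
    return float(np.exp(family.log_cond_similarity(model.params, model.spread, x[None, :])[0]))


def log_lik_matrix(data: DataField, models: Sequence[ModelComponent]) -> np.ndarray:
    """log l(n|m) for every model in `models`; shape (M, N)."""
    return np.stack(
        [m.family.log_cond_similarity(m.params, m.spread, data.X) for m in models]
    )


def _renormalized_rates(models: Sequence[ModelComponent]) -> np.ndarray:
    r = np.array([m.r for m in models], dtype=float)
    tot = r.sum()
    if tot <= 0:
        raise StateError("model rates sum to zero")
    return r / tot


def total_log_similarity(
    data: DataField,
    models: Sequence[ModelComponent],
    include_dormant: bool = False,
    logl: Optional[np.ndarray] = None,
) -> float:
    """log L = sum_n log sum_m r(m) l(n|m).

    By default evaluates the active models with their rates renormalized to
    one; ``include_dormant=True`` evaluates the full participating mixture
    (the quantity the iteration provably increases).  Returns ``-inf`` if
    some datum has zero similarity under every model.
    """
    subset = list(models) if include_dormant else active_models(models)
    if not subset:
        raise StateError("no active models")
    r = _renormalized_rates(subset)
    if logl is None:
        logl = log_lik_matrix(data, subset)
    with np.errstate(divide="ignore"):
        lw = logl + np.log(r)[:, None]
    per_datum = logsumexp(lw, axis=0)
    total = float(per_datum.sum())
    return total if np.isfinite(total) else float("-inf")


def resolve_kappa(penalty: str | float, n_samples: int) -> float:
    """Penalty strength: 'aic' -> 1, 'bic' -> log(N)/2, 'none' -> 0, or numeric."""
    if isinstance(penalty, (int, float)):
        return float(penalty)
    if penalty == "aic":
        return 1.0
    if penalty == "bic":
        if n_samples <= 0:
            raise InputError("N must be positive for the BIC penalty")
        return 0.5 * float(np.log(n_samples))
    if penalty == "none":
        return 0.0
    raise InputError(f"unknown penalty {penalty!r}")


def total_free_params(models: Sequence[ModelComponent]) -> int:
    return int(sum(m.family.n_free_params for m in active_models(models)))


def penalized_similarity(
    loglik: float,
    models: Sequence[ModelComponent],
    n_samples: int,
    penalty: str | float = "aic",
) -> float:
    """log L + log p(N, M) with the skeptic penalty log p = -kappa * k_total."""
    if n_samples <= 0:
        raise InputError(f"N must be positive, got {n_samples}")
    if not np.isfinite(loglik):
        raise InputError("loglik must be finite")
    kappa = resolve_kappa(penalty, n_samples)
    return loglik - kappa * total_free_params(models)


# ---------------------------------------------------------------------------
# Association variables (Eq. 2)
# ---------------------------------------------------------------------------


def associations(
    data: DataField,
    models: Sequence[ModelComponent],
    include_dormant: bool = False,
    logl: Optional[np.ndarray] = None,
) -> np.ndarray:
    """f(m|n) = r(m) l(n|m) / sum_m' r(m') l(n|m'); shape (M, N).

    Every column sums to one.  A datum with zero similarity under every
    model is assigned entirely to the background (clutter) model if one is
    present, else uniformly over models.
    """
    subset = list(models) if include_dormant else active_models(models)
    if not subset:
        raise StateError("no active models")
    r = _renormalized_rates(subset)
    if logl is None:
        logl = log_lik_matrix(data, subset)
    with np.errstate(divide="ignore"):
        lw = logl + np.log(r)[:, None]
    norm = logsumexp(lw, axis=0)
    dead = ~np.isfinite(norm)
    with np.errstate(invalid="ignore"):
        f = np.exp(lw - norm)
    if dead.any():
        bg = [i for i, m in enumerate(subset) if m.is_background]
        f[:, dead] = 0.0
        if bg:
            f[bg[0], dead] = 1.0
        else:
            f[:, dead] = 1.0 / len(subset)
    return f


# ---------------------------------------------------------------------------
# Fixed-point updates (Eq. 3) and rate re-estimation
# ---------------------------------------------------------------------------


def update_parameters(
    data: DataField,
    models: Sequence[ModelComponent],
    f: np.ndarray,
    eps_w: float = EPS_W,
) -> list[ModelComponent]:
    """Responsibility-weighted update of every active model's (params, spread).

    ``f`` must have one row per *active* model (in active order).  A model
    whose total weight falls below ``eps_w`` is left unchanged and flagged
    for deactivation review.  Dormant models are untouched.
    """
    act = active_models(models)
    if f.shape != (len(act), data.n_samples):
        raise InputError(f"f has shape {f.shape}, expected {(len(act), data.n_samples)}")
    out = [m.copy() for m in models]
    act_out = active_models(out)
    for m, w in zip(act_out, f):
        m.flagged = False
        if w.sum() < eps_w:
            m.flagged = True
            continue
        m.params, m.spread = m.family.update(m.params, m.spread, data.X, w)
    return out


def update_rates(
    f: np.ndarray,
    n_samples: int,
    models: Sequence[ModelComponent],
    eps_r: float = EPS_R,
    background_floor: float = 0.0,
) -> list[ModelComponent]:
    """r(m) = sum_n f(m|n) / N for active models; dormant models hold a fixed
    floor mass eps_r each; all rates renormalized to sum to one.

    Pinning the dormant rates at an exact reserved budget keeps the rate
    update a constrained M-step over a constant constraint set, which
    preserves exact per-iteration monotonicity.  ``background_floor``
    optionally keeps at least that share of the mixture on the background
    component (the prior that most of the field is clutter); the floor is a
    constraint on the same simplex, so monotonicity is unaffected.
    """
    act = [m for m in models if m.status == ACTIVE]
    dorm = [m for m in models if m.status == DORMANT]
    if f.shape[0] != len(act):
        raise InputError(f"f has {f.shape[0]} rows for {len(act)} active models")
    mass = f.sum(axis=1) / float(n_samples)
    budget = 1.0 - eps_r * len(dorm)
    tot = mass.sum()
    raw = {id(m): (budget * mass[i] / tot if tot > 0 else budget / len(act))
           for i, m in enumerate(act)}
    bg = [m for m in act if m.is_background]
    if bg and background_floor > 0.0:
        b = bg[0]
        floor = background_floor * budget
        if raw[id(b)] < floor and len(act) > 1:
            scale = (budget - floor) / max(budget - raw[id(b)], 1e-300)
            for m in act:
                raw[id(m)] = floor if m is b else raw[id(m)] * scale
    out = []
    for m in models:
        c = m.copy()
        c.r = raw[id(m)] if m.status == ACTIVE else eps_r
        out.append(c)
    return out


def activate_deactivate(
    models: Sequence[ModelComponent],
    threshold: float,
    data: Optional[DataField] = None,
    rng: Optional[np.random.Generator] = None,
    measured_rates: Optional[dict[int, float]] = None,
) -> list[ModelComponent]:
    """Threshold rule for the dormant-model store.

    Dormant models whose (measured) rate exceeds the threshold become
    active, re-initialized vague but keeping their rate; active models whose
    rate falls below the threshold become dormant.  At least one active
    model is always retained (the highest-rate one).  Ties in activation are
    broken lowest index first.
    """
    if not (0.0 < threshold < 1.0):
        raise InputError(f"threshold must be in (0, 1), got {threshold}")
    out = [m.copy() for m in models]
    rates = measured_rates or {}
    original = {m.index: rates.get(m.index, m.r) for m in out}
    for m in sorted(out, key=lambda c: c.index):
        r_eff = rates.get(m.index, m.r)
        if m.status == DORMANT and r_eff > threshold:
            m.status = ACTIVE
            m.r = r_eff
            if data is not None and rng is not None:
                m.params, m.spread = m.family.spawn_vague(data.X, rng)
        elif m.status == ACTIVE and r_eff < threshold and not m.is_background:
            m.status = DORMANT
            m.r = EPS_R
            if data is not None and rng is not None:
                m.params, m.spread = m.family.spawn_vague(data.X, rng)
    if not active_models(out):
        best = max(out, key=lambda c: original[c.index])
        best.status = ACTIVE
        best.r = original[best.index]
    return out


# ---------------------------------------------------------------------------
# Structural moves used inside fit: exact removal cost, merge of duplicates
# ---------------------------------------------------------------------------


def insertion_gain(logl_cand: np.ndarray, log_mix: np.ndarray) -> tuple[float, float]:
    """Best-case change in log L from inserting a candidate component.

    Adding a component with conditional similarity ``exp(logl_cand)`` at
    rate rho (scaling the existing mixture by 1 - rho) changes the
    log-similarity by sum_n log(1 + rho (e_n - 1)), e_n = l_cand(n)/mix(n).
    Returns the maximum over a geometric rate grid and the best rate.
    """
    with np.errstate(over="ignore"):
        e = np.exp(np.minimum(logl_cand - log_mix, 700.0))
    best, best_rho = -np.inf, 0.0
    for rho in 0.5 ** np.arange(1, 11):
        g = float(np.log1p(rho * (e - 1.0)).sum())
        if g > best:
            best, best_rho = g, rho
    return best, best_rho


def removal_cost(f_row: np.ndarray, r_m: float) -> float:
    """Exact change in log L from removing an active component.

    Removing component m and renormalizing the remaining rates changes the
    log-similarity by sum_n log((1 - f(m|n)) / (1 - r_m)) <= 0.
    """
    if r_m >= 1.0:
        return float("-inf")
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log1p(-np.minimum(f_row, 1.0 - 1e-300))) - len(f_row) * np.log1p(-r_m))


def _merge_pass(
    models: list[ModelComponent],
    data: Optional[DataField] = None,
    rng: Optional[np.random.Generator] = None,
    merge_rtol: float = 1.0,
) -> list[ModelComponent]:
    """Merge near-duplicate active components of the same family.

    The lower-index component absorbs the rate; the other returns to the
    dormant store, re-initialized vague.  Exact duplicates leave the mixture
    density unchanged, so the move is likelihood-free.  Returns the list of
    components whose parameters changed.
    """
    act = [m for m in active_models(models) if not m.is_background]
    act.sort(key=lambda c: c.index)
    changed = []
    for i, a in enumerate(act):
        if a.status != ACTIVE:
            continue
        for b in act[i + 1 :]:
            if b.status != ACTIVE or b.family is not a.family:
                continue
            d = a.family.merge_distance(a.params, a.spread, b.params, b.spread)
            if d < merge_rtol:
                a.r += b.r
                b.status = DORMANT
                b.r = EPS_R
                if data is not None and rng is not None:
                    b.params, b.spread = b.family.spawn_vague(data.X, rng)
                changed.append(b)
    return changed


# ---------------------------------------------------------------------------
# Fit configuration and state
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "family",
    "n_models_init",
    "n_dormant",
    "activation_threshold",
    "penalty",
    "kappa",
    "tol",
    "max_iter",
    "seed",
    "init",
    "eps_w",
    "record_history",
    "merge",
    "background_rate_floor",
}


@dataclass
class FitConfig:
    """Flat key-value configuration of a DL fit."""

    family: str = ""
    n_models_init: int = 2
    n_dormant: int = 5
    activation_threshold: Optional[float] = None  # default 1 / (10 * M_max)
    penalty: str | float = "aic"
    kappa: Optional[float] = None  # overrides `penalty` when set
    tol: Optional[float] = None  # default 1e-6 * N
    max_iter: int = 500
    seed: Optional[int] = None
    init: str = "vague"  # or "random_association"
    eps_w: float = EPS_W
    record_history: bool = False
    merge: bool = True
    background_rate_floor: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolved_threshold(self) -> float:
        if self.activation_threshold is not None:
            return self.activation_threshold
        m_max = self.n_models_init + self.n_dormant
        return 1.0 / (10.0 * max(m_max, 1))

    def resolved_kappa(self, n_samples: int) -> float:
        if self.kappa is not None:
            return float(self.kappa)
        return resolve_kappa(self.penalty, n_samples)

    def resolved_tol(self, n_samples: int) -> float:
        return self.tol if self.tol is not None else 1e-6 * n_samples


@dataclass
class FitState:
    """Result of a DL fit: trace, final model set, convergence bookkeeping."""

    iteration: int
    loglik_trace: np.ndarray
    penalized: float
    models: list[ModelComponent]
    converged: bool
    structural_iterations: list[int] = field(default_factory=list)
    n_active_trace: list[int] = field(default_factory=list)
    history: Optional[list[list[ModelComponent]]] = None
    seed: Optional[int] = None

    def to_json_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "converged": bool(self.converged),
            "penalized": float(self.penalized),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "structural_iterations": list(self.structural_iterations),
            "n_active_trace": list(self.n_active_trace),
            "seed": self.seed,
            "models": [
                {
                    "index": m.index,
                    "family": m.family.name,
                    "params": np.asarray(m.params).tolist(),
                    "spread": float(m.spread),
                    "r": float(m.r),
                    "status": m.status,
                    "is_background": m.is_background,
                }
                for m in self.models
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# The vague-to-crisp fit loop
# ---------------------------------------------------------------------------


def _spawn_components(
    data: DataField,
    family: ModelFamily,
    n_active: int,
    n_dormant: int,
    rng: np.random.Generator,
    background: Optional[ModelFamily],
) -> list[ModelComponent]:
    models: list[ModelComponent] = []
    idx = 0
    if background is not None:
        p, s = background.spawn_vague(data.X, rng)
        models.append(
            ModelComponent(idx, background, p, s, r=0.0, status=ACTIVE, is_background=True)
        )
        idx += 1
    for _ in range(n_active):
        p, s = family.spawn_vague(data.X, rng)
        models.append(ModelComponent(idx, family, p, s, r=0.0, status=ACTIVE))
        idx += 1
    for _ in range(n_dormant):
        p, s = family.spawn_vague(data.X, rng)
        models.append(ModelComponent(idx, family, p, s, r=EPS_R, status=DORMANT))
        idx += 1
    act = active_models(models)
    budget = 1.0 - EPS_R * n_dormant
    for m in act:
        m.r = budget / len(act)
    return models


def fit(
    data: DataField,
    family: ModelFamily,
    config: FitConfig,
    seed: Optional[int] = None,
    background: Optional[ModelFamily] = None,
    init_models: Optional[list[ModelComponent]] = None,
    callback: Optional[Callable[[int, float, list[ModelComponent]], None]] = None,
) -> FitState:
    """Run the vague-to-crisp DL iteration to convergence.

    Alternates association (Eq. 2), the fixed-point parameter and rate
    updates (Eq. 3), and data-driven activation/deactivation, until the
    log-similarity changes by less than ``tol`` with a stable model roster,
    or ``max_iter`` is reached.  Identical seed + config + data reproduce
    the result bit for bit.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = data.n_samples
    tol = config.resolved_tol(n)
    threshold = config.resolved_threshold()
    kappa = config.resolved_kappa(n)

    if config.init not in ("vague", "random_association"):
        raise InputError(f"unknown init scheme {config.init!r}")

    f0 = None
    if config.init == "random_association":
        # Random (seeded) association of data to the active models, then one
        # update: the initialization used for the situation-learning runs.
        # Drawn before any component is spawned so the association draw
        # depends only on (seed, counts, N), not on the family's own use of
        # the random stream.
        n_act = (len(active_models(init_models)) if init_models is not None
                 else config.n_models_init + (1 if background is not None else 0))
        f0 = rng.random((n_act, n))
        f0 /= f0.sum(axis=0)

    if init_models is not None:
        models = [m.copy() for m in init_models]
    else:
        models = _spawn_components(
            data, family, config.n_models_init, config.n_dormant, rng, background
        )

    if f0 is not None:
        models = update_parameters(data, models, f0, config.eps_w)
        models = update_rates(f0, n, models,
                              background_floor=config.background_rate_floor)

    logl_part = log_lik_matrix(data, models)
    loglik = total_log_similarity(data, models, include_dormant=True, logl=logl_part)
    if not np.isfinite(loglik):
        bad = int(np.argmax(~np.isfinite(logsumexp(logl_part, axis=0))))
        raise StateError(f"non-finite similarity at initialization (datum {bad})")
    trace = [loglik]
    structural: list[int] = []
    n_active_trace = [len(active_models(models))]
    history: Optional[list[list[ModelComponent]]] = (
        [[m.copy() for m in models]] if config.record_history else None
    )

    converged = False
    iteration = 0
    if not np.isfinite(tol):
        # Degenerate tolerance: nothing can improve by less than infinity.
        return FitState(0, np.array(trace), _pen(loglik, models, n, kappa), models,
                        False, structural, n_active_trace, history, seed)

    def _refresh_rows(logl: np.ndarray, changed: Sequence[ModelComponent]) -> None:
        pos = {id(m): i for i, m in enumerate(models)}
        for m in changed:
            logl[pos[id(m)]] = m.family.log_cond_similarity(m.params, m.spread, data.X)

    def _f_from_logl(logl: np.ndarray, subset_rows: list[int],
                     subset: list[ModelComponent]) -> np.ndarray:
        r = _renormalized_rates(subset)
        with np.errstate(divide="ignore"):
            lw = logl[subset_rows] + np.log(r)[:, None]
        norm = logsumexp(lw, axis=0)
        dead = ~np.isfinite(norm)
        with np.errstate(invalid="ignore"):
            f = np.exp(lw - norm)
        if dead.any():
            bg = [i for i, m in enumerate(subset) if m.is_background]
            f[:, dead] = 0.0
            if bg:
                f[bg[0], dead] = 1.0
            else:
                f[:, dead] = 1.0 / len(subset)
        return f

    roster_changed_last = False
    last_admission = -5
    for iteration in range(1, config.max_iter + 1):
        # E-step over the full participating mixture (active + dormant floor),
        # reusing the similarity matrix computed at the end of the previous
        # iteration (the model set is unchanged in between).
        all_rows = list(range(len(models)))
        f_part = _f_from_logl(logl_part, all_rows, list(models))
        act_rows = [i for i, m in enumerate(models) if m.status == ACTIVE]
        f_act = f_part[act_rows]
        measured = {models[i].index: f_part[i].sum() / n for i in range(len(models))}

        # M-step: parameters of active models, then rates (constrained).
        models = update_parameters(data, models, f_act, config.eps_w)
        models = update_rates(f_act, n, models,
                              background_floor=config.background_rate_floor)

        logl_part = log_lik_matrix(data, models)
        loglik = total_log_similarity(data, models, include_dormant=True, logl=logl_part)
        delta = loglik - trace[-1]
        if not roster_changed_last and delta < -MONO_RTOL * max(1.0, abs(trace[-1])):
            raise MonotonicityError(
                f"log-similarity decreased by {-delta:.3g} at iteration {iteration}"
            )
        trace.append(loglik)

        # Structural phase -------------------------------------------------
        roster_changed_last = False
        near_stationary = abs(delta) < max(100.0 * tol, 1e-6 * abs(loglik), 1e-12)

        just_deactivated: set[int] = set()

        # (a) merge persistent duplicates once the fit is near stationary
        if config.merge and near_stationary:
            changed = _merge_pass(models, data, rng)
            if changed:
                roster_changed_last = True
                just_deactivated.update(m.index for m in changed)
                _refresh_rows(logl_part, changed)

        # (b) skeptic-penalty pruning: threshold-starved models any time,
        #     full review at stationarity; a removal is accepted only if the
        #     penalized similarity does not decrease.
        if not roster_changed_last and kappa >= 0:
            act = active_models(models)
            act_rows = [i for i, m in enumerate(models) if m.status == ACTIVE]
            f_full = _f_from_logl(logl_part, act_rows, act)
            r_act = _renormalized_rates(act)
            candidates = []
            for i, m in enumerate(act):
                if m.is_background:
                    continue
                starved = measured.get(m.index, m.r) < threshold or m.flagged
                if starved or near_stationary:
                    cost = removal_cost(f_full[i], r_act[i])
                    gain = kappa * m.family.n_free_params
                    if cost + gain >= 0 and len(act) > 1:
                        candidates.append((cost + gain, m))
            if candidates:
                _, victim = max(candidates, key=lambda t: t[0])
                victim.status = DORMANT
                victim.r = EPS_R
                victim.params, victim.spread = victim.family.spawn_vague(data.X, rng)
                roster_changed_last = True
                just_deactivated.add(victim.index)
                _refresh_rows(logl_part, [victim])

        # (c) activation of dormant models that earn their keep.  A dormant
        # model's pinned floor rate can never itself cross the threshold, so
        # admission works like the mirror image of pruning: a candidate is
        # seeded at a poorly-explained datum, privately adapted against the
        # active mixture, and activated iff inserting it at its optimal rate
        # raises the log-similarity by more than the skeptic penalty of its
        # parameters.  Probes are rate-limited (they cost about one
        # parameter sweep), with a forced probe before convergence so a
        # converged fit implies no admissible candidate remained.
        if (near_stationary and not roster_changed_last and kappa > 0
                and (iteration - last_admission >= 5 or abs(delta) < tol)):
            last_admission = iteration
            act_rows_now = [i for i, m in enumerate(models) if m.status == ACTIVE]
            act_now = [models[i] for i in act_rows_now]
            with np.errstate(divide="ignore"):
                log_mix = logsumexp(
                    logl_part[act_rows_now]
                    + np.log(_renormalized_rates(act_now))[:, None],
                    axis=0,
                )
            pi = threshold
            q = np.quantile(log_mix, 0.1)
            pool = np.flatnonzero(log_mix <= q)
            for j, (i, m) in enumerate(
                    sorted(enumerate(models), key=lambda im: im[1].index)):
                if m.index in just_deactivated or m.status != DORMANT:
                    continue
                # Alternate anchors between the worst-explained data (finds
                # structure the mixture misses outright) and uniform draws
                # (finds structure hiding inside a too-broad component,
                # which is *better* explained than genuine clutter and so
                # never reaches the worst-explained pool).
                if len(pool) and j % 2 == 0:
                    anchor = int(rng.choice(pool))
                else:
                    anchor = int(rng.integers(n))
                cand_p, cand_s = m.family.spawn_from_datum(
                    data.X[anchor], data.X, rng)
                cand_p, cand_s = m.family.adapt_candidate(
                    cand_p, cand_s, data.X, log_mix, pi, rng)
                logl_c = m.family.log_cond_similarity(cand_p, cand_s, data.X)
                gain, rho = insertion_gain(logl_c, log_mix)
                if gain > kappa * m.family.n_free_params + 1e-9:
                    m.status = ACTIVE
                    m.r = rho
                    m.params, m.spread = cand_p, cand_s
                    roster_changed_last = True
                    _refresh_rows(logl_part, [m])

        if roster_changed_last:
            # Re-establish a valid rate vector on the new roster.
            act = active_models(models)
            budget = 1.0 - EPS_R * len(dormant_models(models))
            tot = sum(m.r for m in act)
            for m in act:
                m.r = budget * m.r / tot if tot > 0 else budget / len(act)
            structural.append(iteration)

        n_active_trace.append(len(active_models(models)))
        if history is not None:
            history.append([m.copy() for m in models])
        if callback is not None:
            callback(iteration, loglik, models)
        logger.info(
            "iter=%d logL=%.6f active=%d%s",
            iteration, loglik, len(active_models(models)),
            " [structural]" if roster_changed_last else "",
        )

        if not roster_changed_last and abs(delta) < tol and iteration > 1:
            converged = True
            break

    return FitState(
        iteration=iteration,
        loglik_trace=np.array(trace),
        penalized=_pen(trace[-1], models, n, kappa),
        models=models,
        converged=converged,
        structural_iterations=structural,
        n_active_trace=n_active_trace,
        history=history,
        seed=seed,
    )


def _pen(loglik: float, models: Sequence[ModelComponent], n: int, kappa: float) -> float:
    return loglik - kappa * total_free_params(models)
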