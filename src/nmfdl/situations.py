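"""Situation learning from binary object co-occurrence data.

A "situation" is a higher-level concept defined by a characteristic subset
of co-occurring objects, observed amid a majority of purely random object
collections ("clutter").  The generator plants K important situation types
in an N x D binary matrix: every instance of a type contains its k_rel
relevant objects plus k_rand random extras, clutter rows contain random
objects only, and the rows are shuffled.  The DL engine with a Bernoulli
model family then has to rediscover the relevant-object sets, starting
from a seeded random association of rows to an (arbitrary) number of
initial models.

Relation markers are supported as extra binary columns that behave exactly
like objects: a type's marker columns are always present in its instances
and the learning algorithm is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    ACTIVE,
    DataField,
    FitConfig,
    FitState,
    InputError,
    ModelComponent,
    fit,
)
from .families import BernoulliFamily


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass
class SituationGenConfig:
    """Parameters of the planted-situation generator.

    Defaults reproduce the study conditions of the demonstration: 1,000
    objects, 10 important situation types of 10 relevant + 40 random
    objects each, and 16,000 total rows of which half are clutter.
    """

    n_objects: int = 1000
    n_types: int = 10
    k_rel: int = 10
    k_rand: int = 40
    n_per_type: int = 800
    n_clutter: int = 8000
    k_clutter: int = 50  # = k_rel + k_rand: clutter indistinguishable by row sum
    markers_per_type: int = 0
    overlap: bool = False  # relevant sets disjoint across types by default
    seed: int = 0


def caption_gen_config(seed: int = 0) -> SituationGenConfig:
    """The alternative composition stated alongside the data figure:
    10 important situations plus 5,000 clutter rows."""
    return SituationGenConfig(n_per_type=1, n_clutter=5000, seed=seed)


@dataclass
class SituationTruth:
    relevant_sets: list[list[int]]  # per type, sorted object ids (incl. markers)
    type_of_row: np.ndarray  # -1 for clutter
    marginal_rand: float  # marginal presence rate of a non-relevant object


@dataclass
class SituationData:
    matrix: np.ndarray  # (N, D) binary
    column_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or min(self.matrix.shape) < 1:
            raise InputError("situation matrix must be non-empty and 2-D")
        if not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise InputError("situation matrix entries must be in {0, 1}")


def generate_situations(
    config: SituationGenConfig,
) -> tuple[SituationData, SituationTruth]:
    """Plant K situation types plus clutter; rows shuffled, seeded."""
    c = config
    d_total = c.n_objects + c.n_types * c.markers_per_type
    if c.k_rel + c.k_rand > c.n_objects:
        raise InputError("k_rel + k_rand must not exceed n_objects")
    if not c.overlap and c.n_types * c.k_rel > c.n_objects:
        raise InputError("disjoint relevant sets need n_types * k_rel <= n_objects")
    if min(c.n_types, c.k_rel) < 0 or c.n_per_type < 0 or c.n_clutter < 0:
        raise InputError("counts must be non-negative")
    rng = np.random.default_rng(c.seed)

    # Relevant object sets (disjoint unless overlap allowed), plus markers.
    if c.overlap:
        rel_sets = [
            np.sort(rng.choice(c.n_objects, size=c.k_rel, replace=False))
            for _ in range(c.n_types)
        ]
    else:
        perm = rng.permutation(c.n_objects)
        rel_sets = [
            np.sort(perm[k * c.k_rel : (k + 1) * c.k_rel]) for k in range(c.n_types)
        ]
    marker_sets = [
        np.arange(c.n_objects + k * c.markers_per_type,
                  c.n_objects + (k + 1) * c.markers_per_type)
        for k in range(c.n_types)
    ]

    n_rows = c.n_types * c.n_per_type + c.n_clutter
    X = np.zeros((n_rows, d_total), dtype=np.int8)
    type_of_row = np.full(n_rows, -1, dtype=int)
    row = 0
    for k in range(c.n_types):
        rel = rel_sets[k]
        others = np.setdiff1d(np.arange(c.n_objects), rel)
        for _ in range(c.n_per_type):
            X[row, rel] = 1
            X[row, marker_sets[k]] = 1
            if c.k_rand:
                X[row, rng.choice(others, size=c.k_rand, replace=False)] = 1
            type_of_row[row] = k
            row += 1
    for _ in range(c.n_clutter):
        if c.k_clutter:
            X[row, rng.choice(c.n_objects, size=c.k_clutter, replace=False)] = 1
        row += 1

    order = rng.permutation(n_rows)
    X = X[order]
    type_of_row = type_of_row[order]

    labels = [f"obj{i}" for i in range(c.n_objects)] + [
        f"marker{k}_{j}" for k in range(c.n_types) for j in range(c.markers_per_type)
    ]
    marginal = c.k_rand / max(c.n_objects - c.k_rel, 1)
    truth = SituationTruth(
        relevant_sets=[
            sorted(np.concatenate([rel_sets[k], marker_sets[k]]).tolist())
            for k in range(c.n_types)
        ],
        type_of_row=type_of_row,
        marginal_rand=marginal,
    )
    return SituationData(X, labels), truth


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def situation_fit_config(
    n_models_init: int = 20,
    n_dormant: int = 3,
    max_iter: int = 250,
    penalty: str | float = "aic",
    **kwargs,
) -> FitConfig:
    """Default engine configuration for situation learning (20 initial
    models, seeded random-association initialization)."""
    return FitConfig(
        family="bernoulli",
        n_models_init=n_models_init,
        n_dormant=n_dormant,
        max_iter=max_iter,
        penalty=penalty,
        init="random_association",
        **kwargs,
    )


def fit_situations(
    data: SituationData,
    config: Optional[FitConfig] = None,
    seed: Optional[int] = None,
    record_history: bool = False,
) -> FitState:
    """Learn situation models with the Bernoulli family.

    Starts from a seeded random association of the rows to the initial
    models followed by one closed-form update, then runs the DL iteration;
    surplus models end up absorbing the clutter and are pruned or merged by
    the skeptic penalty.
    """
    config = config or situation_fit_config()
    if record_history:
        config = FitConfig(**{**config.to_dict(), "record_history": True})
    X = np.ascontiguousarray(data.matrix, dtype=float)
    family = BernoulliFamily(X.shape[1])
    return fit(DataField(X, binary=True), family, config, seed=seed)


def bernoulli_similarity(p: np.ndarray, x: np.ndarray) -> float:
    """l(n|m) for one binary vector under a situation model (log-space product)."""
    from .families import bernoulli_log_lik

    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise InputError("dimension mismatch between model and datum")
    return float(np.exp(bernoulli_log_lik(x[None, :], p)[0]))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _concept_models(models: Sequence[ModelComponent] | FitState) -> list[ModelComponent]:
    if isinstance(models, FitState):
        models = models.models
    return [m for m in models if m.status == ACTIVE and not m.is_background]


def truth_prototypes(truth: SituationTruth, dim: int) -> np.ndarray:
    """K x D expected presence rates: relevant objects at one, the rest at
    their generative marginal."""
    protos = np.full((len(truth.relevant_sets), dim), truth.marginal_rand)
    for k, rel in enumerate(truth.relevant_sets):
        protos[k, rel] = 1.0
    return protos


def recovery_error(
    models: Sequence[ModelComponent] | FitState,
    truth: SituationTruth | np.ndarray,
    dim: Optional[int] = None,
) -> float:
    """Mean absolute deviation between learned and true situation profiles.

    Truth types are matched one-to-one to the active models by the optimal
    assignment minimizing the summed mean-|p - prototype| distance (models
    left over — e.g. clutter absorbers — are ignored); a truth type with no
    model available counts a full error of one.  Result is in [0, 1].
    """
    act = _concept_models(models)
    if isinstance(truth, SituationTruth):
        if dim is None:
            if not act:
                raise InputError("cannot infer dimension without active models")
            dim = len(act[0].params)
        protos = truth_prototypes(truth, dim)
    else:
        protos = np.asarray(truth, dtype=float)
    K = protos.shape[0]
    if K < 1:
        raise InputError("need at least one truth type")
    if not act:
        return 1.0
    P = np.stack([np.asarray(m.params, dtype=float) for m in act])
    cost = np.abs(protos[:, None, :] - P[None, :, :]).mean(axis=2)  # K x M
    rows, cols = linear_sum_assignment(cost)
    total = cost[rows, cols].sum() + (K - len(rows)) * 1.0
    return float(total / K)


def relevant_object_sets(
    models: Sequence[ModelComponent] | FitState, k_rel: int
) -> list[list[int]]:
    """Per model, the k_rel columns with the highest presence rate.

    Ties at the boundary are broken lowest object id first.
    """
    out = []
    for m in _concept_models(models):
        p = np.asarray(m.params, dtype=float)
        order = np.argsort(-p, kind="stable")
        out.append(sorted(order[:k_rel].tolist()))
    return out


def all_sets_recovered(
    models: Sequence[ModelComponent] | FitState,
    truth: SituationTruth,
) -> bool:
    """True when every planted relevant set is read off some learned model."""
    k_rel = len(truth.relevant_sets[0])
    got = {tuple(s) for s in relevant_object_sets(models, k_rel)}
    return all(tuple(s) in got for s in truth.relevant_sets)
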