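"""Phase-cone event detection on a simulated sensor array.

A "phase cone" is a circular spatiotemporal activity pattern on a sensor
array — a ring of elevated amplitude that expands or contracts over time —
used as a model of cognitively related events in EEG-like recordings.  This
module simulates scenes of such events buried in additive Gaussian sensor
noise on an X x Y grid (64 x 64 by default, 5 ms per time step) and
recovers them with the DL engine: parametric traveling-ring models plus one
spatially uniform background component compete for every (x, y, t, A)
sample.

Model form.  A cone with center (x0, y0), radial speed v (> 0 expanding,
< 0 contracting), amplitude a and ring width w predicts

    g(x, y, t) = a * exp(-(rho - R(t))^2 / (2 w^2)),   rho = dist to center,

with ring radius R(t) = v * (t - t0) wherever R(t) >= 0 and zero signal
otherwise; for an expanding cone t0 is the onset, for a contracting cone
t0 is the collapse time.  The conditional similarity of a sample is the
Gaussian density of its amplitude around the predicted value, with the
model's spread as variance; parameter updates are responsibility-weighted
damped Gauss-Newton steps guarded to never decrease the weighted fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    ACTIVE,
    DataField,
    FitConfig,
    FitState,
    InputError,
    ModelComponent,
    ModelFamily,
    fit,
)
from .families import GaussianBackgroundFamily, UniformClutterFamily

# ---------------------------------------------------------------------------
# Scene description and simulation
# ---------------------------------------------------------------------------


@dataclass
class ConeParams:
    """Ground-truth parameters of one cone event (generator convention).

    ``t0`` is the onset time in steps; expanding cones (v > 0) start at ring
    radius zero, contracting cones (v < 0) start at radius ``r0`` (default:
    |v| times the remaining scene duration, so the ring collapses exactly at
    the end of the scene).
    """

    x0: float
    y0: float
    t0: float
    v: float
    a: float
    w: float
    r0: Optional[float] = None

    def __post_init__(self):
        if self.w <= 0 or self.a <= 0 or self.v == 0:
            raise InputError("cone requires w > 0, a > 0, v != 0")

    def collapse_time(self) -> float:
        """Canonical time at which the ring radius is zero."""
        if self.v > 0:
            return self.t0
        if self.r0 is None:
            raise InputError("contracting cone with unresolved r0")
        return self.t0 + self.r0 / abs(self.v)


@dataclass
class ConeScene:
    """Ground truth of a simulation: cone list, noise level, seed."""

    cones: list[ConeParams]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


@dataclass
class SensorArrayData:
    """X x Y x T array of sensor amplitudes; unit sensor spacing, dt in ms."""

    amplitudes: np.ndarray
    dt: float = 5.0

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 3 or min(self.amplitudes.shape) < 1:
            raise InputError("amplitudes must be a non-empty 3-D (x, y, t) array")
        if not np.all(np.isfinite(self.amplitudes)):
            raise InputError("amplitudes must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.amplitudes.shape

    def as_samples(self) -> np.ndarray:
        """Flatten to an (N, 4) sample array with columns (x, y, t, amplitude)."""
        nx, ny, nt = self.dims
        xx, yy, tt = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nt), indexing="ij"
        )
        return np.column_stack(
            [xx.ravel(), yy.ravel(), tt.ravel(), self.amplitudes.ravel()]
        ).astype(float)


def cone_signal(p: ConeParams, x, y, t):
    """Amplitude of one cone event at sensor (x, y) and time t (zero before onset)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    rho = np.sqrt((x - p.x0) ** 2 + (y - p.y0) ** 2)
    if p.v > 0:
        radius = p.v * (t - p.t0)
    else:
        if p.r0 is None:
            raise InputError("contracting cone requires r0 (set explicitly or by the generator)")
        radius = np.maximum(p.r0 + p.v * (t - p.t0), 0.0)
    out = p.a * np.exp(-((rho - radius) ** 2) / (2.0 * p.w**2))
    return np.where(t >= p.t0, out, 0.0)


def generate_phase_cones(
    scene: ConeScene, dims: tuple[int, int, int] = (64, 64, 40)
) -> tuple[SensorArrayData, ConeScene]:
    """Simulate the scene on a grid; returns data and the resolved ground truth.

    Unresolved contracting-cone radii are filled in as |v| * (T - t0).
    """
    nx, ny, nt = dims
    if min(dims) < 1:
        raise InputError("dims must be positive")
    resolved = []
    for c in scene.cones:
        r0 = c.r0
        if c.v < 0 and r0 is None:
            r0 = abs(c.v) * (nt - c.t0)
        resolved.append(ConeParams(c.x0, c.y0, c.t0, c.v, c.a, c.w, r0))
    truth = ConeScene(resolved, scene.noise_sd, scene.seed)

    xx, yy, tt = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nt), indexing="ij")
    amp = np.zeros(dims, dtype=float)
    for c in resolved:
        amp += cone_signal(c, xx, yy, tt)
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sd > 0:
        amp = amp + rng.normal(0.0, scene.noise_sd, size=dims)
    return SensorArrayData(amp), truth


def figure_scene(
    seed: int = 0,
    amplitude: float = 1.0,
    snr: float = 1.0,
    dims: tuple[int, int, int] = (64, 64, 40),
) -> ConeScene:
    """The demonstration composition: two expanding and one contracting event
    on a 64 x 64 array, in noise with per-sample SNR = amplitude / noise_sd.
    """
    nx, ny, nt = dims
    sx, sy = nx / 64.0, ny / 64.0
    cones = [
        ConeParams(x0=18.0 * sx, y0=17.0 * sy, t0=3.0, v=0.9, a=amplitude, w=1.8),
        ConeParams(x0=47.0 * sx, y0=24.0 * sy, t0=8.0, v=0.7, a=amplitude, w=1.8),
        ConeParams(x0=30.0 * sx, y0=48.0 * sy, t0=0.0, v=-0.8, a=amplitude, w=1.8),
    ]
    return ConeScene(cones, noise_sd=amplitude / snr, seed=seed)


# ---------------------------------------------------------------------------
# The traveling-ring model family
# ---------------------------------------------------------------------------


class ConeFamily(ModelFamily):
    """Gaussian traveling-ring model over (x, y, t, amplitude) samples.

    Packed parameters: (x0, y0, t0, v, a, w); spread is the residual
    amplitude variance.  The update is an inner loop of damped Gauss-Newton
    steps on the responsibility-weighted squared residual, accepted only
    when the weighted fit improves, followed by the closed-form spread
    update — so the engine's monotonicity contract holds.
    """

    name = "cone"

    def __init__(
        self,
        dims: tuple[int, int, int],
        n_inner: int = 5,
        w_min: float = 0.6,
        a_min: float = 1e-3,
        v_min: float = 0.02,
        var_floor: float = 1e-8,
        w_init_frac: float = 0.125,
        w_max_frac: float = 0.15,
        anneal: float = 0.9,
    ):
        self.dims = dims
        self.n_inner = int(n_inner)
        self.w_min = float(w_min)
        self.a_min = float(a_min)
        self.v_min = float(v_min)
        self.var_floor = float(var_floor)
        self.w_init_frac = float(w_init_frac)
        # rings wider than a modest fraction of the array are not credible
        # events; the cap removes a degenerate fat-and-slow ring mode that
        # otherwise absorbs whole events without resolving them
        self.w_max_frac = float(w_max_frac)
        self.anneal = float(anneal)
        self._spawn_count = 0  # cycles the stratified initialization

    @property
    def n_free_params(self) -> int:
        return 7  # six cone parameters + residual variance

    # -- geometry ---------------------------------------------------------

    def predict(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        x0, y0, t0, v, a, w = params
        rho = np.sqrt((X[:, 0] - x0) ** 2 + (X[:, 1] - y0) ** 2)
        radius = v * (X[:, 2] - t0)
        live = radius >= 0.0
        g = a * np.exp(-((rho - radius) ** 2) / (2.0 * w**2))
        return np.where(live, g, 0.0)

    def log_cond_similarity(self, params, spread, X):
        if spread <= 0:
            raise InputError(f"spread must be positive, got {spread}")
        resid = X[:, 3] - self.predict(params, X)
        return -0.5 * np.log(2.0 * np.pi * spread) - resid**2 / (2.0 * spread)

    # -- update -----------------------------------------------------------

    def _clip(self, params: np.ndarray) -> np.ndarray:
        nx, ny, nt = self.dims
        x0, y0, t0, v, a, w = params
        x0 = np.clip(x0, -0.25 * nx, 1.25 * nx)
        y0 = np.clip(y0, -0.25 * ny, 1.25 * ny)
        t0 = np.clip(t0, -nt, 2.0 * nt)
        if abs(v) < self.v_min:
            v = self.v_min if v >= 0 else -self.v_min
        a = np.clip(a, self.a_min, None)
        w = np.clip(w, self.w_min, self.w_max_frac * max(nx, ny))
        return np.array([x0, y0, t0, v, a, w])

    def _wsse(self, params, X, weights):
        resid = X[:, 3] - self.predict(params, X)
        return float(weights @ resid**2)

    def _jacobian(self, params, X):
        x0, y0, t0, v, a, w = params
        dx = X[:, 0] - x0
        dy = X[:, 1] - y0
        rho = np.sqrt(dx**2 + dy**2)
        rho_safe = np.maximum(rho, 1e-9)
        radius = v * (X[:, 2] - t0)
        live = radius >= 0.0
        u = rho - radius
        g = a * np.exp(-(u**2) / (2.0 * w**2)) * live
        dg_du = -g * u / w**2
        J = np.empty((X.shape[0], 6))
        J[:, 0] = dg_du * (-dx / rho_safe)  # d u / d x0 = (x0 - x) / rho
        J[:, 1] = dg_du * (-dy / rho_safe)
        J[:, 2] = dg_du * v  # d u / d t0 = v
        J[:, 3] = dg_du * (-(X[:, 2] - t0))  # d u / d v
        J[:, 4] = g / a
        J[:, 5] = g * u**2 / w**3
        resid = X[:, 3] - g
        return J, resid

    def _geometry_refresh(self, params, X, weights):
        """Closed-form re-estimate of the ring geometry from the weighted data.

        Center = amplitude-weighted centroid of the model's samples; (v, t0)
        by weighted linear regression of distance-to-center on time;
        amplitude by least squares given the geometry.  Jumps across the
        basins (speed sign, static-blob mode) that local Gauss-Newton steps
        cannot leave; the caller accepts it only if the weighted fit improves.
        """
        ww0 = weights * np.maximum(X[:, 3], 0.0)
        if ww0.sum() <= 0:
            return None
        t = X[:, 2]
        est = None
        ww = ww0
        for _ in range(3):  # trim-and-refit: de-biases the noise dilution
            s = ww.sum()
            if s <= 0:
                return None
            cx = ww @ X[:, 0] / s
            cy = ww @ X[:, 1] / s
            rho = np.hypot(X[:, 0] - cx, X[:, 1] - cy)
            tm = ww @ t / s
            rm = ww @ rho / s
            var_t = ww @ (t - tm) ** 2 / s
            if var_t <= 1e-9:
                return None
            v = (ww @ ((t - tm) * (rho - rm)) / s) / var_t
            if abs(v) < self.v_min:
                return None
            t0 = -(rm - v * tm) / v
            est = (cx, cy, v, t0)
            radius = v * (t - t0)
            window = np.exp(-((rho - radius) ** 2) / (2.0 * 2.5**2))
            ww = ww0 * window * (radius >= 0.0)
        cx, cy, v, t0 = est
        cand = self._clip(np.array([cx, cy, t0, v, params[4], params[5]]))
        # least-squares amplitude given the geometry
        unit = cand.copy()
        unit[4] = 1.0
        g0 = self.predict(unit, X)
        denom = weights @ g0**2
        if denom > 0:
            cand[4] = np.clip((weights @ (g0 * X[:, 3])) / denom, self.a_min, None)
        return cand

    def update(self, params, spread, X, weights):
        params = np.asarray(params, dtype=float).copy()
        sse = self._wsse(params, X, weights)
        candidates = [self._geometry_refresh(params, X, weights)]
        # time-reversal candidate: a ring locked with the wrong speed sign
        # (expanding mistaken for contracting or vice versa) is a basin the
        # local steps cannot leave; flip v and reflect t0 about the model's
        # weighted mean time so the radii match there.
        ww = weights * np.maximum(X[:, 3], 0.0)
        if ww.sum() > 0:
            t_bar = ww @ X[:, 2] / ww.sum()
            flip = params.copy()
            flip[3] = -params[3]
            flip[2] = 2.0 * t_bar - params[2]
            candidates.append(self._clip(flip))
        for cand in candidates:
            if cand is None:
                continue
            cand_sse = self._wsse(cand, X, weights)
            if cand_sse < sse:
                params, sse = cand.copy(), cand_sse
        lam = 1e-3
        for _ in range(self.n_inner):
            J, resid = self._jacobian(params, X)
            JW = J * weights[:, None]
            H = J.T @ JW
            gvec = JW.T @ resid
            accepted = False
            for _ in range(6):  # damping / step-halving guard
                try:
                    step = np.linalg.solve(H + lam * np.diag(np.maximum(np.diag(H), 1e-12)),
                                           gvec)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = self._clip(params + step)
                cand_sse = self._wsse(cand, X, weights)
                if cand_sse <= sse:
                    params, sse = cand, cand_sse
                    lam = max(lam * 0.3, 1e-6)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
        wsum = weights.sum()
        # annealed cooling: the residual variance may shrink by at most a
        # fixed factor per iteration on its way down to the weighted MLE
        var = max(sse / wsum, self.anneal * spread, self.var_floor)
        return params, float(var)

    # -- initialization and merging ---------------------------------------

    def spawn_vague(self, X, rng):
        # Stratified initialization: centers cycle a 3 x 3 grid with seeded
        # jitter, speed signs alternate, onsets cycle the early/middle/late
        # thirds — so a batch of vague models covers the array and respawned
        # models keep probing cells instead of resampling uniformly.
        nx, ny, nt = self.dims
        amp = X[:, 3]
        i = self._spawn_count
        self._spawn_count += 1
        gx, gy = (i % 3), ((i // 3) % 3)
        x0 = (gx + 0.5) * nx / 3.0 + rng.uniform(-0.12, 0.12) * nx
        y0 = (gy + 0.5) * ny / 3.0 + rng.uniform(-0.12, 0.12) * ny
        v = (1.0 if i % 2 == 0 else -1.0) * rng.uniform(0.5, 1.1)
        # t0 is the zero-radius time: onset for expanding rings (born inside
        # the scene, so early), collapse for contracting ones (so late)
        phase = ((i // 2) % 3) / 3.0
        if v > 0:
            t0 = (0.05 + 0.6 * phase) * nt + rng.uniform(-0.05, 0.05) * nt
        else:
            t0 = (0.65 + 0.5 * phase) * nt + rng.uniform(-0.05, 0.05) * nt
        a = max(float(np.percentile(amp, 99)), 10 * self.a_min)
        w = self.w_init_frac * max(nx, ny)
        spread = float(amp.var()) or 1.0
        return np.array([x0, y0, t0, v, a, w]), spread

    def spawn_from_datum(self, x, X, rng):
        # Candidate for the admission probe, anchored at a poorly-explained
        # sample: a narrow ring born at the sample's position and time.  The
        # anchor typically lies ON a missed ring; the geometry-refresh step
        # inside `update` can then snap the candidate onto the event once
        # its responsibilities cover the surrounding region.
        nx, ny, nt = self.dims
        amp = X[:, 3]
        v = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)
        a = max(float(x[3]), float(np.percentile(amp, 99)), 10 * self.a_min)
        params = self._clip(np.array([x[0], x[1], x[2], v, a, 4.0]))
        spread = float(amp.var()) or 1.0
        return params, spread

    def adapt_candidate(self, params, spread, X, log_mix, pi, rng):
        # Localized version of the generic private adaptation: at low SNR
        # the admission responsibilities have only a ~2-3x contrast per
        # sample, so a global weighted fit is swamped by the sheer number of
        # background samples.  A Gaussian spatial window around the
        # candidate's current center (moving with it) keeps the adaptation
        # anchored to the local structure.
        win = 0.3 * max(self.dims[0], self.dims[1])
        for _ in range(8):
            logl_c = self.log_cond_similarity(params, spread, X)
            with np.errstate(over="ignore"):
                ratio = np.exp(np.minimum(log_mix - logl_c, 700.0))
            resp = 1.0 / (1.0 + ((1.0 - pi) / pi) * ratio)
            d2 = (X[:, 0] - params[0]) ** 2 + (X[:, 1] - params[1]) ** 2
            resp = resp * np.exp(-d2 / (2.0 * win**2))
            if resp.sum() <= 0.0:
                break
            params, spread = self.update(params, spread, X, resp)
        return params, spread

    def merge_distance(self, pa, sa, pb, sb):
        if np.sign(pa[3]) != np.sign(pb[3]):
            return np.inf
        d_center = np.hypot(pa[0] - pb[0], pa[1] - pb[1]) / 2.0
        d_t = abs(pa[2] - pb[2]) / 5.0
        d_v = abs(pa[3] - pb[3]) / 0.6
        return float(max(d_center, d_t, d_v))


# ---------------------------------------------------------------------------
# Fitting, classification, evaluation
# ---------------------------------------------------------------------------


def cone_fit_config(
    n_models_init: int = 10,
    n_dormant: int = 3,
    max_iter: int = 200,
    penalty: str | float = "bic",
    background_rate_floor: float = 0.5,
    **kwargs,
) -> FitConfig:
    """Default engine configuration for the phase-cone pipeline."""
    # the rate floor encodes the prior that most of the array is noise: it
    # keeps the background component pinned on the bulk instead of drifting
    # onto unclaimed event signal
    return FitConfig(
        family="cone",
        n_models_init=n_models_init,
        n_dormant=n_dormant,
        max_iter=max_iter,
        penalty=penalty,
        background_rate_floor=background_rate_floor,
        **kwargs,
    )


def fit_cones(
    data: SensorArrayData,
    config: Optional[FitConfig] = None,
    seed: Optional[int] = None,
    background: str = "gaussian",
    family: Optional[ConeFamily] = None,
    record_history: bool = False,
) -> FitState:
    """Fit traveling-ring models plus one background component to the array.

    ``background="gaussian"`` (default) models the additive sensor noise as
    a spatially uniform Gaussian amplitude distribution;
    ``background="uniform"`` uses the flat amplitude-range clutter model.
    """
    config = config or cone_fit_config()
    if record_history:
        config = FitConfig(**{**config.to_dict(), "record_history": True})
    fam = family or ConeFamily(data.dims)
    if background == "gaussian":
        bg: ModelFamily = GaussianBackgroundFamily(value_col=3)
    elif background == "uniform":
        bg = UniformClutterFamily(value_col=3)
    else:
        raise InputError(f"unknown background {background!r}")
    field_ = DataField(data.as_samples())
    return fit(field_, fam, config, seed=seed, background=bg)


def cone_components(models: Sequence[ModelComponent]) -> list[ModelComponent]:
    return [m for m in models
            if m.status == ACTIVE and not m.is_background and m.family.name == "cone"]


def classify_events(models: Sequence[ModelComponent] | FitState) -> tuple[int, int]:
    """(n_expanding, n_contracting) among active cone models (clutter excluded)."""
    if isinstance(models, FitState):
        models = models.models
    cones = cone_components(models)
    n_exp = sum(1 for m in cones if m.params[3] > 0)
    n_con = sum(1 for m in cones if m.params[3] < 0)
    return n_exp, n_con


@dataclass
class ConeMatch:
    truth_index: int
    fitted_index: Optional[int]
    errors: Optional[dict] = None  # per-parameter absolute errors


@dataclass
class RecoveryReport:
    matches: list[ConeMatch] = field(default_factory=list)
    unmatched_truth: int = 0
    unmatched_fitted: int = 0

    def max_center_error(self) -> float:
        errs = [np.hypot(m.errors["x0"], m.errors["y0"]) for m in self.matches if m.errors]
        if self.unmatched_truth or not errs:
            return float("inf")
        return float(max(errs))

    def all_speed_signs_correct(self) -> bool:
        return (self.unmatched_truth == 0
                and all(m.errors is not None and m.errors["v_sign_ok"] for m in self.matches))


def _canonical(p: ConeParams) -> np.ndarray:
    """(x0, y0, collapse_time, v, a, w): the identifiable parameterization."""
    return np.array([p.x0, p.y0, p.collapse_time(), p.v, p.a, p.w])


def recovery_metrics(
    models: Sequence[ModelComponent] | FitState, truth: ConeScene
) -> RecoveryReport:
    """Greedy matching of fitted to true cones by center + zero-radius-time
    distance; per-parameter absolute errors and unmatched counts.
    """
    if isinstance(models, FitState):
        models = models.models
    if not truth.cones:
        raise InputError("need at least one true cone")
    fitted = [np.asarray(m.params, dtype=float) for m in cone_components(models)]
    truths = [_canonical(c) for c in truth.cones]

    report = RecoveryReport()
    free_fit = list(range(len(fitted)))
    order_cost = []
    for it, tr in enumerate(truths):
        for jf in free_fit:
            fp = fitted[jf]
            cost = np.hypot(tr[0] - fp[0], tr[1] - fp[1]) + abs(tr[2] - fp[2])
            order_cost.append((cost, it, jf))
    order_cost.sort(key=lambda t: (t[0], t[1], t[2]))
    used_t: set[int] = set()
    used_f: set[int] = set()
    pairs = {}
    for cost, it, jf in order_cost:
        if it in used_t or jf in used_f:
            continue
        used_t.add(it)
        used_f.add(jf)
        pairs[it] = jf
    for it, tr in enumerate(truths):
        if it in pairs:
            fp = fitted[pairs[it]]
            errors = {
                "x0": abs(tr[0] - fp[0]),
                "y0": abs(tr[1] - fp[1]),
                "t0": abs(tr[2] - fp[2]),
                "v": abs(tr[3] - fp[3]),
                "a": abs(tr[4] - fp[4]),
                "w": abs(tr[5] - fp[5]),
                "v_sign_ok": bool(np.sign(tr[3]) == np.sign(fp[3])),
            }
            report.matches.append(ConeMatch(it, pairs[it], errors))
        else:
            report.matches.append(ConeMatch(it, None, None))
            report.unmatched_truth += 1
    report.unmatched_fitted = len(fitted) - len(used_f)
    return report
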