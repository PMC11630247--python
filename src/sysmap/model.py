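"""Coupled-ODE trait system: rate evaluation, integration, decomposition.

The dynamic model splits each trait's instantaneous rate of change into an
independent part, a function of the trait's own state, and dependent parts
contributed by every other trait's state::

    dp_i/dt = f_i(p_i; theta_i) + sum_{i' != i} f_{i|i'}(p_{i'}; theta_{ii'})

Each f is a basis expansion (:mod:`sysmap.basis`) in STATE, not time; time
enters only through the trajectory.  Positive dependent functions are read
as cooperation (the other trait accelerates this one), negative as
competition.  Integrating the system with the dependent coefficients zeroed
and subtracting from the full solution isolates the net interactive effect
on each trait.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import legendre as _leg

from .basis import BasisSpec, basis_design, basis_eval
from .errors import IntegrationError, InvalidDomainError, ValidationError

log = logging.getLogger(__name__)

try:  # optional compiled RK4 kernel; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

#: Default RK4 step ceiling in minutes; actual step is min(DEFAULT_STEP_CAP,
#: smallest output interval) / 3, giving at least three substeps per interval.
DEFAULT_STEP_CAP = 3.0


@dataclass
class RateFunction:
    """One rate-function term: a basis expansion with coefficient vector theta."""

    basis: BasisSpec
    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.basis.n_basis,):
            raise ValidationError(
                f"theta has length {self.theta.size}, basis has "
                f"{self.basis.n_basis} functions"
            )

    def __call__(self, values, clip: bool = False):
        return basis_eval(values, self.basis, self.theta, clip=clip)

    def zeroed(self) -> "RateFunction":
        return RateFunction(self.basis, np.zeros_like(self.theta))

    def to_dict(self) -> dict:
        return {**self.basis.to_dict(), "theta": self.theta.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RateFunction":
        return cls(BasisSpec.from_dict(d), np.asarray(d["theta"], dtype=float))


@dataclass
class SystemModel:
    """Full specification of an n-trait coupled system.

    ``dependent`` is keyed by ordered pairs ``(i, i')``: the contribution of
    trait i' to trait i's rate.  A valid model carries exactly n(n-1)
    dependent functions.
    """

    traits: tuple[str, ...]
    independent: dict[str, RateFunction]
    dependent: dict[tuple[str, str], RateFunction]
    initial_state: np.ndarray
    time_domain: tuple[float, float]

    def __post_init__(self):
        self.traits = tuple(self.traits)
        n = len(self.traits)
        if n < 1:
            raise ValidationError("a system model needs at least one trait")
        if set(self.independent) != set(self.traits):
            raise ValidationError("independent functions must cover every trait")
        expected = {(i, j) for i in self.traits for j in self.traits if i != j}
        if set(self.dependent) != expected:
            raise ValidationError(
                f"dependent map must have exactly the {len(expected)} ordered "
                f"trait pairs; got {sorted(self.dependent)}"
            )
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.shape != (n,):
            raise ValidationError("initial_state length must equal trait count")
        t0, t1 = self.time_domain
        if not t0 < t1:
            raise InvalidDomainError(f"degenerate time domain [{t0}, {t1}]")
        self.time_domain = (float(t0), float(t1))

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def zero_dependent(self) -> "SystemModel":
        """Copy with every dependent (interaction) coefficient set to zero."""
        return replace(
            self,
            independent=dict(self.independent),
            dependent={k: f.zeroed() for k, f in self.dependent.items()},
            initial_state=self.initial_state.copy(),
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "independent": {t: f.to_dict() for t, f in self.independent.items()},
            "dependent": {
                f"{i}|{j}": f.to_dict() for (i, j), f in self.dependent.items()
            },
            "initial_state": self.initial_state.tolist(),
            "time_domain": list(self.time_domain),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemModel":
        dep = {}
        for key, fd in d["dependent"].items():
            i, j = key.split("|")
            dep[(i, j)] = RateFunction.from_dict(fd)
        return cls(
            traits=tuple(d["traits"]),
            independent={t: RateFunction.from_dict(f) for t, f in d["independent"].items()},
            dependent=dep,
            initial_state=np.asarray(d["initial_state"], dtype=float),
            time_domain=tuple(d["time_domain"]),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SystemModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        source = str(source)
        if source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DecompositionResult:
    """Trajectories of one trait split into independent and interactive parts.

    ``net_interactive`` is stored as the pointwise difference
    ``full - independent_only``, so the additive identity holds exactly.
    """

    trait: str
    times: np.ndarray
    full: np.ndarray
    independent_only: np.ndarray
    net_interactive: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.full = np.asarray(self.full, dtype=float)
        self.independent_only = np.asarray(self.independent_only, dtype=float)
        if self.net_interactive is None:
            self.net_interactive = self.full - self.independent_only
        else:
            self.net_interactive = np.asarray(self.net_interactive, dtype=float)


def rate_eval(model: SystemModel, state, clip: bool = False) -> np.ndarray:
    """dp/dt at ``state``: independent term plus the sum of dependent terms."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_traits,):
        raise ValidationError(
            f"state length {state.size} != {model.n_traits} traits"
        )
    out = np.empty(model.n_traits)
    for k, trait in enumerate(model.traits):
        r = model.independent[trait](state[k : k + 1], clip=clip)[0]
        for j, other in enumerate(model.traits):
            if other == trait:
                continue
            r += model.dependent[(trait, other)](state[j : j + 1], clip=clip)[0]
        out[k] = r
    return out


def _stacked_thetas(models: list[SystemModel]):
    """Stack coefficients of models sharing traits and basis specs."""
    ref = models[0]
    for m in models[1:]:
        if m.traits != ref.traits:
            raise ValidationError("batched integration requires identical traits")
        for t in ref.traits:
            if m.independent[t].basis != ref.independent[t].basis:
                raise ValidationError("batched integration requires shared bases")
        for k in ref.dependent:
            if m.dependent[k].basis != ref.dependent[k].basis:
                raise ValidationError("batched integration requires shared bases")
    indep = {t: np.stack([m.independent[t].theta for m in models]) for t in ref.traits}
    dep = {k: np.stack([m.dependent[k].theta for m in models]) for k in ref.dependent}
    return ref, indep, dep


def _batch_rates(ref: SystemModel, indep, dep, states: np.ndarray) -> np.ndarray:
    """Rates for G models at G states simultaneously; states is (G, n)."""
    out = np.zeros_like(states)
    for k, trait in enumerate(ref.traits):
        V = basis_design(states[:, k], ref.independent[trait].basis, clip=True)
        out[:, k] += np.einsum("gb,gb->g", V, indep[trait])
        for j, other in enumerate(ref.traits):
            if other == trait:
                continue
            B = ref.dependent[(trait, other)].basis
            Vd = basis_design(states[:, j], B, clip=True)
            out[:, k] += np.einsum("gb,gb->g", Vd, dep[(trait, other)])
    return out


def _clip_states(ref: SystemModel, states: np.ndarray):
    """Clip each trait's state column to its independent-basis domain."""
    clips = 0
    for k, trait in enumerate(ref.traits):
        lo, hi = ref.independent[trait].basis.domain
        col = states[:, k]
        n_bad = int(np.count_nonzero((col < lo) | (col > hi)))
        if n_bad:
            clips += n_bad
            np.clip(col, lo, hi, out=col)
    return clips


def _poly_tensor(models: list[SystemModel], ref: SystemModel):
    """Stack all rate functions as standard polynomials of the scaled state.

    Returns ``(P, a, b, lo, hi)`` with P of shape (G, n, n, dmax+1): entry
    (g, i, j) is the polynomial (in u_j = a_j x_j + b_j) contributed by
    trait j to trait i's rate in model g; the diagonal holds the
    independent terms.  None when a model is outside the fast path
    (non-Legendre bases, or dependent domains differing from the driver's
    independent domain).
    """
    traits = ref.traits
    n = len(traits)
    for m in models:
        for t in traits:
            if m.independent[t].basis.family != "legendre":
                return None
        for (i, j), f in m.dependent.items():
            if f.basis.family != "legendre":
                return None
            if f.basis.domain != m.independent[j].basis.domain:
                return None
    dmax = max(
        [ref.independent[t].basis.order for t in traits]
        + [f.basis.order for f in ref.dependent.values()]
        + [0]
    )
    G = len(models)
    P = np.zeros((G, n, n, dmax + 1))
    for g, m in enumerate(models):
        for i, ti in enumerate(traits):
            c = _leg.leg2poly(m.independent[ti].theta)
            P[g, i, i, : c.size] = c
            for j, tj in enumerate(traits):
                if i == j:
                    continue
                c = _leg.leg2poly(m.dependent[(ti, tj)].theta)
                P[g, i, j, : c.size] = c
    lo = np.array([ref.independent[t].basis.domain[0] for t in traits])
    hi = np.array([ref.independent[t].basis.domain[1] for t in traits])
    a = 2.0 / (hi - lo)
    b = -(hi + lo) / (hi - lo)
    return P, a, b, lo, hi


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _rk4_kernel(P, a, b, lo, hi, x0, t0, times, step):  # pragma: no cover
        G, n, _, D = P.shape
        T = times.shape[0]
        out = np.empty((G, T, n))
        x = x0.copy()
        clips = 0
        for g in range(G):
            for i in range(n):
                if x[g, i] < lo[i]:
                    x[g, i] = lo[i]
                    clips += 1
                elif x[g, i] > hi[i]:
                    x[g, i] = hi[i]
                    clips += 1
        rates = np.empty((4, G, n))
        stage_state = np.empty((G, n))
        t = t0
        for idx in range(T):
            dt_total = times[idx] - t
            if dt_total > 1e-12:
                nsub = int(np.ceil(dt_total / step - 1e-12))
                if nsub < 1:
                    nsub = 1
                h = dt_total / nsub
                for _s in range(nsub):
                    for s in range(4):
                        for g in range(G):
                            for i in range(n):
                                if s == 0:
                                    xs = x[g, i]
                                elif s == 3:
                                    xs = x[g, i] + h * rates[2, g, i]
                                else:
                                    xs = x[g, i] + 0.5 * h * rates[s - 1, g, i]
                                if xs < lo[i]:
                                    xs = lo[i]
                                elif xs > hi[i]:
                                    xs = hi[i]
                                stage_state[g, i] = xs
                        for g in range(G):
                            for i in range(n):
                                acc = 0.0
                                for j in range(n):
                                    u = a[j] * stage_state[g, j] + b[j]
                                    val = P[g, i, j, D - 1]
                                    for d in range(D - 2, -1, -1):
                                        val = val * u + P[g, i, j, d]
                                    acc += val
                                rates[s, g, i] = acc
                    for g in range(G):
                        for i in range(n):
                            xn = x[g, i] + (h / 6.0) * (
                                rates[0, g, i]
                                + 2.0 * rates[1, g, i]
                                + 2.0 * rates[2, g, i]
                                + rates[3, g, i]
                            )
                            if xn < lo[i]:
                                xn = lo[i]
                                clips += 1
                            elif xn > hi[i]:
                                xn = hi[i]
                                clips += 1
                            x[g, i] = xn
                    t += h
                t = times[idx]
            for g in range(G):
                for i in range(n):
                    out[g, idx, i] = x[g, i]
        return out, clips


def integrate_batch(
    models: list[SystemModel], times, step: float | None = None
) -> np.ndarray:
    """Integrate G structurally identical models at once; returns (G, T, n).

    Classic fixed-step RK4; states are clipped to the basis domains at every
    substep (polynomial extrapolation outside the fitted state range is
    meaningless), with clip events logged.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a non-empty strictly increasing 1-D array")
    ref, indep, dep = _stacked_thetas(models)
    t0, t1 = ref.time_domain
    if times[0] < t0 - 1e-9 or times[-1] > t1 + 1e-9:
        raise ValidationError(
            f"requested times [{times[0]}, {times[-1]}] exceed the model time "
            f"domain [{t0}, {t1}]"
        )
    if step is None:
        grid = np.min(np.diff(times)) if times.size > 1 else DEFAULT_STEP_CAP
        step = min(DEFAULT_STEP_CAP, grid) / 3.0
    if _HAVE_NUMBA:
        poly = _poly_tensor(models, ref)
        if poly is not None:
            P, a, b, dlo, dhi = poly
            x0 = np.stack([m.initial_state.astype(float) for m in models])
            out, clips = _rk4_kernel(
                P, a, b, dlo, dhi, x0, float(t0), times, float(step)
            )
            if not np.all(np.isfinite(out)):
                raise IntegrationError("state became non-finite during integration")
            if clips:
                log.debug("integration clipped %d state evaluations", clips)
            return out
    G, n = len(models), ref.n_traits
    states = np.stack([m.initial_state.astype(float) for m in models])
    clips = _clip_states(ref, states)
    out = np.empty((G, times.size, n))
    t = t0
    for idx, t_target in enumerate(times):
        dt_total = t_target - t
        if dt_total > 1e-12:
            n_sub = max(1, int(np.ceil(dt_total / step - 1e-12)))
            h = dt_total / n_sub
            for _ in range(n_sub):
                k1 = _batch_rates(ref, indep, dep, states)
                k2 = _batch_rates(ref, indep, dep, states + 0.5 * h * k1)
                k3 = _batch_rates(ref, indep, dep, states + 0.5 * h * k2)
                k4 = _batch_rates(ref, indep, dep, states + h * k3)
                states = states + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                clips += _clip_states(ref, states)
                t += h
                if not np.all(np.isfinite(states)):
                    raise IntegrationError(
                        f"state became non-finite at t = {t:g} min", time_reached=t
                    )
            t = t_target
        out[:, idx, :] = states
    if clips:
        log.debug("integration clipped %d state evaluations to basis domains", clips)
    return out


def integrate(model: SystemModel, times, step: float | None = None) -> np.ndarray:
    """Numerical solution from ``initial_state``, evaluated at ``times``.

    Fixed-step classic RK4 with step = min(3 min, output interval)/3 by
    default; deterministic, and accurate to well below 1e-6 for the smooth
    drydown dynamics this package targets.
    """
    return integrate_batch([model], times, step=step)[0]


def decompose(model: SystemModel, times, trait: str) -> DecompositionResult:
    """Split one trait's fitted trajectory into independent and interactive parts.

    Integrates the full system and the system with every dependent
    coefficient zeroed; the net interactive effect is their pointwise
    difference (exactly, by construction).
    """
    if trait not in model.traits:
        raise ValidationError(f"trait {trait!r} not in model traits {model.traits}")
    k = model.traits.index(trait)
    full = integrate(model, times)[:, k]
    indep = integrate(model.zero_dependent(), times)[:, k]
    return DecompositionResult(
        trait=trait, times=np.asarray(times, dtype=float), full=full,
        independent_only=indep,
    )


def interaction_score(
    model: SystemModel,
    pair: tuple[str, str],
    state_range: tuple[float, float],
    n_grid: int = 201,
    neutral_rtol: float = 1e-9,
):
    """Mean of the dependent function f_{i|i'} over a uniform state grid.

    Returns ``(score, label)`` with label ``cooperation`` for a positive
    mean, ``competition`` for a negative one, and ``neutral`` when the mean
    is within ``neutral_rtol * range width`` of zero.
    """
    if pair not in model.dependent:
        raise ValidationError(f"{pair!r} is not an ordered trait pair of the model")
    lo, hi = state_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise InvalidDomainError(f"degenerate state range [{lo}, {hi}]")
    grid = np.linspace(lo, hi, n_grid)
    score = float(np.mean(model.dependent[pair](grid, clip=True)))
    tol = neutral_rtol * (hi - lo)
    if score > tol:
        label = "cooperation"
    elif score < -tol:
        label = "competition"
    else:
        label = "neutral"
    return score, label
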