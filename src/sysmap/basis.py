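"""Nonparametric bases for rate functions.

Rate functions of the coupled trait system are expansions in either
unnormalized Legendre polynomials (P_n with P_n(1) = 1) or cubic B-splines,
evaluated on a per-trait state domain that is affinely mapped to [-1, 1].
The Legendre family is the workhorse of functional trait mapping; B-splines
are offered as the usual alternative for wigglier rate shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as _leg
from scipy.interpolate import BSpline

from .errors import InvalidDomainError, OutOfDomainError

#: Relative tolerance (fraction of domain width) within which values outside
#: the domain are silently clipped to the edge before basis evaluation.
CLIP_RTOL = 1e-8

_CUBIC = 3


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional function basis.

    Parameters
    ----------
    family : {"legendre", "bspline"}
        ``legendre``: unnormalized Legendre polynomials P_0..P_order on the
        domain mapped to [-1, 1].  ``bspline``: cubic B-splines with
        ``order`` uniformly spaced interior knots.
    order : int
        Polynomial degree (legendre) or interior knot count (bspline).
    domain : (float, float)
        Closed state interval on which the basis lives; must be
        non-degenerate.
    """

    family: str
    order: int
    domain: tuple[float, float]

    def __post_init__(self):
        if self.family not in ("legendre", "bspline"):
            raise InvalidDomainError(f"unknown basis family {self.family!r}")
        if self.order < 0:
            raise InvalidDomainError(f"basis order must be >= 0, got {self.order}")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
            raise InvalidDomainError(f"degenerate basis domain [{lo}, {hi}]")
        object.__setattr__(self, "domain", (float(lo), float(hi)))

    @property
    def n_basis(self) -> int:
        """Number of basis functions (order+1 legendre, order+4 cubic bspline)."""
        if self.family == "legendre":
            return self.order + 1
        return self.order + _CUBIC + 1

    def with_domain(self, domain: tuple[float, float]) -> "BasisSpec":
        return BasisSpec(self.family, self.order, domain)

    def to_dict(self) -> dict:
        return {"family": self.family, "order": self.order, "domain": list(self.domain)}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(d["family"], int(d["order"]), tuple(d["domain"]))


def scale_to_domain(x, domain: tuple[float, float]):
    """Affinely map ``x`` from ``domain`` onto [-1, 1] (lo -> -1, hi -> +1)."""
    lo, hi = domain
    if lo >= hi:
        raise InvalidDomainError(f"degenerate domain [{lo}, {hi}]")
    return (2.0 * np.asarray(x, dtype=float) - (lo + hi)) / (hi - lo)


def _check_and_clip(values: np.ndarray, spec: BasisSpec, clip: bool) -> np.ndarray:
    lo, hi = spec.domain
    tol = CLIP_RTOL * (hi - lo)
    if clip:
        return np.clip(values, lo, hi)
    bad = (values < lo - tol) | (values > hi + tol)
    if np.any(bad):
        offender = float(values[bad][0])
        raise OutOfDomainError(
            f"value {offender:g} outside basis domain [{lo:g}, {hi:g}]"
        )
    return np.clip(values, lo, hi)


def basis_design(values, spec: BasisSpec, clip: bool = False) -> np.ndarray:
    """Design matrix of shape (len(values), spec.n_basis).

    Row k holds the basis functions evaluated at ``values[k]`` after mapping
    the domain to [-1, 1].  Values outside the domain raise
    :class:`OutOfDomainError` unless within a rounding tolerance or
    ``clip=True`` (integration callers clip; see module docs).
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    values = _check_and_clip(values, spec, clip)
    u = scale_to_domain(values, spec.domain)
    if spec.family == "legendre":
        return _leg.legvander(u, spec.order)
    # cubic B-spline with `order` uniform interior knots on [-1, 1]
    interior = np.linspace(-1.0, 1.0, spec.order + 2)[1:-1]
    knots = np.concatenate([[-1.0] * (_CUBIC + 1), interior, [1.0] * (_CUBIC + 1)])
    return BSpline.design_matrix(u, knots, _CUBIC, extrapolate=False).toarray()


def basis_eval(values, spec: BasisSpec, theta, clip: bool = False) -> np.ndarray:
    """Evaluate the expansion sum_k theta_k B_k at ``values``."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_basis,):
        raise ValueError(
            f"theta length {theta.shape} does not match {spec.n_basis} basis functions"
        )
    return basis_design(values, spec, clip=clip) @ theta


# ---------------------------------------------------------------------------
# Anchored bases.
#
# An additive rate decomposition f_i(p_i) + sum f_{i|i'}(p_{i'}) is only
# identified up to constants: any constant can be moved between the
# independent term and an interaction term without changing the dynamics.
# We pin the interaction terms by requiring f_{i|i'}(ref) = 0 at a reference
# driver state (default 0: a trait at zero contributes nothing to any other
# trait's rate).  The anchored basis spans exactly the functions in the
# original span that vanish at ref, with one fewer degree of freedom.
# ---------------------------------------------------------------------------

DEFAULT_ANCHOR = 0.0


def _ref_row(spec: BasisSpec, ref: float) -> np.ndarray:
    """Basis functions evaluated at the (possibly out-of-domain) anchor state."""
    u = float(scale_to_domain(ref, spec.domain))
    if spec.family == "legendre":
        return _leg.legvander(np.array([u]), spec.order)[0]
    # B-splines have compact support; an anchor outside [-1, 1] evaluates to 0
    interior = np.linspace(-1.0, 1.0, spec.order + 2)[1:-1]
    knots = np.concatenate([[-1.0] * (_CUBIC + 1), interior, [1.0] * (_CUBIC + 1)])
    uc = min(max(u, -1.0), 1.0)
    row = BSpline.design_matrix(np.array([uc]), knots, _CUBIC).toarray()[0]
    return row if -1.0 <= u <= 1.0 else np.zeros_like(row)


def n_anchored(spec: BasisSpec) -> int:
    """Free coefficient count of the anchored basis (one less than n_basis)."""
    return spec.n_basis - 1


def anchored_design(values, spec: BasisSpec, ref: float = DEFAULT_ANCHOR,
                    clip: bool = False) -> np.ndarray:
    """Design matrix of the anchored basis {B_k - B_k(ref) * 1, k >= 1}.

    For the Legendre family B_0 = 1, so the columns are simply
    P_k(u) - P_k(u_ref) for k = 1..order; for B-splines the constant is the
    partition-of-unity sum of all basis functions.
    """
    D = basis_design(values, spec, clip=clip)
    r = _ref_row(spec, ref)
    return D[:, 1:] - r[1:]


def theta_from_anchored(coef, spec: BasisSpec, ref: float = DEFAULT_ANCHOR) -> np.ndarray:
    """Full coefficient vector of the function sum_k coef_k (B_k - B_k(ref))."""
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (n_anchored(spec),):
        raise ValueError(
            f"anchored coefficient length {coef.size} != {n_anchored(spec)}"
        )
    theta = np.concatenate([[0.0], coef])
    shift = float(_ref_row(spec, ref)[1:] @ coef)
    if spec.family == "legendre":
        theta[0] -= shift  # constant direction is P_0
    else:
        theta -= shift  # constant direction is sum of all B-splines
    return theta


def anchored_from_theta(theta, spec: BasisSpec, ref: float = DEFAULT_ANCHOR) -> np.ndarray:
    """Free coordinates of a full coefficient vector satisfying f(ref) = 0."""
    theta = np.asarray(theta, dtype=float)
    if spec.family == "legendre":
        return theta[1:].copy()
    return theta[1:] - theta[0]
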