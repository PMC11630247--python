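"""Critical soil water content from the midday transpiration response.

Below a critical volumetric soil water content (theta_cri) the plant can no
longer sustain its midday transpiration and TR falls with further drying;
above it, TR is water-unlimited and flat.  The estimator is the standard
continuous two-segment broken-stick fit to paired midday (VWC, TR)
observations: a flat wet segment (optionally free-sloped) joined at the
breakpoint to a declining dry segment.  The breakpoint is located by a
grid search over interior VWC quantiles followed by golden-section
refinement; segment parameters are least squares conditional on the
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .data import TrajectorySet
from .errors import EmptyWindowError, UnidentifiableBreakpointError, ValidationError

MIN_POINTS = 10
#: Default midday clock window, half-open, minutes since midnight.
DEFAULT_WINDOW = (660.0, 780.0)  # 11:00-13:00


@dataclass
class ThetaCriFit:
    """Broken-stick fit: breakpoint, wet-segment level, dry-segment slope."""

    theta_cri: float
    plateau_level: float
    slope_dry: float
    rss: float
    se_theta: float | None = None

    def to_dict(self) -> dict:
        return {
            "theta_cri": self.theta_cri,
            "plateau_level": self.plateau_level,
            "slope_dry": self.slope_dry,
            "rss": self.rss,
            "se_theta": self.se_theta,
        }


def extract_midday(
    traj_set: TrajectorySet,
    window: tuple[float, float] = DEFAULT_WINDOW,
    start_clock_min: float = 0.0,
    x_trait: str = "TR",
    y_trait: str = "VWC",
):
    """Paired (VWC, TR) observations whose clock time falls in the window.

    ``window`` is half-open [start, end) in minutes since midnight; sample
    timestamps are minutes since experiment start, offset by
    ``start_clock_min``.  Pairs with either member missing are dropped.
    """
    lo, hi = window
    if hi <= lo:
        raise EmptyWindowError(f"degenerate clock window [{lo}, {hi})")
    vwc_all, tr_all = [], []
    for sid, d in traj_set.by_sample().items():
        if x_trait not in d or y_trait not in d:
            continue
        times = d[x_trait].times
        clock = np.mod(times + start_clock_min, 1440.0)
        sel = (clock >= lo) & (clock < hi)
        tr = d[x_trait].values[sel]
        vwc = d[y_trait].values[sel]
        ok = np.isfinite(tr) & np.isfinite(vwc)
        vwc_all.append(vwc[ok])
        tr_all.append(tr[ok])
    if not vwc_all or not np.concatenate(vwc_all).size:
        raise EmptyWindowError(
            f"no paired ({y_trait}, {x_trait}) observations in clock window [{lo}, {hi})"
        )
    return np.concatenate(vwc_all), np.concatenate(tr_all)


class ThetaCriRegressor(BaseEstimator, RegressorMixin):
    """Continuous two-segment (broken-stick) regression of TR on VWC.

    Parameters
    ----------
    free_wet_slope : bool
        False (default) keeps the wet segment flat; True allows a free
        slope above the breakpoint.
    n_grid : int
        Breakpoint candidates on interior VWC quantiles (2.5%-97.5%).
    n_boot : int
        Pair-resampling bootstrap replicates for the breakpoint SE
        (0 = skip).
    random_state : int
        Bootstrap seed.

    Attributes
    ----------
    theta_cri_, plateau_, slope_, rss_, se_theta_
    """

    def __init__(self, free_wet_slope=False, n_grid=200, quantile_lo=0.025,
                 quantile_hi=0.975, n_boot=0, random_state=0):
        self.free_wet_slope = free_wet_slope
        self.n_grid = n_grid
        self.quantile_lo = quantile_lo
        self.quantile_hi = quantile_hi
        self.n_boot = n_boot
        self.random_state = random_state

    def _rss_at(self, theta, v, y):
        below = np.minimum(v - theta, 0.0)
        cols = [np.ones_like(v), below]
        if self.free_wet_slope:
            cols.append(np.maximum(v - theta, 0.0))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), beta

    def _search(self, v, y):
        qs = np.linspace(self.quantile_lo, self.quantile_hi, self.n_grid)
        cand = np.unique(np.quantile(v, qs))
        interior = cand[(cand > v.min()) & (cand < v.max())]
        if interior.size == 0:
            raise UnidentifiableBreakpointError(
                "no interior breakpoint candidates (all points on one side)"
            )
        rss = np.array([self._rss_at(c, v, y)[0] for c in interior])
        best = int(np.argmin(rss))
        ties = np.flatnonzero(rss <= rss[best] + 1e-12)
        best = int(ties[0])  # smallest theta among ties
        lo = interior[max(0, best - 1)]
        hi = interior[min(interior.size - 1, best + 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda th: self._rss_at(th, v, y)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun <= rss[best] + 1e-12:
                return float(res.x)
        return float(interior[best])

    def fit(self, X, y):
        v = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(v) & np.isfinite(y)
        v, y = v[ok], y[ok]
        if v.size < MIN_POINTS:
            raise ValidationError(
                f"{v.size} points; broken-stick fit needs >= {MIN_POINTS}"
            )
        theta = self._search(v, y)
        rss, beta = self._rss_at(theta, v, y)
        flat_resid = y - y.mean()
        flat_rss = float(flat_resid @ flat_resid)
        if rss >= flat_rss - 1e-12 * max(1.0, flat_rss):
            raise UnidentifiableBreakpointError(
                "no breakpoint improves on the single-segment fit "
                f"(RSS {rss:.6g} vs flat {flat_rss:.6g})"
            )
        self.theta_cri_ = theta
        self.plateau_ = float(beta[0])
        self.slope_ = float(beta[1])
        self.wet_slope_ = float(beta[2]) if self.free_wet_slope else 0.0
        self.rss_ = rss
        self.se_theta_ = None
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            boots = []
            for _ in range(self.n_boot):
                idx = rng.integers(0, v.size, v.size)
                try:
                    boots.append(self._search(v[idx], y[idx]))
                except UnidentifiableBreakpointError:
                    continue
            if len(boots) > 1:
                self.se_theta_ = float(np.std(boots, ddof=1))
        return self

    def predict(self, X):
        v = np.asarray(X, dtype=float).ravel()
        out = self.plateau_ + self.slope_ * np.minimum(v - self.theta_cri_, 0.0)
        if self.free_wet_slope:
            out = out + self.wet_slope_ * np.maximum(v - self.theta_cri_, 0.0)
        return out

    @property
    def fit_(self) -> ThetaCriFit:
        return ThetaCriFit(
            theta_cri=self.theta_cri_, plateau_level=self.plateau_,
            slope_dry=self.slope_, rss=self.rss_, se_theta=self.se_theta_,
        )


def fit_theta_cri(
    vwc, tr, free_wet_slope: bool = False, n_boot: int = 0, random_state: int = 0
) -> ThetaCriFit:
    """Fit the broken-stick midday response and return the breakpoint fit."""
    est = ThetaCriRegressor(
        free_wet_slope=free_wet_slope, n_boot=n_boot, random_state=random_state
    )
    est.fit(vwc, tr)
    return est.fit_
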