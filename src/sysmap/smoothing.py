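"""Curve smoothing, derivative estimation, and genotype-mean curves.

Gradient matching needs the observed trajectories as smooth curves with
derivatives.  The smoother is a least-squares cubic regression spline whose
interior knots are spaced ``bandwidth_minutes`` apart: with the default
24-h bandwidth the spline tracks the multi-day drydown envelope and leaves
diurnal oscillation in the residual; a 2-h bandwidth resolves sub-daily
structure.  Derivatives come from the spline's analytic derivative, never
from finite differences of noisy data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .data import TraitTrajectory, TrajectorySet
from .errors import TooShortError, ValidationError

log = logging.getLogger(__name__)

MIN_POINTS = 10

#: Default bandwidth: one day, so the fitted ODE captures the drydown
#: envelope.  Use ~120 for explicit sub-daily modeling.
DEFAULT_BANDWIDTH_MIN = 1440.0


@dataclass
class SmoothedTrajectory:
    """Smoothed values and analytic first derivative of one trajectory."""

    sample_id: str
    genotype_id: str
    replicate: int
    trait: str
    times: np.ndarray
    values_hat: np.ndarray
    derivs_hat: np.ndarray

    def __post_init__(self):
        if not (len(self.times) == len(self.values_hat) == len(self.derivs_hat)):
            raise ValidationError("smoothed arrays must share one length")


def _fit_spline(times: np.ndarray, values: np.ndarray, bandwidth: float):
    lo, hi = times[0], times[-1]
    n_interior = max(0, int(np.floor((hi - lo) / bandwidth)) - 1)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior else np.array([])
    # keep the LS problem overdetermined even for short series
    max_knots = max(0, len(times) - 8)
    if interior.size > max_knots:
        interior = interior[:: int(np.ceil(interior.size / max_knots))] if max_knots else np.array([])
    return LSQUnivariateSpline(times, values, interior, k=3)


def smooth_trajectory(
    traj: TraitTrajectory, bandwidth_minutes: float = DEFAULT_BANDWIDTH_MIN
) -> SmoothedTrajectory:
    """Smooth a single trajectory; missing values are bridged only inside the
    observed span (leading/trailing gaps stay NaN)."""
    mask = np.isfinite(traj.values)
    n_obs = int(mask.sum())
    if n_obs < MIN_POINTS:
        raise TooShortError(
            f"{traj.sample_id}/{traj.trait}: {n_obs} observed points "
            f"(need >= {MIN_POINTS})"
        )
    t_obs, v_obs = traj.times[mask], traj.values[mask]
    spl = _fit_spline(t_obs, v_obs, bandwidth_minutes)
    inside = (traj.times >= t_obs[0]) & (traj.times <= t_obs[-1])
    vals = np.full_like(traj.values, np.nan)
    ders = np.full_like(traj.values, np.nan)
    vals[inside] = spl(traj.times[inside])
    ders[inside] = spl.derivative()(traj.times[inside])
    return SmoothedTrajectory(
        sample_id=traj.sample_id,
        genotype_id=traj.genotype_id,
        replicate=traj.replicate,
        trait=traj.trait,
        times=traj.times.copy(),
        values_hat=vals,
        derivs_hat=ders,
    )


def smooth_trajectories(
    traj_set: TrajectorySet, bandwidth_minutes: float = DEFAULT_BANDWIDTH_MIN
) -> list[SmoothedTrajectory]:
    """Smooth every trajectory of a set; all-missing trajectories are skipped
    with a warning, too-short ones raise."""
    out = []
    for tr in traj_set.trajectories:
        if tr.n_observed == 0:
            log.warning("skipping all-missing trajectory %s/%s", tr.sample_id, tr.trait)
            continue
        out.append(smooth_trajectory(tr, bandwidth_minutes))
    return out


def deflate_diurnal(
    traj: TraitTrajectory,
    bandwidth_minutes: float = DEFAULT_BANDWIDTH_MIN,
    period_minutes: float = 1440.0,
    profile_window_minutes: float = 90.0,
) -> TraitTrajectory:
    """Remove a multiplicative daily cycle from a flux-like trait.

    Transpiration-type fluxes are modulated by a roughly repeatable daily
    profile (light-driven, zero at night).  The profile is estimated as the
    clock-binned mean of observation/envelope ratios across days, smoothed
    circularly and normalized to unit day-mean, then divided out.  The
    corrected series equals the underlying dynamic state up to one overall
    scale factor, so rate-function signs and shapes are preserved.
    """
    mask = np.isfinite(traj.values)
    if mask.sum() < MIN_POINTS:
        return traj
    t_obs, v_obs = traj.times[mask], traj.values[mask]
    envelope = _fit_spline(t_obs, v_obs, bandwidth_minutes)(t_obs)
    scale = np.median(np.abs(envelope))
    safe = np.abs(envelope) > 0.05 * scale
    ratio = np.ones_like(v_obs)
    ratio[safe] = v_obs[safe] / envelope[safe]
    # clock-binned profile, averaged over days
    step = np.median(np.diff(traj.times)) if traj.times.size > 1 else period_minutes
    n_bins = max(1, int(round(period_minutes / step)))
    bins = (np.round(np.mod(t_obs, period_minutes) / step).astype(int)) % n_bins
    prof = np.ones(n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=ratio, minlength=n_bins)
    got = counts > 0
    prof[got] = sums[got] / counts[got]
    # circular moving-average smoothing of the profile
    half = max(1, int(round(profile_window_minutes / (2 * step))))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    prof = np.convolve(np.concatenate([prof[-half:], prof, prof[:half]]), kernel,
                       mode="same")[half:-half]
    prof /= prof.mean()
    prof = np.maximum(prof, 1e-3)
    all_bins = (np.round(np.mod(traj.times, period_minutes) / step).astype(int)) % n_bins
    corrected = traj.values / prof[all_bins]
    return TraitTrajectory(
        traj.sample_id, traj.genotype_id, traj.replicate, traj.trait,
        traj.times.copy(), corrected, traj.unit,
    )


def deflate_diurnal_set(
    traj_set: TrajectorySet, traits=("TR",), **kwargs
) -> TrajectorySet:
    """Apply :func:`deflate_diurnal` to the named traits of every sample."""
    out = [
        deflate_diurnal(tr, **kwargs) if tr.trait in traits else tr
        for tr in traj_set.trajectories
    ]
    return TrajectorySet(out, traj_set.traits, traj_set.grid_minutes)


def genotype_mean_curves(traj_set: TrajectorySet) -> TrajectorySet:
    """Pointwise replicate means per genotype and trait (missing excluded
    pairwise), the mean vectors the system model is fitted to by default.

    Output sample ids are ``<genotype>:mean`` so mean-level curves are
    recognizable downstream.
    """
    groups: dict[tuple[str, str], list[TraitTrajectory]] = {}
    for tr in traj_set.trajectories:
        groups.setdefault((tr.genotype_id, tr.trait), []).append(tr)
    empty = []
    means = []
    for (gid, trait), members in groups.items():
        ref_times = members[0].times
        for m in members[1:]:
            if not np.array_equal(m.times, ref_times):
                raise ValidationError(
                    f"genotype {gid}/{trait}: replicates not on a shared time grid"
                )
        stack = np.stack([m.values for m in members])
        counts = np.sum(np.isfinite(stack), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(
                counts > 0, np.nansum(stack, axis=0) / np.maximum(counts, 1), np.nan
            )
        if not np.any(np.isfinite(mean)):
            empty.append(f"{gid}/{trait}")
            continue
        means.append(
            TraitTrajectory(
                sample_id=f"{gid}:mean",
                genotype_id=gid,
                replicate=1,
                trait=trait,
                times=ref_times.copy(),
                values=mean,
                unit=members[0].unit,
            )
        )
    if empty:
        raise ValidationError(
            "genotypes with zero complete time points: " + ", ".join(sorted(empty))
        )
    return TrajectorySet(means, traits=traj_set.traits, grid_minutes=traj_set.grid_minutes)
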