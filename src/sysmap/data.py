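"""Containers for replicated multi-trait time series.

Time is minutes since experiment start, 0-based.  Missing observations are
explicit NaN gaps, never silently dropped, so replicate alignment on the
shared sampling grid is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

PHENOTYPE_COLUMNS = ["sample_id", "genotype_id", "replicate", "time_min", "trait", "value", "unit"]


@dataclass
class TraitTrajectory:
    """One trait of one pot (sample) over time.

    Volumetric soil water content ("VWC") is a volume fraction; its
    non-missing values must lie in [0, 1].
    """

    sample_id: str
    genotype_id: str
    replicate: int
    trait: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError(
                f"{self.sample_id}/{self.trait}: times and values must be equal-length 1-D"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.sample_id}/{self.trait}: times must be strictly increasing"
            )
        if int(self.replicate) < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be a positive integer")
        self.replicate = int(self.replicate)
        if self.trait == "VWC":
            obs = self.values[np.isfinite(self.values)]
            if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
                raise ValidationError(
                    f"{self.sample_id}: VWC values outside [0, 1] "
                    f"(range [{obs.min():g}, {obs.max():g}])"
                )

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(np.isfinite(self.values)))


@dataclass
class TrajectorySet:
    """A collection of trait trajectories on a nominally shared grid."""

    trajectories: list[TraitTrajectory]
    traits: tuple[str, ...]
    grid_minutes: float = 3.0

    def __post_init__(self):
        self.traits = tuple(self.traits)
        for tr in self.trajectories:
            if tr.trait not in self.traits:
                raise ValidationError(
                    f"trajectory {tr.sample_id}/{tr.trait}: trait not in {self.traits}"
                )
        by_sample: dict[str, np.ndarray] = {}
        for tr in self.trajectories:
            ref = by_sample.setdefault(tr.sample_id, tr.times)
            if ref.shape != tr.times.shape or not np.array_equal(ref, tr.times):
                raise ValidationError(
                    f"sample {tr.sample_id}: trajectories do not share one time grid"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trajectories:
            seen.setdefault(tr.sample_id)
        return list(seen)

    @property
    def genotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.trajectories:
            seen.setdefault(tr.genotype_id)
        return list(seen)

    def get(self, sample_id: str, trait: str) -> TraitTrajectory:
        for tr in self.trajectories:
            if tr.sample_id == sample_id and tr.trait == trait:
                return tr
        raise KeyError((sample_id, trait))

    def by_sample(self) -> dict[str, dict[str, TraitTrajectory]]:
        out: dict[str, dict[str, TraitTrajectory]] = {}
        for tr in self.trajectories:
            out.setdefault(tr.sample_id, {})[tr.trait] = tr
        return out

    def subset_genotypes(self, genotype_ids) -> "TrajectorySet":
        keep = set(genotype_ids)
        return TrajectorySet(
            [tr for tr in self.trajectories if tr.genotype_id in keep],
            self.traits,
            self.grid_minutes,
        )

    # -- tidy-frame conversion --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frames = []
        for tr in self.trajectories:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": tr.sample_id,
                        "genotype_id": tr.genotype_id,
                        "replicate": tr.replicate,
                        "time_min": tr.times,
                        "trait": tr.trait,
                        "value": tr.values,
                        "unit": tr.unit,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)[PHENOTYPE_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, traits=None, grid_minutes: float = 3.0) -> "TrajectorySet":
        if traits is None:
            traits = tuple(pd.unique(df["trait"]))
        trajectories = []
        for (sid, trait), g in df.groupby(["sample_id", "trait"], sort=False):
            g = g.sort_values("time_min")
            trajectories.append(
                TraitTrajectory(
                    sample_id=str(sid),
                    genotype_id=str(g["genotype_id"].iloc[0]),
                    replicate=int(g["replicate"].iloc[0]),
                    trait=str(trait),
                    times=g["time_min"].to_numpy(dtype=float),
                    values=g["value"].to_numpy(dtype=float),
                    unit=str(g["unit"].iloc[0]) if "unit" in g else "",
                )
            )
        return cls(trajectories, traits=traits, grid_minutes=grid_minutes)
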