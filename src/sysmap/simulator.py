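"""Synthetic lysimeter drydown experiments with known genetic effects.

The default scenario emulates a progressive-drought experiment: 32 inbred
lines, five replicate pots each, transpiration rate (TR) and volumetric
soil water content (VWC) logged every 3 minutes for six consecutive days
after water withholding.  Pots are covered, so soil water changes only
through transpiration.

Baseline dynamics (per minute, TR in g/min, VWC as volume fraction)::

    dX/dt = a - kX  +  k(18 Y - 10 Y^2)      (TR relaxes toward a
                                              water-dependent target)
    dY/dt =  0      -  c X                   (transpiration draws down
                                              soil water)

with k = 1/1440 (one-day relaxation), a = -2k, c = 1e-5.  The TR target
X*(Y) = -2 + 18Y - 10Y^2 is positive-saturating in soil water, so TR rises
for the first days while water is ample and declines from about the fourth
day — the two-phased drydown pattern.  The drawdown term is negative in TR
(competition); the uptake term is positive in VWC (cooperation).  Both
dependent functions vanish at a zero driver state, matching the anchored
identifiability convention of the estimators.

Observation model: a multiplicative diurnal factor
1 + A * max(0, sin(2*pi*(clock - 6 h)/24 h)) on TR only (zero at night,
amplitude A = 0.6 by default), then additive Gaussian noise per trait.
SNP dosages are binomial(2, MAF) per line; causal SNPs shift named anchored
interaction coefficients additively per dosage copy.  Random streams are
split per pot, so changing the replicate count leaves earlier pots
untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .basis import BasisSpec, anchored_from_theta, theta_from_anchored
from .association import GenotypeMatrix
from .data import TraitTrajectory, TrajectorySet
from .errors import ConfigRejectionError, InsufficientSpanError, ValidationError
from .model import RateFunction, SystemModel, integrate_batch
from .smoothing import genotype_mean_curves, smooth_trajectories

GENERATOR_VERSION = "1"

K_RELAX = 1.0 / 1440.0  # one-day TR relaxation rate, 1/min
C_DRAWDOWN = 1.0e-5  # VWC loss per unit TR per minute
TR_DOMAIN = (0.0, 6.0)
VWC_DOMAIN = (0.0, 0.5)


def default_baseline_model(days: int = 6) -> SystemModel:
    """The documented default two-trait drydown system (see module docs)."""
    tr_i = BasisSpec("legendre", 3, TR_DOMAIN)
    vwc_i = BasisSpec("legendre", 3, VWC_DOMAIN)
    tr_d = BasisSpec("legendre", 2, TR_DOMAIN)  # f_{VWC|TR}(X)
    vwc_d = BasisSpec("legendre", 2, VWC_DOMAIN)  # f_{TR|VWC}(Y)
    k, c = K_RELAX, C_DRAWDOWN
    # f_TR(X) = -2k - kX on [0, 6]:   X = 3(u+1)  ->  -5k - 3k u
    f_tr = RateFunction(tr_i, k * np.array([-5.0, -3.0, 0.0, 0.0]))
    # f_VWC(Y) = 0 (covered pot: no independent soil-water change)
    f_vwc = RateFunction(vwc_i, np.zeros(4))
    # f_TR|VWC(Y) = k (18 Y - 10 Y^2) on [0, 0.5]:  Y = (u+1)/4
    #   -> k (-0.625 u^2 + 3.25 u + 3.875); u^2 = (2 P2 + 1)/3
    f_tr_vwc = RateFunction(vwc_d, k * np.array([3.875 - 0.625 / 3, 3.25, -1.25 / 3]))
    # f_VWC|TR(X) = -c X on [0, 6]:  -> -3c (u + 1)
    f_vwc_tr = RateFunction(tr_d, c * np.array([-3.0, -3.0, 0.0]))
    return SystemModel(
        traits=("TR", "VWC"),
        independent={"TR": f_tr, "VWC": f_vwc},
        dependent={("TR", "VWC"): f_tr_vwc, ("VWC", "TR"): f_vwc_tr},
        initial_state=np.array([2.6, 0.42]),
        time_domain=(0.0, days * 1440.0),
    )


@dataclass
class CausalEffect:
    """Additive per-dosage shift of one anchored interaction coefficient."""

    snp_id: str
    pair: tuple[str, str]  # dependent function (target trait, driver trait)
    coef_index: int  # index among the anchored (free) coefficients
    effect: float

    def to_dict(self) -> dict:
        return {"snp_id": self.snp_id, "pair": list(self.pair),
                "coef_index": self.coef_index, "effect": self.effect}


@dataclass
class ScenarioConfig:
    """Study design and generative parameters; defaults are the reference
    drydown design (32 lines x 5 replicates, 3-min grid, 6 days)."""

    n_genotypes: int = 32
    n_replicates: int = 5
    days: int = 6
    grid_minutes: float = 3.0
    n_snps: int = 200
    causal_snps: list[CausalEffect] = field(default_factory=list)
    diurnal_amplitude: float = 0.6
    noise_sd: dict = field(default_factory=lambda: {"TR": 0.15, "VWC": 0.005})
    init_sd: dict = field(default_factory=lambda: {"TR": 0.15, "VWC": 0.015})
    init_clip: dict = field(
        default_factory=lambda: {"TR": (2.35, 2.85), "VWC": (0.405, 0.45)}
    )
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    units: dict = field(default_factory=lambda: {"TR": "g/min", "VWC": "m3/m3"})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["causal_snps"] = [c.to_dict() for c in self.causal_snps]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["causal_snps"] = [
            CausalEffect(c["snp_id"], tuple(c["pair"]), int(c["coef_index"]),
                         float(c["effect"]))
            for c in d.get("causal_snps", [])
        ]
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SimTruth:
    """Everything needed to regenerate and to grade recovery: per-genotype
    coefficients, causal effects, seed, generator version."""

    config: ScenarioConfig
    genotype_models: dict  # genotype_id -> SystemModel dict
    causal: list
    seed: int
    version: str = GENERATOR_VERSION

    def to_json(self, path=None) -> str:
        doc = {
            "config": self.config.to_dict(),
            "genotype_models": self.genotype_models,
            "causal": [c.to_dict() for c in self.causal],
            "seed": self.seed,
            "version": self.version,
        }
        s = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        cfg = ScenarioConfig.from_dict(doc["config"])
        return cls(
            config=cfg, genotype_models=doc["genotype_models"],
            causal=cfg.causal_snps, seed=doc["seed"], version=doc["version"],
        )


def _genotype_models(config: ScenarioConfig, baseline: SystemModel,
                     dosages: np.ndarray, snp_ids: list[str]) -> list[SystemModel]:
    models = []
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    # genotype-level starting-state variation (plant size, initial soil
    # water): shared by all replicates of a line, truncated to keep every
    # line inside the two-phase drydown regime
    rng_init = np.random.default_rng([int(config.seed) % (2**31), 3])
    inits = np.empty((config.n_genotypes, len(baseline.traits)))
    for k, t in enumerate(baseline.traits):
        sd = float(config.init_sd.get(t, 0.0))
        draw = baseline.initial_state[k] + rng_init.normal(0.0, sd, config.n_genotypes)
        lo, hi = config.init_clip.get(t, (-np.inf, np.inf))
        inits[:, k] = np.clip(draw, lo, hi)
    for g in range(config.n_genotypes):
        dep = {k: RateFunction(f.basis, f.theta.copy()) for k, f in baseline.dependent.items()}
        for eff in config.causal_snps:
            if eff.pair not in dep:
                raise ValidationError(f"causal effect names unknown pair {eff.pair}")
            if eff.snp_id not in snp_index:
                raise ValidationError(f"causal effect names unknown SNP {eff.snp_id}")
            f = dep[eff.pair]
            free = anchored_from_theta(f.theta, f.basis)
            if not 0 <= eff.coef_index < free.size:
                raise ValidationError(
                    f"coef_index {eff.coef_index} out of range for {eff.pair}"
                )
            free[eff.coef_index] += eff.effect * dosages[g, snp_index[eff.snp_id]]
            dep[eff.pair] = RateFunction(f.basis, theta_from_anchored(free, f.basis))
        models.append(
            SystemModel(
                traits=baseline.traits,
                independent={t: RateFunction(f.basis, f.theta.copy())
                             for t, f in baseline.independent.items()},
                dependent=dep,
                initial_state=inits[g],
                time_domain=baseline.time_domain,
            )
        )
    return models


def diurnal_factor(times_min: np.ndarray, amplitude: float) -> np.ndarray:
    """1 + A*max(0, sin) day cycle, zero at night; day starts 06:00."""
    clock = np.mod(times_min, 1440.0)
    return 1.0 + amplitude * np.maximum(0.0, np.sin(2 * np.pi * (clock - 360.0) / 1440.0))


def simulate_population(
    config: ScenarioConfig, baseline: SystemModel | None = None
):
    """Generate one synthetic experiment.

    Returns ``(TrajectorySet, GenotypeMatrix, SimTruth)``; byte-identical
    for identical config and seed.
    """
    if baseline is None:
        baseline = default_baseline_model(days=config.days)
    seed = int(config.seed) % (2**31)
    lo, hi = config.maf_range
    if not 0 < lo <= hi < 1:
        raise ValidationError(f"maf_range must satisfy 0 < lo <= hi < 1, got {config.maf_range}")

    snp_ids = [f"S{i + 1:04d}" for i in range(config.n_snps)]
    line_ids = [f"G{g + 1:02d}" for g in range(config.n_genotypes)]
    rng_geno = np.random.default_rng([seed, 1])
    mafs = rng_geno.uniform(lo, hi, size=config.n_snps)
    dosages = rng_geno.binomial(2, mafs, size=(config.n_genotypes, config.n_snps)).astype(float)

    models = _genotype_models(config, baseline, dosages, snp_ids)

    times = np.arange(0.0, config.days * 1440.0, config.grid_minutes)
    clean = integrate_batch(models, times)  # (G, T, n)
    # reject scenarios whose noise-free dynamics saturate a basis-domain
    # edge (the integrator clips there, so the data would be unphysical)
    # or leave the physical VWC range
    for k, trait in enumerate(baseline.traits):
        lo, hi = baseline.independent[trait].basis.domain
        vmin, vmax = float(clean[:, :, k].min()), float(clean[:, :, k].max())
        if vmin <= lo + 1e-9 or vmax >= hi - 1e-9:
            raise ConfigRejectionError(
                f"scenario drives {trait} to its domain edge "
                f"(range [{vmin:g}, {vmax:g}] vs domain [{lo:g}, {hi:g}]); "
                "adjust effects or baseline"
            )
        if trait == "VWC" and (vmin < 0.0 or vmax > 1.0):
            raise ConfigRejectionError(
                f"scenario drives VWC outside [0, 1] (range [{vmin:g}, {vmax:g}])"
            )

    day_factor = diurnal_factor(times, config.diurnal_amplitude)
    trajectories = []
    for g, gid in enumerate(line_ids):
        for r in range(1, config.n_replicates + 1):
            rng_pot = np.random.default_rng([seed, 2, g, r])
            for k, trait in enumerate(baseline.traits):
                vals = clean[g, :, k].copy()
                if trait == "TR":
                    vals = vals * day_factor
                sd = float(config.noise_sd.get(trait, 0.0))
                if sd > 0:
                    vals = vals + rng_pot.normal(0.0, sd, size=vals.shape)
                else:
                    rng_pot.normal(0.0, 1.0, size=vals.shape)  # keep streams aligned
                if trait == "VWC":
                    vals = np.clip(vals, 0.0, 1.0)
                trajectories.append(
                    TraitTrajectory(
                        sample_id=f"{gid}_R{r}", genotype_id=gid, replicate=r,
                        trait=trait, times=times.copy(), values=vals,
                        unit=config.units.get(trait, ""),
                    )
                )
    traj_set = TrajectorySet(trajectories, traits=baseline.traits,
                             grid_minutes=config.grid_minutes)
    n_chrom = 11  # cowpea karyotype
    positions = pd.DataFrame(
        {
            "chrom": [f"Vu{(i % n_chrom) + 1:02d}" for i in range(config.n_snps)],
            "pos": [100_000 + 50_000 * (i // n_chrom) for i in range(config.n_snps)],
        },
        index=snp_ids,
    )
    G = GenotypeMatrix(sample_ids=line_ids, snp_ids=snp_ids, codes=dosages,
                       positions=positions)
    truth = SimTruth(
        config=config,
        genotype_models={gid: m.to_dict() for gid, m in zip(line_ids, models)},
        causal=list(config.causal_snps),
        seed=seed,
    )
    return traj_set, G, truth


@dataclass
class DrydownReport:
    """Outcome of the qualitative two-phase drydown check."""

    passed: bool
    violations: dict  # genotype -> list of messages
    n_genotypes: int

    def summary(self) -> str:
        n_bad = sum(1 for v in self.violations.values() if v)
        head = "PASS" if self.passed else "FAIL"
        lines = [f"{head}: {self.n_genotypes - n_bad}/{self.n_genotypes} genotypes show the two-phase drydown pattern"]
        for gid, msgs in sorted(self.violations.items()):
            for m in msgs:
                lines.append(f"  {gid}: {m}")
        return "\n".join(lines)


def qualitative_drydown_check(
    traj_set: TrajectorySet, bandwidth_minutes: float = 1440.0, tol: float = 1e-3
) -> DrydownReport:
    """Check the expected drydown phenomenology on genotype means.

    (a) the 24-h-smoothed VWC is non-increasing (tolerance ``tol`` of its
    range); (b) the TR daily mean — averaged per calendar day, which
    removes the diurnal cycle exactly — peaks strictly after day 1 and
    declines afterward.
    """
    for trait in ("TR", "VWC"):
        if trait not in traj_set.traits:
            raise ValidationError(f"drydown check needs trait {trait!r}")
    means = genotype_mean_curves(traj_set)
    smoothed = {(s.genotype_id, s.trait): s for s in smooth_trajectories(means, bandwidth_minutes)}
    violations: dict[str, list[str]] = {}
    genotypes = means.genotype_ids
    for gid in genotypes:
        msgs = []
        vwc = smoothed[(gid, "VWC")]
        span_days = (vwc.times[-1] - vwc.times[0]) / 1440.0
        if span_days < 3:
            raise InsufficientSpanError(
                f"{span_days:.1f} days of data; drydown check needs >= 3"
            )
        v = vwc.values_hat[np.isfinite(vwc.values_hat)]
        vtol = tol * max(np.ptp(v), 1e-12)
        rises = np.diff(v) > vtol
        if rises.any():
            msgs.append(
                f"VWC increases at {int(rises.sum())} of {rises.size} steps"
            )
        raw = means.get(f"{gid}:mean", "TR")
        ok = np.isfinite(raw.values)
        day_idx = (raw.times[ok] // 1440.0).astype(int)
        day_idx -= day_idx.min()
        daily = np.array([raw.values[ok][day_idx == d].mean() for d in range(day_idx.max() + 1)])
        peak = int(np.argmax(daily))
        ttol = tol * max(np.ptp(daily), 1e-12)
        if peak == 0:
            msgs.append("TR daily mean peaks on day 1 (no initial rise)")
        after = daily[peak:]
        if np.any(np.diff(after) > ttol):
            msgs.append("TR daily mean rises again after its peak")
        violations[gid] = msgs
    passed = not any(violations.values())
    return DrydownReport(passed=passed, violations=violations, n_genotypes=len(genotypes))
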