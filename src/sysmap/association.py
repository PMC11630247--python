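"""Genome scan for loci that alter trait-trait interaction parameters.

The scan asks, SNP by SNP, whether genotype (dosage) classes of the mapping
lines differ in the coupled-ODE coefficients — by default in the dependent
(interaction) coefficients only, i.e. in the relative contributions of
cooperation and competition between traits.

Engine
------
Stage 1 fits every line's mean curves by gradient matching (shared basis
domains across lines so coefficients are comparable), yielding one
coefficient vector per line for the varying parameter subset.  Stage 2 is,
per SNP, the likelihood-ratio test of a multivariate Gaussian model for
those vectors with class-specific versus common means (common covariance):
the classical one-way Wilks-lambda LRT.  The statistic carries the Bartlett
small-sample scale, -(n - 1 - (q + g)/2) log(Lambda), and is referred to
chi-square with (g - 1) * q degrees of freedom — at 32 lines this is the
calibration that makes the nominal test size hold.  Benjamini-Hochberg
controls the FDR over all *tested* SNPs; permutation p-values are an
opt-in exact alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .basis import theta_from_anchored
from .covariance import CovarianceModel
from .data import TrajectorySet
from .errors import ValidationError
from .estimation import (
    DEFAULT_BANDWIDTH_MIN,
    GradientMatcher,
    collect_curves,
    gradient_match_pooled,
    observed_domains,
)
from .model import RateFunction
from .smoothing import deflate_diurnal_set, genotype_mean_curves, smooth_trajectories

log = logging.getLogger(__name__)

DEFAULT_MIN_CLASS = 3


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix: lines x SNPs, codes 0/1/2, NaN = missing."""

    sample_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray
    positions: pd.DataFrame | None = None  # columns chrom, pos indexed like snp_ids

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        obs = self.codes[np.isfinite(self.codes)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValidationError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ScanResult:
    """Per-SNP LRT scan table plus the settings that produced it.

    ``table`` columns: snp_id, chrom, pos, n, n_classes, df, lrt, p, q,
    delta columns per ordered trait pair, tested.
    """

    table: pd.DataFrame
    alpha: float
    vary: str
    n_tested: int = 0
    n_untested: int = 0
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[(t["tested"]) & (t["q"] <= self.alpha)]


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: q-values and rejection flags.

    NaN p-values are excluded from the testing universe and returned as
    NaN q / non-rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    q = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    mask = np.isfinite(p)
    if mask.any():
        pm = p[mask]
        if np.any((pm < 0) | (pm > 1)):
            raise ValidationError("p-values must lie in [0, 1]")
        rej, qv, *_ = multipletests(pm, alpha=alpha, method="fdr_bh")
        q[mask] = qv
        reject[mask] = rej
    return q, reject


def _merge_small_classes(dosages: np.ndarray, min_class_size: int):
    """Merge dosage classes smaller than ``min_class_size`` into the nearest
    dosage class; returns per-line class labels (or None if < 2 remain)."""
    labels = dosages.astype(float).copy()
    while True:
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) <= 1:
            return None
        small = [c for c, n in zip(classes, counts) if n < min_class_size]
        if not small:
            return labels
        # merge the rarest small class first; ties to the lower dosage
        order = np.argsort([counts[list(classes).index(c)] for c in small])
        c = small[order[0]]
        others = classes[classes != c]
        target = others[np.argmin(np.abs(others - c))]
        labels[labels == c] = target


def _manova_lrt(B: np.ndarray, labels: np.ndarray):
    """Bartlett-scaled Wilks-lambda LRT of class-specific mean vectors.

    Returns (stat, df, p, class_means) or None when the within-class
    scatter cannot support the test.
    """
    classes = np.unique(labels)
    n, q = B.shape
    g = len(classes)
    if g < 2 or n - g < q + 1:
        return None
    grand = B.mean(axis=0)
    Tc = B - grand
    T = Tc.T @ Tc
    W = np.zeros((q, q))
    class_means = {}
    for c in classes:
        Xc = B[labels == c]
        class_means[c] = Xc.mean(axis=0)
        Wc = Xc - class_means[c]
        W += Wc.T @ Wc
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return None
    log_lambda = logdet_w - logdet_t  # log Wilks' Lambda, <= 0
    scale = n - 1 - (q + g) / 2.0
    stat = max(0.0, -scale * log_lambda)
    df = q * (g - 1)
    p = float(chi2.sf(stat, df))
    return stat, df, p, class_means


class InteractionScan(BaseEstimator):
    """Genome-wide LRT scan over interaction (or all) rate coefficients.

    Parameters
    ----------
    vary : {"dependent", "independent", "all"}
        Which coefficient subset may differ between genotype classes under
        the alternative.  Default "dependent": SNPs are tested for altering
        the interaction terms.
    min_class_size : int
        Dosage classes with fewer lines are merged into the nearest class.
    alpha : float
        FDR level for the rejection flags.
    matcher : GradientMatcher or None
        Stage-1 fitter; None uses defaults (Legendre 3/2, 24-h bandwidth,
        genotype means).
    covariance : CovarianceModel or None
        Accepted for pipeline symmetry; the coefficient-based LRT estimates
        the between-line covariance from the data, so this setting only
        affects optional likelihood refinement paths, not the default scan.

    Attributes
    ----------
    result_ : ScanResult
    coef_ : (n_lines, q) per-line coefficient matrix for the varying subset
    line_ids_ : line order of ``coef_``
    """

    def __init__(
        self,
        vary="dependent",
        min_class_size=DEFAULT_MIN_CLASS,
        alpha=0.05,
        matcher: GradientMatcher | None = None,
        covariance: CovarianceModel | None = None,
        bandwidth_minutes=DEFAULT_BANDWIDTH_MIN,
    ):
        self.vary = vary
        self.min_class_size = min_class_size
        self.alpha = alpha
        self.matcher = matcher
        self.covariance = covariance
        self.bandwidth_minutes = bandwidth_minutes

    # -- stage 1 -----------------------------------------------------------
    def _line_coefficients(self, traj_set: TrajectorySet):
        m = self.matcher if self.matcher is not None else GradientMatcher(
            bandwidth_minutes=self.bandwidth_minutes
        )
        traits = tuple(m.traits) if m.traits is not None else traj_set.traits
        data = genotype_mean_curves(traj_set) if m.use_means else traj_set
        if m.diurnal_deflate:
            data = deflate_diurnal_set(
                data, m.diurnal_deflate, bandwidth_minutes=m.bandwidth_minutes
            )
        smoothed = smooth_trajectories(data, m.bandwidth_minutes)
        curves = collect_curves(smoothed, traits)
        domains = m.domains or observed_domains(curves, traits, pad=m.domain_pad)
        pooled = gradient_match_pooled(
            curves, traits,
            spec_indep=(m.indep_family, m.indep_order),
            spec_dep=(m.dep_family, m.dep_order),
            domains=domains, anchor=m.anchor, vary=self.vary,
        )
        line_ids = pooled["lines"]
        rows = [
            np.concatenate([
                pooled["per_line"][g][key]
                for key in self._block_keys(traits)
            ])
            for g in line_ids
        ]
        self.pooled_ = pooled
        self.domains_ = domains
        self.traits_ = traits
        self.anchor_ = m.anchor
        return line_ids, np.asarray(rows)

    def _pairs(self, traits):
        return [(i, j) for i in traits for j in traits if i != j]

    def _block_keys(self, traits):
        keys = []
        if self.vary in ("dependent", "all"):
            keys += [("dep", i, j) for (i, j) in self._pairs(traits)]
        if self.vary in ("independent", "all"):
            keys += [("indep", t) for t in traits]
        if not keys:
            raise ValidationError(f"vary must name a non-empty subset, got {self.vary!r}")
        return keys

    def _delta_scores(self, class_means, labels_sorted, pairs):
        """Interaction-score change from the lowest to the highest dosage class."""
        lo, hi = labels_sorted[0], labels_sorted[-1]
        if self.vary == "independent":
            return {pair: np.nan for pair in pairs}
        out = {}
        pos = 0
        for pair in pairs:
            spec = self.pooled_["specs_dep"][pair]
            q = spec.n_basis - 1
            scores = {}
            for c in (lo, hi):
                theta = theta_from_anchored(
                    class_means[c][pos : pos + q], spec, ref=self.anchor_
                )
                f = RateFunction(spec, theta)
                grid = np.linspace(*spec.domain, 101)
                scores[c] = float(np.mean(f(grid, clip=True)))
            out[pair] = scores[hi] - scores[lo]
            pos += q
        return out

    # -- stage 2 -----------------------------------------------------------
    def fit(self, X: TrajectorySet, genotypes: GenotypeMatrix):
        common = [s for s in genotypes.sample_ids if s in set(X.genotype_ids)]
        if not common:
            raise ValidationError(
                "no overlap between phenotype genotype_ids and genotype sample_ids"
            )
        if len(common) < len(genotypes.sample_ids) or len(common) < len(X.genotype_ids):
            log.warning(
                "scanning the intersection of %d lines (phenotypes: %d, genotypes: %d)",
                len(common), len(X.genotype_ids), len(genotypes.sample_ids),
            )
        line_ids, B = self._line_coefficients(X.subset_genotypes(common))
        idx = [genotypes.sample_ids.index(g) for g in line_ids]
        codes = genotypes.codes[idx, :]
        self.line_ids_ = line_ids
        self.coef_ = B

        pairs = self._pairs(self.traits_)
        rows = []
        n_tested = 0
        for s, snp in enumerate(genotypes.snp_ids):
            dos = codes[:, s]
            obs = np.isfinite(dos)
            rec = {
                "snp_id": snp, "n": int(obs.sum()), "n_classes": 0, "df": np.nan,
                "lrt": np.nan, "p": np.nan, "q": np.nan, "tested": False,
            }
            for pair in pairs:
                rec[f"delta_{pair[0]}_{pair[1]}"] = np.nan
            labels = _merge_small_classes(dos[obs], self.min_class_size) if obs.any() else None
            if labels is not None:
                res = None
                try:
                    res = _manova_lrt(B[obs], labels)
                except np.linalg.LinAlgError:  # pragma: no cover - defensive
                    log.warning("fit failure at SNP %s; marked untested", snp)
                if res is not None:
                    stat, df, p, class_means = res
                    uniq = np.unique(labels)
                    deltas = self._delta_scores(class_means, uniq, pairs)
                    rec.update(
                        n_classes=len(uniq), df=df, lrt=stat, p=p, tested=True,
                        **{f"delta_{i}_{j}": deltas[(i, j)] for (i, j) in pairs},
                    )
                    n_tested += 1
            rows.append(rec)
        table = pd.DataFrame(rows)
        if genotypes.positions is not None:
            table = table.merge(
                genotypes.positions.reset_index(names="snp_id"), on="snp_id", how="left"
            )
        else:
            table["chrom"] = ""
            table["pos"] = np.nan
        q, reject = bh_fdr(table["p"].to_numpy(), alpha=self.alpha)
        table["q"] = q
        table["reject"] = reject
        front = ["snp_id", "chrom", "pos", "n", "n_classes", "df", "lrt", "p", "q"]
        table = table[front + [c for c in table.columns if c not in front]]
        self.result_ = ScanResult(
            table=table, alpha=self.alpha, vary=self.vary,
            n_tested=n_tested, n_untested=len(rows) - n_tested, pairs=pairs,
        )
        log.info("scan: %d SNPs tested, %d untested", n_tested, len(rows) - n_tested)
        return self

    # -- permutation null --------------------------------------------------
    def permutation_p(self, genotypes: GenotypeMatrix, snp_id: str,
                      n_perm: int = 1000, seed: int = 0) -> float:
        """Empirical p for one SNP by permuting line labels.

        p = (1 + #{permuted stat >= observed}) / (n_perm + 1).
        """
        if n_perm < 100:
            raise ValidationError("n_perm must be >= 100 for a stable tail")
        s = genotypes.snp_ids.index(snp_id)
        idx = [genotypes.sample_ids.index(g) for g in self.line_ids_]
        dos = genotypes.codes[idx, s]
        obs = np.isfinite(dos)
        labels = _merge_small_classes(dos[obs], self.min_class_size)
        if labels is None:
            return float("nan")
        B = self.coef_[obs]
        res = _manova_lrt(B, labels)
        if res is None:
            return float("nan")
        observed = res[0]
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            r = _manova_lrt(B, perm)
            if r is not None and r[0] >= observed:
                exceed += 1
        return (1 + exceed) / (n_perm + 1)


def scan_snps(
    traj_set: TrajectorySet,
    genotypes: GenotypeMatrix,
    basis_indep=("legendre", 3),
    basis_dep=("legendre", 2),
    cov: CovarianceModel | None = None,
    vary: str = "dependent",
    alpha: float = 0.05,
    min_class_size: int = DEFAULT_MIN_CLASS,
    bandwidth_minutes: float = DEFAULT_BANDWIDTH_MIN,
) -> ScanResult:
    """Scan every SNP for genotype-class differences in model coefficients."""
    matcher = GradientMatcher(
        indep_family=basis_indep[0], indep_order=basis_indep[1],
        dep_family=basis_dep[0], dep_order=basis_dep[1],
        bandwidth_minutes=bandwidth_minutes,
    )
    scan = InteractionScan(
        vary=vary, min_class_size=min_class_size, alpha=alpha,
        matcher=matcher, covariance=cov,
    )
    scan.fit(traj_set, genotypes)
    return scan.result_


def permutation_null(
    traj_set: TrajectorySet,
    genotypes: GenotypeMatrix,
    snp_id: str,
    n_perm: int = 1000,
    seed: int = 0,
    **scan_kwargs,
) -> float:
    """Empirical permutation p-value for one SNP (full staging included)."""
    scan = InteractionScan(**scan_kwargs)
    scan.fit(traj_set, genotypes)
    return scan.permutation_p(genotypes, snp_id, n_perm=n_perm, seed=seed)
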