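"""Theoretical null distribution of G and G' under hierarchical sampling.

Two levels of randomness inflate G relative to the chi-square(1)
expectation even without a QTL: binomial sampling of the ``a`` effective
alleles that form each bulk (a = 2n for a diploid F2 bulk of n
segregants, a = n for homozygous diploid segregants), then Poisson read
counts at mean coverage C per bulk.  A delta-method treatment of the 2x2
likelihood-ratio statistic under this scheme gives the closed forms

    E[G]   = 1 + C/a
    Var[G] = 2 (1 + C/a)^2
    Cov(G_i, G_j) = 2 (C/a)^2 (1 - 2 r_ij)^2

where r_ij is the recombination fraction between sites i and j: the
bulk-composition noise is shared between linked sites (linkage
disequilibrium correlation 1 - 2r among F2 gametes) while sequencing
noise is independent per site.  In the limit C << a these reduce to the
chi-square(1) moments (1, 2).  At the order of this approximation the
moments do not depend on the null allele frequency p0 (the p0*q0 factors
cancel against the estimated margins), so segregation distortion enters
only through the observed frequencies, not the null calibration.

The smoothed statistic G' = sum_j k_j G_j inherits E[G'] = E[G] and

    Var[G'] = sum_j k_j^2 Var[G] + sum_{j != l} k_j k_l Cov(G_j, G_l).

Its right tail is well approximated by a log-normal with parameters
matched to these two moments, which is what the scan p-values use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .smooth import KernelSpec, _kernel, _per_chrom, _windows, haldane_r


@dataclass(frozen=True)
class DesignParams:
    """Experimental design behind a null model.

    n: bulk size per tail (individuals); coverage: mean reads per site per
    bulk (a per-bulk pair is averaged, mirroring how unequal run coverages
    are handled in practice); N: F2 population size (optional, only
    validated against n); effective_alleles: alleles sampled per bulk,
    2n for diploid F2 segregants, n for homozygous diploids; p0: null
    frequency of the high allele (0.5 absent segregation distortion).
    """

    n: int
    coverage: float | tuple[float, float]
    N: int | None = None
    homozygous: bool = False
    effective_alleles: int | None = None
    p0: float = 0.5

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("bulk size n must be positive")
        if self.N is not None and 2 * self.n > self.N:
            raise ValueError("two bulks of n individuals cannot exceed the F2 size N")
        if self.mean_coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        a = self.alleles_per_bulk
        if a not in (self.n, 2 * self.n):
            raise ValueError("effective_alleles must be n (homozygous) or 2n (diploid)")

    @property
    def mean_coverage(self) -> float:
        if isinstance(self.coverage, (tuple, list)):
            return float(np.mean(self.coverage))
        return float(self.coverage)

    @property
    def alleles_per_bulk(self) -> int:
        if self.effective_alleles is not None:
            return self.effective_alleles
        return self.n if self.homozygous else 2 * self.n


@dataclass(frozen=True)
class NullModel:
    """Log-normal null: moments (mean, var) and implied (mu, sigma)."""

    mean: float
    var: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("null mean must be positive")
        if self.var < 0:
            raise ValueError("null variance must be non-negative")
        mu, sigma = lognormal_from_moments(self.mean, self.var)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @classmethod
    def from_mu_sigma(cls, mu: float, sigma: float) -> "NullModel":
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        mean = float(np.exp(mu + sigma**2 / 2.0))
        var = float((np.exp(sigma**2) - 1.0) * np.exp(2.0 * mu + sigma**2))
        return cls(mean=mean, var=var)


def null_moments_g(design: DesignParams) -> tuple[float, float]:
    """(E[G], Var[G]) under the two-level null; (1, 2) when C << alleles."""
    rho = design.mean_coverage / design.alleles_per_bulk
    return 1.0 + rho, 2.0 * (1.0 + rho) ** 2


def lognormal_from_moments(mean: float, var: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) with the given mean and variance."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if var < 0:
        raise ValueError("variance must be non-negative")
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean**2 / np.sqrt(var + mean**2))
    return float(mu), float(np.sqrt(sigma2))


def null_moments_gprime(design: DesignParams, positions, spec: KernelSpec,
                        mode: str = "hierarchical", chroms=None,
                        position_unit: str = "bp", cm_per_kb: float | None = None):
    """Per-site (E[G'], Var[G']) arrays for a scan's site positions.

    'hierarchical' combines per-site Var[G] with the between-site
    covariances over each window (genetic distances via Haldane's map,
    converted from bp with ``cm_per_kb`` when positions are physical).
    'sequencing_only' is the fixed-bulks null: G ~ chi-square(1) iid, so
    E[G'] = 1 and Var[G'] = 2 * sum of squared kernel weights.
    """
    pos = np.asarray(positions, dtype=float)
    half = spec.half_width_in(position_unit)
    if position_unit == "cm":
        to_cm = 1.0
    else:
        rate = cm_per_kb if cm_per_kb is not None else spec.cm_per_kb
        if rate is None:
            raise ValueError("cm_per_kb required to turn bp distances into map distances")
        to_cm = rate / 1000.0
    if mode not in ("hierarchical", "sequencing_only"):
        raise ValueError("mode must be 'hierarchical' or 'sequencing_only'")

    mean_g, var_g = null_moments_g(design)
    rho = design.mean_coverage / design.alleles_per_bulk
    blocks = [(0, len(pos))] if chroms is None else _per_chrom(chroms)
    e_out = np.empty(len(pos))
    v_out = np.empty(len(pos))
    for start, stop in blocks:
        p = pos[start:stop]
        lo, hi = _windows(p, p, half)  # no reflection: theoretical windows use real sites
        for i in range(len(p)):
            sl = slice(lo[i], hi[i])
            w = _kernel((p[sl] - p[i]) / half, spec.shape)
            w = w / w.sum()
            if mode == "sequencing_only":
                e_out[start + i] = 1.0
                v_out[start + i] = 2.0 * np.dot(w, w)
                continue
            e_out[start + i] = mean_g
            d_cm = np.abs(p[sl, None] - p[None, sl]) * to_cm
            decay2 = (1.0 - 2.0 * haldane_r(d_cm)) ** 2
            cov = 2.0 * rho**2 * decay2
            np.fill_diagonal(cov, var_g)
            v_out[start + i] = float(w @ cov @ w)
    return e_out, v_out


def pvalues_lognormal(values, model: NullModel):
    """Upper-tail p-values and z-scores of ln(G') under a log-normal null.

    p is strictly decreasing in the value; a value of 0 maps to p = 1
    (and z = -inf).
    """
    if model.sigma <= 0:
        raise ValueError("degenerate null model (sigma = 0) has no tail")
    v = np.asarray(values, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    if np.any(v < 0):
        raise ValueError("statistic values must be non-negative")
    with np.errstate(divide="ignore"):
        z = (np.log(v) - model.mu) / model.sigma
    p = stats.norm.sf(z)
    if scalar:
        return float(p[0]), float(z[0])
    return p, z
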