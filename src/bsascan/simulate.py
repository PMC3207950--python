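"""F2 bulk-segregant simulator, truncation-selection theory and drivers.

One replicate emulates a complete BSA-sequencing experiment on a single
chromosome segment carrying one (optional) additive QTL at its centre:

1. N F2 individuals receive a QTL genotype with Mendelian probabilities
   (1/4, 1/2, 1/4) and genotypic values (-delta/2, 0, +delta/2);
2. phenotype = genotypic value + Normal(0, residual_sd); individuals are
   ranked and the n lowest / n highest form the two bulks (ties broken
   by index);
3. each selected chromosome's marker haplotype is built outward from its
   QTL allele, switching parental phase between adjacent markers with
   the Haldane recombination fraction for their spacing (independent
   intervals, no interference).  Homozygous-diploid designs double a
   single gamete per individual (n effective alleles per bulk), diploid
   designs carry two independent gametes (2n);
4. per marker and bulk, the two allele counts are independent Poisson
   draws with means C*p and C*(1-p), p the realised bulk frequency.

Markers are uniformly spaced at ``snp_density_d`` per cM over
``chrom_length_cm``; the QTL is itself the central marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gstat import g_statistic
from .nulldist import DesignParams, NullModel, null_moments_gprime
from .robustnull import estimate_null_robust
from .smooth import KernelSpec, haldane_r, smoothing_matrix


def qtl_effect_for_variance(frac_variance: float, residual_sd: float = 1.0) -> float:
    """Homozygote difference delta such that the additive QTL explains the
    given fraction of total phenotypic variance (QTL variance delta^2/8)."""
    if not 0.0 <= frac_variance < 1.0:
        raise ValueError("variance fraction must lie in [0, 1)")
    if frac_variance == 0.0:
        return 0.0
    v_qtl = frac_variance / (1.0 - frac_variance) * residual_sd**2
    return float(np.sqrt(8.0 * v_qtl))


@dataclass(frozen=True)
class SimDesign:
    """Specification of one simulated BSA experiment.

    Defaults are the reference simulation conditions used throughout the
    package's calibration study: an F2 of 1000 with bulks of 150 (15% per
    tail), 50x mean coverage per bulk, a 10 cM chromosome bearing 25
    uniformly spaced SNPs per cM, and the QTL (if any) at the centre.
    ``qtl_effect_delta = 0`` encodes the null hypothesis.
    """

    N: int = 1000
    n: int = 150
    C: float = 50.0
    chrom_length_cm: float = 10.0
    snp_density_d: float = 25.0
    qtl_effect_delta: float = 0.0
    residual_sd: float = 1.0
    qtl_pos_cm: float | None = None  # default: centre of the chromosome
    homozygous: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if 2 * self.n > self.N:
            raise ValueError("cannot select two bulks of n from fewer than 2n individuals")
        if self.snp_density_d <= 0 or self.chrom_length_cm <= 0:
            raise ValueError("positive chromosome length and SNP density required")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.C <= 0:
            raise ValueError("coverage must be positive")

    @property
    def effective_alleles(self) -> int:
        return self.n if self.homozygous else 2 * self.n

    @property
    def marker_cm(self) -> np.ndarray:
        m = int(round(self.chrom_length_cm * self.snp_density_d)) + 1
        return np.arange(m) / self.snp_density_d

    @property
    def qtl_index(self) -> int:
        cm = self.marker_cm
        target = self.qtl_pos_cm if self.qtl_pos_cm is not None else self.chrom_length_cm / 2.0
        return int(np.argmin(np.abs(cm - target)))

    def to_design_params(self) -> DesignParams:
        return DesignParams(n=self.n, coverage=self.C, N=self.N, homozygous=self.homozygous)


def _bulk_frequencies(design: SimDesign, rng: np.random.Generator):
    """Realised high-allele frequency per marker in the low and high bulk."""
    N, n = design.N, design.n
    qi = design.qtl_index
    cm = design.marker_cm
    geno = rng.binomial(2, 0.5, N)  # copies of the high allele at the QTL
    pheno = (geno - 1) * (design.qtl_effect_delta / 2.0) + design.residual_sd * rng.standard_normal(N)
    order = np.argsort(pheno, kind="stable")  # stable sort = ties broken by index
    freqs = []
    for members in (order[:n], order[N - n:]):
        gb = geno[members]
        alleles = np.zeros((n, 2), dtype=np.int8)
        alleles[gb == 2] = 1
        alleles[gb == 1, 0] = 1
        chrom_alleles = alleles[:, :1] if design.homozygous else alleles
        q_allele = chrom_alleles.reshape(-1)
        nc = q_allele.size
        hap_freq = np.empty(len(cm))
        hap_freq[qi] = q_allele.mean()
        for sl, spacings in (
            (slice(qi + 1, len(cm)), np.diff(cm[qi:])),
            (slice(qi - 1, None, -1), np.diff(cm[qi::-1]) * -1),
        ):
            k = len(spacings)
            if k == 0:
                continue
            r = haldane_r(np.abs(spacings))
            flips = rng.random((nc, k)) < r
            parity = np.cumsum(flips, axis=1) & 1
            hap_freq[sl] = (q_allele[:, None] ^ parity).mean(axis=0)
        freqs.append(hap_freq)
    return freqs[0], freqs[1]


def simulate_f2_bulks(design: SimDesign, rng: np.random.Generator | None = None):
    """Simulate one experiment; returns (site-counts table, info dict).

    The table has the standard counts columns plus 'cm'; info carries the
    realised true bulk frequencies and the causal marker index.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    p_low, p_high = _bulk_frequencies(design, rng)
    C = design.C
    table = pd.DataFrame({
        "chrom": "sim1",
        # nominal physical coordinates at 1 cM/kb (1-based)
        "pos": np.round(design.marker_cm * 1000).astype(np.int64) + 1,
        "cm": design.marker_cm,
        "n_hi_L": rng.poisson(C * p_low),
        "n_lo_L": rng.poisson(C * (1.0 - p_low)),
        "n_hi_H": rng.poisson(C * p_high),
        "n_lo_H": rng.poisson(C * (1.0 - p_high)),
    })
    info = {"p_low": p_low, "p_high": p_high, "qtl_index": design.qtl_index}
    return table, info


def truncation_selection_theory(alpha: float, p0: float, selected_fraction: float):
    """Selection intensity and expected allele-frequency shift under
    truncation selection: i = phi(x)/p at truncation point x, and
    delta_p = i * p0 * (1 - p0) * alpha for standardised locus effect alpha."""
    if not 0.0 < selected_fraction < 1.0:
        raise ValueError("selected_fraction must lie in (0, 1)")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    x = stats.norm.isf(selected_fraction)
    intensity = stats.norm.pdf(x) / selected_fraction
    expected_dp = intensity * p0 * (1.0 - p0) * alpha
    return float(intensity), float(expected_dp)


def _simulate_scan_stats(design: SimDesign, spec: KernelSpec, reps: int,
                         rng: np.random.Generator):
    """Per-replicate G scans and smoothed G' (reps x markers arrays)."""
    cm = design.marker_cm
    K = smoothing_matrix(cm, spec, position_unit="cm")
    g_all = np.empty((reps, len(cm)))
    for rep in range(reps):
        p_low, p_high = _bulk_frequencies(design, rng)
        n1 = rng.poisson(design.C * p_low)
        n2 = rng.poisson(design.C * (1.0 - p_low))
        n3 = rng.poisson(design.C * p_high)
        n4 = rng.poisson(design.C * (1.0 - p_high))
        ok = (n1 + n2 > 0) & (n3 + n4 > 0)
        if not ok.all():  # pathologically shallow site: no information, G = 0
            n2 = np.where(ok, n2, 1)
            n4 = np.where(ok, n4, 1)
            g = g_statistic(n1, n2, n3, n4)
            g[~ok] = 0.0
        else:
            g = g_statistic(n1, n2, n3, n4)
        g_all[rep] = g
    return g_all, g_all @ K.T


@dataclass
class NullCalibration:
    """Observed focal-SNP moments and type-I error rates under three nulls."""

    design: SimDesign
    spec: KernelSpec
    reps: int
    g_focal: np.ndarray
    gprime_focal: np.ndarray
    theory_model: NullModel
    robust_model: NullModel | None
    rates: dict = field(default_factory=dict)

    @property
    def g_moments(self):
        return float(self.g_focal.mean()), float(self.g_focal.var(ddof=1))

    @property
    def gprime_moments(self):
        return float(self.gprime_focal.mean()), float(self.gprime_focal.var(ddof=1))


def run_null_calibration(design: SimDesign, spec: KernelSpec, reps: int,
                         rng: np.random.Generator | None = None,
                         levels=(0.05, 0.01),
                         robust: str = "pooled") -> NullCalibration:
    """Replicate the null experiment and score the focal SNP three ways.

    Rates at each nominal level are reported for (a) the naive
    chi-square(1) cutoff on raw G, (b) the theoretical log-normal null of
    G' from the closed-form moments, and (c) the robust empirical null.
    ``robust='pooled'`` fits the 5-step estimator once on the focal G'
    sample pooled across replicates (an iid draw from the null);
    'per_replicate' refits on each 1-chromosome scan, which is far more
    conservative because scan values are heavily autocorrelated.
    """
    if design.qtl_effect_delta != 0.0:
        raise ValueError("null calibration requires a design with qtl_effect_delta = 0")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    g_all, gp_all = _simulate_scan_stats(design, spec, reps, rng)
    qi = design.qtl_index
    g_focal, gp_focal = g_all[:, qi], gp_all[:, qi]

    cm = design.marker_cm
    e_gp, v_gp = null_moments_gprime(design.to_design_params(), cm, spec,
                                     mode="hierarchical", position_unit="cm")
    theory = NullModel(mean=float(e_gp[qi]), var=float(v_gp[qi]))

    rates: dict = {}
    for lev in levels:
        rates[("naive_chi2", lev)] = float(np.mean(g_focal > stats.chi2.isf(lev, df=1)))
        z_crit = stats.norm.isf(lev)
        thr = np.exp(theory.mu + z_crit * theory.sigma)
        rates[("lognormal_theory", lev)] = float(np.mean(gp_focal > thr))

    robust_model = None
    if robust == "pooled":
        robust_model = estimate_null_robust(gp_focal)
        for lev in levels:
            thr = np.exp(robust_model.mu + stats.norm.isf(lev) * robust_model.sigma)
            rates[("robust", lev)] = float(np.mean(gp_focal > thr))
    elif robust == "per_replicate":
        hits = {lev: 0 for lev in levels}
        usable = 0
        for rep in range(reps):
            try:
                model = estimate_null_robust(gp_all[rep], min_sites=10)
            except ValueError:
                continue
            usable += 1
            for lev in levels:
                thr = np.exp(model.mu + stats.norm.isf(lev) * model.sigma)
                hits[lev] += gp_focal[rep] > thr
        for lev in levels:
            rates[("robust", lev)] = hits[lev] / max(usable, 1)
    elif robust != "none":
        raise ValueError("robust must be 'pooled', 'per_replicate' or 'none'")

    return NullCalibration(design=design, spec=spec, reps=reps, g_focal=g_focal,
                           gprime_focal=gp_focal, theory_model=theory,
                           robust_model=robust_model, rates=rates)


def run_power(designs, spec: KernelSpec, reps: int,
              rng: np.random.Generator | None = None,
              levels=(0.05, 0.01, 0.001)) -> pd.DataFrame:
    """Power grid: one row per design with mean causal-site G' and the
    fraction of replicates significant at each level under the naive
    chi-square(1) null (raw G) and the theoretical log-normal null (G')."""
    designs = list(designs)
    if not designs:
        raise ValueError("empty design grid")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for design in designs:
        g_all, gp_all = _simulate_scan_stats(design, spec, reps, rng)
        qi = design.qtl_index
        g_focal, gp_focal = g_all[:, qi], gp_all[:, qi]
        cm = design.marker_cm
        e_gp, v_gp = null_moments_gprime(design.to_design_params(), cm, spec,
                                         mode="hierarchical", position_unit="cm")
        theory = NullModel(mean=float(e_gp[qi]), var=float(v_gp[qi]))
        row = {
            "N": design.N, "n": design.n, "C": design.C,
            "delta": design.qtl_effect_delta, "reps": reps,
            "mean_gprime_causal": float(gp_focal.mean()),
            "mean_g_causal": float(g_focal.mean()),
        }
        for lev in levels:
            row[f"power_naive_{lev:g}"] = float(np.mean(g_focal > stats.chi2.isf(lev, df=1)))
            thr = np.exp(theory.mu + stats.norm.isf(lev) * theory.sigma)
            row[f"power_gprime_{lev:g}"] = float(np.mean(gp_focal > thr))
        rows.append(row)
    return pd.DataFrame(rows)
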