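"""Kernel smoothing of the G statistic (Nadaraya-Watson regression).

G' at a focal SNP is the weighted average of G over all SNPs within a
half-bandwidth W of it.  Averaging across neighbours is justified
because true allele-frequency divergence is conserved between closely
linked sites while Poisson read-depth noise is not.  Weights come from
the tricube kernel ``(1 - D^3)^3`` with standardised distance
``D = |x_j - x_focal| / W`` (0 at the focal site, 1 at the window edge),
normalised to sum to one per window; a rectangular kernel is available
for comparison.  Each chromosome is smoothed independently, with a
reflected copy of the series appended beyond both ends so that edge
estimates are not biased by one-sided windows; reflected positions are
trimmed from the output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

# Full width at half maximum of the expected G' peak, in cM, for a causal
# allele fixed in one bulk and at frequency 0.5 in the other (computed by
# expected_gprime_profile; cached as the matched-filter reference width).
_REFERENCE_PEAK_FWHM_CM = 24.84

#: half-bandwidth range (full window 25-40 cM) recommended for single-QTL scans
SINGLE_PEAK_WINDOW_CM = 30.0
#: smoothing ratio for resolving adjacent peaks (fraction of the peak FWHM)
ADJACENT_PEAK_RATIO = 0.7


def haldane_r(cm) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, no interference:
    r = (1 - exp(-2 d / 100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing kernel: shape, half-bandwidth and its unit.

    ``half_width`` is the half-bandwidth W (window edge at distance W from
    the focal site).  ``unit`` is 'bp' or 'cm'; when positions are physical
    but W is genetic (or vice versa), ``cm_per_kb`` supplies a constant
    genome-wide conversion.
    """

    half_width: float
    unit: str = "bp"
    shape: str = "tricube"
    cm_per_kb: float | None = None

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.unit not in ("bp", "cm"):
            raise ValueError("unit must be 'bp' or 'cm'")
        if self.shape not in ("tricube", "rectangular"):
            raise ValueError("shape must be 'tricube' or 'rectangular'")

    def half_width_in(self, unit: str) -> float:
        """Half-bandwidth expressed in 'bp' or 'cm' position units."""
        if unit == self.unit:
            return self.half_width
        if self.cm_per_kb is None:
            raise ValueError("cm_per_kb required to convert between bp and cM")
        if self.unit == "cm":  # genetic W, physical positions
            return self.half_width / self.cm_per_kb * 1000.0
        return self.half_width * self.cm_per_kb / 1000.0


def _kernel(d_std: np.ndarray, shape: str) -> np.ndarray:
    if shape == "tricube":
        w = (1.0 - np.abs(d_std) ** 3) ** 3
        return np.where(np.abs(d_std) < 1.0, w, 0.0)
    return np.where(np.abs(d_std) <= 1.0, 1.0, 0.0)


def tricube_weights(distances, spec: KernelSpec) -> np.ndarray:
    """Normalised kernel weights for in-window offsets from a focal site."""
    d = np.abs(np.asarray(distances, dtype=float))
    half = spec.half_width
    if np.any(d > half):
        raise ValueError("all supplied sites must lie within the half-bandwidth")
    w = _kernel(d / half, spec.shape)
    total = w.sum()
    if total == 0:
        raise ValueError("window has no weight (all sites at the support edge)")
    return w / total


def _reflect(pos: np.ndarray, values: np.ndarray, half: float):
    """Append reflected (position, value) pairs about both terminal sites."""
    left = (pos > pos[0]) & (pos <= pos[0] + half)
    right = (pos < pos[-1]) & (pos >= pos[-1] - half)
    ext_pos = np.concatenate([(2 * pos[0] - pos[left])[::-1], pos, (2 * pos[-1] - pos[right])[::-1]])
    ext_val = np.concatenate([values[left][::-1], values, values[right][::-1]])
    offset = int(left.sum())
    return ext_pos, ext_val, offset


def _windows(ext_pos: np.ndarray, focal_pos: np.ndarray, half: float):
    lo = np.searchsorted(ext_pos, focal_pos - half, side="left")
    hi = np.searchsorted(ext_pos, focal_pos + half, side="right")
    return lo, hi


def _per_chrom(chroms):
    chroms = np.asarray(chroms)
    _, starts = np.unique(chroms, return_index=True)
    starts = np.sort(starts)
    bounds = list(starts) + [len(chroms)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def smooth_gprime(positions, g_values, spec: KernelSpec, chroms=None, position_unit: str = "bp") -> np.ndarray:
    """Kernel-smoothed G' at every site, chromosome by chromosome.

    ``positions`` must be sorted non-decreasing within each chromosome and
    expressed in ``position_unit`` ('bp' or 'cm').
    """
    pos = np.asarray(positions, dtype=float)
    g = np.asarray(g_values, dtype=float)
    half = spec.half_width_in(position_unit)
    if chroms is None:
        blocks = [(0, len(pos))]
    else:
        blocks = _per_chrom(chroms)
    out = np.empty_like(g)
    for start, stop in blocks:
        p, v = pos[start:stop], g[start:stop]
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be sorted within each chromosome")
        ext_pos, ext_val, _ = _reflect(p, v, half)
        lo, hi = _windows(ext_pos, p, half)
        res = np.empty(len(p))
        for i in range(len(p)):
            sl = slice(lo[i], hi[i])
            w = _kernel((ext_pos[sl] - p[i]) / half, spec.shape)
            res[i] = np.dot(w, ext_val[sl]) / w.sum()
        out[start:stop] = res
    return out


def kernel_weight_sumsq(positions, spec: KernelSpec, chroms=None, position_unit: str = "bp") -> np.ndarray:
    """Per-site sum of squared normalised weights (k' of the
    sequencing-only null; equals 1/m for a rectangular kernel over m sites)."""
    pos = np.asarray(positions, dtype=float)
    half = spec.half_width_in(position_unit)
    blocks = [(0, len(pos))] if chroms is None else _per_chrom(chroms)
    out = np.empty(len(pos))
    for start, stop in blocks:
        p = pos[start:stop]
        ext_pos, _, _ = _reflect(p, np.zeros_like(p), half)
        lo, hi = _windows(ext_pos, p, half)
        res = np.empty(len(p))
        for i in range(len(p)):
            w = _kernel((ext_pos[lo[i]:hi[i]] - p[i]) / half, spec.shape)
            w = w / w.sum()
            res[i] = np.dot(w, w)
        out[start:stop] = res
    return out


def smoothing_matrix(positions, spec: KernelSpec, chroms=None, position_unit: str = "bp") -> np.ndarray:
    """Row-stochastic matrix K with G' = K @ G, reflection folded in.

    Reflected copies contribute their weight back to the original site, so
    K is exactly the linear map applied by :func:`smooth_gprime`.  Useful
    when many scans share one set of positions (e.g. simulation replicates)
    and for the between-site covariance terms of the smoothed null.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    half = spec.half_width_in(position_unit)
    blocks = [(0, n)] if chroms is None else _per_chrom(chroms)
    K = np.zeros((n, n))
    for start, stop in blocks:
        p = pos[start:stop]
        idx = np.arange(start, stop)
        left = (p > p[0]) & (p <= p[0] + half)
        right = (p < p[-1]) & (p >= p[-1] - half)
        ext_pos = np.concatenate([(2 * p[0] - p[left])[::-1], p, (2 * p[-1] - p[right])[::-1]])
        ext_idx = np.concatenate([idx[left][::-1], idx, idx[right][::-1]])
        lo, hi = _windows(ext_pos, p, half)
        for i in range(len(p)):
            sl = slice(lo[i], hi[i])
            w = _kernel((ext_pos[sl] - p[i]) / half, spec.shape)
            w /= w.sum()
            np.add.at(K[start + i], ext_idx[sl], w)
    return K


def expected_gprime_profile(freq_L, freq_H, coverage, effective_alleles,
                            distance_grid_cm, map_function=haldane_r, p0: float = 0.5):
    """Expected G' around a QTL versus map distance, and its half-width.

    The true bulk frequencies at offset x attenuate towards the null
    frequency p0 through the linkage disequilibrium decay implied by the
    map function: ``p_b(x) = p0 + (p_b(0) - p0) * (1 - 2 r(x))``.  The
    expected statistic is the null mean ``1 + C/a`` plus the
    large-count divergence of the attenuated frequencies from p0,

        2 C * sum_bulks [ p ln(p/p0) + q ln(q/q0) ].

    Returns ``(profile, hwhm_cm)`` where hwhm is the offset at which the
    excess over the null baseline halves (numerically scanned).
    """
    for f in (freq_L, freq_H):
        if not 0.0 <= f <= 1.0:
            raise ValueError("bulk frequencies must lie in [0, 1]")
    grid = np.asarray(distance_grid_cm, dtype=float)
    if np.any(grid < 0):
        raise ValueError("distances must be non-negative")
    baseline = 1.0 + coverage / effective_alleles

    def signal(x):
        decay = 1.0 - 2.0 * map_function(x)
        s = 0.0
        for f0 in (freq_L, freq_H):
            p = p0 + (f0 - p0) * decay
            for a, a0 in ((p, p0), (1.0 - p, 1.0 - p0)):
                if np.ndim(a) == 0:
                    s += a * np.log(a / a0) if a > 0 else 0.0
                else:
                    s = s + np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0) / a0), 0.0)
        return 2.0 * coverage * s

    profile = baseline + signal(grid)
    peak = signal(0.0)
    if peak <= 0:
        return profile, np.nan
    hwhm = brentq(lambda x: signal(x) - 0.5 * peak, 1e-9, 500.0)
    return profile, float(hwhm)


def recommend_bandwidth(target: str, cm_per_kb: float) -> KernelSpec:
    """Rule-of-thumb physical bandwidth from a genome-average cM/kb rate.

    'single_peak' targets a full window of ~30 cM (middle of the 25-40 cM
    recommendation, smoothing ratio 1-1.5 of the expected peak FWHM);
    'resolve_adjacent_peaks' shrinks the window to a smoothing ratio of
    ~0.7 so nearby peaks are not merged by the low-pass filter.
    """
    if cm_per_kb <= 0:
        raise ValueError("cm_per_kb must be positive")
    if target == "single_peak":
        full_cm = SINGLE_PEAK_WINDOW_CM
    elif target == "resolve_adjacent_peaks":
        full_cm = ADJACENT_PEAK_RATIO * _REFERENCE_PEAK_FWHM_CM
    else:
        raise ValueError("target must be 'single_peak' or 'resolve_adjacent_peaks'")
    half_bp = (full_cm / 2.0) / cm_per_kb * 1000.0
    return KernelSpec(half_width=half_bp, unit="bp", shape="tricube", cm_per_kb=cm_per_kb)
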