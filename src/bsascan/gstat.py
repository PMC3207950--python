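"""Per-site G statistic and observed bulk allele frequencies.

At every biallelic site the data are a 2x2 table of read counts
(low/high bulk x high/low parental allele).  The G statistic is the
likelihood-ratio goodness-of-fit statistic for independence of bulk and
allele,

    G = 2 * sum_cells O * ln(O / E),

with expected counts ``E = row_margin * column_margin / total`` and the
convention ``0 * ln 0 = 0``.  Unlike allele-frequency differences, G
scales with read depth and therefore carries the strength of evidence at
each site.  No continuity or Williams correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = ("n_hi_L", "n_lo_L", "n_hi_H", "n_lo_H")


@dataclass(frozen=True)
class SiteCounts:
    """Allele-depth table of a single biallelic site.

    ``n_hi_L``/``n_lo_L`` are reads carrying the high- and low-parent
    allele in the low bulk; ``n_hi_H``/``n_lo_H`` the same for the high
    bulk.  ``pos`` is a 1-based physical coordinate; ``cm`` an optional
    genetic-map coordinate.
    """

    chrom: str
    pos: int
    n_hi_L: int
    n_lo_L: int
    n_hi_H: int
    n_lo_H: int
    cm: float | None = None

    def __post_init__(self) -> None:
        counts = (self.n_hi_L, self.n_lo_L, self.n_hi_H, self.n_lo_H)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative allele count at {self.chrom}:{self.pos}")


def _xlogy(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    # O * ln(O/E) with the 0*ln 0 = 0 convention; cells with O == 0 contribute 0.
    out = np.zeros_like(o, dtype=float)
    nz = o > 0
    out[nz] = o[nz] * np.log(o[nz] / e[nz])
    return out


def g_statistic(n_hi_L, n_lo_L, n_hi_H, n_lo_H):
    """Likelihood-ratio G for one site or elementwise over arrays.

    Both bulk totals must be positive (zero-depth sites should have been
    filtered at read time).  A site monomorphic in both bulks (an allele
    margin of zero) gets G = 0 rather than NaN, keeping the scan dense
    for smoothing.
    """
    n1, n2, n3, n4 = (np.asarray(a, dtype=float) for a in (n_hi_L, n_lo_L, n_hi_H, n_lo_H))
    scalar = n1.ndim == 0
    n1, n2, n3, n4 = np.atleast_1d(n1, n2, n3, n4)
    m_lo, m_hi = n1 + n2, n3 + n4
    if np.any(m_lo == 0) or np.any(m_hi == 0):
        raise ValueError("zero total depth in a bulk; filter such sites before scoring")
    r_hi, r_lo = n1 + n3, n2 + n4
    total = m_lo + m_hi
    g = np.zeros_like(n1)
    for obs, row, col in ((n1, r_hi, m_lo), (n2, r_lo, m_lo), (n3, r_hi, m_hi), (n4, r_lo, m_hi)):
        expected = row * col / total
        g += _xlogy(obs, expected)
    g *= 2.0
    # clip tiny negative rounding residue from cancellation at G ~ 0
    np.clip(g, 0.0, None, out=g)
    return float(g[0]) if scalar else g


def allele_freqs(n_hi_L, n_lo_L, n_hi_H, n_lo_H):
    """Observed high-parent allele frequency in each bulk: (p_hat_L, p_hat_H)."""
    n1, n2, n3, n4 = (np.asarray(a, dtype=float) for a in (n_hi_L, n_lo_L, n_hi_H, n_lo_H))
    scalar = n1.ndim == 0
    n1, n2, n3, n4 = np.atleast_1d(n1, n2, n3, n4)
    m_lo, m_hi = n1 + n2, n3 + n4
    if np.any(m_lo == 0) or np.any(m_hi == 0):
        raise ValueError("zero total depth in a bulk")
    p_lo, p_hi = n1 / m_lo, n3 / m_hi
    if scalar:
        return float(p_lo[0]), float(p_hi[0])
    return p_lo, p_hi


def add_gstat(table: pd.DataFrame) -> pd.DataFrame:
    """Append p_hat_L, p_hat_H and G columns to a site-counts table."""
    cols = [table[c].to_numpy() for c in COUNT_COLUMNS]
    p_lo, p_hi = allele_freqs(*cols)
    out = table.copy()
    out["p_hat_L"] = p_lo
    out["p_hat_H"] = p_hi
    out["G"] = g_statistic(*cols)
    return out
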