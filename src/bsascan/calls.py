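"""Multiple-testing correction and QTL region calling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class QTLRegion:
    """A maximal run of consecutive significant sites on one chromosome.

    Coordinates are 1-based inclusive site positions; the peak is the
    in-region maximum of G' (leftmost site on ties).
    """

    chrom: str
    start_pos: int
    end_pos: int
    n_sites: int
    peak_pos: int
    peak_gprime: float

    def __post_init__(self) -> None:
        if not self.start_pos <= self.peak_pos <= self.end_pos:
            raise ValueError("peak must lie inside the region")


def bh_fdr(pvalues, q: float = 0.01):
    """Benjamini-Hochberg step-up: (q-values, significance mask) at FDR q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("target FDR must lie in (0, 1)")
    reject, qvalues, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvalues, reject


def call_regions(scan: pd.DataFrame, gprime_col: str = "Gprime",
                 max_gap_sites: int = 0) -> list[QTLRegion]:
    """Decompose the significance mask into maximal per-chromosome runs.

    ``scan`` must be sorted by (chrom, pos) and carry 'chrom', 'pos',
    ``gprime_col`` and a boolean 'significant' column.  A run is broken by
    any interleaved non-significant site unless ``max_gap_sites`` > 0
    allows that many to be bridged (bridging sites are not counted as
    members).  Runs never span chromosomes.
    """
    regions: list[QTLRegion] = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        gp = grp[gprime_col].to_numpy()
        sig = grp["significant"].to_numpy(dtype=bool)
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i - prev > max_gap_sites + 1:
                regions.append(_make_region(str(chrom), pos, gp, sig, run_start, prev))
                run_start = i
            prev = i
        regions.append(_make_region(str(chrom), pos, gp, sig, run_start, prev))
    return regions


def _make_region(chrom, pos, gp, sig, start, stop) -> QTLRegion:
    member = np.arange(start, stop + 1)
    member = member[sig[member]]
    peak_local = member[int(np.argmax(gp[member]))]  # argmax is leftmost on ties
    return QTLRegion(
        chrom=chrom,
        start_pos=int(pos[start]),
        end_pos=int(pos[stop]),
        n_sites=int(member.size),
        peak_pos=int(pos[peak_local]),
        peak_gprime=float(gp[peak_local]),
    )
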