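"""Reading per-site allele counts and writing scan results.

Input is either a tab-separated table with header
``chrom pos n_hi_L n_lo_L n_hi_H n_lo_H`` or a VCF 4.x file with
per-sample allele depths (AD) for the two pooled bulk samples.  Internal
coordinates are 1-based (VCF convention); BED output converts to 0-based
half-open.  Sites that are not biallelic, cannot be parsed, or have zero
total depth in either bulk carry no usable information and are skipped
with a logged count (kept in ``DataFrame.attrs['n_skipped']``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import QTLRegion
from .gstat import COUNT_COLUMNS

logger = logging.getLogger(__name__)

TSV_COLUMNS = ("chrom", "pos") + COUNT_COLUMNS

SCAN_COLUMNS = ("chrom", "pos", "p_hat_L", "p_hat_H", "G", "Gprime",
                "pvalue", "qvalue", "significant")


def read_site_counts(source, format: str = "tsv", sample_names=None,
                     high_allele: str = "alt") -> pd.DataFrame:
    """Read an ordered site-counts table from TSV or VCF.

    For VCF, ``sample_names`` is the (low bulk, high bulk) pair and
    ``high_allele`` says which VCF allele is the high-parent allele
    ('alt' by default; G is invariant to the choice, only the reported
    allele frequencies flip).
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        table, skipped = _read_tsv(path)
    elif format == "vcf":
        if sample_names is None or len(sample_names) != 2:
            raise ValueError("VCF input needs sample_names=(low_bulk, high_bulk)")
        if high_allele not in ("ref", "alt"):
            raise ValueError("high_allele must be 'ref' or 'alt'")
        table, skipped = _read_vcf(path, sample_names, high_allele)
    else:
        raise ValueError("format must be 'tsv' or 'vcf'")

    if len(table) == 0:
        raise ValueError(f"no usable biallelic sites in {path}")
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    dup = table.duplicated(["chrom", "pos"])
    if dup.any():
        raise ValueError(f"duplicate positions in {path}, first at row {int(np.flatnonzero(dup)[0])}")
    if skipped:
        logger.warning("%s: skipped %d unusable site(s)", path, skipped)
    table.attrs["n_skipped"] = skipped
    return table


def _read_tsv(path: Path):
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    table = table[list(TSV_COLUMNS)].copy()
    for col in ("pos",) + COUNT_COLUMNS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values % 1 != 0)
        if bad.any():
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} at line {int(bad.idxmax()) + 2}")
        table[col] = values.astype(np.int64)
    table["chrom"] = table["chrom"].astype(str)
    usable = (table.n_hi_L + table.n_lo_L > 0) & (table.n_hi_H + table.n_lo_H > 0)
    skipped = int((~usable).sum())
    return table[usable], skipped


def _read_vcf(path: Path, sample_names, high_allele: str):
    import pysam

    vcf = pysam.VariantFile(str(path))
    for name in sample_names:
        if name not in vcf.header.samples:
            raise KeyError(f"sample {name!r} not present in {path}")
    low, high = sample_names
    rows = []
    skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        try:
            ad_low = rec.samples[low]["AD"]
            ad_high = rec.samples[high]["AD"]
        except KeyError:
            skipped += 1
            continue
        if ad_low is None or ad_high is None or None in ad_low[:2] or None in ad_high[:2]:
            skipped += 1
            continue
        ref_l, alt_l = int(ad_low[0]), int(ad_low[1])
        ref_h, alt_h = int(ad_high[0]), int(ad_high[1])
        if high_allele == "alt":
            row = (alt_l, ref_l, alt_h, ref_h)
        else:
            row = (ref_l, alt_l, ref_h, alt_h)
        if row[0] + row[1] == 0 or row[2] + row[3] == 0:
            skipped += 1
            continue
        rows.append((rec.chrom, rec.pos) + row)
    vcf.close()
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS)), skipped


def write_counts(table: pd.DataFrame, dest) -> None:
    """Write a site-counts table in the TSV input format."""
    table[list(TSV_COLUMNS)].to_csv(dest, sep="\t", index=False)


def write_scan(results: pd.DataFrame, dest) -> None:
    """Write the per-site scan table (TSV, floats at 12 significant digits)."""
    if len(results) == 0:
        raise ValueError("refusing to write an empty scan")
    cols = [c for c in SCAN_COLUMNS if c in results.columns]
    out = results[cols].copy()
    out["significant"] = out["significant"].astype(int)
    out.to_csv(dest, sep="\t", index=False, float_format="%.12g")


def read_scan(source) -> pd.DataFrame:
    """Read back a scan table written by :func:`write_scan`."""
    table = pd.read_csv(source, sep="\t")
    table["significant"] = table["significant"].astype(bool)
    table["chrom"] = table["chrom"].astype(str)
    return table


def write_regions(regions: list[QTLRegion], bed_dest, table_dest=None) -> None:
    """Write called regions as BED (0-based half-open) and, optionally, a
    peak table (TSV with 1-based peak coordinate and peak G')."""
    with open(bed_dest, "w") as fh:
        fh.write("# QTL regions (0-based half-open); name column holds the peak position\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\tpeak@{r.peak_pos}\t{r.peak_gprime:.6g}\n")
    if table_dest is not None:
        rows = [
            {"chrom": r.chrom, "start_pos": r.start_pos, "end_pos": r.end_pos,
             "n_sites": r.n_sites, "peak_pos": r.peak_pos, "peak_gprime": r.peak_gprime}
            for r in regions
        ]
        pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos", "n_sites",
                                    "peak_pos", "peak_gprime"]).to_csv(
            table_dest, sep="\t", index=False, float_format="%.12g")
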