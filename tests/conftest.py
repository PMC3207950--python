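import numpy as np
import pandas as pd
import pytest

from bsascan.gstat import COUNT_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tables(rng):
    """Random 2x2 allele-depth tables with positive bulk totals."""
    def make(n, low=0, high=60):
        t = rng.integers(low, high, size=(n, 4))
        t[:, 1] += (t[:, 0] + t[:, 1] == 0)
        t[:, 3] += (t[:, 2] + t[:, 3] == 0)
        return t
    return make


@pytest.fixture
def counts_table():
    return pd.DataFrame({
        "chrom": ["2", "2", "2", "3", "3"],
        "pos": [100, 250, 500, 40, 90],
        "n_hi_L": [10, 12, 30, 9, 10],
        "n_lo_L": [0, 8, 10, 11, 10],
        "n_hi_H": [0, 3, 10, 10, 10],
        "n_lo_H": [10, 17, 30, 10, 10],
    })


@pytest.fixture
def tsv_file(tmp_path, counts_table):
    def write(table=None, name="counts.tsv"):
        path = tmp_path / name
        (counts_table if table is None else table).to_csv(path, sep="\t", index=False)
        return path
    return write


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlowbulk\thighbulk
"""


@pytest.fixture
def vcf_file(tmp_path):
    """Write a small uncompressed VCF with AD fields for two bulk samples."""
    def write(records, name="bulks.vcf"):
        path = tmp_path / name
        lines = [VCF_HEADER]
        for pos, ref, alt, ad_low, ad_high in records:
            lines.append(
                f"chr1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT:AD\t"
                f"0/1:{','.join(map(str, ad_low))}\t0/1:{','.join(map(str, ad_high))}\n"
            )
        path.write_text("".join(lines))
        return path
    return write


def table_counts(table):
    return [table[c].to_numpy() for c in COUNT_COLUMNS]


def brute_force_bh(p, q):
    """Exhaustive Benjamini-Hochberg step-up: check every k for p_(k) <= k q / m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask
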