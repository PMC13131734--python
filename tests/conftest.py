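import numpy as np
import pandas as pd
import pytest

from pleiomr import motif
from pleiomr.sumstats_io import SummaryStats


def make_sumstats_df(rows):
    """Rows of (variant_id, chrom, pos, ea, oa, eaf, beta, se, p, n)."""
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "eaf",
            "beta",
            "se",
            "p",
            "n",
        ],
    )


@pytest.fixture
def five_row_df():
    return make_sumstats_df(
        [
            ("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1e-6, 1000),
            ("rs2", "1", 200, "C", "T", 0.5, -0.05, 0.03, 0.04, 1000),
            ("rs3", "1", 300, "G", "A", 0.2, 0.00, 0.02, 0.99, 1000),
            ("rs4", "2", 100, "T", "C", 0.7, 0.20, 0.05, 1e-4, 1000),
            ("rs5", "2", 500, "A", "C", 0.1, -0.15, 0.04, 2e-4, 1000),
        ]
    )


@pytest.fixture
def five_row_file(tmp_path, five_row_df):
    path = tmp_path / "sumstats.tsv"
    five_row_df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def asym_pwm():
    """A deliberately non-palindromic 6-bp PWM with a unique consensus ACGTAC."""
    strong, weak = 0.97, 0.01
    site = "ACGTAC"
    mat = np.full((len(site), 4), weak)
    for i, b in enumerate(site):
        mat[i, "ACGT".index(b)] = strong
    return motif.Pwm(name="asym", matrix=mat)


def stats_from_df(df, **kw):
    return SummaryStats(df, **kw)
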