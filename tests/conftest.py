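import numpy as np
import pandas as pd
import pytest

from poolscan.variants import PoolPanel, PoolSample, VariantTable


def make_table(panel, records):
    """Build a VariantTable from (chrom, pos, ref, alt, qual, in_cat, flags,
    [(ref_reads, alt_reads) per pool]) tuples."""
    rows, refs, alts = [], [], []
    for chrom, pos, ref, alt, qual, in_cat, flags, counts in records:
        rows.append((chrom, pos, ref, alt, qual, in_cat, frozenset(flags)))
        refs.append([c[0] for c in counts])
        alts.append([c[1] for c in counts])
    df = pd.DataFrame(rows, columns=VariantTable.SITE_COLUMNS)
    shape = (len(rows), len(panel))
    return VariantTable(panel, df,
                        np.array(refs, dtype=np.int64).reshape(shape),
                        np.array(alts, dtype=np.int64).reshape(shape))


@pytest.fixture
def two_pool_panel():
    return PoolPanel([
        PoolSample("alpha", 35, 2, {"coat": "black"}, longitude=11.3, latitude=44.5),
        PoolSample("beta", 35, 2, {"coat": "white"}, longitude=-0.5, latitude=43.2),
    ])


@pytest.fixture
def three_pool_panel():
    return PoolPanel([
        PoolSample("alpha", 35),
        PoolSample("beta", 35),
        PoolSample("gamma", 30),
    ])


@pytest.fixture
def small_table(two_pool_panel):
    return make_table(two_pool_panel, [
        ("1", 100, "A", "G", 30.0, True, set(), [(21, 21), (40, 2)]),
        ("1", 250, "C", "T", 25.0, False, set(), [(30, 10), (15, 25)]),
        ("2", 50, "G", "C", 40.0, True, {"strand_bias"}, [(42, 0), (20, 20)]),
    ])
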