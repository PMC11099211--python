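import numpy as np
import pandas as pd
import pytest

from epiexpr.methylome import MethylationMatrix
from epiexpr.simulate import ExprSimConfig, MethylSimConfig, simulate_counts, simulate_methylome


def make_matrix(meth_rows, total_rows, samples, groups, chroms=None, positions=None):
    """Build a small MethylationMatrix from plain lists of rows."""
    n = len(meth_rows)
    chroms = chroms or ["chr1"] * n
    positions = positions or [100 * (i + 1) for i in range(n)]
    idx = pd.MultiIndex.from_arrays([chroms, positions], names=["chrom", "pos"])
    meth = pd.DataFrame(meth_rows, index=idx, columns=samples)
    total = pd.DataFrame(total_rows, index=idx, columns=samples)
    return MethylationMatrix(meth, total, pd.Series(groups, index=samples))


@pytest.fixture(scope="session")
def small_methylome():
    """A 2,000-CpG methylome with 10 planted DMRs (session-cached)."""
    cfg = MethylSimConfig(n_chroms=1, chrom_length=1_500_000, n_cpgs=2_000,
                          n_dmrs_planted=10, seed=42)
    return simulate_methylome(cfg)


@pytest.fixture(scope="session")
def small_counts():
    """A 600-probe/500-gene panel with planted DEGs and 2 degraded samples."""
    cfg = ExprSimConfig(n_probes=600, n_genes=500, n_per_group=6,
                        n_deg_planted=40, n_degraded_samples=2, seed=42)
    return simulate_counts(cfg)
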