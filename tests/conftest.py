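import numpy as np
import pandas as pd
import pytest

from ctcpa.genome_io import SEG_COLUMNS
from ctcpa.normalization import build_panel_cache, pon_from_cache
from ctcpa.segmentation import CODE_STATE, SegmentProfile, stouffer
from ctcpa.synthetic_cohort import CohortConfig, default_grid, simulate_healthy_panel


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def config57():
    return CohortConfig()


@pytest.fixture(scope="session")
def panel57(grid, config57):
    return simulate_healthy_panel(grid, config57, seed=101)


@pytest.fixture(scope="session")
def cache57(panel57):
    return build_panel_cache(panel57)


@pytest.fixture(scope="session")
def pon57(cache57):
    return pon_from_cache(cache57, np.arange(cache57.n_donors))


def profile_from_codes(grid, usable, codes, sample_id="S", z=None):
    """Build a SegmentProfile whose segments are the maximal constant runs
    of per-bin state codes (-1/0/+1) over the usable bins."""
    rows = []
    for chrom in grid.chrom_order():
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(usable[sl]) + sl.start
        if idx.size == 0:
            continue
        start = 0
        c = codes[idx]
        for i in range(1, idx.size + 1):
            if i == idx.size or c[i] != c[start]:
                sub = idx[start:i]
                seg_z = stouffer(z[sub]) if z is not None else float(c[start]) * 10.0
                rows.append((chrom, int(grid.start[sub[0]]), int(grid.end[sub[-1]]),
                             i - start, seg_z, CODE_STATE[int(c[start])]))
                start = i
    return SegmentProfile(
        sample_id=sample_id,
        segments=pd.DataFrame(rows, columns=SEG_COLUMNS[1:]),
    )
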