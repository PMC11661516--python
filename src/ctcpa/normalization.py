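"""Per-bin z-score normalization against a panel of normals.

Each sample is depth-normalized (usable bins scaled to a fixed total),
GC-corrected with a LOESS fit of count versus GC, and compared bin-by-bin
to the per-bin mean/SD of identically processed healthy donors.  The panel
can be reduced by one donor (leave-one-out) or resampled with replacement
(bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_io import BinCountMatrix, BinGrid

DEPTH_TOTAL = 1e6
MIN_USABLE_BINS = 50
LOESS_FRAC = 0.3


@dataclass
class PoNModel:
    """Per-bin reference mean/SD of GC-corrected, depth-normalized donor
    counts.  Bins whose donor SD is zero are demoted to unusable."""

    donor_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        if len(self.donor_ids) < 2:
            raise ValueError("panel of normals needs at least 2 donors")
        if not np.all(self.sd[self.usable] > 0):
            raise ValueError("usable bins must have positive SD")


@dataclass
class NormalizedProfile:
    """One sample's ratio / log2-ratio / z-score track over usable bins
    (NaN elsewhere)."""

    sample_id: str
    z: np.ndarray
    ratio: np.ndarray
    log2_ratio: np.ndarray
    usable: np.ndarray


def depth_normalize(counts: np.ndarray, usable: np.ndarray) -> np.ndarray:
    total = counts[usable].sum()
    if total <= 0:
        raise ValueError("sample has zero usable-bin coverage")
    return counts.astype(float) * (DEPTH_TOTAL / total)


def gc_correct(counts: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Divide counts by a LOESS estimate of the count-vs-GC trend,
    normalized to mean 1 over usable bins.

    Deterministic; requires >= 50 usable bins.  Unusable bins pass through
    unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    usable = grid.usable & np.isfinite(grid.gc)
    if usable.sum() < MIN_USABLE_BINS:
        raise ValueError(f"need >= {MIN_USABLE_BINS} usable bins for GC correction")
    if not np.any(counts[usable] > 0):
        raise ValueError("all-zero sample; cannot GC-correct")
    gc = grid.gc[usable]
    y = counts[usable]
    if np.ptp(gc) < 1e-9:
        # flat GC: no trend to remove
        return counts.copy()
    fit = lowess(y, gc, frac=LOESS_FRAC, it=1, xvals=gc)
    fit = np.clip(fit, 1e-6 * max(y.mean(), 1.0), None)
    g = fit / fit.mean()
    out = counts.copy()
    out[usable] = y / g
    return out


def prepare_sample(counts: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Depth-normalize then GC-correct one sample's raw counts."""
    return gc_correct(depth_normalize(counts, grid.usable), grid)


@dataclass
class PanelCache:
    """Donor profiles processed once so leave-one-out and bootstrap panels
    reduce to column selections."""

    grid: BinGrid
    donor_ids: tuple[str, ...]
    corrected: np.ndarray  # n_bins x n_donors

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    def index_of(self, donor_id: str) -> int:
        try:
            return self.donor_ids.index(donor_id)
        except ValueError:
            raise KeyError(f"donor {donor_id!r} not in panel") from None


def build_panel_cache(panel: BinCountMatrix) -> PanelCache:
    cols = [prepare_sample(panel.counts[:, i], panel.grid)
            for i in range(len(panel.sample_ids))]
    return PanelCache(
        grid=panel.grid,
        donor_ids=tuple(panel.sample_ids),
        corrected=np.column_stack(cols),
    )


def pon_from_cache(cache: PanelCache, columns: np.ndarray | list[int]) -> PoNModel:
    cols = np.asarray(columns, dtype=int)
    if cols.size < 2:
        raise ValueError("panel of normals needs at least 2 donors")
    sub = cache.corrected[:, cols]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    # relative floor: identical donor columns leave sd ~ 1e-13 * mean from
    # rounding, which must still count as zero variance
    sd_floor = 1e-9 * np.maximum(np.abs(mean), 1.0)
    usable = cache.grid.usable & np.isfinite(sd) & (sd > sd_floor) & (mean > 0)
    if not usable.any():
        raise ValueError("degenerate panel: no bin retains positive variance")
    mean = np.where(usable, mean, np.nan)
    sd = np.where(usable, sd, np.nan)
    return PoNModel(
        donor_ids=tuple(cache.donor_ids[i] for i in cols),
        mean=mean, sd=sd, usable=usable,
    )


def build_pon(panel: BinCountMatrix, exclude_sample: str | None = None) -> PoNModel:
    """Panel-of-normals statistics, optionally leaving one donor out (the
    healthy-donor self-normalization rule)."""
    cache = build_panel_cache(panel)
    if exclude_sample is None:
        cols = np.arange(cache.n_donors)
    else:
        if cache.n_donors < 3:
            raise ValueError("leave-one-out requires at least 3 donors")
        drop = cache.index_of(exclude_sample)
        cols = np.array([i for i in range(cache.n_donors) if i != drop])
    return pon_from_cache(cache, cols)


def bootstrap_columns(
    n_donors: int, n_iter: int, seed: int
) -> np.ndarray:
    """Donor index resamples (with replacement, to panel size) for each
    bootstrap iteration; deterministic given seed."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_donors, size=(n_iter, n_donors))


def bootstrap_pon(
    panel: BinCountMatrix, n_iter: int = 100, seed: int = 0
) -> list[PoNModel]:
    """Bootstrap the panel of normals: each iteration resamples donors with
    replacement to the full panel size."""
    cache = build_panel_cache(panel)
    return bootstrap_pons_from_cache(cache, n_iter=n_iter, seed=seed)


def bootstrap_pons_from_cache(
    cache: PanelCache, n_iter: int, seed: int,
    exclude: str | None = None,
) -> list[PoNModel]:
    if exclude is None:
        pool = np.arange(cache.n_donors)
    else:
        drop = cache.index_of(exclude)
        pool = np.array([i for i in range(cache.n_donors) if i != drop])
    draws = bootstrap_columns(pool.size, n_iter, seed)
    out = []
    for it in range(n_iter):
        cols = pool[draws[it]]
        # a degenerate resample (all copies of one donor) has zero variance
        # everywhere; redraw deterministically by shifting one slot
        if np.unique(cols).size < 2:
            cols = cols.copy()
            cols[0] = pool[(draws[it][0] + 1) % pool.size]
        out.append(pon_from_cache(cache, cols))
    return out


def normalize_sample(
    counts: np.ndarray, pon: PoNModel, grid: BinGrid, sample_id: str = "sample"
) -> NormalizedProfile:
    """Ratio and z-score of one sample against a panel of normals.

    Invariant to total sequencing depth (counts are rescaled first) and
    equivariant under bin permutation.
    """
    if counts.shape[0] != grid.n_bins:
        raise ValueError("sample length does not match grid")
    if pon.usable.sum() < 0.5 * grid.usable.sum():
        raise ValueError(">50% of usable bins lost in panel; refusing to normalize")
    corrected = prepare_sample(counts, grid)
    z = np.full(grid.n_bins, np.nan)
    ratio = np.full(grid.n_bins, np.nan)
    u = pon.usable
    ratio[u] = corrected[u] / pon.mean[u]
    z[u] = (corrected[u] - pon.mean[u]) / pon.sd[u]
    with np.errstate(divide="ignore"):
        log2r = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), -np.inf)
    log2r = np.where(u, log2r, np.nan)
    return NormalizedProfile(
        sample_id=sample_id, z=z, ratio=ratio, log2_ratio=log2r, usable=u.copy()
    )


def normalize_against_cache(
    counts_corrected: np.ndarray, pon: PoNModel, sample_id: str = "sample"
) -> np.ndarray:
    """z-track for an already prepared (depth-normalized, GC-corrected)
    sample; fast path used in bootstrap loops."""
    z = np.full(pon.usable.shape, np.nan)
    u = pon.usable
    z[u] = (counts_corrected[u] - pon.mean[u]) / pon.sd[u]
    return z
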