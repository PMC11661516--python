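"""Circular binary segmentation of per-bin z-scores.

Each chromosome's usable-bin z vector is split recursively: the candidate
arc (i, j] maximizing a two-sample t-like statistic against its complement
is accepted when its permutation p-value falls below ``alpha``, and the
three resulting pieces are segmented further.  Because an arc and its
circular complement share the same statistic, scanning all non-wrapping
arcs covers the circular candidate set.

Segment z-scores use the Stouffer combination  sum(z) / sqrt(n_bins), so
evidence accumulates with segment size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import SEG_COLUMNS, BinGrid
from .normalization import NormalizedProfile

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"
STATE_CODE = {LOSS: -1, NEUTRAL: 0, GAIN: 1}
CODE_STATE = {v: k for k, v in STATE_CODE.items()}

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_BINS = 3
DEFAULT_Z_CALL = 3.0

_PERM_BLOCK = 100


@dataclass
class SegmentProfile:
    """Ordered segments for one sample.

    ``segments`` columns: chrom, start, end, n_bins, seg_z, state; segments
    partition the usable bins of each chromosome.  ``iteration`` records
    which bootstrap panel produced the profile (None for the base panel,
    "consensus" for majority profiles).
    """

    sample_id: str
    segments: pd.DataFrame
    iteration: int | str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SEG_COLUMNS[1:] if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segments lack columns {missing}")


def stouffer(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(z.sum() / np.sqrt(len(z))) if len(z) else float("nan")


from functools import lru_cache


@lru_cache(maxsize=512)
def _arc_index(n: int, min_bins: int):
    """Valid arc endpoints (i, j) with min_bins <= j-i <= n-min_bins, plus
    the per-arc weights of the t-like statistic (shared by all data vectors
    of length n)."""
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    k = j - i
    valid = (k >= min_bins) & (k <= n - min_bins)
    ii, jj = i[valid], j[valid]
    kk = (jj - ii).astype(float)
    cc = n - kk
    inv_k = 1.0 / kk
    inv_c = 1.0 / cc
    w = 1.0 / np.sqrt(inv_k + inv_c)
    return ii, jj, inv_k, inv_c, w


def _arc_stats(S: np.ndarray, n: int, sd: float, min_bins: int) -> np.ndarray:
    """|t| statistic for every valid arc; ``S`` is a prefix-sum vector or a
    batch of them (leading axis = permutations)."""
    ii, jj, inv_k, inv_c, w = _arc_index(n, min_bins)
    if S.ndim == 1:
        arc = S[jj] - S[ii]
        tot = S[-1]
    else:
        arc = S[:, jj] - S[:, ii]
        tot = S[:, -1][:, None]
    diff = arc * inv_k - (tot - arc) * inv_c
    return np.abs(diff) * (w / sd)


def max_arc_split(
    x: np.ndarray, min_bins: int
) -> tuple[float, int, int] | None:
    """Best circular split of ``x``: (statistic, i, j) with arc x[i:j].
    None when no admissible arc exists or the vector is constant."""
    n = len(x)
    if n < 2 * min_bins:
        return None
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        return None
    S = np.concatenate(([0.0], np.cumsum(x)))
    T = _arc_stats(S, n, sd, min_bins)
    ii, jj, *_ = _arc_index(n, min_bins)
    best = int(np.argmax(T))
    tmax = float(T[best])
    if tmax <= 0:
        return None
    return tmax, int(ii[best]), int(jj[best])


def _split_significant(
    x: np.ndarray, tobs: float, alpha: float, n_perm: int,
    min_bins: int, rng: np.random.Generator,
) -> bool:
    """Permutation test of the maximal arc statistic, evaluated in blocks
    with early rejection once p >= alpha is guaranteed."""
    if alpha <= 0:
        return False
    n = len(x)
    sd = float(np.std(x, ddof=1))  # permutation-invariant
    stop = alpha * n_perm  # once exceedances reach this, p >= alpha
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_BLOCK, n_perm - done)
        P = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        S = np.concatenate((np.zeros((b, 1)), np.cumsum(P, axis=1)), axis=1)
        T = _arc_stats(S, n, sd, min_bins)
        exceed += int((T.max(axis=1) >= tobs - 1e-12).sum())
        done += b
        if exceed >= stop:
            return False
    return exceed / n_perm < alpha


def _segment_vector(
    x: np.ndarray, alpha: float, n_perm: int, min_bins: int,
    rng: np.random.Generator,
) -> list[int]:
    """Sorted interior breakpoints of ``x`` (indices where new segments
    start)."""
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        best = max_arc_split(seg, min_bins)
        if best is None:
            return
        tobs, i, j = best
        if not _split_significant(seg, tobs, alpha, n_perm, min_bins, rng):
            return
        cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
        breaks.extend(cuts)
        for a, b in zip([lo] + cuts, cuts + [hi]):
            if b - a >= 2 * min_bins:
                recurse(a, b)

    recurse(0, len(x))
    return sorted(breaks)


def cbs_segment(
    profile: NormalizedProfile,
    grid: BinGrid,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_bins: int = DEFAULT_MIN_BINS,
    seed: int = 0,
    iteration: int | str | None = None,
) -> SegmentProfile:
    """Segment one normalized profile chromosome by chromosome.

    Chromosomes with fewer than ``2 * min_bins`` usable bins become a single
    segment.  All states are ``neutral``; see :func:`call_states`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in grid.chrom_order():
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(profile.usable[sl]) + sl.start
        if idx.size == 0:
            continue
        x = profile.z[idx]
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite z on {chrom}")
        breaks = _segment_vector(x, alpha, n_perm, min_bins, rng)
        bounds = [0] + breaks + [idx.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            sub = idx[a:b]
            rows.append(
                (chrom, int(grid.start[sub[0]]), int(grid.end[sub[-1]]),
                 b - a, stouffer(x[a:b]), NEUTRAL)
            )
    seg = pd.DataFrame(rows, columns=SEG_COLUMNS[1:])
    return SegmentProfile(sample_id=profile.sample_id, segments=seg, iteration=iteration)


def call_states(profile: SegmentProfile, z_call: float = DEFAULT_Z_CALL) -> SegmentProfile:
    """Assign gain/loss to segments with |seg_z| strictly above ``z_call``."""
    seg = profile.segments.copy()
    z = seg["seg_z"].to_numpy(dtype=float)
    state = np.where(z > z_call, GAIN, np.where(z < -z_call, LOSS, NEUTRAL))
    seg["state"] = state
    return SegmentProfile(
        sample_id=profile.sample_id, segments=seg, iteration=profile.iteration
    )


def bin_state_codes(profile: SegmentProfile, grid: BinGrid, usable: np.ndarray) -> np.ndarray:
    """Expand a segment profile to per-bin state codes (-1/0/+1) over the
    grid; bins outside ``usable`` get 0."""
    codes = np.zeros(grid.n_bins, dtype=np.int8)
    for chrom, grp in profile.segments.groupby("chrom", sort=False):
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(usable[sl]) + sl.start
        pos = 0
        for r in grp.itertuples(index=False):
            nb = int(r.n_bins)
            codes[idx[pos:pos + nb]] = STATE_CODE[r.state]
            pos += nb
        if pos != idx.size:
            raise ValueError(
                f"segments of {profile.sample_id} do not partition {chrom}: "
                f"{pos} vs {idx.size} usable bins"
            )
    return codes


def consensus_states(
    profiles: list[SegmentProfile],
    grid: BinGrid,
    usable: np.ndarray,
    z: np.ndarray | None = None,
) -> tuple[np.ndarray, SegmentProfile]:
    """Per-bin majority state across bootstrap profiles; ties go to neutral.

    Maximal runs of identical consensus state are re-assembled into a
    consensus :class:`SegmentProfile` whose seg_z values are Stouffer
    combinations of ``z`` (NaN when no z track is supplied).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    votes = np.zeros((grid.n_bins, 3), dtype=np.int32)  # loss, neutral, gain
    for p in profiles:
        codes = bin_state_codes(p, grid, usable)
        for code, col in ((-1, 0), (0, 1), (1, 2)):
            votes[:, col] += codes == code
    top = votes.max(axis=1)
    consensus = np.zeros(grid.n_bins, dtype=np.int8)
    is_tie = (votes == top[:, None]).sum(axis=1) > 1
    consensus[(votes[:, 2] == top) & ~is_tie] = 1
    consensus[(votes[:, 0] == top) & ~is_tie] = -1
    consensus[~usable] = 0

    rows = []
    for chrom in grid.chrom_order():
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(usable[sl]) + sl.start
        if idx.size == 0:
            continue
        codes = consensus[idx]
        run_start = 0
        for i in range(1, idx.size + 1):
            if i == idx.size or codes[i] != codes[run_start]:
                sub = idx[run_start:i]
                seg_z = stouffer(z[sub]) if z is not None else float("nan")
                rows.append(
                    (chrom, int(grid.start[sub[0]]), int(grid.end[sub[-1]]),
                     i - run_start, seg_z, CODE_STATE[int(codes[run_start])])
                )
                run_start = i
    seg = pd.DataFrame(rows, columns=SEG_COLUMNS[1:])
    prof = SegmentProfile(
        sample_id=profiles[0].sample_id, segments=seg, iteration="consensus"
    )
    return consensus, prof
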