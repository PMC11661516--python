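"""CPA and ctCPA scores, cumulative patient profiles and detection
thresholds.

CPA summarizes one segmented sample as the length-weighted mean |segment
z-score| (lengths cancel in 100-Mb units, so the score is the "per 100-Mb"
deviation).  ctCPA projects a sample's bin z-scores onto the patient's
cumulative CNV profile — the union of gains/losses seen in any serial
sample up to a horizon, with conflicting regions excluded — and averages
the signed segment z-scores:  score = sum_i Z_i * D_i / n.

Detection thresholds are the maximum score observed across healthy donors
(leave-one-out normalized); positivity is strict (score > threshold), so
the defining healthy maximum itself is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import BinGrid
from .segmentation import SegmentProfile, stouffer

MODE_EQ1 = "eq1"
MODE_LENGTH_WEIGHTED = "length_weighted"


@dataclass
class CumulativeProfile:
    """Patient-specific directed CNV space up to a horizon timepoint.

    ``segments`` columns: chrom, start, end, n_bins, direction (+1/-1);
    ``excluded`` holds the gain/loss-conflicting intervals.  ``bin_direction``
    and ``bin_excluded`` are the same information per grid bin.
    """

    patient_id: str
    horizon: str
    segments: pd.DataFrame
    excluded: pd.DataFrame
    sample_ids: tuple[str, ...]
    bin_direction: np.ndarray
    bin_excluded: np.ndarray
    segment_bins: list[np.ndarray] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def is_empty(self) -> bool:
        return self.n_segments == 0


@dataclass
class ScoreResult:
    """A per-sample score: the median over bootstrap-iteration scores, plus
    the threshold used and the resulting positivity flag."""

    sample_id: str
    kind: str  # "CPA" | "ctCPA"
    iteration_scores: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.iteration_scores = np.asarray(self.iteration_scores, dtype=float)
        if self.iteration_scores.size == 0:
            raise ValueError("no iteration scores")

    @property
    def score(self) -> float:
        return float(np.median(self.iteration_scores))

    @property
    def positive(self) -> bool:
        if self.threshold is None:
            raise ValueError("no threshold set")
        return classify_sample(self.score, self.threshold)


def cpa_score(profile: SegmentProfile) -> float:
    """Length-weighted mean absolute segment z-score (>= 0).

    Segments are assumed autosomal; sex chromosomes must be excluded
    upstream (they are unusable in the grid and never segmented).
    """
    seg = profile.segments
    if len(seg) == 0:
        raise ValueError("empty segment profile")
    length = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    z = np.abs(seg["seg_z"].to_numpy(dtype=float))
    return float((z * length).sum() / length.sum())


def _runs(codes: np.ndarray, idx: np.ndarray):
    """Yield (code, bin-index-array) for maximal constant runs of ``codes``
    over the positions ``idx``."""
    start = 0
    for i in range(1, idx.size + 1):
        if i == idx.size or codes[i] != codes[start]:
            yield int(codes[start]), idx[start:i]
            start = i


def build_cumulative_profile(
    profiles: Sequence[SegmentProfile],
    timepoints: Sequence[str],
    grid: BinGrid,
    usable: np.ndarray,
    horizon: str,
    patient_id: str = "patient",
) -> CumulativeProfile:
    """Union of non-neutral consensus intervals from all samples at or
    before ``horizon``.

    Where a gain from one sample overlaps a loss from another, the
    overlapping bins are excluded; the non-conflicting remainders keep
    their direction.  Recurrent identical calls count once.  An empty
    result is valid (scores are undefined downstream).
    """
    from .segmentation import bin_state_codes

    if len(profiles) != len(timepoints):
        raise ValueError("profiles and timepoints must align")
    if horizon not in timepoints:
        raise ValueError(f"horizon {horizon!r} not among timepoints {list(timepoints)}")
    upto = list(timepoints).index(horizon) + 1

    gain_any = np.zeros(grid.n_bins, dtype=bool)
    loss_any = np.zeros(grid.n_bins, dtype=bool)
    used = []
    for prof, tp in zip(profiles[:upto], timepoints[:upto]):
        codes = bin_state_codes(prof, grid, usable)
        gain_any |= codes == 1
        loss_any |= codes == -1
        used.append(prof.sample_id)

    direction = np.zeros(grid.n_bins, dtype=np.int8)
    direction[gain_any & ~loss_any] = 1
    direction[loss_any & ~gain_any] = -1
    excluded = gain_any & loss_any

    seg_rows, excl_rows, seg_bins = [], [], []
    for chrom in grid.chrom_order():
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(usable[sl]) + sl.start
        if idx.size == 0:
            continue
        for code, sub in _runs(direction[idx], idx):
            if code != 0:
                seg_rows.append(
                    (chrom, int(grid.start[sub[0]]), int(grid.end[sub[-1]]),
                     sub.size, code)
                )
                seg_bins.append(sub)
        for flag, sub in _runs(excluded[idx].astype(np.int8), idx):
            if flag:
                excl_rows.append(
                    (chrom, int(grid.start[sub[0]]), int(grid.end[sub[-1]]))
                )
    return CumulativeProfile(
        patient_id=patient_id,
        horizon=horizon,
        segments=pd.DataFrame(
            seg_rows, columns=["chrom", "start", "end", "n_bins", "direction"]
        ),
        excluded=pd.DataFrame(excl_rows, columns=["chrom", "start", "end"]),
        sample_ids=tuple(used),
        bin_direction=direction,
        bin_excluded=excluded,
        segment_bins=seg_bins,
    )


def ctcpa_from_z(
    z: np.ndarray, cum: CumulativeProfile, mode: str = MODE_EQ1
) -> float:
    """Evaluate the ctCPA equation on one z track.

    Per directed segment i, Z_i is the Stouffer combination of the bin
    z-scores inside the interval; the score is sum(Z_i * D_i) / n
    (``eq1``) or the length-weighted variant sum(Z_i * D_i * L_i) / sum(L_i)
    (``length_weighted``).
    """
    if cum.is_empty:
        raise ValueError("no patient-specific CNV space")
    if mode not in (MODE_EQ1, MODE_LENGTH_WEIGHTED):
        raise ValueError(f"unknown mode {mode!r}")
    zd = []
    for bins, d in zip(cum.segment_bins, cum.segments["direction"]):
        vals = z[bins]
        vals = vals[np.isfinite(vals)]
        zi = stouffer(vals) if vals.size else 0.0
        zd.append(zi * int(d))
    zd = np.asarray(zd, dtype=float)
    if mode == MODE_EQ1:
        return float(zd.mean())
    length = (cum.segments["end"] - cum.segments["start"]).to_numpy(dtype=float)
    return float((zd * length).sum() / length.sum())


def ctcpa_score(
    z_iterations: np.ndarray | Sequence[np.ndarray],
    cum: CumulativeProfile,
    sample_id: str = "sample",
    mode: str = MODE_EQ1,
) -> ScoreResult:
    """ctCPA over bootstrap iterations: one z track per panel iteration,
    reported as the median."""
    z_iterations = np.atleast_2d(np.asarray(z_iterations, dtype=float))
    scores = [ctcpa_from_z(zi, cum, mode=mode) for zi in z_iterations]
    return ScoreResult(sample_id=sample_id, kind="ctCPA", iteration_scores=np.array(scores))


def healthy_threshold_cpa(healthy_scores: Sequence[float]) -> float:
    """ctDNA detection cut-off: the maximum CPA across healthy donors."""
    scores = np.asarray(list(healthy_scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 healthy scores")
    return float(scores.max())


def ctcpa_threshold(
    cum: CumulativeProfile,
    donor_z_iterations: dict[str, np.ndarray],
    mode: str = MODE_EQ1,
) -> float:
    """Patient-specific ctCPA cut-off: the maximum donor score on the
    patient's cumulative profile.

    ``donor_z_iterations`` maps donor id to an (n_iter x n_bins) z matrix
    from leave-one-out panels; each donor's score is the median over its
    iterations, mirroring the patient-side procedure.
    """
    if cum.is_empty:
        raise ValueError("no patient-specific CNV space")
    scores = [
        ctcpa_score(zmat, cum, sample_id=d, mode=mode).score
        for d, zmat in donor_z_iterations.items()
    ]
    if not scores:
        raise ValueError("no healthy donors supplied")
    return float(max(scores))


def classify_sample(score: float, threshold: float) -> bool:
    """Positive iff score strictly exceeds the threshold."""
    if not (np.isfinite(score) and np.isfinite(threshold)):
        raise ValueError("score and threshold must be finite")
    return bool(score > threshold)
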