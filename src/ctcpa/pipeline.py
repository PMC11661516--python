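"""End-to-end cohort scoring.

Wires normalization, segmentation and scoring together: leave-one-out
panels for healthy donors, bootstrap panels for patient samples, consensus
states across iterations, cumulative per-patient profiles per horizon, and
the healthy-maximum detection thresholds for both CPA and ctCPA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import SCHEDULE, BinCountMatrix
from .normalization import (
    PanelCache,
    bootstrap_pons_from_cache,
    build_panel_cache,
    normalize_against_cache,
    pon_from_cache,
    prepare_sample,
    NormalizedProfile,
)
from .scoring import (
    build_cumulative_profile,
    classify_sample,
    cpa_score,
    ctcpa_score,
    ctcpa_threshold,
    healthy_threshold_cpa,
)
from .segmentation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_BINS,
    DEFAULT_N_PERM,
    DEFAULT_Z_CALL,
    SegmentProfile,
    call_states,
    cbs_segment,
    consensus_states,
)

SCORE_COLUMNS = [
    "sample", "patient", "timepoint", "months", "cpa", "cpa_threshold",
    "cpa_positive", "ctcpa", "ctcpa_threshold", "ctcpa_positive",
    "n_segments", "horizon",
]


@dataclass
class ScoringParams:
    n_boot: int = 100
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    min_bins: int = DEFAULT_MIN_BINS
    z_call: float = DEFAULT_Z_CALL
    mode: str = "eq1"


def _profile_from_z(z: np.ndarray, usable: np.ndarray, sample_id: str) -> NormalizedProfile:
    return NormalizedProfile(
        sample_id=sample_id, z=z, ratio=np.full_like(z, np.nan),
        log2_ratio=np.full_like(z, np.nan), usable=usable & np.isfinite(z),
    )


def _iterate_sample(
    corrected: np.ndarray,
    pons: list,
    grid,
    sample_id: str,
    params: ScoringParams,
    cbs_seeds: list[int],
) -> tuple[float, np.ndarray, SegmentProfile, np.ndarray]:
    """Per-iteration CBS + state calls for one prepared sample.

    Returns (median CPA, per-iteration z matrix, consensus profile, base z).
    """
    z_iters = np.vstack(
        [normalize_against_cache(corrected, pon, sample_id) for pon in pons]
    )
    # segment on the bins usable in every iteration so consensus voting is
    # defined over a common partition
    usable_all = pons[0].usable.copy()
    for pon in pons[1:]:
        usable_all &= pon.usable
    cpas = []
    profiles = []
    for it, pon in enumerate(pons):
        prof = _profile_from_z(z_iters[it], usable_all, sample_id)
        seg = cbs_segment(
            prof, grid, alpha=params.alpha, n_perm=params.n_perm,
            min_bins=params.min_bins, seed=cbs_seeds[it], iteration=it,
        )
        seg = call_states(seg, z_call=params.z_call)
        cpas.append(cpa_score(seg))
        profiles.append(seg)
    if len(pons) > 1:
        z_med = np.full(z_iters.shape[1], np.nan)
        has_val = np.isfinite(z_iters).any(axis=0)
        z_med[has_val] = np.nanmedian(z_iters[:, has_val], axis=0)
    else:
        z_med = z_iters[0]
    _, consensus = consensus_states(profiles, grid, usable_all, z=z_med)
    return float(np.median(cpas)), z_iters, consensus, z_med


def score_cohort(
    counts: BinCountMatrix,
    params: ScoringParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Score every sample of a cohort.

    Healthy donors (role == healthy) form the panel and are scored with
    leave-one-out panels; patient samples are scored against bootstrap
    panels of the full donor set.  Returns the scores table plus a detail
    dict (consensus profiles, cumulative profiles, thresholds).
    """
    params = params or ScoringParams()
    grid = counts.grid
    meta = counts.samples
    donor_ids = [s for s in counts.sample_ids if meta.loc[s, "role"] == "healthy"]
    patient_sids = [s for s in counts.sample_ids if meta.loc[s, "role"] == "patient"]
    if len(donor_ids) < 3:
        raise ValueError("need at least 3 healthy donors")

    cache = build_panel_cache(counts.subset(donor_ids))
    root = np.random.SeedSequence(seed)
    ss_donor, ss_patient, ss_cbs = root.spawn(3)
    cbs_seed_rng = np.random.default_rng(ss_cbs.generate_state(1)[0])

    def draw_seeds(k: int) -> list[int]:
        return [int(v) for v in cbs_seed_rng.integers(0, 2**31 - 1, size=k)]

    # --- healthy donors: leave-one-out (+ bootstrap of the reduced panel)
    donor_cpa: dict[str, float] = {}
    donor_z: dict[str, np.ndarray] = {}
    donor_boot_seeds = np.random.default_rng(
        ss_donor.generate_state(1)[0]
    ).integers(0, 2**31 - 1, size=len(donor_ids))
    for d_i, donor in enumerate(donor_ids):
        if params.n_boot > 1:
            pons = bootstrap_pons_from_cache(
                cache, n_iter=params.n_boot,
                seed=int(donor_boot_seeds[d_i]), exclude=donor,
            )
        else:
            pool = [i for i in range(cache.n_donors) if i != cache.index_of(donor)]
            pons = [pon_from_cache(cache, pool)]
        corrected = cache.corrected[:, cache.index_of(donor)]
        cpa_med, z_iters, _, _ = _iterate_sample(
            corrected, pons, grid, donor, params, draw_seeds(len(pons))
        )
        donor_cpa[donor] = cpa_med
        donor_z[donor] = z_iters
    cpa_thr = healthy_threshold_cpa(list(donor_cpa.values()))

    # --- patient samples: bootstrap panels of the full donor set
    if params.n_boot > 1:
        pat_pons = bootstrap_pons_from_cache(
            cache, n_iter=params.n_boot, seed=int(ss_patient.generate_state(1)[0])
        )
    else:
        pat_pons = [pon_from_cache(cache, np.arange(cache.n_donors))]

    sample_cpa: dict[str, float] = {}
    sample_z: dict[str, np.ndarray] = {}
    sample_consensus: dict[str, SegmentProfile] = {}
    for sid in patient_sids:
        corrected = prepare_sample(counts.column(sid), grid)
        cpa_med, z_iters, consensus, _ = _iterate_sample(
            corrected, pat_pons, grid, sid, params, draw_seeds(len(pat_pons))
        )
        sample_cpa[sid] = cpa_med
        sample_z[sid] = z_iters
        sample_consensus[sid] = consensus

    usable_all = pat_pons[0].usable.copy()
    for pon in pat_pons[1:]:
        usable_all &= pon.usable

    # --- cumulative profiles and ctCPA per horizon
    rows = []
    cum_profiles: dict[tuple[str, str], object] = {}
    for donor in donor_ids:
        rows.append(
            (donor, "", "", np.nan, donor_cpa[donor], cpa_thr,
             classify_sample(donor_cpa[donor], cpa_thr),
             np.nan, np.nan, False, 0, "")
        )
    patients = sorted({meta.loc[s, "patient"] for s in patient_sids})
    for pid in patients:
        sids = [s for s in patient_sids if meta.loc[s, "patient"] == pid]
        sids.sort(key=lambda s: SCHEDULE[meta.loc[s, "timepoint"]])
        tps = [meta.loc[s, "timepoint"] for s in sids]
        profiles = [sample_consensus[s] for s in sids]
        for sid, tp in zip(sids, tps):
            cum = build_cumulative_profile(
                profiles, tps, grid, usable_all, horizon=tp, patient_id=pid
            )
            cum_profiles[(pid, tp)] = cum
            cpa_med = sample_cpa[sid]
            if cum.is_empty:
                ct, ct_thr, ct_pos = np.nan, np.nan, False
            else:
                res = ctcpa_score(sample_z[sid], cum, sample_id=sid, mode=params.mode)
                ct = res.score
                ct_thr = ctcpa_threshold(cum, donor_z, mode=params.mode)
                ct_pos = classify_sample(ct, ct_thr)
            rows.append(
                (sid, pid, tp, SCHEDULE[tp], cpa_med, cpa_thr,
                 classify_sample(cpa_med, cpa_thr), ct, ct_thr, ct_pos,
                 cum.n_segments, tp)
            )
    scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    details = {
        "donor_cpa": donor_cpa,
        "donor_z": donor_z,
        "cpa_threshold": cpa_thr,
        "consensus": sample_consensus,
        "cumulative": cum_profiles,
        "usable": usable_all,
        "panel_cache": cache,
        "patient_pons": pat_pons,
        "sample_z": sample_z,
    }
    return scores, details


def write_scores(scores: pd.DataFrame, path: str) -> None:
    out = scores.copy()
    for col in ("cpa", "cpa_threshold", "ctcpa", "ctcpa_threshold", "months"):
        out[col] = out[col].map(
            lambda v: "nan" if not np.isfinite(v) else "%.6g" % v
        )
    for col in ("cpa_positive", "ctcpa_positive"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_scores(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("cpa_positive", "ctcpa_positive"):
        df[col] = df[col].astype(bool)
    return df
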