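"""Synthetic cfDNA cohort generator with known ground truth.

Healthy panels are negative-binomial bin counts with a smooth GC bias;
patient series mix a diploid background with tumor-derived copy number
segments at a per-timepoint tumor fraction via the standard admixture
model ``ratio = 1 + tf * (cn - 2) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import (
    SCHEDULE,
    BinCountMatrix,
    BinGrid,
    ClinicalTable,
    GenomeBuild,
    make_bin_grid,
    mini_build,
)

GAIN_CHROMS = ("chr1", "chr3")  # mini-build chromosomes carrying gains
LOSS_CHROMS = ("chr2", "chr4")  # mini-build chromosomes carrying losses


@dataclass(frozen=True)
class CNVSegmentSpec:
    """A tumor copy-number segment: interval plus integer copy number != 2."""

    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.cn == 2:
            raise ValueError("CN must differ from the diploid 2")
        if self.cn < 0:
            raise ValueError("CN must be non-negative")
        if self.end <= self.start:
            raise ValueError("empty CNV interval")


@dataclass(frozen=True)
class TumorTrajectory:
    """Ordered (timepoint label, tumor fraction) pairs plus CNVs that only
    become active from a given timepoint onward (clonal evolution at
    progression)."""

    points: tuple[tuple[str, float], ...]
    added_cnvs: tuple[tuple[str, CNVSegmentSpec], ...] = ()

    def __post_init__(self) -> None:
        for label, tf in self.points:
            if label not in SCHEDULE:
                raise ValueError(f"unknown timepoint label {label!r}")
            if not (0.0 <= tf <= 1.0):
                raise ValueError(f"tumor fraction {tf} outside [0, 1]")
        labels = [l for l, _ in self.points]
        months = [SCHEDULE[l] for l in labels]
        if months != sorted(months):
            raise ValueError("timepoints must be in schedule order")

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in self.points]

    def tf_at(self, label: str) -> float:
        for l, tf in self.points:
            if l == label:
                return tf
        raise KeyError(label)

    def cnvs_at(self, label: str, base: list[CNVSegmentSpec]) -> list[CNVSegmentSpec]:
        month = SCHEDULE[label]
        active = list(base)
        for from_label, spec in self.added_cnvs:
            if SCHEDULE[from_label] <= month:
                active.append(spec)
        return active


@dataclass(frozen=True)
class CohortConfig:
    n_healthy: int = 57
    n_patients: int = 16
    mean_count: float = 2000.0        # mean reads per 1000-kb bin (~2.5x)
    dispersion: float = 400.0         # NegBin size; per-bin CV ~5-6%
    gc_coeffs: tuple[float, float] = (0.6, -2.5)  # linear, quadratic in (gc-0.45)
    pd_lag_months: float = 1.5        # radiographic PD lag after ctDNA rise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 2:
            raise ValueError("need at least 2 healthy donors")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def expected_copy_ratio(cn: int, tf: float) -> float:
    """Expected read-depth ratio of a bin at tumor copy number ``cn`` in a
    plasma mixture with tumor fraction ``tf``."""
    if cn < 0:
        raise ValueError("copy number must be non-negative")
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tumor fraction must lie in [0, 1]")
    return 1.0 + tf * (cn - 2) / 2.0


def gc_bias(gc: np.ndarray, coeffs: tuple[float, float]) -> np.ndarray:
    """Smooth quadratic bias curve g(gc), normalized to mean 1 over the
    finite entries so the genome-wide expected depth is unchanged."""
    x = np.asarray(gc, dtype=float) - 0.45
    a1, a2 = coeffs
    g = 1.0 + a1 * x + a2 * x**2
    g = np.clip(g, 0.05, None)
    finite = np.isfinite(g)
    return g / g[finite].mean()


def default_gc_table(build: GenomeBuild, bin_size: int, seed: int = 12345) -> pd.DataFrame:
    """Deterministic per-bin GC fractions: a smooth positional wave plus a
    small reproducible jitter, spanning roughly 0.33-0.62."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, (name, length) in enumerate(zip(build.names, build.lengths)):
        n = math.ceil(length / bin_size)
        pos = np.arange(n)
        wave = 0.47 + 0.10 * np.sin(2 * np.pi * (pos / 37.0 + 0.13 * ci))
        gc = np.clip(wave + rng.normal(0.0, 0.02, n), 0.25, 0.75)
        for i in range(n):
            rows.append((name, i * bin_size, float(gc[i])))
    return pd.DataFrame(rows, columns=["chrom", "start", "gc"])


def default_grid(bin_size: int = 1_000_000) -> BinGrid:
    """The miniature test grid: mini build tiled at 1000-kb with
    deterministic GC values."""
    build = mini_build()
    return make_bin_grid(build, bin_size, default_gc_table(build, bin_size))


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _draw_sample(
    rng: np.random.Generator, grid: BinGrid, config: CohortConfig,
    copy_ratio: np.ndarray | None = None,
) -> np.ndarray:
    g = gc_bias(grid.gc, config.gc_coeffs)
    g = np.where(np.isfinite(g), g, 1.0)
    mu = config.mean_count * g
    if copy_ratio is not None:
        mu = mu * copy_ratio
    return _negbin(rng, mu, config.dispersion)


def simulate_healthy_panel(
    grid: BinGrid, config: CohortConfig, seed: int
) -> BinCountMatrix:
    """Negative-binomial healthy cfDNA counts with the configured GC bias;
    deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    counts = np.column_stack(
        [_draw_sample(rng, grid, config) for _ in range(config.n_healthy)]
    )
    ids = [f"HD{i + 1:03d}" for i in range(config.n_healthy)]
    samples = pd.DataFrame(
        {"role": "healthy", "patient": None, "timepoint": None, "day": np.nan},
        index=pd.Index(ids, name="sample"),
    )
    return BinCountMatrix(grid=grid, counts=counts, samples=samples)


def _check_disjoint(cnvs: list[CNVSegmentSpec]) -> None:
    by_chrom: dict[str, list[CNVSegmentSpec]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, specs in by_chrom.items():
        specs = sorted(specs, key=lambda s: s.start)
        for a, b in zip(specs, specs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping CNV specs on {chrom}: {a} / {b}")


def copy_ratio_track(
    grid: BinGrid, cnvs: list[CNVSegmentSpec], tf: float
) -> np.ndarray:
    """Per-bin expected copy ratio for a CNV set at tumor fraction ``tf``.
    A bin belongs to a CNV if its midpoint falls inside the interval."""
    _check_disjoint(cnvs)
    ratio = np.ones(grid.n_bins)
    mid = (grid.start + grid.end) / 2.0
    for spec in cnvs:
        inside = (grid.chrom == spec.chrom) & (mid >= spec.start) & (mid < spec.end)
        ratio[inside] = expected_copy_ratio(spec.cn, tf)
    return ratio


def true_bin_states(grid: BinGrid, cnvs: list[CNVSegmentSpec]) -> np.ndarray:
    """Ground-truth per-bin direction: +1 gain, -1 loss, 0 neutral."""
    states = np.zeros(grid.n_bins, dtype=np.int8)
    mid = (grid.start + grid.end) / 2.0
    for spec in cnvs:
        inside = (grid.chrom == spec.chrom) & (mid >= spec.start) & (mid < spec.end)
        states[inside] = 1 if spec.cn > 2 else -1
    return states


@dataclass
class SeriesTruth:
    """Ground truth for one simulated patient series."""

    patient_id: str
    timepoints: list[str]
    tf: dict[str, float]
    bin_states: dict[str, np.ndarray]  # per timepoint, +1/-1/0 per bin
    cnvs: dict[str, list[CNVSegmentSpec]]


def simulate_patient_series(
    grid: BinGrid,
    cnvs: list[CNVSegmentSpec],
    traj: TumorTrajectory,
    config: CohortConfig,
    seed: int,
    patient_id: str = "P001",
) -> tuple[BinCountMatrix, SeriesTruth]:
    """Simulate one longitudinal patient: per timepoint, counts whose mean is
    scaled by the admixture copy ratio inside active CNV bins."""
    _check_disjoint(cnvs)
    rng = np.random.default_rng(seed)
    cols, ids, tps, days = [], [], [], []
    truth = SeriesTruth(patient_id, [], {}, {}, {})
    for label, tf in traj.points:
        active = traj.cnvs_at(label, cnvs)
        _check_disjoint(active)
        ratio = copy_ratio_track(grid, active, tf)
        cols.append(_draw_sample(rng, grid, config, copy_ratio=ratio))
        sid = f"{patient_id}_{label}"
        ids.append(sid)
        tps.append(label)
        days.append(SCHEDULE[label] * 30.44)
        truth.timepoints.append(label)
        truth.tf[label] = tf
        truth.bin_states[label] = true_bin_states(grid, active) if tf > 0 else np.zeros(
            grid.n_bins, dtype=np.int8
        )
        truth.cnvs[label] = active
    samples = pd.DataFrame(
        {"role": "patient", "patient": patient_id, "timepoint": tps, "day": days},
        index=pd.Index(ids, name="sample"),
    )
    return BinCountMatrix(grid=grid, counts=np.column_stack(cols), samples=samples), truth


def _random_cnvs(
    rng: np.random.Generator, grid: BinGrid, n_gain: int, n_loss: int,
    min_bins: int = 20, max_bins: int = 40,
) -> list[CNVSegmentSpec]:
    """Place non-overlapping gains/losses on the designated chromosome sets."""
    specs: list[CNVSegmentSpec] = []
    taken: dict[str, list[tuple[int, int]]] = {}

    def place(chroms: tuple[str, ...], cn_options: tuple[int, ...]) -> None:
        for _ in range(1000):  # rejection sampling
            chrom = chroms[rng.integers(len(chroms))]
            sl = grid.chrom_slice(chrom)
            n_chrom = sl.stop - sl.start
            width = int(rng.integers(min_bins, max_bins + 1))
            if width >= n_chrom:
                continue
            start_bin = int(rng.integers(0, n_chrom - width))
            s = int(grid.start[sl.start + start_bin])
            e = int(grid.end[sl.start + start_bin + width - 1])
            if any(s < te and ts < e for ts, te in taken.get(chrom, [])):
                continue
            taken.setdefault(chrom, []).append((s, e))
            cn = int(cn_options[rng.integers(len(cn_options))])
            specs.append(CNVSegmentSpec(chrom, s, e, cn))
            return
        raise RuntimeError("could not place CNV without overlap")

    for _ in range(n_gain):
        place(GAIN_CHROMS, (3, 4))
    for _ in range(n_loss):
        place(LOSS_CHROMS, (1,))
    return specs


@dataclass
class Cohort:
    panel: BinCountMatrix
    series: list[BinCountMatrix]
    truths: list[SeriesTruth]
    clinical: ClinicalTable

    def all_counts(self) -> BinCountMatrix:
        """Panel and patient samples concatenated into one matrix."""
        counts = np.column_stack([self.panel.counts] + [s.counts for s in self.series])
        samples = pd.concat([self.panel.samples] + [s.samples for s in self.series])
        return BinCountMatrix(grid=self.panel.grid, counts=counts, samples=samples)


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    grid: BinGrid | None = None,
    shedding_fraction: float = 0.5,
) -> Cohort:
    """Wire the generators into a full cohort: a healthy panel, 16 patients
    with 4-7 serial samples each, and clinical outcomes whose radiographic
    PD trails the ctDNA rise by ``config.pd_lag_months``.

    Roughly ``shedding_fraction`` of patients shed ctDNA (tumor fraction
    falling under therapy, rising again before progression); the rest have
    tumor fraction 0 throughout.
    """
    config = config or CohortConfig()
    if seed is None:
        seed = config.seed
    grid = grid or default_grid()
    root = np.random.SeedSequence(seed)
    panel_seed, patient_seed = root.spawn(2)
    panel = simulate_healthy_panel(grid, config, panel_seed.generate_state(1)[0])

    rng = np.random.default_rng(patient_seed.generate_state(1)[0])
    series, truths = [], []
    clin_rows = []
    followups = ["W6", "M3", "M6"]
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        # 4 mandatory on-treatment samples + random follow-ups -> 4..7 total
        extra = [f for f in followups if rng.random() < 0.7]
        labels = ["BL", "F5", "F10", "END"] + extra
        sheds = rng.random() < shedding_fraction
        if sheds:
            tf0 = float(rng.uniform(0.08, 0.25))
            decay = float(rng.uniform(0.1, 0.35))
            tf_end = tf0 * decay
            on_tx = {"BL": tf0, "F5": tf0 * 0.7, "F10": tf0 * 0.45, "END": tf_end}
            rise_label = extra[rng.integers(len(extra))] if extra else None
            tfs = []
            rising = False
            for lab in labels:
                if lab in on_tx:
                    tfs.append((lab, on_tx[lab]))
                else:
                    if lab == rise_label:
                        rising = True
                    tfs.append((lab, min(tf0 * 1.5, 0.4) if rising else tf_end * 0.8))
            cnvs = _random_cnvs(rng, grid, n_gain=2, n_loss=2)
            traj = TumorTrajectory(points=tuple(tfs))
            if rise_label is not None:
                pd_month = SCHEDULE[rise_label] + config.pd_lag_months
            else:
                pd_month = SCHEDULE["END"] + float(rng.uniform(2.0, 6.0))
        else:
            cnvs = []
            traj = TumorTrajectory(points=tuple((lab, 0.0) for lab in labels))
            pd_month = float(rng.uniform(3.0, 10.0))
        s, t = simulate_patient_series(
            grid, cnvs, traj, config,
            seed=int(rng.integers(0, 2**31 - 1)), patient_id=pid,
        )
        series.append(s)
        truths.append(t)
        clin_rows.append(
            {
                "patient": pid,
                "pfs_months": round(pd_month, 3),
                "event": True,
                "pd_months": (round(pd_month, 3),),
            }
        )
    clin = ClinicalTable(table=pd.DataFrame(clin_rows).set_index("patient"))
    return Cohort(panel=panel, series=series, truths=truths, clinical=clin)


def write_truth(truths: list[SeriesTruth], path: str) -> None:
    """TSV of active CNVs and tumor fractions per sample timepoint."""
    with open(path, "w") as fh:
        fh.write("patient\ttimepoint\ttf\tchrom\tstart\tend\tcn\n")
        for t in truths:
            for label in t.timepoints:
                tf = t.tf[label]
                specs = t.cnvs[label] if tf > 0 else []
                if not specs:
                    fh.write(f"{t.patient_id}\t{label}\t{tf:.6g}\t.\t.\t.\t.\n")
                for spec in specs:
                    fh.write(
                        f"{t.patient_id}\t{label}\t{tf:.6g}\t{spec.chrom}"
                        f"\t{spec.start}\t{spec.end}\t{spec.cn}\n"
                    )
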