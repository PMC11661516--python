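"""Genome coordinate model and on-disk formats.

All coordinates are 0-based half-open (BED convention), both in memory and
in every file this module reads or writes.  Writers are deterministic:
stable row ordering and fixed ``%.6g`` float formatting, so identical
inputs yield byte-identical files.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

#: Plasma sampling schedule: label -> months from treatment start.
#: Baseline, after 5 and 10 fractions (~7/14 days), end of treatment
#: (~21 days), then follow-up visits at 6 weeks, 3 and 6 months after the
#: treatment end.
SCHEDULE: dict[str, float] = {
    "BL": 0.0,
    "F5": 0.23,
    "F10": 0.47,
    "END": 0.70,
    "W6": 2.08,
    "M3": 3.70,
    "M6": 6.70,
}

#: GRCh37/hg19 chromosome lengths (bp); optional full-scale build.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosomes with lengths and an autosome flag.

    Sex chromosomes are identifiable so they can be excluded from scoring.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    autosome: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lengths) == len(self.autosome)):
            raise ValueError("names, lengths and autosome must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def is_autosome(self, name: str) -> bool:
        return self.autosome[self.names.index(name)]


def mini_build() -> GenomeBuild:
    """Miniature test build: four autosomes (120/100/80/60 Mb) plus one
    sex chromosome (60 Mb)."""
    return GenomeBuild(
        names=("chr1", "chr2", "chr3", "chr4", "chrX"),
        lengths=(120_000_000, 100_000_000, 80_000_000, 60_000_000, 60_000_000),
        autosome=(True, True, True, True, False),
    )


def hg19_build() -> GenomeBuild:
    names = tuple(HG19_LENGTHS)
    return GenomeBuild(
        names=names,
        lengths=tuple(HG19_LENGTHS[n] for n in names),
        autosome=tuple(n not in ("chrX", "chrY") for n in names),
    )


@dataclass
class BinGrid:
    """Ordered genomic bins tiling each chromosome without overlap.

    ``usable`` marks bins eligible for normalization/scoring; sex-chromosome
    bins and bins lacking GC values are always unusable.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    usable: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        n = len(self.chrom)
        if not all(len(a) == n for a in (self.start, self.end, self.gc, self.usable)):
            raise ValueError("grid arrays must have equal length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        widths = self.end - self.start
        if np.any(widths <= 0):
            raise ValueError("bins must have positive width")
        # tiling check: consecutive bins on a chromosome must abut, and
        # only the last bin per chromosome may be short
        for c in self.chrom_order():
            sl = self.chrom_slice(c)
            s, e = self.start[sl], self.end[sl]
            if s[0] != 0:
                raise ValueError(f"{c}: first bin must start at 0")
            if np.any(s[1:] != e[:-1]):
                raise ValueError(f"{c}: bins do not tile the chromosome")
            if np.any(e[:-1] - s[:-1] != self.bin_size):
                raise ValueError(f"{c}: interior bin width != bin_size")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    def chrom_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chrom_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.chrom == name)
        if idx.size == 0:
            raise KeyError(name)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"bins of {name} are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def keys(self) -> np.ndarray:
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)],
            dtype=object,
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.allclose(self.gc, other.gc, equal_nan=True)
            and np.array_equal(self.usable, other.usable)
        )


def parse_bin_key(key: str) -> tuple[str, int, int]:
    m = _KEY_RE.match(key)
    if m is None:
        raise ValueError(f"malformed bin key: {key!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


def make_bin_grid(
    build: GenomeBuild,
    bin_size: int,
    gc_source: Mapping[tuple[str, int], float] | pd.DataFrame,
) -> BinGrid:
    """Tile every chromosome of ``build`` into ``bin_size`` bins.

    ``gc_source`` maps ``(chrom, start)`` to a GC fraction (a DataFrame with
    columns chrom/start/gc is also accepted).  Bins without a GC value are
    flagged unusable with a warning; sex-chromosome bins are always unusable.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if isinstance(gc_source, pd.DataFrame):
        gc_map = {
            (str(r.chrom), int(r.start)): float(r.gc)
            for r in gc_source.itertuples(index=False)
        }
    else:
        gc_map = dict(gc_source)

    chroms, starts, ends, gcs, usable = [], [], [], [], []
    n_missing = 0
    for name, length, is_auto in zip(build.names, build.lengths, build.autosome):
        n = math.ceil(length / bin_size)
        for i in range(n):
            s = i * bin_size
            e = min(s + bin_size, length)
            gc = gc_map.get((name, s), np.nan)
            ok = is_auto
            if not np.isfinite(gc) or not (0.0 <= gc <= 1.0):
                gc = np.nan
                if is_auto:
                    n_missing += 1
                ok = False
            chroms.append(name)
            starts.append(s)
            ends.append(e)
            gcs.append(gc)
            usable.append(ok)
    if n_missing:
        log.warning("%d autosomal bins lack GC values; flagged unusable", n_missing)
    return BinGrid(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts),
        end=np.array(ends),
        gc=np.array(gcs),
        usable=np.array(usable),
        bin_size=bin_size,
    )


def write_bin_grid(grid: BinGrid, path: str) -> None:
    """BED-style grid: chrom, start, end, gc, usable (0/1)."""
    with open(path, "w") as fh:
        fh.write("# ctcpa bin grid; coordinates 0-based half-open\n")
        fh.write(f"# bin_size={grid.bin_size}\n")
        for c, s, e, g, u in zip(grid.chrom, grid.start, grid.end, grid.gc, grid.usable):
            gtxt = "." if not np.isfinite(g) else FLOAT_FMT % g
            fh.write(f"{c}\t{s}\t{e}\t{gtxt}\t{int(u)}\n")


def read_bin_grid(path: str) -> BinGrid:
    bin_size = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                m = re.search(r"bin_size=(\d+)", line)
                if m:
                    bin_size = int(m.group(1))
                continue
            if not line:
                continue
            c, s, e, g, u = line.split("\t")
            rows.append((c, int(s), int(e), np.nan if g == "." else float(g), bool(int(u))))
    if not rows:
        raise ValueError(f"empty bin grid: {path}")
    if bin_size is None:
        bin_size = max(e - s for _, s, e, _, _ in rows)
    chrom, start, end, gc, usable = map(np.array, zip(*rows))
    return BinGrid(
        chrom=chrom.astype(object), start=start.astype(np.int64),
        end=end.astype(np.int64), gc=gc.astype(float),
        usable=usable.astype(bool), bin_size=bin_size,
    )


# ---------------------------------------------------------------------------
# bin-count matrices


@dataclass
class BinCountMatrix:
    """Read counts per bin (rows, matching a :class:`BinGrid`) per sample
    (columns) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``role`` (healthy |
    patient), ``patient``, ``timepoint`` and ``day``; the latter three may be
    missing for healthy donors but are mandatory for patient samples.
    """

    grid: BinGrid
    counts: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.n_bins, len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.grid.n_bins} bins x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        for col in ("role", "patient", "timepoint", "day"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad_role = set(self.samples["role"]) - {"healthy", "patient"}
        if bad_role:
            raise ValueError(f"unknown sample roles: {sorted(bad_role)}")
        pat = self.samples[self.samples["role"] == "patient"]
        missing = pat.index[pat["patient"].isna() | pat["timepoint"].isna()]
        if len(missing):
            raise ValueError(
                f"patient samples lacking patient/timepoint metadata: {list(missing)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "BinCountMatrix":
        pos = [self.sample_ids.index(s) for s in sample_ids]
        return BinCountMatrix(
            grid=self.grid,
            counts=self.counts[:, pos],
            samples=self.samples.loc[list(sample_ids)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinCountMatrix):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.counts, other.counts)
            and self.sample_ids == other.sample_ids
        )


def write_bin_counts(m: BinCountMatrix, path: str) -> None:
    """TSV with a ``#sample`` metadata line per sample, then a header row of
    sample ids and one row per bin keyed ``chrom:start-end``."""
    with open(path, "w") as fh:
        fh.write("# ctcpa bin counts; coordinates 0-based half-open\n")
        for sid, row in m.samples.iterrows():
            pat = "." if pd.isna(row["patient"]) else str(row["patient"])
            tp = "." if pd.isna(row["timepoint"]) else str(row["timepoint"])
            day = "." if pd.isna(row["day"]) else FLOAT_FMT % float(row["day"])
            fh.write(f"#sample\t{sid}\t{row['role']}\t{pat}\t{tp}\t{day}\n")
        fh.write("bin\t" + "\t".join(m.sample_ids) + "\n")
        keys = m.grid.keys()
        for i in range(m.grid.n_bins):
            fh.write(keys[i] + "\t" + "\t".join(str(v) for v in m.counts[i]) + "\n")


def read_bin_counts(path: str, grid: BinGrid | None = None) -> BinCountMatrix:
    """Inverse of :func:`write_bin_counts`.

    When ``grid`` is given, bin keys must match it exactly (hard error naming
    the first offending bin); otherwise a minimal grid is reconstructed from
    the keys (GC unknown, all bins usable).
    """
    meta: dict[str, dict] = {}
    header: list[str] | None = None
    keys: list[str] = []
    data: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#sample\t"):
                _, sid, role, pat, tp, day = line.split("\t")
                meta[sid] = {
                    "role": role,
                    "patient": None if pat == "." else pat,
                    "timepoint": None if tp == "." else tp,
                    "day": np.nan if day == "." else float(day),
                }
                continue
            if line.startswith("#") or not line:
                continue
            parts = line.split("\t")
            if header is None:
                if parts[0] != "bin":
                    raise ValueError(f"expected 'bin' header, got {parts[0]!r}")
                header = parts[1:]
                continue
            keys.append(parts[0])
            vals = [int(v) for v in parts[1:]]
            if any(v < 0 for v in vals):
                raise ValueError(f"negative count at bin {parts[0]}")
            data.append(vals)
    if header is None:
        raise ValueError(f"no header row in {path}")
    missing_meta = [s for s in header if s not in meta]
    if missing_meta:
        raise ValueError(f"missing sample metadata for: {missing_meta}")
    if grid is not None:
        want = grid.keys()
        if len(keys) != len(want):
            raise ValueError(
                f"bin count mismatch: file has {len(keys)}, grid has {len(want)}"
            )
        for got, exp in zip(keys, want):
            if got != exp:
                raise ValueError(f"bin key mismatch: file has {got!r}, grid expects {exp!r}")
    else:
        parsed = [parse_bin_key(k) for k in keys]
        chrom = np.array([p[0] for p in parsed], dtype=object)
        start = np.array([p[1] for p in parsed], dtype=np.int64)
        end = np.array([p[2] for p in parsed], dtype=np.int64)
        grid = BinGrid(
            chrom=chrom, start=start, end=end,
            gc=np.full(len(keys), np.nan), usable=np.ones(len(keys), bool),
            bin_size=int((end - start).max()),
        )
    samples = pd.DataFrame.from_dict(meta, orient="index").loc[header]
    samples.index.name = "sample"
    return BinCountMatrix(grid=grid, counts=np.array(data, dtype=np.int64), samples=samples)


# ---------------------------------------------------------------------------
# segments (SEG-like TSV)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "seg_z", "state"]


def write_segments(profiles: Iterable, path: str) -> None:
    """SEG-style TSV: sample, chrom, start, end, n_bins, seg_z, state.

    ``profiles`` is an iterable of objects with ``sample_id`` and a
    ``segments`` DataFrame.  Segments must not overlap within a sample.
    """
    rows = []
    for p in profiles:
        seg = p.segments
        for chrom, grp in seg.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(
                    f"overlapping segments for sample {p.sample_id} on {chrom}"
                )
        for r in seg.itertuples(index=False):
            rows.append((p.sample_id, r.chrom, int(r.start), int(r.end),
                         int(r.n_bins), float(r.seg_z), r.state))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("# ctcpa segments; coordinates 0-based half-open\n")
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sid, chrom, s, e, nb, z, st in rows:
            ztxt = "nan" if not np.isfinite(z) else FLOAT_FMT % z
            fh.write(f"{sid}\t{chrom}\t{s}\t{e}\t{nb}\t{ztxt}\t{st}\n")


def read_segments(path: str) -> list:
    """Read a SEG-style TSV back into a list of segment profiles."""
    from .segmentation import SegmentProfile  # local import, avoids cycle

    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != SEG_COLUMNS:
        raise ValueError(f"unexpected SEG columns: {list(df.columns)}")
    out = []
    for sid, grp in df.groupby("sample", sort=True):
        seg = grp.drop(columns="sample").reset_index(drop=True)
        out.append(SegmentProfile(sample_id=str(sid), segments=seg))
    return out


# ---------------------------------------------------------------------------
# clinical metadata


@dataclass
class ClinicalTable:
    """Per-patient outcome data.

    ``table`` is indexed by patient id with columns ``pfs_months``,
    ``event`` (bool), ``pd_months`` (tuple of ascending months, possibly
    empty) and optional covariates (``os_months``, ``age``, ``gtv_cm3``,
    ``modality``, ``dissemination``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dup = sorted(t.index[t.index.duplicated()])
            raise ValueError(f"duplicate patient id(s): {dup}")
        for col in ("pfs_months", "event", "pd_months"):
            if col not in t.columns:
                raise ValueError(f"clinical table lacks column {col!r}")
        if t["pfs_months"].isna().any():
            bad = sorted(t.index[t["pfs_months"].isna()])
            raise ValueError(f"PFS missing for patient(s): {bad}")
        if (t["pfs_months"] < 0).any():
            raise ValueError("PFS must be non-negative")

    @property
    def patients(self) -> list[str]:
        return list(self.table.index)

    def pd_dates(self, patient: str) -> tuple[float, ...]:
        return self.table.loc[patient, "pd_months"]

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, ClinicalTable):
            return NotImplemented
        return self.table.equals(other.table)


_CLINICAL_OPTIONAL = ["os_months", "age", "gtv_cm3", "modality", "dissemination"]


def _parse_pd_months(txt) -> tuple[float, ...]:
    if txt is None or (isinstance(txt, float) and np.isnan(txt)) or txt == "" or txt == ".":
        return ()
    vals = [float(v) for v in str(txt).split(";")]
    return tuple(sorted(vals))


def read_clinical(path: str) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient": str})
    if "patient" not in df.columns:
        raise ValueError("clinical TSV lacks 'patient' column")
    if df["patient"].duplicated().any():
        dup = sorted(df["patient"][df["patient"].duplicated()])
        raise ValueError(f"duplicate patient id(s): {dup}")
    df = df.set_index("patient")
    df["pd_months"] = [_parse_pd_months(v) for v in df.get("pd_months", [""] * len(df))]
    df["event"] = df["event"].astype(bool)
    keep = ["pfs_months", "event", "pd_months"] + [
        c for c in _CLINICAL_OPTIONAL if c in df.columns
    ]
    return ClinicalTable(table=df[keep])


def write_clinical(clin: ClinicalTable, path: str) -> None:
    t = clin.table.sort_index()
    cols = ["pfs_months", "event", "pd_months"] + [
        c for c in _CLINICAL_OPTIONAL if c in t.columns
    ]
    with open(path, "w") as fh:
        fh.write("patient\t" + "\t".join(cols) + "\n")
        for pid, row in t.iterrows():
            vals = []
            for c in cols:
                v = row[c]
                if c == "pd_months":
                    vals.append(";".join(FLOAT_FMT % x for x in v) if v else ".")
                elif c == "event":
                    vals.append(str(int(v)))
                elif isinstance(v, float):
                    vals.append("." if not np.isfinite(v) else FLOAT_FMT % v)
                else:
                    vals.append(str(v))
            fh.write(str(pid) + "\t" + "\t".join(vals) + "\n")
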