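"""Signal tracks, regions and binned profile extraction.

A :class:`SignalTrack` stores dense per-position values for each chromosome
(``NaN`` marks missing data, which is distinct from a measured 0.0).  Raw
mapped tags can be converted to fragment coverage with
:func:`tag_extension_coverage`, normalized to a log2 occupancy ratio with
:func:`log2_occupancy`, and sampled into a fixed-resolution region x bin
matrix with :func:`extract_region_matrix`.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "COVERAGE",
    "LOG2_RATIO",
    "Region",
    "SignalTrack",
    "RegionProfile",
    "RegionMatrix",
    "tag_extension_coverage",
    "log2_occupancy",
    "extract_region_matrix",
    "read_bed",
    "read_bedgraph",
    "read_wiggle",
    "write_bedgraph",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

#: value-semantics flags for SignalTrack.kind
COVERAGE = "coverage"
LOG2_RATIO = "log2"

DEFAULT_PSEUDOCOUNT = 0.25


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region {self.id!r}: end ({self.end}) must be > start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"region {self.id!r}: negative start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, delta: int, new_id: str | None = None) -> "Region":
        return replace(
            self,
            id=new_id if new_id is not None else self.id,
            start=self.start + delta,
            end=self.end + delta,
        )


class SignalTrack:
    """Dense per-position signal values keyed by chromosome.

    Parameters
    ----------
    data:
        Mapping of chromosome name to a float array holding one value per
        ``resolution`` bases, ``NaN`` meaning "no data here".
    resolution:
        Base pairs per stored value (>= 1).
    kind:
        Either :data:`COVERAGE` (raw read coverage) or :data:`LOG2_RATIO`.
    """

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        resolution: int = 1,
        kind: str = COVERAGE,
    ) -> None:
        if resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {resolution}")
        if kind not in (COVERAGE, LOG2_RATIO):
            raise ValueError(f"unknown track kind {kind!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        self.resolution = int(resolution)
        self.kind = kind

    @classmethod
    def zeros(cls, genome_sizes: Mapping[str, int], resolution: int = 1,
              kind: str = COVERAGE) -> "SignalTrack":
        data = {
            chrom: np.zeros(-(-size // resolution))
            for chrom, size in genome_sizes.items()
        }
        return cls(data, resolution=resolution, kind=kind)

    @classmethod
    def missing(cls, genome_sizes: Mapping[str, int], resolution: int = 1,
                kind: str = COVERAGE) -> "SignalTrack":
        data = {
            chrom: np.full(-(-size // resolution), np.nan)
            for chrom, size in genome_sizes.items()
        }
        return cls(data, resolution=resolution, kind=kind)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.data[chrom]

    def defined_mean(self) -> float:
        """Mean over every position with a defined (non-missing) value."""
        total = 0.0
        count = 0
        for arr in self.data.values():
            ok = ~np.isnan(arr)
            total += float(arr[ok].sum())
            count += int(ok.sum())
        if count == 0:
            raise ValueError("track has no defined values")
        return total / count


@dataclass(frozen=True)
class RegionProfile:
    """One region's binned signal values."""

    region: Region
    values: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        expected = self.region.length // self.bin_size
        if self.region.length % self.bin_size != 0:
            raise ValueError(
                f"region {self.region.id!r}: length {self.region.length} not "
                f"divisible by bin size {self.bin_size}"
            )
        if len(vals) != expected:
            raise ValueError(
                f"region {self.region.id!r}: expected {expected} bins, got {len(vals)}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.values)


class RegionMatrix:
    """An ordered set of equal-length region profiles sharing one bin size."""

    def __init__(self, profiles: Sequence[RegionProfile]) -> None:
        if not profiles:
            raise ValueError("RegionMatrix requires at least one profile")
        m = profiles[0].n_bins
        b = profiles[0].bin_size
        for p in profiles:
            if p.n_bins != m:
                raise ValueError(
                    f"profile {p.region.id!r} has {p.n_bins} bins, expected {m}"
                )
            if p.bin_size != b:
                raise ValueError("mixed bin sizes in RegionMatrix")
        ids = [p.region.id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in RegionMatrix")
        self.profiles = list(profiles)
        self.values = np.vstack([p.values for p in profiles])
        self.bin_size = b

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        bin_size: int = 1,
        ids: Sequence[str] | None = None,
        regions: Sequence[Region] | None = None,
    ) -> "RegionMatrix":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        n, m = values.shape
        if regions is None:
            if ids is None:
                ids = [f"region_{i}" for i in range(n)]
            regions = [
                Region(str(ids[i]), ".", 0, m * bin_size) for i in range(n)
            ]
        profiles = [
            RegionProfile(regions[i], values[i], bin_size) for i in range(n)
        ]
        return cls(profiles)

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def ids(self) -> list[str]:
        return [p.region.id for p in self.profiles]

    def __len__(self) -> int:
        return self.n


# ---------------------------------------------------------------------------
# coverage / normalization
# ---------------------------------------------------------------------------

def tag_extension_coverage(
    tags: Iterable[Region],
    extension_len: int,
    genome_sizes: Mapping[str, int],
) -> SignalTrack:
    """Pile up mapped tags extended from their 5' end to ``extension_len``.

    Each tag contributes 1 to every base from its 5' end extending
    ``extension_len`` bases in its strand direction, clipped at chromosome
    ends.  Returns a per-base raw coverage track.
    """
    if extension_len <= 0:
        raise ValueError(f"extension_len must be > 0, got {extension_len}")
    # difference arrays: O(tags) updates then one cumsum per chromosome
    diffs = {c: np.zeros(int(size) + 1) for c, size in genome_sizes.items()}
    for tag in tags:
        if tag.chrom not in genome_sizes:
            raise ValueError(f"tag {tag.id!r} on unknown chromosome {tag.chrom!r}")
        size = int(genome_sizes[tag.chrom])
        if tag.start < 0 or tag.end > size:
            raise ValueError(
                f"tag {tag.id!r} ({tag.chrom}:{tag.start}-{tag.end}) outside "
                f"chromosome bounds [0, {size})"
            )
        if tag.strand == "+":
            lo = tag.start
            hi = min(tag.start + extension_len, size)
        elif tag.strand == "-":
            # 5' end of a minus-strand tag is its last base (end - 1)
            hi = tag.end
            lo = max(tag.end - extension_len, 0)
        else:
            raise ValueError(
                f"tag {tag.id!r} has unknown strand {tag.strand!r}; "
                "tags must be stranded (+/-)"
            )
        diffs[tag.chrom][lo] += 1.0
        diffs[tag.chrom][hi] -= 1.0
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return SignalTrack(data, resolution=1, kind=COVERAGE)


def log2_occupancy(
    coverage: SignalTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SignalTrack:
    """Transform raw coverage into a log2 ratio versus the genome-wide mean.

    ``value(b) = log2((cov(b) + pseudocount) / (mean_cov + pseudocount))``
    where ``mean_cov`` is taken over all positions with defined coverage.
    """
    if coverage.kind != COVERAGE:
        raise ValueError("log2_occupancy expects a raw coverage track")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_cov = coverage.defined_mean()
    if mean_cov <= 0:
        raise ValueError("coverage track is all zero; cannot normalize")
    data = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for chrom, arr in coverage.data.items():
            data[chrom] = np.log2((arr + pseudocount) / (mean_cov + pseudocount))
    return SignalTrack(data, resolution=coverage.resolution, kind=LOG2_RATIO)


def extract_region_matrix(
    track: SignalTrack,
    regions: Sequence[Region],
    bin_size: int,
) -> tuple[RegionMatrix, list[Region]]:
    """Sample ``track`` into a region x bin matrix at ``bin_size`` resolution.

    Each bin holds the arithmetic mean of the track values it covers.  A
    region with at least one missing base in any bin — including regions
    falling outside the track — is excluded and returned in ``dropped``;
    the order of retained regions is preserved.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions supplied")
    length = regions[0].length
    for r in regions:
        if r.length != length:
            raise ValueError(
                f"all regions must have the same length; {r.id!r} has "
                f"{r.length}, expected {length}"
            )
    if length % bin_size != 0:
        raise ValueError(
            f"region length {length} not divisible by bin size {bin_size}"
        )
    res = track.resolution
    if bin_size % res != 0:
        raise ValueError(
            f"bin size {bin_size} not divisible by track resolution {res}"
        )
    per_bin = bin_size // res
    kept: list[RegionProfile] = []
    dropped: list[Region] = []
    for r in regions:
        if r.chrom not in track.data or r.start % res or r.end % res:
            dropped.append(r)
            continue
        arr = track.data[r.chrom]
        lo, hi = r.start // res, r.end // res
        if lo < 0 or hi > len(arr):
            dropped.append(r)
            continue
        vals = arr[lo:hi]
        if np.isnan(vals).any():
            dropped.append(r)
            continue
        binned = vals.reshape(-1, per_bin).mean(axis=1)
        kept.append(RegionProfile(r, binned, bin_size))
    if not kept:
        raise ValueError("no regions retained after gap filtering")
    return RegionMatrix(kept), dropped


# ---------------------------------------------------------------------------
# text I/O (UTF-8, tab-delimited, '#' comments ignored)
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield line.split("\t")


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3/BED6 intervals; names default to ``chrom:start-end``."""
    regions: list[Region] = []
    seen: dict[str, int] = {}
    for fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed BED line {fields!r}")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"{chrom}:{start}-{end}"
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        strand = fields[5] if len(fields) >= 6 else "."
        regions.append(Region(name, chrom, start, end, strand))
    return regions


def read_bedgraph(
    path: str | Path,
    genome_sizes: Mapping[str, int] | None = None,
    kind: str = LOG2_RATIO,
) -> SignalTrack:
    """Read a bedGraph file into a per-base track (uncovered = missing)."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}: malformed bedGraph line {fields!r}")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        intervals.setdefault(chrom, []).append((start, end, value))
    if genome_sizes is None:
        genome_sizes = {
            c: max(end for _, end, _ in ivs) for c, ivs in intervals.items()
        }
    track = SignalTrack.missing(genome_sizes, resolution=1, kind=kind)
    for chrom, ivs in intervals.items():
        if chrom not in track.data:
            raise ValueError(f"{path}: chromosome {chrom!r} not in genome sizes")
        arr = track.data[chrom]
        for start, end, value in ivs:
            if end > len(arr):
                raise ValueError(
                    f"{path}: interval {chrom}:{start}-{end} exceeds "
                    f"chromosome size {len(arr)}"
                )
            arr[start:end] = value
    return track


def read_wiggle(
    path: str | Path,
    genome_sizes: Mapping[str, int] | None = None,
    kind: str = LOG2_RATIO,
) -> SignalTrack:
    """Read fixed-step wiggle (1-based starts) into a per-base track."""
    chunks: dict[str, list[tuple[int, int, float]]] = {}
    chrom = None
    pos = step = span = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(part.split("=", 1) for part in line.split()[1:])
                chrom = attrs["chrom"]
                pos = int(attrs["start"]) - 1  # wiggle is 1-based
                step = int(attrs.get("step", 1))
                span = int(attrs.get("span", step))
                chunks.setdefault(chrom, [])
                continue
            if line.startswith("variableStep"):
                raise ValueError("variableStep wiggle is not supported")
            if chrom is None:
                raise ValueError(f"{path}: data line before fixedStep header")
            chunks[chrom].append((pos, pos + span, float(line)))
            pos += step
    if genome_sizes is None:
        genome_sizes = {c: max(e for _, e, _ in ivs) for c, ivs in chunks.items()}
    track = SignalTrack.missing(genome_sizes, resolution=1, kind=kind)
    for c, ivs in chunks.items():
        arr = track.data[c]
        for start, end, value in ivs:
            arr[start:end] = value
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write defined track values as run-length-merged bedGraph intervals."""
    res = track.resolution
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            arr = track.data[chrom]
            start = None
            current = None
            for i, v in enumerate(arr):
                if np.isnan(v):
                    if start is not None:
                        fh.write(f"{chrom}\t{start * res}\t{i * res}\t{current:g}\n")
                        start = None
                    continue
                if start is None:
                    start, current = i, v
                elif v != current:
                    fh.write(f"{chrom}\t{start * res}\t{i * res}\t{current:g}\n")
                    start, current = i, v
            if start is not None:
                fh.write(f"{chrom}\t{start * res}\t{len(arr) * res}\t{current:g}\n")


def write_matrix_tsv(matrix: RegionMatrix, path: str | Path) -> None:
    """Write a region x bin matrix: id column + one column per bin offset."""
    b = matrix.bin_size
    with open(path, "w", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["region_id"] + [str(i * b) for i in range(matrix.m)])
        for prof in matrix.profiles:
            writer.writerow([prof.region.id] + [repr(float(v)) for v in prof.values])


def read_matrix_tsv(path: str | Path) -> RegionMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`.

    The bin size is inferred from the header's bin-offset columns.
    """
    rows = list(_data_lines(path))
    if len(rows) < 2:
        raise ValueError(f"{path}: matrix file needs a header and >= 1 row")
    header = rows[0]
    offsets = [int(x) for x in header[1:]]
    if len(offsets) >= 2:
        bin_size = offsets[1] - offsets[0]
        if bin_size <= 0 or any(
            offsets[i + 1] - offsets[i] != bin_size for i in range(len(offsets) - 1)
        ):
            raise ValueError(f"{path}: header bin offsets are not evenly spaced")
    else:
        bin_size = 1
    ids = []
    values = []
    for fields in rows[1:]:
        if len(fields) != len(header):
            raise ValueError(f"{path}: row {fields[0]!r} has wrong column count")
        ids.append(fields[0])
        values.append([float(x) for x in fields[1:]])
    return RegionMatrix.from_values(np.array(values), bin_size=bin_size, ids=ids)
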