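"""Genomic intervals: BED/FASTA I/O, overlap partitioning, matched backgrounds.

Coordinates are 0-based half-open throughout (BED convention).  The
matched-background generator draws random intervals with the same length
multiset as a template peak set, constrained to lie inside allowed regions
(e.g. the promoter space a tiling array represents) and to avoid the real
peaks, so that peak-versus-background classifiers are not confounded by
genomic location or length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np


class BedError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Random interval placement failed within the allowed number of tries."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        key = lambda iv: (iv.chrom, iv.start, iv.end)
        return PeakSet(self.name, sorted(self.intervals, key=key))

    def lengths(self) -> list[int]:
        return [iv.length for iv in self.intervals]

    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]


@dataclass
class OverlapPartition:
    """A/B1/B2/C split of two replicate peak sets.

    A: set1 peaks overlapping nothing in set2; B1: set1 peaks overlapping
    set2; B2: set2 peaks overlapping set1; C: set2 peaks overlapping nothing
    in set1.  Overlap means >= 1 shared base unless a minimum overlap
    fraction is requested.
    """

    A: PeakSet
    B1: PeakSet
    B2: PeakSet
    C: PeakSet

    def subsets(self) -> dict[str, PeakSet]:
        return {"A": self.A, "B1": self.B1, "B2": self.B2, "C": self.C}


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read BED3/BED4; comment, track and browser lines are skipped.

    Malformed coordinates raise :class:`BedError` naming the line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"{path.name}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(
                    fields[0], start, end, fields[3] if len(fields) > 3 else None
                )
            except ValueError as exc:
                raise BedError(f"{path.name}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return PeakSet(name or path.stem, intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def extract_sequences(peaks: PeakSet, genome: str | Path) -> dict[str, str]:
    """Uppercase sequence per peak id from an (indexed-on-first-use) FASTA."""
    from pyfaidx import Fasta

    fasta = Fasta(str(genome), sequence_always_upper=True)
    out: dict[str, str] = {}
    for iv in peaks:
        if iv.chrom not in fasta:
            raise KeyError(f"peak {iv.id}: unknown sequence {iv.chrom!r}")
        if iv.end > len(fasta[iv.chrom]):
            raise ValueError(
                f"peak {iv.id}: end {iv.end} beyond {iv.chrom} length {len(fasta[iv.chrom])}"
            )
        out[iv.id] = str(fasta[iv.chrom][iv.start : iv.end])
    return out


def _overlap_mask(query: PeakSet, subject: PeakSet, min_fraction: float = 0.0) -> np.ndarray:
    """Boolean per query interval: overlaps any subject interval."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    arrays = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        arrays[chrom] = (starts, ends, ivs)
    mask = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        if iv.chrom not in arrays:
            continue
        starts, ends, ivs = arrays[iv.chrom]
        k = int(np.searchsorted(starts, iv.end, side="left"))
        for j in range(k):
            ov = min(iv.end, ends[j]) - max(iv.start, starts[j])
            if ov > 0 and (min_fraction <= 0.0 or ov >= min_fraction * iv.length):
                mask[i] = True
                break
    return mask


def partition_overlap(
    set1: PeakSet, set2: PeakSet, min_fraction: float = 0.0
) -> OverlapPartition:
    """Partition two peak sets by mutual coordinate overlap (>= 1 bp default)."""
    m1 = _overlap_mask(set1, set2, min_fraction)
    m2 = _overlap_mask(set2, set1, min_fraction)
    return OverlapPartition(
        A=PeakSet("A", [iv for iv, m in zip(set1, m1) if not m]),
        B1=PeakSet("B1", [iv for iv, m in zip(set1, m1) if m]),
        B2=PeakSet("B2", [iv for iv, m in zip(set2, m2) if m]),
        C=PeakSet("C", [iv for iv, m in zip(set2, m2) if not m]),
    )


def place_random_intervals(
    lengths: Sequence[int],
    allowed: PeakSet,
    rng: np.random.Generator,
    exclude: Iterable[GenomicInterval] = (),
    max_tries: int = 1000,
    name_prefix: str = "bg",
) -> list[GenomicInterval]:
    """Place intervals of the given lengths uniformly inside allowed regions.

    Rejection sampling: a region is chosen with probability proportional to
    the number of valid start offsets for the length, then a uniform offset;
    candidates overlapping ``exclude`` or a previously placed interval are
    rejected.  Lengths are placed in descending order to reduce failures; the
    emitted intervals keep the order of the requested ``lengths``.
    """
    regions = list(allowed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        occupied.setdefault(iv.chrom, []).append((iv.start, iv.end))

    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    placed: list[GenomicInterval | None] = [None] * len(lengths)
    for rank, idx in enumerate(order):
        length = int(lengths[idx])
        fits = [r for r in regions if r.length >= length]
        if not fits:
            raise PlacementError(f"no allowed region can hold an interval of length {length}")
        weights = np.array([r.length - length + 1 for r in fits], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            region = fits[int(rng.choice(len(fits), p=weights))]
            start = region.start + int(rng.integers(0, region.length - length + 1))
            end = start + length
            clash = any(
                start < e and s < end for s, e in occupied.get(region.chrom, ())
            )
            if not clash:
                placed[idx] = GenomicInterval(
                    region.chrom, start, end, f"{name_prefix}_{idx:05d}"
                )
                occupied.setdefault(region.chrom, []).append((start, end))
                break
        else:
            raise PlacementError(
                f"could not place interval of length {length} after {max_tries} tries"
            )
    return [iv for iv in placed if iv is not None]


def generate_random_peaks(
    template: PeakSet,
    allowed: PeakSet,
    seed: int,
    exclude: PeakSet | None = None,
    max_tries: int = 1000,
    name: str = "background",
) -> PeakSet:
    """Matched random background: same size and length multiset as ``template``.

    Every output interval lies wholly within one allowed region, avoids all
    ``exclude`` intervals (default: the template itself) and every other
    output interval.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    excl = template if exclude is None else exclude
    placed = place_random_intervals(
        template.lengths(), allowed, rng, exclude=list(excl), max_tries=max_tries
    )
    return PeakSet(name, placed)
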