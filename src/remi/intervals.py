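"""Genomic interval data model, BED I/O and the overlap engine.

Every downstream analysis in this package — seven-way mark-combination
classification, REMI signature scoring against a transcription-factor site
catalogue, fold-change binning, multi-sample presence/absence selection —
reduces to questions about interval overlap, so this module is the single
place those semantics are defined:

* Coordinates are 0-based half-open, the BED convention. Touching
  intervals (``end == start``) do **not** overlap.
* The default overlap criterion everywhere is >= 1 bp; operations that
  accept ``min_overlap_bp`` let callers demand more.
* Strand is ignored throughout: histone-mark peaks are unstranded.
* Chromosome names are matched as exact strings; no ``chr`` prefix
  normalisation is attempted (explicit beats silent renaming).

The engine is vectorised numpy: each :class:`PeakSet` keeps, per
chromosome, its start/end arrays sorted by start together with a running
maximum of ends, so "does this query interval overlap anything" is two
``searchsorted`` calls. Pair enumeration (:func:`intersect`) walks the
query set and slices candidates from the sorted target arrays; it is
worst-case quadratic but linear-ish on real peak data, and is validated
against a brute-force all-pairs oracle in the test suite.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

#: Histone marks / chromatin factors a PeakSet may be labelled with.
VALID_MARKS = ("EZH2", "H3K4me3", "H3K27me3", "H3K27ac")


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an id and optional signal.

    Parameters
    ----------
    chrom
        Chromosome name, matched as an exact string.
    start, end
        0-based half-open coordinates in bp; ``end > start >= 0``
        (empty intervals are rejected).
    id
        Stable identifier, unique within a :class:`PeakSet`.
    intensity
        Non-negative peak signal in arbitrary enrichment units, or
        ``None`` when the source file carried no signal column.
    """

    chrom: str
    start: int
    end: int
    id: str
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"negative intensity for interval {self.id!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap length in bp with ``other`` (0 if disjoint or trans-chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class _ChromArrays(NamedTuple):
    """Per-chromosome numpy view of a PeakSet, sorted by start."""

    lo: int  # offset of this chromosome's block in the interval tuple
    starts: np.ndarray
    ends: np.ndarray
    end_cummax: np.ndarray
    ids: tuple


class PeakSet:
    """An immutable, sorted collection of peaks from one source.

    Intervals are stored sorted by ``(chrom, start, end)``. Duplicate
    coordinates (identical chrom/start/end) and duplicate ids are
    rejected — one peak caller emits one call per locus.

    Attributes
    ----------
    name
        Free-text label, e.g. ``"N1_H3K4me3_d0"``.
    mark
        One of :data:`VALID_MARKS`, or ``None`` for mark-agnostic sets
        (consensus universes, CpG islands, ...).
    sample
        Patient / sample label, or ``None``.
    timepoint_days
        Non-negative days on treatment, or ``None``.
    sources
        For sets produced by :func:`merge_union`: mapping from merged
        interval id to the tuple of ``(source set name, interval id)``
        pairs it absorbed. ``None`` otherwise.
    """

    __slots__ = (
        "name",
        "mark",
        "sample",
        "timepoint_days",
        "intervals",
        "sources",
        "_idx",
    )

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        name: str = "",
        mark: str | None = None,
        sample: str | None = None,
        timepoint_days: int | None = None,
        sources: Mapping[str, tuple] | None = None,
    ) -> None:
        if mark is not None and mark not in VALID_MARKS:
            raise ValueError(f"unknown mark {mark!r}; expected one of {VALID_MARKS}")
        if timepoint_days is not None and timepoint_days < 0:
            raise ValueError("timepoint_days must be non-negative")
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id))
        for prev, cur in zip(ivs, ivs[1:]):
            if (prev.chrom, prev.start, prev.end) == (cur.chrom, cur.start, cur.end):
                raise ValueError(
                    f"duplicated interval {cur.chrom}:{cur.start}-{cur.end} "
                    f"({prev.id!r}, {cur.id!r})"
                )
        seen: set[str] = set()
        for iv in ivs:
            if iv.id in seen:
                raise ValueError(f"duplicate interval id {iv.id!r}")
            seen.add(iv.id)
        self.name = name
        self.mark = mark
        self.sample = sample
        self.timepoint_days = timepoint_days
        self.intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.sources = dict(sources) if sources is not None else None
        self._idx: dict[str, _ChromArrays] | None = None

    @classmethod
    def _from_sorted(
        cls,
        intervals: tuple,
        name: str = "",
        mark: str | None = None,
        sample: str | None = None,
        timepoint_days: int | None = None,
        sources: Mapping[str, tuple] | None = None,
    ) -> "PeakSet":
        """Internal fast path: caller guarantees sorted, validated input."""
        ps = cls.__new__(cls)
        ps.name = name
        ps.mark = mark
        ps.sample = sample
        ps.timepoint_days = timepoint_days
        ps.intervals = intervals
        ps.sources = dict(sources) if sources is not None else None
        ps._idx = None
        return ps

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        bits = [f"{len(self)} intervals"]
        if self.name:
            bits.append(f"name={self.name!r}")
        if self.mark:
            bits.append(f"mark={self.mark}")
        return f"PeakSet({', '.join(bits)})"

    def ids(self) -> tuple[str, ...]:
        """Interval ids in sorted (chrom, start) order."""
        return tuple(iv.id for iv in self.intervals)

    def subset(self, ids: Iterable[str], name: str | None = None) -> "PeakSet":
        """A new PeakSet restricted to ``ids`` (all must be present)."""
        wanted = set(ids)
        kept = [iv for iv in self.intervals if iv.id in wanted]
        missing = wanted - {iv.id for iv in kept}
        if missing:
            raise KeyError(f"ids not in PeakSet: {sorted(missing)[:5]}...")
        return PeakSet._from_sorted(
            tuple(kept),
            name=name if name is not None else f"{self.name}_subset",
            mark=self.mark,
            sample=self.sample,
            timepoint_days=self.timepoint_days,
        )

    # -- numpy index ---------------------------------------------------------

    def _index(self) -> dict[str, _ChromArrays]:
        if self._idx is None:
            idx: dict[str, _ChromArrays] = {}
            lo = 0
            n = len(self.intervals)
            while lo < n:
                chrom = self.intervals[lo].chrom
                hi = lo
                while hi < n and self.intervals[hi].chrom == chrom:
                    hi += 1
                block = self.intervals[lo:hi]
                starts = np.fromiter((iv.start for iv in block), dtype=np.int64)
                ends = np.fromiter((iv.end for iv in block), dtype=np.int64)
                idx[chrom] = _ChromArrays(
                    lo=lo,
                    starts=starts,
                    ends=ends,
                    end_cummax=np.maximum.accumulate(ends),
                    ids=tuple(iv.id for iv in block),
                )
                lo = hi
            self._idx = idx
        return self._idx


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------


def _exists_overlap(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_end_cummax: np.ndarray,
) -> np.ndarray:
    """Boolean per query: does it overlap (>=1 bp) any target interval?

    Targets must be sorted by start with ``t_end_cummax`` the running max
    of their ends; correctness with nested intervals follows because any
    overlapping target has ``start < q_end`` and contributes its end to
    the prefix maximum.
    """
    hi = np.searchsorted(t_starts, q_ends, side="left")
    out = np.zeros(len(q_starts), dtype=bool)
    nz = hi > 0
    out[nz] = t_end_cummax[hi[nz] - 1] > q_starts[nz]
    return out


def overlaps_any(a: PeakSet, b: PeakSet) -> np.ndarray:
    """Membership flag per ``a``-interval: overlaps >= 1 bp of ``b``.

    Returns a boolean array aligned with ``a.intervals`` / ``a.ids()``.
    """
    flags = np.zeros(len(a), dtype=bool)
    b_idx = b._index()
    for chrom, arrs in a._index().items():
        tb = b_idx.get(chrom)
        if tb is None:
            continue
        flags[arrs.lo : arrs.lo + len(arrs.starts)] = _exists_overlap(
            arrs.starts, arrs.ends, tb.starts, tb.end_cummax
        )
    return flags


def intersect(
    a: PeakSet, b: PeakSet, min_overlap_bp: int = 1
) -> list[tuple[str, str]]:
    """All ``(a_id, b_id)`` pairs whose overlap length is >= ``min_overlap_bp``.

    The pair list is ordered by ``a``'s sorted order, then ``b``'s, and
    contains no duplicates; ``intersect(a, b)`` and ``intersect(b, a)``
    are transposes of each other.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pairs: list[tuple[str, str]] = []
    b_idx = b._index()
    for chrom, arrs in a._index().items():
        tb = b_idx.get(chrom)
        if tb is None:
            continue
        # candidate b's satisfy b.start <= a.end - min_overlap
        hi = np.searchsorted(tb.starts, arrs.ends - (min_overlap_bp - 1), side="left")
        for i in range(len(arrs.starts)):
            h = hi[i]
            if h == 0:
                continue
            ov = np.minimum(tb.ends[:h], arrs.ends[i]) - np.maximum(
                tb.starts[:h], arrs.starts[i]
            )
            for j in np.nonzero(ov >= min_overlap_bp)[0]:
                pairs.append((arrs.ids[i], tb.ids[j]))
    return pairs


def merge_union(sets: Sequence[PeakSet], name: str = "union") -> PeakSet:
    """Union of peak sets with overlapping or book-ended intervals merged.

    Returns maximal merged intervals with fresh ids ``u000001, ...`` in
    (chrom, start) order; each merged interval records the contributing
    ``(source set name, interval id)`` pairs in ``result.sources``.
    Book-ended intervals (``end == next.start``) are fused: the consensus
    universe is about contiguous covered territory, even though touching
    intervals do not *overlap* under the >=1 bp criterion.
    """
    if not sets:
        raise ValueError("merge_union needs at least one PeakSet")
    rows: list[tuple[str, int, int, str, str]] = []
    for k, ps in enumerate(sets):
        label = ps.name or f"set{k}"
        for iv in ps.intervals:
            rows.append((iv.chrom, iv.start, iv.end, label, iv.id))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    merged: list[GenomicInterval] = []
    sources: dict[str, tuple] = {}
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_src: list[tuple[str, str]] = []

    def _flush() -> None:
        if cur_chrom is None:
            return
        mid = f"u{len(merged) + 1:06d}"
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end, mid))
        sources[mid] = tuple(cur_src)

    for chrom, start, end, label, ivid in rows:
        if chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
            cur_src.append((label, ivid))
        else:
            _flush()
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_src = [(label, ivid)]
    _flush()
    return PeakSet(merged, name=name, sources=sources)


# ---------------------------------------------------------------------------
# BED I/O (gzip-transparent)
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(
    path,
    dialect: str = "auto",
    name: str = "",
    mark: str | None = None,
    sample: str | None = None,
    timepoint_days: int | None = None,
) -> PeakSet:
    """Read a BED file into a :class:`PeakSet`.

    Dialects: ``bed3`` (coordinates only; ids are synthesised as
    ``iv000001, ...`` in file order), ``bed4`` (column 4 is the id) and
    ``bed6`` (column 5 is the peak intensity; strand is read and
    discarded). ``auto`` picks by column count — 5 or more columns are
    treated as carrying an intensity. A missing intensity column yields
    ``intensity=None``, not zero.
    """
    if dialect not in ("auto", "bed3", "bed4", "bed6"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    intervals: list[GenomicInterval] = []
    count = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            ncol = len(fields)
            eff = dialect
            if eff == "auto":
                eff = "bed3" if ncol == 3 else ("bed4" if ncol == 4 else "bed6")
            need = {"bed3": 3, "bed4": 4, "bed6": 5}[eff]
            if ncol < need:
                raise BedParseError(
                    f"{path}, line {lineno}: expected >= {need} columns, got {ncol}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise BedParseError(
                    f"{path}, line {lineno}: end <= start ({start}, {end})"
                )
            count += 1
            ivid = fields[3] if eff in ("bed4", "bed6") else f"iv{count:06d}"
            intensity = None
            if eff == "bed6":
                try:
                    intensity = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}, line {lineno}: non-numeric intensity {fields[4]!r}"
                    ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, ivid, intensity))
            except ValueError as exc:
                raise BedParseError(f"{path}, line {lineno}: {exc}") from exc
    return PeakSet(
        intervals,
        name=name or str(path),
        mark=mark,
        sample=sample,
        timepoint_days=timepoint_days,
    )


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED4, or BED6 if any interval has an intensity.

    Coordinates and ids round-trip bit-exactly through :func:`read_bed`.
    """
    with_intensity = any(iv.intensity is not None for iv in peaks)
    with _open_text(path, "wt") as fh:
        for iv in peaks:
            if with_intensity:
                score = "0" if iv.intensity is None else f"{iv.intensity:.6g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
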