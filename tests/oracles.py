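"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive — O(n*m) all-pairs scans and
boolean coverage arrays — and shares no code with the package's
searchsorted/prefix-max engine.
"""

from __future__ import annotations

import numpy as np

from remi import GenomicInterval, PeakSet


def brute_pairs(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> set:
    """All-pairs overlap enumeration."""
    out = set()
    for iva in a:
        for ivb in b:
            if iva.overlap_bp(ivb) >= min_overlap_bp:
                out.add((iva.id, ivb.id))
    return out


def brute_flags(a: PeakSet, b: PeakSet) -> list[bool]:
    """Per-a-interval membership by exhaustive scan."""
    return [any(iva.overlap_bp(ivb) >= 1 for ivb in b) for iva in a]


def coverage_merge(sets, max_coord: int) -> list[tuple[str, int, int]]:
    """Merged intervals via a boolean coverage array sweep per chromosome.

    Book-ended intervals produce contiguous covered runs, matching the
    union semantics of ``merge_union``.
    """
    chroms = sorted({iv.chrom for ps in sets for iv in ps})
    merged = []
    for chrom in chroms:
        cov = np.zeros(max_coord + 1, dtype=bool)
        for ps in sets:
            for iv in ps:
                if iv.chrom == chrom:
                    cov[iv.start : iv.end] = True
        diff = np.diff(cov.astype(np.int8))
        starts = np.nonzero(diff == 1)[0] + 1
        ends = np.nonzero(diff == -1)[0] + 1
        if cov[0]:
            starts = np.concatenate(([0], starts))
        if cov[-1]:
            ends = np.concatenate((ends, [len(cov)]))
        merged.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return merged


def brute_nearest(peaks: PeakSet, tss_frame) -> list[str | None]:
    """All-pairs nearest-TSS assignment with the package's tie rule."""
    out = []
    for iv in peaks:
        best: tuple[int, str] | None = None
        for row in tss_frame.itertuples():
            if row.chrom != iv.chrom:
                continue
            if iv.start <= row.pos < iv.end:
                d = 0
            elif row.pos < iv.start:
                d = iv.start - row.pos
            else:
                d = row.pos - (iv.end - 1)
            cand = (d, row.gene_id)
            if best is None or cand < best:
                best = cand
        out.append(best[1] if best is not None else None)
    return out


def random_peakset(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_start: int = 9_000,
    max_width: int = 500,
    name: str = "random",
    with_intensity: bool = False,
) -> PeakSet:
    """A random peak set with unique coordinates (duplicates re-drawn)."""
    seen = set()
    ivs = []
    while len(ivs) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_start))
        width = int(rng.integers(1, max_width + 1))
        key = (chrom, start, start + width)
        if key in seen:
            continue
        seen.add(key)
        intensity = float(rng.uniform(1, 100)) if with_intensity else None
        ivs.append(
            GenomicInterval(chrom, start, start + width, f"{name}{len(ivs):05d}",
                            intensity)
        )
    return PeakSet(ivs, name=name)
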