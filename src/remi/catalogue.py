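"""Transcription-factor site catalogue (ReMap-style merged ChIP-seq sites).

A flat collection of ``(factor name, interval)`` entries, the natural
export of a merged TF ChIP-seq catalogue as BED4 with the factor name in
the name column. The catalogue is queried one way only: "does this peak
contain >= 1 validated site of factor F" — so it keeps, per factor and
chromosome, start-sorted site arrays with a running end maximum for
vectorised existence queries.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .intervals import GenomicInterval, _open_text


class TFCatalogue:
    """Factor-labelled genomic sites with per-factor overlap indices."""

    def __init__(self, entries: Iterable[tuple[str, GenomicInterval]]) -> None:
        self.entries: tuple[tuple[str, GenomicInterval], ...] = tuple(entries)
        self.factors: frozenset[str] = frozenset(f for f, _ in self.entries)
        self._index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, GenomicInterval]]:
        return iter(self.entries)

    def sites_for(self, factor: str) -> tuple[GenomicInterval, ...]:
        return tuple(iv for f, iv in self.entries if f == factor)

    def factor_index(
        self, factor: str
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts sorted, running max of ends) for one factor."""
        if self._index is None:
            idx: dict[str, dict[str, list[tuple[int, int]]]] = {}
            for f, iv in self.entries:
                idx.setdefault(f, {}).setdefault(iv.chrom, []).append(
                    (iv.start, iv.end)
                )
            built: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
            for f, chroms in idx.items():
                built[f] = {}
                for chrom, se in chroms.items():
                    se.sort()
                    starts = np.fromiter((s for s, _ in se), dtype=np.int64)
                    ends = np.fromiter((e for _, e in se), dtype=np.int64)
                    built[f][chrom] = (starts, np.maximum.accumulate(ends))
            self._index = built
        if factor not in self.factors:
            raise KeyError(f"factor {factor!r} not in catalogue")
        return self._index.get(factor, {})

    @classmethod
    def from_bed(cls, path) -> "TFCatalogue":
        """Read BED4 where the name column is the factor name."""
        entries = []
        count = 0
        with _open_text(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}, line {lineno}: catalogue needs 4 BED columns"
                    )
                count += 1
                entries.append(
                    (
                        fields[3],
                        GenomicInterval(
                            fields[0],
                            int(fields[1]),
                            int(fields[2]),
                            f"site{count:07d}",
                        ),
                    )
                )
        return cls(entries)

    def to_bed(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for factor, iv in self.entries:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{factor}\n")
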