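"""Seven-way mark-combination classification of cis-regulatory elements.

A cis-regulatory element that is positive for at least one of EZH2,
H3K4me3 or H3K27me3 falls into exactly one of the seven non-empty
combinations of the three marks. Codes 3, 4 and 7 (EZH2+H3K4me3,
EZH2-only, H3K4me3-only) and the pairing of codes 1 and 2 with the
EZH2+H3K27me3 combinations are fixed by the published numbering; codes
1/2/5/6 are pinned here as 1 = triple-positive, 2 = EZH2+H3K27me3,
5 = H3K4me3+H3K27me3 (bivalent, EZH2-negative), 6 = H3K27me3-only.
The mapping is a module constant and can be overridden per call.

Membership is binary peak overlap (>= 1 bp) of each element of the
consensus universe against each mark's own peak calls — no signal
cutoff. The module also annotates promoter status (TSS +/- window),
nearest gene, bivalency and CpG-island overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, merge_union, overlaps_any, _open_text

#: The three marks whose combinations define the subgroups.
MARK_TRIO = ("EZH2", "H3K4me3", "H3K27me3")

#: Default combination -> subgroup code mapping (codes 3, 4, 7 and the
#: {1,2} pair are anchored by the published numbering; 1/2/5/6 pinned here).
DEFAULT_SUBGROUP_CODES: Mapping[frozenset, int] = {
    frozenset({"EZH2", "H3K4me3", "H3K27me3"}): 1,
    frozenset({"EZH2", "H3K27me3"}): 2,
    frozenset({"EZH2", "H3K4me3"}): 3,
    frozenset({"EZH2"}): 4,
    frozenset({"H3K4me3", "H3K27me3"}): 5,
    frozenset({"H3K27me3"}): 6,
    frozenset({"H3K4me3"}): 7,
}

#: Inverse mapping, code -> mark combination.
CODE_TO_COMBINATION: Mapping[int, frozenset] = {
    v: k for k, v in DEFAULT_SUBGROUP_CODES.items()
}

_BIVALENT = frozenset({"H3K4me3", "H3K27me3"})


@dataclass(frozen=True)
class SubgroupLabel:
    """One of the seven mark-combination subgroups."""

    code: int
    combination: frozenset

    @property
    def is_bivalent(self) -> bool:
        """Carries both the active (H3K4me3) and silent (H3K27me3) mark."""
        return _BIVALENT <= self.combination


@dataclass
class MarkProfile:
    """A sample x timepoint bundle of peak sets keyed by mark."""

    sample: str
    timepoint_days: int
    peaks_by_mark: Mapping[str, PeakSet]

    def __post_init__(self) -> None:
        if not any(m in self.peaks_by_mark for m in MARK_TRIO):
            raise ValueError(
                f"MarkProfile needs at least one of {MARK_TRIO}; "
                f"got {sorted(self.peaks_by_mark)}"
            )


def build_universe(profile: MarkProfile) -> PeakSet:
    """Consensus element universe: merged union over all marks' peaks."""
    return merge_union(
        [profile.peaks_by_mark[m] for m in sorted(profile.peaks_by_mark)],
        name=f"{profile.sample}_d{profile.timepoint_days}_universe",
    )


def classify_subgroups(
    profile: MarkProfile,
    universe: PeakSet | None = None,
    code_map: Mapping[frozenset, int] = DEFAULT_SUBGROUP_CODES,
) -> tuple[dict[str, SubgroupLabel], dict[int, int]]:
    """Assign every universe element one of the seven subgroup labels.

    Returns ``(labels, counts)`` where ``labels`` maps element id ->
    :class:`SubgroupLabel` and ``counts`` maps each code 1..7 to the
    number of elements carrying it (zeros included). Counts always sum
    to the universe size: the seven labels partition the universe.
    """
    if universe is None:
        universe = build_universe(profile)
    member: dict[str, np.ndarray] = {}
    for mark in MARK_TRIO:
        if mark in profile.peaks_by_mark:
            member[mark] = overlaps_any(universe, profile.peaks_by_mark[mark])
    labels: dict[str, SubgroupLabel] = {}
    counts: dict[int, int] = {code: 0 for code in sorted(code_map.values())}
    ids = universe.ids()
    for i, ivid in enumerate(ids):
        combo = frozenset(m for m, flags in member.items() if flags[i])
        if not combo:
            raise RuntimeError(
                f"element {ivid} overlaps no mark: universe is not the "
                "union of the profile's peak sets"
            )
        code = code_map[combo]
        labels[ivid] = SubgroupLabel(code=code, combination=combo)
        counts[code] += 1
    return labels, counts


def compare_subgroup_counts(
    before: Mapping[int, int], after: Mapping[int, int]
) -> dict[int, float | None]:
    """Percent change per code: ``100 * (after - before) / before``.

    A code with ``before == 0`` maps to ``None`` (undefined), never a
    division error.
    """
    out: dict[int, float | None] = {}
    for code in sorted(set(before) | set(after)):
        b = before.get(code, 0)
        a = after.get(code, 0)
        out[code] = None if b == 0 else 100.0 * (a - b) / b
    return out


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------


@dataclass
class TssTable:
    """Gene TSS positions: a frame with columns gene_id, chrom, pos (0-based)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"gene_id", "chrom", "pos"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"TssTable frame missing columns {sorted(missing)}")
        if len(self.frame) == 0:
            raise ValueError("TSS table is empty")

    def __len__(self) -> int:
        return len(self.frame)

    def _by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, grp in self.frame.groupby("chrom", sort=True):
            grp = grp.sort_values(["pos", "gene_id"])
            out[chrom] = (
                grp["pos"].to_numpy(dtype=np.int64),
                grp["gene_id"].to_numpy(dtype=object),
            )
        return out

    @classmethod
    def from_bed(cls, path) -> "TssTable":
        """BED4 where the name column is the gene id; TSS = interval start."""
        rows = []
        with _open_text(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}, line {lineno}: need 4 BED columns")
                rows.append((fields[3], fields[0], int(fields[1])))
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "pos"]))

    @classmethod
    def from_gff(cls, path) -> "TssTable":
        """GFF3-like input, gene features only; TSS = feature start (strand ignored)."""
        rows = []
        with _open_text(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9 or fields[2].lower() != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if gene is None:
                    continue
                rows.append((gene, fields[0], int(fields[3]) - 1))  # GFF is 1-based
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "pos"]))


def read_tss(path) -> TssTable:
    """Sniff BED4 vs GFF-like gene annotation and parse accordingly."""
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##gff"):
                return TssTable.from_gff(path)
            if line.startswith(("#", "track", "browser")):
                continue
            ncol = len(line.split("\t") if "\t" in line else line.split())
            return TssTable.from_gff(path) if ncol >= 9 else TssTable.from_bed(path)
    raise ValueError(f"{path}: empty annotation file")


def annotate_promoters(
    universe: PeakSet, tss: TssTable, window_bp: int = 2000
) -> tuple[np.ndarray, list[str | None]]:
    """Promoter flags and nearest gene per universe element.

    An element is a promoter element iff it overlaps the window
    ``[tss - window_bp, tss + window_bp)`` of some TSS; with
    ``window_bp=0`` only elements covering the TSS base itself qualify.
    The nearest gene minimises the bp distance from the element to the
    TSS (0 if the TSS falls inside the element); ties break to the
    lexicographically smaller gene id. Elements on chromosomes absent
    from the TSS table get ``nearest_gene=None``.

    Returns ``(is_promoter, nearest_gene)`` aligned with ``universe``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom = tss._by_chrom()
    n = len(universe)
    is_promoter = np.zeros(n, dtype=bool)
    nearest: list[str | None] = [None] * n
    for i, iv in enumerate(universe):
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            continue
        pos, genes = entry
        # promoter window test
        if window_bp > 0:
            lo = int(np.searchsorted(pos, iv.start - window_bp, side="right"))
            hi = int(np.searchsorted(pos, iv.end + window_bp, side="left"))
        else:
            lo = int(np.searchsorted(pos, iv.start, side="left"))
            hi = int(np.searchsorted(pos, iv.end, side="left"))
        is_promoter[i] = hi > lo
        # nearest gene: TSS inside the element => distance 0
        in_lo = int(np.searchsorted(pos, iv.start, side="left"))
        in_hi = int(np.searchsorted(pos, iv.end, side="left"))
        if in_hi > in_lo:
            nearest[i] = min(genes[in_lo:in_hi])
            continue
        cands: list[tuple[int, str]] = []
        if in_lo > 0:
            cands.append((iv.start - int(pos[in_lo - 1]), genes[in_lo - 1]))
        if in_hi < len(pos):
            cands.append((int(pos[in_hi]) - (iv.end - 1), genes[in_hi]))
        d_min = min(d for d, _ in cands)
        nearest[i] = min(g for d, g in cands if d == d_min)
    return is_promoter, nearest


def annotate_cpg(universe: PeakSet, cpg: PeakSet) -> np.ndarray:
    """CpG-island flag per universe element (>= 1 bp overlap)."""
    if len(cpg) == 0:
        return np.zeros(len(universe), dtype=bool)
    return overlaps_any(universe, cpg)


@dataclass(frozen=True)
class AnnotatedElement:
    """A universe element with its subgroup and annotations."""

    interval: GenomicInterval
    subgroup: SubgroupLabel
    is_promoter: bool
    is_bivalent: bool
    is_cpg: bool
    nearest_gene: str | None


def annotate_elements(
    profile: MarkProfile,
    tss: TssTable,
    cpg: PeakSet | None = None,
    window_bp: int = 2000,
    code_map: Mapping[frozenset, int] = DEFAULT_SUBGROUP_CODES,
) -> pd.DataFrame:
    """One-stop classification + annotation of a profile's element universe.

    Returns a frame with one row per universe element: element_id, chrom,
    start, end, subgroup, combination, is_promoter, is_bivalent, is_cpg,
    nearest_gene.
    """
    universe = build_universe(profile)
    labels, _ = classify_subgroups(profile, universe, code_map=code_map)
    is_prom, nearest = annotate_promoters(universe, tss, window_bp=window_bp)
    if cpg is not None:
        is_cpg = annotate_cpg(universe, cpg)
    else:
        is_cpg = np.zeros(len(universe), dtype=bool)
    rows = []
    for i, iv in enumerate(universe):
        lab = labels[iv.id]
        rows.append(
            {
                "element_id": iv.id,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "subgroup": lab.code,
                "combination": "+".join(sorted(lab.combination)),
                "is_promoter": bool(is_prom[i]),
                "is_bivalent": lab.is_bivalent,
                "is_cpg": bool(is_cpg[i]),
                "nearest_gene": nearest[i],
            }
        )
    return pd.DataFrame(rows)
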