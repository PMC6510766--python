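"""Multi-sample presence/absence peak selection and gene-list emission.

Implements "found in all of these samples but in none of those" queries
over a consensus universe — e.g. peaks present in both relapsed/
refractory samples and absent from all treatment-naive ones — plus the
nearest-gene list for a selected peak set. "Found in" is binary overlap
(>= 1 bp) against each sample's own peak calls; an optional intensity
floor can tighten "present" to "present and not merely residual".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import TssTable, annotate_promoters
from .intervals import PeakSet, overlaps_any


@dataclass
class SampleGroupQuery:
    """Presence/absence query: required samples and forbidden samples."""

    require_all: tuple[PeakSet, ...] = field(default_factory=tuple)
    forbid_any: tuple[PeakSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.require_all = tuple(self.require_all)
        self.forbid_any = tuple(self.forbid_any)
        if not self.require_all and not self.forbid_any:
            raise ValueError("query needs at least one required or forbidden sample")
        req = {ps.sample or ps.name for ps in self.require_all}
        forb = {ps.sample or ps.name for ps in self.forbid_any}
        clash = req & forb
        if clash:
            raise ValueError(f"samples both required and forbidden: {sorted(clash)}")


def select_specific_peaks(
    query: SampleGroupQuery,
    universe: PeakSet,
    min_intensity: float | None = None,
) -> PeakSet:
    """Universe elements present in every required and no forbidden sample.

    ``universe`` should be the merged union of all samples in the query.
    With ``min_intensity`` set, a sample peak only counts as "present"
    if its intensity is >= the floor — presence/absence alone can
    understate differences when a mark is low but not absent.
    """

    def _maybe_floor(ps: PeakSet) -> PeakSet:
        if min_intensity is None:
            return ps
        kept = [
            iv
            for iv in ps
            if iv.intensity is not None and iv.intensity >= min_intensity
        ]
        return PeakSet(kept, name=ps.name, mark=ps.mark, sample=ps.sample,
                       timepoint_days=ps.timepoint_days)

    keep = np.ones(len(universe), dtype=bool)
    for ps in query.require_all:
        keep &= overlaps_any(universe, _maybe_floor(ps))
    for ps in query.forbid_any:
        keep &= ~overlaps_any(universe, _maybe_floor(ps))
    ids = [iv.id for iv, k in zip(universe, keep) if k]
    return universe.subset(ids, name="specific_peaks") if ids else PeakSet(
        [], name="specific_peaks"
    )


def genes_for_peaks(peaks: PeakSet, tss: TssTable) -> list[str]:
    """Deduplicated, sorted list of nearest genes for a peak set.

    Nearest-gene rules (distance 0 when the TSS falls inside the peak;
    ties to the lexicographically smaller id) match promoter
    annotation. Peaks on chromosomes absent from the TSS table are
    skipped.
    """
    if len(peaks) == 0:
        return []
    _, nearest = annotate_promoters(peaks, tss)
    return sorted({g for g in nearest if g is not None})
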