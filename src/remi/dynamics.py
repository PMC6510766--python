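"""Longitudinal peak-intensity dynamics: rank, split at FC=1.5, bin, score.

The procedure mirrors the ratio-rank-bin analysis of H3K4me3 intensity
under treatment: per-element fold change between two timepoints on a
common consensus universe, a total ranking from most increased to most
decreased, a three-way split at FC = 1.5 (increased: FC >= 1.5;
decreased: FC <= 1/1.5; stable: the rest — both boundaries closed), the
ranked order cut into consecutive 1000-peak bins, and each bin's REMI
composition scored against the all-peaks composition, aggregated over
named factor groups by unweighted mean.

Cross-timepoint normalisation is a pluggable pre-step; the default
scales the later timepoint's total signal to the earlier one's
(global H3K4me3 levels are treated as stable, so only relative
redistribution is of interest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import TFCatalogue
from .intervals import PeakSet
from .scoring import build_signature, score_vs_reference


@dataclass(frozen=True)
class FactorGroup:
    """A named set of transcription factors scored jointly."""

    name: str
    factors: frozenset

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError(f"factor group {self.name!r} is empty")


#: The four co-ordinately behaving factor groups: A = polycomb-linked
#: (enriched where H3K4me3 decreases), B = B-cell lineage factors
#: (enriched where it increases), C = promoter-machinery-linked factors,
#: D = SMAD2-4 (evenly distributed / treatment-insensitive).
DEFAULT_FACTOR_GROUPS: tuple[FactorGroup, ...] = (
    FactorGroup("A", frozenset({"EZH2", "SUZ12", "CtBP2"})),
    FactorGroup("B", frozenset({"BCL11A", "IKZF1", "BATF", "SMAD1"})),
    FactorGroup("C", frozenset({"KDM5A", "IRF3", "GATAD1", "SNAPC1"})),
    FactorGroup("D", frozenset({"SMAD2", "SMAD3", "SMAD4"})),
)


@dataclass
class FoldChangeTable:
    """Per-element intensity ratios between two timepoints, ranked.

    ``fc`` is a Series indexed by element id, sorted largest-to-smallest
    (ties broken by id, so the ranking is total); ``excluded`` lists the
    universe elements dropped for missing either timepoint or a
    non-positive denominator.
    """

    universe: PeakSet
    t1: int
    t2: int
    fc: pd.Series
    intensity_t1: pd.Series
    intensity_t2: pd.Series
    excluded: tuple[str, ...]

    def ranked_ids(self) -> tuple[str, ...]:
        return tuple(self.fc.index)


@dataclass
class FCSplit:
    """Three-way partition of the fc-defined elements at a threshold."""

    increased: tuple[str, ...]
    decreased: tuple[str, ...]
    stable: tuple[str, ...]
    threshold: float


@dataclass(frozen=True)
class Bin:
    """One consecutive slice of the ranked order (1-based index)."""

    index: int
    ids: tuple[str, ...]
    partial: bool


@dataclass
class BinSeries:
    """Per-bin, per-group mean scores over the ranked bins.

    ``scores`` is a frame indexed by bin index with one column per
    factor group.
    """

    scores: pd.DataFrame
    bins: tuple[Bin, ...]


def read_intensities(path) -> pd.DataFrame:
    """TSV with columns element_id, timepoint_days, intensity (+ optional sample)."""
    frame = pd.read_csv(path, sep="\t")
    need = {"element_id", "timepoint_days", "intensity"}
    missing = need - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def compute_fold_changes(
    universe: PeakSet,
    intensities: pd.DataFrame,
    t1: int,
    t2: int,
    normalize: str | None = "total",
) -> FoldChangeTable:
    """FC = intensity(t2) / intensity(t1) per universe element, ranked.

    ``intensities`` must carry element_id, timepoint_days, intensity for
    a single sample. Elements missing either timepoint, outside the
    universe, or with non-positive t1 intensity are excluded and
    reported in ``excluded``. ``normalize="total"`` rescales t2 so both
    timepoints have equal total signal over the shared elements;
    ``normalize=None`` uses raw values.
    """
    if normalize not in (None, "total"):
        raise ValueError(f"unknown normalisation {normalize!r}")
    ids = set(universe.ids())
    sub = intensities[intensities["timepoint_days"].isin([t1, t2])]
    wide = sub.pivot_table(
        index="element_id", columns="timepoint_days", values="intensity"
    )
    for t in (t1, t2):
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide.loc[[i for i in wide.index if i in ids]]
    ok = wide[t1].notna() & wide[t2].notna() & (wide[t1] > 0)
    excluded = tuple(sorted(set(universe.ids()) - set(wide.index[ok])))
    wide = wide[ok]
    if len(wide) == 0:
        raise ValueError(f"no element has intensities at both {t1} and {t2} days")
    i1 = wide[t1].astype(float)
    i2 = wide[t2].astype(float)
    if normalize == "total":
        i2 = i2 * (i1.sum() / i2.sum())
    fc = (i2 / i1).rename("fc")
    order = sorted(fc.index, key=lambda e: (-fc[e], e))
    fc = fc.loc[order]
    return FoldChangeTable(
        universe=universe,
        t1=t1,
        t2=t2,
        fc=fc,
        intensity_t1=i1.loc[order],
        intensity_t2=i2.loc[order],
        excluded=excluded,
    )


def split_by_fc(table: FoldChangeTable, threshold: float = 1.5) -> FCSplit:
    """Closed-boundary split: FC >= thr increased, FC <= 1/thr decreased."""
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    fc = table.fc
    inc = tuple(fc.index[fc >= threshold])
    dec = tuple(fc.index[fc <= 1.0 / threshold])
    stab = tuple(fc.index[(fc > 1.0 / threshold) & (fc < threshold)])
    return FCSplit(increased=inc, decreased=dec, stable=stab, threshold=threshold)


def bin_ranked_peaks(table: FoldChangeTable, bin_size: int = 1000) -> list[Bin]:
    """Cut the ranked order into consecutive bins of ``bin_size`` ids.

    The final partial bin is retained and flagged (so plots can grey it
    out); concatenating all bins reproduces the ranked order exactly.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ranked = table.ranked_ids()
    bins = []
    for k, lo in enumerate(range(0, len(ranked), bin_size), start=1):
        ids = ranked[lo : lo + bin_size]
        bins.append(Bin(index=k, ids=ids, partial=len(ids) < bin_size))
    return bins


def group_score_series(
    bins: Sequence[Bin],
    universe: PeakSet,
    catalogue: TFCatalogue,
    groups: Sequence[FactorGroup] = DEFAULT_FACTOR_GROUPS,
    pseudocount: float = 0.5,
) -> BinSeries:
    """Score each bin's composition against the all-peaks composition.

    Per bin and factor group: build the bin's signature, score it
    against the signature of all binned peaks together, and average the
    group's factor scores (unweighted). A group factor absent from the
    catalogue is an error naming the factor.
    """
    for grp in groups:
        missing = grp.factors - catalogue.factors
        if missing:
            raise ValueError(
                f"factor(s) {sorted(missing)} of group {grp.name!r} "
                "missing from catalogue"
            )
    all_ids = [i for b in bins for i in b.ids]
    all_sig = build_signature(universe.subset(all_ids, name="all_binned"), catalogue)
    rows = {}
    for b in bins:
        sig = build_signature(
            universe.subset(b.ids, name=f"bin{b.index}"), catalogue
        )
        profile = score_vs_reference(sig, all_sig, pseudocount=pseudocount)
        rows[b.index] = {g.name: profile.group_mean(g.factors) for g in groups}
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "bin"
    return BinSeries(scores=frame, bins=tuple(bins))


def top_bottom_subsets(
    table: FoldChangeTable,
    split: FCSplit,
    stratum: str,
    promoter_ids: set[str],
) -> tuple[PeakSet, PeakSet]:
    """Top (most increased) and bottom (most decreased) peaks of a stratum.

    ``stratum`` is ``"promoter"`` or ``"non-promoter"``; membership is
    decided by ``promoter_ids``. Each side is returned as a PeakSet
    ready for :func:`remi.scoring.score_subset_vs_all`; either may be
    empty.
    """
    if stratum not in ("promoter", "non-promoter"):
        raise ValueError("stratum must be 'promoter' or 'non-promoter'")

    def _in_stratum(eid: str) -> bool:
        return (eid in promoter_ids) == (stratum == "promoter")

    top_ids = [e for e in split.increased if _in_stratum(e)]
    bot_ids = [e for e in split.decreased if _in_stratum(e)]
    mk = lambda ids, tag: PeakSet(
        [iv for iv in table.universe if iv.id in set(ids)],
        name=f"{tag}_{stratum}",
    )
    return mk(top_ids, "top"), mk(bot_ids, "bottom")


def plot_bin_series(series: BinSeries, path, title: str = "") -> None:
    """Line plot of per-bin group scores (bin 1 = most increased)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for col in series.scores.columns:
        ax.plot(series.scores.index, series.scores[col], marker="o", label=col)
    partial = [b.index for b in series.bins if b.partial]
    for x in partial:
        ax.axvspan(x - 0.5, x + 0.5, color="0.9", zorder=0)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("rank bin (1 = most increased)")
    ax.set_ylabel("group score (log2)")
    if title:
        ax.set_title(title)
    ax.legend(title="group", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
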