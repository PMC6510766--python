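"""Synthetic peak-call scenarios with planted ground truth.

Generates every input the pipeline consumes — per-sample/mark/timepoint
peak BEDs, a factor-labelled site catalogue, TSS and CpG annotation and
a per-timepoint intensity table — from a single seeded configuration, so
every downstream stage can be tested against known truth without any
download. Generation starts at the peak-call level: no reads, no signal
tracks.

Planted structure
-----------------
* Non-overlapping consensus *elements* are placed per chromosome with a
  minimum gap, widths log-normal (promoter elements wider than
  non-promoter ones, the usual H3K4me3 geometry).
* Each element draws a true subgroup from the seven-way mark-combination
  mixture; the marks of that combination each realise a peak over the
  element with a small independent boundary jitter (smaller than half
  the minimum gap, so elements never fuse).
* Each factor of the TF catalogue drops >= 0 sites into elements by a
  Bernoulli draw whose rate is the factor's background co-occurrence
  rate times the multipliers of every stratum the element belongs to
  (subgroup, bivalency, promoter status, fold-change class, RR-specific
  status, CpG status), optionally times a smooth rank gradient
  ``fc_gradient ** u`` where ``u`` is the element's descending planted
  fold-change percentile (u = 1 at the most decreased element).
* Each element draws a fold-change class (increased/decreased/stable)
  with a planted log2 effect; intensities per sample and timepoint are
  log-normal around a per-element baseline with the effect ramping
  linearly in time and i.i.d. noise on the log2 scale.
* A configurable fraction of elements is RR-specific: present only in
  relapsed/refractory samples, absent (all marks, all timepoints) from
  treatment-naive ones.

Determinism: one seed, one byte stream — regenerating a scenario with
the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import TFCatalogue
from .classify import CODE_TO_COMBINATION, MarkProfile, TssTable
from .intervals import GenomicInterval, PeakSet, overlaps_any, write_bed

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFSpec:
    """One catalogue factor: background rate plus planted enrichments.

    ``enrichments`` is a tuple of ``(stratum, multiplier)`` pairs;
    strata are ``"subgroup:<code>"``, ``"bivalent"``, ``"promoter"``,
    ``"non_promoter"``, ``"fc:<class>"``, ``"rr_specific"``, ``"cpg"``.
    ``fc_gradient`` > 1 plants a smooth enrichment gradient toward the
    most-decreased end of the planted fold-change ranking.
    """

    name: str
    background_rate: float
    enrichments: tuple[tuple[str, float], ...] = ()
    fc_gradient: float = 1.0


@dataclass(frozen=True)
class SampleSpec:
    """One patient sample: label, TN/RR status, assay timepoints (days)."""

    name: str
    status: str
    timepoints: tuple[int, ...]


@dataclass(frozen=True)
class FCClassSpec:
    """A fold-change class: mixture proportion and planted log2 effect."""

    name: str
    proportion: float
    log2_effect: float


@dataclass
class ScenarioConfig:
    """Full description of a synthetic scenario (see module docstring)."""

    genome: tuple[tuple[str, int], ...]
    n_elements: int
    n_genes: int
    samples: tuple[SampleSpec, ...]
    subgroup_mixture: Mapping[int, float]
    tf_catalogue: tuple[TFSpec, ...]
    fc_classes: tuple[FCClassSpec, ...]
    promoter_fraction: float = 0.5
    promoter_width_median: int = 1000
    nonpromoter_width_median: int = 600
    width_log_sd: float = 0.35
    min_width: int = 250
    max_width: int = 4000
    min_gap: int = 300
    jitter_bp: int = 40
    site_width: int = 15
    fc_effect_jitter_sd: float = 0.0
    intensity_log2_mean: float = 6.0
    intensity_log2_sd: float = 1.0
    intensity_noise_sd: float = 0.1
    rr_specific_fraction: float = 0.0
    cpg_rate_bivalent: float = 0.7
    cpg_rate_other: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        probs = np.array([self.subgroup_mixture.get(c, 0.0) for c in range(1, 8)])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("subgroup_mixture must sum to 1 over codes 1-7")
        if (probs < 0).any():
            raise ValueError("subgroup_mixture proportions must be >= 0")
        fc_p = np.array([c.proportion for c in self.fc_classes])
        if not np.isclose(fc_p.sum(), 1.0) or (fc_p < 0).any():
            raise ValueError("fc class proportions must be >= 0 and sum to 1")
        for tf in self.tf_catalogue:
            if not 0 <= tf.background_rate <= 1:
                raise ValueError(f"rate for {tf.name!r} outside [0, 1]")
            for stratum, mult in tf.enrichments:
                if mult <= 0:
                    raise ValueError(f"multiplier for {tf.name!r}/{stratum} <= 0")
            if tf.fc_gradient <= 0:
                raise ValueError(f"fc_gradient for {tf.name!r} <= 0")
        for s in self.samples:
            if s.status not in ("TN", "RR"):
                raise ValueError(f"sample {s.name!r} status must be TN or RR")
        if self.jitter_bp * 2 >= self.min_gap:
            raise ValueError("jitter must be < min_gap/2 so elements never fuse")
        if self.min_width <= 2 * self.jitter_bp + self.site_width:
            raise ValueError("min_width too small for jitter + site placement")


#: Factor groups A-D with their background co-occurrence rates; filler
#: factors pad the catalogue to 50, cycling through a few rates.
_NAMED_FACTORS = (
    "EZH2", "SUZ12", "CtBP2",            # group A
    "BCL11A", "IKZF1", "BATF", "SMAD1",  # group B
    "KDM5A", "IRF3", "GATAD1", "SNAPC1", # group C
    "SMAD2", "SMAD3", "SMAD4",           # group D
)
_FILLER_RATES = (0.05, 0.08, 0.1, 0.15, 0.2)


def standard_scenario(**overrides) -> ScenarioConfig:
    """The standard study-design scenario.

    Two 50 Mb chromosomes, 20,000 consensus elements, 1,000 genes, five
    samples (three treatment-naive, two relapsed/refractory) assayed
    before treatment, at 1 or 7 days, and at 56 days; a 50-factor
    catalogue containing the named groups A-D plus filler factors.
    Planted structure mirrors the analyses downstream: group A enriched
    in the decreased fold-change class and in bivalent elements, group B
    in the increased class, group C at promoters, group D flat; EZH2 and
    SUZ12 additionally enriched in the 4% RR-specific elements.
    """
    tf_specs = [
        TFSpec("EZH2", 0.1, (("fc:decreased", 2.5), ("bivalent", 3.0),
                             ("rr_specific", 4.0))),
        TFSpec("SUZ12", 0.1, (("fc:decreased", 2.5), ("bivalent", 3.0),
                              ("rr_specific", 4.0))),
        TFSpec("CtBP2", 0.1, (("fc:decreased", 2.5),)),
        TFSpec("BCL11A", 0.12, (("fc:increased", 2.5),)),
        TFSpec("IKZF1", 0.12, (("fc:increased", 2.5),)),
        TFSpec("BATF", 0.12, (("fc:increased", 2.5),)),
        TFSpec("SMAD1", 0.12, (("fc:increased", 2.5),)),
        TFSpec("KDM5A", 0.1, (("promoter", 2.0),)),
        TFSpec("IRF3", 0.1, (("promoter", 2.0),)),
        TFSpec("GATAD1", 0.1, (("promoter", 2.0),)),
        TFSpec("SNAPC1", 0.1, (("promoter", 2.0),)),
        TFSpec("SMAD2", 0.1),
        TFSpec("SMAD3", 0.1),
        TFSpec("SMAD4", 0.1),
    ]
    for k in range(len(tf_specs) + 1, 51):
        tf_specs.append(TFSpec(f"TF{k:02d}", _FILLER_RATES[k % len(_FILLER_RATES)]))
    cfg = ScenarioConfig(
        genome=(("chr1", 50_000_000), ("chr2", 50_000_000)),
        n_elements=20_000,
        n_genes=1_000,
        samples=(
            SampleSpec("N1", "TN", (0, 7, 56)),
            SampleSpec("N2", "TN", (0, 7, 56)),
            SampleSpec("N3", "TN", (0, 7, 56)),
            SampleSpec("R1", "RR", (0, 1, 56)),
            SampleSpec("R2", "RR", (0, 1, 56)),
        ),
        subgroup_mixture={1: 0.06, 2: 0.08, 3: 0.06, 4: 0.08,
                          5: 0.08, 6: 0.14, 7: 0.50},
        tf_catalogue=tuple(tf_specs),
        fc_classes=(
            FCClassSpec("increased", 0.15, 1.0),
            FCClassSpec("decreased", 0.15, -1.0),
            FCClassSpec("stable", 0.70, 0.0),
        ),
        rr_specific_fraction=0.04,
        seed=1,
    )
    return replace(cfg, **overrides) if overrides else cfg


def recovery_scenario(multiplier: float, n_factors: int = 20) -> ScenarioConfig:
    """Planted-enrichment recovery conditions.

    20,000 single-mark elements whose increased fold-change class (half
    the elements, ~10,000 peaks) carries one factor at ``multiplier``
    times the 0.1 background co-occurrence rate, amid background-only
    factors. Scoring the increased class against its complement should
    recover ``log2(multiplier)``.
    """
    factors = [TFSpec("PLANTED", 0.1, (("fc:increased", multiplier),))]
    factors += [TFSpec(f"BG{k:02d}", 0.1) for k in range(1, n_factors)]
    return ScenarioConfig(
        genome=(("chr1", 50_000_000), ("chr2", 50_000_000)),
        n_elements=20_000,
        n_genes=500,
        samples=(SampleSpec("S1", "TN", (0, 56)),),
        subgroup_mixture={7: 1.0},
        tf_catalogue=tuple(factors),
        fc_classes=(
            FCClassSpec("increased", 0.5, 1.0),
            FCClassSpec("stable", 0.5, 0.0),
        ),
        seed=0,
    )


def null_binning_scenario() -> ScenarioConfig:
    """Rank-binning null: 20,000 peaks, groups A-D factors at rate 0.1,
    no planted enrichment anywhere, fold changes pure noise."""
    factors = tuple(TFSpec(name, 0.1) for name in _NAMED_FACTORS)
    return ScenarioConfig(
        genome=(("chr1", 50_000_000), ("chr2", 50_000_000)),
        n_elements=20_000,
        n_genes=500,
        samples=(SampleSpec("S1", "TN", (0, 56)),),
        subgroup_mixture={7: 1.0},
        tf_catalogue=factors,
        fc_classes=(FCClassSpec("stable", 1.0, 0.0),),
        seed=0,
    )


def gradient_binning_scenario(max_multiplier: float = 2.0) -> ScenarioConfig:
    """Planted bottom-bin gradient: group A factors' co-occurrence rate
    rises smoothly toward the most-decreased end of the planted
    fold-change ranking (up to ``max_multiplier`` x background), with
    continuous planted effects so the realised ranking tracks the
    planted one."""
    factors = tuple(
        TFSpec(name, 0.1, fc_gradient=max_multiplier)
        if name in ("EZH2", "SUZ12", "CtBP2")
        else TFSpec(name, 0.1)
        for name in _NAMED_FACTORS
    )
    cfg = null_binning_scenario()
    return replace(cfg, tf_catalogue=factors, fc_effect_jitter_sd=0.4)


def rr_specific_scenario() -> ScenarioConfig:
    """Relapsed/refractory-specific selection conditions: five samples
    (three TN, two RR), 8% of 10,000 elements present only in the RR
    samples and carrying EZH2/SUZ12 sites at 4x background."""
    factors = [
        TFSpec("EZH2", 0.1, (("rr_specific", 4.0),)),
        TFSpec("SUZ12", 0.1, (("rr_specific", 4.0),)),
    ]
    factors += [TFSpec(f"BG{k:02d}", 0.1) for k in range(1, 11)]
    return ScenarioConfig(
        genome=(("chr1", 30_000_000), ("chr2", 30_000_000)),
        n_elements=10_000,
        n_genes=500,
        samples=(
            SampleSpec("N1", "TN", (0,)),
            SampleSpec("N2", "TN", (0,)),
            SampleSpec("N3", "TN", (0,)),
            SampleSpec("R1", "RR", (0,)),
            SampleSpec("R2", "RR", (0,)),
        ),
        subgroup_mixture={7: 1.0},
        tf_catalogue=tuple(factors),
        fc_classes=(FCClassSpec("stable", 1.0, 0.0),),
        rr_specific_fraction=0.08,
        seed=0,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """An in-memory generated scenario plus its ground truth."""

    config: ScenarioConfig
    seed: int
    truth: pd.DataFrame
    mark_peaks: dict[tuple[str, str, int], PeakSet]
    catalogue: TFCatalogue
    tss: TssTable
    cpg_islands: PeakSet
    intensities: pd.DataFrame

    def element_universe(self) -> PeakSet:
        """The true consensus universe (ids = element ids)."""
        return PeakSet(
            [
                GenomicInterval(r.chrom, r.start, r.end, r.element_id)
                for r in self.truth.itertuples()
            ],
            name="universe",
        )

    def mark_profile(self, sample: str, timepoint_days: int) -> MarkProfile:
        marks = {
            mark: ps
            for (s, mark, t), ps in self.mark_peaks.items()
            if s == sample and t == timepoint_days
        }
        if not marks:
            raise KeyError(f"no peak sets for {sample} at {timepoint_days} days")
        return MarkProfile(
            sample=sample, timepoint_days=timepoint_days, peaks_by_mark=marks
        )

    def intensity_table(self, sample: str) -> pd.DataFrame:
        sub = self.intensities[self.intensities["sample"] == sample]
        return sub[["element_id", "timepoint_days", "intensity"]].reset_index(
            drop=True
        )

    def align_truth(self, universe: PeakSet) -> pd.DataFrame:
        """Truth rows matched 1:1 (by overlap) onto a derived universe.

        Returns the truth frame reordered to ``universe`` order with a
        ``universe_id`` column; raises if the match is not a bijection
        (which would mean the derived universe fused or lost elements).
        """
        elements = self.element_universe()
        flags = overlaps_any(universe, elements)
        if len(universe) != len(elements) or not flags.all():
            raise ValueError(
                f"universe ({len(universe)}) does not match the "
                f"{len(elements)} planted elements one-to-one"
            )
        aligned = self.truth.copy()
        aligned["universe_id"] = [iv.id for iv in universe]
        return aligned


def _allocate_counts(n: int, lengths: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of n elements over chromosomes."""
    quota = np.array(lengths, dtype=float) * n / sum(lengths)
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _stratum_mask(stratum: str, truth: pd.DataFrame) -> np.ndarray:
    if stratum.startswith("subgroup:"):
        return (truth["subgroup"] == int(stratum.split(":", 1)[1])).to_numpy()
    if stratum.startswith("fc:"):
        return (truth["fc_class"] == stratum.split(":", 1)[1]).to_numpy()
    simple = {
        "bivalent": truth["bivalent"],
        "promoter": truth["promoter"],
        "non_promoter": ~truth["promoter"],
        "rr_specific": truth["rr_specific"],
        "cpg": truth["cpg"],
    }
    if stratum not in simple:
        raise ValueError(f"unknown enrichment stratum {stratum!r}")
    return simple[stratum].to_numpy()


def generate_bundle(config: ScenarioConfig, seed: int | None = None) -> Bundle:
    """Generate a full in-memory scenario; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_elements
    chroms = [c for c, _ in config.genome]
    lengths = [l for _, l in config.genome]
    per_chrom = _allocate_counts(n, lengths)

    # --- promoter flags, widths, placement (elements in genomic order) ----
    promoter = np.zeros(n, dtype=bool)
    n_prom = min(config.n_genes, int(round(config.promoter_fraction * n)))
    promoter[rng.choice(n, size=n_prom, replace=False)] = True
    med = np.where(
        promoter, config.promoter_width_median, config.nonpromoter_width_median
    )
    widths = (
        np.rint(med * np.exp(rng.normal(0.0, config.width_log_sd, n)))
        .astype(np.int64)
        .clip(config.min_width, config.max_width)
    )
    starts = np.empty(n, dtype=np.int64)
    chrom_arr = np.empty(n, dtype=object)
    lo = 0
    for chrom, length, k in zip(chroms, lengths, per_chrom):
        w = widths[lo : lo + k]
        need = int(w.sum()) + (k + 1) * config.min_gap
        if need > length:
            raise ValueError(
                f"infeasible packing: {k} elements of total width {w.sum()} "
                f"+ gaps need {need} bp but {chrom} has {length}"
            )
        slack = length - int(w.sum()) - (k + 1) * config.min_gap
        parts = rng.random(k + 1)
        extra = np.floor(parts / parts.sum() * slack).astype(np.int64)
        gaps = config.min_gap + extra
        starts[lo : lo + k] = np.cumsum(gaps[:k]) + np.concatenate(
            ([0], np.cumsum(w[:-1]))
        )
        chrom_arr[lo : lo + k] = chrom
        lo += k
    ends = starts + widths
    element_ids = np.array([f"e{i + 1:06d}" for i in range(n)], dtype=object)

    # --- planted classes ---------------------------------------------------
    codes_avail = np.arange(1, 8)
    probs = np.array([config.subgroup_mixture.get(c, 0.0) for c in codes_avail])
    subgroup = rng.choice(codes_avail, p=probs, size=n)
    bivalent = np.isin(subgroup, [1, 5])

    fc_names = [c.name for c in config.fc_classes]
    fc_probs = np.array([c.proportion for c in config.fc_classes])
    fc_effects = np.array([c.log2_effect for c in config.fc_classes])
    fc_idx = rng.choice(len(fc_names), p=fc_probs, size=n)
    fc_class = np.array(fc_names, dtype=object)[fc_idx]
    planted_log2fc = fc_effects[fc_idx]
    if config.fc_effect_jitter_sd > 0:
        planted_log2fc = planted_log2fc + rng.normal(
            0.0, config.fc_effect_jitter_sd, n
        )

    rr_specific = rng.random(n) < config.rr_specific_fraction
    cpg = rng.random(n) < np.where(
        bivalent, config.cpg_rate_bivalent, config.cpg_rate_other
    )

    # descending planted-FC percentile: u=0 most increased, u=1 most decreased
    order = np.argsort(-planted_log2fc, kind="stable")
    u = np.empty(n)
    u[order] = np.arange(n) / max(n - 1, 1)

    # --- genes: one TSS at the midpoint of each promoter element ----------
    gene_rows = []
    g = 0
    for i in np.nonzero(promoter)[0]:
        g += 1
        gene_rows.append(
            (f"G{g:05d}", chrom_arr[i], int((starts[i] + ends[i]) // 2), element_ids[i])
        )
    gene_frame = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "pos", "element_id"])
    tss = TssTable(gene_frame[["gene_id", "chrom", "pos"]].copy())

    truth = pd.DataFrame(
        {
            "element_id": element_ids,
            "chrom": chrom_arr,
            "start": starts,
            "end": ends,
            "subgroup": subgroup,
            "bivalent": bivalent,
            "promoter": promoter,
            "cpg": cpg,
            "rr_specific": rr_specific,
            "fc_class": fc_class,
            "planted_log2fc": planted_log2fc,
        }
    )
    truth = truth.merge(
        gene_frame[["element_id", "gene_id"]], on="element_id", how="left"
    )

    # --- TF sites ----------------------------------------------------------
    entries: list[tuple[str, GenomicInterval]] = []
    site_count = 0
    for tf in config.tf_catalogue:
        rate = np.full(n, tf.background_rate)
        for stratum, mult in tf.enrichments:
            rate[_stratum_mask(stratum, truth)] *= mult
        if tf.fc_gradient != 1.0:
            rate = rate * np.power(tf.fc_gradient, u)
        rate = np.clip(rate, 0.0, 1.0)
        hits = rng.random(n) < rate
        offsets = rng.integers(0, widths - config.site_width + 1, size=n)
        for i in np.nonzero(hits)[0]:
            site_count += 1
            s = int(starts[i] + offsets[i])
            entries.append(
                (
                    tf.name,
                    GenomicInterval(
                        chrom_arr[i], s, s + config.site_width,
                        f"site{site_count:07d}",
                    ),
                )
            )
    catalogue = TFCatalogue(entries)

    # --- CpG islands (a sub-interval of each flagged element) -------------
    cpg_ivs = []
    cpg_half = rng.integers(50, 200, size=n)
    for i in np.nonzero(cpg)[0]:
        mid = int((starts[i] + ends[i]) // 2)
        h = int(min(cpg_half[i], widths[i] // 2 - 1))
        cpg_ivs.append(
            GenomicInterval(chrom_arr[i], mid - h, mid + h, f"cpg{i + 1:06d}")
        )
    cpg_islands = PeakSet(cpg_ivs, name="cpg_islands")

    # --- intensities -------------------------------------------------------
    base = rng.normal(config.intensity_log2_mean, config.intensity_log2_sd, n)
    t_max = max(t for s in config.samples for t in s.timepoints) or 1
    int_parts = []
    for samp in config.samples:
        present = ~rr_specific | (samp.status == "RR")
        for t in samp.timepoints:
            noise = rng.normal(0.0, config.intensity_noise_sd, n)
            vals = np.round(
                np.power(2.0, base + planted_log2fc * (t / t_max) + noise), 4
            )
            int_parts.append(
                pd.DataFrame(
                    {
                        "sample": samp.name,
                        "element_id": element_ids[present],
                        "timepoint_days": t,
                        "intensity": vals[present],
                    }
                )
            )
    intensities = pd.concat(int_parts, ignore_index=True)

    # --- per-sample/mark/timepoint peak sets -------------------------------
    j = config.jitter_bp
    mark_peaks: dict[tuple[str, str, int], PeakSet] = {}
    mark_ivs: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for mark in ("EZH2", "H3K4me3", "H3K27me3"):
        member = np.array(
            [mark in CODE_TO_COMBINATION[c] for c in subgroup], dtype=bool
        )
        idxs = np.nonzero(member)[0]
        js = rng.integers(-j, j + 1, size=len(idxs))
        je = rng.integers(-j, j + 1, size=len(idxs))
        ivs = []
        for i, ds, de in zip(idxs, js, je):
            s = max(int(starts[i] + ds), 0)
            e = int(ends[i] + de)
            ivs.append((i, GenomicInterval(chrom_arr[i], s, e, f"{element_ids[i]}_{mark}")))
        mark_ivs[mark] = ivs
    # intervals are generated in (chrom, start) order, so the fast
    # presorted constructor is safe; TN samples drop RR-specific elements
    variants: dict[tuple[str, bool], tuple] = {}
    for mark, ivs in mark_ivs.items():
        variants[(mark, True)] = tuple(iv for _, iv in ivs)
        variants[(mark, False)] = tuple(
            iv for i, iv in ivs if not rr_specific[i]
        )
    for samp in config.samples:
        all_present = samp.status == "RR" or not rr_specific.any()
        for t in samp.timepoints:
            for mark in mark_ivs:
                kept = variants[(mark, all_present)]
                if not kept:
                    continue
                mark_peaks[(samp.name, mark, t)] = PeakSet._from_sorted(
                    kept,
                    name=f"{samp.name}_{mark}_d{t}",
                    mark=mark,
                    sample=samp.name,
                    timepoint_days=t,
                )

    return Bundle(
        config=config,
        seed=config.seed if seed is None else seed,
        truth=truth,
        mark_peaks=mark_peaks,
        catalogue=catalogue,
        tss=tss,
        cpg_islands=cpg_islands,
        intensities=intensities,
    )


# ---------------------------------------------------------------------------
# On-disk bundles and the truth report
# ---------------------------------------------------------------------------


def truth_report(bundle: Bundle) -> dict:
    """Ground-truth tables as a JSON-serialisable dict.

    Contains the planted per-element attributes, the planted per-factor
    rates/enrichments, the fold-change class definitions and the sample
    design — the oracle every downstream test measures against.
    """
    truth = bundle.truth.copy()
    truth["gene_id"] = truth["gene_id"].where(truth["gene_id"].notna(), None)
    return {
        "seed": bundle.seed,
        "elements": truth.to_dict(orient="records"),
        "factors": [
            {
                "name": tf.name,
                "background_rate": tf.background_rate,
                "enrichments": [list(e) for e in tf.enrichments],
                "fc_gradient": tf.fc_gradient,
            }
            for tf in bundle.config.tf_catalogue
        ],
        "fc_classes": [asdict(c) for c in bundle.config.fc_classes],
        "samples": [asdict(s) for s in bundle.config.samples],
    }


def generate_scenario(
    config: ScenarioConfig, outdir, seed: int | None = None
) -> Bundle:
    """Generate a scenario and write it to ``outdir`` (see layout below).

    Layout::

        outdir/
          peaks/<sample>_<mark>_d<t>.bed   per-sample/mark/timepoint calls
          universe.bed                     true consensus element universe
          catalogue.bed                    BED4 TF site catalogue
          tss.bed                          BED4 gene TSS (1 bp records)
          cpg.bed                          BED3 CpG islands
          intensities.tsv                  sample/element/timepoint/intensity
          ground_truth.json                planted truth (the test oracle)
    """
    bundle = generate_bundle(config, seed=seed)
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    for (samp, mark, t), ps in sorted(bundle.mark_peaks.items()):
        write_bed(ps, out / "peaks" / f"{samp}_{mark}_d{t}.bed")
    write_bed(bundle.element_universe(), out / "universe.bed")
    bundle.catalogue.to_bed(out / "catalogue.bed")
    with open(out / "tss.bed", "w") as fh:
        for row in bundle.tss.frame.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.gene_id}\n")
    with open(out / "cpg.bed", "w") as fh:
        for iv in bundle.cpg_islands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    bundle.intensities.to_csv(out / "intensities.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_report(bundle), fh, indent=0, default=str)
    return bundle
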