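"""REMI signature construction and scoring.

REMI ("ReMap and Epigenetic Marks Intersection") characterises a peak
population by its *signature*: for every transcription factor in a
merged site catalogue, the number (and fraction) of population elements
containing at least one validated site of that factor. Two populations
are then compared by a per-factor enrichment score.

Score form
----------
The score used throughout is a log2 fraction ratio with a
population-size-scaled pseudocount::

    score[f] = log2( (f_test + p) / (f_ref + p) ),
    p = pseudocount / max(n_test, n_ref)

This functional form is a documented reconstruction — the original
supplementary equations are not reproduced here — chosen because it has
the qualitative properties the analyses rely on: identically zero when
test and reference compositions agree (including the all-zero factor),
antisymmetric under swapping test and reference, monotone in the test
fraction, and convergent to the pure log-ratio for large populations.
Output headers flag the form so downstream consumers know which
definition produced the numbers. Statistical significance is *not*
attached to scores; :func:`binomial_score_se` provides the analytic
binomial standard error used by the synthetic-recovery checks.

The three reference conventions in use:

* reference = unweighted average of several samples' signatures
  (:func:`reference_from_average`) — cross-sample comparison;
* reference = the all-peaks signature of the parent population
  (:func:`score_subset_vs_all`) — subset composition analysis;
* the same all-peaks reference applied per rank bin — see
  :mod:`remi.dynamics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import TFCatalogue
from .intervals import PeakSet, _exists_overlap

#: One-line provenance note emitted in score table headers.
SCORE_FORM_NOTE = (
    "score = log2((f_test+p)/(f_ref+p)), p = pseudocount/max(n_test, n_ref); "
    "reconstructed log-ratio form"
)


@dataclass
class Signature:
    """Per-factor co-occurrence composition of one peak population.

    ``per_factor_count[f]`` is the number of population elements that
    contain >= 1 site of factor ``f``. Counts are integers for real
    populations but may be fractional for averaged reference signatures
    (so that averaged fractions are represented exactly).
    """

    population_name: str
    n_peaks: int
    per_factor_count: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_peaks <= 0:
            raise ValueError("signature undefined on empty population")
        for f, c in self.per_factor_count.items():
            if not 0 <= c <= self.n_peaks:
                raise ValueError(
                    f"count for {f!r} ({c}) outside [0, {self.n_peaks}]"
                )

    @property
    def factors(self) -> frozenset[str]:
        return frozenset(self.per_factor_count)

    @property
    def per_factor_fraction(self) -> dict[str, float]:
        return {f: c / self.n_peaks for f, c in self.per_factor_count.items()}


@dataclass
class ScoreProfile:
    """Ranked per-factor scores of a test population against a reference.

    ``scores`` preserves ranking order: most enriched first, most
    depleted last, ties broken by factor name.
    """

    scores: dict[str, float]
    reference_name: str
    pseudocount: float
    test_fraction: dict[str, float] = field(default_factory=dict)
    ref_fraction: dict[str, float] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        return list(self.scores.items())

    def top(self, k: int = 1) -> list[str]:
        return [f for f, _ in self.ranked()[:k]]

    def group_mean(self, factors: Iterable[str]) -> float:
        """Unweighted mean score over a factor group."""
        vals = [self.scores[f] for f in factors]
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f,
                "test_fraction": self.test_fraction.get(f, math.nan),
                "ref_fraction": self.ref_fraction.get(f, math.nan),
                "score": s,
                "rank": i + 1,
            }
            for i, (f, s) in enumerate(self.ranked())
        ]
        frame = pd.DataFrame(rows)
        frame.attrs["score_form"] = SCORE_FORM_NOTE
        return frame


def build_signature(population: PeakSet, catalogue: TFCatalogue) -> Signature:
    """Count, per factor, the population elements containing >= 1 site.

    An element with several sites of one factor counts once for that
    factor. Raises on an empty population (fractions undefined).
    """
    if len(population) == 0:
        raise ValueError("signature undefined on empty population")
    counts: dict[str, float] = {}
    pop_idx = population._index()
    for factor in sorted(catalogue.factors):
        total = 0
        fac_idx = catalogue.factor_index(factor)
        for chrom, arrs in pop_idx.items():
            sites = fac_idx.get(chrom)
            if sites is None:
                continue
            starts, end_cummax = sites
            total += int(
                _exists_overlap(arrs.starts, arrs.ends, starts, end_cummax).sum()
            )
        counts[factor] = total
    return Signature(
        population_name=population.name or "population",
        n_peaks=len(population),
        per_factor_count=counts,
    )


def _check_factor_match(a: Signature, b: Signature) -> None:
    if a.factors != b.factors:
        only_a = sorted(a.factors - b.factors)
        only_b = sorted(b.factors - a.factors)
        raise ValueError(
            f"signatures cover different factor sets; only in "
            f"{a.population_name!r}: {only_a}; only in "
            f"{b.population_name!r}: {only_b}"
        )


def score_vs_reference(
    test: Signature, reference: Signature, pseudocount: float = 0.5
) -> ScoreProfile:
    """Per-factor log2 fraction-ratio score of ``test`` against ``reference``.

    Factors are returned ranked from most enriched to most depleted.
    """
    _check_factor_match(test, reference)
    p = pseudocount / max(test.n_peaks, reference.n_peaks)
    ft = test.per_factor_fraction
    fr = reference.per_factor_fraction
    scores = {
        f: math.log2((ft[f] + p) / (fr[f] + p)) for f in test.per_factor_count
    }
    ranked = dict(sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])))
    return ScoreProfile(
        scores=ranked,
        reference_name=reference.population_name,
        pseudocount=pseudocount,
        test_fraction=ft,
        ref_fraction=fr,
    )


def reference_from_average(signatures: Sequence[Signature]) -> Signature:
    """Unweighted average of several signatures, as a reference signature.

    Per-factor fraction is the plain mean of the input fractions;
    ``n_peaks`` is the floor of the mean population size and counts are
    rescaled (possibly fractionally) so fractions are preserved exactly.
    """
    if not signatures:
        raise ValueError("need at least one signature to average")
    first = signatures[0]
    for sig in signatures[1:]:
        _check_factor_match(first, sig)
    n = int(math.floor(np.mean([s.n_peaks for s in signatures])))
    counts = {
        f: n * float(np.mean([s.per_factor_fraction[f] for s in signatures]))
        for f in first.per_factor_count
    }
    return Signature(
        population_name="average(" + ",".join(s.population_name for s in signatures) + ")",
        n_peaks=n,
        per_factor_count=counts,
    )


def score_subset_vs_all(
    subset: PeakSet,
    all_peaks: PeakSet,
    catalogue: TFCatalogue,
    pseudocount: float = 0.5,
) -> ScoreProfile:
    """Score a sub-population against its parent population's composition.

    ``subset`` must be contained in ``all_peaks`` by id. The reference
    is the all-peaks signature, so a subset drawn uniformly from the
    parent scores ~0 everywhere and ``subset == all_peaks`` scores
    exactly 0.
    """
    missing = set(subset.ids()) - set(all_peaks.ids())
    if missing:
        raise ValueError(
            f"subset is not contained in all_peaks; foreign ids: "
            f"{sorted(missing)[:5]}"
        )
    test = build_signature(subset, catalogue)
    reference = build_signature(all_peaks, catalogue)
    return score_vs_reference(test, reference, pseudocount=pseudocount)


def binomial_score_se(rate: float, n: int, n_factors: int = 1) -> float:
    """Delta-method SE of a log2 fraction-ratio score under the null.

    For a bin of ``n`` elements whose per-factor co-occurrence fraction
    has expectation ``rate``, the score's sampling SD is approximately
    ``sqrt(rate*(1-rate)/n) / (rate * ln 2)``; averaging over
    ``n_factors`` independent factors divides by ``sqrt(n_factors)``.
    Used only by synthetic-recovery and null-flatness checks.
    """
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    se = math.sqrt(rate * (1 - rate) / n) / (rate * math.log(2))
    return se / math.sqrt(n_factors)
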