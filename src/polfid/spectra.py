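"""rpoB base-substitution spectra: calling, window filtering, classification.

Rifampicin-resistant isolates carry base substitutions in a short central
window of the rpoB gene; by convention only substitutions at 1-based positions
1516-1717 are scored. Each substitution is collapsed by Watson-Crick
complementation onto one of six base-pair classes (a change observed at a G or
T on the reference strand is expressed through its complement), and tabulated
into class counts, transition/transversion totals, percentages and
per-position tallies.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "SUBSTITUTION_CLASSES",
    "TRANSITION_CLASSES",
    "COMPLEMENT",
    "WINDOW_LO",
    "WINDOW_HI",
    "SubstitutionCall",
    "SpectrumTable",
    "call_substitutions",
    "classify_substitution",
    "filter_window",
    "tabulate_spectrum",
    "find_hotspots",
    "compare_spectra",
]

#: the six base-pair substitution classes, reference pair -> mutant pair
SUBSTITUTION_CLASSES = ("CG->GC", "CG->AT", "CG->TA", "AT->TA", "AT->CG", "AT->GC")
#: purine<->purine / pyrimidine<->pyrimidine classes
TRANSITION_CLASSES = frozenset({"CG->TA", "AT->GC"})

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default scoring window within the rpoB gene (1-based, closed)
WINDOW_LO = 1516
WINDOW_HI = 1717


@dataclass(frozen=True)
class SubstitutionCall:
    """A single base substitution in one isolate (reference-strand coords)."""

    position: int
    ref: str
    alt: str
    isolate: str = ""

    def __post_init__(self) -> None:
        if self.ref not in COMPLEMENT or self.alt not in COMPLEMENT:
            raise DataError(f"non-canonical base in call: {self.ref}->{self.alt}")
        if self.ref == self.alt:
            raise DataError("ref and alt must differ")


@dataclass(frozen=True)
class SpectrumTable:
    """Six-class tabulation of a set of in-window substitution calls."""

    counts: Mapping[str, int]
    per_position: Mapping[int, Mapping[str, int]]
    total: int
    transitions: int
    transversions: int

    @property
    def percents(self) -> dict[str, float]:
        """Per-class percentage of total calls; empty when total is 0."""
        if self.total == 0:
            return {}
        return {c: 100.0 * self.counts[c] / self.total for c in SUBSTITUTION_CLASSES}

    @property
    def transition_percent(self) -> float:
        if self.total == 0:
            raise DataError("percentages undefined for an empty spectrum")
        return 100.0 * self.transitions / self.total

    @property
    def transversion_percent(self) -> float:
        if self.total == 0:
            raise DataError("percentages undefined for an empty spectrum")
        return 100.0 * self.transversions / self.total

    def position_totals(self) -> dict[int, int]:
        return {p: sum(c.values()) for p, c in self.per_position.items()}


def call_substitutions(
    ref_seq: str, isolate_seq: str, offset: int = WINDOW_LO, isolate: str = ""
) -> list[SubstitutionCall]:
    """Compare a pre-aligned, ungapped isolate sequence against the reference.

    One call is emitted per mismatching position (``position = offset +
    index``); positions where either sequence carries an ambiguous base (not
    A/C/G/T) are skipped.
    """
    ref_seq = str(ref_seq).upper()
    isolate_seq = str(isolate_seq).upper()
    if len(ref_seq) != len(isolate_seq):
        raise DataError(
            f"sequence length mismatch: ref {len(ref_seq)} vs isolate {len(isolate_seq)}"
        )
    calls = []
    for i, (r, a) in enumerate(zip(ref_seq, isolate_seq)):
        if r == a or r not in COMPLEMENT or a not in COMPLEMENT:
            continue
        calls.append(SubstitutionCall(position=offset + i, ref=r, alt=a, isolate=isolate))
    return calls


def classify_substitution(call: SubstitutionCall) -> tuple[str, str]:
    """Collapse a call to its base-pair class and transition/transversion kind."""
    ref, alt = call.ref, call.alt
    if ref in ("G", "T"):  # express via the complementary strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    cls = f"{ref}{COMPLEMENT[ref]}->{alt}{COMPLEMENT[alt]}"
    if cls not in SUBSTITUTION_CLASSES:  # pragma: no cover - exhaustive by construction
        raise DataError(f"unclassifiable substitution {call.ref}->{call.alt}")
    kind = "transition" if cls in TRANSITION_CLASSES else "transversion"
    return cls, kind


def filter_window(
    calls: Iterable[SubstitutionCall], lo: int = WINDOW_LO, hi: int = WINDOW_HI
) -> list[SubstitutionCall]:
    """Keep calls with lo <= position <= hi (closed interval, 1-based)."""
    if lo > hi:
        raise ParameterError(f"invalid window [{lo}, {hi}]")
    return [c for c in calls if lo <= c.position <= hi]


def tabulate_spectrum(calls: Iterable[SubstitutionCall]) -> SpectrumTable:
    """Tabulate window-filtered calls into a six-class spectrum table."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    per_position: dict[int, Counter] = defaultdict(Counter)
    transitions = 0
    total = 0
    for call in calls:
        cls, kind = classify_substitution(call)
        counts[cls] += 1
        per_position[call.position][cls] += 1
        transitions += kind == "transition"
        total += 1
    return SpectrumTable(
        counts=counts,
        per_position={p: dict(c) for p, c in sorted(per_position.items())},
        total=total,
        transitions=transitions,
        transversions=total - transitions,
    )


def find_hotspots(table: SpectrumTable, min_fraction: float = 0.05) -> list[int]:
    """Positions holding at least ``min_fraction`` of all calls.

    Sorted by count descending, then position ascending.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ParameterError("min_fraction must be in (0, 1]")
    totals = table.position_totals()
    threshold = min_fraction * table.total
    hits = [p for p, n in totals.items() if n >= threshold and n > 0]
    return sorted(hits, key=lambda p: (-totals[p], p))


def compare_spectra(
    table1: SpectrumTable,
    table2: SpectrumTable,
    n_resamples: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo chi-square contingency test between two class spectra.

    Utility plumbing for exploratory strain-vs-strain comparison; permutes
    class labels between the two samples to obtain the null distribution of
    the chi-square statistic (valid at the small per-class counts typical of
    spectra). Returns (statistic, p).
    """
    from scipy import stats as _stats

    obs = np.array(
        [[table1.counts[c] for c in SUBSTITUTION_CLASSES],
         [table2.counts[c] for c in SUBSTITUTION_CLASSES]]
    )
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        raise DataError("need at least two non-empty classes to compare spectra")

    def chi2_stat(tab: np.ndarray) -> float:
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        return float(((tab - expected) ** 2 / expected).sum())

    stat = chi2_stat(obs)
    rng = np.random.default_rng(seed)
    n1 = int(obs[0].sum())
    pooled = np.repeat(np.arange(obs.shape[1]), obs.sum(axis=0))
    exceed = 0
    for _ in range(n_resamples):
        rng.shuffle(pooled)
        row1 = np.bincount(pooled[:n1], minlength=obs.shape[1])
        tab = np.vstack([row1, obs.sum(axis=0) - row1])
        if chi2_stat(tab) >= stat - 1e-12:
            exceed += 1
    return stat, (exceed + 1) / (n_resamples + 1)
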