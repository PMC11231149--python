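"""One-migrant-per-generation onset detection and the speciation interval.

The OMPG rule holds that divergence by drift proceeds once fewer than one
migrant per local population per generation arrives.  For each unordered
island pair we track the per-generation migration events divided by two
(the number of populations involved) and smooth with a trailing moving
average.  The first generation in which two of the three pair averages are
below threshold marks the onset of the first allopatric speciation event;
the first generation in which all three are below marks the second.  The
difference is the speciation interval, and an interval of at most the
cutoff (10 generations by default) is classified as simultaneous
speciation — the regime that leaves a hard polytomy in a reconstructed
phylogeny.

"Fell below" is read strictly (< threshold), the first crossing wins with
no hysteresis, and averages are evaluated only once the window is full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PAIR_LABELS, PAIRS


@dataclass(frozen=True)
class SpeciationResult:
    """Outcome of one simulation run.

    ``onset_first``/``onset_second`` are the generations of the 2-of-3 and
    3-of-3 threshold crossings (None if never reached).  ``first_isolated``
    names the island common to the two pairs below threshold at the first
    onset — the island that speciated first — or None when all three pairs
    crossed together (a hard polytomy).  Censored runs hit the generation
    cap or went extinct before the second onset.
    """

    onset_first: int | None
    onset_second: int | None
    interval: int | None
    simultaneous: bool
    censored: bool
    censor_reason: str | None = None
    first_isolated: str | None = None
    n_generations: int | None = None

    @classmethod
    def censored_result(
        cls,
        generation: int,
        cutoff: int,
        reason: str,
        onset_first: int | None = None,
        first_isolated: str | None = None,
    ) -> "SpeciationResult":
        return cls(
            onset_first=onset_first,
            onset_second=None,
            interval=None,
            simultaneous=False,
            censored=True,
            censor_reason=reason,
            first_isolated=first_isolated,
            n_generations=generation,
        )


@dataclass
class MigrantSeries:
    """Per-pair, per-generation mean migrants per population.

    ``means`` has shape (T, 3) with columns in pair order A-B, A-C, B-C:
    raw pair migration counts already divided by two.
    """

    means: np.ndarray
    window: int = 50

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.means.shape[1] != len(PAIRS):
            raise ValueError("means must have one column per island pair")
        if np.any(self.means < 0):
            raise ValueError("migrant means must be non-negative")

    @property
    def moving_averages(self) -> np.ndarray:
        """Trailing moving averages, NaN until the window is full."""
        return np.column_stack(
            [moving_average(self.means[:, k], self.window) for k in range(3)]
        )

    def to_frame(self):
        import pandas as pd

        ma = self.moving_averages
        data = {"generation": np.arange(len(self.means))}
        for k, lab in enumerate(PAIR_LABELS):
            data[f"migrants_{lab}"] = self.means[:, k]
            data[f"ma_{lab}"] = ma[:, k]
        return pd.DataFrame(data)


def moving_average(series, window: int) -> np.ndarray:
    """Trailing mean of the most recent ``window`` values.

    Entries before index ``window - 1`` are NaN (the average is undefined
    until ``window`` values exist).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size == 0:
        raise ValueError("series is empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    out = np.full(x.size, np.nan)
    if x.size >= window:
        c = np.concatenate(([0.0], np.cumsum(x)))
        out[window - 1:] = (c[window:] - c[:-window]) / window
    return out


def detect_onsets(
    series: MigrantSeries, threshold: float = 1.0
) -> tuple[int | None, int | None]:
    """First generations at which >=2 then all 3 pair averages are below
    threshold.

    Either onset is None if the series ends before the crossing.  The
    qualifying pairs need not stay below threshold: the first crossing
    wins.
    """
    below = series.moving_averages < threshold  # NaN compares False
    n_below = below.sum(axis=1)
    first_idx = np.flatnonzero(n_below >= 2)
    second_idx = np.flatnonzero(n_below == 3)
    onset_first = int(first_idx[0]) if first_idx.size else None
    onset_second = int(second_idx[0]) if second_idx.size else None
    return onset_first, onset_second


def first_isolated_island(below_flags) -> str | None:
    """Island common to the two below-threshold pairs at the first onset.

    Returns None when all three pairs are below (ties: hard polytomy).
    """
    below_flags = np.asarray(below_flags, dtype=bool)
    if below_flags.sum() == 3:
        return None
    pairs = [PAIRS[k] for k in np.flatnonzero(below_flags)]
    (common,) = set(pairs[0]) & set(pairs[1])
    return common


def speciation_interval(onsets: tuple[int | None, int | None]) -> int:
    """Generations between the first and second speciation onsets."""
    first, second = onsets
    if first is None or second is None:
        raise ValueError("cannot compute an interval for a censored run")
    return int(second) - int(first)


def classify_simultaneous(interval: int, cutoff: int = 10) -> bool:
    """True iff the interval is at most the cutoff (inclusive)."""
    if interval < 0:
        raise ValueError("interval must be non-negative")
    return interval <= cutoff


class OnsetDetector:
    """Online OMPG onset detector over a rolling window.

    Feed per-generation pair means (raw pair counts / 2) with
    :meth:`update`; the detector maintains trailing sums over the window
    and records the two onset generations, enabling early stopping.
    Equivalent to :func:`detect_onsets` over the stored series.
    """

    def __init__(self, window: int = 50, threshold: float = 1.0):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.threshold = threshold
        self._buffer = np.zeros((window, 3))
        self._sums = np.zeros(3)
        self._t = 0  # generations seen
        self.onset_first: int | None = None
        self.onset_second: int | None = None
        self.first_isolated: str | None = None

    def update(self, pair_means) -> None:
        pair_means = np.asarray(pair_means, dtype=float)
        slot = self._t % self.window
        self._sums += pair_means - self._buffer[slot]
        self._buffer[slot] = pair_means
        self._t += 1
        if self._t < self.window or self.onset_second is not None:
            return
        below = (self._sums / self.window) < self.threshold
        n_below = int(below.sum())
        gen = self._t - 1
        if self.onset_first is None and n_below >= 2:
            self.onset_first = gen
            self.first_isolated = first_isolated_island(below)
        if n_below == 3:
            self.onset_second = gen

    def result(self, generation: int, cutoff: int = 10) -> SpeciationResult:
        """Finalize, censoring if the second onset was never reached."""
        if self.onset_second is None:
            return SpeciationResult.censored_result(
                generation=generation,
                cutoff=cutoff,
                reason="max_generations reached before second onset",
                onset_first=self.onset_first,
                first_isolated=self.first_isolated,
            )
        interval = speciation_interval((self.onset_first, self.onset_second))
        return SpeciationResult(
            onset_first=self.onset_first,
            onset_second=self.onset_second,
            interval=interval,
            simultaneous=classify_simultaneous(interval, cutoff),
            censored=False,
            first_isolated=self.first_isolated,
            n_generations=generation,
        )
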