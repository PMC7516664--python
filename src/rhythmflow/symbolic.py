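"""Ordinal-pattern symbolization and symbolic-recurrence quantification.

A scalar series :math:`\\{x_t\\}_{t=1}^{T}` is mapped to a symbol series of
length :math:`\\bar T = T - m + 1` by replacing each window
:math:`(x_t, \\dots, x_{t+m-1})` with its ordinal pattern — the permutation of
time offsets that sorts the window ascending (the Bandt–Pompe construction).
The alphabet has :math:`m!` symbols.  Ties are broken by temporal order
(earlier offset ranks lower), the standard convention for ordinal patterns;
an optional seeded dither is available to break ties stochastically instead,
which matters for percussive data with silent runs of equal amplitude.

Recurrence of symbols is quantified per symbol,

.. math:: SRR(\\pi) = \\frac{c_\\pi (c_\\pi - 1)}{\\bar T (\\bar T - 1)},

where :math:`c_\\pi` counts occurrences of :math:`\\pi`; the numerator is the
number of ordered off-diagonal time pairs on which :math:`\\pi` recurs, so the
count form is exactly the double sum over the symbolic-recurrence plot.  The
total rate ``SRR`` sums over the alphabet, recurrence probabilities are
``P(pi) = SRR(pi)/SRR``, and the recurrence entropy is the base-2 Shannon
entropy of ``P``.  For an i.i.d. series ``SRR`` approaches ``1/m!`` and the
entropy approaches ``log2(m!)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import LengthError
from .ingest import AmplitudeSeries

__all__ = [
    "ordinal_patterns",
    "pattern_labels",
    "symbolize",
    "SymbolSeries",
    "RecurrenceProfile",
    "recurrence_plot",
    "srr_profile",
    "recurrence_entropy_from_counts",
]


def ordinal_patterns(m: int) -> list[tuple[int, ...]]:
    """All ordinal patterns of length ``m`` in lexicographic order.

    Pattern ``(1, 2, 0)`` reads: the smallest value sits at offset 1, the
    middle one at offset 2, the largest at offset 0.
    """
    return list(itertools.permutations(range(m)))


def pattern_labels(m: int) -> list[str]:
    """Stable string form of each pattern, e.g. ``'120'`` (used in CSV/plots)."""
    return ["".join(map(str, p)) for p in ordinal_patterns(m)]


@lru_cache(maxsize=None)
def _encoding(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Powers-of-m vector and a lookup table from mixed-radix code to symbol index."""
    powers = m ** np.arange(m)
    lut = np.full(m**m, -1, dtype=np.int64)
    for i, p in enumerate(ordinal_patterns(m)):
        lut[int(np.dot(p, powers))] = i
    return powers, lut


@dataclass(frozen=True)
class SymbolSeries:
    """Ordinal-pattern codes for one series.

    ``codes[t]`` indexes :func:`ordinal_patterns`\\ ``(m)`` and encodes the
    pattern of the window starting at ``t``; there are ``T - m + 1`` of them.
    """

    codes: np.ndarray
    m: int
    trial_id: Optional[str] = None
    player_id: Optional[str] = None
    session: Optional[int] = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 1:
            raise ValueError("codes must be 1-D")
        k = math.factorial(self.m)
        if codes.size and (codes.min() < 0 or codes.max() >= k):
            raise ValueError(f"codes out of range for alphabet of {k} symbols")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return self.codes.size

    @property
    def alphabet_size(self) -> int:
        return math.factorial(self.m)

    @property
    def patterns(self) -> list[tuple[int, ...]]:
        return [ordinal_patterns(self.m)[c] for c in self.codes]


def symbolize(
    series: Union[AmplitudeSeries, Sequence[float], np.ndarray],
    m: int = 3,
    dither: float = 0.0,
    seed: Optional[int] = None,
) -> SymbolSeries:
    """Map a scalar series to its ordinal-pattern symbol series.

    Parameters
    ----------
    series
        An :class:`~rhythmflow.ingest.AmplitudeSeries` or plain array of
        length ``T >= m``.
    m
        Embedding (pattern) length; 3 by default, 2 as the short alternative.
    dither
        If positive, add seeded i.i.d. uniform jitter of this half-width
        before ranking, so exact ties are broken stochastically rather than
        by temporal order.
    """
    ids = {}
    if isinstance(series, AmplitudeSeries):
        ids = dict(
            trial_id=series.trial_id, player_id=series.player_id, session=series.session
        )
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
    if m < 2:
        raise ValueError("m must be at least 2")
    if x.ndim != 1 or x.size < m:
        raise LengthError(f"series of length {x.size} is too short for m={m}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if dither > 0:
        x = x + np.random.default_rng(seed).uniform(-dither, dither, x.size)
    windows = sliding_window_view(x, m)
    # stable argsort == ties broken by temporal order
    perms = np.argsort(windows, axis=1, kind="stable")
    powers, lut = _encoding(m)
    codes = lut[perms @ powers]
    return SymbolSeries(codes=codes, m=m, **ids)


@dataclass(frozen=True)
class RecurrenceProfile:
    """Per-symbol recurrence counts and the statistics derived from them.

    ``counts[k]`` is the number of occurrences of symbol ``k`` in the symbol
    series of length ``n``; all rates use the count closed form, which equals
    the explicit double loop over the recurrence plot.
    """

    counts: np.ndarray
    n: int
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or np.any(c < 0):
            raise ValueError("counts must be a 1-D array of non-negative integers")
        if c.sum() != self.n:
            raise ValueError("counts must sum to the series length n")
        if self.n < 2:
            raise LengthError("recurrence quantification needs at least 2 symbols")
        object.__setattr__(self, "counts", c)

    @property
    def recurrence_weights(self) -> np.ndarray:
        """Ordered recurrence pair counts per symbol, ``c (c - 1)``."""
        c = self.counts.astype(float)
        return c * (c - 1.0)

    @property
    def srr_by_symbol(self) -> np.ndarray:
        return self.recurrence_weights / (self.n * (self.n - 1.0))

    @property
    def srr(self) -> float:
        return float(self.srr_by_symbol.sum())

    @property
    def entropy_defined(self) -> bool:
        """False when no symbol recurs; probabilities are then undefined."""
        return bool(self.recurrence_weights.sum() > 0)

    @property
    def probabilities(self) -> np.ndarray:
        """Recurrence probabilities ``P(pi) = SRR(pi) / SRR`` (NaN if SRR=0)."""
        w = self.recurrence_weights
        tot = w.sum()
        if tot == 0:
            return np.full_like(w, np.nan)
        return w / tot

    @property
    def entropy(self) -> float:
        """Base-2 Shannon entropy of the recurrence probabilities.

        NaN (flagged via :attr:`entropy_defined`) when there is no recurrence
        at all, since the probabilities divide by SRR.
        """
        return recurrence_entropy_from_counts(self.counts)

    def as_frame(self):
        """Per-symbol counts/rates as a DataFrame (CSV-export friendly)."""
        import pandas as pd

        labels = (
            list(self.labels)
            if self.labels is not None
            else [str(i) for i in range(self.counts.size)]
        )
        return pd.DataFrame(
            {
                "symbol": labels,
                "count": self.counts,
                "srr": self.srr_by_symbol,
                "probability": self.probabilities,
            }
        )


def recurrence_entropy_from_counts(counts: np.ndarray) -> float:
    """Entropy (bits) of the recurrence distribution implied by symbol counts."""
    c = np.asarray(counts, dtype=float)
    w = c * (c - 1.0)
    tot = w.sum()
    if tot <= 0:
        return float("nan")
    p = w[w > 0] / tot
    return float(-(p * np.log2(p)).sum())


def recurrence_plot(sym: SymbolSeries) -> np.ndarray:
    """Materialize the symbol-resolved recurrence matrix.

    Entry ``(t, s)`` holds the shared symbol code when positions ``t != s``
    carry the same symbol, and -1 otherwise; the diagonal is set to -1 so the
    matrix only encodes countable recurrences.  Intended for rendering and
    for oracle tests — metric computation uses the count closed form.
    """
    codes = sym.codes
    if codes.size < 2:
        raise LengthError("recurrence plot needs at least 2 symbols")
    eq = codes[:, None] == codes[None, :]
    mat = np.where(eq, codes[None, :], -1)
    np.fill_diagonal(mat, -1)
    return mat


def srr_profile(sym: SymbolSeries) -> RecurrenceProfile:
    """Univariate recurrence profile (rates, probabilities, entropy) of a series."""
    if len(sym) < 2:
        raise LengthError("recurrence quantification needs at least 2 symbols")
    counts = np.bincount(sym.codes, minlength=sym.alphabet_size)
    return RecurrenceProfile(
        counts=counts, n=len(sym), labels=tuple(pattern_labels(sym.m))
    )
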