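"""Permutation nulls by random re-pairing, and session-level comparisons.

The significance machinery asks whether pairs that actually played together
show more recurrence structure and information flow than pairs that never
met.  The null is built by randomly re-matching the 2N individual recordings
of one session into N artificial pairs (a uniform random perfect matching),
recomputing the metric for every artificial pair, and storing the mean; the
observed mean is compared against 20,000 such resampled means.  SRR and
recurrence entropy are tested two-sided, mutual information and transfer
entropy one-sided (upper), matching the direction of the scientific
hypothesis.  Between-session changes use a paired t-test and within-pair
consistency a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, StateError
from .information import (
    _joint_srr_entropy_batch,
    _mi_batch,
    _te_batch,
    dyad_metrics,
)
from .simulate import Cohort
from .symbolic import SymbolSeries, symbolize

__all__ = [
    "NullDistribution",
    "PermutationTestResult",
    "SessionComparison",
    "CohortTable",
    "repair_null",
    "permutation_test",
    "session_comparison",
    "build_cohort_table",
    "session_symbol_matrix",
    "METRIC_SIDEDNESS",
]

METRIC_SIDEDNESS = {"srr": "two", "entropy": "two", "mi": "one", "te": "one"}


@dataclass
class NullDistribution:
    """Resampled means of one metric for one session.

    ``samples[r]`` is the mean metric over the N artificial pairs (2N player
    values for transfer entropy) of resample ``r``; ``observed`` is the mean
    under the true pairing.
    """

    metric: str
    samples: np.ndarray
    observed: float
    sidedness: str
    session: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise StateError("null distribution has no samples")
        if not np.isfinite(self.observed):
            raise StateError("observed mean is not finite")

    @property
    def n_reps(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PermutationTestResult:
    metric: str
    session: Optional[int]
    observed: float
    p_value: float
    significant: bool
    sidedness: str
    n_reps: int
    null_lo: float  # 2.5th percentile
    null_median: float
    null_hi: float  # 97.5th percentile


def _codes_matrix(individuals: Sequence) -> np.ndarray:
    arrs = []
    for s in individuals:
        if isinstance(s, SymbolSeries):
            arrs.append(s.codes)
        else:
            arrs.append(symbolize(s).codes)
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise PairingError("individual series must all have the same length")
    return np.vstack(arrs)


def _pair_values(
    codes: np.ndarray, pairs: np.ndarray, metric: str, K: int, mode: str
) -> np.ndarray:
    a = codes[pairs[:, 0]]
    b = codes[pairs[:, 1]]
    if metric == "mi":
        return _mi_batch(a, b, K, mode)
    if metric == "srr":
        return _joint_srr_entropy_batch(a, b, K)[0]
    if metric == "entropy":
        return _joint_srr_entropy_batch(a, b, K)[1]
    if metric == "te":
        return np.concatenate(
            [_te_batch(a, b, K, mode), _te_batch(b, a, K, mode)]
        )
    raise ValueError(f"unknown metric {metric!r}")


def repair_null(
    individuals: Sequence,
    metric: str,
    n_reps: int = 20_000,
    seed: Optional[int] = None,
    mode: str = "literal",
    session: Optional[int] = None,
) -> NullDistribution:
    """Null distribution of the mean metric under random re-pairing.

    Parameters
    ----------
    individuals
        Per-player data for one session (symbol series, amplitude series or
        arrays), ordered so that elements ``2i`` and ``2i+1`` form true pair
        ``i``; the observed mean is computed from that pairing.
    metric
        One of ``srr``, ``entropy`` (joint pair-symbol recurrence of the
        dyad), ``mi``, or ``te`` (for which each artificial pair contributes
        both directions, 2N values).
    n_reps
        Number of random perfect matchings (20,000 by default).

    The original pairing is not excluded from the matchings; self-pairing is
    impossible because a matching never pairs an individual with itself.
    """
    if metric not in METRIC_SIDEDNESS:
        raise ValueError(f"metric must be one of {sorted(METRIC_SIDEDNESS)}")
    codes = _codes_matrix(individuals)
    n_ind = codes.shape[0]
    if n_ind % 2 or n_ind < 4:
        raise PairingError(f"need an even number (>= 4) of individuals, got {n_ind}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    K = int(codes.max()) + 1 if codes.size else 1
    K = max(K, 6)
    true_pairs = np.arange(n_ind).reshape(-1, 2)
    observed = float(_pair_values(codes, true_pairs, metric, K, mode).mean())
    rng = np.random.default_rng(seed)
    samples = np.empty(n_reps)
    for r in range(n_reps):
        pairs = rng.permutation(n_ind).reshape(-1, 2)
        samples[r] = _pair_values(codes, pairs, metric, K, mode).mean()
    return NullDistribution(
        metric=metric,
        samples=samples,
        observed=observed,
        sidedness=METRIC_SIDEDNESS[metric],
        session=session,
    )


def permutation_test(null: NullDistribution) -> PermutationTestResult:
    """Empirical p-value and the 95-percentile significance flag.

    One-sided (upper) p is the add-one estimator
    ``(1 + #{null >= observed}) / (n_reps + 1)``, never exactly zero; the
    two-sided p doubles the smaller tail and is capped at 1.  The boolean
    flag applies the percentile rule: observed above the 95th percentile
    (one-sided) or outside the 2.5–97.5 band (two-sided).
    """
    s = null.samples
    obs = null.observed
    R = null.n_reps
    ge = int(np.sum(s >= obs))
    le = int(np.sum(s <= obs))
    lo, med, hi = np.percentile(s, [2.5, 50.0, 97.5])
    if null.sidedness == "one":
        p = (1 + ge) / (R + 1)
        significant = obs > np.percentile(s, 95.0)
    else:
        p = min(1.0, 2.0 * min(1 + ge, 1 + le) / (R + 1))
        significant = (obs < lo) or (obs > hi)
    return PermutationTestResult(
        metric=null.metric,
        session=null.session,
        observed=obs,
        p_value=float(p),
        significant=bool(significant),
        sidedness=null.sidedness,
        n_reps=R,
        null_lo=float(lo),
        null_median=float(med),
        null_hi=float(hi),
    )


@dataclass
class CohortTable:
    """Metric tables for a whole cohort.

    ``pairs`` has one row per pair and session (srr, entropy, mi);
    ``players`` one row per player and session with the transfer entropy the
    focal player received from their partner, plus expertise columns when a
    participant table was supplied.
    """

    pairs: pd.DataFrame
    players: pd.DataFrame

    def values_by_session(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        """Aligned session-1 and session-2 value arrays for one metric."""
        df, unit = (
            (self.players, ["pair_id", "player_id"])
            if metric == "te"
            else (self.pairs, ["pair_id"])
        )
        col = "te" if metric == "te" else metric
        wide = df.pivot_table(index=unit, columns="session", values=col)
        if 1 not in wide.columns or 2 not in wide.columns:
            raise PairingError("both sessions are required for a comparison")
        if wide[[1, 2]].isna().any().any():
            raise PairingError("some units are missing a session value")
        return wide[1].to_numpy(float), wide[2].to_numpy(float)


@dataclass(frozen=True)
class SessionComparison:
    """Paired t-test and Pearson correlation between the two sessions."""

    metric: str
    n: int
    t: float
    df_t: int
    p_t: float
    r: float
    t_r: float
    df_r: int
    p_r: float
    degenerate: bool = False  # zero-variance difference: t undefined


def session_comparison(table: CohortTable, metric: str) -> SessionComparison:
    """Compare a metric between sessions and measure within-unit consistency.

    The t-test has ``N - 1`` degrees of freedom and the correlation
    ``N - 2``, with N the number of pairs (players for transfer entropy).
    """
    v1, v2 = table.values_by_session(metric)
    n = v1.size
    diff = v1 - v2
    degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
    if degenerate:
        t_stat, p_t = (0.0, float("nan")) if np.allclose(diff, 0) else (np.nan, np.nan)
    else:
        t_stat, p_t = stats.ttest_rel(v1, v2)
    r, p_r = stats.pearsonr(v1, v2)
    df_r = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_r = r * np.sqrt(df_r / (1.0 - r**2)) if abs(r) < 1 else np.inf
    return SessionComparison(
        metric=metric,
        n=n,
        t=float(t_stat),
        df_t=n - 1,
        p_t=float(p_t),
        r=float(r),
        t_r=float(t_r),
        df_r=df_r,
        p_r=float(p_r),
        degenerate=degenerate,
    )


def session_symbol_matrix(
    cohort: Cohort, session: int, m: int = 3
) -> tuple[list, np.ndarray]:
    """Symbolize every individual of one session, ordered by true pair.

    Returns ``(individual_ids, codes)`` where rows ``2i`` and ``2i+1`` of
    ``codes`` are the two players of pair ``i`` — the layout
    :func:`repair_null` expects.
    """
    ids, arrs = [], []
    for pair_id in cohort.pair_ids:
        dyad = cohort.dyads[(pair_id, session)]
        for player, series in (("a", dyad.series_a), ("b", dyad.series_b)):
            ids.append((pair_id, player))
            arrs.append(symbolize(series, m=m).codes)
    return ids, np.vstack(arrs)


def build_cohort_table(
    cohort: Cohort, m: int = 3, mode: str = "literal", lag: int = 1
) -> CohortTable:
    """Compute all pair- and player-level metrics for a synthetic cohort.

    The player rows carry the transfer entropy *received* by the focal
    player (partner -> focal) and, when the cohort has expertise records,
    the focal and partner Likert scores and years of practice.
    """
    pair_rows, player_rows = [], []
    expertise = cohort.participants.set_index(["pair_id", "player_id"])
    for (pair_id, session), dyad in sorted(cohort.dyads.items()):
        dm = dyad_metrics(
            dyad.series_a,
            dyad.series_b,
            m=m,
            mode=mode,
            lag=lag,
            pair_id=pair_id,
            session=session,
        )
        pair_rows.append(
            {
                "pair_id": pair_id,
                "session": session,
                "srr": dm.srr,
                "entropy": dm.entropy,
                "mi": dm.mi,
            }
        )
        received = {"a": dm.te_b_to_a, "b": dm.te_a_to_b}
        for focal, partner in (("a", "b"), ("b", "a")):
            row = {
                "pair_id": pair_id,
                "player_id": focal,
                "session": session,
                "te": received[focal],
            }
            if (pair_id, focal) in expertise.index:
                row["focal_collab"] = expertise.loc[(pair_id, focal), "likert"]
                row["focal_years"] = expertise.loc[(pair_id, focal), "years"]
                row["partner_collab"] = expertise.loc[(pair_id, partner), "likert"]
                row["partner_years"] = expertise.loc[(pair_id, partner), "years"]
            player_rows.append(row)
    pairs = pd.DataFrame(pair_rows)
    if not expertise.empty:
        likert = expertise["likert"].unstack()
        years = expertise["years"].unstack()
        extra = pd.DataFrame(
            {
                "pair_id": likert.index,
                "sum_collab": likert["a"].values + likert["b"].values,
                "diff_collab": np.abs(likert["a"].values - likert["b"].values),
                "sum_years": years["a"].values + years["b"].values,
                "diff_years": np.abs(years["a"].values - years["b"].values),
            }
        )
        pairs = pairs.merge(extra, on="pair_id", how="left")
    return CohortTable(pairs=pairs, players=pd.DataFrame(player_rows))
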