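"""End-to-end orchestration: ingest -> symbolize -> metrics -> nulls -> models.

``run_study`` takes a :class:`RunConfig` and either a data directory laid
out as ``pair<id>/session<1|2>/player<a|b>.{wav,csv}`` (with a
``participants.csv`` beside it) or a synthetic-cohort request, and produces
the full analysis bundle: cohort metric tables, null summaries, session
comparisons, model summaries, figures, and a manifest that pins the
configuration and seed so any output can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError
from .expertise import GlmTermTests, fit_mi_model, fit_te_model
from .figures import plot_null_panels, plot_recurrence
from .inference import (
    CohortTable,
    build_cohort_table,
    permutation_test,
    repair_null,
    session_comparison,
    session_symbol_matrix,
)
from .ingest import (
    AmplitudeSeries,
    downsample_amplitude,
    load_wav,
    read_amplitude_csv,
    trim_session,
    write_amplitude_csv,
)
from .simulate import Cohort, DyadSimConfig, SyntheticDyad, generate_cohort
from .symbolic import SymbolSeries, symbolize

logger = logging.getLogger("rhythmflow")

__all__ = ["RunConfig", "StudyResult", "run_study", "load_cohort", "write_simulated_cohort"]

METRICS = ("srr", "entropy", "mi", "te")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one analysis run.

    ``dt_s=0.15`` with ``m=3`` is the primary configuration; ``dt_s=0.10``
    (same m) and ``m=2`` (same dt) are the robustness alternatives.
    """

    dt_s: float = 0.15
    m: int = 3
    skip_head_s: float = 0.0
    aggregation: str = "max"
    n_reps: int = 20_000
    seed: int = 0
    mi_mode: str = "literal"
    lag: int = 1
    families: str = "both"
    n_pairs: int = 30
    n_sessions: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    config: RunConfig
    table: CohortTable
    null_summaries: pd.DataFrame
    nulls: list  # (NullDistribution, PermutationTestResult)
    comparisons: pd.DataFrame
    models: dict  # (response, session) -> GlmTermTests
    cohort: Cohort


def load_cohort(data_dir, config: RunConfig) -> Cohort:
    """Read a recorded cohort from the on-disk layout into a Cohort object."""
    root = Path(data_dir)
    part_path = root / "participants.csv"
    participants = (
        pd.read_csv(part_path)
        if part_path.exists()
        else pd.DataFrame(columns=["pair_id", "player_id", "likert", "years"])
    )
    dyads = {}
    pair_dirs = sorted(p for p in root.glob("pair*") if p.is_dir())
    if not pair_dirs:
        raise FormatError(f"no pair<id>/ directories found under {root}")
    for pair_dir in pair_dirs:
        for sess_dir in sorted(pair_dir.glob("session*")):
            session = int(sess_dir.name.removeprefix("session"))
            series = {}
            for player in "ab":
                candidates = list(sess_dir.glob(f"player{player}.*"))
                if not candidates:
                    raise FormatError(
                        f"missing player{player} file in {sess_dir}"
                    )
                path = candidates[0]
                ids = dict(
                    trial_id=pair_dir.name, player_id=player, session=session
                )
                if path.suffix == ".wav":
                    waveform, rate = load_wav(path)
                    s = downsample_amplitude(
                        waveform, rate, config.dt_s, config.aggregation, **ids
                    )
                elif path.suffix == ".csv":
                    s = read_amplitude_csv(path, dt_s=config.dt_s, **ids)
                else:
                    raise FormatError(f"unsupported file type: {path}")
                if config.skip_head_s > 0:
                    s = trim_session(s, config.skip_head_s)
                series[player] = s
            dyads[(pair_dir.name, session)] = SyntheticDyad(
                series_a=series["a"], series_b=series["b"], truth={}
            )
    n_sessions = max(s for _, s in dyads)
    truth = {pid: {} for pid, _ in dyads}
    return Cohort(
        participants=participants, dyads=dyads, truth=truth, n_sessions=n_sessions
    )


def run_study(
    config: RunConfig,
    data_dir=None,
    out_dir=None,
    simulate: bool = False,
) -> StudyResult:
    """Run the complete analysis and optionally write the output bundle."""
    t0 = time.time()
    if simulate:
        sim_cfg = DyadSimConfig(dt_s=config.dt_s)
        cohort = generate_cohort(
            config.n_pairs,
            seed=config.seed,
            config=sim_cfg,
            n_sessions=config.n_sessions,
        )
        logger.info("simulated cohort: %d pairs, %d sessions",
                    config.n_pairs, config.n_sessions)
    elif data_dir is not None:
        cohort = load_cohort(data_dir, config)
        logger.info("loaded cohort from %s: %d dyad-sessions",
                    data_dir, len(cohort.dyads))
    else:
        raise ValueError("either data_dir or simulate=True is required")

    table = build_cohort_table(cohort, m=config.m, mode=config.mi_mode, lag=config.lag)
    logger.info("metrics: %d pair rows, %d player rows (%.1fs)",
                len(table.pairs), len(table.players), time.time() - t0)

    seeds = np.random.SeedSequence([int(config.seed), 777]).generate_state(
        2 * len(METRICS) * cohort.n_sessions
    ) % (2**31 - 1)
    nulls = []
    rows = []
    k = 0
    for session in range(1, cohort.n_sessions + 1):
        _, codes = session_symbol_matrix(cohort, session, m=config.m)
        sym_list = [SymbolSeries(codes=c, m=config.m) for c in codes]
        for metric in METRICS:
            null = repair_null(
                sym_list,
                metric,
                n_reps=config.n_reps,
                seed=int(seeds[k]),
                mode=config.mi_mode,
                session=session,
            )
            k += 1
            test = permutation_test(null)
            nulls.append((null, test))
            rows.append(dataclasses.asdict(test))
    null_summaries = pd.DataFrame(rows)
    logger.info("nulls: %d distributions x %d reps (%.1fs)",
                len(nulls), config.n_reps, time.time() - t0)

    comp_rows = []
    if cohort.n_sessions >= 2:
        for metric in METRICS:
            comp_rows.append(dataclasses.asdict(session_comparison(table, metric)))
    comparisons = pd.DataFrame(comp_rows)

    models: dict = {}
    has_expertise = not cohort.participants.empty
    if has_expertise:
        for session in range(1, cohort.n_sessions + 1):
            try:
                models[("mi", session)] = fit_mi_model(
                    table.pairs, session=session, families=config.families
                )
                models[("te", session)] = fit_te_model(
                    table.players, session=session, families=config.families
                )
            except Exception as exc:
                logger.warning("model fit failed for session %d: %s", session, exc)

    result = StudyResult(
        config=config,
        table=table,
        null_summaries=null_summaries,
        nulls=nulls,
        comparisons=comparisons,
        models=models,
        cohort=cohort,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    logger.info("run complete in %.1fs", time.time() - t0)
    return result


def write_bundle(result: StudyResult, out_dir) -> None:
    """Write every table, the manifest and the figures of a finished run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    result.table.pairs.to_csv(out / "pair_metrics.csv", index=False,
                              float_format=float_fmt)
    result.table.players.to_csv(out / "player_metrics.csv", index=False,
                                float_format=float_fmt)
    result.null_summaries.to_csv(out / "null_summaries.csv", index=False,
                                 float_format=float_fmt)
    if not result.comparisons.empty:
        result.comparisons.to_csv(out / "session_comparisons.csv", index=False,
                                  float_format=float_fmt)
    for (response, session), fitted in result.models.items():
        items = fitted.items() if isinstance(fitted, dict) else [("", fitted)]
        for suffix, f in items:
            name = f"model_{response}_session{session}"
            name += f"_{suffix}" if suffix else ""
            f.terms.to_csv(out / f"{name}.csv", index=False, float_format=float_fmt)
    manifest = {
        "package_version": __version__,
        "config": result.config.as_dict(),
        "config_hash": result.config.config_hash,
        "n_pairs": len(result.cohort.pair_ids),
        "n_sessions": result.cohort.n_sessions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    make_figures(result, out)


def make_figures(result: StudyResult, out_dir) -> list[Path]:
    """Null-distribution panels plus one example recurrence plot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if result.nulls:
        path = out / "null_distributions.png"
        plot_null_panels(result.nulls, path=path)
        written.append(path)
    first = next(iter(sorted(result.cohort.dyads)))
    dyad = result.cohort.dyads[first]
    import matplotlib.pyplot as plt

    ax = plot_recurrence(symbolize(dyad.series_a, m=result.config.m))
    path = out / "recurrence_example.png"
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
    written.append(path)
    return written


def write_simulated_cohort(cohort: Cohort, out_dir) -> None:
    """Dump a synthetic cohort to the standard on-disk layout.

    Per dyad-session a CSV with columns t_index, amp_a, amp_b; plus
    participants.csv and truth.json at the root.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (pair_id, session), dyad in sorted(cohort.dyads.items()):
        d = out / pair_id / f"session{session}"
        d.mkdir(parents=True, exist_ok=True)
        write_amplitude_csv(dyad.series_a, d / "playera.csv")
        write_amplitude_csv(dyad.series_b, d / "playerb.csv")
        pd.DataFrame(
            {
                "t_index": np.arange(len(dyad.series_a)),
                "amp_a": dyad.series_a.values,
                "amp_b": dyad.series_b.values,
            }
        ).to_csv(d / "dyad.csv", index=False, float_format="%.10g")
    cohort.participants.to_csv(out / "participants.csv", index=False)
    truth = {
        pid: {k: v for k, v in t.items() if np.isscalar(v) or isinstance(v, str)}
        for pid, t in cohort.truth.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
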