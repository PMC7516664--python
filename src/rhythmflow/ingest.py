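"""Reading recordings and reducing them to amplitude envelopes.

The analysis operates on one non-negative sound-amplitude value per player
every ``dt_s`` seconds (150 ms by default, the order of an auditory reaction
time).  A two-minute trial at 150 ms therefore yields T = 800 samples.  This
module turns a raw PCM waveform (or a pre-extracted CSV) into that envelope:
the absolute waveform is aggregated over non-overlapping ``dt_s`` bins, with
the per-bin maximum as the default aggregate so that short percussive onsets
are never lost to point sampling; an RMS aggregate is available as an
alternative.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ChannelError, FormatError, LengthError

__all__ = [
    "AmplitudeSeries",
    "load_wav",
    "downsample_amplitude",
    "trim_session",
    "read_amplitude_csv",
    "write_amplitude_csv",
]


@dataclass(frozen=True)
class AmplitudeSeries:
    """A player's sound-amplitude envelope for one trial.

    Parameters
    ----------
    values
        Non-negative amplitudes, one per ``dt_s`` interval.
    dt_s
        Sampling interval in seconds (> 0).
    trial_id, player_id, session
        Optional identifiers carried through the pipeline.
    """

    values: np.ndarray
    dt_s: float
    trial_id: Optional[str] = None
    player_id: Optional[str] = None
    session: Optional[int] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise LengthError("amplitude series must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("amplitude series contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("amplitudes must be non-negative")
        if not (self.dt_s > 0):
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt_s


def load_wav(path: str | os.PathLike, channel: int = 0) -> tuple[np.ndarray, int]:
    """Read one channel of a PCM WAV file as float amplitudes in [-1, 1].

    Returns ``(waveform, native_rate)``.  Integer PCM (16/24/32-bit) is
    rescaled by its full-scale value; float WAV data is passed through.

    Raises
    ------
    FormatError
        If the file is not a readable PCM WAV.
    ChannelError
        If ``channel`` does not exist in the file.
    """
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"could not read WAV file {path!r}: {exc}") from exc

    if data.ndim == 1:
        n_channels = 1
        picked = data
        if channel != 0:
            raise ChannelError(f"mono file has no channel {channel}")
    else:
        n_channels = data.shape[1]
        if not (0 <= channel < n_channels):
            raise ChannelError(
                f"channel {channel} requested but file has {n_channels} channels"
            )
        picked = data[:, channel]

    if np.issubdtype(picked.dtype, np.integer):
        scale = float(np.iinfo(picked.dtype).max)
        waveform = picked.astype(float) / scale
    else:
        waveform = picked.astype(float)
    return waveform, int(rate)


def downsample_amplitude(
    waveform: np.ndarray,
    native_rate: float,
    dt_s: float = 0.15,
    method: str = "max",
    **ids,
) -> AmplitudeSeries:
    """Aggregate ``|waveform|`` over non-overlapping ``dt_s`` bins.

    ``method`` is ``"max"`` (default; maximum absolute amplitude per bin,
    preserving percussive onsets) or ``"rms"``.  A partial trailing bin is
    discarded, so the output has ``floor(duration / dt_s)`` samples.
    Additional keyword arguments (``trial_id`` etc.) are forwarded to the
    resulting :class:`AmplitudeSeries`.
    """
    w = np.abs(np.asarray(waveform, dtype=float))
    if w.ndim != 1 or w.size == 0:
        raise LengthError("waveform must be a non-empty 1-D array")
    bin_len = int(round(dt_s * native_rate))
    if bin_len < 1:
        raise ValueError(f"dt_s * native_rate must be >= 1, got {dt_s * native_rate}")
    n_bins = w.size // bin_len
    if n_bins < 1:
        raise LengthError(
            f"waveform of {w.size} samples is shorter than one {dt_s} s bin"
        )
    binned = w[: n_bins * bin_len].reshape(n_bins, bin_len)
    if method == "max":
        values = binned.max(axis=1)
    elif method == "rms":
        values = np.sqrt((binned**2).mean(axis=1))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return AmplitudeSeries(values=values, dt_s=dt_s, **ids)


def trim_session(series: AmplitudeSeries, skip_head_s: float) -> AmplitudeSeries:
    """Drop the leading ``floor(skip_head_s / dt_s)`` samples.

    Used to exclude an initial backing-track segment from a session.  The
    default pipeline keeps the full trial; trimming is opt-in.
    """
    if skip_head_s < 0:
        raise ValueError("skip_head_s must be non-negative")
    k = int(np.floor(skip_head_s / series.dt_s))
    if k >= len(series):
        raise LengthError(
            f"cannot skip {skip_head_s} s from a {series.duration_s} s series"
        )
    return replace(series, values=series.values[k:])


def read_amplitude_csv(path: str | os.PathLike, dt_s: float, **ids) -> AmplitudeSeries:
    """Read a pre-extracted envelope from a CSV with columns t_index, amplitude."""
    df = pd.read_csv(path)
    if "amplitude" not in df.columns:
        raise FormatError(f"{path!r} has no 'amplitude' column")
    if "t_index" in df.columns:
        df = df.sort_values("t_index")
    return AmplitudeSeries(values=df["amplitude"].to_numpy(float), dt_s=dt_s, **ids)


def write_amplitude_csv(series: AmplitudeSeries, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"t_index": np.arange(len(series)), "amplitude": series.values}
    ).to_csv(path, index=False)
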