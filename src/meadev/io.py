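"""Reading, writing and quality control of MEA spike-time recordings.

A recording is one dish observed on one day in vitro (DIV): per-channel
vectors of spike times in seconds over a fixed duration (nominally 300 s on
a 60-electrode array).  The on-disk format is a plain TSV with ``#`` metadata
comment lines followed by a ``channel<TAB>time_s`` table.

Quality control mirrors standard dish-acceptance practice for developing
cultures: a channel is *active* above 3 spikes/min; a dish is kept only if it
has an acceptable first-week recording (DIV 6-8) plus at least one later
recording (DIV 9-18), each with enough active channels, no excess of
noise-flagged channels, and no collapse (>50 % drop) of network-spike
activity during the second week.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: spike times are quantized to a 25 kHz sampling grid
TIME_QUANTUM_S = 4e-5

#: the three developmental stages used throughout: first week, second week,
#: third week in vitro (inclusive DIV ranges)
DEFAULT_INTERVALS: tuple[tuple[int, int], ...] = ((6, 8), (9, 12), (13, 18))


class ParseError(ValueError):
    """Raised when a spike-time TSV is malformed; message names the line."""


@dataclasses.dataclass
class Recording:
    """One dish x one DIV set of per-channel spike trains.

    Parameters
    ----------
    dish_id : str
        Identifier of the culture dish (MEA).
    div : int
        Day in vitro of the recording.
    duration_s : float
        Recording length in seconds.
    spikes : dict[int, numpy.ndarray]
        Sorted spike times (s) keyed by 1-based channel id.  Channels with
        no spikes may be omitted.
    n_channels : int
        Number of electrodes on the array.
    excluded_channels : tuple[int, ...]
        Channels flagged as noise upstream (no waveforms are carried here,
        so the flag is metadata).  Excluded channels never count as active.
    """

    dish_id: str
    div: int
    duration_s: float
    spikes: dict[int, np.ndarray]
    n_channels: int = 60
    excluded_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.div < 0:
            raise ValueError(f"div must be >= 0, got {self.div}")
        clean: dict[int, np.ndarray] = {}
        for ch, times in sorted(self.spikes.items()):
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(
                    f"channel {ch}: spike times outside [0, {self.duration_s}]"
                )
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"channel {ch}: spike times not strictly increasing")
            clean[ch] = t
        self.spikes = clean

    @property
    def channel_ids(self) -> list[int]:
        return sorted(self.spikes)

    def train(self, channel: int) -> np.ndarray:
        """Spike times of one channel (empty array if it never fired)."""
        return self.spikes.get(channel, np.empty(0))

    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))


@dataclasses.dataclass(frozen=True)
class QCConfig:
    """Recording/dish acceptance thresholds.

    ``min_rate_spikes_per_min`` is a strict lower bound (a channel at exactly
    3 spikes/min is inactive).  ``max_second_week_drop`` bounds the relative
    decrease of network-spike rate between consecutive second-week
    recordings.
    """

    min_rate_spikes_per_min: float = 3.0
    min_active_channels: int = 10
    max_noise_channels: int = 6
    max_second_week_drop: float = 0.5
    # calendar second week in vitro, inclusive, for the drop rule
    second_week_divs: tuple[int, int] = (8, 14)

    def __post_init__(self) -> None:
        if self.min_rate_spikes_per_min < 0 or self.min_active_channels < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_second_week_drop <= 1.0:
            raise ValueError("max_second_week_drop must be in [0, 1]")


def channel_is_active(
    spike_times: np.ndarray, duration_s: float, qc: QCConfig | None = None
) -> bool:
    """True iff the train fires strictly more than ``min_rate_spikes_per_min``."""
    qc = qc or QCConfig()
    t = np.asarray(spike_times)
    return t.size / (duration_s / 60.0) > qc.min_rate_spikes_per_min


def active_channels(rec: Recording, qc: QCConfig | None = None) -> list[int]:
    """Channel ids passing the activity criterion, excluding noise channels."""
    qc = qc or QCConfig()
    excl = set(rec.excluded_channels)
    return [
        ch
        for ch, t in sorted(rec.spikes.items())
        if ch not in excl and channel_is_active(t, rec.duration_s, qc)
    ]


# ---------------------------------------------------------------------------
# TSV I/O


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a spike-time TSV with metadata comment lines."""
    path = Path(path)
    lines = [
        f"# dish={rec.dish_id}",
        f"# div={rec.div}",
        f"# duration_s={rec.duration_s:g}",
        f"# n_channels={rec.n_channels}",
    ]
    if rec.excluded_channels:
        lines.append(
            "# excluded_channels=" + ",".join(str(c) for c in rec.excluded_channels)
        )
    lines.append("channel\ttime_s")
    for ch in rec.channel_ids:
        for t in rec.spikes[ch]:
            lines.append(f"{ch}\t{t:.5f}")
    path.write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path) -> Recording:
    """Parse a spike-time TSV written by :func:`write_recording`.

    Raises :class:`ParseError` naming the offending line for malformed
    headers, unsorted times or times outside ``[0, duration_s]``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    spikes: dict[int, list[float]] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ParseError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["channel", "time_s"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'channel\\ttime_s', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                ch = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            spikes.setdefault(ch, []).append(t)

    for key in ("dish", "div", "duration_s"):
        if key not in meta:
            raise ParseError(f"{path}: missing metadata line '# {key}=...'")
    duration = float(meta["duration_s"])
    for ch, ts in spikes.items():
        arr = np.asarray(ts)
        if arr.size and (arr.min() < 0 or arr.max() > duration):
            raise ParseError(
                f"{path}: channel {ch} has spike time outside [0, {duration}]"
            )
        if np.any(np.diff(arr) <= 0):
            raise ParseError(f"{path}: channel {ch} spike times not strictly increasing")
    excluded: tuple[int, ...] = ()
    if meta.get("excluded_channels"):
        excluded = tuple(int(c) for c in meta["excluded_channels"].split(","))
    return Recording(
        dish_id=meta["dish"],
        div=int(meta["div"]),
        duration_s=duration,
        spikes={ch: np.asarray(ts) for ch, ts in spikes.items()},
        n_channels=int(meta.get("n_channels", 60)),
        excluded_channels=excluded,
    )


def read_cohort(directory: str | Path) -> list[Recording]:
    """Read every ``*.tsv`` recording in a directory."""
    return [read_recording(p) for p in sorted(Path(directory).glob("*.tsv"))]


# ---------------------------------------------------------------------------
# Quality control


def apply_qc(
    recordings: Sequence[Recording], qc: QCConfig | None = None
) -> tuple[list[Recording], list[str]]:
    """Apply dish-level acceptance rules to one dish's recordings.

    Returns the kept recordings and a log of rejection reasons.  The dish is
    kept only if, among recordings with at least ``min_active_channels``
    active channels, there is one at DIV 6-8 and one at DIV 9-18; recordings
    with too many noise channels reject the whole dish, and a drop of
    network-spike rate larger than ``max_second_week_drop`` between
    consecutive second-week recordings also rejects it.
    """
    from .bursts import network_spike_rate  # deferred: avoids module cycle

    qc = qc or QCConfig()
    log: list[str] = []
    if not recordings:
        return [], ["no recordings"]
    dish = recordings[0].dish_id
    if any(r.dish_id != dish for r in recordings):
        raise ValueError("apply_qc expects recordings from a single dish")

    for rec in recordings:
        if len(rec.excluded_channels) > qc.max_noise_channels:
            log.append(
                f"{dish}: rejected, DIV {rec.div} has "
                f"{len(rec.excluded_channels)} noise channels (> {qc.max_noise_channels})"
            )
            return [], log

    ok: list[Recording] = []
    for rec in sorted(recordings, key=lambda r: r.div):
        n_act = len(active_channels(rec, qc))
        if n_act < qc.min_active_channels:
            log.append(
                f"{dish}: dropped DIV {rec.div} recording, only {n_act} active channels"
            )
        else:
            ok.append(rec)

    has_week1 = any(6 <= r.div <= 8 for r in ok)
    has_later = any(9 <= r.div <= 18 for r in ok)
    if not has_week1:
        log.append(f"{dish}: rejected, missing acceptable DIV 6-8 recording")
        return [], log
    if not has_later:
        log.append(f"{dish}: rejected, missing 9-18 recording")
        return [], log

    lo, hi = qc.second_week_divs
    week2 = [r for r in ok if lo <= r.div <= hi]
    for prev, cur in zip(week2, week2[1:]):
        r_prev = network_spike_rate(prev, qc=qc)
        r_cur = network_spike_rate(cur, qc=qc)
        if r_prev > 0 and (r_prev - r_cur) / r_prev > qc.max_second_week_drop:
            log.append(
                f"{dish}: rejected, network spike rate dropped "
                f"{100 * (r_prev - r_cur) / r_prev:.0f}% from DIV {prev.div} to {cur.div}"
            )
            return [], log
    return ok, log


def apply_qc_cohort(
    recordings: Iterable[Recording], qc: QCConfig | None = None
) -> tuple[list[Recording], list[str]]:
    """Group recordings by dish and apply :func:`apply_qc` per dish."""
    by_dish: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_dish.setdefault(rec.dish_id, []).append(rec)
    kept: list[Recording] = []
    log: list[str] = []
    for dish in sorted(by_dish):
        k, l = apply_qc(by_dish[dish], qc)
        kept.extend(k)
        log.extend(l)
    return kept, log


# ---------------------------------------------------------------------------
# Trajectory aggregation


def interval_of(div: int, intervals: Sequence[tuple[int, int]] = DEFAULT_INTERVALS):
    """Index of the DIV interval containing ``div`` (None if outside all)."""
    for i, (lo, hi) in enumerate(intervals):
        if lo <= div <= hi:
            return i
    return None


def aggregate_trajectories(
    features: pd.DataFrame,
    intervals: Sequence[tuple[int, int]] = DEFAULT_INTERVALS,
) -> pd.DataFrame:
    """Per-dish, per-interval arithmetic means of the feature table.

    ``features`` has one row per recording with columns ``dish``, ``div`` and
    the feature columns.  Returns a long-format frame indexed by
    ``(dish, interval)``; intervals without any recording are absent.
    Missing (NaN) feature cells are ignored in the means.
    """
    feat_cols = [c for c in features.columns if c not in ("dish", "div")]
    df = features.copy()
    df["interval"] = [interval_of(d, intervals) for d in df["div"]]
    df = df[df["interval"].notna()]
    out = (
        df.groupby(["dish", "interval"], sort=True)[feat_cols]
        .mean()
        .reset_index()
    )
    out["interval"] = out["interval"].astype(int)
    return out
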