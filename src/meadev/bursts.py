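"""Max-interval burst detection and spike/burst-level features.

Bursts are detected per channel with the max-interval method: a burst opens
at the first inter-spike interval (ISI) at or below ``max_begin_isi_s``,
extends while ISIs stay at or below ``max_end_isi_s``, candidates closer than
``min_ibi_s`` are merged, and candidates shorter than ``min_burst_dur_s`` or
with fewer than ``min_spikes`` spikes are discarded.

Network spikes (near-simultaneous firing across many channels) and network
bursts (overlapping per-channel bursts across many channels) are counted as
maximal supra-threshold runs; the fraction-of-channels thresholds are
configurable because the original analysis software does not publish its
definitions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .io import QCConfig, Recording, active_channels


@dataclasses.dataclass(frozen=True)
class BurstConfig:
    max_begin_isi_s: float = 0.1
    max_end_isi_s: float = 0.2
    min_ibi_s: float = 0.2
    min_burst_dur_s: float = 0.003
    min_spikes: int = 3

    def __post_init__(self) -> None:
        if min(
            self.max_begin_isi_s,
            self.max_end_isi_s,
            self.min_ibi_s,
            self.min_burst_dur_s,
        ) <= 0 or self.min_spikes <= 0:
            raise ValueError("all burst parameters must be positive")
        if self.max_begin_isi_s > self.max_end_isi_s:
            raise ValueError("max_begin_isi_s must not exceed max_end_isi_s")


@dataclasses.dataclass
class Burst:
    """One detected burst on one channel."""

    channel: int
    t_start: float
    t_end: float
    spike_times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclasses.dataclass(frozen=True)
class NetworkEventConfig:
    """Thresholds for network spikes and network bursts.

    A network spike requires spikes from at least ``ceil(ns_frac * n_active)``
    distinct active channels inside ``ns_window_s`` bins; a network burst
    requires at least ``max(2, ceil(nb_frac * n_bursting))`` channels with an
    ongoing burst.
    """

    ns_window_s: float = 0.1
    ns_frac: float = 0.25
    nb_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.ns_window_s <= 0:
            raise ValueError("ns_window_s must be positive")
        if not (0 < self.ns_frac <= 1 and 0 < self.nb_frac <= 1):
            raise ValueError("fractions must be in (0, 1]")


def detect_bursts_max_interval(
    spike_times: np.ndarray, cfg: BurstConfig | None = None, channel: int = 0
) -> list[Burst]:
    """Detect bursts on a single sorted spike train (max-interval method)."""
    cfg = cfg or BurstConfig()
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return []
    isi = np.diff(t)

    # candidate detection: open at ISI <= max_begin, extend while <= max_end
    candidates: list[tuple[int, int]] = []  # inclusive spike index ranges
    i = 0
    n = t.size
    while i < n - 1:
        if isi[i] <= cfg.max_begin_isi_s:
            j = i + 1
            while j < n - 1 and isi[j] <= cfg.max_end_isi_s:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1

    # merge candidates separated by a gap shorter than min_ibi
    merged: list[tuple[int, int]] = []
    for start, end in candidates:
        if merged and t[start] - t[merged[-1][1]] < cfg.min_ibi_s:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    bursts = []
    for start, end in merged:
        n_spk = end - start + 1
        dur = t[end] - t[start]
        if n_spk >= cfg.min_spikes and dur >= cfg.min_burst_dur_s:
            bursts.append(Burst(channel, t[start], t[end], t[start : end + 1]))
    return bursts


def detect_bursts(
    rec: Recording, cfg: BurstConfig | None = None, qc: QCConfig | None = None
) -> dict[int, list[Burst]]:
    """Bursts per active channel of a recording."""
    qc = qc or QCConfig()
    return {
        ch: detect_bursts_max_interval(rec.train(ch), cfg, channel=ch)
        for ch in active_channels(rec, qc)
    }


# ---------------------------------------------------------------------------
# spike-level features


def spike_features(
    rec: Recording, qc: QCConfig | None = None
) -> dict[str, float]:
    """``ch_spikes`` (active channel count), ``mfr`` (Hz) and ``isi`` (s).

    MFR is the mean over active channels of count/duration; ISI is the mean
    over active channels with >= 2 spikes of their mean ISI.  With no active
    channels the rates are 0 and ISI is NaN (missing).
    """
    qc = qc or QCConfig()
    act = active_channels(rec, qc)
    if not act:
        return {"ch_spikes": 0.0, "mfr": 0.0, "isi": math.nan}
    rates = [rec.train(ch).size / rec.duration_s for ch in act]
    isis = [float(np.mean(np.diff(rec.train(ch)))) for ch in act if rec.train(ch).size >= 2]
    return {
        "ch_spikes": float(len(act)),
        "mfr": float(np.mean(rates)),
        "isi": float(np.mean(isis)) if isis else math.nan,
    }


# ---------------------------------------------------------------------------
# burst-level features


def poisson_surprise(n_spikes: int, duration_s: float, rate_hz: float) -> float:
    """Poisson surprise S = -ln P(X >= n) with X ~ Poisson(rate * duration)."""
    mu = rate_hz * duration_s
    # sf(n-1) = P(X >= n); logsf keeps precision for extreme tails
    return float(-stats.poisson.logsf(n_spikes - 1, mu))


def burst_features(
    bursts_by_channel: dict[int, list[Burst]],
    rec: Recording,
    qc: QCConfig | None = None,
) -> dict[str, float]:
    """The 8 per-recording burst statistics.

    Means are taken over channels (for MBR) or over bursts (for duration,
    intra-burst ISI, peak frequency, surprise), never spike-weighted.  With
    zero bursts all burst statistics are NaN and ``ch_bursts`` is 0.
    """
    qc = qc or QCConfig()
    all_bursts = [b for bs in bursts_by_channel.values() for b in bs]
    bursting = {ch: bs for ch, bs in bursts_by_channel.items() if bs}
    out: dict[str, float] = {"ch_bursts": float(len(bursting))}
    if not all_bursts:
        for key in (
            "mbr",
            "burst_duration",
            "ibi",
            "burst_pct_spikes",
            "burst_isi",
            "burst_peakfreq",
            "burst_surprise",
        ):
            out[key] = math.nan
        return out

    minutes = rec.duration_s / 60.0
    out["mbr"] = float(np.mean([len(bs) / minutes for bs in bursting.values()]))
    out["burst_duration"] = float(np.mean([b.duration for b in all_bursts]))

    gaps = []
    for bs in bursting.values():
        for prev, cur in zip(bs, bs[1:]):
            gaps.append(cur.t_start - prev.t_end)
    out["ibi"] = float(np.mean(gaps)) if gaps else math.nan

    act = active_channels(rec, qc)
    total_spikes = sum(rec.train(ch).size for ch in act)
    in_bursts = sum(b.n_spikes for b in all_bursts)
    out["burst_pct_spikes"] = (
        100.0 * in_bursts / total_spikes if total_spikes else math.nan
    )

    isis = [np.diff(b.spike_times) for b in all_bursts]
    out["burst_isi"] = float(np.mean([np.mean(i) for i in isis]))
    out["burst_peakfreq"] = float(np.mean([np.max(1.0 / i) for i in isis]))

    surprises = []
    for ch, bs in bursting.items():
        rate = rec.train(ch).size / rec.duration_s
        for b in bs:
            surprises.append(poisson_surprise(b.n_spikes, b.duration, rate))
    out["burst_surprise"] = float(np.mean(surprises))
    return out


# ---------------------------------------------------------------------------
# network events


def network_spike_rate(
    rec: Recording,
    cfg: NetworkEventConfig | None = None,
    qc: QCConfig | None = None,
) -> float:
    """Network spikes per second.

    The recording is partitioned into ``ns_window_s`` bins; a network spike is
    a maximal run of bins in which at least ``ceil(ns_frac * n_active)``
    distinct active channels fire.
    """
    cfg = cfg or NetworkEventConfig()
    qc = qc or QCConfig()
    act = active_channels(rec, qc)
    if not act:
        return 0.0
    n_bins = int(math.ceil(rec.duration_s / cfg.ns_window_s))
    counts = np.zeros(n_bins, dtype=int)
    for ch in act:
        t = rec.train(ch)
        if t.size:
            bins = np.minimum((t / cfg.ns_window_s).astype(int), n_bins - 1)
            counts[np.unique(bins)] += 1
    thr = math.ceil(cfg.ns_frac * len(act))
    above = counts >= thr
    # count maximal runs of True
    n_events = int(np.sum(above & ~np.concatenate(([False], above[:-1]))))
    return n_events / rec.duration_s


def network_burst_rate(
    bursts_by_channel: dict[int, list[Burst]],
    rec: Recording,
    cfg: NetworkEventConfig | None = None,
) -> float:
    """Network bursts per minute.

    Burst intervals from all channels are overlaid; a network burst is a
    maximal interval during which at least ``max(2, ceil(nb_frac *
    n_bursting_channels))`` channels have an ongoing burst.
    """
    cfg = cfg or NetworkEventConfig()
    bursting = [ch for ch, bs in bursts_by_channel.items() if bs]
    if not bursting:
        return 0.0
    thr = max(2, math.ceil(cfg.nb_frac * len(bursting)))
    events: list[tuple[float, int]] = []
    for bs in bursts_by_channel.values():
        for b in bs:
            events.append((b.t_start, 1))
            events.append((b.t_end, -1))
    # at equal times, process starts before ends so touching bursts overlap
    events.sort(key=lambda e: (e[0], -e[1]))
    depth = 0
    n_events = 0
    above = False
    for _, delta in events:
        depth += delta
        if depth >= thr and not above:
            n_events += 1
            above = True
        elif depth < thr:
            above = False
    return n_events / (rec.duration_s / 60.0)
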