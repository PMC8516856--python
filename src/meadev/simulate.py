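"""Seeded synthetic cohorts of developing MEA recordings.

The generator emulates the development of spontaneous activity in dense
cortical cultures: sparse quasi-Poisson firing in the first week in vitro
that evolves toward synchronized network bursting by the third week.  Each
channel of a recording is the superposition of

* homogeneous Poisson background firing at ``lambda_bg`` Hz on the
  ``n_active`` active channels, and
* network events arriving as a Poisson process at ``nu_nb`` events/min; each
  event independently recruits every active channel with probability
  ``p_part``; a recruited channel emits a burst of ~``burst_len`` spikes with
  exponential intra-burst ISIs (mean ``intra_isi_ms``) starting at the event
  time plus Gaussian per-channel onset jitter.

Three developmental archetypes provide a recoverable ground truth for the
clustering stage: (1) early-synchronized, burst-rich networks, (2) networks
whose synchrony emerges late, and (3) persistently sparse networks.  Each
dish additionally draws a latent *maturity* factor; its third-week value is a
monotone (identity) function of the first-week value plus Gaussian noise of
s.d. ``noise_link``, which makes third-week features predictable from
first-week features by construction.

Spike times are rounded to the 0.04 ms grid of a 25 kHz acquisition system;
duplicates within a channel are coalesced.  All randomness flows from a
single integer seed through counter-based substreams (one per dish/DIV/
channel), so cohorts are bit-identical across runs and independent of
iteration order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TIME_QUANTUM_S, Recording, write_recording

DIV_LO, DIV_HI = 6, 18


def _interp(anchors: tuple[float, float], div: float) -> float:
    """Linear interpolation between the DIV-6 and DIV-18 anchor values."""
    frac = (min(max(div, DIV_LO), DIV_HI) - DIV_LO) / (DIV_HI - DIV_LO)
    return anchors[0] + frac * (anchors[1] - anchors[0])


@dataclasses.dataclass(frozen=True)
class ArchetypeParams:
    """Developmental parameter trajectories of one archetype (or one dish).

    Rate-like parameters are given as ``(value at DIV 6, value at DIV 18)``
    anchor pairs and interpolated linearly in between; ``burst_len``,
    ``intra_isi_ms`` and ``jitter_ms`` are constant across development.
    """

    label: int
    lambda_bg: tuple[float, float]  # background rate per channel, Hz
    nu_nb: tuple[float, float]  # network-event rate, events/min
    p_part: tuple[float, float]  # per-channel recruitment probability
    n_active: tuple[float, float]  # active channel count
    burst_len: float = 8.0  # mean within-burst spike count
    intra_isi_ms: float = 20.0  # mean intra-burst ISI
    jitter_ms: float = 5.0  # s.d. of burst-onset jitter

    def __post_init__(self) -> None:
        for name in ("lambda_bg", "nu_nb"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not all(0.0 <= p <= 1.0 for p in self.p_part):
            raise ValueError("p_part must be in [0, 1]")
        if min(self.n_active) < 0:
            raise ValueError("n_active must be non-negative")
        if self.burst_len < 1 or self.intra_isi_ms <= 0 or self.jitter_ms < 0:
            raise ValueError("invalid burst shape parameters")

    def at(self, div: float) -> dict[str, float]:
        """Effective parameter values on one day in vitro."""
        return {
            "lambda_bg": _interp(self.lambda_bg, div),
            "nu_nb": _interp(self.nu_nb, div),
            "p_part": float(np.clip(_interp(self.p_part, div), 0.0, 1.0)),
            "n_active": float(_interp(self.n_active, div)),
        }

    def scaled(self, m_early: float, m_late: float, n_channels: int) -> "ArchetypeParams":
        """Dish-level copy with rate anchors scaled by the maturity factors.

        Maturity scales the firing/event rates and the active-channel count;
        the recruitment probability is an archetype property and is left
        unscaled (synchrony depth is a network-type trait, its timing a
        maturity trait).
        """

        def sc(anchors, lo=0.0, hi=math.inf):
            return (
                float(np.clip(anchors[0] * m_early, lo, hi)),
                float(np.clip(anchors[1] * m_late, lo, hi)),
            )

        return dataclasses.replace(
            self,
            lambda_bg=sc(self.lambda_bg),
            nu_nb=sc(self.nu_nb),
            n_active=sc(self.n_active, hi=float(n_channels)),
        )


#: default archetypes: (1) early-synchronized high-burst, (2) late-emerging
#: synchrony, (3) persistently sparse
DEFAULT_ARCHETYPES: tuple[ArchetypeParams, ...] = (
    ArchetypeParams(1, lambda_bg=(0.5, 0.6), nu_nb=(20.0, 40.0), p_part=(0.75, 0.95), n_active=(40, 55)),
    ArchetypeParams(2, lambda_bg=(0.3, 1.2), nu_nb=(4.0, 30.0), p_part=(0.3, 0.85), n_active=(25, 48)),
    ArchetypeParams(3, lambda_bg=(0.25, 0.6), nu_nb=(2.0, 8.0), p_part=(0.25, 0.4), n_active=(18, 28)),
)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    n_dishes: int = 60
    n_channels: int = 60
    duration_s: float = 300.0
    div_schedule: tuple[int, ...] = (6, 8, 10, 13, 16, 18)
    archetype_mix: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    archetypes: tuple[ArchetypeParams, ...] = DEFAULT_ARCHETYPES
    maturity_sd: float = 0.08  # dish-to-dish spread of the latent maturity
    noise_link: float = 0.05  # s.d. of the early -> late maturity noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dishes < 1:
            raise ValueError("n_dishes must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(self.archetype_mix) != len(self.archetypes):
            raise ValueError("archetype_mix and archetypes lengths differ")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")


def _substream(*key: int) -> np.random.Generator:
    """Counter-based RNG substream: reproducible regardless of call order."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _quantize(times: np.ndarray, duration_s: float) -> np.ndarray:
    """Round to the sampling grid, keep in-range times, coalesce duplicates."""
    t = np.round(times / TIME_QUANTUM_S) * TIME_QUANTUM_S
    t = t[(t >= 0.0) & (t <= duration_s)]
    return np.unique(t)


def simulate_recording(
    params: ArchetypeParams,
    div: int,
    duration_s: float = 300.0,
    n_channels: int = 60,
    seed: int = 0,
    dish_id: str = "dish",
) -> Recording:
    """Simulate one recording of one dish on one day in vitro."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    eff = params.at(div)
    n_active = int(round(min(eff["n_active"], n_channels)))
    lam = eff["lambda_bg"]
    nu_s = eff["nu_nb"] / 60.0  # events per second
    p_part = eff["p_part"]
    intra_isi_s = params.intra_isi_ms / 1000.0
    jitter_s = params.jitter_ms / 1000.0

    # network events: one substream for the event process, one per event
    rng_ev = _substream(seed, 0)
    n_events = rng_ev.poisson(nu_s * duration_s)
    event_times = np.sort(rng_ev.uniform(0.0, duration_s, size=n_events))

    per_channel: dict[int, list[np.ndarray]] = {ch: [] for ch in range(1, n_active + 1)}
    for k, t_ev in enumerate(event_times):
        rng = _substream(seed, 1, k)
        recruited = rng.random(n_active) < p_part
        for idx in np.nonzero(recruited)[0]:
            onset = t_ev + rng.normal(0.0, jitter_s)
            n_spk = 1 + rng.poisson(params.burst_len - 1.0)
            isis = rng.exponential(intra_isi_s, size=n_spk - 1)
            per_channel[idx + 1].append(onset + np.concatenate(([0.0], np.cumsum(isis))))

    spikes: dict[int, np.ndarray] = {}
    for ch in range(1, n_active + 1):
        rng_bg = _substream(seed, 2, ch)
        n_bg = rng_bg.poisson(lam * duration_s)
        parts = per_channel[ch] + [rng_bg.uniform(0.0, duration_s, size=n_bg)]
        t = _quantize(np.concatenate(parts), duration_s)
        if t.size:
            spikes[ch] = t
    return Recording(dish_id, div, duration_s, spikes, n_channels=n_channels)


def _archetype_assignment(cfg: CohortConfig) -> list[int]:
    """Deterministic dish -> archetype index by largest-remainder rounding."""
    raw = [p * cfg.n_dishes for p in cfg.archetype_mix]
    counts = [int(math.floor(x)) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(cfg.n_dishes - sum(counts)):
        counts[rema[i % len(rema)]] += 1
    out: list[int] = []
    for i, c in enumerate(counts):
        out.extend([i] * c)
    return out[: cfg.n_dishes]


def _derive_seed(*key: int) -> int:
    """Deterministic 31-bit child seed from a key tuple."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(cfg: CohortConfig) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a cohort of dishes; returns recordings and a truth table.

    The truth table has one row per dish and DIV with the archetype label,
    the early/late maturity factors and the effective generative parameters.
    """
    assignment = _archetype_assignment(cfg)
    recordings: list[Recording] = []
    truth_rows = []
    for d, arch_idx in enumerate(assignment):
        dish_id = f"D{d + 1:03d}"
        arch = cfg.archetypes[arch_idx]
        rng = _substream(cfg.seed, 100, d)
        m_early = float(np.clip(rng.normal(1.0, cfg.maturity_sd), 0.7, 1.3))
        m_late = float(np.clip(m_early + rng.normal(0.0, cfg.noise_link), 0.7, 1.3))
        dish_params = arch.scaled(m_early, m_late, cfg.n_channels)
        for div in cfg.div_schedule:
            rec_seed = _derive_seed(cfg.seed, d, div)
            recordings.append(
                simulate_recording(
                    dish_params, div, cfg.duration_s, cfg.n_channels, rec_seed, dish_id
                )
            )
            eff = dish_params.at(div)
            truth_rows.append(
                {
                    "dish": dish_id,
                    "archetype": arch.label,
                    "div": div,
                    "m_early": m_early,
                    "m_late": m_late,
                    **eff,
                }
            )
    return recordings, pd.DataFrame(truth_rows)


def write_cohort(
    recordings: Sequence[Recording],
    truth: pd.DataFrame,
    cfg: CohortConfig,
    out_dir: str | Path,
) -> None:
    """Write recordings as TSVs plus ``truth.csv`` and ``config.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / f"{rec.dish_id}_div{rec.div:02d}.tsv")
    truth.to_csv(out / "truth.csv", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["archetypes"] = [dataclasses.asdict(a) for a in cfg.archetypes]
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2, default=list))
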