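"""Pairwise spike-train synchrony: STTC and density-based electrode clusters.

The spike time tiling coefficient (STTC) of trains A and B is

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) ]

where ``P_A`` is the proportion of A's spikes falling within +-dt of some
spike of B, and ``T_A`` the proportion of recording time tiled by the +-dt
windows around A's spikes (exact interval union, clipped to the recording).
STTC is rate-robust and lies in [-1, 1]; pairs involving an empty train are
assigned 0 ("no measurable correlation") by convention.

Highly synchronized electrode groups are counted by DBSCAN on the distance
matrix d = 1 - STTC, so eps = 0.2 groups electrode pairs with STTC > 0.8.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from sklearn.cluster import DBSCAN

from .io import QCConfig, Recording, active_channels


@dataclasses.dataclass(frozen=True)
class STTCConfig:
    dt_s: float = 0.1
    dbscan_eps: float = 0.2
    dbscan_min_samples: int = 3
    #: if True, a point counts toward its own eps-neighborhood when deciding
    #: core status (the sklearn convention); if False, ``dbscan_min_samples``
    #: neighbors are required besides the point itself.
    min_samples_includes_self: bool = False

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not 0 < self.dbscan_eps < 2:
            raise ValueError("dbscan_eps must be in (0, 2)")
        if self.dbscan_min_samples < 1:
            raise ValueError("dbscan_min_samples must be >= 1")


def tiled_fraction(train: np.ndarray, dt_s: float, duration_s: float) -> float:
    """Fraction of [0, duration] covered by the union of +-dt windows."""
    t = np.asarray(train, dtype=float)
    if t.size == 0:
        return 0.0
    starts = np.clip(t - dt_s, 0.0, duration_s)
    ends = np.clip(t + dt_s, 0.0, duration_s)
    # trains are sorted, so clipped interval ends are non-decreasing and the
    # union length is the sum of each interval minus its overlap with the
    # previous one
    prev_ends = np.concatenate(([-np.inf], ends[:-1]))
    covered = np.sum(np.maximum(0.0, ends - np.maximum(starts, prev_ends)))
    return float(covered / duration_s)


def _prop_within(a: np.ndarray, b: np.ndarray, dt_s: float) -> float:
    """Proportion of spikes in ``a`` within dt of at least one spike of ``b``."""
    lo = np.searchsorted(b, a - dt_s, side="left")
    hi = np.searchsorted(b, a + dt_s, side="right")
    return float(np.mean(hi > lo))


def sttc_pair(
    train_a: np.ndarray,
    train_b: np.ndarray,
    dt_s: float = 0.1,
    duration_s: float = 300.0,
) -> float:
    """STTC of two sorted spike trains; 0 if either train is empty.

    A degenerate denominator (P*T == 1, e.g. one train tiling the whole
    recording with all its spikes matched) makes that term undefined; the
    value of the other term is returned in that case.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0
    ta = tiled_fraction(a, dt_s, duration_s)
    tb = tiled_fraction(b, dt_s, duration_s)
    pa = _prop_within(a, b, dt_s)
    pb = _prop_within(b, a, dt_s)
    terms = []
    if pa * tb != 1.0:
        terms.append((pa - tb) / (1.0 - pa * tb))
    if pb * ta != 1.0:
        terms.append((pb - ta) / (1.0 - pb * ta))
    if not terms:  # both denominators degenerate: perfectly tiling, matched
        return 1.0
    return float(np.mean(terms))


def sttc_matrix(
    rec: Recording,
    cfg: STTCConfig | None = None,
    qc: QCConfig | None = None,
) -> tuple[np.ndarray, list[int], float]:
    """Square STTC matrix over active channels and its upper-triangle mean.

    Returns ``(matrix, channel_ids, mean_sttc)``; with fewer than two active
    channels the mean is NaN.
    """
    cfg = cfg or STTCConfig()
    qc = qc or QCConfig()
    chans = active_channels(rec, qc)
    n = len(chans)
    m = np.eye(n)
    trains = [rec.train(ch) for ch in chans]
    for i in range(n):
        for j in range(i + 1, n):
            v = sttc_pair(trains[i], trains[j], cfg.dt_s, rec.duration_s)
            m[i, j] = m[j, i] = v
    mean = float(np.mean(m[np.triu_indices(n, k=1)])) if n >= 2 else math.nan
    return m, chans, mean


def sttc_dbscan_clusters(matrix: np.ndarray, cfg: STTCConfig | None = None) -> int:
    """Number of DBSCAN clusters of the 1 - STTC distance matrix.

    Noise points are not counted.  Core status follows
    ``cfg.min_samples_includes_self`` (default: the point itself is excluded,
    so 3 required neighbors means a 4-point core neighborhood).
    """
    cfg = cfg or STTCConfig()
    n = matrix.shape[0]
    if n == 0:
        return 0
    d = 1.0 - np.asarray(matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    min_samples = cfg.dbscan_min_samples + (0 if cfg.min_samples_includes_self else 1)
    labels = DBSCAN(
        eps=cfg.dbscan_eps, min_samples=min_samples, metric="precomputed"
    ).fit_predict(d)
    return int(len(set(labels) - {-1}))
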