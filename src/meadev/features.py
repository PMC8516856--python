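"""Assembly of the 18-feature electrophysiological profile of a recording.

The features fall into four groups:

* spikes      — ch_spikes, mfr, network_spikes, isi
* bursts      — ch_bursts, mbr, burst_duration, network_bursts, ibi,
                burst_pct_spikes, burst_isi, burst_peakfreq, burst_surprise
* synchrony   — sttc (mean pairwise STTC), sttc_dbscan (synchronized
                electrode clusters)
* connectivity— node_degree, clustering_coeff, efficiency

Features that are undefined for a recording (e.g. burst statistics with no
bursts) are NaN; downstream consumers decide how to impute.
"""

from __future__ import annotations

import pandas as pd

from . import bursts as _bursts
from . import connectivity as _conn
from . import synchrony as _sync
from .io import QCConfig, Recording

#: canonical order of the 18 features
FEATURES: tuple[str, ...] = (
    "ch_spikes",
    "mfr",
    "network_spikes",
    "isi",
    "ch_bursts",
    "mbr",
    "burst_duration",
    "network_bursts",
    "ibi",
    "burst_pct_spikes",
    "burst_isi",
    "burst_peakfreq",
    "burst_surprise",
    "sttc",
    "sttc_dbscan",
    "node_degree",
    "clustering_coeff",
    "efficiency",
)

#: the balanced two-features-per-group sets used for importance analysis
FEATURE_GROUPS: dict[str, tuple[str, str]] = {
    "spikes": ("ch_spikes", "mfr"),
    "bursts": ("ch_bursts", "mbr"),
    "synchrony": ("sttc", "sttc_dbscan"),
    "connectivity": ("clustering_coeff", "efficiency"),
}


def compute_features(
    rec: Recording,
    qc: QCConfig | None = None,
    burst_cfg: _bursts.BurstConfig | None = None,
    net_cfg: _bursts.NetworkEventConfig | None = None,
    sttc_cfg: _sync.STTCConfig | None = None,
    conn_cfg: _conn.ConnectivityConfig | None = None,
) -> dict[str, float]:
    """All 18 features of one recording, keyed per :data:`FEATURES`."""
    qc = qc or QCConfig()
    out: dict[str, float] = {}
    out.update(_bursts.spike_features(rec, qc))
    out["network_spikes"] = _bursts.network_spike_rate(rec, net_cfg, qc)

    bursts_by_ch = _bursts.detect_bursts(rec, burst_cfg, qc)
    out.update(_bursts.burst_features(bursts_by_ch, rec, qc))
    out["network_bursts"] = _bursts.network_burst_rate(bursts_by_ch, rec, net_cfg)

    matrix, _, mean_sttc = _sync.sttc_matrix(rec, sttc_cfg, qc)
    out["sttc"] = mean_sttc
    out["sttc_dbscan"] = float(_sync.sttc_dbscan_clusters(matrix, sttc_cfg))

    out.update(_conn.graph_metrics(_conn.build_graph(rec, conn_cfg, qc)))
    return {k: out[k] for k in FEATURES}


def feature_table(
    recordings: list[Recording],
    qc: QCConfig | None = None,
    **cfg_kwargs,
) -> pd.DataFrame:
    """One row per recording: dish, div, and the 18 feature columns."""
    rows = []
    for rec in recordings:
        row = {"dish": rec.dish_id, "div": rec.div}
        row.update(compute_features(rec, qc, **cfg_kwargs))
        rows.append(row)
    return pd.DataFrame(rows, columns=["dish", "div", *FEATURES])
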