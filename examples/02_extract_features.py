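"""Extract the 18 electrophysiological features from one recording.

Simulates a single mature, synchronized recording and prints its complete
feature profile with units.
"""

import meadev as md
from meadev.simulate import DEFAULT_ARCHETYPES

rec = md.simulate_recording(DEFAULT_ARCHETYPES[0], div=14, seed=3, dish_id="demo")
features = md.compute_features(rec)

units = {
    "ch_spikes": "channels", "mfr": "Hz", "network_spikes": "events/s",
    "isi": "s", "ch_bursts": "channels", "mbr": "bursts/min",
    "burst_duration": "s", "network_bursts": "events/min", "ibi": "s",
    "burst_pct_spikes": "%", "burst_isi": "s", "burst_peakfreq": "Hz",
    "burst_surprise": "nats", "sttc": "", "sttc_dbscan": "clusters",
    "node_degree": "", "clustering_coeff": "", "efficiency": "",
}
print(f"dish {rec.dish_id}, DIV {rec.div}, {rec.n_spikes()} spikes")
for name, value in features.items():
    print(f"  {name:18s} {value:10.3f} {units[name]}")

# A mature archetype-1 network: most channels spike and burst, the mean STTC
# is high (strong pairwise synchrony), and the connectivity graph is dense
# (high clustering coefficient and efficiency near 1).
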