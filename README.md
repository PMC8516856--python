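# meadev

Characterization and early prediction of developing spontaneous activity in
cultured neuronal networks recorded on microelectrode arrays (MEAs).

Dissociated cortical neurons on a 60-electrode array fire sparsely during
the first week in vitro and develop synchronized network bursting by the
third.  `meadev` quantifies that development with 18 electrophysiological
features of **spikes** (channels with spikes, mean firing rate, network
spikes/s, inter-spike interval), **bursts** (max-interval detection:
channels with bursts, bursting rate, duration, network bursts/min,
inter-burst interval, % spikes in bursts, intra-burst ISI, peak frequency,
Poisson surprise), **synchrony** (spike time tiling coefficient,

    STTC = ½ [ (P_A − T_B)/(1 − P_A T_B) + (P_B − T_A)/(1 − P_B T_A) ],

and DBSCAN counts of highly synchronized electrode groups) and
**connectivity** (node degree, clustering coefficient and global efficiency
of the thresholded significant spike-count-correlation graph).  It then

* clusters per-dish developmental trajectories with a 5×5 hexagonal
  self-organizing map followed by k-means, the number of clusters selected
  by the Davies-Bouldin index, and
* predicts third-week (DIV 13–18) levels of STTC, channels-with-bursts or
  MFR from the 18 first-week (DIV 6–8) features with MARS, an RBF SVM
  (σ = 0.125, C = 6) and a random forest, evaluated by test R², RMSE and
  REC curves, with SMOTE-augmented repeated cross-validation for
  feature-group importance.

A seeded synthetic cohort generator emulates dense-culture development with
three programmed archetypes and a per-dish latent maturity factor, so every
stage of the pipeline can be validated against a known ground truth.  See
`docs/methods.md` for the model and all conventions.

Intended users: electrophysiologists and computational neuroscientists
analysing multi-channel spike-time data from developing cultures, and
anyone needing a fully testable reference implementation of this feature
set.

## Worked example

```python
import meadev as md

# simulate the default 60-dish cohort (three archetypes, DIV 6-18)
cfg = md.CohortConfig(seed=1)
recordings, truth = md.simulate_cohort(cfg)
kept, qc_log = md.apply_qc_cohort(recordings)

# 18 features per recording, then per-dish interval means
table = md.feature_table(kept)
traj = md.aggregate_trajectories(table)

# cluster developmental trajectories (ch_bursts + STTC at 3 intervals)
x, dishes = md.som_input_matrix(traj)
som = md.fit_som(x, md.SOMConfig(seed=0))
res = md.cluster_som(som, x, dishes, seed=0)
print("selected k =", res.k)

# predict third-week STTC from first-week features
rep = md.prediction_report(traj, "sttc", md.PredictConfig(seed=0))
for name, r in rep["models"].items():
    print(f"{name}: test R2 = {r['r2']:.3f}, RMSE = {r['rmse']:.4f}")
```

Output:

```
selected k = 3
mars: test R2 = 0.977, RMSE = 0.0380
svm: test R2 = 0.927, RMSE = 0.0677
rf: test R2 = 0.999, RMSE = 0.0076
```

The Davies-Bouldin index recovers the three programmed developmental
archetypes (k = 3), and all three learners predict a dish's third-week mean
STTC from its first-week profile with R² above 0.9 — the early activity of
a network largely determines its later synchrony, which is the point of the
analysis.  RMSE is in STTC units (the target spans roughly 0.1–0.6 across
archetypes).

Short narrative scripts, one per capability, live in `examples/`; the
`meadev` console command exposes the same stages
(`simulate` / `features` / `cluster` / `predict`) for shell use.

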