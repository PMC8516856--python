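# Methods

`meadev` implements an analysis pipeline for the developing spontaneous
activity of dissociated cortical cultures recorded on microelectrode arrays
(MEAs): quality control and feature extraction from multi-channel spike
trains, clustering of per-dish developmental trajectories, and prediction of
third-week activity levels from first-week activity.  Because no public
recordings accompany this problem setting, a synthetic cohort generator with
a known ground truth stands in for raw data; every downstream stage is
validated against that truth or against independent brute-force oracles.

## Recordings, quality control and developmental staging

A recording is one dish observed on one day in vitro (DIV): per-channel
sorted spike-time vectors (seconds) over a fixed duration, nominally 300 s
on a 60-electrode array, with times quantized to the 0.04 ms grid of a
25 kHz acquisition system.

Quality control follows standard dish-acceptance practice:

* a channel is **active** if it fires strictly more than 3 spikes/min;
* a dish is kept only if it has a first-week recording (DIV 6–8) and at
  least one later recording (DIV 9–18), each with ≥ 10 active channels;
* recordings flagged with more than 6 noise channels reject the dish
  (waveforms are not carried in spike-time tables, so noise channels are an
  upstream metadata flag, not re-detected here);
* a drop of network-spike rate larger than 50 % between consecutive
  second-week recordings rejects the dish.  "Second week" is interpreted as
  the calendar window DIV 8–14 and the comparison is between consecutive
  recordings, the most conservative reading of a rule whose exact window is
  not standardised.

Recordings are grouped into three DIV intervals — 6–8, 9–12, 13–18 — and a
dish's trajectory is the per-interval arithmetic mean of each feature.

## The 18 electrophysiological features

Four groups describe each recording: spikes (`ch_spikes`, `mfr`,
`network_spikes`, `isi`), bursts (`ch_bursts`, `mbr`, `burst_duration`,
`network_bursts`, `ibi`, `burst_pct_spikes`, `burst_isi`, `burst_peakfreq`,
`burst_surprise`), synchrony (`sttc`, `sttc_dbscan`) and connectivity
(`node_degree`, `clustering_coeff`, `efficiency`).

**Bursts** use the max-interval method: open a burst at the first ISI
≤ 0.1 s, extend while ISIs ≤ 0.2 s, merge candidates separated by less than
0.2 s, then discard candidates with fewer than 3 spikes or shorter than
3 ms.  Merging precedes the minimum-spike/duration filters, mirroring the
standard implementation order.  `burst_surprise` is the Legendy–Salcman
Poisson surprise, −ln P(X ≥ n) with X ~ Poisson(channel rate × burst
duration); the natural log is used (the base is configurable in the sense
that the value can be rescaled; the feature is reported in nats).

**Network events** have no universal definition across analysis packages,
so both thresholds are explicit configuration: a *network spike* is a
maximal run of 100 ms bins in which ≥ ⌈0.25 × n_active⌉ distinct active
channels fire; a *network burst* is a maximal interval during which
≥ max(2, ⌈0.25 × n_bursting⌉) channels have an ongoing burst.  These
defaults are documented choices, not claims about any proprietary tool.

**Synchrony** is the spike time tiling coefficient (STTC) with
Δt = 100 ms,

    STTC = ½ [ (P_A − T_B)/(1 − P_A T_B) + (P_B − T_A)/(1 − P_B T_A) ],

with tiling fractions computed as exact interval unions clipped to the
recording.  Conventions: empty trains give STTC = 0 ("no measurable
correlation", keeps matrix means finite); a degenerate denominator
(P·T = 1) drops that term and returns the other.  The per-recording `sttc`
feature is the mean of the strictly-upper-triangle of the active-channel
matrix.  `sttc_dbscan` counts DBSCAN clusters of the distance matrix
d = 1 − STTC with eps = 0.2 (i.e. electrode pairs with STTC > 0.8) and 3
minimum samples.  Whether the 3 counts the point itself differs between
libraries; the default here requires 3 neighbors *excluding* the point
(`min_samples_includes_self=False` flips to the sklearn convention).

**Connectivity** bins each active channel's train into 100 ms spike counts,
computes Pearson correlations for all pairs with two-sided p-values from
the exact t-transform (n_bins − 2 d.f.), and keeps a binary undirected edge
when p < 0.05 **and** |r| ≥ 0.35.  No multiple-comparison correction is
applied (deliberately: the procedure is a per-pair screen, and the weight
threshold dominates).  The node set is the active channels, so isolated
active channels remain as degree-0 nodes and metrics stay comparable across
development.  Metrics: mean degree, mean local clustering coefficient, and
global efficiency (mean inverse shortest-path length over ordered pairs;
disconnected pairs contribute 0).

Features that are undefined for a recording (no bursts, fewer than two
active channels) propagate as NaN; only the prediction stage mean-imputes
them, with a warning.

## Synthetic cohorts

Each channel superimposes homogeneous Poisson background firing
(`lambda_bg`, Hz) with population *network events* arriving at `nu_nb`
events/min.  An event recruits each of the `n_active` channels
independently with probability `p_part`; a recruited channel emits a burst
of 1 + Poisson(`burst_len` − 1) spikes with exponential intra-burst ISIs
(mean 20 ms — well below the 0.1 s burst-opening threshold, while
background ISIs at ≤ 2 Hz sit well above it) starting at the event time
plus Gaussian onset jitter (s.d. 5 ms).  All parameters evolve linearly in
DIV between anchors at DIV 6 and DIV 18.

Three archetypes emulate the qualitatively distinct developmental patterns
seen in dense cortical cultures (1750–3500 cells/mm²):

| archetype | character | λ_bg (Hz) | ν (events/min) | p_part | n_active |
|---|---|---|---|---|---|
| 1 | early-synchronized, burst-rich | 0.5 → 0.6 | 20 → 40 | 0.75 → 0.95 | 40 → 55 |
| 2 | late-emerging synchrony | 0.3 → 1.2 | 4 → 25 | 0.30 → 0.75 | 25 → 48 |
| 3 | persistently sparse | 0.25 → 0.6 | 2 → 8 | 0.25 → 0.40 | 18 → 28 |

Archetype 1's background rate stays flat while its event rate grows:
maturation concentrates spikes into synchronized bursts (the rising
percentage of spikes in bursts seen in real development), and this is what
allows electrode pairs to exceed STTC 0.8 and exercise the `sttc_dbscan`
feature.

Each dish draws a latent **maturity** factor m_early ~ N(1, 0.08) (clipped
to [0.7, 1.3]) scaling its rates and active-channel count; its third-week
factor is m_late = m_early + N(0, `noise_link`=0.05).  Two consequences are
intentional: third-week features are a monotone function of first-week
features plus noise — predictable by construction, with a high but not
perfect ceiling — and archetype blobs in feature space stay compact and
near-isotropic (maturity deliberately does not scale the recruitment
probability; a purely rank-one spread elongates the blobs into line
segments, which cluster-validity indices then split regardless of scale).
The default cohort is 60 dishes, equal archetype thirds, recorded at DIV
6, 8, 10, 13, 16 and 18.

Randomness flows from one integer seed through counter-based substreams
(per dish, per DIV, per channel), so cohorts are bit-identical under a
fixed seed independent of iteration order.

What the generator does *not* emulate: electrode noise and artifacts,
waveform shapes, cell-density gradients, burst-internal rate profiles
(accelerando/ritardando), inhibition, or non-stationarity within a
recording.  Passing tests therefore demonstrate the *pipeline's*
correctness and the recoverability of planted structure, not biological
claims about real cultures.

## Trajectory clustering

Per-dish trajectories of two representative network features — `ch_bursts`
and `sttc` at each of the three intervals (6 dimensions, z-scored) — are
the inputs to a 5×5 hexagonal self-organizing map: sequential Kohonen
training, random-from-data initialisation, 50 full passes, learning rate
0.05 → 0.01 and neighborhood radius 2/3 of the lattice diameter → 1, both
linear, Gaussian neighborhood on hex (axial) distances.  k-means
(k-means++, 50 restarts) is then applied for k = 2…6 and the
Davies-Bouldin index selects k.

k-means runs on the **occupied** codebook units only (units that are the
best-matching unit of at least one dish).  A map cell stands for the
centroid of the cases that activate it; cells activated by nothing are
lattice-interpolation artifacts and, if clustered, form spurious clusters
of their own that bias the selected k upward.  The flag
`occupied_only=False` restores whole-codebook clustering.  The
Davies-Bouldin index is evaluated on the induced partition of the *dishes*
— the entities being clustered — rather than on the dozen codebook points,
where singleton codebook clusters (zero scatter) would systematically
reward large k.  Coincident centroids give an infinite Davies-Bouldin
term, so degenerate partitions are never selected.  Each dish inherits its
BMU's cluster label; cluster
summaries report mean, median, SEM (n−1; NaN for singletons) and IQR per
feature and interval.

PCA of the z-scored 18-feature table reports per-feature contribution
percentages (squared-loading shares) against the uniform reference line
100/p = 5.56 % for p = 18.

## Prediction

For each dish with both intervals present, the 18 DIV 6–8 means predict the
DIV 13–18 mean of a chosen target (`sttc`, `ch_bursts` or `mfr`).  DIV 9–12
is deliberately excluded from the predictors: the question is what the
*first* week determines.  The split is dish-level, 75/25, seeded.
Predictors are z-scored with training-set statistics.

* **MARS** (in-repo): forward selection of mirrored hinge pairs, ≤ 35
  terms, interaction degree ≤ 5, candidate knots at quantiles over each
  parent basis' support, exact incremental least squares via orthogonal
  projection; backward pruning by GCV with complexity penalty 3.
* **SVM**: RBF kernel, k(x,y) = exp(−σ‖x−y‖²) with σ = 0.125 (sklearn's
  `gamma` is exactly this σ), C = 6.  The target is z-scored during
  fitting and the ε-tube set to 0.01: with a tube of 0.1 (a common library
  default) the attainable R² on a unit-variance target is capped near
  0.97, which would mask genuinely noiseless structure.
* **Random Forest**: 100 trees, 8 candidate variables per split.

Evaluation: test R² (1 − SS_res/SS_tot), RMSE in target units, and REC
curves (fraction of test points within a standardized error tolerance).

Feature-group importance uses the SVM on the four balanced two-feature
groups (spikes, bursts, synchrony, connectivity) under leave-one-in and
leave-one-out strategies plus 18- and 8-feature baselines.  Each strategy
runs fourfold cross-validation repeated 10 times (40 fold evaluations,
mean ± SEM of out-of-fold R²).  SMOTE-style augmentation (k = 20 nearest
neighbors in the joint predictor+target space, interpolation factor 2,
target interpolated jointly with the predictors) is applied to the
*training fold only, after* the split — evaluation folds contain original
rows exclusively, which the tests assert by index bookkeeping.

## Numerical and design notes

* Burst candidate merging happens before the spike-count/duration filters.
* STTC tiling uses exact union lengths with boundary clipping; the pair
  function is validated against an O(n·m) brute-force oracle to 1e-10.
* Graph metrics are validated against a Floyd-Warshall/triangle-count
  oracle; DBSCAN against an exhaustive BFS reference; the Davies-Bouldin
  implementation against both a from-the-definition loop and sklearn.
* Problem sizes: the default cohort (60 dishes × 6 DIVs × 300 s × 60
  channels, ~13 M spikes) was chosen so a full pipeline run takes a few
  minutes on one core; parameter-recovery checks average 10 seeds, the
  clustering chain 5 SOM seeds.
* Known limitations: the simulator's linear DIV interpolation cannot
  produce non-monotone development; `sttc_dbscan` is only weakly exercised
  (few recordings exceed STTC 0.8); SVM accuracy depends on the fixed σ
  interacting with input dimensionality, so importance strategies with
  different feature counts are comparable within, not across, counts; the
  50 %-drop QC rule needs at least two second-week recordings to fire.
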