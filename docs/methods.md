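# Methods

## Task model and time base

All trials share one go-cue-aligned time base (`loopmap.task`): baseline
−3.1 to −2.6 s (500 ms pre-sample), sample −2.6 to −1.3 s (1.3 s), delay
−1.3 to 0 s (1.3 s), response 0 to +1.5 s.  The response-epoch analysis
window is not uniquely determined by the task description; it is fixed here
at the 1.5-s answer window during which a lick is scored, and every
consumer derives epochs from these constants rather than storing its own.

## Atlas stand-in

The reference geometry is parametric: each of 17 lobules (vermal I–X;
hemispheric simplex, Crus 1, Crus 2, paramedian, copula, paraflocculus,
flocculus) is an axis-aligned box, mirror-symmetric about the midline, with
a realistic CCF-scale volume stored as a count of 10-µm voxels — the unit
in which volume enters the normalized density `d = f / V`, which keeps the
classification threshold θ = 1e−11 on its native scale.  Boxes occupy
disjoint (|mediolateral|, anteroposterior) territories, so point→lobule
lookup is unambiguous; this sacrifices the interdigitated folial geometry
of the real cerebellum, which none of the downstream arithmetic needs.
Sub-lobule volumes are prorated by the mediolateral fraction of the parent
box (uniform-density assumption along the split axis).  Mediolateral split
thresholds: simplex 2.5 mm, Crus 1 3.2 mm, Crus 2 2.7 mm from the midline
for the fastigial-pathway maps; 2.2/2.2/1.7 mm plus paramedian 2.2 mm for
the dentate variant.  A point exactly at a threshold is lateral (documented
tie convention).  An optional flag collapses points posterior to a cap
plane (default 7.0 mm) onto it, mimicking histology sections registered to
the last available template section; default off.

## Synthetic data: what it emulates and what it does not

All generators draw from named sub-streams of one root seed
(CRC-32-keyed `SeedSequence` entropy), so stages regenerate independently
and identically.

**Anatomy** (`gen_anatomy`). Per-region counts are Poisson with mean
intensity × volume × a lognormal per-mouse multiplier (σ = 0.4) modelling
infection-rate variability; points are uniform inside the region box.
Default intensities put mossy-fiber input in the conjunction +
input-dominant territories (150 /mm³) and nucleus-projecting Purkinje
somata in the conjunction + output-dominant territories (120 /mm³), with
retrograde label restricted to one hemisphere.  Not emulated: within-lobule
density gradients, laminar structure, registration error.

**Electrophysiology** (`gen_ephys`). Spike trains are inhomogeneous Poisson
on a 50-ms piecewise-constant rate grid; baseline 40 Hz (cerebellar-like),
an untuned +5 Hz during the response epoch, and on selective units a
delay-epoch ramp (0 → 2A, so the delay-epoch mean difference equals the
configured amplitude A; a step variant is available).  Negative rates are
clipped at zero and logged.  A configured fraction of units are Purkinje
cells: an independent CS stream (1 Hz) plus an enforced deletion of SS
within the pause window (10 ms) after each CS — so the generated pause
statistic is exactly 0 by construction.  Not emulated: bursting, firing-rate
drift, cross-unit correlations, real CS→SS rate interactions beyond the
pause.

**Behavior** (`gen_behavior`). Trials carry a balanced random type, a
condition (control, or one of 16 spots × 3 epochs with probability 0.5),
and an outcome: early-lick (5%) and ignore (2%) trials, otherwise Bernoulli
correct at the control performance (0.785 per type) plus any configured
per-(spot, epoch) bias.  P(correct) carries per-mouse and per-session
Gaussian offsets (σ = 0.05 each): the bootstrap's null hypothesis is
"normal behavioral variability" across mice and sessions, so that
variability must exist in the synthetic null.  Outcome flips are
independent per trial; within-session autocorrelation (satiety, lapses) is
not modelled.

**Embeddings** (`gen_embeddings`). The 32-dimensional latent is
per-dimension Gaussian noise smoothed with a variance-preserving Gaussian
kernel (correlation scale 50 ms — fast orofacial movement dynamics; lag
identification is only well-posed when this scale does not swamp the 25-ms
lag spacing).  Units' log rates are linear in the embedding at a configured
lag with sparse ±0.3 weights on 8 of 32 dims (base rate 40 Hz, drift-
corrected so the mean rate is lag-invariant).  Two selectivity routes exist
for the control analyses: a trial-type shift of the first four latent dims
from delay onset (movement-borne selectivity; coupled units always read
those dims), or an additive delay-epoch rate difference independent of the
embedding (movement-free selectivity).

## Analysis procedures and parameters

| Parameter | Default | Notes |
|---|---|---|
| density threshold θ | 1e−11 | on fraction / 10-µm-voxel volume, cross-mouse means |
| KDE kernel | Gaussian product, σ = 20 µm/axis | per mouse, then averaged |
| voxel edge | 100 µm | floor(coordinate/edge) binning |
| selectivity test | Welch two-tailed t-test, P < 0.01 | epoch spike counts, all correct trials |
| preference subset | first 15 trials/type | seeded random subset optional |
| PSTH smoothing | 200-ms centered boxcar | edge-renormalized |
| ramping test | Mann–Whitney U, P < 0.05 | per-trial delay vs baseline rates |
| CS pause | rate(0–10 ms)/baseline < 0.5 | ≥ 20 CS events, else indeterminate |
| typing PSTH | 200-ms bins → 102 bins, z to pre-sample baseline | linear interpolation |
| clustering | top-6 PCs, k-means ×50 restarts, k = 1–20 | Euclidean silhouette |
| bootstrap | 10,000 reps default, α = 0.025 one-sided | 1e6 available via flag |
| BH correction | largest i with P(i) ≤ α·i/16 | step-up, mapped to input order |
| GLM | Poisson, log link, L1 (α = 1e−3), lags ±5 | 80/20 trial split |
| rate smoothing for residuals | 425 ms (25-ms steps), 340 ms (17-ms steps) | centered boxcar |

Numerical and procedural choices where the design was open:

* **Classification operates on cross-mouse mean densities** (matching how
  the profiles are plotted); applying θ per mouse is available through the
  per-mouse profile table.
* **Hemisphere handling**: input maps combine hemispheres; output maps use
  a single hemisphere with halved region volumes (retrograde label is
  ipsilateral).  Both are caller-overridable.
* **t-test variant**: Welch (unequal variance), since epoch count variances
  differ between trial types under rate differences.
* **Significance testing uses all correct trials**, including the
  preference subset; only the selectivity estimate excludes it.
* **102-bin grid** spans −3.1 to +1.5 s (pre-sample through response).  At
  200-ms binning this trial is 23 bins, so "downsampling" to the common
  102-bin grid is linear interpolation; the common grid is what matters for
  clustering, not its direction.
* **Baseline z-scoring** pools per-trial pre-sample bin rates; a baseline
  s.d. below 1e−6 Hz excludes the unit (logged) rather than dividing by
  ~0.
* **No-structure threshold**: silhouette is undefined at k = 1, so k = 1 is
  reported only when every k ≥ 2 silhouette falls below 0.25.  The
  threshold is set above the ~0.2 silhouettes that pure noise reaches in
  6-PC space at desk-scale n (silhouette inflates as k approaches n), while
  genuine archetype structure scores ≥ 0.4 on the same scale.
* **Bootstrap trial resampling is stratified** by (session × condition
  cell), so every replicate retains stim and control trials; implemented by
  the exact multinomial/binomial equivalence of with-replacement category
  counting, with a literal index-resampling reference kept for audits.
  Replicates with Δ = 0 count one half toward "inconsistent"; an exact-zero
  p is reported as 0.5/n_reps.
* **Poisson GLM with log link**: the description "logistic link with
  Poisson statistics" is internally inconsistent; the canonical log link is
  used.  The bin width enters as an offset so weights are rate-scale
  quantities.  Lags share one fixed train/test split; fits warm-start from
  the neighboring lag and use a 1e−4 coordinate-descent tolerance (weight
  correlation with truth changes < 0.01 vs the tight default).
* **Sub-lobule tie, voxel binning, BH mapping** follow the documented
  conventions above; empty inputs raise rather than return silently empty
  results, except where the spec of the operation calls for a flag.

## On the calibration of the hierarchical bootstrap

For a within-session stim-vs-control contrast, three-level resampling
re-adds trial-level noise at every level: the empirical spread of session
(or mouse) contributions already contains the trial noise that the
trial-level resampling then draws again, roughly doubling the replicate
variance relative to the true sampling variance of Δperformance.  With the
sign-fraction one-sided p this makes the test conservative (its realized
size at α = 0.025 is well below nominal in the continuous regime), while
severe per-condition sparsity can push it the other way through the
discreteness of the replicate distribution.  The test suite measures the
realized size and power on synthetic null and effect datasets; users should
read the procedure's p-values as conservative for well-sampled conditions.
This mirrors the published behavior of multi-level bootstrap tests and is a
property of the resampling scheme, not of this implementation.

## Problem sizes used by the test suite

Calibration and recovery checks run at desk scale: 2,000 null units for the
selectivity size check; 500 null and 100 effect datasets of 10 mice × 4
sessions × 200 trials at 2,000 replicates for the bootstrap; 100 seeds for
the voxel model comparison and for each GLM simulation (16–34 trials per
synthetic session).  These sizes give binomial/CLT error bars tight enough
for the asserted bounds while keeping the whole suite in minutes.

## Limitations

The atlas is a box model: region volumes and split thresholds are faithful,
geometry is not, so KDE maps and voxel grids are exercised on synthetic
spatial structure only.  Generated spike trains are Poisson; test
calibration results (e.g., the t-test's realized size) transfer to real
data only insofar as real count variability is near-Poisson at these
epoch lengths.  The movement GLM consumes embeddings as given — the
encoder that produces them from video is out of scope — and the
autoencoder's information content is not emulated beyond a smooth latent
with configurable task coupling.  Single-unit identities are per session;
no cross-session tracking is attempted.
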