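# Methods

`hfodetect` implements an unsupervised detector for high-frequency
oscillations (HFOs) in intracranial EEG. HFOs — brief 80–500 Hz oscillatory
bursts subdivided into ripples (80–250 Hz) and fast ripples (250–500 Hz) —
are a biomarker of epileptogenic tissue, but they share the 80–500 Hz band
with interictal spikes (whose band-pass filter ringing mimics an oscillation)
and with high-amplitude artifacts. The detector therefore runs in two stages:
a deliberately over-sensitive energy screen that forwards every suspicious
150 ms excerpt ("pHFO" candidate), followed by an unsupervised image-domain
stage that sorts candidates into ripples, fast ripples, spikes and artifacts
without any labelled training data.

## Pipeline

1. **Preprocessing.** Recordings are anti-alias resampled to 2,560 Hz.
   Detection runs on the signal after a zero-phase 50 Hz multi-notch
   (second-order IIR sections, Q = 30, odd harmonics 50/150/250/350/450 Hz)
   and a zero-phase 4th-order Butterworth band-pass (80–500 Hz). Odd
   harmonics only: distorted mains interference carries most of its energy
   there, and notching even harmonics would carve holes into the analysis
   band (e.g. 200 Hz). Zero-phase (forward–backward) filtering preserves
   event timing for centre localisation; by default channels are filtered
   continuously, with an optional per-150 ms-segment mode
   (`filter_mode: per_segment`) that accepts boundary transients.

2. **Candidate screening (STE).** The short-time energy is the mean squared
   amplitude per non-overlapping 10 ms frame (26 samples at 2,560 Hz,
   ceiling convention). A channel-adaptive threshold `E0 = Eav + k·SD`
   (default k = 5, population SD) is compared against the frame series; a
   candidate is declared for every maximal run of ≥ 3 consecutive
   supra-threshold frames, centred at the midpoint of the run's first three
   frames, and 150 ms of the *raw* signal around that centre is kept.
   Two numerical choices matter here:
   * The threshold statistics are computed on the frame series with the top
     2% of frames excluded (`ste.trim_fraction`). With events occupying
     ~1% of frames at ~20 dB, the raw SD is dominated by the events
     themselves, making `E0` scale with event energy and pushing shorter
     bursts below three frames; trimming keeps the threshold anchored to
     the background. Candidates closer than one 150 ms window merge,
     keeping the higher-energy one.
   * The first-three-frames centre rule sits early on long events (up to a
     few tens of ms), so candidate-to-annotation matching during evaluation
     uses a 100 ms tolerance — unambiguous because generated events are at
     least 300 ms apart.

3. **Time-frequency imaging.** Each raw candidate window is transformed
   with an analytic generalized Morse CWT (γ = 3, β = 20, time-bandwidth
   P² = 60; 16 voices/octave over 60–600 Hz), evaluated directly in the
   frequency domain as ψ(ω) ∝ ω^β e^{−ω^γ} with symmetric zero-padding.
   The magnitude is min–max normalised per map, rendered through a
   blue→cyan→yellow→red colormap into an 875 × 656 raster, and the red
   channel — monotone in normalised energy by construction, so islands of
   dominant energy saturate it — is area-resized to 64 × 64 ("R-TFM").
   Normalising per map makes island morphology amplitude-invariant, which
   the clustering relies on. The raw (not band-passed) window is imaged so
   spike and artifact morphology survives for the non-HFO classes.

4. **CVAE.** A convolutional variational auto-encoder denoises the R-TFMs:
   encoder = two stride-2 3×3 convolutions (feature maps 64→32→16, 32 then
   64 filters) with ReLU, flattened into parallel linear heads for μ and
   log σ²; decoder mirrors it with a linear layer and two transposed
   convolutions to a 64×64 sigmoid output (feature-map sizes 32×32 and
   16×16 after the two stride-2 stages). Training minimises the
   negative ELBO: per-pixel Bernoulli cross-entropy (pixels live in [0,1];
   a Gaussian/MSE switch exists) plus the closed-form diagonal-Gaussian KL,
   with the reparameterization trick, Adam at 1e-3, batch 32, ≤ 200 epochs.
   Inference decodes the posterior mean (z = μ) for determinism. The model
   is plain NumPy (im2col convolutions, hand-derived gradients, checked
   against finite differences in the test suite); at this network size CPU
   training covers a few hundred maps in seconds per epoch.

5. **Clustering and class assignment.** Reconstructions are flattened
   column-wise into 4096-vectors and grouped into K = 4 clusters, by fuzzy
   c-means by default (fuzziness m = 2, k-means++ initialisation,
   membership-change tolerance 1e-5); K-means, diagonal-covariance GMM and
   mean-shift (median-pairwise-distance bandwidth, modes merged down to 4)
   are alternatives. Clusters are anonymous, so each is assigned a class
   via the spectral centroid (SC) of its members' band-passed windows:
   SC = Σ f_k·|M[k]|² / Σ|M[k]|² over k = 0..N/2, M the DFT of the
   Hamming-windowed signal. Ranking clusters by mean SC descending maps
   them to {fast ripple, ripple, spike, artifact}; the binary HFO flag is
   membership of the top two. Ties break by cluster size (larger = HFO),
   empty clusters map to artifact. The spike-before-artifact ordering is a
   heuristic (both classes sit at the low edge of the band) and is
   config-overridable; it does not affect the binary decision.

6. **Evaluation.** Positive = real HFO (ripple or fast ripple).
   Accuracy/sensitivity/specificity are percentages of the candidate set;
   ratios with empty denominators are reported missing, never zero.
   Supervised baselines (KNN k = 5; SVM with linear, polynomial and RBF
   kernels at C = 1) are scored with *stratified* five-fold CV — plain
   five-fold is unstable under the benchmark's class imbalance — while
   unsupervised models are scored on the whole candidate set, since they
   never consume labels. The detector's event-level recall (fraction of
   injected oscillatory events with a candidate) is reported separately
   from the candidate-level metrics.

## Synthetic benchmark

No public clinical corpus with expert HFO annotations accompanies this
problem, so validation uses a generator whose defaults are the package's
study conditions: 4 channels × 10 min at 2,560 Hz; pink (1/f power)
background at 10 µV RMS plus a 5 µV 50 Hz line component; Poisson event
placement at 9/9/18/10 events·min⁻¹ (ripple / fast ripple / spike /
artifact) with ≥ 300 ms spacing per channel, giving one event per analysis
window. Morphologies and parameters:

| class | waveform | draws |
| --- | --- | --- |
| ripple | Gaussian-windowed sinusoid, σ = dur/6 | f ~ N(160, 25²) Hz clipped [100, 240]; dur ~ U(70, 100) ms |
| fast ripple | same | f ~ N(350, 45²) Hz clipped [260, 480]; dur ~ U(70, 90) ms |
| spike | exponential cusp (τ = dur/14 ≈ 4–6 ms) + negative slow after-wave | dur ~ U(60, 90) ms |
| artifact | white noise band-passed 20–90 Hz, Gaussian envelope | dur ~ U(60, 90) ms |

Amplitudes are calibrated per event so the RMS *in the 80–500 Hz band over
the event support* sits a stated SNR (default 20 dB for every class) above
the channel's band-limited background RMS; the calibration reuses the exact
waveform later injected, so realized SNR matches the target to well within
1 dB. Every draw derives from the single configuration seed.

Deliberate choices, and what they imply about the tests:

* **Durations.** The supra-threshold part of a Gaussian-windowed burst
  spans ≈ 0.75 × duration; durations are chosen so that span exceeds
  ~50 ms and three consecutive 10 ms frames fire at *any* frame alignment.
  Clinical fast ripples are often shorter (10–50 ms); a 3-frame rule at
  10 ms frames cannot see such events, so the generator does not emulate
  them. Passing tests certify the pipeline's behaviour in its design
  regime, not recall on arbitrarily short clinical FRs.
* **Spike sharpness.** A smooth difference-of-Gaussians transient has
  essentially no energy above 80 Hz (Gaussian spectral tails), would never
  trigger the screen, and could not reproduce the classic
  spike-ringing-as-false-HFO failure mode. The cusp component gives the
  spike a realistic 1/f-type high-frequency tail: spikes are detected, and
  their band-passed residue concentrates near the 80 Hz edge (SC ≈ 120 Hz).
* **Artifact spectrum.** Artifacts are modelled as movement/EMG-like
  bursts dominant below the HFO band. An in-band spectrally-flat burst
  would have SC ≈ 290 Hz — above every ripple — and no descending-SC rule
  could rank it below the ripple cluster; low-band-dominant bursts are both
  realistic for movement artifacts and consistent with SC-based class
  assignment. Broadband white artifacts spanning the full HFO band are a
  regime this SC ranking cannot label correctly; with real data of that
  kind the class rank would need a different discriminator.
* The generator does not model physiological cortical sources, volume
  conduction, event co-occurrence across channels, or amplitude drift;
  conclusions about clinical recordings require clinical data.

## Default problem sizes

The shipped benchmark produces ≈ 430–480 candidates. The CVAE trains for 50
epochs by default (loss is within a few percent of its 200-epoch value and
the downstream clustering metrics are unchanged between 50 and 200 epochs
on the benchmark); the `latent_epoch_sweep` harness evaluates the
l ∈ {10..50} × epochs ∈ {100,150,200} grid by snapshotting one training run
per latent size, which is identical to separate runs because the update
sequence is seed-deterministic.

## Known limitations

* The SC rank rule assumes the two HFO clusters have the two largest mean
  centroids; background-only candidates (rare at k = 5) have SC ≈ 230 Hz
  and land in whichever cluster is nearest without affecting the ranking.
* Fuzzy c-means on 4096-dimensional pixel vectors can settle in different
  local optima under different initialisations; the k-means++ seed is part
  of the configuration for reproducibility.
* EDF/EDF+ files are read (via MNE); the simulator writes `.npz` + CSV
  rather than EDF.
* Per-segment filtering (each 150 ms window filtered independently) is
  available but injects boundary transients into the STE trace; continuous
  filtering is the default for that reason.
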