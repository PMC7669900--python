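# Methods

This note records the models implemented in `retroprobe`, the assumptions
behind them, the defaults that matter, and what the synthetic-data layer
does and does not establish about real data.

## Column model of penetrating shanks

A shank advanced against soft neural tissue is treated as an axially loaded
column: clamped at the probe body and pinned at the tip once it dimples the
tissue, giving an effective length constant k = 0.7 (0 < k ≤ 2 accepted).
For a rectangular section the minimum radius of gyration reduces to
t/√12, so the slenderness ratio λ = kL·√12/t is independent of width —
only length, thickness and the end condition control how prone a shank is
to buckle. Class boundaries follow the classical convention, with both
boundary values assigned to the medium class (short λ < 32, medium
32 ≤ λ ≤ 120, long λ > 120).

The Rankine–Gordon load P_R = σ_c·A / (1 + αλ²), α = σ_c/(π²E),
interpolates between material crushing (σ_c·A as λ → 0) and Euler buckling,
and is therefore applicable across the medium-and-long designs of interest;
the pure Euler load is computed alongside for reference only. σ_c is
equated to the tensile strength of the substrate. Public geometry is in µm
and moduli accept GPa/MPa through a convenience constructor; all internal
arithmetic is SI.

Feasibility compares P_R against an insertion-force threshold, default
2 mN — a conservative bound, since intracortical insertion forces span
roughly 0.5–2 mN and the retina is believed to be about as soft as brain
tissue. A tie (P_R exactly at threshold) passes but is flagged marginal.
The scan covers six length–width pairs (140/180/220 µm at 100 µm width,
145/185/225 µm at 50 µm width) at 3/5/7 µm thickness for the two polymers,
plus two silicon references (1000×100×25 and 312×60×25 µm). The scan
reports every design point as computed; the 7 µm 225×50 parylene-C point
computes to ≈1.47 mN and is therefore listed infeasible even though all
other 7 µm points pass.

Note an ordering subtlety in the headline fold differences: dividing the
weakest silicon reference load (0.409 N) by the strongest design-space load
of each polymer gives ≈59× for parylene-C and ≈17× for polyimide — the
softer material yields the larger ratio. The API returns both ratios keyed
by material rather than assuming an order.

## Synthetic recordings

`gen_recording` emulates a stepwise intraretinal insertion at a fixed
20 kHz sampling rate: `n_steps` depth positions of `step_duration_s` (5 s
default) each, 3 or 4 electrodes per shank with electrode 0 (E-1) the
lower stimulation site (25 µm) and the rest upper recording sites (15 µm).

* **Spikes.** A ~1 ms biphasic template (unit negative peak, scaled so its
  area is zero and its energy stays inside the 100 Hz–3 kHz band) is
  planted at Poisson times (20 Hz default) with amplitude `spike_snr` ×
  noise SD (SNR 10, noise 5 µV default). Electrode c starts firing at step
  round(c·(n_steps−1)/(n_channels−1)), reproducing the activity shift from
  the bottom to the upper electrodes as the shank advances; the schedule is
  returned as ground truth.
* **Wild-type LFP.** One 500 ms photopic stimulus per depth step (7.96
  µW/mm², repeatable every 15 s in protocol terms). The evoked response is
  a difference of Gaussians at stimulus onset and offset (σ = 40/60 ms,
  150 µV), an ERG-like waveform the data only show but do not
  parameterise. Its sign for electrode c at step d flips once the
  electrode's depth index d − c reaches `lfp_reversal_depth_index`
  (default 4), emulating the intraretinal ERG polarity reversal; the full
  polarity matrix is ground truth.
* **rd10 mode.** Slow sinusoids at the configured frequencies (defaults
  3.3 and 7 Hz at 100 and 40 µV — the pathologic 3–7 Hz band) shared
  across electrodes, with spike bursts (Poisson(4)+1 spikes, ±20 ms
  jitter, 80% of cycles) phase-locked near the troughs of the primary
  oscillation.

Not modelled: biophysical retina circuitry, electrode impedance and
stimulation artifacts, spatial falloff between electrodes, drift. Passing
recovery tests therefore shows the *analysis operations* are correct and
calibrated, not that they would be robust to every artifact of acquired
recordings.

## Recording analysis choices

* Band split: 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) so spike times are not shifted; spike band 100 Hz–3 kHz,
  LFP ≤ 100 Hz. Sampling below 6 kHz is rejected, off-nominal rates warn.
* Detection: threshold k × MAD/0.6745 on |x| (polarity-agnostic), one
  event per suprathreshold excursion, merged within a 1 ms refractory
  window keeping the larger peak. Default k = 4; the orchestrated workflow
  uses k = 5 because at k = 4 Gaussian noise contributes ~0.5–1 false
  events/s, enough to trip the depth-profile floor (3 spikes) over a 5 s
  step. For noiseless synthetic traces the MAD underflows after filtering,
  so the noise estimate is floored at 10⁻⁶ × max|x|.
* Spectra: single-sided amplitude (2|X|/N), peak picking over 1–20 Hz by
  default, local maxima above 20% of the band maximum, and a band maximum
  below 10⁻⁹ of the global spectral maximum counts as "no peak" (guards
  DC-only traces against FFT round-off).
* Success: at least one upper electrode with ≥ 3 spikes or ≥ 0.5 Hz in the
  last-step window. The underlying experimental criterion is "action
  potentials present", without a printed count; the floor is configurable
  and recorded in outputs.

## Synthetic stacks and trauma quantification

`gen_stack` renders a (z, y, x) two-channel field (default 256×256×3 at
0.76 µm/px — a typical 20× confocal pitch; z-step 7 µm within the 5–9 µm
acquisition range). The green channel is a jittered grid of bright somata
(radius 4 px) over a dim diffuse background with an elliptical void of
exactly `hole_area_um2` at the insertion site (the ground-truth ROI polygon
is the ellipse outline, rescaled so its shoelace area is exact). The red
channel holds Gaussian puncta (radius ≈ 2.5 px, amplitude 200) — the
planted dead-cell count strictly inside the ROI plus 3 background puncta
well outside it — over low Gaussian noise. Puncta are placed with ≥ 4
radii separation, relaxing if the region is cramped.

The measurement pipeline mirrors the classical ImageJ workflow: max
projection; Otsu threshold by default with an explicit override recorded
in the result (reproducibility over operator judgment); binary open with a
3×3 cross; watershed on the lightly smoothed (σ = 0.7 px) distance
transform with marker peaks ≥ 3 px apart; 8-connected labelling; minimum
particle area 4 px. ITA is the ROI polygon area × pixel_size²; a particle
counts when its centroid lies strictly inside the polygon (cells "around"
the hole are counted only if the ROI is drawn to include them); ITR = ITA /
shank cross-section. Auto-proposed ROIs take the largest connected
component darker than 0.3 × the green median (≥ 50 px), absorb red
particles whose footprint touches the void dilated by 5 px, and return the
convex-hull outline tagged `auto-proposed`; imported ROIs are never
silently replaced.

## Condition calibration

Condition presets (PI-50, PaC-50, Si-60 at 187.5 µm/s) carry the observed
mean ± SD of ITA, ITR and dead-cell count. Hole areas are drawn from a
normal truncated at zero and counts from round(truncated-normal) — counts
are not Poisson, since the observed SDs differ from √mean. In both cases
the latent (µ, σ) are solved by two-moment matching so the *observable*
mean and SD equal the targets; this matters near zero, where naive
parameters would inflate a 0.63-mean count to ≈ 0.87. The Si-60 ITA
parameters derive from ITR × its 1500 µm² cross-section since only the
ratio statistics are reported for that condition; its (unreported)
dead-cell parameters are a documented stand-in flagged `assumed`. Drawn
hole areas are floored at 50 µm² to avoid degenerate ellipses (negligible
probability mass). Per-condition sample sizes are not reported; generators
and examples default to 16 shanks per condition (4 insertions × 4 shanks).

## Statistics

* **Lilliefors screen**: KS distance to the normal with estimated mean/SD;
  the null is simulated (default 10⁴ standard-normal samples of matching
  size, seeded) since estimating parameters invalidates the plain KS
  tables. Constant samples and n < 5 are rejected as errors.
* **Pooled bootstrap t-test**: Welch statistic (robust to the unequal
  spreads seen across conditions); under the null both groups share a
  distribution, so replicates resample the pooled (sorted) data with
  replacement to the original sizes; p = (1 + #{|t*| ≥ |t_obs|})/(B + 1)
  never returns exactly zero. Sorting the pool makes p invariant to
  argument order at equal sizes and to adding a common constant. B = 10⁴
  by default. Zero pooled variance returns p = 1 with a warning.
* **Pairwise post-hoc**: all unordered pairs, Bonferroni factor = number of
  pairs tested, stars at 0.05/0.01/0.001 on adjusted p; groups with n < 2
  are skipped with a warning. Sub-seeds are spawned deterministically from
  the family seed.
* **Fisher's exact test**: two-sided by the minimum-likelihood rule, with
  table probabilities formed from exact integer binomials so ties at the
  observed probability resolve exactly (no log-space epsilon).

## Problem sizes and tolerances

Condition-recovery checks use 120 stacks per condition in the test suite
and 150 in the reproduction script (the calibration floor is 100; more
stacks tighten the 2-standard-error acceptance band, at ≈ 0.15 s/stack).
Bootstrap calibration uses 1000 matched-null repetitions at B = 999; the
achieved type-I error is required to sit in [0.03, 0.07] at nominal 0.05.
Spectral checks run on 10 s traces (0.1 Hz resolution). Independent
cross-checks: Fisher vs scipy's implementation (exhaustive at small
margins, sampled up to margin 30), Lilliefors statistic vs statsmodels.

## Known limitations

* The column model ignores tissue dimpling/compression before puncture and
  any rate dependence of the insertion force; the 2 mN threshold is a
  literature-derived constant, not a measured retinal value.
* Trauma analysis operates on maximum projections (no 3-D segmentation,
  no green-channel cell counting), and the ROI convention counts centroids
  strictly inside the polygon.
* The synthetic layer matches first and second moments of the reported
  condition statistics, not their full distributions; recovered
  significance patterns between synthetic conditions demonstrate the
  machinery, not biology.
* Insertion-success generation treats shanks independently; real failures
  cluster within insertions (shared holder mechanics), which would widen
  rate confidence intervals.
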