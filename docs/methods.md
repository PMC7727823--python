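# Methods

## The forward model and its inversion

The package assumes a locally linear structure–property relationship between
instantaneous ¹³C chemical shifts and C–C bond lengths along a conjugated
chain,

    δᵢ(t) = δᵢ⁰ + Σⱼ Mᵢⱼ (dⱼ(t) − dⱼ⁰) + εᵢ(t),

with `M` in ppm/Å. This is an approximation valid for the small thermal
excursions of an equilibrium trajectory (a few hundredths of an Å); it is
deliberately applied far outside that regime when photoproduct Δd patterns
of tens of pm are predicted, which is why the pipeline's output is treated
as semi-quantitative (signs and relative magnitudes, not pm-accurate
lengths) and why implausible predicted lengths are flagged rather than
suppressed.

Two independent inversion routes are implemented:

1. **PC regression** (`fit_pca` → `fit_inverse_model` → `predict_bond_deltas`).
   The per-frame shifts of the feature atoms (default C13–C18) are centred
   but not scaled, and rotated by a full-rank PCA — no components are
   discarded, so PCA is exactly an orthogonal rotation that orders the
   fluctuation directions by variance. Each bond length is then regressed
   (OLS, intercept included) on the PC scores. An experimental Δδ vector is
   rotated into PC space *without* mean subtraction (a difference carries no
   baseline) and mapped through the coefficients. Because the rotation is
   orthogonal and no dimension is dropped, predictions are algebraically
   identical to a direct multivariate regression on centred shifts; the test
   suite asserts this identity to 1e-8 pm. It is the pipeline's central
   invariant: if it ever breaks, a component was silently discarded.
2. **Pseudoinverse** (`pseudoinverse_predict`): Δd = pinv(M)·Δδ through the
   significance-filtered forward matrix. For the square 6-atom × 6-bond
   configuration with a full-rank map the two routes agree to numerical
   precision on noiseless data; with 7 bonds and 6 shift features the system
   is underdetermined and the pseudoinverse returns the minimum-norm
   solution, so exact recovery is not guaranteed and recovery tests use the
   square configuration.

The proportionality constant of the forward relation is fixed at 1 with
units ppm = (ppm/Å)·Å: since the matrix entries carry physical units, any
other constant would be unidentifiable.

### Direction of the fitted regression

The object of prediction is Δd given a measured Δδ, so the regression is
fitted in the inverse direction (bonds on shift components). The forward
matrix `M` is estimated separately and kept for the pseudoinverse
cross-check; agreement of the two framings on noiseless square data is an
acceptance-level test.

### Attenuation bias

Regressing bond lengths on *noisy* shifts dilutes the coefficients
(classical errors-in-variables attenuation): the predicted Δd magnitudes
shrink by roughly λ = σ²ₛᵢ𝗀ₙₐₗ/(σ²ₛᵢ𝗀ₙₐₗ+σ²ₙₒᵢₛₑ) per PC direction. At the
default noise (0.5 ppm against a 2–3 ppm signal sd) this leaves a mean
absolute recovery error of order 1–2 pm on truths of tens of pm — visible in
the worked example, where predictions are systematically slightly smaller in
magnitude than the truth. The bias shrinks with the signal variance of the
trajectory, not with its length.

## Estimating the sensitivity matrix

Each atom's shift is regressed **jointly** on all bond lengths. The
per-pair simple regressions (slope, Pearson r, p) are retained as a
display/table product (`pair_table`), but the matrix entries used for
inversion are the joint slopes: when a shift depends on several bonds, the
pairwise slope of atom i on bond j equals Mᵢⱼ only up to cross-bond sample
covariance, which at n frames contributes spurious leakage of order
(Σₖ|Mᵢₖ|)/√n — percent-level even at n = 10⁴ and never exactly zero. The
joint regression has no such term and recovers the generator map to machine
precision on noiseless data.

Significance of each entry is a t-test on its slope. MD snapshots are
serially correlated, so the OLS standard error is inflated by the lag-1
statistical inefficiency g = (1+ρ̂)/(1−ρ̂) (clipped at ≥1) of the
per-coefficient score series — the product of the regression residual with
the Frisch–Waugh residual of that bond on the other bonds — and the t
degrees of freedom are divided by g. For independent frames g ≈ 1 and the
test stays calibrated (the false-positive rate at α = 0.05 without
correction sits inside the binomial 99% band in the acceptance checks); at
the default generator spacing (dt/τ = 4) frames are effectively independent
and the correction is a near-no-op, but it matters for more finely sampled
input. Multiple testing across the atoms × bonds family is controlled by
Benjamini–Hochberg at α = 0.05 by default (Bonferroni and uncorrected are
available). Entries failing the corrected test are set to exactly 0 and
recorded in the significance mask.

Ties in the per-atom preferred-bond report are broken by first occurrence in
bond order; the dominance ratio is ∞ when only one entry is significant, and
an atom with no significant entry is reported "independent".

## Uncertainties

* **Trajectory averages**: block averaging — the standard error of
  ⌊n/B⌋ contiguous block means (default B = 10 snapshots = 2 ps at the
  200 fs spacing, trailing partial block dropped). The naive sem of
  correlated samples underestimates; block sem at B ≫ τ/dt does not. No
  autocorrelation-time estimation beyond this is attempted.
* **Δd predictions**: seeded circular block bootstrap (block 10 frames) of
  the entire PCA + regression refit, default 200 resamples; the reported
  uncertainty is the sd of the resampled predictions. `n_boot=0` falls back
  to the analytic OLS standard error of the predicted mean response. The
  bootstrap captures sampling noise of the fitted map, not the attenuation
  bias above.

## The surrogate generator

`shiftsense.synthetic` emulates the statistical structure the analysis
assumes, nothing more:

* **Bond dynamics**: independent Ornstein–Uhlenbeck processes per bond,
  exact discrete-time update `d_{t+1} = d0 + φ(d_t−d0) + √(σ²(1−φ²))ε` with
  φ = exp(−dt/τ), initialised from the stationary law. Defaults: snapshot
  spacing dt = 200 fs; relaxation time τ = 50 fs (fast vibrational
  decorrelation — snapshots are nearly independent); stationary sd
  σ_d = 0.015 Å and equilibrium lengths alternating 1.42/1.47 Å, which keep
  a 10⁴-frame trajectory oscillating essentially within the 1.4–1.5 Å band
  expected for conjugated C–C bonds at 300 K. An optional
  `neighbour_coupling` anti-correlates adjacent-bond innovations to
  stress-test the inversion; it is off by default so the ground truth stays
  identifiable.
* **Shifts**: δ0 + M_true·(d−d0) + Gaussian noise (default 0.5 ppm);
  baselines alternate 115/145 ppm to mimic the alternating aromatic-carbon
  pattern. With the default map this yields instantaneous per-atom shift
  spans of roughly 10–20 ppm over 10⁴ frames, the scale seen in
  first-principles trajectories of bilin chromophores.
* **Ground-truth map** (`default_fig3_map`): magnitude s·decayᵈⁱˢᵗ with
  s = 150 ppm/Å, decay 0.4, cut off beyond two bonds; sign (+,−,+) with
  chain distance. Each atom has a preferred bond whose entry keeps full
  magnitude while all others are scaled by (1−asymmetry), default
  asymmetry 0.7 — enough for C17's preferred *non-member* bond (a
  distance-1, negative entry of magnitude 60) to dominate its row. These
  values were fixed by a design-time identifiability analysis: the square
  6×6 map has condition number ≈ 5, so the inversion is well-posed and the
  predicted noisy-recovery error (~1 pm) is dominated by attenuation, not
  conditioning.
* **Pseudo-coordinates**: the chain is embedded collinearly along one axis
  so that consecutive distances reproduce the bond lengths exactly — pure
  bookkeeping for the I/O round-trip tests, not a conformational model.
* **State pairs** (`simulate_state_pair`): the "experimental" Δδ is the
  exact forward image M_true·Δd_true plus optional noise, so end-to-end
  inversion is testable to numerical precision.

All randomness flows from the single spec seed; identical specs reproduce
outputs bitwise.

What the surrogate does **not** emulate: cross-bond covariance of real
vibrations (beyond the optional coupling), anharmonicity, nonlinearity of
the shift–geometry relation, conformational transitions (ring flips,
photoisomerisation itself), and protein-environment effects on the shifts.
Passing recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the stated assumptions — not that those
assumptions hold for any particular protein.

## Bond-order classification

Predicted length = reference + Δd (pm→Å). Thresholds: < 1.40 Å → double,
> 1.44 Å → single, else intermediate; both configurable, bracketing typical
conjugated C=C/C–C lengths inside the observed fluctuation band. Lengths
outside the plausible conjugated C–C window (1.30–1.60 Å by default) are
flagged implausible but still labelled — large inversions can overshoot
physical bond lengths, and hiding that would overstate the method.

Conjugation extent is the longest contiguous run of strictly alternating
single/double labels; intermediate labels terminate a run (a conservative
estimate — the patterns do not correspond to pure single or double bonds,
and counting through an ambiguous bond would inflate the conjugation
length). A ring is included when the run contains a bond with both
endpoints inside it. The two-state antagonism report flags a bond as
opposite only for a strict {single,double} swap.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use n = 1000 frames (inversion,
20 replicates for the noisy case), n = 10 000 (sensitivity recovery and
fluctuation envelope), and 50 replicates × 500 frames (false-positive
control) — large enough for sub-pm noiseless recovery and binomially tight
rate estimates while the full suite runs in seconds. Degenerate inputs have
stated conventions: a constant shift series regressed on a bond gives slope
0, r 0, p 1; a constant bond series is an error (slope unidentified); a
constant shift column is rejected by PCA with the column named. Masked
matrix entries are exactly 0, not small. Bootstrap resamples that produce a
singular refit fall back to the point prediction (vanishingly rare at the
default sizes).

## Known limitations

* Linearity is assumed at Δd scales where it is only qualitative; outputs
  are sign/rank information more than lengths.
* The 6-feature × 7-bond configuration is underdetermined; only the
  minimum-norm solution is reported for it.
* Attenuation from shift noise biases magnitudes downward; the bootstrap
  uncertainty does not include this bias.
* The significance mask depends on the multiple-testing choice; with few
  frames BH at 0.05 can zero genuinely small entries, which then also
  changes the pseudoinverse route.
* Block-based corrections assume stationarity; drifting (non-equilibrated)
  trajectories violate both the OU surrogate and the estimators.
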