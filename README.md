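# shiftsense

Infer **bond-length-change patterns in conjugated chromophores from ¹³C
chemical-shift changes**, by extracting and inverting the *geometric
sensitivity* of isotropic shifts to C–C bond lengths.

## The problem

Photoreceptor proteins built on open-chain tetrapyrrole (bilin) chromophores —
phytochromes and cyanobacteriochromes — tune their absorption colour by
changing the extent of π-conjugation across rings C and D of the cofactor.
Solid-state NMR sees large per-atom ¹³C shift changes (Δδc, up to ~10 ppm)
between the dark state and the photoproducts, but no photoproduct crystal
structures exist, so the structural meaning of those changes is inaccessible
by direct comparison.

The route implemented here is indirect. In a thermally fluctuating molecular
trajectory, instantaneous ¹³C shifts co-vary with instantaneous C–C bond
lengths through an (approximately) linear map with a characteristic
alternating-sign band structure along the conjugated chain:

    Δδᵢ = Σⱼ Mᵢⱼ · Δdⱼ

with `M` in ppm/Å (atoms × bonds). Estimating `M` from trajectory
fluctuations and inverting the relation turns an experimental Δδc vector
(ppm) into a predicted per-bond Δd pattern (pm), which in turn classifies
each bond as single/double/intermediate and yields the effective conjugation
length — shorter conjugation for a hypsochromically shifted photoproduct,
longer for a bathochromic one.

The expensive quantum-chemistry layer that generates the per-frame shifts is
out of scope; it is replaced by a fully parameterised statistical surrogate
(`shiftsense.synthetic`) with known ground truth, so every stage of the
analysis is validated by parameter recovery.

## What is in the package

| module | role |
| --- | --- |
| `shiftsense.trajectory_io` | XYZ/CSV/JSON readers and writers, bond-length series from coordinates, frame alignment |
| `shiftsense.shift_statistics` | trajectory averages, block-averaged uncertainties, fluctuation ranges, pattern comparison |
| `shiftsense.sensitivity` | significance-filtered sensitivity matrix `M`, sign pattern, per-atom preferred-bond (asymmetry) report |
| `shiftsense.inversion` | full-rank PCA of shift fluctuations, inverse regression, Δδ→Δd prediction with bootstrap uncertainties, pseudoinverse cross-check |
| `shiftsense.conjugation` | bond-order classification, alternating-run conjugation extent, two-state antagonism report |
| `shiftsense.synthetic` | Ornstein–Uhlenbeck surrogate trajectories with a known sensitivity map |
| `shiftsense.cli` | `shiftsense simulate / sensitivity / invert / classify / analyze` |

The `analysis/` directory holds numbered driver scripts that run the whole
study on surrogate data and write their tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_trajectory.py   # 5000-frame surrogate bundle
python analysis/03_geometric_sensitivity.py # extract and filter M
python analysis/04_invert_shift_changes.py  # invert two synthetic transitions
python analysis/05_classify_conjugation.py  # bond orders + antagonism
```

`03` recovers the sensitivity structure from the fluctuations alone:

```
sensitivity matrix: 6 atoms x 6 bonds, 27 significant entries (alpha=0.05, bh)
  C13: preferred C13-C14 (150 ppm/Å, ratio 8.4)
  ...
  C17: preferred C18-C19 (60 ppm/Å, ratio 1.3)
max entry error vs ground truth: 0.69% of matrix scale
```

Each atom's dominant ("preferred") bond matches the generator's asymmetric
ground truth — including C17, whose strongest correlation is with a bond it
is not even a member of. `04` then inverts a synthetic "Pg-like" transition
whose true Δd pattern is (−17, +5, −14, 0, +2, +16) pm:

```
Pg-like: predicted Δd per bond (pm), truth in brackets
  C13-C14:  -16.21 ± 0.06  [-17]
  C14-C15:   +1.75 ± 0.19  [+5]
  C15-C16:  -12.53 ± 0.09  [-14]
  C16-C17:   -0.63 ± 0.08  [+0]
  C17-C18:   +2.95 ± 0.19  [+2]
  C18-C19:  +14.97 ± 0.09  [+16]
  mean |error| 1.353 pm
```

The signs and magnitudes of the large changes are recovered; the residual
pm-scale error is the attenuation caused by shift noise in the regressors
(see `docs/methods.md`). `05` classifies the two antagonistic transitions
into opposite single/double patterns and reports the alternating-run
conjugation extent per state:

```
Pg-like: pattern d/s/d/s/s/s (d=double, s=single, i=intermediate); alternating run 4, rings ['C', 'D']; 3 bond(s) outside the plausible window
antagonism Pfr-like vs Pg-like: 50% of shared bonds opposite (C13-C14, C15-C16, C18-C19)
```

Bonds whose predicted lengths overshoot the plausible conjugated C–C window
(1.30–1.60 Å) are flagged rather than hidden: the inversion is
semi-quantitative at these Δd scales, so the flags mark where sign and rank
carry the information, not the absolute length.

Real experimental Δδc vectors enter the same way through small JSON/CSV
files (`shiftsense.inversion.read_shift_delta`, or `--deltas` on the CLI);
none are hard-coded.

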