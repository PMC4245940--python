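# Methods

## The system and the measurements

A T^mCG site in a nucleosome core particle can occupy ten consecutive
rotational positions across one helical turn at the dyad axis; each
position presents a different face of the duplex to the histone
octamer. Three measurement types characterise a position:

1. **Deamination time courses.** After UV irradiation, the
   5-methylcytosine inside a cyclobutane pyrimidine dimer (CPD)
   deaminates to thymine. The assay digests the DNA to mononucleotides
   and separates ³²P-labelled 5-methyl-dC from dT, so each timed
   aliquot yields two band intensities; a terminal aliquot driven to
   complete deamination measures both the CPD photoproduct yield and
   the normalisation for the deaminated fraction.
2. **Hydroxyl-radical footprints.** Cleavage intensity along the
   wrapped DNA oscillates with the ~10–11 bp helical period; minima
   mark backbones against the histone core.
3. **Crystal coordinates.** A nucleosome PDB file gives per-nucleotide
   temperature factors (flexibility proxy) and base/photodimer
   geometry.

## Kinetic model and estimator

The remaining-CPD fraction is assumed to decay as a single first-order
process: `f_rem(t) = A·exp(−k·t)` with `A = 1 − f₀ ≤ 1` because a
variable amount of deamination occurs during sample work-up before the
incubation starts. The estimator is ordinary least squares of
`ln f_rem` on time with a **free intercept** (forcing the line through
zero would bias *k* whenever `f₀ > 0`). Logs are natural; the slope is
`−k`; `t½ = ln2/k` exactly; `σ(t½) = ln2·σ(k)/k²` by first-order error
propagation, and the printed `±` values of the reference table are
treated as 1 SE. The fit is unweighted and `r²` is reported as a
diagnostic.

Two filters precede the fit:

- Points with nonpositive remaining fraction (noise pushes `f_t` past
  `f_inf` near the plateau) are excluded with a logged warning.
- **Plateau guard.** Once the expected remaining fraction falls below
  `PLATEAU_FLOOR = 0.1`, a measurement is noise-dominated: with ~5%
  multiplicative band noise the absolute uncertainty of the remaining
  fraction is roughly 0.05–0.09 regardless of its value, so points in
  the plateau carry enormous, heavily skewed errors on the log scale
  and sit at maximal leverage. An auxiliary exponential fit on the
  *linear* scale (insensitive to the sign of individual noisy points,
  hence free of the selection bias a threshold on observed values would
  introduce) locates the plateau, and times whose expected remaining
  fraction is below the floor are excluded. Monte-Carlo calibration
  (500 replicates per rate, rates 0.017–0.198 h⁻¹, default sampling
  times) shows that without this guard the median bias of *k* reaches
  −60% at the fast end, while with it the median bias stays within
  ~1.6% across the whole measured range. The floor is exposed as a
  parameter (`plateau_floor=0` restores the raw estimator). At least
  three points must survive; otherwise the fit is refused. A
  nonnegative slope is reported as an invalid fit (no detectable
  deamination) rather than an exception, so one flat site does not
  sink a batch.

**Known limitation — SE coverage.** The residual-based OLS standard
error badly undercovers: `ln f_rem` errors are strongly heteroscedastic
(latest points noisiest and highest-leverage) and all points share the
noisy terminal-aliquot normalisation, which correlates their errors.
In simulation the nominal ±1 SE interval covers the true *k* in only
~10–25% of replicates rather than the ~64% a homoscedastic model
would give. Reported SEs should therefore be read as relative quality
indicators, not calibrated confidence intervals.

## Energetics

`ΔΔG‡ = R·T·ln(k_fast/k_slow)` with `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`.
Defaults: 310.15 K for deamination (assay at 37 °C) and 277.15 K for
photoproduct-formation comparisons (irradiation at 4 °C); both
overridable since the temperatures behind the published energy plot are
not stated. Photoproduct **yields** are used as rate proxies for the
formation step — valid for comparing positions if irradiation dose and
duration were identical across them, which the shared-irradiation
design guarantees; it is an approximation wherever yields approach
saturation. The published 0.4–0.6 kcal/mol span for
cleavage/photoproduct formation is not exactly reproducible from the
table extremes at either default temperature (yield extremes give
~0.6–0.7), so no check is pinned to it.

## Mutagenic potential

`potential = (yield_NCP/yield_free)·(k_NCP/k_free)`, the relative rate
of producing a deaminated CPD, ignoring repair and replication. Rate
folds are computed from rate constants (`ln2/t½` ratios), not from the
rounded fold-change columns, to avoid compounding rounding. The
average over positions is the unweighted arithmetic mean — the expected
potential for a rotationally unphased nucleosome — which reproduces the
published 2.3-fold figure. "x-fold lower" values are reported as
reciprocals. The published "5.3-fold lower" at position 1 is not
derivable from the table (the arithmetic gives 5.5); it is paired and
reported as advisory but does not gate the reference report.

## Footprint model

Intensity is modelled as `baseline + amplitude·cos(2π(x − phase)/period)`.
The period is found by grid search (step 0.01 bp, default window
9–12 bp, ties to the smaller period); at each trial period the
subproblem is linear in `(baseline, a, b)` with
`a·cos + b·sin`, solved in closed form, and amplitude/phase follow from
`(a, b)`. The reported phase is the fitted maximum nearest the middle
of the profiled region. Missing intensities are skipped, never imputed.

Orientation calls compare the **observed** intensity at each position
with the fitted baseline: at or above baseline → `outside`, below →
`inside`. For a pure cosine this is identical to thresholding the
fitted cosine itself; on realistic footprints the two differ, and the
observed-value rule is the right one, because protection troughs are
narrower than half a period (backbone–histone contacts span ~3 bp per
turn). A single 10.4 bp harmonic is ≥ baseline on at most 5–6
consecutive integer positions and therefore *cannot* split ten
consecutive positions 3/7 — yet the measured series does exactly that
(three protected positions at 71/72/80, seven exposed at 73–79). The
trough-profile generator (Gaussian dips of σ = 1.4 bp at the cosine
minima) emulates this narrowness, and the observed-vs-baseline rule
reproduces the 3-inside/7-outside split on it.

## Structural geometry

- **Superhelix axis**: centroid of DNA phosphorus atoms plus the
  eigenvector of the smallest covariance eigenvalue (the flat disc's
  normal); sign fixed toward +z (ties toward +x). Clouds whose two
  smallest eigenvalues differ by < 10% are rejected as degenerate.
- **Base orientation angle**: between the vector from the C6–N1 bond
  midpoint to the N3–C4 bond midpoint (crossing the pyrimidine ring
  toward its major-groove edge) and the radial unit vector from the
  axis to the six-atom ring centroid. The cylindrical radial stands in
  for the local histone-surface normal: only the inward/outward
  ordering matters, and the radial realises it without a surface mesh.
- **Mean temperature factor**: unweighted mean B over all atoms of the
  nucleotide (base, sugar and phosphate).
- **Photodimer geometry**: distance between the C5–C6 bond midpoints of
  sequential same-strand pyrimidines, and the C5ᵢ–C6ᵢ–C6ⱼ–C5ⱼ improper
  torsion by the standard four-point formula with the IUPAC sign
  convention (cross-checked against biotite). Note the standard
  identity `d(A,B,C,D) = d(D,C,B,A)`: reversing the residue order
  preserves the torsion; mirror reflection flips its sign.

PDB is the only input format in this version (no mmCIF). Parsing goes
through gemmi with coordinate fields pre-validated so malformed records
are reported with their line number; waters are dropped and alternate
locations resolved to the highest occupancy (ties to file order).
Residue numbering is taken verbatim from the file; mapping residues to
rotational positions 1–10 is the caller's configuration. Because the
exact construction behind the published orientation figure is not
stated, angles computed from real structures are cross-study
comparable only in their ordering, and no numeric check is pinned to
1KX5/3UT9-derived values (those files are optional user inputs, never
downloaded).

## Synthetic data

- **Time courses**: true deaminated fraction
  `f(t) = yield·(1 − (1 − f₀)·exp(−k·t))`; band intensities
  `T = total·f·ε_T`, `mC = total·(1−f)·ε_C` with independent
  log-normal(0, σ²) factors per band (positive phosphorimager counts,
  roughly constant CV; σ defaults to 0.05). The terminal aliquot is
  generated at `f = yield` with the same band noise. `f₀` defaults to
  0.05, emulating extraction-induced deamination. Default times
  {0, 2, 4, 8, 16, 32, 64} h: geometric spacing covering the 3.5–41 h
  half-life range in ~2–3 half-lives at both extremes. One measurement
  per time point, as in the real assay.
- **Cleavage profiles**: cosine plus additive Gaussian noise, clipped
  at zero; the trough variant replaces the sinusoid with narrow
  Gaussian protection dips (above).
- **Idealized nucleosome**: a flat DNA ring (superhelix pitch defaults
  to 0; a positive pitch is supported but tilts the phosphorus-cloud
  principal axes slightly for short wraps) with an exact integer
  number of superhelical turns so the phosphorus centroid sits exactly
  on the rotation axis. Each residue carries a phosphorus atom on the
  backbone circle and a planar hexagonal pyrimidine-ring placeholder
  whose bisecting vector makes angle `ψ = 2π(i−1)/bp_per_turn` with
  the outward radial; ring centroids sit at radius
  `R − 6 + 2·cos ψ` Å and every atom's placeholder B-factor equals its
  radial distance. By construction the orientation-angle minimum and
  the mean-B maximum coincide at residue 1 (built outward) and invert
  half a turn later — ground truth for the structural operations.
  What this fixture does **not** emulate: real base pairs, sequence,
  backbone chemistry, thermal disorder or crystallographic noise;
  passing tests on it validate the geometry code, not any claim about
  real nucleosome structures.

All generators are pure functions of (spec, seed).

## Reference table and printed-precision checks

The packaged site table carries the published per-site yields (%),
half-lives (h, with 1 SE) and fold-change columns: ten T^mCG
nucleosome positions, the pooled free-DNA reference, and the
T^mCA flanking-base variants (15 records). Derived checks compare a
recomputed value with its printed counterpart after round-half-up to
the printed digits, passing if within **one unit in the last printed
digit** — necessary because the published fold columns were rounded
from unrounded raw values, so ratios of printed columns can land one
ulp away (e.g. printed yield fold 1.9 versus 22/12 = 1.83).

## Problem sizes and numerical choices

Stochastic suites use 500 replicates per rate for kinetics recovery and
20–25 replicates for footprint phasing, all with fixed seeds; the whole
test suite runs in well under a minute. Grid period step 0.01 bp;
noiseless-recovery tolerance 1e-9 relative; dihedral/axis comparisons
at 1e-6 degrees/units except against biotite's float32 (1e-3).
Tie-breaks: smaller period on equal RSS; +z (then +x) axis sign;
first-encountered altloc on equal occupancy.
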