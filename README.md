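# nucleocpd

Quantitative analysis of how nucleosome rotational positioning modulates
UV-induced mutagenesis at methylated CpG sites.

Sunlight-induced C→T mutation hotspots in skin cancer arise mainly at
methylated CpG dinucleotides: UV light fuses the adjacent pyrimidines
into a cyclobutane pyrimidine dimer (CPD), the 5-methylcytosine inside
the dimer hydrolytically deaminates to thymine, and translesion
synthesis then fixes the change as a C→T mutation. Both steps —
photoproduct formation and deamination — depend on which face of the
DNA helix the site presents to the histone surface. `nucleocpd`
implements the full analysis chain that turns raw measurements of this
system into comparable per-position numbers:

- **kinetics** — first-order deamination rate constants from
  ³²P gel-band time courses. With band intensities `T` and `mC` and a
  fully deaminated terminal aliquot (`T∞`, `mC∞`), the fraction of CPD
  remaining at time *t* is
  `1 − [T/(T+mC)] / [T∞/(T∞+mC∞)]`, and *k* is the negative slope of
  the ordinary least-squares line through its natural log versus time
  (free intercept; half-life `t½ = ln 2 / k`; photoproduct yield
  `T∞/(T∞+mC∞)`).
- **energetics** — transition-state free-energy differences
  `ΔΔG‡ = R·T·ln(k₁/k₂)` from rate (or yield) ratios.
- **mutagenic potential** — per-rotational-position score
  `(yield_NCP/yield_free) · (k_NCP/k_free)` and its average across a
  helical turn.
- **footprint** — period/phase of the ~10–11 bp hydroxyl-radical
  cleavage oscillation by a single-harmonic cosine fit, with
  inside/outside backbone orientation calls.
- **structure** — per-nucleotide geometry from a nucleosome PDB file:
  superhelix (disc) axis, base orientation angle relative to the
  outward radial, mean crystallographic B-factors, and
  C5–C6/C6–C5 photodimer geometry (interbond distance, improper
  torsion).
- **synthetic** — seeded generators for all three input kinds, plus the
  packaged dyad-site reference table (yields, half-lives and fold
  changes for ten consecutive rotational positions and two
  flanking-base variants).

## Worked example

```python
import math
from nucleocpd import fit_deamination
from nucleocpd.synthetic import TimeCourseSpec, generate_time_course

spec = TimeCourseSpec(k_true=math.log(2) / 13, yield_true=0.12,
                      noise_sigma=0.05, seed=20, site_id="free DNA")
fit = fit_deamination(generate_time_course(spec))
print(fit.half_life_h, fit.yield_percent)
```

Running `python examples/fit_deamination_rates.py` prints

```
free DNA: k = 0.0534 /h (SE 0.0020), half-life = 12.99 h (true 13.0), yield = 11.8% (true 12%), r2 = 0.994, points used = 6
outermost NCP site: k = 0.2053 /h (SE 0.0048), half-life = 3.38 h (true 3.5), yield = 21.7% (true 22%), r2 = 0.999, points used = 4
```

— the fitted half-lives and yields recover the generating values within
the noise, and `points used` shows the fit dropping aliquots whose
remaining-CPD fraction has decayed into the noise floor.

`python examples/energy_and_potential_profile.py` walks the packaged
site table across one helical turn:

```
pos  k(/h)   ddG(kcal/mol)  yield_fold  rate_fold  potential
  1  0.0169         -0.71        0.58       0.32       0.18
  ...
  6  0.1980         +0.81        1.83       3.71       6.81
  ...
average potential over the ten positions: 2.28x free DNA
```

Position 6 (backbone furthest from the histone core) is ~7-fold more
mutagenic than free DNA; position 1 (against the core) ~5-fold less;
a rotationally unphased nucleosome averages 2.3-fold more. The other
examples (`footprint_phasing.py`, `structure_geometry.py`,
`reproduce_published_summary.py`) demonstrate the remaining capabilities
one stage at a time.

A thin CLI mirrors the library:
`nucleocpd fit-deamination|ddg|potential|footprint-phase|structure-geometry|simulate|pipeline|reference-report`
(see `nucleocpd --help`).

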