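# proturn

Intervention-free quantification of protein turnover from expression time
courses.

Measuring how fast a protein is made and destroyed usually requires
perturbing the system — pulse-chase labelling, translation inhibitors,
photoconversion.  When both the mRNA profile and the protein expression of
a gene can be observed from the initiation of expression until homeostasis
(for example by combining an RNA-seq developmental time course with
time-lapse imaging of a GFP protein-trap line in *Drosophila* embryos),
turnover can instead be inferred by fitting a simple kinetic model to the
unperturbed data.

## Model

Protein abundance P(t) is assumed to follow a first-order synthesis–
degradation balance forced by the mRNA abundance M(t):

    dP(t)/dt = Sp · M(t) − Dp · P(t)

with a constant synthesis rate Sp (protein A.U. per mRNA A.U. per hour)
and a constant first-order degradation rate Dp (h⁻¹).  Protein half-life
follows directly from the degradation rate:

    h = ln 2 / Dp

Two complementary fitting directions estimate (Sp, Dp) per biological
replicate by Levenberg–Marquardt nonlinear least squares with 95%
confidence intervals:

* **anterograde** (mRNA → protein): integrate the ODE forward on the
  densely interpolated mRNA profile and fit the result to the protein
  curve;
* **retrograde** (protein → mRNA): describe the protein by a logistic
  curve P(t) = bottom + K / (1 + e^(−r (t − t_i))), invert the ODE
  analytically, M(t) = (dP/dt + Dp·P) / Sp, and fit that image to the
  measured mRNA.

Agreement between the two directions (assessed with a two-tailed
Mann–Whitney test across replicates at significance level 0.01), together
with regression confidence intervals that are much smaller than the
between-replicate biological variability, is the method's internal
consistency check.  Protein replicates are fitted with the
dose-response-style four-parameter logistic (Bottom, Span, logEC50,
HillSlope) with time as the x-variable; the natural logistic parameters
are K = Span, t_i = logEC50, r = HillSlope·ln 10.

The method assumes a single-peak-then-plateau mRNA profile and a sigmoid
protein rise; the `diagnose` tools screen for violations (multiple mRNA
peaks, missing plateau, poor logistic fits, anterograde/retrograde
disagreement).

## Worked example

The package ships a synthetic-data generator whose defaults emulate a
Collagen-IV-like study: true degradation rate 0.12 h⁻¹ (half-life ≈ 6 h),
a pulse-to-plateau mRNA profile on a 0–15 h window sampled every 2 min,
10 replicates with 5% measurement noise and ~20% biological variability
in the rates.

```sh
proturn simulate --seed 42 --out-dir bundle
proturn anterograde bundle/mrna_interpolated.csv bundle/logistic_params.csv \
    --interval-min 2 --start-h 0 --end-h 15 --out-dir antero
proturn halflife antero/degradation_rates.csv
```

which prints

```
anterograde: 10 replicates
median Sp = 0.7214, median Dp = 0.1119 1/h
...
rep_10: Dp = 0.1257 1/h -> half-life 5.51 h
mean half-life = 5.92 h (10 replicates)
```

The median fitted degradation rate (0.112 h⁻¹) sits close to the
generating truth (0.12 h⁻¹); per-replicate scatter reflects the simulated
biological variability, and the mean half-life of 5.9 h recovers the ≈6 h
ground truth.  `proturn anterograde` writes the four output files
(`synthesis_rates.csv`, `degradation_rates.csv`, `synthesis_ci.csv`,
`degradation_ci.csv`; one row per replicate), and

```sh
proturn diagnose bundle/mrna_interpolated.csv bundle/logistic_params.csv
```

reports `verdict: suitable` after checking the mRNA shape, the
anterograde/retrograde consistency and the CI-vs-variability ratio.

For real data the upstream steps are available as `proturn interpolate`
(moving-average smoothing plus natural cubic-spline densification of a
sparse mRNA course onto a uniform minute grid) and `proturn fit-logistic`
(per-replicate 4PL fits with an R² report).  Everything the CLI does is
also importable from `proturn` as plain functions.

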