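# Methods

This note records the models implemented in `lipoquant`, the assumptions
behind them, the numerically delicate choices, and what the synthetic-data
studies do and do not demonstrate.

## SAXS forward model

**Bilayer.** The vesicle membrane is treated as an isolated flat sheet with
a symmetric two-slab SLD profile: a hydrophobic core of half-thickness
`L_t` (alkyl tails) and hydrophilic layers of thickness `L_h` (PC
headgroups). The lamellar intensity is the thin-sheet transform of this
profile; it diverges as q⁻² at low q and carries no vesicle-radius
information. This is deliberate: for vesicles of ~130 nm diameter the
overall form factor oscillates far below the fitted q window, and a closed
vesicle model is known to misrepresent the low-q region of such data, where
large loose aggregates also contribute. Consequently the model should not
be read below q ≈ 0.01 Å⁻¹; a documented option (`q_min` on the fit
problem) restricts refinement to q ≥ 0.02 Å⁻¹ when the low-q upturn is
visibly non-lamellar.

**Protein mixing.** Embedded protein occupies a volume fraction `x` of the
hydrophobic core, replacing tails there (`ρ_i = xρ_p + (1−x)ρ_t`); the
space above and below an embedded protein is taken as solvent, replacing
headgroups in the outer layer (`ρ_o = xρ_s + (1−x)ρ_h`). Both relations
are affine in x, which the tests exploit. The four component SLDs are
fixed inputs (solvent 9.46e-6, tails 8.7e-6, heads 11.8e-6, protein
11.7e-6 Å⁻²); `sld_from_sequence` reproduces the protein value from the
His-tagged AqpZ sequence to within a few percent using a shipped
per-residue volume table (crystallographic consensus volumes; the table is
an argument, so any other convention can be substituted).

**Micelles.** Residual lipid-only aggregates are modelled as core–shell
spheres inheriting the bilayer's geometry and SLDs: core radius `L_t` with
tail SLD, shell thickness `L_h` with headgroup SLD, no protein. This
inheritance is an interpretive choice (a micelle's core is its tail
region); the aggregates' lipid-only composition is supported by
ultracentrifugation evidence in the underlying study. The sphere amplitude
`F(u) = 3(sin u − u cos u)/u³` switches to the series `1 − u²/10` below
u = 1e-4 to avoid catastrophic cancellation.

**Combined curve.** `I(q) = C1·I_lam·exp(−R²q²) + C2·I_mc·exp(−R²q²) + B`.
The Gaussian roughness damping applies to both structured terms, the
background is flat. With R = 0, C2 = 0, B = 0 the curve is exactly
`C1·I_lam`.

## Global refinement

A concentration series (empty control + protein series) is fit
simultaneously: `L_t`, `L_h`, `R` shared; `x`, `C1`, `C2`, `B` per curve.
The objective is the usual weighted sum of squares; the reduced χ² divides
by (points − free parameters).

- **Optimizer.** Bounded trust-region least squares (`scipy`'s `trf`),
  multistarted: the first start is the user/initial values, the remaining
  nine draw the nonlinear parameters (lengths, roughness, fractions) from a
  seeded scrambled-Sobol design over the bounds. The model is linear in
  (C1, C2, B), so every start first receives the weighted-NNLS-optimal
  scales — this makes even remote starts competitive and the refinement
  robust to the mild (L_t, L_h) multimodality. Lowest final χ² wins; ties
  break to the lowest start index, so results are deterministic given the
  seed.
- **Bounds.** x ∈ [0, 0.5], L_t ∈ [8, 25] Å, L_h ∈ [3, 12] Å,
  R ∈ [0, 15] Å, scales and background ≥ 0 — physically plausible windows
  that bracket reported PC-bilayer values.
- **Fixed parameters.** Any parameter can be pinned
  (`GlobalFitProblem.fixed`). The recovery study pins the empty control's
  x at 0, mirroring the published refinement scheme in which a protein
  fraction is reported only for protein-bearing preparations. This
  matters quantitatively: refining a parameter whose true value lies on
  the x ≥ 0 bound leaks a common-mode upward bias (~0.006) into *all*
  fractions through the shared-geometry degeneracy and inflates their
  spread ~20-fold.
- **Confidence intervals.** Profile likelihood: the parameter is scanned
  while all others are re-minimized; the interval is where
  χ²(θ) ≤ χ²_min + Δ with Δ the 1-dof χ² quantile at the requested level
  (0.874 at the default 63.8%). Endpoints are bracketed by doubling steps
  seeded from a column-equilibrated covariance estimate and refined by
  bisection to relative tolerance 1e-3; endpoints beyond the bounds are
  reported as the bound and flagged censored. The inner re-minimizations
  run at tightened tolerances (1e-12): a sloppy re-minimization
  overestimates the profile and silently shrinks the interval. Empirical
  coverage of the 63.8% interval, checked by repeated noise realizations,
  is consistent with its nominal level. Near active bounds the profile is
  visibly asymmetric; this is genuine, not a numerical artifact.

## Stopped-flow kinetics and permeability

Shots are averaged pointwise (resampling onto the first grid if needed),
min–max normalized over the 0–0.4 s window, and auto-oriented to rise
toward the plateau (fitted rates are invariant under affine amplitude
transformations, so orientation is cosmetic). The biphasic model
`y = y_inf − A1·e^(−k1·t) − A2·e^(−k2·t)` is fit on t ≥ dead time from
several deterministic starts built on a half-rise-time rate estimate;
degenerate fits (second amplitude < 1e-3 of the first, or rates within
0.1%) collapse to a flagged single exponential. The reported rate is the
amplitude-weighted mean `K = (A1k1 + A2k2)/(A1+A2)`, with amplitudes
referenced to t = 0 — the convention that makes a noiseless
(0.7, 200; 0.3, 30) trace report K = 149 s⁻¹. The weighting is isolated in
one place so a fast-rate-only convention is a one-line change.

**Dead-time caveat.** Points before the 10 ms dead time are excluded, not
extrapolated. For fast samples this has a structural consequence: with
K ≳ 100 s⁻¹ the fast phase decays by 70–97% inside the dead time, so its
t = 0 amplitude — and hence K — is a backward extrapolation with large
variance even at the exact least-squares optimum. Synthetic round trips
quantify this honestly: at per-shot SNR 50 with 10 shots averaged, the
relative spread of recovered K grows from <2% for slow controls
(~27 s⁻¹) to ~8% at 100 s⁻¹ and tens of percent above 200 s⁻¹. This is
an information limit of the measurement design, not of the fitting; the
reported per-sample SD (spread of single-shot fits) propagates it into
the corrected ratios.

Rate-to-permeability conversion uses the spherical surface-to-volume
ratio: `P_f = K·r/(3·V_w·Δ_osm)`, with the control-corrected K. Default
constants (all configurable, set once in `stopped_flow`): osmotic gradient
0.5 osmol/L (0.25 M NaCl after 1:1 mixing, van 't Hoff factor 2), water
molar volume 18 cm³/mol, soy-PC MW 776 g/mol, tetramer MW 97 kDa, area
per lipid 0.7 nm², four conducting pores per tetramer. Channels per
vesicle follow from the bulk molar lipid-to-protein ratio and a two-leaflet
sphere surface; `p_f = P_f·4πr²/N`. The P_f conversion is a pluggable
callable: published analyses of this experiment used a conversion whose exact
form is not public and which yields ~10× smaller
P_f than the spherical-geometry formula for the same K, so per-channel
values from the default formula land around 2–3×10⁻¹³ cm³/s, one decade
above the canonical ~2×10⁻¹⁴ cm³/s aquaporin benchmark; substituting the
original conversion (once available) through the formula slot reproduces
the benchmark decade with the same channel arithmetic.

## Synthetic data

Generators are pure functions of their spec including the seed.

- **SAXS series.** Log-spaced q ∈ [0.004, 0.35] Å⁻¹, 100 points per curve
  (the resolution of a log-rebinned laboratory curve); fractions
  (0, 0.0094, 0.012, 0.030); L_t = 14.3 Å, L_h = 6.65 Å, R = 5.37 Å;
  C1 = 1 with C2 = 1e-6 — the micelle term then matters only near the
  lamellar form-factor minimum, i.e. a minor aggregate population — and
  B = 1e-11, of the order of the damped high-q signal. Noise is
  multiplicative Gaussian (2% default), a good description of photon
  statistics after azimuthal averaging at laboratory count rates; the
  σ column carries the true per-point noise level.
- **Shrinkage traces.** 400 points over 0.4 s, 10 ms dead time, 10 shots
  per sample; biphasic with amplitude split 0.7/0.3 and fast:slow rate
  ratio 5, rates solved so the amplitude-weighted mean equals K_true;
  additive Gaussian noise 0.02 (per-shot SNR 50).
- **Fixture bundle.** A four-sample on-disk set with rate constants
  26.7 / 96.0 / 152.5 / 254.1 s⁻¹ and matching vesicle metadata, in the
  same ASCII/CSV dialects the readers accept; byte-identical for identical
  seeds.

What passing synthetic tests show: the estimators are consistent and
calibrated when the model that generated the data is the model being fit.
What they do not show: robustness to instrument smearing, to the
unmodelled low-q aggregate scattering, to non-Gaussian outliers, or to
vesicle rupture/reformation during the osmotic challenge — none of which
the generators emulate.

## Scale of the shipped studies

The recovery study runs 50 repetitions of the four-curve refinement at 2%
noise (a few minutes on one CPU); the kinetics round trip 200 trials; the
profile-coverage check 24 repetitions. These sizes give Monte-Carlo
standard errors comfortably below the effects being asserted.

## Known limitations

- Single bilayer only: no multilamellarity, no polydispersity in the layer
  thicknesses, no explicit vesicle form factor, no instrument smearing.
- The micelle parameterization (geometry inherited from the bilayer) is an
  assumption; refining an independent micelle radius is not supported.
- K's amplitude weighting is convention, and ill-conditioned for rates
  fast relative to the dead time (see above).
- The default P_f conversion is the standard spherical-geometry formula;
  absolute P_f/p_f values depend on the conversion convention far more
  than on anything fit from data, hence the pluggable slot.
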