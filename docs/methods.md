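# Methods

## Statistical model

### Node-level comparison

For each of the 84 Desikan-Killiany regions, the subject's weighted degree
`WD_i = Σ_{j≠i} FA_ij` is regressed on an intercept, a group indicator
(patient = 1) and the chosen covariates by ordinary least squares. The test
statistic is the t of the group coefficient with `n − k` residual degrees of
freedom. Covariates enter *the model* rather than being residualized out
first: the in-model form uses the correct degrees of freedom and, with no
covariates, reduces algebraically to the classical pooled-variance
two-sample t (verified to 1e-9 in the tests). Reduced and heightened
integrity are probed as two separate one-sided families — matching how such
directional hypotheses are reported — each corrected on its own by the
Benjamini-Hochberg step-up procedure at q = 0.05 across the 84 regions.
Sex is coded male = 1, medication is a single any-psychotropic boolean
(per-class indicators would be nearly collinear in a cohort where controls
take none).

A numerically perfect fit (residual sum of squares at rounding-error level
relative to the outcome's magnitude) is reported as t = 0 rather than the
0/0 ratio it would otherwise produce; this covers degenerate inputs such as
a constant outcome or an outcome exactly equal to a covariate.

### Link-level comparison

The same regression is applied to each region pair's weight. FA is undefined
on links with no reconstructed streamlines, so a link enters the tested
family only if nonzero in at least `presence_threshold` (default 0.5) of the
subjects *in each group*; setting the threshold to 0 tests all 3486 pairs.
Untested links are reported as absent, not failed, and the FDR family is the
tested set. Significant links are then restricted to those touching a region
flagged by the node-level analysis — the hierarchical logic under which a
connectogram is drawn — and per-region counts are reported out of the 83
candidate links per region.

### Clinical correlation

Associations between WD and clinical scores are partial Pearson correlations:
both the region's WD and the score are residualized on the same covariates
(age+sex, or age+sex+BDI+STAI-T), and p-values use `n − 2 − k` degrees of
freedom. This equals the closed-form partial correlation (cross-checked
against an independent implementation in the tests). Adjusting only the
brain side, Spearman ranks, and a group covariate for the combined-group
analysis are config options. FDR is applied per clinical variable across the
84 regions — one family and one sorted p-value curve per variable; a pooled
family is a config switch. A variable that is itself in the adjustment set
has an identically zero residual and is skipped with a notice. Combined-group
analyses pool residualized data without a group term by default, which means
a pure between-group shift in both WD and a score produces combined-group
correlations absent within either group (Simpson-type behavior — demonstrated
in the tests and worth keeping in mind when reading combined-group results).

Patients with S-FMDRS = 0 (no motor symptoms) can be excluded from severity
scatter plots; statistics use the full sample by default, with a switch to
apply the exclusion to the statistics as well.

## Synthetic cohort generator

The generator starts at the connectome level (no images or streamline
geometry) and emulates the structure the analysis assumes:

* **Demographics and scores.** Ages, mood scores (BDI, STAI-S/T) and SF-36
  subscales are truncated normals per group on each instrument's range
  (BDI 0–63, STAI 20–80, SF-36 0–100), with the pre-truncation parameters
  solved numerically so the *post-truncation* mean and SD match the target
  group moments; the solver weights the mean more heavily, because for the
  most skewed targets (e.g. an SF-36 subscale with SD comparable to its
  distance from the bound) no truncated normal attains the published SD and
  the mean is the quantity downstream effects depend on. Sex is Bernoulli at
  the observed female fraction per group. Illness duration is lognormal.
  Medication is a single any-psychotropic flag whose probability rises with
  the patient's BDI (base rate 0.45).
* **FA connectomes.** One shared sparsity mask at `link_density` (default
  0.6) over the 3486 pairs; per present link, FA = per-link Gaussian noise
  (SD 0.08 around baseline 0.40) plus a per-subject linear shift from age
  (−0.001/year), sex (+0.005 male), BDI (−0.002/point) and STAI-T
  (−0.001/point), clamped to [0.01, 0.95]. Mood scores differ by group, so
  they act as true mediators: group → mood → FA on *every* link.
* **Planted deficit.** Patients additionally lose a constant δ of FA on
  every present link incident to the 19 designated regions. δ is calibrated
  in closed form — within-group WD variance at a degree-m node is
  `m·σ_ε² + m²·var(subject shift)` — so that the *direct* (mood-adjusted)
  standardized WD reduction at the planted regions equals `node_effect_d`
  (default 1.0). The marginal (age/sex-only) effect is direct + mediated and
  is therefore larger; with the default couplings the mediated share alone
  is ≈1 SD of WD, which is why the marginal analysis flags most regions and
  the mood-adjusted analysis retreats toward the planted set. Note the
  unavoidable spillover: a deficit on link (planted, neighbor) also lowers
  the neighbor's WD by δ, about one fifth of the planted effect at default
  density. If the requested d needs δ beyond what the FA bounds allow, the
  generator raises an error stating the attainable maximum.
* **Severity coupling.** A latent severity for patients is built from the
  noise component of WD at the two coupled regions (the component that
  survives covariate adjustment), scaled by a coefficient α, plus independent
  noise. S-FMDRS is a monotone quantile transform of the latent onto a
  zero-inflated marginal (zero probability 21/85, positive part moment-matched)
  — zeros are the *low-severity tail*, i.e. censoring, not independent
  dropout. α is calibrated through the exact attenuation factor of that
  monotone transform (computed by quantile quadrature) and the population
  correlation geometry of the coupled nodes, so the correlation between
  S-FMDRS and covariate-adjusted WD at each coupled node hits
  `clinical_coupling_r` (default −0.5); an unreachable target raises an
  error with the attainable maximum. CGI is a discretized (0–7) version of
  the same latent; SF-36 physical functioning is the decreasing quantile
  transform of it for patients and an independent ceiling-heavy marginal for
  controls.
* **Other weight kinds.** Streamline counts are negative-binomial with mean
  proportional to FA (scale 2000, dispersion 5, floor 1 on present links);
  mean fiber lengths are Normal(60 mm, 15) clamped to [5, 250], uncoupled to
  group — a built-in negative control.

Presets: `null` (no planted effects — type-I calibration), `paper_like`
(the defaults above), `strong_effect` (d = 1.5), `mediation_off` (planted
deficit without the mood path). Identical (config, seed) reproduce the data
bit-for-bit; FA is drawn before the optional weight kinds so it is invariant
to which kinds are requested.

### What the generator does and does not emulate

It reproduces group-level moments, confounding, mediation, a focal planted
deficit and severity coupling — enough to validate error control, power,
attenuation and localization of the analysis chain. It does not model
spatial autocorrelation of FA beyond shared-link geometry, site/scanner
effects, non-Gaussian FA noise, degree heterogeneity across regions
(the mask is homogeneous), comorbidity-specific subgroups, or any
anatomically realistic topology. Passing recovery tests therefore shows the
*statistics* behave as designed under the assumed structure, not that real
cohorts satisfy that structure.

## Numerical choices

* Node/link GLMs share one design matrix, so all outcomes are solved with a
  single vectorized least-squares pass; the single-outcome path is
  cross-checked against a reference OLS implementation in the tests.
* BH-FDR uses the standard step-up with adjusted p
  `min_{k'≥k} p_(k') m / k'` capped at 1; ties share a rank. Decisions are
  `p_adj ≤ q`.
* Weighted degree sums strictly left-to-right per row so results are
  bit-identical to a naive loop.
* Rank-deficient designs raise an error naming the latest redundant column;
  groups need ≥ 3 subjects; correlations need ≥ 5 usable subjects and a
  non-constant variable.
* Connectome files are written at 17 significant digits and parsed with
  round-trip float precision, so write→read is exact. Asymmetry up to 1e-9
  is averaged away; beyond that it is an error. FA up to 1 + 1e-9 is clamped
  to 1.
* All emitted tables are sorted deterministically and formatted at 10
  significant digits; `summary.json` uses sorted keys; a SHA-256 manifest
  accompanies every run.

## Problem sizes

The simulation-backed checks run at 500 replicates (null false-discovery
calibration) and 200 replicates (recovery/attenuation) at the default cohort
size of 85/75; moment and coupling calibrations are verified at 10,000
patients per group, where sampling error is well below the stated ±0.1 and
±0.3 tolerances. The analysis drivers use single default-size cohorts, and
`analysis/05_calibration_experiments.py` repeats the replicate experiments at
reduced counts (100/50) as a quick-look version of the full-scale checks in
the test suite.

## Known limitations

* The default conditions make the marginal group effect brain-wide (mood
  mediation touches every link), so the marginal node analysis saturates at
  the default sample size; the planted-set structure is only identifiable in
  the mood-adjusted model. Cohort-specific discovery counts from any real
  study are not reproduction targets.
* The truncated-normal family cannot reach the published SDs of the most
  skewed bounded scores (some SF-36 subscales, HC BDI); means are matched,
  SDs are as close as the family allows.
* Link-level clinical correlations are out of scope; the clinical analysis
  is node-level WD only.
* No plotting: connectogram edge lists and scatter/curve tables are emitted
  for external tools.
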