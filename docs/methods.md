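# Methods

## Colour measurement

All colour statistics are computed in CIELAB (D65, 2° observer). Images
are assumed colour-managed upstream; the package decodes 8-bit sRGB with
the IEC 61966-2-1 transfer function and the standard 4-digit linear-RGB →
XYZ matrix. The reference white is taken as the image of neutral sRGB
under that matrix (the matrix row sums), so neutral pixels map exactly to
(L\*, 0, 0); with the CIE's independently rounded D65 white, neutrals
carry a spurious |a\*|, |b\*| ≈ 0.003, which is confusing when asserting
that grey input is achromatic. The difference to other implementations is
below 0.05 ΔE and is covered by a cross-check test against scikit-image.

Masks are uint8 label rasters over a fixed registry (background 0,
forehead 1, cheek 2, nose 3, chin 4, periorbital 5, lips 6, brows 7,
eyes 8, other_skin 9 — registry version 1). Overall skin is the union of
the five local areas plus residual skin; periorbital skin is included.
JSON polygon files are rasterized with matplotlib's point-in-polygon test.

Per-region C\* and h_ab are derived from the region-mean (a\*, b\*) pair
rather than by averaging per-pixel polar coordinates: hue is circular and
its arithmetic mean is ill-defined near the achromatic axis. A
`mean_of_pixelwise_polar` switch exists for sensitivity analyses. The
achromatic point a\* = b\* = 0 returns (C\*, h_ab) = (0, 0) and is
flagged.

MCDM uses the CIE76 colour difference, matching its original definition
as a colour-uniformity index; CIEDE2000 is deliberately out of scope.

The adapted Michelson contrast is fixed as (skin − feature)/(skin +
feature) per coordinate — positive when the surrounding skin has the
larger value (e.g. skin lighter than brows), negative e.g. for a\* of
lips redder than skin. "Surrounding skin" is the morphological dilation
of the feature mask by a configurable radius (default 8 px on the 256-px
template), minus the feature, intersected with skin labels. The mouth
contrast shares the lips mask with the lip-colour category. A
non-positive denominator (possible for a\*) yields NaN with a warning;
such values are excluded downstream rather than silently propagated.

## Rating diagnostics and screening

Cronbach's alpha treats observers as items and faces as cases
(inter-observer consistency over faces); its confidence interval is the
Feldt F interval. Cross-panel consistency of the shared faces uses the
Fisher z interval tanh(atanh r ± 1.96/√(n−3)). Ratings are averaged over
observers into one score per face; screening keeps features whose
two-tailed Pearson p (from t = r√((n−2)/(1−r²))) is below 0.05.
No multiple-testing correction is applied by default — the screening is a
liberal pre-filter, and the downstream penalized models do the real
selection — but Benjamini–Hochberg is available behind a flag. Constant
features are excluded with a warning, never silently kept.

## Regression strategies

Predictors are standardized to mean 0, SD 1 (sample SD, ddof = 1) on the
training faces only; test data reuse the training parameters. The
response stays on the rating scale and every model fits an intercept.

* **OLS** — all screened predictors; rank-deficient designs fall back to
  the minimum-norm least-squares solution with a warning (so the N-sweep
  can run at N close to the number of faces).
* **SF / SB** — greedy forward/backward steps minimizing Gaussian AIC,
  n ln(RSS/n) + 2(p + 2); additive constants cancel in comparisons. Ties
  break by registry order. The full trace is recorded.
* **PCR / PLSR** — components on the standardized design (PCA via SVD;
  PLS via NIPALS through scikit-learn); the component count minimizes the
  pooled 10-fold CV RMSE; coefficients are reported back in feature space.
* **RR / LASSO / EN** — penalty λ[(1−α)/2‖β‖₂² + α‖β‖₁] (glmnet
  convention). λ is tuned on a 50-point log grid spanning
  [λ_max · 10⁻⁴, λ_max] with λ_max = max_j |x_jᵀ(y−ȳ)|/(n·max(α, 0.001)),
  the smallest penalty that zeroes all coefficients (KKT bound). EN also
  tunes α over {0, 0.1, …, 1}; ridge solves in closed form via SVD, the
  ℓ1-containing fits use coordinate descent. Selection minimizes the mean
  CV RMSE (the 1-SE rule is available behind a flag); λ ties resolve to
  the stronger penalty.

All tuned methods share one seeded 10-fold partition so comparisons are
paired. Model comparison reports RMSE and R² defined as the squared
Pearson correlation between observed and predicted scores; this
definition is calibration-blind (an affinely distorted prediction still
scores 1), so a conventional coefficient of determination is emitted
alongside for transparency but never used in comparisons. Predictors are
ranked by |standardized coefficient|, with unselected predictors ranked 0.
Correlated predictors are grouped by agglomerative clustering with
distance 1 − |r| and average linkage (both configurable), cut at 0.5 by
default.

## Variable-count simulation

For each predictor count N, a subset of N screened features is drawn
without replacement; OLS and the elastic net are fit on the training
faces and scored on both panels; 30 iterations per N are aggregated to
mean ± SD. At N = 1 regularisation is not applied — both arms reduce to
simple regression, representing the conventional univariate approach.
Subsets are drawn independently per (N, iteration); the same subset feeds
both arms within an iteration (paired comparison), and the elastic net is
re-tuned by 10-fold CV in every iteration. A nested-subsets mode (each
iteration's subsets grow monotonically across N) exists only to test the
monotonicity of OLS training error. The default grid is
{1, 3, 6, 10, 15, 21}, extended by the full screened count in the
pipeline so the sweep ends at the all-relevant-predictors model.

## Synthetic data

The generator emulates the study design the framework targets: a
training panel of 22 observers × 40 faces and an independent testing
panel of 51 observers × 60 new faces, with the 40 training faces re-rated
by the testing panel for consistency checks, all on a 1–7 Likert scale.

**Image level.** Faces are geometric templates (ellipses/rectangles on a
256-px canvas) — anatomically naive on purpose, since only mask semantics
matter to the extractor. Per-face region colours are drawn from a
palette of light East-Asian skin tones (e.g. cheek L\* 60 ± 3, a\* 14 ±
2.5, b\* 16 ± 2) with 60% of skin-region variance shared within a face;
i.i.d. Gaussian pixel noise with per-face SD uniform in [1, 3] ΔE drives
MCDM. Colours are written as sRGB with gamut clipping recorded per face.

**Table level.** The 65 features follow a latent-factor model: one factor
per colour attribute (lightness, redness incl. chroma, yellowness, hue),
one for the MCDM block, one per contrast feature. Loadings are 0.9 for
skin L\*, 0.85 for other skin coordinates and MCDM, 0.8 for contrasts and
0.55 for lip/brow/eye colours, giving within-block correlations of
0.72–0.81 — the "local lightness nearly duplicates average lightness"
redundancy that makes this modelling problem hard. The factors share a
signed common axis (weights ±0.55 for the attractiveness-relevant
factors, small or zero for redness/yellowness/eye contrast): lighter,
warmer-hued, more uniform skin with stronger mouth/brow contrasts
co-occurs across faces. Custom loadings outside [−1, 1] are rejected as
non-positive-semi-definite.

**Ratings.** Observer o rates face f as clamp(round(m + b_o + s_f + d_f +
ε_of), 1, 7) with midpoint m = 4, observer bias b_o ~ N(0, 0.5²), trial
noise ε ~ N(0, 0.8²), a sparse colour score s_f = Σ β_j z_j(f) over 11
supported cues (brow a\* contrast, overall and cheek MCDM, local hue
angles and lightness, mouth contrasts — the cue families the literature
reports as strongest), and a colour-independent face appeal d_f ~ N(0,
0.9²) drawn once per face and shared by every observer in both panels.
The appeal term is essential realism: without it, averaging 22+ observers
leaves almost no residual variance at the face level, colour would
explain ~95% of the score variance, and no model could overfit. With it,
colour carries ~55–60% of the score variance, inter-observer consistency
stays high (alpha ≈ 0.98), and OLS shows the out-of-sample degradation
the framework exists to diagnose. Effect sizes descend from |β| = 0.27
to 0.10 rating units per feature SD (latent SD ≈ 1.2), chosen so each
supported cue has a population marginal correlation of roughly 0.4–0.5
with the mean score — detectable but not trivial at 40 faces, where the
two-tailed critical |r| is 0.312.

What passing tests on this generator do **not** show: robustness to
segmentation errors, camera/display characterisation, non-linear or
interaction effects of colour on judgements, observer demographics, or
any claim about which cues matter for real faces — the planted truth is a
simulation device, not a finding.

## Numerical choices and degenerate inputs

Empty regions raise structured errors naming the region; constant
features and constant score vectors are rejected or flagged, never
imputed. Hue wraps to [0, 360) with the −0° edge mapped to 0. The
stepwise RSS is floored at 10⁻³⁰⁰ before the log. CV fold partitions,
subset draws and all generator draws descend from explicit integer seeds
(the pipeline expands one master seed per stage via `SeedSequence`);
identical configuration reproduces every output byte for byte.

Default problem sizes (the study-design panel sizes, 30-iteration sweeps,
5–30 seed replications in the tests) were chosen to match the emulated
design while keeping a full test run on one CPU within minutes.

## Known limitations

* The geometric face template exercises mask semantics, not realistic
  facial geometry; surround rings can include pixels of several skin
  regions, which is correct behaviour but means region-level permutation
  invariance holds only within measurement masks.
* The adapted-contrast orientation and the hue-as-scalar treatment in
  contrasts are documented choices; the literature leaves both open.
* R² as squared correlation can mask calibration error by design; use
  the accompanying coefficient-of-determination column when calibration
  matters.
* Min-CV-RMSE component selection in PCR/PLSR wanders along flat CV
  curves; the 1-SE rule gives sparser, more stable choices.
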