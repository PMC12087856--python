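# Methods

## The model

Penetration depth is treated as an ordinal five-class outcome
(Surface, SC, Epidermis, Dermis, Distant) of 19 descriptors of the
particle, the skin and the experiment.  The analysis makes no
mechanistic transport assumptions: classifiers learn the mapping
directly, and route inference is purely perturbational — skin
parameters that gate one anatomical route are nudged and the shift in
predicted layer occupancy is read as a route preference, never as
exclusive use of a route.

## Feature encoding

NP size descriptors span orders of magnitude, so diameter, surface
area, volume and concentration enter as log10.  Hydrophobicity lives on
two incompatible scales — logKow for organic-type particles, water
contact angle (degrees) for inorganic ones — and is folded into a
single min–max-normalized column plus a binary scale indicator, so one
ranked "hydrophobicity" variable survives while provenance is kept.
Categoricals (medium, species, region, shape, material class, in vivo)
are one-hot encoded.  Numeric columns are z-standardized with moments
fitted on the modelling set only; hold-out rows and in-silico
populations are pushed through the same fitted transform, so no
information leaks into evaluation.

## Synthetic study conditions

The generator (`npskin.synth`) emulates the statistical shape of a
literature-compiled dataset: ≈24% human skin with a pig-dominant
remainder; an aqueous-majority medium mix (55/25/15/5); core diameters
log-normal with median 45 nm and ln-σ 0.9 (≈80% ≤ 100 nm); ex vivo
temperatures uniform on 22–37 °C against ≈37 °C in vivo (35% of
records); contact times log-normal from 15 min to one week; and MCAR
missingness at literature reporting rates (hydrophobicity 30%,
concentration 15%, temperature 10%, contact time 5%).  Skin descriptors
are drawn around a built-in (species, region) reference table whose
anchors are reported values: human hair-follicle diameters
71.3/97/103.2/140.3/146.3 µm (face/abdomen/arm/back/breast), rat-back
14 µm, pig-abdomen 185 µm, and back-region animal thicknesses
reconstructed from the reported percent differences vs human.  Human
back absolute thicknesses (SC 17 µm, epidermis 70 µm, dermis 2.4 mm)
are literature-typical choices; per-record jitter uses a coefficient of
variation of 0.08 (0.05 for lipid properties).  That CV is deliberately
tighter than the spread across regions: it keeps each (species, region)
group's descriptors identifiable so the planted rule below remains
recoverable at realistic sample sizes.

Labels come from a planted rule: a latent score linear in anchored
z-scaled descriptors, cut at fixed thresholds.  The hair-follicle
diameter coefficient (2.0) dominates; hydrophobicity, core diameter
(log), SC thickness, temperature, lipid properties and follicle density
follow with small coefficients in that order, mirroring the importance
ranking the analysis is meant to recover.  Thresholds sit in
low-density gaps of the score (follicle diameters ≈18.5, 31, 55 and
168 µm), giving class shares ≈ 9/13/14/53/11% — Dermis-heavy, which is
coherent with follicular penetration being scored as dermal.  Gaussian
latent noise (default sd 0.25) makes labels near boundaries stochastic;
`noise_sd=0` gives a fully separable rule that the generator can verify
by direct evaluation.

What the generator does **not** emulate: non-linear descriptor-depth
relationships (the planted score is linear, so linear classifiers are
near-oracle here and the large real-data gap between random forest and
PLS does not reproduce), per-study citation structure, correlated
(non-MCAR) missingness, and NP-dominated penetration — in this
synthetic world depth is skin-dominated, so a population in a fixed
human-back context concentrates in one predicted layer and 5–20% skin
perturbations rarely move it.  Passing tests therefore certify the
machinery (splitting, metrics, importance, scenario accounting), not
real-data effect sizes.

## Imputation

Chained equations: each incomplete column is regressed on all others —
ordinary least squares for numeric columns, multinomial logistic for
one-hot groups — and missing cells are replaced by prediction plus
residual-scale Gaussian noise (class draws from predicted
probabilities), cycling 10 iterations; m = 8 independent chains seeded
`seed + chain`.  Observed cells are never altered.  The default
reduction averages numeric cells and majority-votes categoricals across
chains; `stack` keeps all completions for sensitivity analysis.  The
per-iteration mean absolute change of imputed cells is logged as a
convergence trace.

## Splitting

Hold-out is always a random 20% cut.  Within the modelling set the
train:validation division (75:25) is random or rational:
Kennard-Stone (max–min Euclidean selection, ties to the lowest row
index), k-means with k chosen by the largest second difference of the
within-cluster sum of squares over k = 2..20, or a hexagonal Kohonen
SOM (learning rate decaying 0.05→0.01, Gaussian neighbourhood, grid
side ⌈√(5√n)⌉) with proportional sampling per cluster/unit (≥1 training
point each).  All three operate on the standardized, imputed matrix
with one-hot columns included.

## Classifiers and metrics

Decision tree, random forest (500 trees), k-NN, PLS-DA and RBF kernel
SVM (median-heuristic width, one-vs-one).  PLS-DA is the two-step
formulation — one-hot PLS reduction, then LDA on the x-scores — which
places class boundaries by the latent class structure rather than raw
least-squares responses.  Hyperparameters come from a small documented
grid searched by validation accuracy (tree depth; forest max-features;
k; PLS components ≤ 10; SVM C and kernel-width scale), with the winner
refitted on train+validation.  Labels are trained as ordinal codes
0–4, so estimator tie-breaks resolve toward the shallower layer — the
conservative direction for penetration claims.  Accuracy is exact-class
match; chance-corrected agreement uses Cohen's kappa computed from the
confusion matrix.  k-NN is reported but excluded from the headline 4×4
grid: its neighbourhood vote cannot express within-group depth
boundaries and it is not part of the benchmark grid.

VIP scores use per-component-normalized x-weights and per-component
explained sum of squares, normalized so Σ VIP² equals the number of
x-variables exactly.  Permutation importance shuffles descriptor
groups (one-hot blocks jointly) on validation data, 10 repeats,
rescaled so the top overall descriptor reads 100, with a comparative
reporting threshold of 10; per-layer scores repeat the computation
one-vs-rest.  Caveat: with strongly correlated proxies (body region
determines the follicle-calibre group mean) permutation credit can
split between a descriptor and its proxy.

## Applicability domain and in-silico population

PCA to 3 components (reduced with a warning on rank-deficient input),
convex hull of the training scores, membership by Delaunay simplex
lookup (boundary inclusive).  In-silico NPs are sampled uniformly
between the source dataset's observed min and max per descriptor
(log-uniform for diameter and concentration), categoricals uniformly
over observed levels, geometry re-derived from diameter and shape; the
skin context is fixed to human back at 32 °C, ex vivo, 24 h (all
configurable).  Out-of-domain particles are flagged, not filtered.
Per-layer descriptor ranges are compared by tie-corrected
Kruskal–Wallis with Dunn's pairwise z post hoc; Holm adjustment is the
default (the choice of correction is the package's own).

## Route scenarios

Baseline plus three multiplicative perturbations at 5/10/15/20%:
reduced follicle density (transappendageal gate), increased
lipophilicity + decreased polarity of SC lipids (intercellular gate),
and the polar opposite (intracellular gate).  Only follicle *density*
is perturbed, not diameter.  Occupancy percentages close to 100 within
each medium × scenario cell; deltas are vs the magnitude-0 baseline; a
route label fires when any layer moves by ≥1 percentage point, and
labels are always reported alongside the deltas.

## Species comparison

Back-region SC/epidermis/dermis thickness vectors are z-scored per
layer across species before Euclidean distances — without
standardization the millimetre-scale dermis would swamp the
micrometre-scale SC.  Under the reconstructed values, rabbit and pig
are the two species nearest to human (distances 2.21 and 2.48) with the
rodents far behind; the margin between rabbit and pig is small and
sensitive to the standardization convention.

## Reproducibility

A single top-level seed fans out to per-stage seeds by CRC32 hashing of
the stage name (kept below 2³¹); the pipeline manifest records stage
seeds and artifact SHA-256 checksums, and a rerun under the same seed
is byte-identical.  Default problem sizes — 500 records, m = 8
imputations, 60,000–100,000 in-silico NPs — are the package's study
conditions; tests use smaller instances of the same generators.

## Known limitations

Real compiled literature data is required for the benchmark accuracy
grid (the package reproduces the machinery, not the paper-scale effect
sizes); the planted linear rule makes PLS-DA competitive with random
forest, unlike on real data; the fixed-context in-silico stage can be
degenerate (single predicted layer), which the pipeline records as a
result rather than an error; and Dunn's correction choice, the SOM
grid heuristic, and the hull dimensionality are documented defaults,
not uniquely determined choices.
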