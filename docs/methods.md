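# Methods

## Problem and model

Real α-helices deviate from the canonical geometry (φ = −63°, ψ = −43°,
~3.6 residues per turn, 1.5 Å rise) in recurring ways: they stretch,
kink at a proline, bend gradually, or compact at the C-terminal cap.
`helixvar` characterizes these deviations from Cα geometry alone and asks
whether a helix's sequence (plus four residues of flanking context) is
enough to predict if it is regular or distorted.

The analysis proceeds in five stages.

### 1. Geometric-invariant description of octapeptide windows

Each helix is represented by its ordered Cα coordinates. An 8-residue
sliding window (step 1; consecutive windows share 7 residues) is
summarized by 29 scalars that are invariant under rotation and
translation:

| family | count | definition |
|---|---|---|
| d18 | 1 | Euclidean distance Cα1–Cα8 |
| A158 | 1 | area of triangle (Cα1, Cα5, Cα8) |
| d(i, i+3), i = 1..5 | 5 | span of each 4-residue tetrahedron |
| d(i, i+4), i = 1..4 | 4 | one-turn distances |
| vol(i..i+3), i = 1..5 | 5 | signed volume of consecutive tetrahedra |
| vol(i, i+1, i+2, i+4), i = 1..4 | 4 | signed "handedness" tetrahedra |
| perimeter(i..i+3), i = 1..5 | 5 | 6-edge sum of each tetrahedron |
| area(i, i+2, i+4), i = 1..4 | 4 | skip-one triangle areas |

Signed volumes are scalar triple products / 6; they flip sign under
mirror reflection, so positive handedness volumes identify a right-handed
helix. d18 and A158 are the *gross* descriptors: d18 grows for extended
and kinked helices and shrinks for curved ones; A158 grows whenever the
axis bends. The five (d(i, i+3), vol(i..i+3)) pairs form a *per-position
profile* that is flat for a regular helix and localizes a deformation to
specific tetrahedra. The component order above is frozen
(`geometry.INVARIANT_NAMES`); it includes every descriptor the analysis
interprets, completed to 29 from the same distance/area/perimeter/volume
families.

Ideal helices are constructed by the standard internal-coordinate (NeRF)
chain build with textbook backbone geometry (N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180°).
At the canonical torsions this yields d18 = 10.74 Å and A158 = 10.49 Å²
for an octapeptide, inside the regular-subclass reference bands
(10.64 ± 0.34 Å and 10.40 ± 1.50 Å²).

### 2. Subclass discovery: standardize → PCA → Gaussian mixture

Invariant columns are standardized to zero mean / unit sd (zero-variance
columns get sd 1 with a warning). PCA retains the smallest number `s` of
components reaching a cumulative explained-variance fraction (default
0.80). In PC space a k-component full-covariance Gaussian mixture is
fitted by EM; components correspond one-to-one to conformational
subclasses, and each window is assigned by maximum posterior
responsibility (ties to the lowest component index).

EM details: initialization from seeded k-means hard assignments, 5
restarts (best final log-likelihood kept), convergence when the relative
total log-likelihood change drops below 1e-6 (max 500 iterations), ridge
1e-6 on covariance diagonals to survive degenerate clusters. The
implementation keeps the per-iteration log-likelihood trace, which is
non-decreasing by construction and asserted in tests; on well-separated
data it agrees with scikit-learn's `GaussianMixture` to the reported
tolerances (that library is used as a cross-check only). `k` is a
required input; no model-selection criterion is built in.

Because consecutive windows overlap by 7 residues, the same local
deformation observed at shifted in-window positions produces distinct
but redundant mixture components. `detect_shift_redundancy` compares,
for every pair of sufficiently populated subclasses (≥ 50 members), their
mean (d(i, i+3), vol(i..i+3)) profiles under integer shifts of up to ±4
positions and groups pairs whose best shifted Pearson correlation is
≥ 0.95. Shifts leaving fewer than 3 overlapping positions per profile are
skipped (a Pearson correlation on ≤ 2 points is vacuous), so |shift| = 4
can never win; the representative of a group is its largest member unless
overridden, mirroring manual curation.

### 3. Helix assembly

Maximal runs of consecutive windows (start offsets differing by 1) merge
into helices of length 8 + (run − 1). *Within*-subclass merging breaks
runs at label changes, producing subclass-pure stretches for propensity
statistics; *across*-subclass merging ignores labels and recovers the
full helix, recording the label of every constituent window. Classifier
training keeps across-merged helices of length 8–15 whose windows all
carry a single label (strict purity; mixed helices are discarded),
regular ones as positives and everything else as negatives. Flanks of
up to 4 residues are attached from the parent chain with an explicit
validity mask; chain-terminal positions are masked, never dropped, so the
flank contract is fixed-width.

### 4. Propensity statistics

Propensity is a Chou–Fasman-style ratio: relative frequency of an amino
acid in a context divided by its background relative frequency, > 1
meaning preferred. The background defaults to the pooled composition of
all analyzed helices (overridable). Contexts are: the whole subclass
(overall), positions N1..N4 (first four residues), C4..C1 (last four;
C1 is the final residue), and M1..M4 for helices longer than 12
residues, defined as residues 5..8 — immediately after N4, the only
placement that keeps M and C blocks disjoint for every qualifying length.
No pseudocounts by default (zero counts give propensity 0 and keep the
count for inspection); a +0.5 pseudocount is available. Ranking returns
residues above a threshold (default 1.2), best first, ties alphabetical.

### 5. Sequence classifier

Each training helix is encoded into 440 features: six composition blocks
(whole helix, N-terminus, C-terminus, middle, prior flank, after flank;
20 features each — per-residue relative frequencies within the
subsequence) and four positional one-hot blocks (N1..N4, C4..C1, and the
four positions of each flank; 80 features each), 6·20 + 4·80 = 440.
The middle subsequence is positions 4..6 for length-8 helices and
4..(length−4) otherwise — position 4 deliberately belongs to both the
N-terminus and the middle. No positional features are computed for the
middle (most negative examples have length 8, so such features would be
mostly empty). Masked flank positions contribute zeros. Vectors are
scaled to unit Euclidean length, making the linear kernel a dot product
in [0, 1].

A soft-margin linear SVM (scikit-learn's SVC behind the `train` surface;
C defaults to 1.0, the library default) separates the classes. Feature
weights are recovered from the support-vector expansion
w_j = Σ_i α_i y_i (x_i)_j and must reproduce the decision values
w·x + b to 1e-8 — asserted in tests. Evaluation reports precision
TP/(TP+FP), recall TP/(TP+FN) and their harmonic mean F1, both pooled
over stratified 10-fold cross-validation (pooled confusion counts) and
per fold, plus a 70/30 stratified holdout. Decision values of exactly 0
predict the positive class.

## Synthetic corpus

No redistributable corpus of labeled helix subclasses exists, so the
package generates one with the statistical structure the analysis
assumes. It is a model system, not a physical simulation.

**Geometry.** Each subclass is a parametric deformation of the ideal
helix, applied in an exact axis frame (axis direction from cross
products of successive second differences — exactly radial for a
circular helix — plus an algebraic circle fit for the center):

- *regular*: ideal helix;
- *extended*: axial coordinates scaled ×1.08 (rise ≈ 1.65 Å);
- *kinked*: downstream of residue 5 the helix is rotated 25° about an
  in-plane axis through the kink Cα and shifted 1.2 Å along the axis
  (a proline kink both tilts and locally opens the backbone). The bend
  azimuth is chosen deterministically to maximize the (first, middle,
  last)-Cα triangle area subject to extending the end-to-end distance,
  reproducing the extended-but-bent character of kinked helices;
- *curved*: the helix is re-wound around a circular-arc axis of
  curvature 0.08 Å⁻¹ using its cylindrical coordinates and the arc's
  local frame (a naive coordinate bend stretches the outer fiber and
  *increases* the end-to-end distance; re-winding preserves local
  geometry);
- *c-cap*: the last 3 residues are pulled toward the axis (radius ×0.6,
  graded) with local rise ×0.9 — a compact C-terminal cap.

Isotropic Gaussian coordinate noise (σ = 0.15 Å, roughly coordinate
uncertainty at moderate crystallographic resolution) is added to every
trace. At these defaults the noise-free octapeptide signatures are
d18 = 11.59 (extended) > 10.74 (regular) > 10.30 (c-cap) > 9.32 (curved)
Å, with the kinked class largest in A158 (15.4 vs 10.5 Å²) — the
qualitative ordering the gross invariants are meant to detect — and the
five classes form well-separated clusters in invariant space.

**Sequences.** Each subclass has an overall enrichment profile over a
natural amino-acid background plus positional multinomials for N1..N4 and
C4..C1 (preferred residues boosted 4× before renormalization) and flank
profiles (3× boost; e.g. Gly-enriched before regular helices,
Pro-enriched after). Signature enrichments sit in the 2–4× range:
regular helices favor A/L/I/E/Q and deplete P/G and aromatics; kinked
and curved helices enrich P (3×), D/H (2×) and aromatics; c-cap enriches
H and aromatics with a Gly cap at C1. Setting `uniform_profiles=True`
removes all sequence–label coupling and is the negative control: the
classifier must then fall to the chance level implied by the class
prior.

**Counts and lengths.** Helix lengths follow per-subclass bin
probabilities (l = 8 / 9–15 / >15) matching the coarse empirical
distribution (regular helices long, distorted subclasses mostly minimal).
Generation proportions (regular 0.6885, extended/c-cap 0.1198 each,
kinked 0.0479, curved 0.0240; 5:5:2:1 among the distorted classes) are
solved so that the length-≤15 training subset is 62% regular — the
positive fraction of the reference corpus. The window-level dataset for
mixture studies uses proportions 0.76/0.05/0.05/0.02/0.01 for the five
subclasses plus an 0.11 filler group of mirrored (left-handed) regular
windows, a geometrically distinct sixth cluster whose signed volumes are
negative.

**What passing tests do and do not show.** The generator produces
idealized, well-separated clusters and cleanly parameterized sequence
biases; real helices have correlated noise, boundary ambiguity,
non-Gaussian subclass shapes and much weaker sequence signal. Results on
this corpus validate the *machinery* (invariants, EM, merging, counting,
encoding, training) and the directional relationships, not expected
performance on real structures.

## Numerical choices and degenerate inputs

- Window starts and residue indices are 1-based; windows are closed
  intervals [start, start+7].
- Traces whose consecutive Cα–Cα distances leave (2.0, 4.5) Å warn but
  are processed; duplicated coordinates in a window warn and yield
  forced zeros, not errors, so bulk runs survive malformed inputs.
- Alternate PDB conformer locations resolve to highest occupancy;
  residues without a Cα are skipped with a warning; a missing chain is a
  lookup error.
- PCA at threshold 1.0 returns the numerical rank (eigenvalues above
  1e-10 of the largest).
- Non-standard residue letters contribute nothing to the encoding (with
  a warning); a fully degenerate (zero) encoding is rejected.
- All randomness (noise, sampling, k-means init, fold shuffling) is
  seeded; the pipeline propagates one master seed.

## Pipeline defaults and problem sizes

The default run generates 2,000 helices (≈ 9,000 windows), retains PCs to
80% variance, fits k = 5 components, merges, computes propensity tables
and trains/evaluates the classifier with 10-fold CV — a few minutes on
one CPU. Tests use the 3,000-helix dataset-config default for classifier
checks and 20,000 windows for mixture recovery; these sizes give stable
statistics (mixing-weight recovery to ±0.02, F1 stable to ~0.01) while
staying desk-scale. Stages exchange serialized files only, so invariants
computed from real PDB chains can replace the synthetic corpus at the
`subclass` stage onward.

## Known limitations

- Cα-only geometry: no hydrogen bonds, no DSSP-style assignment; helix
  boundaries must come from labels or upstream annotation.
- The 29-invariant list is a documented completion of the named
  descriptors; other completions of the same families are possible.
- `k` must be chosen by the user; no BIC/AIC.
- Strict purity for training segments discards every mixed helix;
  tolerance for minority windows is not configurable.
- The classifier is linear and uncalibrated; per-sequence features are
  composition fractions and indicators, not class-level propensities
  (which would leak labels).
- The F1 identity F1 = 2PR/(P+R) is enforced throughout; printed
  reference values that disagree with their own P/R by rounding are not
  reproduced.
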