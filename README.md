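# helixvar

Geometric characterization of α-helix structural subclasses and
sequence-based prediction of helix distortions.

Real α-helices are rarely the textbook spiral (φ = −63°, ψ = −43°,
rise ≈ 1.5 Å/residue): they stretch, kink at prolines, curve gradually,
or compact at the C-terminal cap. `helixvar` is for structural
bioinformaticians and protein designers who want to (a) detect and
classify such distortions from Cα coordinates alone and (b) test how far
a helix's amino-acid sequence predicts whether it is regular or
distorted.

## What it does

1. **Invariant description** — every 8-residue window of a Cα trace
   (consecutive windows overlap in 7 residues) is summarized by 29
   rotation/translation-invariant scalars: the end-to-end distance
   d₁₈, the triangle area A₁₅₈, per-tetrahedron spans d(i, i+3), signed
   tetrahedron volumes (whose sign encodes handedness), perimeters and
   skip-one triangle areas. A regular helix has a flat per-position
   profile; a deformation shows up at specific tetrahedra.
2. **Subclass discovery** — invariants are standardized, reduced by PCA
   (components retained to a variance threshold, default 80%), and
   modeled as a k-component Gaussian mixture fitted by EM; windows are
   assigned by maximum posterior. Subclasses that are the same
   deformation at shifted window positions are detected by shifted
   profile correlation.
3. **Helix assembly** — overlapping windows merge into full helices
   (length 8 + windows − 1), either within one subclass (for propensity
   statistics) or across subclasses (for classifier training), with
   4-residue flanking context.
4. **Propensity statistics** — Chou–Fasman-style ratios
   (class frequency / background frequency), overall and per position
   (N1..N4, C4..C1, M1..M4), with preferred-residue ranking.
5. **Sequence classifier** — helices of length 8–15 plus flanks are
   encoded into a unit-normalized 440-feature vector (six 20-dim
   composition blocks + four 80-dim positional one-hot blocks) and
   separated by a soft-margin linear SVM, K(x, x′) = x·x′. Feature
   weights w_j = Σᵢ αᵢ yᵢ (xᵢ)_j recover which sequence signals drive
   the prediction; precision/recall/F1 are reported under stratified
   10-fold cross-validation and a 70/30 holdout.

Because no labeled corpus of helix subclasses is redistributable, the
package ships a first-class synthetic generator (`helixvar.synthetic`)
that emulates one: five geometric subclasses (regular, extended, c-cap,
kinked, curved) as parametric deformations of the ideal helix, paired
with subclass-biased sequences. See `docs/methods.md` for the model,
all defaults, and what the synthetic corpus does and does not show.

## Worked example

Run the full pipeline on a 600-helix synthetic corpus:

```sh
helixvar run --out demo_run --seed 0
# or, from Python:
```

```python
from helixvar.pipeline import RunConfig, run
run(RunConfig(out_dir="demo_run", seed=0, n_helices=600, k=5, folds=5))
```

The log prints (seed 0):

```
generate: 600 helices ({'regular': 422, 'c-cap': 68, 'extended': 62, 'kinked': 40, 'curved': 8})
invariants: 2905 windows x 29 invariants
subclass: k=5, s=7 PCs, weights=[0.024, 0.468, 0.014, 0.083, 0.411]
merge[within]: 690 segments
merge[across]: 600 segments
classify: n=503 (+325/-178) CV P=0.849 R=0.954 F1=0.899
```

and `demo_run/gross_invariants_by_subclass.tsv` contains the
per-component gross descriptors:

```
component  mapped_subclass  n_windows  d18_mean  d18_sd  A158_mean  A158_sd
        0            c-cap         71     10.31    0.21       8.86     1.05
        1          regular       1370     10.70    0.21      10.39     1.03
        2           kinked         40     11.24    0.23      15.67     1.09
        3         extended        194     11.35    0.59      11.29     1.21
        4          regular       1230     10.79    0.19      10.66     0.98
```

Reading this: extended windows are longest end-to-end (d₁₈ 11.35 Å vs
10.70 Å for regular), kinked windows blow up the (1,5,8) triangle area
(15.7 Å² vs 10.4 Å²), c-cap windows are slightly compacted. Two
components both map to "regular": windows of a deformed helix that lie
away from the deformation site look regular — the shift-redundancy
phenomenon that `detect_shift_redundancy` groups. The classifier
separates regular from distorted sequences at F1 ≈ 0.90 on this corpus
(precision 0.849, recall 0.954, 5-fold CV); with the default corpus and
10 folds it reaches F1 ≈ 0.93. `metrics.json`, propensity tables and the
ranked 440 feature weights (proline composition strongly negative,
C1-glycine strongly positive, Leu/Ile/Ala composition positive) land in
the same directory.

## Layout

```
src/helixvar/
  geometry.py        Cα traces, ideal-helix builder, PDB I/O, 29 invariants
  subclass_model.py  standardizer, PCA, EM Gaussian mixture, redundancy
  assembly.py        window merging, flanks, training-segment selection
  propensities.py    overall/positional propensity tables, length bins
  classifier.py      440-feature encoding, linear SVM, evaluation
  synthetic.py       subclass geometry + sequence generator
  pipeline.py / cli.py  staged orchestration and the `helixvar` CLI
```
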