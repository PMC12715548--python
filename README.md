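# factorscape

Dimensional subtyping of brain networks: latent-factor decomposition of
morphometric similarity (MIND) and functional connectivity (FC) matrices,
with behavioral and neurotransmitter-receptor characterization of the
recovered factors.

## The problem

Clinically heterogeneous conditions such as autism spectrum disorder resist
discrete clustering: individuals rarely belong to a single "subtype".  A
dimensional alternative decomposes a cohort of brain-network matrices into a
small number of latent factors and assigns every subject a *loading vector on
the simplex* — a graded profile rather than a class label.  This package
implements that pipeline for two complementary network modalities:

* **FC** — Pearson correlation between regional BOLD time series (state-like,
  dynamic);
* **MIND** (Morphometric Inverse Divergence) — structural similarity between
  regions computed as `MIND(i,j) = 1 / (1 + D(i,j))`, where `D` is the
  symmetrized Kullback–Leibler divergence between the regions' multivariate
  distributions of vertex-wise morphometric features (thickness, volume,
  area, curvature, sulcal depth); trait-like, stable.

Because the MRI cohorts this kind of analysis targets are access-restricted,
the package ships a first-class synthetic-cohort generator with complete
ground truth (factor matrices, simplex loadings, region Gaussians, receptor
maps, behavioral couplings), so every stage is testable by parameter
recovery.

## The model

Each subject's signed matrix is discretized into a "document" over an edge
vocabulary: lower-triangle edge `e` with value `x` contributes
`round(s·max(x,0))` counts of the positive-channel word (hyper-connectivity /
hyper-similarity) and `round(s·max(−x,0))` counts of the negative-channel
word (hypo-).  Smoothed latent Dirichlet allocation with K factors is then
fitted by batch variational EM:

    θ_i ~ Dirichlet(α),  β_k ~ Dirichlet(η),  w | z ~ Multinomial(β_z)

yielding per-factor word distributions (rendered as signed R×R matrices,
`P(pos|k) − P(neg|k)` per edge) and per-subject loadings `θ_i` on the
K-simplex.  The evidence lower bound is tracked every iteration and is
coordinate-ascent monotone; the best of several random restarts is kept.

Fitted factors are characterized by (i) lower-triangle Pearson correlation
with healthy-control average patterns and across modalities
(structure–function coupling), (ii) Pearson correlation of loadings with
behavioral scale scores, and (iii) ordinary least squares of each factor's
first-principal-component summary vector on 19 standardized receptor density
maps, with empirical p-values from a **spin permutation null** (random sphere
rotations, mirrored across hemispheres, with optimal unique reassignment of
parcels) that respects spatial autocorrelation.

## Worked example

```bash
python examples/factor_decomposition.py
```

```
converged: True after 36 iterations (best of 5 restarts)
factor pattern recovery r : [1. 1. 1.]
subject loading recovery r: [0.998 0.998 0.998]
example subject loadings  : [0.057 0.647 0.297] (sum = 1)
```

A 100-subject cohort was generated as Dirichlet(0.5) mixtures of 3 known
signed factors (20 regions, noise SD 0.05), discretized at count scale 10 and
refitted.  After alignment, each recovered factor correlates ~1.0 with its
generating pattern and each loading column correlates ~1.0 with the true
mixing weights — the decomposition is essentially exact at this noise level.
The example subject is read as "65% factor 2, 30% factor 3".

Other examples (`examples/*.py`) cover MIND estimation against the
closed-form Gaussian divergence, Fisher-z run averaging, the
behavior-dissociation analysis, and the receptor spin test.

The full pipeline runs end-to-end from the shell:

```bash
factorscape demo --out demo_out --seed 7
```

which simulates a cohort (20 regions, 60 subjects), computes MIND and FC,
factorizes both modalities (K=3), and writes correspondence, behavior and
receptor tables plus a manifest of output hashes; reruns with the same seed
are byte-identical.

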