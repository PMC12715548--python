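"""Reproduce the structural-vs-functional behavior dissociation on truth.

Behavior scores are coupled to the morphometric (MIND-side) factor loadings
only; functional (FC-side) loadings are independent.  The correlation tables
then show significant MIND cells and null FC cells — the headline dissociation
pattern this package's statistics are designed to detect.
"""

import numpy as np

import factorscape as fs
from factorscape.synthetic import behavior_noise_for_target_r, dirichlet_loading_variance

K, N = 3, 150
rng = np.random.default_rng(1)
load_mind = rng.dirichlet([0.5] * K, N)
load_fc = np.random.default_rng(2).dirichlet([0.5] * K, N)

effects = np.zeros((3, K))
effects[0, 1] = 1.0   # SCQ couples to MIND factor 2
effects[1, 0] = -1.0  # SRS couples (negatively) to MIND factor 1; RBSR is null
noise = behavior_noise_for_target_r(dirichlet_loading_variance(0.5, K), 1.0, 0.3)
behavior = fs.gen_behavior(load_mind, effects, noise_sd=noise, seed=3,
                           scale_names=["SCQ", "SRS", "RBSR"])

for name, loadings in (("MIND", load_mind), ("FC", load_fc)):
    tbl = fs.loading_behavior_correlations(loadings, behavior)
    sig = tbl[tbl.p < 0.005]
    print(f"{name} loadings: {len(sig)} significant cells at p < .005")
    for _, row in sig.iterrows():
        print(f"   {row.factor} x {row.scale}: r = {row.r:+.2f}, p = {row.p:.2g}")

# Expected: MIND cells reach significance at the ~0.3 effect size while no FC
# cell does - behavior tracks the structural, not the functional, loadings by
# construction.  Note that simplex loadings are negatively correlated across
# factors, so a scale coupled to factor 1 can surface through factor 2 as well.
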