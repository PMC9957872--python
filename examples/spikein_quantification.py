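"""Spike-in-calibrated CUT&RUN quantification with a planted fold change.

Simulates negative-binomial counts at 500 loci for WT and mutant genotypes
whose true binding doubles (log2FC = 1) in the mutant, with spike-in depths
deliberately diverging 3-fold across samples, then recovers the fold change
after E. coli spike-in calibration and compares |log2FC| magnitudes between
an affected and an unaffected genotype with a Mann-Whitney test.
"""

import numpy as np

from regboot import (
    SimulationConfig,
    abs_log2fc_compare,
    differential_signal,
    simulate_count_matrix,
)
from dataclasses import replace

cfg = SimulationConfig(seed=11, n_loci=500, nb_mean=100.0,
                       true_log2fc=1.0, spikein_depth_range=3.0)
matrix, truth, groups = simulate_count_matrix(cfg)
print(f"spike-in depths span {matrix.spike_in.max() / matrix.spike_in.min():.1f}x")

tables = differential_signal(matrix, groups, reference="WT")
median_lfc = float(np.median(tables["MUT"]["log2fc"]))
print(f"median recovered log2FC = {median_lfc:.3f} (planted: 1.0)")
print("spike-in scaling removed the depth differences; the estimate tracks"
      " the true binding change, not library size")

# an interaction-corrected genotype with no binding change
cfg0 = replace(cfg, seed=12, true_log2fc=0.0)
matrix0, _, groups0 = simulate_count_matrix(cfg0)
tables0 = differential_signal(matrix0, groups0, reference="WT")
u, p = abs_log2fc_compare(tables["MUT"], tables0["MUT"])
print(f"Mann-Whitney on |log2FC| (affected vs corrected): p = {p:.2e}")
print("a small p says binding departs from WT far more in the affected"
      " genotype than in the corrected one")
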