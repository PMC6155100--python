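"""From one scan's node time series to a connectivity matrix.

Shows the per-scan processing contract: residualize node series on the
nuisance regressors, temporally filter (band chosen by paradigm class),
correlate all node pairs, and vectorize the upper triangle.
"""

import numpy as np

import crossconn as cc

cohort = cc.generate_cohort(cc.SynthConfig(group_sizes=(5, 5), effect_sizes=(0, 0.8), seed=7))
scan = cohort.scan("sub0000", "par0")  # the resting-state paradigm

clean = cc.regress_nuisance(scan)
resid_dot = np.max(np.abs(clean.data @ np.column_stack(
    [np.ones(scan.n_timepoints), scan.nuisance])))
print(f"max |residual . regressor| after nuisance regression: {resid_dot:.2e}")

filtered = cc.temporal_filter(clean, 0.008, 0.1)   # rest: band-pass
conn = cc.compute_connectivity(filtered)
edges = cc.vectorize_edges(conn)

print(f"connectivity matrix: {conn.n_nodes} x {conn.n_nodes}, "
      f"edge vector length {edges.shape[0]} (= N(N-1)/2)")
print(f"mean correlation {edges.mean():.3f}, range [{edges.min():.3f}, {edges.max():.3f}]")
assert np.array_equal(cc.devectorize_edges(edges), conn.matrix)
print("vectorize/devectorize round trip: exact")
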