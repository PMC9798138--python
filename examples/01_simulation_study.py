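"""Simulation study on the Raf pathway: how sample count and timing
affect network recovery.

Simulates time-series from the 11-node Raf signalling network, scores all
node pairs with each association measure and reports the AUROC of
recovering the 19 true directed edges, across series lengths and
sampling intervals (small replicate counts for a quick demonstration).
"""

from phosphonet import simnet as sn

net = sn.load_raf_network()
print(f"Raf network: {net.n_nodes} nodes, {net.n_edges} directed edges\n")

cfg = sn.SimulationConfig(n_datasets=20, seed=0)

print("AUROC vs series length (VAR dynamics, 20 replicates):")
df = sn.run_sweep(net, cfg, lengths=[8, 20, 100], measures=["pearson", "ggm", "mi"])
print(df.groupby(["grid_value", "measure"])["auc"].mean().unstack().round(3))
print("-> recovery improves with more timepoints; at length 8 the 11",
      "variables outnumber the samples and every measure struggles.\n")

print("Grand-mean AUROC over all six measures vs sampling interval")
print("(length-100 series, 60 replicates):")
cfg_i = sn.SimulationConfig(n_datasets=60, seed=0)
df = sn.run_sweep(net, cfg_i, intervals=[1, 2, 3, 4])
print(df.groupby("grid_value")["auc"].mean().round(3))
print("-> intermittent sampling drifts recovery toward chance (0.5): the",
      "lag-1 dependencies that carry the signal are skipped over.  The",
      "residual margin above 0.5 comes from same-time covariance between",
      "nodes sharing an upstream regulator.")
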