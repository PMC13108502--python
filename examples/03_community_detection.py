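"""Multilayer community detection on a planted temporal network.

Generalized Louvain maximises the multilayer modularity Q_G (gamma = 1,
omega = 1); an ensemble of independent runs absorbs the heuristic's
run-to-run variability.
"""

import numpy as np

from dynconn import (
    ModularityConfig,
    PlantedMultilayerSpec,
    count_communities,
    generate_planted_stack,
    modularity_value,
    run_ensemble,
)

spec = PlantedMultilayerSpec(
    n_nodes=16, n_layers=8, n_communities=4, noise_sd=0.05,
    switchers=frozenset({0}), switch_layers=frozenset({4}), seed=2,
)
stack, truth = generate_planted_stack(spec)

config = ModularityConfig(gamma=1.0, omega=1.0, n_iter=100, seed=0)
ensemble = run_ensemble(stack, config)
qs = np.array([p.q_value for p in ensemble])
print(f"{len(ensemble)} runs, Q_G in [{qs.min():.4f}, {qs.max():.4f}]")

stats = count_communities(ensemble)
print(f"communities per layer: mean {stats['mean']:.2f} (SD {stats['sd']:.2f})"
      f" -- planted: {spec.n_communities}")

best = max(ensemble, key=lambda p: p.q_value)
q_truth = modularity_value(stack, truth.labels, config)
print(f"best-run Q {best.q_value:.4f} vs ground-truth labelling Q {q_truth:.4f}")
# with noise_sd this small, the optimiser reaches (or slightly exceeds, via
# noise-fitting) the planted labelling's modularity and the community count
# matches the planted one.
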