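# hetsort

**Spatial sortedness of cell-intrinsic heterogeneity in excitable-cell
networks.**

Electrically coupled excitable cells — the motivating case is the
insulin-secreting beta cells of a pancreatic islet — are not identical:
a minority subpopulation is intrinsically more excitable than the rest.
`hetsort` asks how the *spatial arrangement* of that minority, not just
its size, shapes collective network dynamics. It provides:

* **Single-cell models** — the FitzHugh–Nagumo (FHN) caricature and the
  Sherman–Rinzel–Keizer (SRK) biophysical beta-cell burster, with
  closed-form / eigenvalue-based Hopf-bifurcation detectors. The FHN
  cell destabilises at compound drive G·I ≈ 0.33; the SRK cell at leak
  conductance ḡ_L ≈ 45.21 pS (G = 0), following the level set
  (1 − G)·ḡ_L = const.
* **Network substrates** — Watts–Strogatz small-world rings and an
  islet-like spherical hexagonal-close-packed lattice (1,018 nodes,
  interior coordination 12).
* **A sortedness metric and a sorter** — network sortedness
  A ∈ [−1, 1] measures how spatially clustered the two populations
  are (A ≈ 0 random, A = 1 fully segregated, A < 0 anti-clustered).
  A stochastic label-swapping sorter moves a random arrangement toward
  (or away from) full sortedness one accepted swap at a time, recording
  the whole trajectory so any intermediate arrangement can be replayed.
* **Coupled-network simulation** — diffusive (gap-junction-like)
  voltage coupling via the graph Laplacian, integrated with a stiff
  BDF solver and analytic sparse Jacobians.
* **Collective features** — mean participation P̄ (peaks per node) and
  time-averaged Kuramoto order parameter R̄ from peak-based phases.
* **Parameter sweeps** — Latin-hypercube designs over (drive, coupling,
  sorting iteration), Gaussian-process surrogate surfaces, and
  half-maximum contour extraction; plus a direct drive-scan utility for
  the random-vs-sorted activation threshold.

The headline effect: with strong coupling, *sorting the excitable
minority into a spatial cluster lowers the drive at which the whole
network activates*, and the active network is near-perfectly
phase-locked (R̄ > 0.9).

## Quick start

```python
import numpy as np
from hetsort import (
    FHNParams, find_hopf_fhn, make_bc_lattice, random_partition,
    sort_network, Partition, NetworkModel, sample_initial_conditions,
    simulate_network, summarise, network_sortedness,
)

# 1. single-cell bifurcation point
print(find_hopf_fhn(FHNParams()).critical_value)   # 0.3312...

# 2. islet lattice + random 10% excitable minority
graph = make_bc_lattice()                          # 1,018 nodes
part0 = random_partition(graph.N, 0.1, np.random.default_rng(0))
print(network_sortedness(graph, part0, "boundary_corrected"))  # ~0.0

# 3. sort the minority into a cluster
trace = sort_network(graph, part0, seed=0)
sorted_part = Partition(trace.labels_at(trace.a_final))
print(trace.sortedness_values[-1])                 # ~0.69

# 4. simulate at sub-threshold drive with strong coupling
model = NetworkModel(
    kind="fhn", graph=graph, partition=sorted_part,
    pop_params={1: FHNParams(I=2.0), 2: FHNParams(I=1.0)},
    g_coup=0.1, G=0.253,
)
Y0 = sample_initial_conditions(model, np.random.default_rng(1))
feats = summarise(simulate_network(model, Y0), sorted_part)
print(feats.P_bar, feats.R_bar)                    # ~8 peaks/node, R ~0.97
# the same network with the unsorted labels gives P_bar = 0
```

## Command line

```bash
hetsort graphs make-ws --out g --n 1000 --d 12 --beta 0.2 --seed 0
hetsort graphs make-bc --out islet
hetsort sort --graph islet --out run --seed 0
hetsort simulate --config experiment.yaml --out run
hetsort features --sim run/trajectories.npz --labels run/graph
hetsort sweep run --preset ws-fhn-desk --out sweep.csv --seed 0
hetsort sweep fit --table sweep.csv --out surf.npz
hetsort sweep contour --surface surf.npz --out contour.csv
```

Exit codes: 0 success, 1 invalid input, 2 runtime failure. Logs go to
stderr, data only to files.

## Tests

```bash
python -m pytest -q tests/
```

The suite (~2 min) covers unit behaviour, hypothesis property tests,
and acceptance tests pinning the quantitative results below.

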