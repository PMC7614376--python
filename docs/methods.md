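# Methods

This note documents the models, algorithms, default parameters and
numerical choices implemented in `hetsort`, and the reasoning behind
the design decisions that were not forced by the mathematics.

## 1. Single-cell models

### 1.1 FitzHugh–Nagumo (FHN)

Dimensionless caricature of an excitable cell (`node_models.FHNParams`,
`fhn_rhs`):

```
dV/dt = V − V³/3 − W + G·I − I_coup
τ dW/dt = V + a − b·W
```

| parameter | default | meaning |
|-----------|---------|---------|
| a | 0.7 | recovery offset |
| b | 0.8 | recovery gain |
| τ | 12.5 | recovery time-scale separation |
| I | 1.0 | node excitability (maximum stimulus) |
| G | 0.0 | shared network drive, G ∈ [0, 1] |

The effective stimulus is the compound drive **G·I**; the excitable
minority (population 1) carries I = 2, the majority I = 1, so at a
given network drive G the minority sits closer to threshold.

**Hopf detection** (`find_hopf_fhn`): at an equilibrium V\*, the
Jacobian trace is 1 − V\*² − b/τ and the determinant
(b(V\*² − 1) + 1)/τ. The trace vanishes at V\* = −√(1 − b/τ) (the
low-voltage rest branch); back-substitution into the equilibrium cubic
gives the critical drive in closed form:

```
(G·I)_c = −V* + V*³/3 + (V* + a)/b = 0.3313  (defaults)
```

`find_hopf_fhn_eigen` re-derives the same point by bisecting the real
part of the leading Jacobian eigenvalue; the two agree to < 1e−4 and
cross-check each other in the test-suite. When b/τ ≥ 1 no Hopf
bifurcation exists and the closed form returns `None`.

### 1.2 Sherman–Rinzel–Keizer (SRK)

Three-variable biophysical beta-cell burster (`SRKParams`, `srk_rhs`):

```
Cm dV/dt = −I_K − I_Ca − I_KCa − I_L − I_coup
dn/dt    = (n∞(V) − n) / τ_n(V)
dc/dt    = −f (α I_Ca + k_Ca c)
```

with

```
I_K   = g_K n (V − V_K)
I_Ca  = g_Ca m∞(V) h∞(V) (V − V_Ca)
I_KCa = g_KCa c/(K_d + c) (V − V_K)
I_L   = g_L (1 − G) (V − V_K)
x∞(V) = 1 / (1 + exp((V_x − V)/S_x)),  x ∈ {m, n, h}
τ_n(V) = τ̄ / (exp((V − V̄)/κ₁) + exp(−(V − V̄)/κ₂))
```

| parameter | default | units | parameter | default | units |
|-----------|---------|-------|-----------|---------|-------|
| Cm | 5310 | fF | V_m | 4 | mV |
| g_K | 2500 | pS | S_m | 14 | mV |
| g_Ca | 1400 | pS | V_n | −15 | mV |
| g_KCa | 30000 | pS | S_n | 5.6 | mV |
| g_L | 100 | pS | V_h | −10 | mV |
| V_K | −75 | mV | S_h | −10 | mV |
| V_Ca | 110 | mV | τ̄ | 60 | ms |
| K_d | 100 | µM | V̄ | −75 | mV |
| f | 0.001 | — | κ₁ | 65 | mV |
| α | 4.5061e−6 | µM/(fA·ms) | κ₂ | 20 | mV |
| k_Ca | 0.03 | ms⁻¹ | G | 0 | — |

Design resolutions adopted here (both validated numerically):

* **Sign of S_h.** h is an inactivation gate, so its logistic must run
  downhill in voltage: S_h = −10 mV. With S_h = +10 the cell never
  bursts and the Hopf point moves far from 45 pS.
* **τ_n form.** τ_n is the two-exponential expression above (a skewed
  bell peaking near V̄ + 18 mV with τ_n(V̄) = τ̄/2), not
  τ̄·(e₁ + e₂).

With these choices the G = 0 Hopf bifurcation sits at
**g_L = 45.21 pS** (`find_hopf_srk`, Brent bisection of the real part
of the leading complex eigenvalue pair over g_L, bracket 5–400 pS).
Because the dynamics depend on (g_L, G) only through g_L(1 − G), the
Hopf locus obeys the level-set relation **(1 − G)·g_L(Hopf) = 45.21 pS**
exactly; the test-suite checks it at G ∈ {0.25, 0.5, 0.75}.

The glucose-like drive G enters by *suppressing the leak*: larger G →
smaller effective leak → more excitable. The minority population
carries g_L = 60 pS, the majority g_L = 100 pS (less excitable); the
burst period lengthens with g_L (checked at G = 0.7: mean interburst
interval ≈ 1.25 s at g_L = 60 vs ≈ 3.2 s at g_L = 120).

Equilibria are found by reducing to one dimension (n = n∞(V),
c = −α I_Ca(V)/k_Ca) and scanning + Brent-solving the V-residual from
the hyperpolarised end, which selects the physiological rest branch.

## 2. Network substrates (`graphs`)

### 2.1 Watts–Strogatz (WS)

`make_ws_graph(N, D, beta, seed)` wraps `networkx.watts_strogatz_graph`
(ring of N nodes, D nearest neighbours, rewiring probability β) and
retries with an incremented seed until connected (the retry count is
recorded in `family_params`). Defaults N = 1000, D = 12, β = 0.2. Edge
count is exactly N·D/2 for every β; at β = 0.2 the fraction of edges
joining nodes within ring distance D/2 ("local edges") is 0.80 ± 0.02.
Nodes carry unit-circle coordinates for plotting only.

### 2.2 Islet-like lattice (betaC)

`make_bc_lattice` builds a sphere of hexagonal-close-packed lattice
points (coordination 12, like cells in a tissue): generate an hcp
block, centre a sphere on a **tetrahedral hole** at
(1/2, √3/6, √6/6) — an off-lattice centre chosen to break distance-shell
ties — and keep the `n_nodes` nearest points. Pairs at nearest-neighbour
distance (one lattice spacing) are connected. The default 1,018-node
sphere has 5,286 edges, every node more than one spacing inside the
surface has the full coordination 12, and the frozen squared radius is
92/3 spacings².

Node counts are only achievable between distance shells; a count that
falls inside a shell (e.g. 57 or 342) raises `ValueError` naming the
nearest achievable count. For the desk-scale sweeps we use the
347-node sphere (the achievable count nearest one third of 1,018).
Nodes are ordered by radial distance from the sphere centre.

Graphs serialise to text (`.edges` / `.nodes` with a JSON metadata
comment); `read_graph` validates ids, symmetry, duplicates and
connectivity and reports offending line numbers.

## 3. Sortedness and the sorter (`sortedness`)

### 3.1 Metric

For node i with neighbour set J_i, let s_i be the number of neighbours
sharing i's population label.

* plain node sortedness: ã_i = s_i / |J_i|
* boundary-corrected: ã_i = s_i / J + [label(i) = 2] · (J − |J_i|)/J,
  with J = 12 the bulk coordination — missing neighbours of surface
  nodes count as phantom majority cells, so the majority is not
  penalised for occupying the surface.

Network sortedness averages ã over each population (Ā_k) and combines:

```
A = (−1 + Σ_k Ā_k) / (K − 1) ∈ [−1/(K−1), 1]
```

A ≈ 0 for random labellings (mean |A| < 0.005 over 50 seeds on
WS(1000, 12, 0.2)), A = 1 when populations are fully segregated, and
A = −1 for the alternating two-colouring of an even cycle (exact on
the 6-ring fixture).

### 3.2 Sorter

`sort_network` performs stochastic label-swap ascent (or descent with
`direction="backward"`) for K = 2:

1. Compute the sortedness change ΔA for **every** cross-population pair
   (i, j) using an O(1)-per-pair incremental formula over precomputed
   per-node tallies (verified against full recomputation to < 4e−16 on
   exhaustive small-graph pair sets).
2. If no pair strictly improves (ε = 1e−12), terminate — this makes
   convergence an exhaustive certificate, not a patience heuristic.
3. Otherwise draw one improving pair with probability proportional to
   f(i)·f(j), where f is the node-selection pdf, and swap labels. (A
   single weighted draw from the improving subset is distributed
   identically to rejection sampling without replacement from f.)

Selection pdfs:

* `uniform` (WS default) — every node of a population equally likely.
* `radial` (betaC default) — equal selection mass per occupied radial
  shell (8 shells), i.e. f ∝ 1/#{population members in the node's
  shell}. This favours sparsely populated central shells so the
  minority cluster condenses in the bulk rather than smearing across
  the populous surface shells.
* `radial_literal` — f ∝ shell occupancy, the literal "proportional to
  shell membership" reading, kept behind a flag for comparison.

The returned `SortingTrace` stores the initial labels and every
accepted swap, so the arrangement at any iteration a ∈ [0, a_final]
can be replayed exactly (`labels_at`); sweeps index arrangements by
a/a_final. On WS(1000, 12, 0.2) a forward sort converges in ≈ 290
accepted swaps (A: 0.01 → 0.68, ~2 s); on the 1,018-node lattice in
≈ 200 swaps (A: −0.01 → 0.69 boundary-corrected).

## 4. Coupled-network simulation (`netsim`)

Nodes couple diffusively through voltage (gap-junction-like):
I_coup = ḡ_coup (L V) with L the combinatorial graph Laplacian, so
coupling currents sum to zero identically and vanish on the uniform
(synchronous) manifold — both used as test oracles.

Initial conditions (`sample_initial_conditions`): FHN
V ~ N(−1, (1/6)²), W = 0; SRK V ~ N(−68, (68/6)²) mV, n = 0,
c ~ N(0.57, (0.57/6)²) µM truncated at 0 (a concentration cannot be
negative; the truncation affects ~10⁻⁹ of draws).

Integration: `scipy.solve_ivp` BDF with analytic Jacobians — block
per-node Jacobians plus ḡ_coup L/C in the V–V block — dense below
N = 200, sparse above. Default tolerances rtol = 1e−5, atol = 1e−8;
horizons (0, 500) with 2,000 samples (FHN) and (0, 300 s) with 20,000
samples (SRK), i.e. ≥ 5 oscillation periods in active regimes. The
first 25% of the horizon is flagged transient and excluded from
features. The ḡ_coup = 0 network reproduces independent single-cell
integrations; this identity is tested at rtol = 1e−9 because at the
default tolerance limit-cycle *phase* drift between different solver
step sequences dominates the pointwise error.

## 5. Collective features (`features`)

* **Participation P̄** — mean number of prominent peaks per node of the
  feature variable (V for FHN, cytosolic Ca²⁺ for SRK) over the
  post-transient window. Peaks: `scipy.signal.find_peaks` with
  prominence 0.2 × the *population-wide* signal range (so a flat node
  is not promoted to "oscillating" by its own noise floor) and a
  5-sample minimum separation.
* **Synchrony R̄** — each node with ≥ 2 peaks gets a phase that grows
  linearly by 2π between consecutive peaks; R̄ is the time average of
  the Kuramoto order parameter magnitude over oscillating nodes. If
  < 10% of nodes oscillate, R̄ is reported as 0 with
  `synchrony_defined=False` (a near-silent network has no meaningful
  collective phase).
* **Interburst intervals** — silent gaps between contiguous
  above-threshold voltage episodes (threshold = range midpoint),
  keeping only gaps > half the longest gap; this discards intra-burst
  inter-spike gaps while still working when each "burst" is a single
  prolonged spike.

## 6. Sweeps and surrogates (`sweeps`)

Study conditions (per model family):

| family | G range | ḡ_coup range | strong ḡ_coup | minority/majority |
|--------|---------|--------------|----------------|-------------------|
| FHN | 0.15–0.34 | 0.02–0.1 | 0.1 | I = 2 / I = 1 |
| SRK | 0.2–0.6 | 2–10 pS | 10 pS | g_L = 60 / 100 pS |

with a 10% minority fraction throughout.

`latin_hypercube` (scipy `qmc`) stratifies each axis; the sorting axis
is sampled as a *fraction* of each sample's own a_final so samples with
different convergence lengths are comparable. `run_sweep` rebuilds
graph, partition, sort and initial conditions per sample from named
seed substreams, records failures as rows rather than aborting, and
checkpoints finished rows to CSV for restartable long runs.

`fit_surrogate` fits a Gaussian process (constant × anisotropic RBF +
white noise, standardised inputs, normalised targets, ≥ 20 rows
required) and evaluates it on a regular grid; `half_max_contour`
extracts the half-maximum level set with scikit-image
(`find_contours` in 2-D, `marching_cubes` in 3-D), returning
data-coordinate vertices, or an empty list when the level is outside
the field's range. The machinery is verified on synthetic analytic
functions (sigmoid recovery to < 0.15, contour vertices within 0.1 of
the analytic half-max line).

**Problem sizes.** The full study design (thousands of LHS samples on
1,000-node networks) is a cluster workload. The package ships two
tiers: `*-desk` presets (60–80 samples, WS N = 250 / lattice N = 347,
shortened horizons; minutes on a laptop) and full-scale presets
(5,000–20,000 samples) with the same code path. The desk tier is what
the test-suite and `run_transition_scan` exercise; the headline
*trend* — the sorted network's half-maximum activation drive is
strictly lower than the random arrangement's (0.24 vs 0.27 at desk
scale, seed 3) — is robust at this size even though the full heatmaps
are not.

## 7. Reproducibility

All randomness flows from `numpy.random.SeedSequence` master seeds
through named substreams (graph / partition / sorter / initial
conditions), so every artefact is reproducible from one integer.
`run_experiment` writes the graph, sorting trace, trajectories,
features, the fully resolved configuration and stage timings to an
output directory. `scripts/acceptance.py --seed S --out F` recomputes
the headline numbers (see README).

## 8. Limitations

* The sorter is implemented for exactly two populations (K = 2); the
  metric itself is general-K.
* Sorter cost is O(n₁·n₂·J) per accepted swap (exhaustive improving-set
  construction); fine up to a few thousand nodes, not tuned beyond.
* Peak-based phases are undefined for nodes with < 2 peaks; R̄ near the
  activation threshold (few oscillating nodes) should be interpreted
  together with `synchrony_defined` and P̄.
* Desk-scale presets demonstrate trends, not converged surfaces; GP
  surfaces from < 100 samples are qualitative.
* The betaC lattice is a perfect hcp sphere: no packing disorder,
  vasculature or cell-size variability.
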