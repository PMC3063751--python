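# fluctuogram

Temporal elastic-network analysis of protein trajectories: turn the
sequential windows of a molecular-dynamics trajectory into a time series of
mechanical coupling networks, find the residues whose coupling responds to a
molecular signal (e.g. ion binding), and correlate them with co-evolving
positions from a statistical coupling analysis of a sequence alignment.

## Who this is for

Computational structural biologists studying allosteric communication:
situations where a ligand acts on a distal site without any large
conformational change, so the signal must travel through changes in the
*stiffness* of inter-residue contacts rather than through their geometry.

## The model

A protein is coarse-grained to two sites per residue — the Cα position for
the backbone and the sidechain center of mass (glycine keeps one site; a
bound ion is its own site).  Each trajectory window is modelled as an
elastic network

```
E = Σ_bonds ½ k_ij (d_ij − b_ij)²
```

whose bond pool contains every site pair that comes within 10 Å anywhere in
the trajectory.  Per window, the rest lengths `b_ij` are the mean inter-site
distances and the force constants `k_ij` are obtained by **fluctuation
matching**: normal-mode analysis predicts each bond's thermal variance
`⟨δd²⟩_ENM = k_B T êᵀ(C_ii + C_jj − 2C_ij)ê` from the Hessian pseudoinverse
`C`, and the update

```
k ← max(0, k + α k_B T (1/⟨δd²⟩_MD − 1/⟨δd²⟩_ENM))
```

is iterated until the RMS force-constant change drops below
0.005 kcal/mol/Å².  The window-ordered sequence of networks — the
*fluctuogram* — is then reduced to residue-level series: the coupling
`k_IJ(t)` (sum of force constants between residues I and J),
`k_I = Σ_{J≠I} k_IJ`, the two-state difference `Δk_I`, the window-to-window
change `δk_I`, the conformational change `Δb_I`, and the bounded relative
variation `ψ_I ∈ [−1, 1]`.

Residues are selected as putative communication hot-spots by three criteria
on the window statistics of `k_IJ` (mean ⟨k⟩, spread σ, maximum k^max):
**A** — hubs with ≥ N_cut well-separated partners at ⟨k_IJ⟩ ≥ 2.5 kcal/mol/Å²;
**B** — members of strongly coupled pairs (⟨k_IJ⟩ ≥ K_B);
**C** — members of strongly *varying* pairs (k^max ≥ K_C and σ/⟨k⟩ ≥ s_C).
Selections are scored against reference residue sets (mutation sites, SCA
sectors) by hit rate and coverage with a ±1-residue tolerance, against a
10,000-round random-picking baseline.

The SCA arm filters an alignment (gap limits, ≥95 % redundancy removal),
reduces it to a binary consensus matrix, weights the absolute column
covariance by conservation gradients, and reads co-evolving *sectors* off
the 2nd and 3rd eigenvectors (distance-from-origin cutoff 0.07, angular
clustering), with eigenvalue significance calibrated by column permutation.

All fixtures are synthetic and exact: the `synth` module samples
trajectories from the multivariate Gaussian a known network defines
(covariance `k_B T H⁺`), concatenates two-state trajectories with recorded
change points, and plants co-evolving sectors in generated alignments, so
every analysis stage is tested against ground truth.

## Worked example

Recover the force constants of a known 20-site network from 4000 sampled
frames:

```python
import numpy as np
from fluctuogram import (make_toy_network, sample_from_network,
                        measure_targets, fluctuation_match)

net = make_toy_network(n_sites=20, n_extra_contacts=8, k_range=(1.0, 20.0), seed=1)
traj = sample_from_network(net, n_frames=4000, seed=2)
targets = measure_targets(traj, net.bond_indices)
fitted, trace = fluctuation_match(targets)

rel = (fitted.force_constants - net.force_constants) / net.force_constants
print(f"converged: {trace.converged} after {trace.n_iterations} iterations")
print(f"RMS relative error of recovered force constants: {np.sqrt((rel**2).mean()):.3f}")
for b in range(3):
    i, j = net.bond_indices[b]
    print(f"bond ({i},{j}): true k = {net.force_constants[b]:6.2f}, "
          f"recovered k = {fitted.force_constants[b]:6.2f} kcal/mol/A^2")
```

prints

```
converged: True after 1 iterations
RMS relative error of recovered force constants: 0.027
bond (0,1): true k =  11.26, recovered k =  11.19 kcal/mol/A^2
bond (0,8): true k =  15.70, recovered k =  15.81 kcal/mol/A^2
bond (0,11): true k =  11.06, recovered k =  10.28 kcal/mol/A^2
```

The matcher converges in a single step here because this chain-plus-contacts
network is under-braced: its bond strains are independent internal
coordinates, so the inverse-variance initialization is already the fixed
point.  Densely braced networks (bonds > 3N−6) couple the modes and take a
handful of iterations; the 2.7 % residual error is the sampling noise of
4000 frames.

The same pipeline is scriptable from the shell:

```
fluctuogram synth --out-dir data --n-frames 4000
fluctuogram fluctuogram --traj data/trajectory.xyzt --window 400 --out-dir run
fluctuogram metrics --run-dir run
fluctuogram select --run-dir run --out run/selected.tsv
```

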