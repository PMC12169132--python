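# hemodyn

Comparative two-state conformational-ensemble analysis for oxygen-transport
functional units.

Molluscan hemocyanins bind O₂ at a dinuclear copper centre inside each
~400-residue functional unit (FU).  Oxygenation rigidifies the FU, buries
solvent-exposed surface, and closes the transient tunnel through which O₂
reaches the active site; a conserved glutamate acts as a molecular shutter
whose rotamer gates the tunnel bottleneck.  Testing such a mechanism from
molecular-dynamics output requires a chain of ensemble analyses that are
usually scattered across separate tools.  `hemodyn` packages that chain as
one tested library with a CLI, for structural bioinformaticians comparing an
oxygenated-like and a deoxygenated-like ensemble of a single protein chain:

* **Flexibility/compactness** — Kabsch superposition, RMSD(t),
  per-residue RMSF (iterative mean alignment), radius of gyration
  R_g = √(Σmᵢ|rᵢ−r_com|²/Σmᵢ), and the differential-RMSF rule
  |ΔRMSF| ≥ 0.5 Å (deoxy − oxy).
* **Essential dynamics** — diagonalisation of the Cα positional covariance
  C = ⟨Δx Δxᵀ⟩; component exclusion (e.g. a tail-dominated PC1); counts of
  components reaching 95% cumulative variance; two-state subspace
  comparison via the dot-product matrix D_ij = |v_i^A·v_j^B|,
  RMSIP = √(Σ_ij D_ij²/m) with subspace overlap RMSIP²×100, the Hess
  covariance overlap, per-mode maximum dot products; KDE maps of PC
  projections; modevector displacement fields.
* **Solvent accessibility** — Shrake–Rupley SASA (probe 1.4 Å, 960
  points/atom) with the differential rule |ΔSASA| ≥ 0.2 nm².
* **Tunnels** — free-radius grid r(x) = minᵢ(|x−aᵢ|−vdwᵢ), Dijkstra
  lowest-cost paths from a buried seed to bulk solvent
  (edge weight = step/max(r,ε)²), bottleneck radius, throughput
  TP = exp(−Σ len/r²) ∈ (0,1], average-linkage clustering of centerlines at
  3.0 Å, per-cluster statistics, and the ≥70% bottleneck-residue rule.
* **Residue interaction networks** — typed contacts (VDW, HBOND, IONIC,
  PIPISTACK, PICATION), per-state occurrence frequencies averaged across
  replicates, exclusive/shared classification at threshold 0.3, and bounded
  (≤2-step) neighbourhoods of a focal residue.
* **Domain rotation** — per-frame angle of domain II after domain-I
  alignment (COM-vector and rotation-matrix methods), compared between
  states by a two-sided Mann–Whitney U test (exact for small samples).
* **Conservation** — affine-gap Needleman–Wunsch over BLOSUM62 and MSA
  column classing (conserved / conservative / non-conservative by log-odds
  sign).
* **Synthetic two-state generator** — a first-class module that plants
  recoverable ground truth (state-dependent loop amplitudes, a two-rotamer
  gate with state-dependent open probability, a shell pore gated by that
  rotamer, typed contacts with state-dependent probabilities, a small
  domain-II rotation), so the entire pipeline is testable without external
  trajectories.

## Worked example

Generate a small synthetic study (200 frames × 2 replicates per state) and
run the full comparison:

```python
from hemodyn.synthetic import SyntheticSpec
from hemodyn.config import ComparisonConfig
from hemodyn.pipeline import run_comparison

spec = SyntheticSpec(n_frames=200, n_replicates=2, seed=7)
config = ComparisonConfig(synthetic=spec, window=(20, 200), stride=5,
                          outdir="demo_out")
bundle = run_comparison(config)
```

Inspecting the bundle prints:

```
differential-RMSF flags (|Δ| ≥ 0.5 Å): [46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 56, 374, 375, 376, 377, 378]
gate ΔSASA (deoxy − oxy): +0.70 nm²
tunnel snapshots deoxy/oxy: 65/6 (10.8-fold)
top deoxy tunnel cluster: Avg_BR 2.30 Å, Avg_thru 0.31
domain rotation oxy vs deoxy: 1.35° vs 0.25° (Mann-Whitney p = 8.8e-26)
RIN edges around Glu352: exclusive_oxy=[(43, 352, 'IONIC'), (62, 352, 'HBOND'), (202, 352, 'VDW')]
                         exclusive_deoxy=[(352, 355, 'VDW')]
```

Reading the output: the flagged residues are exactly the two planted
flexible loops (46–56 and 374–378, more mobile without bound cargo); the
gate residue 352 gains ~0.7 nm² of exposure in the deoxygenated-like state
because its side chain swings out of the tunnel aperture; the open-gate
state produces ~10× more accepted tunnel snapshots, with a bottleneck
radius near the planted 2.5 Å aperture; the planted ~1.46° inward rotation
of domain II upon oxygenation is recovered and highly significant; and the
gate's contact network switches from oxy-exclusive couplings (His43, His62,
Leu202) to a deoxy-exclusive contact with residue 355.  The run directory
(`demo_out/`) holds the same results as TSV/JSON tables plus a manifest.

The CLI mirrors the library:

```bash
hemodyn generate --out fixtures --seed 7 --frames 200 --replicates 2
hemodyn analyze --config run.yaml --seed 7 --out results_dir
hemodyn align sequences.fasta
```

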