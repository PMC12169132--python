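# Methods

This note records the models, conventions and numerical choices behind
`hemodyn`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
establish about real data.

## Ensembles, windows and selections

An ensemble is a topology plus an `(F, N, 3)` Å coordinate stack with one
label per frame (simulation time in ns, or an index).  All comparative
analyses operate on an *analysis window* cut on those labels — by default
100–1000 with every tenth frame kept — so an equilibrated segment can be
selected regardless of storage stride.  Per-state profiles pool the
windowed frames of all replicates; contact frequencies are computed per
replicate and averaged unweighted, so replicates of unequal length carry
equal weight (the convention for replicate-averaged interaction networks).
Differential quantities are always *deoxygenated-like minus
oxygenated-like*.

Selections are expressions over residue ranges, atom names, and chains
(`"resid 1:407 and calpha"`), with named selections (`core`, `domain1`,
`domain2`, …) stored on the topology.  Internal indices are 0-based;
residue numbers are 1-based (PDB convention).  Van der Waals radii are the
Bondi set with a 1.7 Å fallback for unknown elements.

## Flexibility and compactness

RMSD uses the least-squares proper rotation (Kabsch); RMSF aligns all
frames to their evolving mean (two passes) before taking
RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ per Cα.  Two passes suffice because the second
pass changes the mean by less than the fit residual; frame-1 alignment is
deliberately avoided since it imprints one frame's noise on every residue.
A consequence worth knowing: the rigid-body fit absorbs a fraction of any
*collective* displacement (roughly the ratio of moving to fitted atoms),
so measured RMSF of a concerted loop is biased low by a few percent — the
generator's convergence checks therefore compare the alignment-free second
moment with planted truth, and the ±0.5 Å differential rule is applied to
a contrast (≈0.9 Å) that survives the bias.  R_g is mass-weighted by
default.  RMSD/RMSF/PCA default to Cα atoms — the standard
essential-dynamics choice; active-site analyses can select heavy atoms
instead.  Flagging rules are boundary-inclusive (|Δ| ≥ threshold).

## Essential dynamics

The positional covariance of the superposed, selected coordinates is
diagonalised directly (`eigh`); eigenvalues are clipped at zero and sorted
descending; an independent SVD route (λ_k = s_k²/(F−1)) agrees to 1e-8 and
serves as the test oracle.  Excluded components (PC1 by default, mirroring
the common case of a disordered-tail-dominated first mode) stay in the
object but are skipped by variance accounting, comparison and projections;
component numbering always refers to pre-exclusion ranks so "PC2" is
stable.  With F < 3N the spectrum is rank-deficient — the code warns and
the comparison metrics remain valid for the leading modes.  Because no
single "subspace overlap" definition is universal, the comparison reports
the full dot-product matrix, RMSIP with RMSIP²×100, the Hess covariance
overlap, and per-mode maxima averaged over A-modes, B-modes and both.
KDE maps use Scott's rule on a 100×100 grid spanning the data ± 3
bandwidths, renormalised to integrate to 1 on the grid.  Modevector fields
are exact by construction: extremes x̄ ± c√λ·v, field 2c√λ·v.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-spiral lattice; 960 points/atom
keeps the per-atom discretisation error below ~0.6% of the inflated-sphere
area (worst case measured against a 16000-point reference), and a
randomised quasi-Monte-Carlo oracle agrees within 1%.  Probe radius 1.4 Å
(water).  Totals are reported in Å² and the two-state differential in nm²
(1 nm² = 100 Å²) — the mixed-unit convention of the comparative
literature — with the conversion centralised.  Note that SASA is a local
criterion: enclosed cavity surface counts as accessible, which is the
standard behaviour of the algorithm, not a defect.

## Tunnels

A deliberate grid reimplementation of Voronoi-based channel finding,
chosen for testability and convergence rather than bit-compatibility with
any existing tool.  Free radius r(x) = minᵢ(|x−aᵢ|−vdwᵢ) is evaluated on a
0.6 Å grid covering the relevant atoms + 4 Å.  *Bulk solvent* is the
region where a `bulk_radius` (default 3.0 Å) sphere fits, connected to the
box boundary; this parameter must exceed the widest bottleneck of
interest, otherwise cavity and exterior merge and "tunnel" is undefined.
Traversal is restricted to voxels with r ≥ probe (1.5 Å, the van der Waals
radius of O₂), which guarantees accepted bottlenecks ≥ probe and keeps
each tunnel inside its own aperture.  Edge weight is step/max(r_mid, ε)²
with ε = 0.1 Å; path cost is the sum and throughput exp(−cost), so the
stated 0–1 range and "higher = more relevant" ordering hold, and a
constant-radius path scores exp(−L/r²) exactly.  Shortest paths come from
Dijkstra with predecessors; candidate exits are merged when either their
exit points or their path bottleneck points fall within 3 Å (near-duplicate
routes through one aperture fan out in the exterior and cannot be merged
on exits alone).  At most 5 tunnels are kept per frame.  Bottleneck
estimates converge as spacing shrinks; halving the spacing moves them by
less than the coarser spacing.  Clustering: centerlines resampled to 20
equidistant points, mean point-to-point distance, average linkage cut at
3.0 Å, clusters ranked by average throughput; snapshot counts are divided
by the replicate count (hence fractional values).  Bottleneck-lining
residues are those with an atom surface within bottleneck + 0.5 Å of the
bottleneck point; "crucial" means lining ≥ 70% of a cluster's snapshots
(boundary inclusive).

## Residue interaction networks

Typed contacts use fixed literature cutoffs (VDW: d ≤ rᵢ+rⱼ+0.5 Å; HBOND:
donor–acceptor ≤ 3.5 Å; IONIC: opposite formal charges ≤ 4.0 Å;
PIPISTACK: centroids ≤ 5.5 Å with inter-plane angle ≤ 30° or ≥ 150°;
PICATION: cation–centroid ≤ 5.0 Å), applied per interaction type and
skipping pairs closer than 3 in sequence.  The criteria are versioned in
one dataclass and config-overridable, since different network generators
draw these lines slightly differently.  The presence threshold (0.3) is
applied per (pair, type) key; a pair may carry several typed edges.
Neighbourhood extraction is breadth-first over edges strong in either
state, depth ≤ 2 by default.

## Domain rotation

Every strided frame is superposed on a reference by the domain-I Cα; the
default angle is between the frame's and reference's COM₂−COM₁ vectors,
with the rotation-matrix angle (arccos((tr R −1)/2)) as a cross-check that
also sees twist about the inter-COM axis.  The pipeline fits and measures
on *rigid domain cores* — flexible loops and the tail excluded — the
conventional choice, and the one that keeps loop modes from leaking into
the angle.  Significance uses the two-sided Mann–Whitney U (exact when
both n ≤ 8 without ties, else the tie-corrected normal approximation; a
Welch t-test is available).  The reference is a single deoxygenated-like
structure; because that reference is itself one noisy frame, the measured
between-state difference sits slightly below the planted offset (its COM
vector is tilted by one draw of the noise) — visible in the acceptance
numbers and expected.

## Conservation

Affine-gap global alignment (gap open 10, extend 0.5; a length-L gap costs
10 + (L−1)·0.5) over BLOSUM62 with X-scores set to 0; co-optimal
tracebacks resolve deterministically.  Column classing against the
reference residue: identical column → conserved; all substitutions with
log-odds ≥ 0 → conservative; any negative score or gap → non-conservative.
The ≥ 0 line is a design choice — reports always carry the raw minimum
score so a looser reading (e.g. accepting −1 substitutions between
chemically similar residues) remains available.  MSAs are consumed, not
computed.

## The synthetic two-state system

The generator emulates a replicated two-state simulation study of one
~420-residue functional unit: two labelled states × replicates × i.i.d.
frames.  Default study conditions: 5 replicates × 1000 frames, loops 46–56
and 374–378 with collective amplitudes 0.55 Å (oxy-like) / 1.5 Å
(deoxy-like) on a 0.25 Å i.i.d. baseline, a 1.2 Å flexible tail (408–423)
excluded from core analyses, gate residue 352 open with probability 0.9
(deoxy-like) vs 0.1 (oxy-like), a 9 Å shell with a 2.5 Å aperture sealed
to an ~0.4 Å annular gap when the gate plugs it, six typed contacts around
the gate (three oxy-exclusive at 0.85/0.20, two shared at 0.80, one
deoxy-exclusive), and a 1.46° mean rotation of domain II in the oxy-like
state with 0.05° jitter.  The backbone is a compact serpentine lattice
(3.8 Å within rows, 5.0 Å pitch): consecutive-residue spacing is protein-
like, non-consecutive pairs stay outside every contact cutoff, and domain
levers are tens of Å rather than the hundreds a straight helix would give.
Frames are i.i.d. — every downstream analysis is an ensemble statistic, so
autocorrelation would only slow convergence.  One master seed; state s,
replicate r uses stream seed + r + 10000·index(s).

Deliberate abstractions: gate and contact pseudo-atoms sit directly at the
shell aperture and at detached, mutually isolated contact sites rather
than being chained to their Cα.  This makes every planted quantity exact
by construction (aperture radius, contact distances, exposure contrast)
at the cost of local geometric realism.  The generator therefore validates
the *analysis chain* — that each method recovers a known signal of
realistic magnitude through the full pipeline — and not force-field
physics, solvent structure, side-chain packing or temporal correlation;
passing tests say nothing about sampling convergence on real
trajectories.

Planted truth is analytic: per-residue RMSF = √(3·SD² + loop amplitude²),
gate open fractions, per-gate-state bottlenecks, the verbatim contact
probability table, and the mean rotation offsets.

## Problem sizes and determinism

Validation runs use sizes at which every planted effect is separated from
its decision boundary by several standard errors: the full-pipeline check
uses 1000 frames × 2 replicates per state (91 analysed frames per
replicate after the 100–1000/stride-10 window), 2000 frames for RMSF
convergence (5% band), 5000 samples for spectrum recovery (10% band), and
10⁵-point quasi-Monte-Carlo SASA oracles (1% band).  All stochastic tests
are seeded; the pipeline is deterministic given config + master seed, and
two runs with the same seed produce byte-identical tables.

## Known limitations

Single chain, PDB dialect only (no mmCIF/altloc/XTC); hydrogen-free
models, so hydrogen-bond detection is heavy-atom distance only; the tunnel
search is grid-resolution-limited (bottlenecks carry O(spacing) error) and
its cost functional, while satisfying the documented ordering properties,
is not numerically identical to any particular published tool; rotamer
binning uses fixed 120° sectors, not a rotamer library; conservation
consumes precomputed MSAs.
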