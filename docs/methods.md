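# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical choices, what the synthetic generator does and
does not emulate, and known limitations.

## Coarse graining and residue correspondence

Structures are reduced to one node per residue: the Cα atom for amino acids,
the backbone P atom for nucleotides. Residues lacking the representative
atom are skipped with a warning; only the first model of a multi-model file
is read; among altloc conformers the highest-occupancy one is kept (ties →
first in file). Insertion codes are part of residue identity.

Residue correspondence between two states is established by *author
numbering*, not sequence alignment: residues pair when (aliased chain id,
residue number, insertion code, node kind) match. This is appropriate when
the compared depositions share numbering for their common components, which
is the design here; an explicit chain alias map handles depositions that
rename chains. Unmatched residues are reported, never silently dropped.
Sequence-alignment-based mapping is deliberately out of scope.

## Superposition and deviation

Rigid superposition is the least-squares optimum (Kabsch; computed through
`scipy.spatial.transform.Rotation.align_vectors`, always a proper rotation).
RMSD is recomputed from residuals rather than taken from the solver, which
loses precision near zero.

Per-residue deviations are Euclidean distances after a single complex-level
superposition. Significance uses the `mean + 2·SD` rule over the deviation
distribution; a spread below 1e-6 Å (identical structures up to float
noise — three orders below PDB coordinate precision) flags nothing.

Per-chain (local) RMSD has two fit modes. `fit-on-self` superposes on the
chain itself and measures internal deformation only; `fit-on-reference`
keeps the complex superposed on the reference component (the rRNA scaffold)
and therefore includes the chain's rigid displacement within the complex.
The default is `fit-on-reference`, because the deviation analysis couples
local RMSD with orientation change relative to the scaffold; both modes are
exposed because published comparisons rarely state which was used.

**Angle of deviation.** After superposing state B onto state A using only
the reference chains, the optimal rotation `R_p` between a target chain's
paired node sets (centroids removed) is computed and its rotation angle
`θ = arccos((tr R_p − 1)/2)` reported in degrees, in [0°, 180°]. This is
the unique rotation angle of the best-fit rigid motion of that chain; where
published angle values were produced by unspecified in-house code, agreement
can only be expected up to that definitional ambiguity.

## Anisotropic network model

Nodes within the cutoff `r_c` (default 15 Å, the value used for ribosomal
complexes) are joined by springs of uniform constant γ (default 1,
arbitrary units — all fluctuation outputs are relative). The same cutoff
and γ apply to protein–protein, protein–RNA and RNA–RNA pairs; no per-type
parameters are published for the mixed Cα/P network. The Hessian
super-elements are `H_ij = −γ d dᵀ/|d|²` off-diagonal and row-sum-zero on
the diagonal, giving exact translational invariance.

Modes come from a dense symmetric eigendecomposition up to N ≈ 6,000 nodes
and a shift-invert Lanczos partial solve above (shift σ = −1e-6·λ_max keeps
the factorised matrix nonsingular). The partial solve fetches soft modes in
doubling batches until the variance-based selection (below) is *certified*
identical to the full-spectrum rule under both extremes of what the
unfetched stiff remainder could contribute, and falls back to the dense
solve when certification would need most of the spectrum. The agreement
contract (identical selected-mode fluctuations within 1e-6 relative) is
tested.

Exactly six rigid-body modes are discarded (five for collinear node sets),
after verifying they are numerical zeros (|λ| < 1e-8·λ_max). Zero modes are
identified by count rather than by threshold alone because thin elongated
structures have genuine physical modes softer than any reasonable relative
tolerance; such ultra-soft retained modes are logged. Eigenvector sign is
fixed by making the first non-negligible component positive, so outputs are
reproducible across LAPACK builds.

**Mode selection.** "Variance" of mode k is its `1/λ_k` share over all
nonzero modes — the standard ENM pseudo-inverse weighting. The selected set
is the smallest soft-mode prefix whose cumulative share reaches
`variance_fraction` (default 0.8).

Mean-square fluctuations are `msf_i = Σ_k (1/λ_k)|v_k,i|²` over selected
modes (equivalently, diagonal 3×3-block traces of the mode-truncated
pseudo-inverse). Z-scores are computed per complex by default — a per-chain
option exists because either convention is defensible — and |Z| > 2 marks
highly flexible sites. Cross-correlations are the covariance normalised by
its diagonal. B-factor agreement is the Pearson correlation between msf and
the experimental B column over nodes that have one.

## Perturbation response scanning

Response to a unit force `f` at node i is `ΔR = H⁺F` with `H⁺` the
pseudo-inverse over nonzero modes. The response matrix uses squared
displacement magnitudes, `P_ij = E_f |ΔR_j|²`, because the expectation over
force directions uniform on the sphere has the closed form
`P_ij = ⅓‖B_ji‖²_F` (`B_ji` = 3×3 block of `H⁺` coupling responder j to
perturbed i, using `E[ffᵀ] = I/3`). The Monte-Carlo estimator (default
1,000 unit forces per residue, seeded and reproducible) converges to this
closed form at the 1/√n rate; both routes are exposed and the analytic one
is the pipeline default.

Convention: rows index the perturbed node, columns the responding node, so
effectiveness is a row mean and sensitivity a column mean. Published prose
sometimes states the transpose; the convention here follows the standard
PRS formulation, and on the normalised matrix the two conventions differ
only by which profile carries which name.

Each row is normalised by its diagonal self-response (`P_ii → 1`), which
prevents intrinsically floppy sites from dominating by sheer magnitude.
Profiles are means over off-diagonal entries (the diagonal is the constant
1 after normalisation; including it cannot change Z-scores). Effectors are
nodes with effectiveness Z > 2, sensors sensitivity Z > 2; the threshold is
interpreted as a Z-score since the published "greater than two" carries no
units. Directional (vector-alignment) PRS is out of scope.

The subunit interaction matrix marks chains c ≠ d as coupled when any
cross-chain entry has `Z(P_ij) >` `pair_threshold` (default 2, standardised
over off-diagonal entries); the published analysis never states its
"affects" threshold, so it is an exposed parameter. The matrix is
symmetrised; self-interaction is undefined.

## Residue interaction networks

Published residue-interaction networks for this problem were built with
atom-level interaction typing (RING); at coarse-grained resolution this
package substitutes a documented distance-based contact network: edge when
inter-node distance ≤ 8 Å, weight 1/distance (closer = stronger), path
length = distance (closer = shorter hop). Consequently absolute centrality
values are not comparable to atom-typed networks; bound-vs-unbound
*comparisons* are the supported use. Degree counts incident edges;
betweenness and closeness use the length metric; on disconnected graphs
closeness is normalised per component (Wasserman–Faust) and logged.
Top-fraction selection takes ⌈f·N⌉ nodes with deterministic
(chain, residue) tie-breaking.

## Communication model

Affinity is binary contact (cutoff shared with the ENM, 15 Å) — a
coarse-grained surrogate for atom-contact counts that preserves the Markov
structure at node resolution. The walk steps from i to j with probability
`a_ij/d_i`. Hitting times solve the first-step equations
`(I − T_{−j,−j})h = 1` directly, one dense solve per target; commute times
are the symmetrisation. Exact identities (commute = 2|E|·effective
resistance on unit-affinity graphs; metricity; agreement with simulated
walks) are tested.

Sensor→effector paths are minimum-total-weight paths on the contact graph
with edge weight `C(i,j)` (options: symmetrised hitting, or unit hop
count — the published analysis does not state its weighting, only that one
path per sensor–effector pair was drawn). Ties are broken by the
lexicographically smallest node sequence, so path sets and edge-usage
counts are exactly reproducible. Unreachable pairs yield per-pair "no path"
records.

## Synthetic data

`make_state_pair` emulates the unbound/bound comparison design: a compact
spherical-shell scaffold chain of P nodes (phyllotaxis spiral, ~5.9 Å
spacing — a stand-in for a folded rRNA core, not a real fold) with compact
self-avoiding globular protein chains (~3.8 Å Cα spacing) docked at
guaranteed 6 ± 0.3 Å contact distance around its equator. The bound state
applies a planted rigid rotation of one chain about its centroid, Gaussian
coordinate noise on all nodes, and optionally an mRNA-like strand threaded
5 Å above the outer surface of two chains. Ground truth records the exact
angle, displaced node set and ligand contact set (recounted from emitted
coordinates). Defaults — 300 nodes, 12° rotation, σ = 0.2 Å — keep every
dense stage in seconds while preserving the multi-chain
scaffold-plus-proteins architecture; chain collisions (< 2 Å) abort
generation. A three-state series (half rotation + no ligand → full rotation
+ ligand) mirrors the unbound/intermediate/bound design, with an
independent noise stream per state.

`make_allosteric_fixture` plants a unique communication bridge: two
terminal globules that touch only a central chain with twice the node
density (hence higher contact degree and random-walk affinity). Every
terminal-to-terminal path must cross the bridge, and on generated fixtures
≥80% of path edge-crossings lie on bridge or bridge-interface edges.

What passing on synthetic data does **not** show: the geometry is
idealised (no secondary structure, no sequence, no side chains, uniform
contact density), noise is isotropic Gaussian rather than
resolution-dependent experimental error, and B-factors are a smooth radial
surrogate. Recovery of planted signals demonstrates the correctness of the
machinery, not the biological accuracy of any particular inference on real
depositions.

## Scale of the shipped experiments

Tests and the acceptance script run fixtures of 15–300 nodes (the
~300-node default pair; 138-node bridge fixtures; 15–40-node property
fixtures), chosen so the dense eigendecompositions, N response solves and
N hitting-time solves each complete in seconds. A ribosome-scale run
(~5,500 nodes) uses the same code paths with the sparse mode solver; only
its dense-vs-sparse contract, not its wall-clock, is part of the test
suite.

## Known limitations

- Residue pairing requires shared author numbering; depositions that
  renumber need external curation beyond the chain alias map.
- The binary contact affinity ignores contact *counts*; a heavy-atom
  contact-count affinity would change hitting times quantitatively.
- PRS uses squared displacement magnitudes; directionality information is
  discarded.
- Hitting-time solves are O(N⁴) overall; fine to a few thousand nodes,
  beyond which a Laplacian-pseudo-inverse formulation would be preferable.
- Quantitative reproduction of published per-protein RMSD/angle tables for
  the real 30S/30S_IC/70S_IC depositions additionally depends on the
  missing-residue modelling used upstream, which is outside this package.
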