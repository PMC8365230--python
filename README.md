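# ribomech

Comparative coarse-grained mechanics of multi-chain protein/RNA complexes.

`ribomech` quantifies what changes — structurally and dynamically — when a
large ribonucleoprotein assembly binds a ligand, the motivating case being a
small ribosomal subunit before and after mRNA binding (30S → 30S initiation
complex → 70S initiation complex). Given two or three states of a complex in
PDB format it computes, per state pair:

- **Structural deviation** — optimal rigid superposition (Kabsch), global and
  per-chain RMSD, per-residue Cα/P deviations flagged at
  `d > ⟨d⟩ + 2σ`, and the *angle of deviation*: after superposing the
  complexes on a reference component (the rRNA scaffold), the rotation angle
  `θ = arccos((tr R_p − 1)/2)` of the best-fit rotation `R_p` of each protein
  chain between states.
- **Elastic-network dynamics** — an anisotropic network model (ANM) with one
  node per residue (Cα for amino acids, P for nucleotides), springs of
  constant γ = 1 within 15 Å; normal modes from the 3N×3N Hessian, soft modes
  kept up to 80% of the 1/λ variance share; per-node mean-square fluctuations
  Z-scored, with |Z| > 2 marking highly flexible sites; cross-correlations
  and B-factor agreement.
- **Perturbation response scanning (PRS)** — linear response `ΔR = H⁺F` to
  unit forces applied one residue at a time (≥1,000 random directions per
  residue, or the analytic closed form
  `P_ij = ⅓‖H⁺_ji‖²_F`); row means give per-residue *effectiveness*, column
  means *sensitivity*; Z > 2 calls effectors and sensors, and a chain×chain
  matrix marks subunit pairs coupled by above-threshold cross-responses.
- **Residue interaction networks** — contact graphs (8 Å, weight = 1/d) with
  degree, betweenness and closeness centrality, top-10% node selection, and
  bound-vs-unbound centrality deltas and edge gain/loss.
- **Communication pathways** — a Markov random walk on the contact graph;
  hitting times `H(j|i)` from first-step linear systems, commute times
  `C(i,j) = H(j|i) + H(i|j)`; one commute-weighted shortest path per
  (sensor, effector) pair with deterministic tie-breaking and per-edge
  crossing counts.

A synthetic-data generator builds multi-chain complexes with planted ground
truth (a known chain rotation, coordinate noise, a threaded mRNA-like ligand,
a uniquely bridging stiff chain), so the entire pipeline is testable without
downloads.

## Worked example

Generate a synthetic unbound/bound pair (~300 nodes; a 120-node rRNA-like
scaffold, four globular protein chains, a planted 12° rotation of chain C,
0.2 Å coordinate noise, an mRNA-like ligand threaded past chains A and B),
then compare the states:

```sh
ribomech synth --seed 1 --out-dir example
ribomech compare example/unbound.pdb example/bound.pdb --reference-chains R
```

```json
{
  "global_rmsd": 0.7363708557667746,
  "per_protein": [
    {"chain": "A", "local_rmsd": 0.3169, "angle_of_deviation": 0.4443},
    {"chain": "B", "local_rmsd": 0.3446, "angle_of_deviation": 0.2820},
    {"chain": "C", "local_rmsd": 1.7249, "angle_of_deviation": 11.8871},
    {"chain": "D", "local_rmsd": 0.3622, "angle_of_deviation": 0.6356}
  ]
}
```

Chain C — the chain with the planted 12° rotation — stands out both in local
RMSD (1.72 Å vs ≈0.34 Å for the undisturbed chains, which reflect only the
0.2 Å noise) and in its recovered rotation angle (11.89°, within the noise
floor of the planted 12°). The flexibility and PRS stages run the same way:

```sh
ribomech enm example/unbound.pdb --out example/flex.csv
# 157 modes selected; 20 highly flexible nodes; wrote example/flex.csv
ribomech prs example/unbound.pdb --out example/prs.csv
# 17 effectors, 14 sensors; wrote example/prs.csv
```

The full pipeline (`ribomech run --config cfg.yaml`) runs every stage over
all pairwise state combinations and writes CSV/JSON/TSV reports plus a
manifest that records every parameter, enough to reproduce each output.

Real depositions are analysed the same way — point the config at the PDB
files and supply a chain alias map if chain identifiers differ between
depositions. Structures are expected to be complete (gap-filled); modelling
missing residues is an external preprocessing step.

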