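# Methods

## Model

`metalsite` treats metal ion–binding site recognition as order-free local
structural alignment. A *binding residue* is any residue with at least one
non-hydrogen atom within 3.5 Å of an ion center; a *template* is the full
binding shell of one ion — it must contain more than two binding residues,
each with a complete N/Cα/C backbone. The alignment unit is the backbone
triplet of a single residue. Triplets exclude the preceding carbonyl
carbon and the following amide nitrogen, so they carry no backbone-torsion
information: two residues align on local frame alone, which is what lets
sequence-discontinuous but spatially clustered shells match.

For query triplets σ₁..σ_m and template triplets τ₁..τ_n the method

1. computes the proper least-squares superposition Mᵢⱼ for all m×n pairs
   (Kabsch via SVD with determinant correction; reflections are never
   accepted; collinear triplets are rejected — backbone N/Cα/C is never
   collinear in practice, the bond angle is ≈111°);
2. links pairs (i,j) and (k,l) when **both**
   RMSD(Mᵢⱼ·σ_k, τ_l) ≤ d_c and RMSD(M_kl·σᵢ, τⱼ) ≤ d_c — a symmetric,
   two-sided criterion, so the linkage graph is undirected by
   construction;
3. takes single-linkage clusters = connected components of that graph
   (scipy's `connected_components` computes the transitive closure);
4. reduces each cluster to a one-to-one correspondence greedily by
   ascending triplet-fit RMSD, ties broken by (query index, template
   index); clusters aligning fewer than `min_cluster_size` residues are
   discarded.

Each surviving cluster receives a structure term
`s_str = max(0, 1 − RMSD/rmsd_max)` where the RMSD is recomputed by a
fresh Kabsch fit on the matched Cα sets (not reusing any triplet
transform), and a sequence term
`s_seq = Σ BLOSUM62(q,t) / Σ BLOSUM62(t,t)`, i.e. the alignment score
normalized by the template fragment's self-score — its maximum attainable
value, so `s_seq = 1` iff the fragments are residue-identical. Clusters
qualify only when `RMSD < rmsd_max` (strict) and `s_seq > θ` (strict). The
combined score is the product: both conservation signals are required, and
either term at zero zeroes the evidence.

Per residue, raw scores sum the combined scores of every qualifying
cluster containing that residue across all templates of the queried metal
(evidence accumulates over independent templates; `max` aggregation is
available). Raw vectors are z-normalized per query chain with the
*population* standard deviation; an all-constant vector maps to all-zero
z-scores rather than dividing by zero. Normalizing per chain over the full
template scan is what makes a single per-metal calling threshold
meaningful across proteins of different sizes and match densities.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| binding cutoff | 3.5 | Å | definition of a binding residue (ion center to nearest non-H atom) |
| min site residues | 3 | — | "more than two" rule for a usable template |
| chain length filter | ≥ 51 | residues | "more than 50 residues" read strictly |
| d_c | 2.0 | Å | linkage threshold; must be stricter than the 3 Å cluster-RMSD bound, else clusters could chain through geometry the RMSD filter would reject |
| rmsd_max | 3.0 | Å | upper bound of acceptable local-alignment Cα-RMSD |
| θ (theta_seq) | 0.30 | — | sequence-conservation floor; per-metal overrides supported |
| min_cluster_size | 3 | residues | mirrors the template rule |
| z thresholds | CA 1.6, CU 1.8, MG 1.8, FE 1.0, MN 1.0, ZN 2.2 | — | per-metal calling thresholds at FPR ≤ 5 % |
| identity threshold | 0.25 | fraction | redundancy removal: single linkage over global-alignment identity |

The published account pairs the Mg²⁺ threshold (1.8) with TPR 61.4 % and
Mn²⁺ (1.0) with 37.0 %, while its summary table assigns 61.4 % to Mn²⁺ and
37.0 % to Mg²⁺; the defaults here follow the threshold assignment of the
running text. Since the original per-metal θ values were never published,
θ defaults to a single global 0.30.

Reconstruction choices (the source's equation bodies for the score terms
are not available in full): the linear RMSD map anchored at the stated 3 Å
bound; self-score normalization as the only reading of "maximum sequence
alignment score" that bounds s_seq at 1; product combination; sum
aggregation. Exponential RMSD decay and mean combination are selectable
via `ScoringParams` for sensitivity checks. The 1/N_c prefactor of the
per-residue score is a per-chain scale factor absorbed exactly by
z-normalization, so it is not applied separately.

## Leave-one-out and evaluation

Templates whose source structure id equals the query's are excluded at
prediction time (the exclusion unit is the PDB entry, not the chain or
the individual template — the most conservative of the three readings).
Structure ids round-trip through written PDB files via a `REMARK  99
STRUCTURE_ID` line, falling back to the HEADER idCode and then the file
name. Truth labels for evaluation are recomputed from geometry
(`find_binding_residues`) for every ion of the evaluated metal. Per metal,
z-scores and labels are pooled over all chains of all structures holding
that metal; ACC/TPR/FPR come from the pooled 2×2 table, the ROC enumerates
every distinct threshold, and "overall" micro-averages (pools) the
per-metal confusion counts. With `target_fpr` set, the calling threshold
is the smallest midpoint between consecutive distinct scores whose FPR
meets the constraint, which maximizes TPR under it. TPR with zero
positives is reported as NaN with a warning, never silently 0.

## Synthetic data

The generator builds chains by natural-extension placement with ideal
bond lengths (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å) and
conformation dihedrals (α-helix −57/−47, strand −120/+120, or seeded
irregular φ/ψ), plus a Cβ stub; consecutive Cα–Cα distances come out at
3.80 Å as they must for trans peptides. Metal sites are planted by a
deterministic coarse-to-fine grid search for an ion position with every
chosen residue within 2.8 Å (typical coordination distances are 2.0–2.6 Å,
comfortably inside the 3.5 Å label cutoff even after noise) and every
other residue beyond 4.3 Å; the placement is verified by a brute-force
distance scan and infeasible requests raise with diagnostics. Planted
binder identities follow the residue preferences observed for each metal
(e.g. CYS/CYS/HIS for Zn²⁺, ASP/GLU/ASN for Ca²⁺); decoy positions draw
from residue types that score ≤ +1 in BLOSUM62 against every binder type,
mimicking the chemical distinctiveness of real coordination shells.

The benchmark (`make_benchmark`, defaults: 20 structures, 40 residues,
helix, sites at positions 13/16/17, noise σ = 0.1 Å, metals ZN and CA
round-robin) makes every structure a Gaussian-perturbed, rigidly moved
copy of one base structure per metal, so each structure's site is a noisy
rigid copy of a shared motif and leave-one-out prediction is exercised
across structures. Truth labels are always regenerated from the final
perturbed geometry, never assumed from the construction.

What passing on this benchmark shows: the geometry engine, clustering,
scoring, normalization and evaluation machinery are correct and
rigid-motion invariant, and the method recovers sites whose templates
exist in the library under realistic coordinate noise. What it does not
show: performance on real crystal structures — the benchmark has no
side-chain rotamers, no alternate conformations, no missing atoms, no
structurally divergent homologous sites, and its decoy background is
chemically cleaner than a real proteome. The published large-scale
accuracy figures were measured on a curated 1,109-chain set that depends
on a historical PDB snapshot and external classifications, and are out of
desk-scale reach by design; nothing here claims to reproduce them.

## Numerical notes and edge cases

- An ideal helix has exact screw symmetry, so on noise-free ideal
  geometry a shifted correspondence can superpose as perfectly as the
  true one; the sequence term disambiguates in the benchmark, and the
  exact-copy unit tests use irregular conformations where the geometric
  optimum is unique.
- Compatibility matrices are computed blockwise (≈32 MB cap) so large
  m×n scans stay within memory.
- Altloc policy: keep blank or 'A' conformers, higher occupancy wins,
  'A' preferred on ties. Hydrogens are dropped on read. First MODEL only.
  MSE and other non-standard amino acids stay in chains, read as 'X' for
  scoring ('X' scores 0 against everything, including itself).
- Metals are identified by the element field of single-atom HETATM
  groups, never by name — an ATOM record named "CA" is a Cα carbon, not
  calcium. Ions embedded in multi-atom hetero groups (e.g. heme Fe) are
  not treated as free ions.
- Binding shells may span chains; the template records each residue's
  chain.
- Library JSON stores coordinates at 3 decimals, matching PDB precision.

## Known limitations

- No mmCIF input; no symmetry mates or biological assemblies.
- Redundancy curation uses global-alignment identity
  (matches / alignment length, BLOSUM62, gap open −11 / extend −1) with
  single-linkage grouping; superfamily-level balancing against an external
  structural classification is out of scope.
- θ and the z thresholds are fixed defaults, not learned; there is no
  training loop.
- The m×n×(pair²) scan is exhaustive by default; the BLOSUM prefilter
  (`prefilter=True`) trades completeness for speed on large queries.
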