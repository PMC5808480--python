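# Methods

## Model overview

`enstab` analyses how point variants change a protein's conformational
behaviour using harmonic elastic-network models rather than molecular
dynamics. The chain of computation is:

1. build an anisotropic network model (ANM) of each structure;
2. sweep a perturbation coordinate along the most collective low-frequency
   normal modes to produce a conformer ensemble;
3. score every hydrogen bond geometrically in every conformer and express
   its stability as the fraction of conformers in which it is formed (SEA);
4. compare each variant's SEA vector with the wild type's, attribute the
   squared deviation to individual bonds, and call the persistent outliers
   "destructive" bonds;
5. independently, derive pairwise mechanical stiffness maps from the same
   ANM and correlate them with external annotations (conservation scores,
   patient survival times).

## Elastic network and conformer ensembles

Nodes within `cutoff` (default 8 Å) are joined by springs of identical
constant γ (default 1, all stiffness output is in units of γ). The Hessian
carries the standard ANM 3×3 blocks `H_ij = −(γ/R_ij²)(R_ij ⊗ R_ij)` with
diagonal blocks closing each row to zero. A connected network has exactly
six zero modes (rigid translations/rotations); any other count aborts the
run because downstream bookkeeping assumes it.

Mode selection uses the entropy-based collectivity
`κ = exp(−Σ p_i ln p_i)/N` with `p_i` the normalised squared nodal
displacement: the `n_modes` (default 5) non-trivial modes of highest
collectivity are swept. Ties in collectivity resolve toward lower frequency;
near-degenerate eigenvalues are logged because their order is then
solver-dependent.

The perturbation coordinate DQ runs from −100 to +100 in steps of 20
(11 values, hence 5 × 11 = 55 conformers per structure, the dq = 0 conformer
being the input itself). DQ is dimensionless; the package maps |dq| = 100 to
a physical amplitude via `amplitude_scale` (default 2 Å of maximum nodal
displacement, with eigenvectors rescaled to unit maximum nodal displacement
so the amplitude is interpretable). SEA values should always be read
together with the amplitude used.

Node policy: ensembles default to `heavy_atoms` — hydrogens are not
independent nodes (they would triple the eigenproblem for no gain at this
resolution) but ride rigidly with the nearest node of their own residue so
they exist in every conformer for bond detection. Stiffness maps default to
`calpha` plus one node per metal ion, the standard ANM coarse-graining for
residue-indexed quantities.

## Hydrogen bonds and SEA

A bond is scored purely geometrically: donor heavy atom N/O with a hydrogen
within 1.2 Å covalent range, acceptor any N/O, bond present iff the
donor–acceptor distance is ≤ 3.0 Å and the donor–H–acceptor angle is
≥ 135°. Both thresholds are configuration keys; the defaults are the common
trajectory-analysis defaults. Bonds are orientation-specific (donor →
acceptor) and keyed by chain, residue number and atom names, which requires
consistent residue numbering between wild type and variants (checked before
table assembly). Intra-residue pairs and water are excluded.

`SEA_i^m = N_i^m / |ensemble|` where `N_i^m` counts the conformers of
structure *m* containing bond *i*. The table is built over the union of
bonds seen anywhere, with explicit zeros for absent bonds: this makes the
deviation D symmetric in which structure first revealed a bond.

## Destructive-bond detection

Per variant *m*: `D^m = sqrt(Σ_i (SEA_i^m − SEA_i^WT)²)` and per bond
`ξ_j^m = (SEA_j^m − SEA_j^WT)² / (D^m)²` (so Σ_j ξ_j^m = 1 whenever
D^m > 0; a variant identical to the wild type is flagged and given a zero ξ
row rather than NaNs).

Table H histograms each variant's ξ values into nine bins of width 0.1.
Read literally the ninth bin `[0.8, 0.9)` would leave a bond carrying the
whole deviation uncounted, so bin 9 closes at 1.0 inclusive. By default a
variant's row counts only bonds present in that variant or the wild type
(`variant_present_bonds`); counting the full union is available as
`union_bonds`. `S̄_H` — the mean of bins 2–9 — counts bonds contributing
more than 10% of (D)².

Variants are then clustered by their H rows (mean shift, flat kernel,
bandwidth estimated from the data); every cluster whose mean S̄_H exceeds
zero contributes its members to the "high-contribution" selection. The mean
contribution ξ̄_j over the selected variants is tail-thresholded: the
threshold is the empirical (1 − tail) quantile (linear interpolation, tail
default 5%) of the *nonzero* ξ̄ values — bonds that never deviate form a
point mass at zero that would otherwise dominate the quantile base. Bonds
at or above the threshold are destructive; the explained fraction is the
mean share of (D^m)² they carry over the selected variants.

With a background of grid-rounded noise, most bonds acquire a small nonzero
ξ̄, so the 5% tail generally contains somewhat more bonds than any planted
signal; recovery of planted signals is therefore assessed as recall plus
top-rank identity, not set equality (see the test suite).

## Mechanical stiffness

For nodes i, j the compliance under uniaxial extension is
`c_ij = Σ_k λ_k⁻¹ [(u_k(j) − u_k(i))·n̂_ij]²` over non-trivial modes, and
`κ_ij = 1/c_ij` (the uniaxial-extension effective-spring formulation). All
non-trivial modes are used by default; truncating the sum can only drop
positive compliance terms, so truncated κ is biased stiff (tested). Pairs
whose compliance underflows 1e−12 carry an +inf sentinel, are flagged, and
are excluded from means and quantiles.

Summaries: `K̄_i` is the row mean over actual partners (a `same_chain`
scope is available where a per-subunit reading is wanted); `κ_site,i` is the
κ row of a named metal node. Tail extraction returns the keys of the
rightmost `fraction` of a distribution, defined as everything at or above
the ⌈fraction·n⌉-th largest value — this makes ties inclusive and the
fraction → 1 limit return every key, which interpolated quantiles do not.

The transmission path between two sites is the widest path (maximising the
minimum edge κ) on the contact graph of node pairs within 8 Å, computed via
the maximum spanning tree; it operationalises "a chain of spatially close,
mutually stiff residues" as a concrete graph criterion.

## Statistics

Mean shift uses a flat kernel with every point as a seed (deterministic for
a fixed input order); the bandwidth estimator is pinned in-package as the
mean distance to the k-th nearest neighbour with k = int(quantile·n),
counting the point itself, so results do not drift with library versions.
Hierarchical outlier ranking orders items by mean distance to all others
(average-linkage merge table returned for dendrogram inspection; ties break
stably by item id). Pearson correlations use the two-sided t-approximation;
the two-sample Kolmogorov–Smirnov test is the asymptotic two-sided form;
multiple testing uses Benjamini–Hochberg at 5% FDR. List-intersection
significance is one-sided hypergeometric enrichment over a stated position
universe (default 306 = two chains of 153); positional co-occurrence of two
residue lists is the Pearson correlation of their 10-bin occupancy vectors
over that universe.

## Synthetic data

The generators define the study conditions the tests run under:

- **Toy structures** are backbone-only (N, H, CA, C, O per residue).
  The helix geometry is built from ideal internal coordinates with
  dihedrals (φ, ψ) = (−59°, −50°), chosen so the i→i+4 amide ladder sits
  at N···O ≈ 2.8 Å and D–H–A ≈ 166°, well inside the default criteria.
  The hairpin geometry is an explicit antiparallel two-strand ladder (not a
  physical β-sheet) guaranteeing a cross-strand bond per rung. A seeded
  0.03 Å jitter breaks exact symmetry, which would otherwise create
  degenerate modes. Chains are laid ~7 Å apart so dimers have inter-chain
  elastic contacts at the 8 Å cutoff. Metals are placed at the centroid of
  their coordinating residues' CA atoms.
- **Variants** add Gaussian coordinate noise (stated σ) to all atoms of the
  listed residues only.
- **Planted SEA tables** draw the wild-type column uniformly on the 1/55
  occupancy grid, add grid-rounded noise (σ = 0.02) elsewhere, and shift
  planted (bond, variant) entries by δ = 0.4 away from the nearer boundary
  (5 planted bonds of 200, 9 variants by default).
- **Survival tables** follow `s = a + b·κ + N(0, σ²)` truncated at
  0.1 years; with b = −0.5 and σ = 1.146 the planted correlation at n = 32
  is ≈ −0.4.

What the toys do *not* emulate: side chains (so no side-chain H-bonds or
packing), realistic secondary-structure mixtures, crystallographic noise,
or physically meaningful spring constants. Passing tests demonstrate the
correctness of the algorithms and their statistical behaviour under the
stated generative model, not predictive accuracy on real proteins.

## Problem sizes and numerical choices

The default test/acceptance study uses 12-residue two-chain toys
(≈ 120 atoms, ≈ 96 heavy-atom nodes), 36 structures, 55 conformers each
(1980 total) — sizes chosen so a full end-to-end run completes in seconds
while every code path (multi-chain bonds, metals, clustering, tails) is
exercised. Hessians are diagonalised exactly (`scipy.linalg.eigh`); no
rotation–translation-block projection is implemented, though configuration
files may carry an `nrbl` key for compatibility (it is ignored). Rigid-mode
detection uses a relative threshold of 1e−8·λ_max. Degenerate inputs
(identical points in clustering, variants identical to the wild type,
zero-width DQ sweeps, single-cluster outcomes) return flagged, well-defined
results rather than NaNs wherever a sensible value exists.

## Known limitations

- The DQ → Ångström amplitude map is a modelling choice; absolute SEA
  values depend on it, though comparisons across structures at a fixed
  amplitude do not.
- Bond identity by residue numbering cannot follow insertions/deletions —
  only substitution variants are supported.
- The high-contribution selection depends on the mean-shift bandwidth
  estimate; with few variants or near-identical H rows the selection can
  collapse to empty (reported, with the tail step then skipped).
- Stiffness κ is reported in units of γ; only ratios and orderings are
  physically meaningful.
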