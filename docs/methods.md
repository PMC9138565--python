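# Methods

## Scope and model

`scrsasa` characterises single-chain protein structures through their
solvent-accessible surface area (SASA) and clusters proteins by
SASA-derived descriptors. The SASA of an atom is the area traced by the
centre of a solvent probe (water, radius 1.4 Å) rolling over the van der
Waals surface; equivalently, the part of the sphere of radius
r_vdw + r_probe not buried inside any neighbouring atom's expanded
sphere. All downstream quantities — per-residue areas, burial classes,
whole-protein totals (TSA and its polar/apolar and backbone/side-chain
decompositions TPS, TAS, BBS, SCS), structurally-conserved-region (SCR)
fingerprints — derive from this per-atom integral.

## Surface-area integration

Areas are computed by Shrake–Rupley sphere-point sampling: a
deterministic golden-spiral lattice of `n_points` test points (default
960) is scattered on each atom's expanded sphere, a point counts as
buried when it lies inside **or exactly on** a neighbour's expanded
sphere (the tie rule makes the integral a deterministic function of the
coordinates), and the accessible area is the expanded-sphere area times
the free-point fraction. At 960 points the isolated-sphere closed form
4π(r+1.4)² is reproduced to better than 0.5 %, the two-sphere
spherical-cap closed form to ~0.3 %, and a high-density Monte-Carlo
estimate to <1 % on random clouds; doubling the lattice moves per-atom
areas by well under 2 %. `n_points` is exposed rather than fixed because
the analytic server methods this emulates have no finite lattice to
match.

Two numerical choices deserve note:

* **Lattice orientation.** A fixed lab-frame lattice is not
  rotation-invariant at finite `n_points`. The lattice is therefore
  oriented by a structure-intrinsic frame (centroid, farthest atom,
  farthest-from-that atom, ties by lowest index), which makes every
  buried/free decision — hence every area — exactly equivariant under
  rigid motion. Collinear structures leave an azimuthal degree of
  freedom, but their buried sets are axially symmetric, so the
  completion does not affect areas. An explicit orientation can be
  passed to pin the lattice instead (used, e.g., to verify the
  monotonicity property that deleting an atom never shrinks another
  atom's area).
* **Neighbour search.** Candidate occluders come from a k-d tree query
  of radius r_i + max_j r_j, filtered to actual overlaps. This is an
  implementation detail with a hard contract, tested directly: results
  are identical to the all-pairs loop to 1e-9 Å².

Radii are the Chothia united-atom values (C 1.87, N 1.65, O 1.40,
S 1.85 Å) with a 1.4 Å probe; hydrogens are stripped on input and never
modelled. Polarity follows the element (N, O polar; C, S apolar), which
defines the TPS/TAS split. All radii are configurable through a
`RadiiTable` (YAML-loadable); the packaged reference table records which
radii produced it.

## Burial classification (nucleus / surface)

A residue's relative accessibility is its side-chain SASA divided by the
mean side-chain SASA of the same residue type X in a Gly-X-Gly
tripeptide over an ensemble of 30 random conformations. Glycine, having
no side chain, is referenced and classified by its all-atom SASA.
Ratios above 0.5 mark *surface* residues, below 0.2 *nucleus*, the rest
*intermediate*; both comparisons are strict, so ratios of exactly 0.5 or
0.2 fall in the intermediate class.

"Random conformation" is made precise as: φ uniform in (−180°, 0°), ψ
uniform in (−180°, 180°), ω fixed at 180° (trans), side-chain χ angles
uniform per rotatable bond, with rejection of conformers in which any
two atoms from non-adjacent residues approach closer than 0.6× the sum
of their van der Waals radii (bounded retries). The packaged reference
(`data/gxg_reference_n30.tsv`) was generated once with ensemble size 30
and seed 42 and ships with full provenance in its header; regenerating
with the same arguments is bit-identical, and `build_reference` (or the
`build-ref` CLI command) produces variants.

The per-protein environment summary totals nucleus and surface SASA
(each split into apolar/backbone/side-chain parts) and reports a
per-residue average, (nucleus + surface SASA)/denominator. The
denominator defaults to the number of classified (nucleus + surface)
residues; full sequence length is available as an option. The two
readings differ materially and published per-residue averages of this
kind are not always explicit about which is meant, so the choice is a
configuration field rather than a constant.

## Sequence descriptors

The ProtParam-style descriptor set: residue count; molecular weight from
ExPASy average isotopic residue masses minus one water per peptide bond;
isoelectric point by bisection on the Bjellqvist charge model
(residue-specific N-terminal pKa values, |net charge| < 1e-4 at the
reported pH); counts of Asp+Glu and Arg+Lys; Ikai aliphatic index
100·(fA + 2.9 fV + 3.9 (fI+fL)); and Kyte–Doolittle GRAVY. Every one of
these is a function of amino-acid composition alone (plus the N-terminal
residue identity for pI), which the test suite checks as a permutation
invariance.

The package ships the published compositions of the eight
*Amycolatopsis eburnea* lipases (UniProt A0A3R9KNJ9, A0A3R9DUJ4,
A0A427T6P4, A0A3R9KMI2, A0A3R9EQB2, A0A3R9F8T1, A0A3R9DV90,
A0A427T2R3). Because the descriptors are composition functions, a
*surrogate* sequence with the published composition — one Met placed
first, mirroring the initiator methionine of full-length bacterial
entries, remaining residues in a fixed order — reproduces each entry's
published descriptor values exactly. Surrogates carry no positional
information and are labelled synthetic; when network access exists, the
`fetch` command downloads the real records.

## Secondary structure

Chou–Fasman prediction with the 1978 propensity and bend-frequency
tables (Chou & Fasman, *Adv. Enzymol.* 47:45–148, 1978). Helix
nucleation requires a window of 6 with ≥4 residues of Pα ≥ 1.00, sheet a
window of 5 with ≥3 of Pβ ≥ 1.00; runs extend while the mean propensity
of the advancing tetrapeptide stays ≥ 1.00. A turn is flagged at i when
the bend product f(i)f(i+1)f(i+2)f(i+3) exceeds 7.5e-5 and the mean turn
propensity of the window exceeds 1.00 and both the mean Pα and mean Pβ.
Helix/sheet/turn masks are kept as possibly-overlapping tracks — the
convention of the classical servers, whose per-class percentages can sum
above 100 — with a resolved single-label track (turns win; helix/sheet
overlap runs go to the larger run-mean propensity) derived from them.
Per-class percentages are indicative descriptors, not quantities with an
external ground truth.

## Structurally conserved regions and fingerprints

Chimera-style structural superposition is replaced by a defined,
reproducible alignment-column criterion: a column of a rectangular
multiple alignment is conserved when it is gap-free in every sequence
and its majority residue frequency is ≥ `min_conservation` (default
0.5); maximal conserved runs of ≥ `min_len` (default 5) columns become
regions. Explicit intervals (BED-like TSV, 0-based half-open, alignment
coordinates) can be supplied instead, which is the recommended route
when regions come from an external structural tool. Residue-index maps
are built with per-sequence gap-skipping cursors.

The SCR-SASA fingerprint of a protein is the ordered vector of residue
SASA totals over all SCR columns (side-chain-only areas are a config
alternative). Fingerprints of one SCR set share their length by
construction, which makes them valid clustering observations; their
Pearson correlation matrix and the residue-type counts over SCR
positions are reported alongside.

## Clustering

Observations are compared by Euclidean distance and merged
agglomeratively under the Ward criterion, implemented via the
Lance–Williams recurrence on squared distances

    d²(k, i∪j) = [(nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖ d²ᵢⱼ] / (nᵢ+nⱼ+nₖ),

with ties broken toward the smallest index pair. Heights are the root
Ward distance — two singletons at Euclidean distance d merge at height d
— matching the common dendrogram convention (and scipy's), which the
tests pin against both an exhaustive from-scratch reference
(d(A,B) = √(2|A||B|/(|A|+|B|)) · ‖c_A − c_B‖ recomputed from raw points
at every step) and scipy's independent implementation. Ward linkage is
reducible, so heights never decrease. Dendrograms serialise to Newick
with node elevations at half the merge height (a two-leaf tree of height
4 renders `(a:2.0,b:2.0);`); cophenetic heights are ultrametric by
construction.

Two observation sets are clustered: (a) the whole-protein 9-component
summary vector (TPS, TAS, TSA, SCS, BBS, nucleus total, surface total,
per-residue average SASA, residue count), which is length-independent
and therefore valid across proteins of unequal size, optionally
z-scored; and (b) the equal-length SCR-SASA fingerprints. Pairwise
similarity percentages are reported as 100·(1 − h/h_root) from
cophenetic heights; this transform is an explicit, pluggable choice —
percentage similarities from dendrograms have no single standard
definition — and the numbers it yields should be compared only under
the same transform.

## Synthetic data: what it emulates and what it does not

The generator produces everything the pipeline consumes, with known
ground truth:

* **Ideal-geometry peptides** from per-residue (φ, ψ, ω) via the NeRF
  internal-coordinate construction with standard backbone bond lengths
  and angles (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles
  121.7/111.2/116.2/120.8°). Side chains are grafted from the idealised
  chemical-component templates shipped with biotite (rigid 3-point
  superposition on N/CA/C) and re-dihedralised about the standard χ
  bonds; chirality is the templates' L-configuration. φ = −57°, ψ = −47°
  reproduces the α-helical CA(i)–CA(i+3) spacing of 5.2 Å.
* **Gly-X-Gly conformer ensembles** under the dihedral scheme above,
  clash-rejected, deterministic in (X, n, seed).
* **Labelled families**: groups share a random-coil backbone template;
  each non-reference group shifts the dihedrals of a contiguous third of
  the chain by 60–120° and substitutes `n_edits` positions (defaults:
  3 groups × 3 members, length 40, jitter σ 0.2 Å, 8 edits); members add
  isotropic Gaussian coordinate jitter. Equal lengths make the
  ground-truth alignment the ungapped stack of the sequences.

What passing tests on these fixtures shows: the geometry, integration,
classification and clustering machinery is internally correct, and
planted group structure of realistic magnitude is recovered exactly
(adjusted Rand index 1.0 at k = 3). What it does not show: fidelity to
experimentally determined structures. The fixtures have no rotamer
preferences, no compact tertiary packing (random coils are far more
extended than folded proteins, so surface/nucleus proportions differ
from globular values), no indels between family members, and idealised
bond geometry throughout. Published table values that depend on
undeposited homology models are for the same reason treated as
illustrative context, not as test oracles.

## Degenerate inputs and tie rules

Coincident atoms are an error (both atoms named); lattice points exactly
on a neighbour sphere count as buried; conserved-region ties do not
arise (maximal runs are unique); Ward ties break on the smallest index
pair; ratios exactly at a burial threshold are intermediate; zero-length
sequences, ragged alignments, zero-variance fingerprints and
sub-nucleation-window sequences are rejected with named errors.

## Known limitations

* Sampling-based SASA: per-atom error is bounded by the lattice density,
  not zero as in analytic (Gauss–Bonnet) methods.
* Proline's ring is kept at template geometry; its χ angles are not
  sampled.
* The alignment-column SCR criterion is a stand-in for
  structure-superposition methods and will differ from them on distantly
  related sequences.
* Secondary-structure percentages follow the overlapping-mask
  convention; they are not comparable to single-label (DSSP-style)
  percentages.
* The per-residue average SASA depends on the denominator convention
  (see above); cross-study comparison requires fixing it.
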