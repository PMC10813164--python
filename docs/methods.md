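# Methods

This note records the models, algorithmic choices and parameter defaults
behind `ditps3d`, what the synthetic benchmark does and does not emulate,
and the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Sequence analysis

**Signature motifs.** The class-diagnostic aspartate motifs are matched as
patterns over the one-letter alphabet: `DDXXD` = `DD..D`, `DXDD` = `D.DD`,
`FEHXW` = `FEH.W`, with `FERLW`, `LHS`, `PNV` literal and `PIX` = `PI.`.
The NSE/DTE triad, whose per-position spelling varies across the
literature, is matched permissively as `[ND]D..[ST].[ED]`. Class
assignment: class I if DDXXD or NSE/DTE is present without DXDD, class II
for the converse, bifunctional I/II when motifs of both kinds co-occur,
unknown otherwise.

**Domain splitting.** Explicit domain ranges (1-based inclusive) always
win. Without them, the N/C boundary is the round-half-up midpoint between
the end of the last class II anchor hit (DXDD/LHS, βγ region) and the start
of the first class I anchor hit (DDXXD/NSE-DTE, α domain):
`boundary = (end_II + start_I + 1) // 2`. The midpoint convention is a
package decision — no published per-family boundary exists — and is only a
fallback; curated range columns are the primary path.

**Percent identity.** Global alignment under BLOSUM62 with affine gaps
(open 10, extend 0.5; a length-L gap costs 10 + 0.5·(L−1)), terminal gaps
penalized in the score. Identity = 100 × identical columns ÷ alignment
length counting internal gap columns, with terminal-gap overhang columns
excluded from the denominator: N/C domain slices differ in length by
construction and the overhang would otherwise dominate the value. The
aligner is Biopython's `PairwiseAligner`; the test suite checks its scores
against an independent naive Gotoh DP and checks the identity value against
the set of identities realised by optimal alignments (co-optimal alignments
can differ in identity; any optimal value is accepted).

**Sequence similarity networks.** Edges are thresholded on percent identity
(minimum score) by default. An E-value mode is provided for comparability
with BLAST-derived networks, using the Karlin–Altschul form
E = K·m·n·exp(−λS) with the gapped BLOSUM62 constants λ = 0.267,
K = 0.041; it shares the thresholding semantics (edge iff E ≤ cutoff).
Isolated nodes are retained so cluster counts remain meaningful.

## Structural analysis

**Shells.** A residue belongs to the shell of radius r iff any of its heavy
atoms lies within r (inclusive) of any ligand heavy atom; the whole residue
is then retained, in chain order — the `byres all within r` selection.
Hydrogens are discarded at parse time. Radii 4, 6, 8, 10 Å are the
defaults; nesting of shells across radii is an invariant the suite checks.

**TM-score.** TM = (1/L)·Σ 1/(1 + (dᵢ/d₀(L))²) with
d₀(L) = 1.24·(L−15)^⅓ − 1.8 clamped below at 0.5 Å. TM is asymmetric in
the normalizing length; both normalizations are computed and their mean is
the scalar entry in similarity matrices (both values are retained on the
alignment object for sensitivity checks).

**Alignment.** The sequence-order-dependent aligner alternates (i) Kabsch
superposition on the current pair set, re-fit on the pairs closer than
max(d₀, 1 Å), and (ii) global dynamic programming over the TM kernel score
matrix with gap opening −0.6 and free extension, until the pair set repeats
or 30 iterations. Seeds come from gapless diagonal threading at sampled
shifts plus short windows (lengths 5 and half of the shorter chain). For a
fixed correspondence the TM-optimal transform is found by the classic
fragment-grow-and-refine iteration. On 8-residue toys the aligner is tested
against an exhaustive search over all monotone correspondences (each scored
with the same transform optimizer) to 10⁻³; the heuristic's reach beyond
toy sizes is bounded by its seeds, as for any threading-seeded aligner.

**Kabsch.** SVD-based least squares with the determinant correction so only
proper rotations are returned; collinear point sets are rejected because
the rotation is then underdetermined.

## 3D motifs

**Site alignment.** The largest shell is the reference; every other site is
matched to it independently. Each residue is described by its sorted vector
of intra-shell Cα distances (order-free); candidate pairs are scored by the
fraction of greedily matched descriptor entries agreeing within 1.5 Å plus
a +0.2 bonus for identical residue letters (capped at 1), and resolved by
maximum-weight Hungarian assignment. The assignment is refined by iterating
Kabsch superposition, dropping pairs deviating by more than 3 Å, and
re-assigning by spatial proximity (≤ 10 rounds). Because descriptor scores
saturate on small shells, refinement is multi-start: rigid 3-point seeds
are generated from every triplet of a 5-anchor farthest-point subset of the
reference (site triplets must reproduce the triplet's mutual distances
within 1.5 Å). The final mapping maximizes a sequence-aware kernel,
Σ [1/(1 + devᵢ²) + 0.2·(identical letters)]: the distance kernel rewards
many tight pairs and cannot be gamed by trading a distorted superposition
for a few extra loose matches, and the identity term resolves approximate
geometric self-symmetries of a site that distances alone cannot.

**Extraction.** Per reference column, coverage c = fraction of sites with a
matched residue and tightness g = max(0, 1 − mean deviation / 3 Å). Columns
pass with c > 0.6 and g > 0.4 (both gates independently configurable; the
two cutoffs are the conventional representativeness thresholds for this
kind of site-motif mining, operationalized here on fully specified scores).
The consensus letter is the modal residue; alternatives are letters seen in
≥ 20% of sites. Template geometry is the across-site consensus: each site
is superposed onto the reference and matched Cα coordinates are averaged
per column. Averaging halves the coordinate noise a raw single-site
template would carry, which matters because the search tolerances below are
only a few standard deviations of the inter-site jitter.

**Search.** Candidate residue tuples are enumerated by identity (strict:
every position must show the consensus or an allowed alternative; relaxed:
at most one violation), pruned by pairwise Cα distance compatibility with
the template (±1.5 Å per pair), superposed by Kabsch, and accepted at
RMSD ≤ 2 Å, sorted by (mismatches, RMSD). The DFS enumeration is proven
equal to a brute-force scan over all residue tuples on small queries; the
distance pruning removes only tuples the brute-force predicate would also
reject, so the equality is structural, not statistical.

## Product chemistry

Morgan (ECFP4-equivalent, radius 2) bit fingerprints folded to 2048 bits —
RDKit's Morgan generator; bit (not count) fingerprints with Dice similarity
2|A∩B|/(|A|+|B|); both the radius and width are config-exposed. Enzyme-pair
product similarity is the mean Dice over the full cross-product of the two
product sets; a single-product pair reduces to one value. The matrix
diagonal is computed like any pair — a multi-product enzyme with dissimilar
products has self-similarity < 1 — and the diagonal is excluded from all
correlations. Carbon skeletons: delete non-carbon atoms, set every
remaining bond to single order (dropping stereo), keep the largest carbon
component, return its canonical SMILES; curated skeleton labels take
precedence over this reduction when both exist, since published skeleton
taxonomies encode expert decisions the reduction cannot reproduce.

## Statistics

AAC over the 20 standard letters (X skipped, count noted); GAAC over
aliphatic {G,A,V,L,M,I}, aromatic {F,Y,W}, positive {K,R,H}, negative
{D,E}, uncharged {S,T,C,P,N,Q}. Preferential value = shell frequency ÷
full-sequence frequency, flagged undefined (never divided) where the
denominator is zero. Pearson r from the closed form with a two-sided t-test
on n−2 degrees of freedom; the pair universe for every correlation is the
unordered distinct enzyme pairs present in all factors, diagonal excluded,
with listwise deletion. No multiple-testing correction is applied to the
factor-pair table by default (a Benjamini–Hochberg flag exists). Group
comparisons use the two-sided Mann–Whitney U — distribution-free, matching
the box-plot style of the similarity distributions — exact for combined
n ≤ 20 without ties, tie-corrected normal approximation otherwise.

## Synthetic cohorts

The generator emits exactly the formats the readers consume (annotation
TSV, FASTA, PDB with a HETATM ligand) plus a JSON ground-truth file, all
byte-deterministic in the seed (single RNG stream).

* **Pocket.** A GGPP-like 5-atom ligand stub at the origin; six motif
  residues (D, W, F, Y, S, R — conserved identities reported for these
  enzymes) at fixed template coordinates within 6 Å of the ligand, jittered
  N(0, σ²) per axis with σ = 0.3 Å; two decoy residues per enzyme at random
  positions in a 4.2–6.8 Å band; optionally two family-specific pocket
  residues shared within a family. All pocket Cα placements respect a
  2.8 Å steric separation — real Cα pairs cannot coincide, and without this
  exclusion random decoys occasionally sit on a template slot and corrupt
  the reference site.
* **Backbone.** The remaining residues form a self-avoiding random Cα trace
  (3.8 Å steps, glycine-like N/CA/C/O stubs) kept ≥ 11.5 Å from the pocket
  centre. Chain continuity is intentionally broken where pocket residues
  interleave the trace: every downstream computation is geometric, not
  energetic, so a physically continuous backbone would add cost without
  adding test power.
* **Sequences.** Family-specific iid backgrounds over the 19 non-aspartate
  letters (so aspartate motifs exist only where planted), per-enzyme point
  mutations at rate 0.08, class signature motifs (`DLDD` in the N half,
  `DDLID` in the C half) per the class mix {I: 0.40, II: 0.35, I/II: 0.25}
  — proportions in the range reported for curated collections — and pocket
  letters written at the pocket positions. Each sequence is verified to
  classify to its planted label at generation time (rare background
  spellings of the NSE/DTE triad are re-drawn).
* **Products.** Three scaffold families (linear isoprenoids, labdane-like
  decalins, abietane-like aromatics; within-family Dice ≈ 0.5–0.8,
  between ≈ 0.1–0.4), one or two products per enzyme, a shared bridge
  molecule at rate 0.1. Exactly round(0.16·n) enzymes draw their products
  from a foreign family. That defection fraction is the coupling knob: it
  was calibrated once, by simulating held-out seeds and measuring the
  pairwise Pearson correlation between full-sequence identity and product
  Dice at n = 50, to a planted coupling of 0.5; the deterministic count
  (rather than per-enzyme coin flips) pins the realized correlation tightly
  around the target.
* **Held-out sites.** One enzyme per family carries a single substitution
  (to alanine) at a random motif position — the target for the relaxed
  motif-search benchmark.

What passing tests on this cohort do **not** show: realistic fold
similarity (backbones are independent random walks, so global TM between
enzymes is low and carries no family signal), realistic side-chain
chemistry in the pocket (stub atoms only), realistic sequence composition
(no aspartate outside planted motifs), or the label noise and docking-pose
uncertainty of real curated datasets. The cohort tests the machinery —
shell extraction, alignment, motif mining, correlation recovery — under
controlled signal and noise, not the biology.

## Problem sizes and defaults

Default cohorts are 18 enzymes (chain length 80) for full-pipeline runs,
9 enzymes for the single-family motif benchmark, and 50 (sequences and
products only) for coupling recovery; the acceptance script uses 20 motif
seeds and 3 coupling seeds. These sizes give stable recovery statistics
while keeping any single run in the seconds-to-a-minute range on one core.

## Known limitations

* The structural aligner is a compact TM iterator, not a full TM-align: no
  secondary-structure seeding and no circular-permutation search. Its
  optimality is verified only at toy sizes.
* Site alignment matches each site to the reference independently; a true
  multiple alignment (consistency across sites) could rescue columns the
  pairwise matching loses.
* At small site counts the coverage gate (> 0.6) admits chance geometric
  matches: with five sites, three coincidental ≤ 3 Å matches suffice, so
  motifs extracted from very few sites may carry an extra position.
* Motif search enumerates by identity and geometry without a persistent
  pair index; fine for single structures and small screens, not for
  proteome-scale sets.
* E-value mode uses fixed Karlin–Altschul constants for one scoring scheme;
  identity thresholds are the supported default.
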