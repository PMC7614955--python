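# Methods

## The model

Proton-translocating NAD(P) transhydrogenase (NTH) is treated as an
ordered sequence of architectural elements: an NAD(H)-binding domain I, an
NADP(H)-binding domain III, and stretches of transmembrane (TM) helices.
Two single-chain configurations exist in eukaryotes. The αβ isoform has
domain I amino-terminal (domain I, one stretch of 14 TM helices, domain
III); the βα isoform is inverted (a stretch of typically 9 helices, domain
III, domain I, a stretch of typically 4). The package makes three kinds of
inference:

1. **Isoform classification.** The configuration call is made from domain
   order alone — αβ iff domain I starts before domain III. TM-stretch
   structure is treated as characteristic, not defining: departures from
   the template only raise quality flags. A missing domain yields
   AMBIGUOUS. Because hydride transfer needs domains I and III on the same
   membrane side, an odd number of TM helices strictly between them is
   physically impossible and yields INVALID (the parity rule). Zero
   helices between the domains is even and therefore valid — this is the
   normal βα situation, where the two domains are adjacent between the
   stretches.

2. **Paralogue grouping.** βα-type genes across Apicomplexa and chromerids
   descend from two ancestral paralogues (groups I and II). A query is
   assigned to the group whose reference set has the smaller mean pairwise
   distance; the margin (absolute difference of the two means) quantifies
   support and calls below `min_margin` stay UNASSIGNED. This deliberately
   avoids depending on how a tree resolves deep branches; a
   neighbor-joining tree with outgroup rooting is provided for visual
   cross-checking.

3. **Dollo loss inference.** Each lineage's complement reduces to three
   binary characters (αβ, βα/I, βα/II), treated independently. Under a
   single gain at or above the root and irreversible loss, the minimal
   scenario for a character on a rooted tree puts one loss on every edge
   subtending a maximal all-absent subtree; the count of such edges is the
   minimal loss number (verified against exhaustive search over edge
   subsets on all trees with ≤ 12 edges). Candidate topologies are ranked
   by total losses across characters, ascending, ties broken by name.

## Tunable parameters

TM scan (dimensionless Kyte–Doolittle hydropathy units; lengths in
residues): `window=19`, `threshold=1.6`, `min_helix_len=15`,
`max_helix_len=30`, `min_loop_len=4` — classical scanning defaults for
membrane proteins. `max_gap=80` separates stretches: two helices further
apart than 80 residues, or separated by a soluble-domain hit, belong to
different stretches. `X` scores 0.0; other non-canonical characters are
rejected with the offending position.

Domain scan: packaged position score matrices built from
Rossmann-fold-style consensus strings authored in this repository (domain
I carries the classical GXGXXG dinucleotide-binding fingerprint). Match
cells score 4, everything else 0; the acceptance threshold is 60 % of each
motif's maximum, which sits far more than three standard deviations above
the score distribution on unplanted background sequence (tested), and
tolerates roughly 40 % point mutation before a planted motif is missed.
These matrices are a functional desk-scale stand-in for profile-HMM domain
annotation; output of real annotation tools can be substituted via
`parse_external_annotations` (canonical TSV: `protein_id`,
`feature_type` ∈ {NAD_binding, NADP_binding, TMhelix}, `start`, `end`,
1-based inclusive — convert real predictor exports to this layout; all
internal coordinates are 0-based half-open).

Isoform calls: `helix_tolerance=2` helices per stretch before a
TM_COUNT_DEVIATION flag ("typically 9 and 4" implies natural variation).

Distances and grouping: global alignment with match +1, mismatch −1, gap
−2 (no affine extension) — the smallest defensible scheme, configurable;
`p_distance` = mismatches over aligned non-gap columns, `poisson` =
−ln(1−p) capped at `max_distance=10`; `min_margin=0.02` expected
substitutions per site excludes coin-flip group assignments.

All tunables live in one validated `RunConfig` (YAML + flag overrides;
unknown keys rejected).

## Numerical and design choices

* Hydropathy windows are truncated at the termini (exact means over the
  available residues), so the profile of a reversed sequence is the
  reversed profile.
* Above-threshold runs closer than `min_loop_len` merge; runs longer than
  `max_helix_len` are split recursively at the lowest-profile interior
  position **among positions leaving both pieces ≥ `min_helix_len`**
  (leftmost minimum on ties). Restricting the cut this way avoids the
  degenerate 1-residue fragments an unrestricted lowest-point cut produces
  on flat hydropathy plateaus. Runs shorter than `min_helix_len` are
  extended into free flanking sequence, left side first.
* Greedy motif-hit selection orders candidates by higher score, then
  smaller start — deterministic.
* A TM stretch overlapping a domain hit is truncated at the domain
  boundary; helices swallowed by the hit are dropped and the survivors
  regrouped on either side.
* Neighbor joining clamps negative intermediate branch lengths to zero and
  resolves ties deterministically; rooting places the root at the midpoint
  of the outgroup's pendant edge.
* A character absent from every tip is reported as `root_present=False`,
  zero losses, flag NEVER_OBSERVED: absence alone is not evidence the gene
  ever existed. The root-edge-loss convention (one loss for an all-absent
  clade) applies only when the caller asserts ancestral presence — the
  situation of piroplasmids, whose loss is inferred from their relatives.
* The candidate topologies encode only the published monophyly constraints
  (see the fixture names); branching order beyond those constraints is a
  documented free choice, and the single-αβ-loss result is invariant to
  the placement of Nephromycida within the non-gregarine/marosporid clade
  (tested).
* Within-group copy number (e.g. tandem duplicates in *Porospora*, two
  group-I genes in *Cryptosporidium*) is kept at the gene-record level
  only; the matrix characters are presence/absence.

## What the generators emulate — and what they do not

`make_isoform_sequence` plants loops drawn from {E,D,K,R,S,T,N,Q,G,P},
helix blocks of 21 residues from {L,I,V,F}, 25-residue loops, and the
motif-library consensus segments, in template order; a 120-residue spacer
separates consecutive stretches that have no domain between them, so
stretch splitting is exercised through both mechanisms (gap length and
domain hits). Point mutations are applied uniformly per residue. This
emulates the *architecture* of real NTH chains, not their statistics: real
helices have mixed composition and marginal hydropathy, real loops contain
hydrophobic residues, real domains are hundreds of residues with
position-specific conservation, and real evolution is not uniform
substitution. Passing tests therefore demonstrate that the scanning,
assembly, parity and classification logic is correct on sequences whose
ground truth is known exactly — they do not calibrate the scanner's
sensitivity on genuine proteomes, for which external TM/domain predictions
should be supplied through the annotation-table interface.

`simulate_complement_evolution` samples, per character, loss on each edge
whose parent still carries the character (once lost, stays lost). Truth
records both the sampled loss edges and the *identifiable* losses — the
maximal subtrees left without any surviving tip. The two differ when every
child of a node loses independently: tip data cannot distinguish that from
a single earlier loss, so recovery is asserted against the identifiable
set. Inference on the generating tree recovers the identifiable loss edges
exactly in every replicate with at least one surviving tip (tested over
500 replicates at loss probability 0.1 on an 8-leaf tree), and the
generating topology ranks first among candidate topologies in the
majority of loss-pattern-informative replicates.

`make_paralog_families` founds groups I and II by mutating one ancestor
independently at divergence 0.3, then spawns members at noise 0.1 —
mean-distance assignment recovers ≥ 90 % of query labels at these
defaults. The packaged `synthetic_group_refs.fasta` is generated by this
function (fixed seed) and is synthetic: it stands in for real group I/II
reference sequences, which users should substitute when available.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: template proteins of ~700–770 residues, exhaustive Dollo
verification on 1,000 random trees with ≤ 12 edges, neighbor-joining
exactness on 200 random trees with ≤ 10 leaves, and 500 simulated
complement-evolution replicates on an 8-leaf tree. These sizes were chosen
to give exhaustive or near-exhaustive coverage of the combinatorial cores
while keeping a full run in well under a minute.

## Known limitations

* No profile-HMM or neural-network topology prediction; no E-values; no
  inside/outside membrane orientation (sidedness is handled relationally
  by the parity rule).
* No multiple sequence alignment, maximum-likelihood or Bayesian tree
  inference, and no bootstrap supports; neighbor joining is a
  deterministic stand-in.
* No probabilistic gain/loss rate models and no horizontal-transfer
  inference; characters are assumed independent.
* The motif library defines domains I/III functionally for synthetic and
  annotation-supplied data; it is not a curated domain database.
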