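# Methods

This note documents the statistical procedures implemented in `rnacov`,
the choices made where the underlying definitions leave room, and what
the synthetic benchmark does and does not demonstrate.

## Event counting on a non-binary tree

Taxonomy trees are heavily multifurcating, so classic Fitch parsimony
(set intersection/union on binary trees) is replaced by a majority rule:
the ancestral pair state of an internal node is the pair type occurring
most frequently among the informative leaves of its subtree (the
"equality set"). Informative means an unambiguous nucleotide, not a gap,
at both columns; gapped or ambiguous leaves are excluded from both the
majority vote and event counting, because substitutions are defined on
nucleotides and no gap-event semantics exist. Ties in the majority vote
are broken lexicographically on the ordered pair string (A < C < G < U),
a deterministic rule chosen because no tie rule is inherent to the
method; ties are rare on real data and the choice only matters for
exactly balanced subtrees.

Events are evaluated parent → child at every internal node, using
assigned states for internal children and observed states for leaf
children. The de-duplication rule is per node and per distinct pair
type: if an ancestor assigned U:A has children carrying A:U twelve times,
A:U contributes one positive event at that node. A child pair type
differing from the parent in both positions is positive even when the
exchange is not canonical (e.g. U:A → A:C): the definition is "both
positions changed", not "changed into a Watson–Crick partner". Unary
chains (which NCBI taxdump import collapses) cannot generate events,
since a node's majority equals its single child's majority.

CPE is positive/(positive+negative). Pairs with no events have no CPE;
pairs under the total-event floor (default 10) are retained in the event
table but flagged and excluded from the CPE score matrix, which reduces
background noise in the downstream ranking at no cost to strongly
covarying pairs.

## Frequency statistics

All entropies and information quantities are in bits (base-2 logs). The
base only rescales scores, and every calling decision downstream is made
on ratios except the entropy-difference filter, which is therefore
defined on base-2 values.

The per-column conservation score is Shannon entropy over the five
states A, C, G, U and gap; the gap frequency is a genuine term (a column
half-deleted is informative), while IUPAC ambiguity codes are excluded
from numerator and denominator alike. The convention is low = conserved;
`ColumnProfile.inverted_conservation()` returns 2 − H for users who
expect the opposite.

For the pair statistics (MIxy, OMES, pair-type tables, purity,
canonical fractions) a sequence contributes only when it has an
unambiguous nucleotide at *both* columns — base-pair covariation is a
statement about nucleotides. Ambiguity codes never count as matches or
mismatches; they shrink the effective sample. A consequence worth
noting: the textbook bound MI ≤ min(H_x, H_y) holds against the
entropies of the pair table's marginals, not against the gap-inclusive
conservation entropies, because the two are computed on different
supports.

MIp subtracts the average-product correction
`APC(a,b) = mean_MI(a,·) · mean_MI(·,b) / overall_mean_MI`, with all
means taken over the candidate pairs actually scored (the post-filter
set), matching the pipeline's data flow; a full-matrix run simply makes
that set all pairs. A uniform MI matrix yields exactly zero MIp
everywhere; Z-standardization of a constant matrix is undefined and
raises. The MIp/Z calling cutoff is exposed in the configuration
(default 4.0) but the shipped pipeline calls MIp through Joint N-Best,
which needs no distributional cutoff.

OMES sums (observed − expected)²/N over all 16 dinucleotide cells,
observed or not; expected counts are products of marginal counts over
the effective sample size.

## Candidate filtering and calling

The coarse filter keeps a pair when (1) the two columns' conservation
entropies differ by at most 0.2 bits and (2) its MIxy ranks within the
top 100 partners of *both* columns, with ranks computed over the
entropy-compatible pairs. This reduces the quadratic pair enumeration
(5,234,230 pairs for a 3236-column alignment) by orders of magnitude
before any tree traversal; truly covarying columns have near-identical
variation patterns and therefore near-identical entropies, which is what
makes the filter safe.

Joint N-Best calls a pair when the columns are reciprocal best partners
and both second-best/best ratios are ≤ 0.5. The reciprocity requirement
is part of the method's logic (the best partner of X is Y and vice
versa); ties for best partner break toward the lower column index and
are logged. A column with a single scored partner gets ratio 0 —
maximally unambiguous, since no competitor exists — and is flagged so
users can exclude such degenerate calls. Columns whose best score is not
positive are not callable. Lowering the threshold can only remove calls
(monotonicity), and each column appears in at most one passed pair.

Call sets from different statistics are merged as a set union with
provenance tags (PEC-only / MI-only / both); the MI call set is itself
the union of the MIxy and MIp calls.

## Helix extension, purity, neighbor effects

Helix extension explores both outward (i−1, j+1) and inward (i+1, j−1)
steps from every nucleation pair, accepting a step while the canonical
fraction — sequences forming G:C, C:G, A:U, U:A, G:U or U:G over
sequences ungapped and unambiguous at both columns — is at least 0.85,
and stopping at the first failure or the alignment edge. Restricting the
denominator to ungapped sequences is a choice (the 85% rule does not
specify gap handling) and is configurable. When two extensions claim the
same column with different partners, the higher canonical fraction wins
and the conflict is logged.

The purity walk ranks pair types by frequency (ties lexicographic),
always accepts the top type, and accepts a further type only if both its
5′ and 3′ nucleotides are unused among accepted types — i.e. it covaries
with every accepted type. Purity is the summed frequency of accepted
types. In the GU-plus variant, G:U/U:G neither blocks nor is blocked by
the four Watson–Crick canonical types, crediting wobble pairs that occur
inside regular helices; GU-plus purity is never lower than plain purity
(each exemption can displace at most one later, lower-frequency type).

Neighbor effects are CPE-scored pairs not already called as base pairs
with (1) one-directional N-Best ratio ≥ 0.85, (2) CPE ≥ 0.25 and
(3) ≥ 10 total events. The ratio definition is one-directional
(per column); this implementation requires both columns' ratios to meet
the threshold and reports the smaller of the two, the stricter of the
two possible readings — the alternative (either column suffices) admits
more, weaker candidates. With a reference structure each effect is
annotated with the hydrogen-bond class of the position pair and, when
coordinates exist, the Euclidean distance between base centers. A base
center is the centroid of the Watson–Crick-edge atoms (A: N1, C2, N6;
G: N1, N2, O6; C: N3, O2, N4; U: N3, O2, O4), an explicit convention
exposed in the reader since "the atoms that form the hydrogen bonds" is
not a unique atom list.

Evaluation against a reference structure labels each ranked call TP
(annotated secondary or tertiary pair at the mapped reference positions)
or FP, reports calls on reference-gapped columns as unmappable, and
emits the precision-of-top-N curve.

## Synthetic benchmark

The generator evolves sequences root → leaves on a rooted multifurcating
tree (star and balanced shapes are also available). Substitutions are
per-edge Bernoulli events rather than a continuous-time model: the
event-counting statistic is discrete, and a discrete generator makes the
emitted substitution history an exact ground truth. Root states are
drawn uniformly per column or pair; planted pairs jump between the four
canonical Watson–Crick types (optionally visiting G:U), unpaired columns
substitute independently, conserved columns never change, gap columns
are all-gap.

Default conditions: 200 leaves, 120 columns, 8 standalone compensatory
pairs plus 4 helix blocks of 3 stacked pairs in which only the middle
pair varies — 12 varying pairs and 8 invariant flanks, 20 truth pairs in
all — per-edge substitution probability 0.08 for both compensatory and
unpaired columns, 10% conserved and 5% gap columns. The rate is chosen
so that a varying pair accumulates roughly 15–25 phylogenetic events on
a 200-leaf tree — comfortably above the 10-event floor, comparable to a
moderately variable rRNA column pair — and the dataset stays small
enough that the full pipeline runs in seconds.

What passing on this benchmark shows: the engine recovers planted
compensatory signal essentially perfectly (precision/recall ≈ 1 at the
default operating point) and helix extension recovers invariant flanks.
What it does not show: robustness to alignment error, indel evolution,
rate heterogeneity across lineages, non-canonical pair exchanges, or
taxonomy trees that disagree with the true gene tree — all present in
real rRNA data and none modeled by the generator. Occasionally an
extension continues one step past a planted block into adjacent
near-constant columns that happen to be canonical in ≥ 85% of sequences;
this mirrors the behaviour expected on real data, where extension errors
concentrate at helix ends, and is counted against the method in the
reported numbers rather than patched in the generator.

## Numerical and degenerate-input conventions

Zero-probability terms contribute nothing to entropies and MI; MI is
clamped at 0 against −1e-12-scale float noise. Pairs with fewer than two
jointly informative sequences are skipped with a logged reason rather
than scored. Empty pair tables make purity undefined (error). Missing
coordinates yield null distances with a warning, never a crash. All
user-facing coordinates are 1-based; TSV outputs are sorted
deterministically so identical inputs produce bitwise-identical outputs.
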