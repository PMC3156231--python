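# Methods

## Sequence model and validation

The unit of analysis is a protein chain over the 20 canonical residues.
Non-canonical characters (X, B, Z, U, `*`, gaps) are removed — not remapped —
before featurization, because every descriptor below is defined only over the
native residue types and removal keeps the composition denominators well
defined.  A cleaned sequence must have at least 21 residues: the Fourier
block retains 10 non-constant frequency components of an L-point transform,
which requires `L ≥ 2·10 + 1` for the retained terms to sit below the
conjugate-symmetry fold-over of a real signal.  How ambiguous residues should
be treated is a package policy, not something the underlying method defines;
removal is the most conservative choice for frequency-based descriptors.

## Descriptors

**Amino acid composition (AAC).** 20 normalized frequencies, alphabetical
residue order everywhere in the package.

**Gapped dipeptide composition DC(g).** For gap `g`, the 400 ordered-pair
frequencies of residues `g+1` positions apart, with denominator `L − 1 − g`
(the number of g-gapped pairs) so each 400-vector sums to exactly 1.  The
default pipeline uses g = 0 and g = 1 only: coupling between nearby residues
carries more signal than distant pairs, and every additional gap adds 400
dimensions to an already long vector.

**Complexity factor (CF).** The Lempel–Ziv complexity: the number of
components in the sequence's exhaustive synthesis history, where each step
either inserts a new symbol or copies the longest fragment reproducible from
the already-synthesized prefix (component Q is reproducible while it occurs
as a substring of prefix+Q minus its last character).  The factor is the raw
integer count, not length-normalized.  A homopolymer of length ≥ 2 always has
complexity 2 (one insertion, one copy).

**Fourier spectrum components (FSC).** Each sequence is converted to three
digit signals by mapping residues to hydrophobicity, hydrophilicity and
side-chain-mass values.  The shipped table
(`src/nrpred/data/property_scales.tsv`) carries the standard pseudo-amino-
acid-composition value set; any table with the same three named columns can
be substituted via configuration.  The three scales have incommensurable
units (hydrophobicity ~1, side-chain mass ~100 Da), so each is standardized
to zero mean and unit population standard deviation over the 20 residues
before signal construction.  The DFT `X(k) = Σ x(n)·exp(−2πikn/L)` is then
evaluated at k = 1..10 and each term contributes its amplitude `|X(k)|` and
phase `arg X(k)`.  The k = 0 term is excluded: for a real signal its phase is
identically zero and its amplitude only duplicates composition information.
Phases are reported as 0 whenever the amplitude is below 1e-12, since the
argument of a near-zero complex number is numerical noise.

## Fusion weights

The 881 components are concatenated as AAC (20, unweighted), DC(0) and DC(1)
(400 each, × `w_dc`), CF (1, × `w_cf`), FSC (60, × `w_fsc`).  Defaults:
`w_dc = 20`, `w_cf = 0.001`, `w_fsc = 0.01`.

The dipeptide weight of 20 puts one DC component (mean magnitude
20 × 1/400 = 0.05) on the same per-component scale as one AAC component
(mean 1/20 = 0.05) while letting the 800 DC dimensions dominate the
Euclidean metric in aggregate — the dipeptide blocks are the main carriers
of subfamily signal.  The CF and FSC weights follow the same per-component
scale argument: the raw complexity grows like `L / log20 L` (≈ 10²
for typical chains) and the amplitude of a standardized random signal like
`√L` (≈ 10¹), so unit weights would make the metric >99.9% CF+FSC and
reduce the classifier to a length detector.  The defaults bring both blocks
to the composition scale; they are deliberate package-level calibrations of
a design quantity the feature construction leaves open, set once from this
scale analysis, and overridable via `--weights-cf` / `--weights-fsc` or the
config file.

Fusion is a weighted concatenation, not a sum-normalized form: phase
components are signed, so normalizing by the vector sum would be ill-defined.

## Fuzzy K-nearest-neighbor rule

Memberships follow the inverse-distance-power form with exponent
`2/(m−1)` over the K nearest Euclidean neighbors, crisp reference
memberships, and the argmax decision.  Numerical and degenerate-case
choices:

* distances are normalized per query by the smallest positive neighbor
  distance before exponentiation — the membership ratio is invariant under
  this scaling, and it keeps the computation finite for `m` close to 1
  (where the exponent explodes and the rule degenerates to 1-NN, the
  correct limit);
* a neighbor distance below 1e-12 means the query coincides with reference
  points; membership is then a uniform vote over the coincident neighbors
  only, preserving the crisp limit instead of dividing by zero;
* distance ties at the K-boundary are broken by reference insertion order,
  and argmax ties toward the class of the single nearest neighbor, then by
  class order — both purely for determinism;
* no feature rescaling happens inside the classifier; all scaling lives in
  the fusion weights.

Defaults `K = 3`, `m = 2.0`: K stays below the smallest real subfamily size
(five sequences) so that even its members can find same-class neighbors
during leave-one-out evaluation, and `m = 2` is the standard fuzzy-KNN
setting.  The grid search (below) is the principled way to set both.

## Cascade and evaluation protocol

Level 1 classifies NR vs NONNR over the full labeled collection; level 2
holds exactly the NR-labeled sequences with subfamily tags.  A query
predicted NONNR stops at level 1.

The jackknife (leave-one-out) test is the evaluation standard: each sample
is predicted with itself removed from every reference set it occurs in, so
the result is unique for a given dataset — no sampling arbitrariness.  The
per-class MCC at the 7-class level is computed one-vs-rest from each class's
confusion quadrants (TP/FP/TN/FN); a confusion table with a zero marginal
gets MCC 0 by convention and is flagged in the report.  Classes with no
evaluated samples are reported as not applicable rather than zero.  No
class-imbalance correction is applied at level 1.

`grid_search` evaluates the jackknife at every point of K ∈ {1..15},
m ∈ {1.1, 1.2, …, 3.0} (both configurable) and returns the full surface;
ties resolve to the smallest K, then the smallest m.  The feature-ablation
table re-optimizes (K, m) per descriptor subset, since a fixed setting tuned
for the full 881-D metric has no reason to be optimal for a 20-D one.

The independent-test path refuses any overlap between test and training
data, by identifier or by exact sequence match.

## The synthetic family generator

`nrpred.simulate` emulates the study conditions of a seven-subfamily
receptor problem with a diverse negative background: by default 8 classes ×
20 sequences of length 80–120 — seven classes each defined by a distinct
planted motif of 40 residues, plus a motif-free NONNR background — with
per-residue substitution noise at rate 0.01 (substitutions always change the
residue, so the nominal rate is the realized rate).  All randomness flows
from one seed; a spec reproduces byte-identical FASTA output.

Motif residues are drawn from a single shared, compositionally biased
profile (a Dirichlet draw with concentration 0.3 over the 20 residues)
rather than uniformly.  This mirrors real conserved superfamily domains,
whose residue usage is atypical — receptor DNA-binding domains, for
instance, are cysteine/arginine-rich zinc fingers — and it is what makes
the level-1 problem learnable at all: if motifs were drawn from the same
uniform distribution as the background, a motif-free query would be
equidistant in expectation from every reference (the mean displacement of a
motif class and its variance reduction cancel exactly), and the
receptor/background decision would collapse to the class prior.  The bias
displaces every receptor-like family off the center of the background cloud.

What the generator does **not** emulate: real length distributions (hundreds
of residues, family-dependent), phylogenetic correlation between subfamilies
(real subfamilies share the superfamily domain and are mutually similar;
synthetic motifs are independent draws), compositional drift along real
chains, and a negative set drawn from real, internally structured protein
families.  Passing the synthetic checks therefore demonstrates that the
pipeline is implemented correctly and separates separable families — not
that the published benchmark accuracies transfer to arbitrary real data.

Evaluation sizes used throughout the tests and the acceptance script —
160-sequence collections, 140-sequence subfamily references, five noise
levels, three seeds, 100 label shuffles — were chosen as the smallest sizes
at which the measured quantities are stable to well under the tolerances
being asserted.

## Known limitations

* The published learning and independent sets are not redistributable with
  the package; benchmark-dependent checks require the user to supply
  `data/benchmark_s1.fasta` (see README).
* The CF and FSC fusion weights are package calibrations (scale-matching
  argument above), so descriptor-subset accuracies involving those blocks
  depend on them; the DC weight of 20 is fixed by the feature design.
* Lempel–Ziv complexity is computed by direct substring search, quadratic in
  sequence length in the worst case — irrelevant at protein scale (≤ a few
  thousand residues) but not suited to genome-length strings.
* The fuzzy K-NN reference sets are held dense in memory; the intended
  regime is the benchmark scale (≲ 1,000 sequences), and no approximate
  nearest-neighbor indexing is provided.
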