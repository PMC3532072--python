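# Methods

## Scope and model

`micontact` scores covariation between the columns of a paired-domain
MSA — an alignment of homologues of a two-domain protein in which one
row is the sequence of a reference structure and each structural domain
owns a disjoint set of alignment columns.  Correlated mutations between
the domains are the signal: if two residues are in contact across the
interface, a change in one tends to be compensated by a change in the
other.  All scores are estimated by plug-in (empirical frequency)
probabilities with natural logarithms and no pseudocounts or sequence
weighting; the scores therefore depend on the MSA alone.

## Filtering and standardisation

A column is *eligible* iff it belongs to a domain, has no gap in any
row, and has entropy > 0.  Gapped columns are excluded because gap
symbols are not residues and empirically degrade MI-based prediction;
zero-entropy columns are excluded because a conserved column yields MI
exactly 0 with any partner and carries no covariation evidence.  Raw
scores exactly equal to 0 (a threshold of 1e-12 absorbs floating-point
noise, and tiny negative values are clamped to 0 first) are removed
*before* any mean is taken: the zero-MI pairs would otherwise bias the
APC/CPS normalisers and the standardisation moments.  Each surviving
table — and the per-column entropy profile — is z-scored over its own
entries using the sample (n−1) standard deviation, making scores
comparable across alignments of different size and diversity.

## The variants and their normalisers

* **MIp.**  `APC(J;K) = M̄I(J)·M̄I(K)/M̄I`, all means over the surviving
  inter-domain pairs (the per-column mean averages over the column's
  partners in the opposite domain).  Only inter-domain pairs are
  computed, so this is the natural domain adaptation of the original
  whole-protein mean.
* **MIc.**  `CPS(J;K)` averages `MI(J;L)·MI(K;L)` over third columns
  *L*.  For an inter-domain pair, no choice of *L* makes both factors
  inter-domain, so by default (`cps_l_scope="all"`) *L* ranges over
  *all* eligible columns of both domains and the full intra- + inter-
  domain MI matrix is computed for CPS purposes, with `n` = total
  eligible columns in the 1/(n−2) average.  The domain adaptation is
  applied to the normaliser instead: the mean CPS under the square root
  runs over the surviving inter-domain pairs only.  The alternative
  `"opposite_only"` scope (L restricted to the partner domain of J)
  is exposed as a configuration switch.  Zero-MI values contribute 0 to
  CPS sums; the denominator is not adjusted.
* **MI3D / MIp3D.**  The triple score is the total correlation
  `H(J)+H(K)+H(L)−H(J;K;L)` of a domain-1 column and a same-patch
  domain-2 column pair (reference residues strictly < 4.5 Å apart;
  both directions, a domain-2 column against a domain-1 patch, are
  enumerated when distances are supplied).  `APC3D` is the printed
  product-of-means form `m(J)·m(K)·m(L)/m`; per-column means run over
  the surviving triples containing the column — in the first slot for
  the single-domain column, in either patch slot for the other two,
  since the patch pair is unordered.  Note the units asymmetry: when
  all means coincide at *c*, APC3D = *c*², a squared score.  The form
  is implemented exactly as defined; consequences are discussed under
  Limitations.
* **Reduced alphabet.**  The 7-category physiochemical map (Small
  S,G,A,P; Hydrophobic V,M,I,L,C; Negative D,E; Aromatic F,Y,W; Polar
  Q,T,N; favoured positive R,H; disfavoured positive K — lysine is
  split out because it is rare at interfaces) is applied to the MSA
  before scoring; RA variants are definitionally the full-alphabet
  scores of the merged-symbol alignment.  Merging can only lower a
  column's entropy, so reduction can add zero-entropy exclusions.

## Residue annotation

Surface/buried labels come from a per-residue relative accessibility
table (isolated-domain and in-complex values, e.g. JOY- or DSSP-
derived); computing solvent accessibility is deliberately out of scope.
A residue is surface iff isolated accessibility > 7 % (strict).  It is
a contact iff additionally its minimum inter-atomic distance to the
partner domain is < 4.5 Å (strict; all atoms present in the coordinate
file are used, hydrogens included) and its accessibility differs
between the isolated and complexed states by more than 0.5 percentage
points — the tolerance is a package choice, configurable, since "is
different" needs a numeric reading.  Alternate conformations are
resolved per atom name by highest occupancy, then first.  Labels attach
to whole MSA columns through the reference row.

## Evaluation

Each residue receives the maximum (default; mean available) surviving
standardised score of its column over partners in the other domain —
the maximum, because a single strong covariation partner is the
contact signature, and averaging dilutes it.  Precision–recall curves
use the 1st–100th percentiles of the observed scores as cutoffs
(prediction rule: score ≥ cutoff) plus an explicit all-inclusive
cutoff at the minimum score, so the curve always ends at recall 1 and
precision = prevalence.  Precision "at 20 % recall" uses the
conservative step convention — the precision at the highest cutoff
whose recall still reaches the target, with no interpolation.  MCC is
computed on the same grid, defined as 0 when a confusion-matrix margin
vanishes.  Subsampling stability draws `n_reps` random 70 %
sub-alignments (the reference row is always retained so annotations
stay mappable; the subsample has exactly ⌊0.7·n⌋ rows including it),
rebuilds the mask and table each time, and reports the mean, sample sd
and standard error of the precision at target recall; a ≥ 200-sequence
gate (disable-able) keeps subsamples above the 125-sequence minimum
commonly recommended for stable MI estimation.  The binomial top-k
test compares the contact count among the k best-scored candidates to
Binomial(k, positives/candidates) via the upper tail P(X ≥ hits); ties
at the k-th score either expand the selection (default, warning) or
truncate deterministically by column index.

## Synthetic data

The generator plants exactly the features the scores respond to:
iid uniform background columns over an m-letter alphabet (default
m = 20); covarying pairs/triples as bijection mixtures (with
probability = coupling the partner symbol is a fixed random bijection
of the first; otherwise independent); fully conserved and gapped
columns; and annotations realised as one-atom-per-residue coordinates
that satisfy the planted constraints exactly (contact pairs 4.0 Å
apart in private pockets, everything else ≥ 4.5 Å across domains,
patch pairs co-located 4.0 Å apart).  Surface accessibility is planted
at 30 % (surface) vs 2 % (buried), dropping to 18 % in complex for
contacts.  An optional phylogenetic-noise mode assigns rows to two
clades with distinct ancestral sequences and iid per-site resampling;
the shared clade identity correlates otherwise-independent columns,
producing the background that APC/CPS corrections are designed to
suppress.  (A single shared ancestor was considered and rejected: with
one star centre, columns remain independent across rows and no
background correlation arises.)  Everything is deterministic given the
spec seed.

What the generator does **not** emulate: realistic phylogenies and
substitution processes, alignment errors, column-dependent gap
patterns, or the entropy gradients of real surfaces.  Passing the
recovery tests therefore shows the estimators detect the covariation
signal they are defined to measure under clean conditions — not that
they reach any particular precision on real protein families.

## Problem sizes and numerical choices

The test battery uses alignments of 30 + 30 columns and 200–500
sequences (100 seeds for recovery rates; 20 sweep points for the
zero-entropy diagnostic), sizes at which plug-in pairwise estimates are
well conditioned and the full suite runs in well under a minute per
criterion.  Oracle-equivalence checks run exhaustive pure-python
brute-force evaluations on ≤ 6-sequence, ≤ 5-column alignments at
1e-12.  Pairwise scores use integer-coded columns and bincount joint
tallies; CPS matrices come from a single matrix product.  Degenerate
inputs raise named errors rather than returning NaN: empty columns,
single-class evaluation labels, all-equal score tables (sd = 0), zero
normaliser means, domains with no eligible columns.

## Known limitations

* The plug-in estimator is biased upward by ≈ (k₁−1)(k₂−1)/(2n) nats
  for independent columns; with the full 20-letter alphabet and
  hundreds of sequences this background is substantial, which is
  exactly why the APC/CPS-corrected variants and per-table z-scoring
  matter in practice.
* Triple scores square the problem: with 20³ joint states the total
  correlation of independent columns saturates toward log n, and the
  product-of-means APC3D grows quadratically in the score scale, so
  MIp3D can over-penalise the strongest triples.  The recovery tests
  for the 3D variants accordingly use a reduced state space (6-letter
  alphabet) and moderate couplings, where the estimator is adequately
  sampled; the same trade-off is visible in the full-alphabet variants'
  weaker published performance.
* `subsample` keeps exactly ⌊fraction·n⌋ rows while retaining the
  reference unconditionally (reference + (⌊fraction·n⌋−1) random
  others), a compromise between an exact subsample size and mappable
  annotations.
* Whether the reference sequence should be removed before scoring is
  an open modelling question; it is kept, and its weight is one row
  among hundreds.
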