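# Methods

## DNA states and the rule engine

The library chemistry behind an rAAV HiFi run leaves a signature in
each read's alignment: a molecule made by annealing two genome strands
(duplex) aligns end to end; a molecule made by the genome's own 3' ITR
priming second-strand synthesis (fill-up) is a palindrome whose two
halves map as primary + one supplementary alignment on opposite
strands, folded inside an ITR; a snapback has the same geometry folded
elsewhere; a multimeric artifact shatters into many supplementary
alignments.  The classifier encodes this as threshold rules on three
features per primary record: soft-clip fraction, SA-tag entry count,
and the fold-point location.

Decisions baked into the implementation:

* **Clip fraction** is (left + right clipped bases of the primary
  record) / full query length.  Hard clips count like soft clips, and
  the denominator is the full query length including clips; insertions
  and deletions do not enter the denominator.
* **Supplementary count** comes from the primary record's SA tag,
  de-duplicated by (reference, position, strand) — robust against BAMs
  whose supplementary records were filtered or duplicated.  Secondary
  alignments are ignored throughout.
* **Interval endpoints**: duplex strictly below 0.10; the fold band is
  the closed interval [0.40, 0.60] with *exactly* one supplementary
  alignment; multimer is at least 0.75 clipping with at least four
  supplementary alignments.  Rules are evaluated duplex → multimer →
  fill-up/snapback; at the default thresholds the regions are disjoint
  (verified by a grid test) so the order is inert, but it pins the
  behaviour of custom, overlapping configurations.
* Reads in the gaps of the rules (clip 0.10–0.40 or 0.60–0.75, or a
  fold-band read with 2–3 supplementary alignments) are labelled
  `other` rather than force-assigned to the nearest state.

### Fold-point (symmetry-axis) detection

A perfect fold-back read is its own reverse complement; the fold sits
at the query midpoint.  For the primary and each same-reference
supplementary alignment we project the query end *facing* the midpoint
onto the reference (forward-strand segment in the first half of the
query → its reference end; and so on for the other three cases).  If
any such inner-end coordinate falls within an annotated ITR interval
expanded by ±`itr_axis_tol`, the axis is "in an ITR".  The tolerance
defaults to 100 nt — the scale of an ITR (~145 nt) and of alignment
fuzziness at palindromic fold points, where the aligner's split
position within the self-complementary ITR is not reproducible at
base resolution.  How close a fold must be to count is genuinely
underdetermined; the value is configurable and its effect is confined
to the fill-up/snapback boundary.

### Full-length rule

A read is full-length iff the union span of its primary and
same-reference supplementary alignments starts within 50 bp of the
annotated genome start, ends within 50 bp of the annotated stop, and
the read length lies in 2L ± 150 bp.  The group span (not the primary
span alone) matters because a fill-up's two halves individually cover
only half the genome.  The denominator of the full-length percentage
is all reads whose primary maps to the vector reference.  Note the
deliberate consequence: an L-length duplex covering the whole genome
is *not* full-length under this metric, because only molecules doubled
by second-strand synthesis can satisfy the 2L window.  Pure-duplex
populations therefore report 0 % full-length; this tension between
"covers the genome" and "full-length by the metric" is inherent to the
definition and documented rather than patched.

## Contaminant base fractions

Aligned bases (CIGAR M/=/X on the query) of each primary record are
attributed to the category of its reference (vector, human, ecoli,
repcaphelper, other — assigned by a name→category map, not inferred
from sequence).  Fractions are percentages of total aligned bases and
sum to 100 by construction.

## Yield and quantitation models

* **Expected ssDNA mass**: m = n_vg / 6.022e23 × (L × 307.97 + 18.02)
  grams, with 307.97 g/mol per nucleotide and one 18.02 g/mol water
  term per molecule.  The formula is implemented exactly as published;
  the per-molecule (rather than per-bond) water term makes the result
  an upper-bound-style approximation whose error is < 0.002 % at
  genome scale.
* **Yield ratio**: (measured ng/µl × volume µl, converted to grams) /
  expected mass.  Dimensionless; 1.0 means the extraction recovered
  exactly the titer-implied amount.
* **dsDNA interference**: the ssDNA assay dye binds dsDNA too.  With
  spiking rows (ds_i, ss_i) and replicate-mean readouts y_i, the model
  y = ss + f·ds is fitted by origin-constrained least squares on the
  residuals r_i = y_i − ss_i:  f = Σ ds_i r_i / Σ ds_i².  Replicates
  are averaged first, matching how such tables are reported.  The fit
  method itself is a design choice (no method is stated alongside the
  published factor): origin-constrained OLS uses all rows, is
  closed-form, and treats ssDNA as contributing 1:1.  A per-row-ratio
  estimator (`method="ratio"`) and a two-coefficient fit releasing the
  ssDNA slope (`fit_ss_coef=True`) are exposed for sensitivity checks
  — the ss-only row of the packaged table reads 21.5 for 20 ng/µl
  input, i.e. a 1.075× slope, but the default keeps it pinned at 1.
  On the packaged table f = 4.46, i.e. 4.5 at one decimal.
* **Correction**: true ssDNA ≈ measured − f × ds_estimate, floored at
  0 with a warning (a negative value flags an overestimated dsDNA
  content or factor).

## Mass-photometry boundary transfer

Fraction boundaries measured in kDa transfer to the sequencing axis as
nt = (mass − mass_empty) / 0.33 kDa·nt⁻¹, then ×2 because double-strand
synthesis doubled every molecule before library preparation.  Data in
the empty fraction are excluded on both axes (empty capsids cannot be
sequenced) and the partial/full populations are renormalised to sum to
100 %.

## G4 scanning

The scanner enumerates every decomposition of a window into four equal
G-runs (≥ `min_g_group`, default 2) and three loops within
[`loop_min`, `loop_max`] (default 0–36) of total length ≤ `max_length`
(default 30).  A run of many Gs legitimately spawns all eligible
sub-run decompositions; that is what makes "including overlaps" counts
orders of magnitude larger than non-overlapping ones.  The default
parameter set is internally redundant: with a 30-nt cap a loop can
never reach 36 nt, so the length cap dominates.

The G-score orders candidates by stability plausibility.  Its exact
value is an implementation-defined lexicographic encoding —
score = 10⁶·g − 10³·(l1+l2+l3) − (max loop − min loop) — guaranteeing
that more tetrads always outrank fewer, then shorter total loops, then
more equal loops.  Only these orderings are meaningful; absolute
scores are not comparable to any external tool's scale.  The
non-overlapping subset is chosen greedily by descending score (ties:
leftmost, then shortest), which a constructed-chain test distinguishes
from interval-scheduling alternatives.  Scanning is single-strand by
design: G4 formation is strand-specific, and the caller decides
whether to also scan the reverse complement.

## Synthetic data

The generator emulates the *structure* of an aligned rAAV HiFi run,
not its noise: a toy genome (GC-rich random palindromic ITRs of 145 nt
flanking a random payload; the real AAV2 ITR sequence is not modelled),
reads of each state with exact alignment geometry emitted directly as
SAM (no aligner in the loop), 5'-truncation mixtures, contaminant
reads on synthetic references, spiking tables under measured =
ss + f·ds + N(0, σ), and mass-photometry populations under
mass = mass_empty + 0.33·length + noise.  Defaults: genome length
3342 nt; state mix 25/40/20/15 % duplex/fill-up/snapback/multimer
(all states well represented, fill-ups dominant as in a well-behaved
second-strand synthesis); 20 % of fragments 5'-truncated by 50–800 nt;
10 % contaminant reads (5 % human, 3 % E. coli, 2 % RepCapHelper);
fold-point jitter 0 by default, with ±20 nt as the documented
imperfect-symmetry setting.  Snapback fold points are placed at least
(axis tolerance + jitter + 10) nt away from any ITR so the planted
labels are unambiguous by construction.

What passing tests therefore show: the feature derivation, rule
engine, full-length caller and summaries are exact inverses of the
generator's geometry, and the fitted models recover planted
parameters.  What they cannot show: behaviour under base-calling
error, aligner-specific clipping ambiguity in real palindromic reads,
chimeric adapter artifacts, or biological ITR secondary structure —
validation against real aligned runs remains the user's
responsibility.

## Problem sizes and numerics

The classification round-trip is exercised at 10,000 reads, parameter
recovery at 1,000 replicate spiking tables (σ = 1.0 ng/µl), the scanner
oracle at 200 random sequences up to 60 nt, and the boundary grids
exhaustively; each suite completes in seconds.  All randomness flows
from a single integer seed through `numpy.random.default_rng`; CSV and
JSON outputs are byte-reproducible under a fixed seed.  Percentages use
exact integer counts; contaminant fractions sum to 100 within 1e-9.

## Known limitations

* Fill-up vs snapback separation inherits the axis tolerance; folds
  within ~100 nt of an ITR boundary are intrinsically ambiguous.
* Multimers are not sub-classified (chimera vs rolling-hairpin product
  are indistinguishable in this feature space).
* The published full-length percentages and G4 counts of real vector
  lots are not reproduced here: they require the deposited sequencing
  data and the unprinted plasmid sequences.  The property-based suites
  stand in for them.
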