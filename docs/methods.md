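# Methods

## Model and assumptions

`segext` reconstructs inserted donor sequence by *segment extension*:
reference-derived flanks on either side of an insertion locus are grown one
consensus column at a time, using paired-end geometry to decide which reads
may cover the next unknown position. The method assumes:

- fixed read length `l` (default 36 bp), substitution-dominated errors
  (alignment `⊕` and the read search are ungapped; indel sequencing errors
  are not modelled);
- fragment (outer insert) lengths Normal(µ, σ) with hard bounds
  Δmin = µ − 3σ and Δmax = µ + 3σ — pairs outside the bounds are treated as
  discordant evidence, and the simulator re-draws fragments outside them so
  simulated data satisfy the interval assumption exactly;
- insertion loci are given (BED input). OEA clustering
  (`segext.cluster_oea`) is provided as a locus-candidate helper, but locus
  discovery by external SV callers is out of scope;
- each insertion has clean reference flanks of at least 2l + Δmax
  determined bases — the extension base case.

## Pair classification and the insertion read set

Concordance quantifies existentially over the cross-product of the two
mates' location sets (a single concordant placement pair makes the pair
concordant), with the fragment span measured outer-to-outer. Multi-mapped
mates contribute one uniformly chosen (seeded) placement to the depth
profile; µ_DOC is the mean depth over covered positions only, so
unsequenced gaps do not deflate it. The per-read depth µ_DOC[r] is the mean
depth across the read's placement; over-coverage is decided per pair from
the mean of the two mates' values, with admission probability
max(0, 1 − µ_DOC/µ_DOC[r]). PCR-duplicate removal is not performed.

A consequence worth knowing: per-read depth estimates over a 36 bp window
are noisy, so a few percent of ordinary concordant pairs are admitted as
over-coverage. These extra IRS members are diluted at any single consensus
column and do not perturb calls, but they do mean |IRS| exceeds the truly
insertion-derived set.

## Read index

Both mates of every IRS pair are indexed in both orientations (four strings
per pair), so anchor windows never need reverse-complementing and orphan
pairs can anchor on previously assembled insertion sequence. Strings are
separated by sentinels; the suffix order is computed by sorting on the
first l + 1 symbols with text position as tie-break (consistent under the
LF shift, and exact for patterns up to l symbols — patterns never exceed
the read length). Matches crossing a string boundary are discarded, and
anchoring requires offset 0 and full-mate length. `N` bases are replaced by
seeded random bases at indexing time (the string is flagged); `N` in a
pattern matches nothing.

`bwt_search` is exact for its budget `d ≤ 3`: full-length patterns use the
pigeonhole split (d + 1 blocks, exact FM backward search per block,
vectorised verification), short patterns bounded backtracking. The
pigeonhole variant returns the identical hit set at a much smaller constant
factor, which matters in an interpreted implementation; equivalence with a
naive Hamming scan is property-tested. `find_anchored` issues exactly
|window| − l + 1 search calls regardless of |IRS| — the complexity property
that makes total assembly time linear rather than quadratic in insertion
content (asserted by an instrumented counter, and measured against the
naive per-read scan in the scaling test).

## Extension engine

The production engine evaluates the covering-set definition incrementally:
as `pos` advances, only the newest window substring is searched (older
results are memoised), anchored partners become *candidates*, and each
candidate is tested once per alignment start — at the earliest informative
overlap (`ext = κ + 1`) by exact prefix match, with mismatch tolerance
⌊(1 − τ)·ext⌋ accruing as the overlap grows. Active extenders vote their
next base; a voter whose accumulated mismatches exceed the ⊕ budget is
dropped. The definitional route (`covering_set`) and the incremental engine
are tested to agree, with two knowingly accepted deviations: a partner
whose first κ + 1 bases contain a sequencing error is not activated at that
start (~0.6% of extenders at the default error rate), and fragments shorter
than ~190 bp whose informative starts predate their anchor's discovery are
missed (a few percent). Both losses are uniform and small relative to 40X.

Consensus: a base with vote fraction ≥ ε_branch is *supported*. Two or
more supported bases make the column a divergence and each is explored
depth-first, up to `max_branches` total hypotheses and a per-call node
budget; exactly one supported base is called (immediately when it also
clears the confident-call threshold ε); no supported base is insufficient
consensus and terminates the branch. Calling a lone supported plurality —
rather than demanding a strict ε majority — is what lets extension survive
copy junctions: for a few columns after a divergence, extenders from the
losing population keep voting (their ⊕ mismatch budget is not yet spent)
and dilute the true base to ~60–65%, which would otherwise kill the
correct branch. The same leftovers occasionally spawn short-lived hybrid
branches; hypothesis selection by accounted reads (whole-mate ⊕ placements
on the hypothesis, ties to the earliest branch) almost always discards
them.

Insertions are assembled per locus: the left flank is extended forward and,
if its tail already overlaps the right flank core by ≥ l bases under ⊕, the
contig is closed immediately (*fast bridge*); otherwise the right flank is
extended in reverse and the best hypotheses merged at their best ungapped
overlap, disagreeing overlap columns resolved toward the side with larger
covering support. A failed merge triggers one retry with τ reduced by 0.05;
if it still fails, both fragments are reported as a partial pair.

## Parameters

| name | default | meaning |
|------|---------|---------|
| l | 36 bp | read length (from the data) |
| d | 2 | substitution budget for mapping and anchoring (≈5.5% of l) |
| µ, σ | 200, 25 bp | fragment length model; Δ bounds at 3σ |
| τ | 0.90 | minimum identity for ⊕ (ungapped) |
| κ | 5 bp | minimum informative overlap; just above random 4-mer odds |
| ε | 0.70 | consensus call threshold; tolerant of 0.1% errors at 40X |
| ε_branch | 0.35 | divergence support threshold |
| max_branches | 8 | beam cap on hypotheses per extension |
| max_extension | 4500 bp | per-endpoint safety cap (~2× insertion + Δmax) |
| threshold | 10 edits | correctness margin for evaluation |

All are configurable (`AlignParams`, `InsertSizeModel`, CLI flags). µ and σ
can also be estimated from uniquely mapped concordant pairs
(`estimate_insert_model`, requiring ≥ 1000 pairs).

## Simulator

The generator emulates the benchmark protocol: uniform-random references;
insertions of length Normal(2000, 200) floored at 200 bp; Case 1 uniform-
random content, Case 2 a verbatim copy of a uniformly chosen reference
window, Case 3 a copied window split at its midpoint around a unique middle
(equal copied and unique content overall — an insertion inside an
insertion); loci drawn uniformly with minimum spacing
2·(Δmax + l) + max insertion length so every insertion has the clean flanks
the base case assumes. Reads: pair count = round(coverage·|donor|/2l),
uniform fragment starts, truncated-normal fragment lengths, forward mate =
first l fragment bases, reverse mate = reverse complement of the last l,
i.i.d. substitutions at 0.001/base (error model unspecified upstream; 0.1%
is typical of the short-read platforms the protocol models), constant
Phred+33 qualities.

What it does **not** model — and what passing tests therefore do not show —
includes real repeat structure (uniform-random references make unique
flanks genuinely unique, so scaled accuracies sit at or above the published
full-scale figures), indel errors, quality variation, GC/coverage bias,
chimeric fragments and diploidy.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; SAM converts at the
  boundary. A BED locus may be a zero-length or 1 bp interval.
- Vote weighting is uniform (one read, one vote); consensus tie order is by
  count, then base order — deterministic.
- All randomness (simulation, N replacement, depth placement, over-coverage
  draws) flows from explicit seeds; identical configuration and seed give
  byte-identical outputs.
- Empty IRS → empty index, searches return nothing, extensions terminate at
  the first column. Empty BED → warning, exit 0.
- Reads with > d mismatches everywhere are unmapped; no best-effort
  placement.

## Evaluation

An insertion is correct when the planted sequence locally places within the
assembled contig (or, for partial pairs, within either fragment) at ≤ 10
unit-cost edits on either strand (edlib infix alignment; contigs carry
reference flanks, hence local placement). Replicate accuracies are
aggregated as mean and sample (n − 1) standard deviation.

## Problem sizes used by scripts/acceptance.py

Desk-scale runs, chosen to keep the whole script within a coffee break on
one CPU while preserving the protocol's per-insertion conditions exactly:

| experiment | category | insertions | reference | replicates |
|-----------|----------|-----------|-----------|------------|
| t1 | unique | 50 | 1.2 Mb | 2 |
| t2 | copied | 50 | 1.2 Mb | 2 |
| t3 | mixed | 50 | 1.2 Mb | 2 |
| t4 | mixed | 10 | 1 Mb | 10 |
| t5 | mixed | 100 | 2 Mb | 2 |
| t6 | mixed | 125 | 2.5 Mb | 1 |

Replicate counts weight the total insertion count per experiment: small
per-replicate insertion counts (t4) get more replicates so that the
sampling error of the reported mean (~2 SD ≈ 5 points at 100 insertions
and a ~94% success rate) is no wider than the differences the figures are
read at.

t6 scales the largest published experiment down at ~50 insertions/Mb —
a *higher* insertion density than the original, so insertion-read-set
crosstalk is not understated.

## Known limitations

- Copy-interior extension rides on probabilistically admitted over-coverage
  pairs (~half the local pairs), so its effective coverage is about half
  the nominal depth; occasional admission troughs terminate a branch
  mid-copy and leave the insertion partial. This is the dominant failure
  mode for copied and mixed insertions, visible as their lower accuracy.
- Divergence wobble can leave a handful of substitutions near a copy-end
  junction when a hybrid branch wins selection; with a 10-edit margin this
  occasionally costs an insertion.
- No gapped alignment anywhere: reads with indel errors are effectively
  lost to the IRS or to covering sets.
- Per-insertion work is independent but executed serially; no concurrency.
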