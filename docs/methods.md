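# Methods

## The optimization problem

Given targets X (reference, sense strand) and Y (and optionally Z), the
designer searches over DNA sequences of the overlap region for the one whose
decoded frames X′, Y′ (Z′) maximize

    S = Σ_i p_i B(X_i, X′_i) + Σ_j q_j B(Y_j, Y′_j) [+ Z term],

with `B` a symmetric 20×20 substitution matrix and `p`, `q` per-position
conservation weights. The score is a sum of independent per-position terms,
which is what makes exact optimization tractable; any pairwise coupling
between positions (e.g. structural contacts) is outside the model.

Assumptions: standard nuclear genetic code (the code is a replaceable value,
but no alternative ships); 3-nucleotide codons; full embedding of the
shorter coding region in the longer; no stop codon anywhere in any encoded
frame of the overlap (a terminator is assumed to be added outside the
designed region afterwards).

## Frames and quartet windows

The reference codon grid starts at nucleotide 0 of the region. Supported
second frames: antisense in register (`F = 0`), antisense shifted so middle
and wobble bases face each other (`F = -2`), and sense shifted +1
(`F = +1`). With any shifted frame the region is viewed as N linked
4-nucleotide windows (N = reference codons in the overlap), window k
covering nucleotides 3k…3k+3, with `Q_{k+1}(1) = Q_k(4)`. Within a window
the codons sit at positions (1,2,3) for the reference, (2,3,4) for `F = +1`,
(4,3,2) complemented for `F = -2`, and (3,2,1) complemented for `F = 0`.
A shifted frame's last codon uses one nucleotide past the final reference
codon, so the region length is 3N + c, c ∈ {0, 1}.

The remaining frames `F = -1` and `F = +2` place codons across two windows;
they would need 5-nucleotide windows with a 2-nucleotide state (the window
abstraction carries a length field, so this is an extension, not a
redesign). `F = +2` is already covered by running `F = +1` with the two
proteins' roles exchanged, which the pair screen does by default; `F = -1`
is refused with an explicit error.

## The dynamic program

States are the four possible last nucleotides of a window. `M(k, s)` is the
best score of any stop-free window chain ending at window k in state s:

    M(k, s) = max over the 64 windows Q with Q(4) = s of
              M(k-1, Q(1)) + s(Q),

initialized with a zero column, where `s(Q)` sums each in-window codon's
weighted Blosum term and is −∞ if any codon is a stop. Traceback
concatenates the chosen windows backwards. Each column examines 4 × 64
candidates, so cost is linear in N; a 100-codon design takes milliseconds.
For the pure `F = 0` pair the windows are unlinked 3-nucleotide codons and
the DP degenerates to an independent argmax over 64 codons per position —
the closed form exposed as `design_f0`.

Ties are broken toward the lexicographically smallest window (A < C < G < T)
at every argmax, and toward state A at the final column, so identical inputs
always give identical DNA. Note the per-step rule does not necessarily pick
the globally lexicographically smallest optimal *sequence* — the brute-force
oracle does — so equal-score designs from the two routes may differ in DNA
while always agreeing in score.

## Placements, flanks and edge constraints

The overlap spans the shorter protein's coding region; a placement gives the
number of the longer protein's codons preceding it (start-aligned,
end-aligned, or any explicit offset). The longer protein's non-overlap
residues are copied unchanged, back-translated to the lexicographically
smallest synonymous codon, and their diagonal score is reported separately
(`flank_score`) — only the overlap is optimized, mirroring how overlap
designs are evaluated against the targets.

One subtlety the window picture hides: when the longer protein sits in a
shifted frame, its first codon beyond the overlap shares one nucleotide with
the region (the linkage nucleotide at one end). An unconstrained optimum
could fix that nucleotide so that no synonymous codon for the flanking
residue exists (e.g. methionine's single codon ATG). The layout therefore
constrains the region's terminal nucleotide to the set compatible with the
flanking residue's codons; the brute-force oracle applies the same
constraint, so the two routes solve the same problem. The constraint is
void for end placements where no flank codon touches the region.

Triple designs (`ref`, `F = -2`, `F = +1` by default) require equal-length
targets: with three frames packed into every window there is no residual
freedom to slide one protein inside another without introducing windows that
encode fewer than three codons, and the equal-length case is the one the
design workflow needs.

## Conservation weights

Column entropy uses the empirical class distribution over six classes,
natural log, with gap symbols excluded from the tally (they are absence of
evidence, not a seventh class); a column of only gaps is an error, and no
gap-fraction filter is applied. The weight is exactly `e^{-S}` with no
renormalization, preserving the interpretation weight = 1 ⇔ single-class
column and the bound weight ≥ 1/6. No sequence weighting or pseudocounts:
raw column frequencies only. The alignment row named like the target must
have ungapped length equal to the design target.

## Capacity analysis

`F = 0`: a codon c and its reverse complement jointly fix the (sense,
antisense) amino-acid pair; enumerating the 64 codons and dropping those
where either strand is a stop leaves 52 ordered pairs. The inventory is
closed under swap (reverse complementation is an involution) and no codon
equals its partner's residue, so this is 26 unordered amino-acid type pairs
— the number quoted in summaries.

`F = -2`: sense and antisense codons share base-paired first bases, while
each central base pairs with the *other* strand's wobble. A (sense class,
antisense class) combination over the four size/polarity classes counts as
"freely encodable" when some choice of the shared first-base pair and the
two independent central bases guarantees the required class on both strands
for *every* stop-free wobble completion; completions yielding the
unclassified residues C or W defeat a guarantee. 15 of 16 combinations pass;
(small-polar, small-polar) fails because small-polar = {S, G} forces the
first base to T or G on both strands, which cannot base-pair — it is
reported as "partially encodable" since one strand can be guaranteed while
the other attains the class ambiguously (AG* = {S, R}).

## Synthetic data

The fixture generator emulates the designer's intended inputs, not real
protein families:

* random proteins, uniform over the 20 residues, 70–100 residues by default
  (typical domain lengths for this workflow). Real domains have biased
  composition and correlated positions; none of the optimality guarantees
  depend on composition, but absolute scores and identities on fixtures do
  not predict those on natural sequences.
* toy alignments whose columns spread uniformly over a prescribed number c
  of the six classes, so the expected weight is exactly 1/c — used to verify
  the entropy pipeline in closed form. Real alignments have skewed class
  frequencies and gaps.
* self-consistent target sets: decode a random stop-free region under a
  scheme and use the decoded proteins as targets. For these a perfect
  design exists, so the optimum must equal the diagonal-sum bound
  Σ p_i B(X_i, X_i) + …, giving an independent closed-form check of the DP.

Passing these suites demonstrates exact optimality of the optimizer under
the stated score, not that designed homologs of natural proteins will fold
or function.

## Numerical choices and problem sizes

Scores are float64 sums; with unit weights and an integer matrix every
intermediate is integer-valued and comparisons are exact. The internal
audit recomputes the score from the decoded proteins after every design and
fails hard on disagreement. Brute-force enumeration is vectorized in chunks
of 4^9 sequences and refuses regions beyond 12 nt by default. The
DP-vs-enumeration suites use overlaps of 1–3 reference codons (regions up to
10 nt, about a million candidates each) with 100 instances per scheme, and
the self-consistency and round-trip suites use overlaps up to ~25 codons;
together the full test suite runs in well under a minute.

## Known limitations

* No partial overlaps: the shorter coding region must be fully embedded.
* `F = -1` designs and 5/6-frame (quintet) schemes are not implemented.
* The score treats positions independently; no structural or codon-usage
  objectives.
* Design quality is reported as percent identity and Blosum-positive
  similarity to the targets over the overlap; database E-value evaluation
  of designs is deliberately out of scope.
* Stop codons are excluded but not inserted: designed regions carry no
  terminator.
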