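# Methods

## Model overview

`gramprom` decides, per sequence window, whether the window looks like
a human RNA Pol II core promoter, and where its TSS most likely sits.
The decision combines two independent lines of evidence:

1. **Grammatical**: does the window contain an arrangement of
   core-promoter elements (TATA-box, initiator, DPE, BRE), and/or a CpG
   island, consistent with a context-free grammar of known promoter
   architectures?
2. **Structural**: does a DNA physico-chemical profile of the window
   show the wide peak or cleft that human core promoters exhibit near
   the TSS?

The pipeline per window is: CpG-island detection → exhaustive
tokenization against the part library → grammar parse → structural
profile → extremum detection → two-tier thresholding.

## The grammar and its parser

Nonterminals are N = {S, S1, S2, T, I, D, B, G, C}; the 19 default
production rules couple a CpG-presence flag (C) with ordered element
arrangements separated by bounded gaps, written `G(lo,hi)`. Two rules
in the default set are verbatim duplicates (R8 and R13) and one
arrangement subsumes another; both are kept so rule-id traces match the
printed rule set, and the parser deduplicates structurally identical
templates only for speed.

**Template expansion.** The rule set is non-recursive above the
terminal level, so the grammar is flattened once into *templates*: each
template is (CpG required?, ordered element list, inter-element gap
constraints), obtained by depth-first expansion from S in rule order
(19 templates for the default grammar: one CpG-only, nine arrangements
each in a CpG-required and a CpG-free variant).

**Token semantics.** The part library expands each element's character
classes into all concrete terminal sequences (24 TATA, 288 Inr, 8 BRE,
24 DPE by class-size products), each with a stable identifier.
Tokenization is exhaustive: every occurrence of every terminal at every
offset is a token, and overlapping interpretations coexist. A greedy
left-to-right lexer can commit to a coincidental match and miss a valid
parse; exhaustive matching produces a superset that the parser filters
by derivability, which is the intended resolution of coincidental
matches.

**Acceptance.** A template is satisfied when its CpG requirement
matches the window's island flag and an ordered, non-overlapping token
choice exists with every inter-element distance
`start(next) − end(prev)` (end exclusive) inside the gap bounds. The
CpG-required variant demands island presence; the CpG-free variant
imposes *no* requirement (the grammar has no negation device, so "no C
in the derivation" cannot mean "island absent"). Flanking gaps from
`S → G S1 G` may be length 0: an element at the window edge is not
rejected on a technicality. Derivations are collected in rule order,
tokens left to right, capped at `max_derivations` (default 100); the
first is "best". The parser is cross-checked against an independent
brute-force enumerator (regex matching plus full Cartesian assignment)
in the test suite.

Note a structural consequence of the printed rule set: the rule
`S2 → I` makes any window containing a single initiator match
grammar-acceptable. With 288 initiator terminals, essentially every
1201 nt window of natural composition is grammar-accepted; the grammar
tier therefore mostly routes windows to the laxer structural threshold
rather than rejecting outright, and the structural evidence carries the
specificity. This mirrors the high false-positive rate of the grammar
alone and the gain from adding structure.

## CpG islands

G+C content is (#G+#C)/len; the observed/expected CpG ratio is
N_CG·len/(N_C·N_G), defined as 0 when the window has no C or no G.
Islands are detected by a 200 nt window sliding at 1 nt steps (window
= the minimum island length, step chosen for nt resolution); a window
passes at GC > 0.5 (strict) and o/e ≥ 0.6 (inclusive). Overlapping
passing windows merge into a span, the span's edges are trimmed to its
first/last C-or-G base (window smearing otherwise drags A/T flanks into
the island and would let a sub-minimum CG run qualify), and the trimmed
substring is re-verified against all three criteria before being
reported; the reported statistics are those of the island substring.
Island presence anywhere in the window sets the `c0` flag.

## Structural profiles and the extremum detector

Each property scale maps every di- or trinucleotide to a real value;
word size and peak/cleft direction are fixed per property (bendability
and nucleosome positioning are trinucleotide scales; base stacking,
propeller twist, A-philicity, Z-DNA, B-DNA twist and denaturation are
dinucleotide). The raw profile is the word-by-word conversion; a
centered moving average of window 3 nt, step 1, gives the smoothed
profile. The shipped scale tables are editable TSV defaults
approximating published experimental scales (Ornstein base stacking,
el Hassan & Calladine propeller twist, Ho Z-DNA, Gorin helical twist,
and Brukner-/Satchwell-style trinucleotide tables among others);
correctness tests construct synthetic scales and never depend on the
shipped numbers.

The detector scores the strongest candidate extremum inside a center
region (±500 nt around the window midpoint, matching the 500 bp
evaluation tolerance):

- baseline = median of the smoothed profile **outside** the center;
- spread = 1.4826 × MAD of the same flank values (floored at 1e-9);
- candidate value = extreme (max for peaks, min for clefts) of a
  `feature_width` (default 50 nt) moving average of the smoothed
  profile within the center;
- magnitude = (value − baseline)/spread, signed; the call passes when
  |magnitude| meets the threshold with the sign matching the property's
  direction.

The feature-width average is load-bearing. The promoter structural
signature spans a few hundred bp, while a single window-3-smoothed
position is an order statistic over ~1000 center positions of a
bounded series (profiles cannot exceed the scale's extreme word
values): empirically, background minima average −3.3 spread units
pointwise — indistinguishable from a genuine planted cleft (~−3).
Averaging at feature scale separates them cleanly (background minima
≥ −1.7 across thousands of simulated windows, wide planted clefts ≈
−3). Setting `feature_width=1` recovers the pointwise detector. Robust
(median/MAD) flank statistics keep the baseline stable when a
neighboring window's signal leaks into the flanks. Degenerate constant
flanks hit the spread floor and report very large magnitudes, which is
the desired behavior for constructed inputs.

## The composite decision

Two thresholds operationalize "grammar evidence makes the structural
check easier": grammar-accepted windows need |magnitude| ≥ 2.5
(`threshold_grammar_backed`), grammar-rejected windows ≥ 3.5
(`threshold_structure_only`). A literal single-threshold reading would
make grammar acceptance irrelevant to the decision; observed
performance of grammar+structure over grammar alone implies the
combination must matter, and setting the tiers equal recovers the
literal reading. Thresholds are in robust-z units of the feature-width
detector above; the defaults sit between the background extreme (~1.7)
and the planted/expected signal (~3) with the stricter tier reserved
for windows with no grammatical support.

The TSS estimate is the extremum position, snapped to the nearest
initiator token within `inr_snap_dist` (100 nt) when the grammar
accepts — the initiator spans +1, but with exhaustive tokenization the
first derivation's initiator alone is an unreliable anchor (incidental
TATA/Inr pairs at legal gaps occur in most kilobase-scale windows), so
the structural extremum does the locating and the initiator refines it.

**Scanning** cuts 1201 nt windows at 200 nt steps (the −1000..+200
convention puts a labelled window's TSS at offset 1000); windows whose
longest N-run exceeds 50 nt are skipped (assembly gaps would pollute
the profile), and windows with interior Ns are profiled on their
largest N-free segment. Promoter calls are thresholded per window and
then merged: single-linkage clustering joins calls whose consecutive
TSS estimates are within 1000 bp (the phrase "falling within 1000 bp"
is ambiguous between a gap and a diameter criterion; gap/single-linkage
was chosen), and the cluster reports the arithmetic mean position,
rounded half-up.

**Evaluation** matches predictions to annotated TSS greedily
nearest-first, one-to-one, within `max_dist` (default 500 bp; ties
break leftward). Every unmatched prediction counts as a false positive
by default — stricter than counting only predictions inside gene
bodies, which requires gene annotation; passing gene intervals enables
that laxer policy. Unmatched annotations are false negatives.
P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), zero denominators give 0.

## Pattern inference (credit assignment)

Candidate element patterns can be scored against positive/negative
training sequences: each scan of a training sequence increments the
pattern's use count `fr`; matching a positive or rejecting a negative
is a correct recognition (`u+`), the converse incorrect (`u−`);
strength = (u+ − u−)/fr. Matching is counted once per sequence
regardless of site multiplicity. The strongest candidate per element
wins, ties breaking toward fewer expansions then lexicographic pattern
text. Candidate generation (`random_patterns`) draws class sizes from
a configurable distribution under a required seed.

## Synthetic data

The generator emulates exactly the statistical structure the method
reads — first-order composition, motif occurrences, CpG statistics,
k-mer scale sums — and nothing more:

- **Background** is i.i.d. at a stated G+C fraction (default 0.40,
  genome-like). No higher-order Markov structure, repeats, or
  isochores: passing tests demonstrates correct mechanics on sequence
  whose only promoter-like features are the planted ones, not
  performance on real genomes, where element and island base rates
  differ.
- **Promoter windows** (1201 nt, TSS at offset 1000) plant a chosen
  template's terminals at gap-consistent offsets (initiator anchored on
  the TSS), optionally a ≥400 nt CpG-island segment at GC ≈ 0.65
  (o/e ≈ 1 by independence), and a structural extremum: a run of
  scale-extreme words (greedy walk through the scale) substituted
  around the TSS, default width 200 nt to emulate the few-hundred-bp
  structural region. The run length is calibrated so the feature-scale
  displacement targets `amplitude` spread units, saturating at the
  scale's extreme value — on bounded dinucleotide scales an amplitude
  of 8 saturates to roughly −3 detector units, intentionally: word
  substitution cannot exceed the physics of the scale. Windows are
  re-verified post hoc (parser accepts; requested island detectable)
  with deterministic redraws. A strong cleft run on a GC-extreme scale
  is itself CpG-island-like — true of real GC-rich promoters too — so
  "no island" is not enforced on planted promoter windows.
- **Negative windows** come in three purity modes: `raw` (no
  rejection, for false-positive-rate measurement), `composite`
  (resampled until the full classifier and the island detector are both
  negative), and `parse` (additionally grammar-rejected; feasible only
  for short sequences since a single chance initiator match accepts a
  window under the `S2 → I` rule).
- **Chromosomes** embed promoter windows at fixed spacing (default
  5000 nt ≥ window) in background, returning the truth TSS set.

All generators are seed-deterministic (identical spec + seed →
identical bytes), with per-plant seeds derived from the master seed.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; BED output 0-based;
human-readable CLI output 1-based. Sequences normalize to lowercase
{a,c,g,t,n}; IUPAC ambiguity codes are rejected by default or mapped to
`n` on request. Profiles reject words containing `n` (callers mask
first). Empty token lists parse to rejection unless the CpG-only route
applies. o/e with no C or G is 0. The spread floor (1e-9) makes
constant-flank magnitudes finite. Cluster positions round half-up.
Window tails shorter than the window width are dropped unless
explicitly allowed.

## Problem sizes used in the shipped checks

The test suite exercises the parser–oracle equivalence on 200 random
300 nt sequences plus ~50 constructed near-miss arrangements (gap off
by one), and the end-to-end path on a ~102 kb synthetic chromosome with
20 planted promoters plus twenty 50 kb pure-background chromosomes —
sizes at which the brute-force oracle stays exhaustive and a full run
completes in well under a minute on one core.

## Known limitations

- Default scanning is single-strand; `--both-strands` scans the
  reverse complement and maps coordinates back.
- The shipped structural scale values are literature-derived defaults,
  editable as data files; absolute magnitudes (not the detector's
  z-scores) depend on them.
- The grammar has no stochastic weights and no inference of production
  rules from data; pattern inference covers terminals only.
- Evaluation offers no ROC/AUPR or bootstrap intervals.
- CpG-island presence is computed over the whole window, not a
  TSS-proximal subregion.
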