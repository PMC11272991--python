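# Methods

## The identification problem

A barcoding identification takes a query sequence, ranks its matches
against a species-labelled reference collection, and asks whether the top
of the ranking is owned by a single species. Whether that works is a
property of the *barcode gap*: identification is reliable only when
interspecific divergence exceeds intraspecific divergence. In *Acropora*
both standard markers (the mitochondrial putative control region, mtCR,
and the nuclear *PaxC* intron) sit near or below the gap, and distinct
species can carry literally identical haplotypes. The package therefore
couples the identification rules to an evaluation layer (leave-one-out
self-identification) and a simulator that generates data on either side
of the gap.

## Alignment and scoring

Hits are produced by exact local alignment (Smith–Waterman with affine
gaps), standing in for a megablast search against a curated local
database. Scoring defaults are the classic blastn scheme — match +2,
mismatch −3, gap open 5, gap extend 2 — with a gap of length *k* costing
`open + k·extend`. Raw scores are rescaled to bit scores with
Karlin–Altschul parameters λ = 0.625 nats, K = 0.41:
`bits = (λS − ln K)/ln 2`. E-values (`m·n·2^−bits`, with n the summed
reference length) are reported but never used in decisions. Ambiguity
codes score as mismatches everywhere — including N against N — and never
count as identities. Percent identity is `100 · identities / columns`
(gap columns included), stored at 3 decimals; bit scores are stored at 1
decimal. All tie tests in the decision rules happen at exactly these
precisions, the granularity of the reports such decisions are made from.

The engine (`acroid/_sw.py`) is a numba-jitted full dynamic programme
plus a banded variant used only when it is provably exact: for an
equal-length pair with *h* scoring mismatches, any alignment path that
touches a diagonal offset *d* satisfies
`score ≤ match·L − min(match·d, open + extend·d)`, while the main-diagonal
path scores `match·L − (match−mismatch)·h`; the band is chosen as the
smallest *d* whose bound falls strictly below the diagonal score, so the
banded optimum equals the global optimum. This makes the all-pairs
workloads (leave-one-out on 1–2 kb sequences) run in milliseconds per
pair without any heuristic approximation. The kernels are cross-checked
in the test suite against an independent exact aligner
(scikit-bio's `pair_align`, which implements the same gap convention).

Hit tables keep one hit per subject, sorted by (bit score desc, percent
identity desc, subject id asc) — the third key makes the order total, so
repeated runs and permuted databases give identical tables.

## Species labels

Labels are parsed to (genus, epithet, qualifier). `sp.`/`cf.`/`aff.` are
recognised open-nomenclature qualifiers; any other non-binomial
decoration (bare genus, strain/isolate tags, malformed epithets) becomes
qualifier OTHER. All qualified labels are *ambiguous*: they compete in
the ranking like any other candidate, but an ambiguous winner is reported
as `ASSIGNED_AMBIGUOUS` and excluded from every "assigned" tally. Species
identity is compared at binomial level (normalised genus + epithet),
ignoring the qualifier; named hybrids are treated as ordinary binomials.
Genus abbreviations ("A.") expand to a configurable default genus. How
infra-specific decorations should be normalised is genuinely open; the
OTHER bucket is this package's choice and is deliberately conservative
(ambiguous rather than guessed).

## The decision tree

Per query and locus, evaluated over *distinct species* (multiple hits to
one species never constitute a tie):

1. *Barcode mode only*: if exactly one species has a hit at exactly
   100.000% identity, assign it (`UNIQUE_100`).
2. If the top (1-decimal) bit score over **all** hits belongs to one
   species, assign it (`BITSCORE_TOP`).
3. Among the bit-score-tied hits, if the top (3-decimal) identity belongs
   to one species, assign it (`IDENTITY_TIEBREAK`).
4. Otherwise the query is an irresolvable tie (`UNASSIGNED_TIE`).

Genome mode (whole-mitogenome queries) drops step 1: at genome length a
perfect-identity shortcut is not meaningful, and ranking starts at the
bit score. Note an intentional literalism: in barcode mode with two or
more species at 100%, step 2 may assign a species whose best hit is below
100% identity if it owns the top bit score; such cases are visible in
`rule_path` for audit. "100% identity" carries no coverage requirement by
default; a minimum alignment length is exposed (`min_aln_length`,
default 0) for users who want one.

Two-locus concordance: a specimen gets a final species only when both
loci return `ASSIGNED` with the same binomial; ambiguous assignments
never concur; exactly one assigned locus yields a preliminary,
single-marker identity.

## Leave-one-out evaluation

Each record of a database is queried against the database minus itself
and assigned in genome mode. Species with a single record are excluded as
queries — a singleton cannot be self-identified — but remain as hit
subjects, which matters: a query whose nearest neighbour is another
species' singleton is *misled*, not unassigned. Verdicts compare the
assigned binomial to the record's own label; `UNASSIGNED` (ties, no
hits, or an ambiguous winner) counts in the denominator, because an
identification that returns no name has still failed. The success rate is
reported to 2 decimals. Because alignment is symmetric, the evaluator
computes each unordered pair once and assembles all per-record hit tables
from the pairwise matrix; a test pins this route to the naive per-query
search. With an `anchor`, all sequences are first rotated so the anchor's
best match starts at position 0 — the normalisation needed before
comparing circular mitogenomes assembled at arbitrary origins. The
rotation is anchor-seeded, not a full cyclic-alignment optimisation: it
fixes the origin from one conserved marker, which suffices for databases
that share any conserved region, and is exactly invertible (a rotated
database yields the same evaluation as the unrotated one).

## The simulator

Per locus: one uniform-random ancestor sequence; each species' haplotype
is the ancestor mutated at per-site probability `inter_div`; with
probability `share_prob` a species replaces its haplotype with a copy of
another species' current haplotype (so sharing can chain and collapse
several species onto one sequence — the zero-distance species pairs that
produce irresolvable 100%-identity ties); each specimen is its species'
haplotype mutated at `intra_div`; each locus of each specimen drops out
with probability `dropout`. Substitutions are uniform over the three
alternative bases; divergence parameters are raw per-site substitution
probabilities (no multiple-hit correction). There are no indels by
default — identity ties, not gaps, drive the failure mode — though an
`indel_rate` knob exists. One seed drives everything; per-locus
substreams are derived by fixed offsets so adding a locus leaves earlier
loci byte-identical.

Defaults describe a two-marker trade survey at the scale of ~127
specimens: 16 species × 8 colonies; mtCR 800 bp with dropout 2/127,
*PaxC* 600 bp with dropout 57/127 (the observed recovery failure rates of
the two markers in trade-sample barcoding); intraspecific divergence
0.002 (mtCR) and 0.005 (*PaxC*) per site; interspecific divergence 0.01
and 0.02; `share_prob` 0.25. No quantitative divergence estimates exist
for these markers in the literature at this resolution, so the divergence
and sharing defaults are this package's choices, set once to sit near the
barcode gap — low enough that sharing and ties occur, high enough that
clean assignments exist. What the simulator does *not* emulate: coalescent
genealogies, the *PaxC* length polymorphism, recombination,
sequencing/chimera error, and database misidentifications. Passing tests
therefore show that the machinery behaves correctly across divergence
regimes, not that real *Acropora* data will show any particular success
rate.

## Problem sizes used in tests and analyses

The power-curve suites use a single 1 kb locus, 10 species × 4 specimens,
20 replicates per grid point (tests) or 8 (acceptance script), pooling
reference and specimens into one database of 50 records per replicate.
The mitogenome-style analysis (`analysis/04`) uses 119 records over 25
species with 9 singletons at 2 kb — the identity structure of a genome
collection at desk scale. The two-locus survey runs at the full default
128 specimens. These sizes are the package's stated study conditions;
success rates quoted in the README come from running the scripts at seed
1.

## Numerical and degenerate-input choices

* Sample (n−1) standard deviation for identity spreads; "over 99%" is a
  strict inequality.
* Histogram bins for top-hit identity are width 0.5 over [90, 100], last
  bin closed; values below 90 collect under an underflow key; queries
  with no hits contribute to the tie histogram (k = 0) but to no identity
  bin.
* Mean/SD over an empty set are reported as missing, never 0; a
  leave-one-out run with no evaluable records reports a missing success
  rate; `success_rate` on a fully excluded table is an error.
* Floating-point sums in summaries are computed over sorted values, so
  reports are permutation-invariant bit for bit.
* Locus verification requires the winning locus to clear a 50-bit floor
  and to win outright; an inter-locus tie is `UNKNOWN`.
* All file outputs serialise floats at fixed precision (identities 3 dp,
  bit scores 1 dp) so repeated runs diff clean.

## Known limitations

* The banded-alignment certificate applies only to equal-length pairs;
  unequal pairs always pay the full O(mn) cost.
* `read_tabular_hits` cannot recover raw scores from tabular input;
  ingested hits carry `raw_score = 0` and are ranked purely by the stored
  bit scores and identities, which is all the decision rules use.
* The supplementary-table readers apply a best-effort default column
  mapping; real spreadsheets need a mapping file, and only flat
  per-sample layouts are supported.
* Species labels are normalised syntactically; no taxonomic synonym
  resolution is attempted.
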