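# Methods

## Problem setting

A homology-search array asks a question that is usually answered by
sequence alignment — "which genes of species A have conserved homologs in
species B?" — with a hybridization experiment instead. Single-copy genes of
a sequenced species (here called "human", species A) are represented by one
60-mer oligonucleotide probe each; labeled mRNA from an unsequenced species
(here "squid", species B) is hybridized to the array; probes that light up
strongly are read as evidence that the sample species carries a transcript
close to the probe at the nucleotide level. The approach works only if the
probes are specific: any probe that is close, in edit distance, to a
*non-target* gene would report cross-hybridization rather than homology.
This package implements the probe-design procedure, a simulator that stands
in for the wet-lab experiment, and the downstream intensity-threshold
analysis.

## Infix edit distance

The specificity score of a candidate probe `p` against a gene `g` is the
infix (semi-global) Levenshtein distance

    d(p, g) = min { Lev(p, s) : s a substring of g },

i.e. unit-cost edits with free gaps at both ends of the gene. The full DP
formulation has first row zero and takes the minimum of the last row. This
is the only reading of "edit distance between a probe and a gene" under
which a threshold of 11 on a 60-mer is meaningful: a *global* distance
would be dominated by the length difference between a 60-mer and a
kilobase-scale transcript.

The production path (`infix_edit_distance`) wraps edlib's banded
semi-global aligner with an early-exit cap `k`; the screen never needs
distances above `distance_threshold + 1`, so the cap defaults there and a
capped-out result counts as "specific". A hand-written full-DP oracle
(`brute_force_infix_distance`, NumPy row recurrence with the running-minimum
trick for the insertion dependency) is kept as an independent cross-check
and is used by the test suite on tens of thousands of random instances.

Conventions, chosen for determinism and conservatism:

* `N` matches nothing — cost 1 against every base including another `N`.
  Internally `N` is remapped to distinct out-of-alphabet symbols on the
  probe and gene sides before alignment.
* Among equally good match locations the smallest half-open end offset is
  reported.
* The distance is bounded by the probe length (all-deletions alignment
  against the empty infix), so `cap = len(probe)` is effectively uncapped.

A q-gram lower bound (`qgram_lower_bound`) is available as a prefilter:
each edit destroys at most `q` of the probe's overlapping q-grams, so
`ceil(missing/q)` never exceeds the true distance. For 60-mer probes the
bound cannot exceed `ceil(50/q)`, which for the default `q = 11` is 5 —
below any useful cap — so the hot path short-circuits the bound evaluation
entirely and relies on the capped aligner alone, which is faster in
practice anyway. The bound stays in the API (and under property test)
because it is the correct gate for shorter probes or larger caps.

## Probe design

Per species, with defaults in parentheses:

1. **Candidate extraction** — windows of `probe_length` (60 bp) at starts
   0, `step` (50 bp), 2·`step`, … 0-based half-open; windows containing `N`
   are dropped; a transcript shorter than one window is removed as
   `too_short`.
2. **Within-species screen** — each candidate's score is its minimum infix
   distance to every *other* transcript of the same species, both strands
   by default (`check_reverse_complement`), computed with the capped
   aligner. Nearest-gene ties break to the smallest id.
3. **Selection** — keep candidates with score strictly greater than
   `distance_threshold` (11) *and* last base strictly more than
   `three_prime_margin` (20 bp) from the transcript's 3' end; of the
   keepers take the largest start (the 3'-most — oligo-dT-primed labeling
   makes 3'-proximal signal strongest). No keeper ⇒ gene removed as
   `no_specific_candidate`; this is where duplicated and multi-copy genes
   fall out, since their siblings sit within a few edits of every window.
4. **Single-gene check** — a probe whose exact sequence (either strand)
   occurs in more than one transcript of its own species is removed
   (`multi_copy_exact`).
5. **Cross-species filter** — a probe within `distance_threshold` of any
   transcript of the *other* species is removed
   (`cross_species_conflict`), so the two probe sets can share one array.

Both species are designed by the same procedure. Strand handling is a
single flag applied to every specificity computation; it is on by default
because one-color cDNA labeling can present either-strand complements.
Stored `min_cross_distance` values are capped at `cap`; a stored value
equal to `cap` means "at least this far from every non-target".

The thresholds are strict comparisons ("more than eleven", "more than
20 bp"), and the 3'-margin is measured from the probe's **last** base to
the transcript end (`dist_to_3prime = L − (start + probe_length)`).

## Hybridization simulator

The simulator replaces the wet lab so that the analysis is testable end to
end. It emulates three things: divergence of an ortholog set, a two-sample
(head/body) expression design, and the scanner readout.

**Ortholog evolution** (`evolve_ortholog`): per site, one categorical event
— substitution to a uniformly random different base
(`substitution_rate` = 0.10), deletion (0.01), or retention plus insertion
of one random base (0.01). Defaults emulate the deeply conserved coding
cores such an array can actually see (~90% identity); genes outside that
conserved fraction are invisible to a 60-mer probe regardless. There is no
codon structure, no site-rate heterogeneity, no large indels — so passing
tests say the *pipeline* recovers what the signal model encodes, not that
real squid mRNA would behave this way.

**Signal model** (`simulate_intensity`):

    I = (s · A · exp(−k·d) + B) · ε,   clipped to [0, 2^20]

with `d` the probe's minimum infix distance to the best expressed target,
`s` that target's expression scalar, amplitude `A` = 1e5, decay
`k` = 0.3 per edit, additive background `B ~ N(50, 10²)` truncated at 0,
and mean-one lognormal noise `ε` with CV 0.1. The exponential decay is an
explicit stand-in for hybridization thermodynamics; `k` = 0.3 is chosen so
that at the design threshold of 11 edits a cross-hybridizing target retains
under 5% of full signal (exp(−3.3) ≈ 0.037), which is the premise of the
specificity screen. The 2^20 ceiling models the scanner's 20-bit dynamic
range. In `generate_experiment` each probe reads its *dominant* expressed
hybridizer (argmax of `s·exp(−k·d)`); contributions beyond 40 edits are
treated as zero, which is far below one intensity unit at any realistic
amplitude.

**Experiment design** (`ExperimentDesign.randomize`): a shared expressed
gene set (default 70% of genes) with lognormal base levels (σ = 0.4)
identical in head and body, except designated differential genes, which get
scalars `(√f, 1/√f)` in alternating direction so their true fold change is
exactly `f` and both intensities stay inside the scanner range. Sharing the
expressed set between samples keeps "differential" meaning what the truth
table says: with independent per-sample sets, every single-sample gene
would be an extreme fold change and recovery statistics would be
uninterpretable.

Evolution, expression design and measurement noise run on separate seeded
RNG streams; identical seeds give byte-identical output tables.

## Analysis

* **Detection**: `intensity > background_mean + 2.6·background_sd` — a
  documented stand-in for the scanner vendor's proprietary significance
  call; it does not claim to reproduce the vendor's counts.
* **Homolog candidates**: `intensity > 1000` (strict) on the linear scale.
  The rationale: cross-hybridization loses signal so rapidly with edit
  distance that intensities this high indicate a genuine nearby homolog.
* **Known/new split**: candidates intersected with a precomputed homolog
  pair table (sequence-level homology search itself is out of scope; the
  table is an input).
* **Differential expression**: per probe, fold change
  `max(h+c, b+c)/min(h+c, b+c)` with floor `c` = `min_intensity_for_fc`
  (default 50, a typical background mean) guarding against near-zero
  denominators; regulation "up" = higher in head. Reported when the fold
  change meets `fold_change_min` (default 2) and at least one sample is a
  homolog candidate. The list is threshold-based by design — no test
  statistic, no multiple-testing correction — mirroring how such arrays
  are read.
* **Venn summary**: three-set region counts over gene identifiers — genes
  called by A-probes, genes called by B-probes (mapped through the pair
  table onto A-side ids where a pair exists), and the pair table's A-side
  genes. Counts sum to the union size.

## Numerical and degenerate-input choices

* All threshold comparisons strict; all tie-breaks lexicographic or
  smallest-offset; gene processing order is sorted by id — two runs on the
  same inputs are byte-identical.
* Empty gene in the distance kernel returns `len(probe)`, not an error.
* An empty transcript set after self-exclusion reports `CAP_EXCEEDED`
  (maximally specific).
* Intensities above 2^20 on ingest are clamped with a warning; negative
  intensities are hard errors.
* Probe tables round-trip exactly (floats written with `repr`).

## Problem sizes

The test suite and the acceptance script generate everything at run time:
oracle agreement on 10,000 random (probe ≤ 20, gene ≤ 100) instances,
q-gram bound validity on 5,000, design-rule conformance on a 50-gene
random set re-verified post hoc with the brute-force oracle, and
parameter-recovery simulations on 200 genes with 20 designated fold-100
differential genes. These sizes exercise every rule and tie-break while
keeping a full run in tens of seconds.

## Known limitations

* The exponential signal model and the detection rule are stand-ins; their
  shape, not their constants, is what the analysis depends on.
* The evolution model is site-independent and uniform; real divergence is
  rate-heterogeneous and would lower recovery for fast-evolving genes.
* Multi-copy gene families are excluded by design — the method targets
  single-copy genes; probing families would need a different strategy.
* The published array's catalog counts (probe totals, detected-probe
  counts, candidate-gene lists) depend on specific transcript snapshots
  and raw array data and are not reproduced here; the package reproduces
  the procedure and its arithmetic, not those datasets.
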