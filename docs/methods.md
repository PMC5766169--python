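# Methods

## The measurement model

Chemical probing of elongating transcripts reads out two coordinates per
sequenced cDNA. A nascent RNA's 3′ end marks the position of the RNA
polymerase that was synthesizing it, so the length `L` of a transcription
intermediate identifies it. DMS methylates unpaired adenines (N1) and
cytosines (N3) far faster than paired ones and does not produce RT-blocking
adducts on G/U; reverse transcription primed from an adapter ligated to the
RNA 3′ end runs 3′→5′ and halts one nucleotide downstream of a modified
base. A paired-end library therefore yields, per molecule, the pair
`(L, m)`: the reverse mate's 3′-most aligned coordinate gives `L`
(polymerase position) and the forward mate's 5′-most aligned coordinate
minus one gives `m` (the modified base). `spetfold` consumes such
alignments in transcript coordinates (1-based, closed, SAM convention) and
reconstructs per-intermediate structure signals from them.

Under single-hit kinetics the molecule may carry several methylations but
RT reports only the 3′-most one. Writing `p_j` for the per-base
modification probability of position `j` (`p_mod_unpaired` on unpaired
A/C, `p_mod_paired` on paired A/C, 0 on G/U),

    P(stop = m | L) = p_m · ∏_{j>m, j≤L} (1 − p_j),
    P(full length | L) = ∏_{j≤L} (1 − p_j).

This law has two structural consequences the pipeline must respect:
coverage (the number of cDNAs spanning a position) decays multiplicatively
toward the 5′ end (RT attrition), and stops within `min_read_len` of an
intermediate's 3′ end are unobservable because the forward read would be
too short to map (the blind region).

## Pipeline stages

**Pairing (`align_io`).** Forward and reverse mates, mapped independently
(sense-only / antisense-only), are re-joined by read name. Mates mapping
to disjoint transcript sets are dropped and counted; a pair consistently
mapping to k transcripts is emitted k times at weight 1/k, which conserves
total signal across repeated genes (bacterial rRNA operons); a `drop`
policy is available. The reverse mate's far coordinate is computed through
reference-consuming CIGAR operations, not taken from POS. A soft-clip at
the forward mate's 5′ end hides the true stop, so such pairs are kept for
coverage only. Counters form two exact conservation identities (read-name
level and pair level) that are asserted in the tests.

**Counting (`counting`).** Stops and coverage are accumulated per
`(L, position)`; coverage is derived from the implied cDNA extent
`(m+1 .. L)` rather than the sequenced read footprint, because both cDNA
ends are known and the window filters need per-position coverage over
whole regions. Each intermediate row stores a histogram of cDNA 5′ starts;
coverage is its running sum, which keeps storage sparse and makes the
within-intermediate monotonicity (coverage non-decreasing toward 3′) hold
by construction. Genes are split into ten equally sized transcription
deciles by the floor rule (decile d of length L spans
`⌊(d−1)L/10⌋+1 .. ⌊dL/10⌋`) and intermediates whose 3′ end falls in the
same decile are pooled. Duplicate collapsing (one record per
`(transcript, L, stop)`) yields polymerase-occupancy profiles.

**Reactivity (`reactivity`).** Scoring is treated-only: the raw score of
a covered A/C position is its pooled stop weight; G/U and uncovered
positions are missing. Normalization is 90% Winsorising — values are
capped at the 95th percentile of their window and divided by it — using
the nearest-rank percentile (the value at sorted rank `⌈0.95·n⌉`), which
is deterministic and identical across ecosystems. Whole profiles use
50-nt sliding windows with a 25-nt offset; positions covered by two
windows get the mean of their normalized values; terminal partial windows
are normalized as-is when they hold at least two values. No lower-tail
flooring is applied: stop counts are non-negative, and scaling to the
95th percentile alone keeps the transform idempotent and scale-invariant
(both asserted). Heatmaps distinguish the blind region from untranscribed
positions.

**Windowed comparison (`deciles`).** The structural-change statistic
slides a dynamically sized window collecting 40 A/C residues (offset
20 A/C) and scores it on each eligible pair of consecutive deciles
(Prev, Next). Filters: median coverage ≥ 100 and ≥ 1 RT stop per A/C on
average, required in *both* deciles (a comparison is only meaningful when
both sides are measurable); positionally, the window must end no more
than 200 nt before the Prev decile's start and at least 25 nt before its
end — anchored on Prev because its 3′ boundary is what truncates
coverage. The 40 values are split into two chunks of 20 A/C residues,
each Winsorised independently ("half-normalization"), which cancels the
RT-attrition gradient across the window; the chunks are defined by A/C
residues, not literal nucleotides, since the window itself is — a literal
20-nt reading would leave most of the window unnormalized. Pearson r and
the Gini index `G = Σᵢⱼ|xᵢ−xⱼ|/(2n²μ)` are computed pairwise-complete
over positions non-missing in both vectors (at least 10 shared values
required). Calls: `CHANGED` when r < 0.8; `STABLE` when r > 0.8 and
|ΔGini| < 0.1; everything else — high correlation with redistributed
signal, degenerate (all-zero) halves, zero variance, too few shared
values — is `AMBIGUOUS`, a third class added because the two published
criteria do not partition the (r, ΔGini) plane. No multiple-testing
correction is applied and no per-window p-values are produced.

**Structure classification (`structure`).** Mature secondary structures
arrive as plain dot-brackets (pseudoknotted inputs are rejected, not
flattened — soft-constraint folds are knot-free and silent flattening
corrupts range labels). A paired base is `SHORT_RANGE` when its partner
lies in the same transcription decile, `LONG_RANGE` otherwise (boundary-
spanning pairs are long-range); the lower-coordinate partner is the 5′
side. Enrichment of long-range bases inside `CHANGED` windows is an
upper-tail hypergeometric test whose universe is all A/C bases inside
filter-passing windows (the per-base reading of the published bar-plot
statistic; configurable). Nascent-versus-mature reactivity comparisons
take each base's nascent value from its own transcription decile and use
only 5′-side bases for the paired categories (the 3′ side of a nascent
helix is next to the polymerase and generally unresolved); homogeneity is
assessed by one-way ANOVA. "Minimal structural element" is
operationalized as a maximal single-branch hairpin: grown outward from a
hairpin-closing pair through stacked pairs, bulges and internal loops,
stopped by multiloops, and required to contain only short-range pairs;
elements are rescaled to a 21-bin relative grid for the metaprofile.

## The synthetic-data generator

`sim` inverts the measurement model into a generator. A
`FoldingTrajectory` maps each intermediate length on a sampling grid
(default: every 10 nt plus the full length — a stand-in for the unknown
true intermediate distribution, deliberately free of polymerase kinetics)
to a dot-bracket of exactly that length. Three scenarios are built in:

* `cooperative_hairpin` — every helix appears, all pairs at once, in the
  first intermediate covering its 3′ strand and persists; local elements
  fold as soon as they are transcribed.
* `transient_sequestration` — a 5′ block is unpaired on emergence, pairs
  with a decoy, is released when a competitor sequesters the decoy, and
  finally pairs with its true 3′ partner: the canonical non-cooperative
  pattern for the 5′ halves of long-range helices.
* `user_supplied` — validated pass-through.

Planted transitions are *derived* from the structures: for each decile,
each position's pooled state is PAIRED/UNPAIRED when constant across all
intermediates of the decile that have transcribed it, MIXED otherwise;
maximal A/C runs whose definite state flips between consecutive deciles
are recorded as ground truth.

Reads are emitted error-free with exact per-base Bernoulli draws (the
closed-form stop law is *not* sampled directly, so the distributional
tests against it remain independent), deterministic under a single seed.
Unmappable pairs (blind region) are written as unmapped SAM records —
what an aligner would report — and flagged in the truth table.

Default rates `p_mod_unpaired = 0.15`, `p_mod_paired = 0.01` give a 15:1
single-hit contrast; `min_read_len = 15` and `read_len = 35` mirror
common short-read trimming practice. What the generator does *not*
emulate: sequencing errors, mismapping, ligation and fragmentation
biases, polymerase pausing, thermodynamic folding, or partial
modification gradients — so green tests certify the *analysis* under the
stated measurement model, not robustness to real-library artifacts.

## The planted-transition benchmark

`benchmark` builds ~1-kb transcripts that mix both folding modes with
unambiguous per-window ground truth. The background is a tiling of 24-nt
hairpin modules (8-bp stem, 4-nt loop carrying two unpaired A/C — at
least two high-reactivity anchors per 20-residue normalization chunk, so
the nearest-rank P95 always lands on a genuinely reactive value). Each
planted transition converts one transcription decile into a G/T-only
quiet zone (no probing signal, no RT attrition) holding a 12-residue
`ACACACACACAC` block early in the decile; its reverse-complement partner
(G/T-only, hence silent) ends just before the next decile's first sampled
intermediate. The block is therefore unpaired in every pooled
intermediate of its own decile and paired in every one of the next — a
clean planted flip — while being observable outside the blind region from
most Prev-decile intermediates. The quiet zone is extended 5′ base by
base until the block's A/C indices end exactly on a window-grid boundary,
so exactly one analysis window (inside the positional filter band) ends
at the block; this removes the otherwise arbitrary dependence of
per-window truth on how the A/C grid happens to cut a planted event.

Study sizes: 20 transcripts of 960–1040 nt, three transitions each at
boundaries sampled from deciles 3–8 with a minimum gap of two, 500 read
pairs per intermediate (≈5000 per decile), aggregated over 20 independent
seeds. The per-intermediate depth is chosen so that the published filter
thresholds (median coverage ≥ 100) remain satisfiable under RT attrition
at the default modification rates; at an order of magnitude less depth
the attrition alone pushes every window below the coverage filter and the
comparison machinery is never exercised. Scoring: sensitivity is the
fraction of scored (non-filtered) windows with truth `changed` that are
called `CHANGED`; specificity the fraction of truth-`stable` scored
windows called `STABLE`; windows containing any MIXED pooled state have
no unambiguous truth and are excluded from both denominators (they are
still scored and reported). The long-range enrichment test pools the
hypergeometric counts over transcripts and seeds.

## Numerical choices and degenerate inputs

* Nearest-rank percentiles throughout; no interpolation.
* All-zero Winsorising windows return zeros with a `degenerate` flag
  (no division); windows with fewer than two values return missing.
* Gini is computed by the sorted-rank identity (O(n log n), equal to the
  double sum to ~1e-15) and is NaN for empty or zero-mean vectors, which
  propagates to an `AMBIGUOUS` call.
* Pearson with zero variance on either side is NaN → `AMBIGUOUS`.
* Weight conservation at every aggregation step is exact to 1e-9 and
  asserted; stop positions satisfy `1 ≤ m < L` by construction and
  violating alignments are rejected with named reasons.
* The hypergeometric tail is `P(X ≥ k)` via the survival function;
  inconsistent counts (`k > min(K, n)`) raise instead of clamping.

## Known limitations

* Transcriptome coordinates only; no genome-coordinate mode, alignment,
  or adapter trimming.
* Treated-only scoring; no untreated-control subtraction and no
  mutational-profiling (MaP) mode.
* The decile pooled-state ground truth is defined on the simulator's
  sampling grid; real intermediate mixtures are continuous.
* The 5′-most deciles of long genes are systematically data-poor under
  RT attrition; the filters remove them rather than rescuing them.
* Reported fractions of stable/changed windows on synthetic data are
  properties of the simulated scenario mix, not estimates of any
  biological quantity.
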