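# Methods

This note documents the models, parameter choices and numerical
decisions behind `hetrseq`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinate convention

Intervals are 1-based with an inclusive start and an exclusive end, so
`length = end - start`. This choice makes the printed lengths of the
packaged curated-region table exact arithmetic identities (for example
`136127..136558` with length 431), which the test suite asserts for
every row whose printed end coordinate is self-consistent. One row
(`2820376..2822006`, printed length 678) is internally inconsistent in
the source table; the fixture flags it `end_reliable = n` and it is
excluded from length checks. BED I/O converts explicitly to and from
BED's 0-based half-open frame; GFF3 uses its native 1-based inclusive
end. Whether the table's coordinates are themselves 0- or 1-based
against the reference genome cannot be settled without that genome;
only the length relation is asserted.

Fold-change cells form a closed sentinel domain — a signed numeric fold
with |value| ≥ 1 (negative = lower in the hetR-null mutant), `NA`,
`Low coverage`, or `"n / 0"` (n wild-type reads dropping to zero mutant
reads, compared as infinite magnitude). Sentinels are parsed into
explicit objects and never silently coerced to numbers.

## Synthetic sequencing design

The generator emulates the study's design at desk scale: a 1-Mb i.i.d.
genome at 41.2% GC (the organism's approximate composition), 40-bp
single-end reads, and 200 000 reads per sample instead of the original
~40 million — chosen to keep a full-pipeline run under ten seconds
while leaving ~20 expected background read starts per 100-bp window, a
regime where the Poisson machinery is exercised realistically.

**Fragment model.** A pulled-down fragment is centered either uniformly
on the genome (background) or on a planted site with Gaussian jitter of
one fragment-length standard deviation; its length is Gaussian
(mean 200 bp, SD 40 bp, truncated below the read length); the read
covers the fragment's 5′-most 40 bases on a uniformly chosen strand.
This reproduces the twin-peak geometry the curation stage must detect:
plus-strand read starts pile up half a fragment length upstream of the
site and minus-strand 5′ ends the same distance downstream. Reads
overhanging the genome ends are redrawn, so read counts are conserved
exactly. No sequencing-error, quality-score or duplicate-read model is
included, and reads are emitted at their true coordinates (alignment
error is out of scope).

**Enrichment.** `enrichment_ratio` r sets the fraction of IP fragments
drawn at sites as `n_sites · (r − 1) · fragment_mean / genome_length`
(capped at 1), which makes the fragment rate over a site's footprint
r times the background rate. The control sample contains no
site-conditioned fragments; its window counts pass a Poisson dispersion
test. The IP and control are simulated as same-condition samples; the
study's control was harvested two hours later than the IP, and any
time-offset background shift is deliberately not modelled.

**Expression.** Per-gene baselines are log-normal around 200 expected
reads; mutant abundance of dependent genes is divided by the effect
size (default 8, matching the fold changes reported for the strongest
targets); multiplicative Gaussian noise with CV 0.1 perturbs every
measurement; RPKM is the standard reads-per-kilobase-per-million
definition. Both samples under 10 reads serialize as `Low coverage`; a
positive WT count with zero mutant reads serializes as `"n / 0"`.

**Study construction.** `simulate_study` plants "regulatory" sites
100–300 bp upstream of genes marked mutant-dependent and "decoy" sites
with identical geometry and enrichment upstream of unaffected genes, so
decoys fail exactly one curation filter (misregulation). Functional
categories are drawn from fixed genome-wide proportions, with
regulatory target genes preferentially labelled with one category to
give the enrichment stage a planted signal.

What passing tests show: the pipeline recovers what it is designed to
recover under its own generative assumptions (point-source binding,
uniform background, independent reads). What they do not show:
robustness to mappability structure, GC bias, copy-number variation,
duplicated reads, or broad/composite binding — none of which the
generator emulates.

## Peak calling

The original analysis used a proprietary workbench; only its parameters
are published (100-bp window, Poisson distribution, 5% FDR, WT control,
2-of-3 technical-replicate retention). This implementation makes every
unstated choice explicit and configurable:

- non-overlapping window tiling (the last window may be truncated);
- library-size normalization `s = n_IP / n_ctrl`;
- null rate `λ = max(ε, s·k_ctrl, s·mean(k_ctrl))` with pseudocount
  ε = 0.5. The genome-wide floor `s·mean(k_ctrl)` is essential for
  error control: with a per-window plug-in estimate alone, windows
  where the control count fluctuates low produce arbitrarily small
  p-values under the null and the realized false-discovery proportion
  is uncontrolled. A single global floor (not a local background model)
  restores super-uniform null p-values at the cost of sensitivity only
  in regions of genuinely depressed background. It can be disabled
  (`CallerParams.global_lambda_floor = False`).
- upper-tail p-values via the Poisson survival function (stable in the
  far tail; no 1 − CDF subtraction);
- windows with zero IP reads are excluded from testing — they cannot be
  significant, and excluding them changes m in the step-up (documented,
  configurable via `min_ip_reads`);
- Benjamini–Hochberg step-up at q = 0.05; adjacent significant windows
  at gap ≤ 1 window are merged; the summit is the maximum of read-body
  coverage inside the merged span; fold enrichment is
  `K_IP / max(ε, s·K_ctrl)` over the span.

The replicate screen reruns the identical parameter set on each random
third of the IP reads and keeps full-data peaks overlapping (≥ 1 bp,
configurable) replicate peaks in at least 2 of 3 calls. Because the
workbench's exact algorithm is unpublished, the study's raw peak count
is not an equivalence target; the test suite instead checks FDR control
on null simulations (mean false-discovery proportion ≤ q within
Monte-Carlo error) and recall ≥ 0.9 on planted sites at 10× enrichment.

## Curation

The study's screen was performed by eye; `hetrseq` operationalizes it:

- **Fold filter**: fold enrichment ≥ 3, boundary inclusive.
- **Twin peak**: read-start tracks per strand are smoothed with a 25-bp
  moving average; summits are per-strand argmaxes within the peak; the
  correlation score is the best Pearson correlation between the plus
  track and the minus track shifted back by d over d ∈ [20, 400] bp
  (max_shift defaults to twice the mean fragment length). A peak
  qualifies when the summit shift is positive, at most max_shift, and
  the correlation reaches 0.5. Peaks with fewer than 10 reads on either
  strand are rejected with a NaN score.
- **Misregulation**: a flanking gene with |signed fold| ≥ 1.5 at 0 h or
  6 h. The threshold is deliberately permissive (the curated table
  contains |fold| values near 1) and configurable. Sentinel folds are
  indeterminate and never exclude a peak; one qualifying side suffices
  (the study does not say whether one or both sides were required).
- **Proximity**: "upstream" is defined on the neighbour gene's coding
  strand. A peak is within-500-bp-upstream when it overlaps
  `[start − 500, start)` of the gene's 5′ start; downstream-of-TSS when
  it lies wholly between a TSS assigned to the gene (same strand,
  within 1 kb of the start codon) and the start codon; not-applicable
  when entirely 3′ of the gene; beyond-500-bp-upstream otherwise. All
  four conditions are mirror-symmetric under genome reflection, which
  the suite verifies end to end. Overlap with an annotated 5′UTR also
  qualifies.

Every annotated peak carries an audit mapping filter → outcome, so the
raw-to-curated funnel can be reconstructed exactly.

## Motif scanning and consensus

The seed PWM derives from the printed site `GGGTCTAgCCCagCA`: an
uppercase base receives probability 0.91, a lowercase base 0.55, the
remainder uniform over the other bases, `N` equals the background. (The
actual matrix from the prior study is not available; these weights
render "strongly" and "weakly conserved" as sharp and soft columns
respectively.) The scanning background is the whole-genome 0-order
composition rather than the scanned regions' own composition, because
curated regions are a few hundred bases and their composition estimate
would be noisy; both are configurable.

Score p-values are exact up to discretization: per-column log-odds are
rounded to a 10⁻³-bit grid and the column score distributions under the
background are convolved, giving the full score distribution in one
pass; the placement error is bounded by width × grid (0.015 bits at
width 15). The suite checks the result against exhaustive 4^w
enumeration for widths ≤ 8. Zero-probability cells are floored at
10⁻¹² rather than scored −∞ so the distribution stays finite;
candidate k-mers containing such bases score far below any threshold.

Scanning evaluates both strands at every offset via the
reverse-complemented matrix; minus-strand hit coordinates refer to the
forward strand and matched sequences are reverse-complemented. When
both orientations of the same offset pass (a palindromic tie, which the
imperfect palindrome invites), the better-scoring orientation is kept,
the plus strand winning exact ties. No multiple-testing correction is
applied across scan positions (fixed-threshold scanning semantics);
q-values are out of scope.

The consensus is an ungapped stack of the equal-width, strand-corrected
matched sequences — a deliberate simplification of alignment-based
consensus building, justified because all hits share the scanning PWM's
width and register. Per-column information content is computed from raw
site frequencies relative to the background (2 bits maximum under a
uniform background); the IUPAC letter is the minimal code covering all
bases at frequency ≥ 0.25, uppercase at IC ≥ 1 bit. The output PWM adds
a background-weighted pseudocount of 0.25.

## Enrichment

`fold(c) = (hit fraction in c) / (genome fraction in c)` with the
number of distinct hit genes as denominator (a gene with several
categories counts once per category). A hypergeometric upper tail
accompanies each fold as a significance annotation. No ontology-graph
propagation and no correction across categories (raw p-values,
documented); enrichment at ≥ 3-fold is flagged inclusively.

## Reproducibility

A single master seed fans out to per-stage sub-seeds through a fixed
`SeedSequence` derivation; identical configuration and seed reproduce
byte-identical outputs, which the suite asserts file by file. Problem
sizes used by the test and acceptance runs — 1-Mb genome, 200k reads
per sample, 30 planted sites (or 10 regulatory + 5 decoys), 100 null
simulations at 50k reads — were chosen as the package's standard
desk-scale conditions.

## Known limitations

- Single-replicon analyses only in the curation CLI path (the caller
  itself handles multiple replicons).
- The Poisson test conditions on the control as a plug-in rate rather
  than modelling its sampling noise; the global floor compensates under
  the null but a joint binomial/conditional test would be sharper.
- The twin-peak detector assumes point-source binding; broad or
  composite binding modes will fail the shift bound.
- No operon inference: "misregulated neighbour" means the immediately
  flanking gene, not a downstream operon member.
- The by-eye judgments behind the study's own 38 → 26 reduction are not
  reproducible and are not a target; only the filters' structure is.
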