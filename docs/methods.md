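# Methods

This note describes the models and procedures implemented in
`grainmir`, the defaults they use, the numerical choices behind them,
and what the synthetic-data tests do and do not demonstrate about real
data.

## Read cleanup

Reads are canonicalised to uppercase DNA (U→T) at ingest; all internal
sequence space is DNA because genome matching is DNA-space, and
structures are converted back to RNA only for folding and display.

Adapter trimming removes the read suffix from the leftmost position
where a prefix of the 3′ adapter matches exactly over at least
`min_overlap` bases (default 6; a shorter match is accepted only when
the read ends before the adapter does). Reads with no adapter
occurrence are rejected rather than passed through: with a fixed
sequencing cycle count, a genuine 18–26 nt insert always runs into the
adapter, so an adapter-free read is not a credible insert. Adapter
sequence and overlap are configuration values — they are
platform-specific and no single default is universal.

Filtering drops reads outside 18–26 nt, reads containing N
(class `ambiguous`), and reads occurring as exact substrings of any
catalog contaminant on either strand. Catalog matching replaces a
repeat/ncRNA masking tool: it has the same contract (remove rRNA, tRNA,
snRNA, snoRNA fragments) without an external dependency, but it is only
as complete as the supplied catalog. Every removed read is attributed
to exactly one class, so

    raw = clean + no_adapter + empty + empty_insert + short + long
          + ambiguous + contaminant

holds identically; the test suite asserts this on every run.
Collapsing to unique sequences orders by descending count, then
lexicographically, making all downstream iteration order-deterministic.

## Genome placement

Mapping is exact, ungapped and both-stranded: zero mismatches is the
defining contract, and the multi-mapper policy is a cap (`max_hits`,
default 20) above which a read is flagged `multi_mapped_discarded`.
The cap emulates a repeat-reporting limit whose exact semantics differ
between aligners; it is configurable because no published default
governs it. The index is a 12-mer hash with verification extension —
purely an implementation detail, as the tests compare it against naive
full-string scans.

## Known-miRNA annotation

A read is compared gaplessly against each precursor window whose start
is within ±2 nt of an annotated mature start and whose end is within
±2 nt of the mature end (so the shift pair is determined by the read
length). Up to 2 substitutions are tolerated; no indels. The best
assignment minimises (mismatches, |shift5|+|shift3|, name) — a total
order, so matching is invariant under read reordering. Family names
collapse member letters, letter ranges, arm tags and `.N` variant
suffixes to the `miR<number>` stem (miR444b.2 → miR444, miR1874-5p →
miR1874). Family tables count read copies, not unique sequences, and a
read contributes once regardless of how many precursors of a family it
matches, avoiding double counting. miRNA\* status is decided from the
folded precursor: a read on the arm opposite the precursor's annotated
mature arm is a star; reads spanning the hairpin loop are
undetermined.

## Folding

Secondary structure is computed by maximum base pairing (Nussinov-style
dynamic programming) over Watson–Crick and G:U pairs with a minimum
hairpin loop of 3 nt. Maximum pairing, rather than free-energy
minimisation, was chosen because it is deterministic, parameter-free
and exactly checkable: the suite verifies the optimum against
exhaustive enumeration of all nested structures on random short
sequences. The traceback is made unique by pairing each position with
its leftmost optimal partner. The trade-off is physical realism: a
max-pairing structure can be denser than a thermodynamic one,
especially near the hairpin apex, which is why downstream steps avoid
relying on individual pairs (see star location below). The `fold.fold`
signature is the seam where a thermodynamic folder could be
substituted without changing any downstream contract. The O(n³) fill
is JIT-compiled when numba is available, with an identical pure-Python
fallback; inputs are capped at 300 nt, comfortably above the largest
excised window (read + 260 nt flank).

## Novel hairpin discovery

Each mapped read not explained by the known catalog anchors a window
search: for every extension d ∈ {20, 40, …, 260} one window reaching d
nt upstream and one reaching d nt downstream of the read (26 per hit
before clipping at chromosome ends; minus-strand windows are
reverse-complemented so the read is in sense orientation).

Within a folded window the star arm is located by projecting the
mature interval through the stem's antiparallel register: for paired
position i, i + partner(i) is constant along a clean helix, and the
modal register over all paired mature positions is robust to the
sloppy pairing a maximum-pairing fold produces near the apex. The
projected partner span is then shifted by 2 nt so each strand of the
duplex carries the canonical 2-nt 3′ overhang of a Dicer product. The
search requires ≥ 60% of mature positions paired — low enough that
near-perfect planted hairpins always pass, high enough that windows
without a genuine stem fail; fewer paired positions, a mature interval
spanning the loop, or a projected star overlapping the mature interval
all abort the window.

Duplex imperfections are counted between paired anchor columns:
symmetric unpaired columns count one mismatch each, and each maximal
run of unpaired bases on a single strand counts one bulge; terminal
3′ overhangs are free. Mismatches are counted per duplex column (i.e.
over mature-arm positions), not once per strand. Acceptance requires
mismatches ≤ 6, bulges ≤ 3, and at least one read whose hit lies
within ±2 nt of the predicted star interval — the same end tolerance
used for isomiR matching, reflecting Dicer-product heterogeneity. The
star-read requirement is the decisive false-positive guard: random
max-pairing folds frequently show stems, but a second independent read
population at the predicted star coordinates essentially never arises
from background.

Among a hit's windows, the accepted candidate with the fewest
mismatches + bulges, then the shortest precursor, is kept.
Overlapping candidate loci are then merged across strands — the
reverse complement of a hairpin is itself a hairpin, and star reads
rediscover their own precursor with the roles swapped — keeping the
candidate with the most mature-read support. This yields one row per
genomic locus.

## Target scoring

The penalty scheme (mismatch 1.0, G:U 0.5, gap 2.0, at most one
single-base gap, no terminal gaps, report sites ≤ 5.0) produces the
half-integer score ladder familiar from plant target-prediction
practice, with 0 a perfect site. No position-dependent (seed-region)
weighting is applied: the observed score range is reproducible without
it, and the per-column scorer is the seam where position weights could
be added. All window/gap placements are enumerated and the best score
per site interval is kept; the suite checks the scan against an
independently written brute-force oracle. Cleavage-site mapping
converts a clone 5′ end at transcript position t inside a site to the
1-based miRNA position `site_end − t` (the miRNA 5′ end faces the
site's 3′ end); ends outside the site are counted off-target.

## Chip analysis

Chips are (stage, replicate) pairs. Normalisation subtracts the
per-chip background mean (floored at 0) and scales each chip so its
median matches the cross-chip reference median, taken as the *lower*
median over chip medians — deterministic for any chip count. Median
scaling assumes most probes are unchanged between chips; analyses of
populations where every probe shifts (e.g. the simulated
multiplier-recovery property) use background subtraction only.

Detection requires mean > 3× background SD, CV < 0.5, ≥ 50% of spots
individually above 3× background SD, and mean ≥ 32 (the non-expressing
floor, applied to normalised signals). Fold changes are rounded
half-up to 2 decimals. t-tests are Student's two-sample tests on
log2(signal + 1) — the same scale used for clustering matrices; two
zero-variance groups with equal means give p = 1. Regulation applies
the 2-fold rule between consecutive stages, with probes never reaching
a mean of 100 excluded as `low_abundance` and conflicting directions
reported `unchanged` with the flag visible in the table rather than
silently resolved. No multiple-testing correction is applied by
default, matching the convention of reporting raw p-values for small
probe sets. 2^−ΔΔCt takes (treated, calibrator) Ct pairs for target
and reference and returns the relative fold.

## Synthetic data: what it does and does not show

The generator emulates the study conditions end to end: planted
hairpins whose star arm reverse-complements the mature arm (up to ≤ 6
deliberate mutations), a read-length mixture with 22.3% at 21 nt and
50.5% at 24 nt and the remaining lengths sharing the rest uniformly,
contaminant fragments drawn from a catalog, and chip signals
base × stage-multiplier × log-normal noise (unit mean; σ² = ln(1+CV²))
plus Gaussian background. Category counts come from one multinomial
draw, so they sum exactly to the requested read number, and every
generator derives its substream deterministically from a single
integer seed, making all outputs bit-reproducible.

What passing tests show: the pipeline's logic is internally coherent —
planted signals are recovered with recall 1.0 and zero background
false positives on an i.i.d. ACGT genome, category accounting is
exact, and planted chip multipliers are recovered within a few
percent. What they do not show: performance on real genomes (repeats,
segmental duplications and miRNA families violate the i.i.d.
background and the one-candidate-per-locus merge), real sequencing
error (only ±2-nt end shifts are modelled, no substitutions or
quality effects), real chip artefacts (no cross-hybridisation, dye or
spatial effects), or thermodynamic folding accuracy (max pairing is a
combinatorial surrogate). Fixture sizes (tiny: 1 × 10 kb chromosome,
3 novel + 1 known hairpin, 3,000 reads, 12 probes; demo: 20 kb, 5 + 2,
20,000 reads, 40 probes) were chosen so a full run completes in
seconds while every stage still sees non-trivial input.

## Known limitations

- Loop detection for star assignment uses the innermost pair of the
  fold; on precursors with strongly self-structured loops the
  5p/3p boundary can shift by a few nucleotides (reads near the loop
  may be called undetermined).
- Genomic-context annotation of candidates (intergenic/intron/UTR) is
  reported only when the caller supplies annotation; it is `NA`
  otherwise.
- The target scanner allows at most one gap and no seed-region
  weighting; heavily bulged sites score worse than a
  thermodynamics-aware predictor would report.
- Detection-call repeat-probe logic treats replicate signals as the
  repeating spots; within-chip duplicate spots are not modelled
  separately.
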