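# Methods

## The measurement being modelled

A 4C-seq experiment converts spatial proximity to one bait restriction
fragment into read counts over all other fragments. The double-digestion
protocol modelled here (primary NlaIII/`CATG`, secondary DpnII/`GATC`)
produces 100 bp single-end reads with a fixed anatomy: an inline sample
barcode, then the bait fragment's 3'-terminal segment ending in the
primary-enzyme site, then the sequence of whichever fragment was ligated
to the bait. Two read classes are artefacts of the chemistry rather than
contacts: *self-ligation* reads, where the bait circularised onto
itself, and *undigested* reads, where the bait-end site was never cut
and the read continues into the genomically adjacent fragment. Both are
removed before quantitation.

## Generative model

The simulator draws a uniform-random reference (seeded; retried
deterministically until it contains ≥ 20 primary sites and a bait
fragment carrying ≥ 1 secondary site), digests it in silico, and builds
a per-condition contact profile over fragments:

* baseline weight of fragment *i*: `(1 + |mid(i) − mid(bait)|)^(−α)`
  with decay exponent α = 1 by default. No generative contact model is
  implied by the protocol itself; a power law is the standard stylised
  form of contact-frequency distance decay and produces the
  characteristic near-bait enrichment of viewpoint tracks while keeping
  recovery tests non-trivial.
* planted fold changes: each entry `(interval, condition, fold)`
  multiplies the weights of all fragments overlapping the interval, for
  that condition only, before renormalisation. A point interval selects
  the single containing fragment. Folds perturb other fragments only
  through the partition sum, so the expected measured ratio at a planted
  region is `F · Z_ref / Z_alt`, slightly shrunk toward 1 — a real
  property of count-share data, not an artefact.
* the bait fragment, the two bait-adjacent fragments, and fragments
  shorter than `min_capture_length` (default 20 bp) are forced to zero
  probability. The first is definitional (self-ligation is not a
  contact). The adjacent fragments are zeroed because reads landing
  there are *operationally indistinguishable* from undigested
  read-through — the filter removes them regardless, so a model that
  placed genuine contact mass there would simply be simulating signal
  the pipeline is required to discard. Very short fragments are excluded
  because their reads cannot be uniquely assigned (the same fragments
  are effectively unmappable for an aligner on real data).

Reads are then a seeded three-way mixture: `undigested_fraction` of
reads read straight through the uncut bait-end site into genomic
sequence (defaults 0.10 undigested + 0.05 self-ligation; real 4C
libraries vary widely, and both parameters are explicit), the
self-ligation fraction recaptures the bait, and the remainder sample
fragments from the contact profile. Every read carries its source
fragment and category in a truth table. The model deliberately omits
PCR duplicates, sequencing errors, paired ends and chimeric junctions;
consequently, passing recovery tests demonstrates the correctness of
the extraction arithmetic, not robustness to base-calling noise or
mapping ambiguity on a repetitive genome.

## Extraction pipeline

Demultiplexing requires a unique nearest barcode within
`max_mismatches` (default 0; ties are unassigned; prefix-nested barcode
tables are rejected outright). Trimming removes the bait-end segment —
defined as the bait fragment's terminal 20 bp plus the primary motif,
mirroring where a common reverse primer would sit — and flags reads
without it as non-bait.

Assignment realises the "uniquely mapping reads only" contract
explicitly: a read is assigned iff its first `min_match_length` bases
(default 20) equal the genomic k-mer beginning at exactly one fragment
start. Keys extend past a fragment's own end when the fragment is
shorter than k, which is what an aligner's start-position assignment
would do and is required for undigested read-through to land on the
adjacent fragment even when that fragment is tiny. A `both_ends` mode
additionally indexes reverse-complemented fragment ends for libraries
captured from either strand. For externally aligned data, `assign_sam`
applies a literal `MAPQ ≥ 42` filter and assigns by alignment start.

The bait-proximal filter zeroes the bait fragment (tallied as
self-ligation) and the adjacent fragments (tallied as undigested).
Filtering both, with separate tallies, is a deliberate choice: only the
adjacent fragment is strictly an undigestion artefact, but the bait's
own count is uninformative for contacts in any reading. The module
maintains exact accounting — assigned + bad-barcode + non-bait +
unmapped + ambiguous + filtered equals the input read count.

## Quantitation

Fixed windows attribute each fragment to the window containing its
start coordinate (a convention; the oracle tests use the same one), and
cross-library normalisation scales every track *up* to the
highest-coverage library so the reference track's values are preserved.
Adaptive windows close greedily at the first fragment where the
combined cross-sample count reaches the target; the terminal remainder
window is kept. Relative scores divide by the sample's assigned total
(the `assigned` depth basis; the pre-filter library size can be used
instead via `per_million`). Differences are plain subtraction on
identically normalised tracks — no pseudo-counts and no log transform,
so a lost contact is exactly the negative of the equivalent gain.
bedGraph output carries sample/scheme/normalisation in the header and
serialises scores to 6 significant digits.

## Validation studies and their sizes

The study sizes were chosen to give each check clear statistical room
on one CPU: digestion against a naive substring-scan oracle on 100
random 10 kb sequences; exact accounting on a 4-barcode, 40 000-read
lane; the undigested filter at fraction 0.2 with 100 000 reads
(binomial SE ≈ 0.0013, well inside the ±0.01 band); and fold-change
recovery on a 200 kb reference with 200 000 reads per sample and 20
seeded replicates.

In the recovery study, condition B carries planted folds of 2, 3 and 5
at three 10-kb regions and 0.5 at a fourth ("looped-out") region, each
spanning one track window. Window-sized regions are the honest analogue
of real enhancer/super-enhancer peaks, which manifest coherently at
track resolution; a single ~250 bp fragment among ~40 per window would
be averaged away by construction (expected window ratio
`(39 + F)/40`), making window-level recovery impossible for any
correct pipeline. With window-sized regions the expected measured ratio
is `F/Z_B` with `Z_B ≈ 1.18` under these conditions, i.e. recovery
within ~15% of the planted fold, and the subtraction track's sign at
the planted windows is essentially deterministic at this depth.

## Numerical and degenerate-input choices

Cuts sit at motif *ends*, applied uniformly to both enzymes;
overlapping motif occurrences each cut; `N` never matches. A motif
occurrence ending exactly at the sequence end produces no empty
terminal fragment. Boundary coordinates are half-open, so a bait
position on a fragment boundary belongs to the rightward fragment.
Probability renormalisation tolerances are 1e-9 (profile sums) and the
relative-track sum is exact to 1e-12 by construction. Standard-curve
fitting is ordinary least squares on log10 quantity (scipy linregress);
degenerate designs (< 3 points, a single distinct quantity,
non-positive quantities) raise rather than fit. Negative
background-subtracted ChIP signals floor at 0 with a warning instead of
propagating. The 3C "linear range" control is operationalised as the
first interior titration point whose Ct is strictly between the
titration extremes and whose centred-difference local slope is within
15% of the fitted slope (configurable).

## Known limitations

Single-chromosome references only (multi-record FASTA digests
per-record in the CLI, but the simulator and trans contacts are out of
scope). The internal assigner is exact-match; it is an arithmetic
reference for the uniqueness contract, not a substitute for alignment
on real, error-containing data — use the SAM path for that. The
adaptive-window rule is the greedy ≥-target form; other readings
("approximately equal counts") would shift window boundaries slightly.
No statistical significance calling is attempted on difference tracks.
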