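# fourc

Quantitation of 4C-seq viewpoint interaction profiles, with a
ground-truth simulator and the companion qPCR arithmetic used in
chromatin-conformation studies.

Circularised chromosome conformation capture with sequencing (4C-seq)
measures which genomic regions contact one chosen "bait" restriction
fragment — typically a gene promoter — in three-dimensional nuclear
space. Chromatin is fixed, digested with a primary enzyme (NlaIII,
`CATG`), ligated, re-digested with a secondary enzyme (DpnII, `GATC`)
and re-ligated; inverse PCR outward from the bait then amplifies every
captured partner fragment, and single-end sequencing reads of the form

    [inline barcode][bait-end segment ... CATG][captured fragment sequence]

report one contact each. `fourc` implements the complete extraction and
quantitation path from such reads to genome-browser-ready interaction
and differential tracks, for people analysing viewpoint experiments
(e.g. enhancer–promoter rewiring between two cell states) or developing
methods against simulated truth.

## What it computes

For fragment *i* with per-sample read count `n_i` after demultiplexing,
bait trimming, unique assignment and bait-proximal filtering:

* **Fixed-window (absolute) tracks** — `S_w = Σ_{i: start(i) ∈ w} n_i`
  over 10 kb windows *w*, cross-normalised so each library's total is
  scaled up to the deepest library
  (`S_w ← S_w · max_j N_j / N`), optionally expressed per million
  sequenced reads.
* **Adaptive-window (relative) tracks** — windows grown left to right
  until the combined cross-sample count reaches a target (default
  50 000), then `S_w = (Σ_{i∈w} n_i) / N` so each sample's scores sum
  to 1 regardless of depth.
* **Difference tracks** — windowwise `S_w^A − S_w^B` on identically
  normalised tracks; positive values are gained contacts, negative
  values lost contacts.
* **Filtering** — reads from the bait fragment itself (self-ligation)
  and from bait-adjacent fragments (undigested chromatin) are removed
  and tallied before any quantitation, and every input read is accounted
  for in exactly one category.
* **qPCR quantities** — standard-curve fitting
  `Ct = intercept + slope·log10(q)` and inversion; ChIP percent input
  `100·(IP − noAb)/(input/input_fraction)`; 3C interaction frequency
  `library / linear-range control`; RT-qPCR fold change
  `(target/reference)/calibrator`.

The built-in simulator generates references with realistic restriction
structure, condition-specific contact profiles with power-law distance
decay and planted enhancer fold changes, barcoded reads with tunable
undigested/self-ligation fractions, and a per-read truth table — so
every pipeline stage is testable against known ground truth.

## Worked example

Two conditions on a 200 kb reference, bait at 100 kb, with a 3-fold
contact gain planted at 140–150 kb in the "infected" condition,
200 000 reads per sample:

```python
from fourc import *
from fourc.synthetic_data import SimulationConfig, EnhancerFold

config = SimulationConfig(
    sequence_length=200_000, bait_position=100_000, reads_per_sample=200_000,
    enhancer_folds=(EnhancerFold(140_000, 150_000, "infected", 3.0),),
    undigested_fraction=0.1, self_ligation_fraction=0.05, seed=42,
)
ref = generate_reference(config)
fmap = ref.fragment_map
tracks = {}
for cond, bc in [("uninfected", BarcodeSpec("uninfected", "TGCACC")),
                 ("infected", BarcodeSpec("infected", "ACGTGG"))]:
    profile = build_profile(fmap, config, cond, ref.bait)
    reads, truth = simulate_reads(ref, fmap, profile, bc, config)
    res = process_library(reads, [bc], ref.sequence, fmap, ref.bait,
                          ref.bait_end_sequence())
    tracks[cond] = fixed_window_track(res.count_vectors[cond], fmap, 10_000)
a, b = normalize_to_max_library([tracks["uninfected"], tracks["infected"]])
d = subtract_tracks(b, a)
```

prints (via the obvious `print` statements):

```
fragments: 737  bait fragment: 349
uninfected: assigned=170051 undigested=20032 self=9917
infected: assigned=170163 undigested=19842 self=9995
enhancer window [140000,150000): uninfected=4697.1 infected=13082.0 ratio=2.79 difference=8384.9
```

Reading this: ~15% of each library is removed as undigested or
self-ligated (the planted 0.10 + 0.05), the remaining reads form the
tracks, and at the planted enhancer window the normalised score ratio
(2.79) recovers the simulated 3-fold gain — slightly shrunk because the
gained contacts also enlarge the infected library's total — while the
difference track is strongly positive there. `write_bedgraph(d, "chrS",
"diff.bedgraph")` serialises any track for a genome browser.

The same pipeline is available from the shell:

```bash
fourc simulate --length 200000 --seed 42 --reads 200000 \
      --barcode-table barcodes.tsv --out-dir sim/
fourc extract --fastq sim/reads.fastq --fasta sim/reference.fa \
      --barcode-table barcodes.tsv --bait-position 100000 --out-dir counts/
fourc quantitate counts/*.counts.tsv --fragments sim/fragments.bed \
      --window 10000 --out-dir tracks/
fourc diff tracks/infected.bedgraph tracks/uninfected.bedgraph --out diff.bedgraph
```

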