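# doublebox

Analysis toolkit for mapping bacterial replication-initiator (DnaA) binding
from ChIP-seq coverage and testing whether a **double DnaA box** — two 9-mer
DnaA boxes (consensus `TTATCCACA`) whose cores are separated by 2–3 bp —
predicts in-vivo binding better than the classical single box.

It is aimed at bacterial regulatory genomicists who have replicate
ChIP/control coverage tracks for a single replicon and want a reproducible,
fully scriptable version of the region-calling → motif → genome-scan →
rank-recovery analysis, plus a synthetic-data generator so the whole pipeline
can be validated against planted ground truth without any external download.

## What it computes

1. **Bound-region calling.** Point peaks are detected in the smoothed ratio
   of replicate-averaged ChIP to control coverage (or supplied as a BED
   file), merged when closer than 100 bp (single linkage), and scored as
   *coverage relative to control*: the mean normalized ChIP coverage over a
   201 bp window centred on the region, divided by the same quantity for the
   control. Regions scoring below 3, or inside excluded (e.g. repetitive)
   intervals, are discarded.
2. **Single-box PWM.** 101 bp windows around retained region centres go
   through a seeded-EM motif finder (any number of occurrences per window,
   both strands, default width 11 = one flank + 9-mer core + one flank); the
   PWM is then rebuilt from the identified site sequences:
   `p_ij = (c_ij + α·b_j) / (n + α)` with pseudocount α distributed by the
   background composition *b*.
3. **Double-box PWMs.** Tandem composition of the single-box matrix: plain
   concatenation puts the two cores 2 bp apart (width 22); inserting one
   background-distributed column puts them 3 bp apart (width 23).
4. **Genome scanning with exact p-values.** Windows on both strands are
   scored by log-odds, `S = Σ_i log2(p_i[x_i] / b[x_i])` (bits), and
   converted to p-values from the exact distribution of the discretized
   score under the 0-order background, computed by positionwise convolution
   (0.001-bit bins). Matches with p ≤ 1e-4 are reported.
5. **Predictive-power comparison.** Hits from the 2 bp and 3 bp double-box
   scans are pooled, deduplicated and ranked by score; each bound region is
   assigned the best-ranked hit within 100 bp of its centre; the cumulative
   recovery curve (regions recovered vs. rank) is compared between the
   single-box and double-box models.

A synthetic-data module generates genomes with planted single/double boxes of
known spacing, mismatch load and enrichment strength, plus replicate
negative-binomial ChIP/control coverage with Gaussian enrichment bumps, so
every stage is testable against known truth.

## Worked example

```bash
doublebox simulate --profile small --seed 1 --out demo
# wrote 7 files to demo (8 planted sites)

doublebox run --genome demo/genome.fa \
    --chip demo/chip_1.bedgraph --chip demo/chip_2.bedgraph \
    --control demo/control_1.bedgraph --control demo/control_2.bedgraph \
    --seed 1 --out demo/out
# 5 regions; double-box reaches 80% recovery at rank 4, single at rank 8
```

The 50 kb `small` fixture plants five strong double boxes (spacings 2 and 3,
strengths 8–10) and three weak sites. The run retains five bound regions:

```
#centre  label  relative_coverage  n_peaks  excluded  reason
7101            5.657              1        False
27706           5.5256             1        False
36086           4.8549             1        False
41162           5.9994             1        False
48004           6.0474             1        False
```

Each centre lies within ~10 bp of a planted strong site and each relative
coverage is close to its simulation expectation (≈ (1 + 0.76·strength)/1.25
for the default 75 bp bump and 0.25 denominator pseudocount). The comparison
table (`demo/out/comparison.tsv`) shows the double-box model recovering the
regions faster than the single-box model at every rank:

```
#n_regions  area_between  b_dominates  rank80_single  rank80_double
5           12.0          True         8              4
```

Stage outputs (`regions.tsv`, `motifs.meme`, `hits_*.tsv`,
`associations_*.tsv`, `curve_*.tsv`, `manifest.json`) are plain text so any
stage can be inspected, bypassed or substituted; the manifest records the
full configuration and seed needed to reproduce every byte.

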