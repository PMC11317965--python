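# Methods

## The model

DnaA binds 9 bp boxes (consensus `TTATCCACA`). The analysis asks whether the
preferred in-vivo binding unit is a *double* box — two 9-mer cores on the
same strand separated by 2 or 3 bp, the footprint of a DnaA dimer — rather
than a single box. The package operationalizes this as a model comparison:
a single-box PWM learned from bound regions versus tandem double-box PWMs at
2 and 3 bp core spacing, compared by how early ranked genome-wide matches
recover the ChIP-defined bound regions.

## Region calling

Coverage tracks are per-base depths, depth-normalized so each track sums to
the genome length (mean normalized depth 1); this makes replicate averaging
well-defined and makes the ChIP/control ratio unit-free. Peak detection is a
deliberately simple stand-in (the upstream caller used for the original data
is external to this package): the replicate-averaged ChIP and control tracks
are Gaussian-smoothed (default sd 50 bp), their ratio — with a 0.25
pseudocount in the denominator — is thresholded at `min_fold` (default 2.5),
and local maxima are thinned to a 100 bp minimum separation, higher maxima
winning. A user-supplied peak BED bypasses detection entirely.

Aggregation merges consecutive peaks with gaps strictly below 100 bp
(single linkage); a gap of exactly 100 bp splits. The region centre is the
midpoint of the first and last member peaks, rounded half up. Scoring uses
the window *mean* of normalized depth over 201 bp (ratio is identical to the
window sum for equal-length windows); the 0.25-normalized-unit denominator
pseudocount guards against zero control coverage, which the original
description leaves unspecified. Filtering is strict (`ratio < 3` discarded;
exactly 3 retained) and exclusion intervals drop regions by centre
membership; dropped regions are kept in the output flagged with a reason.

## Motif discovery and PWM construction

The finder is a seeded EM stand-in for MEME's any-number-of-repetitions
mode, not a MEME port. Candidate sites are all width-mers of both strands of
the input windows. Seeds are the most over-represented width-mers, counted
over a 2-mismatch Hamming ball so planted occurrences that differ only in
flanking bases reinforce a common seed; seeds are deduplicated by canonical
(lexicographically smaller of forward/reverse-complement) orientation, ties
broken lexicographically for determinism. Each seed initializes a
two-component mixture (motif vs. 0-order background) with per-site occupancy
`z_i = γ·LR_i / (γ·LR_i + 1 − γ)`; EM iterates until the motif information
content changes by < 1e-6 (cap 200 iterations). Among refined seeds the
winner maximizes total information content (per-motif IC × expected
occurrence count) — a proxy for the log-likelihood ratio that, unlike raw
IC, is not fooled by a sharp two-occurrence chance repeat.

The scanning PWM is then *rebuilt* from the hard-called site sequences
(z > 0.5, one orientation per locus) with pseudocount 0.1 distributed by the
background — mirroring the two-step procedure of identifying enriched
sequences first and generating the PWM from them. The site alignment
legitimately includes imperfect boxes (bound regions' double boxes often
pair one perfect with one 5–7/9 core), so core columns carry probabilities
around 0.8–0.97 rather than being near-deterministic.

Motif width defaults to 11 (one flank per side of the 9-mer core): with
flanks f, plain tandem concatenation spaces the cores 2f apart, so f = 1
makes plain concatenation exactly the 2 bp double box and one inserted
background column the 3 bp form. Other widths are allowed, with supported
spacings reinterpreted as 2f and 2f+1.

## Scanning and exact p-values

Log-odds scores in bits against a 0-order background (strand-averaged base
composition of the scanned genome by default, so forward and reverse scans
are symmetric). Per-column scores are floored into 0.001-bit bins; the exact
distribution of the binned window score under the background is built by
columnwise convolution, and p(s) = P(score ≥ s) comes from its tail, making
reported p-values conservative to one bin. The scanner computes window
scores in the same binned space, so scan decisions and the DP table are
exactly consistent (verified against brute-force enumeration over all 4^w
k-mers for w ≤ 6). Windows containing N are never scored. The p ≤ 1e-4
reporting threshold is inclusive. Overlapping hits, including self-overlaps
of the tandem motif, are all reported.

## Ranking and recovery

Hits from one or more scans are pooled; duplicates — identical (start,
strand, motif) — keep the higher score; sorting is score-descending with
ties broken by p-value, then start, then strand (+ first). A region is
associated with the lowest-ranked hit whose *nearest base* lies within
100 bp of the region centre (configurable to hit start or midpoint;
nearest-base is the most permissive defensible reading). The recovery curve
counts regions with best rank ≤ r; curve comparison reports ranks at
50/80/100 % recovery, the per-rank difference and its area, extending the
shorter curve flat.

## Synthetic data

The generator emulates the study design: an i.i.d. background genome
(default GC 0.5) with planted sites, and replicate ChIP/control coverage.
Control coverage is negative binomial around a background mean of 10 reads
(dispersion 0.2 — ChIP coverage is overdispersed relative to Poisson); ChIP
coverage adds a Gaussian bump per plant (sd 75 bp, a stand-in for
fragment-length smearing) of height strength × background mean. With those
defaults a plant of strength s scores a relative coverage of roughly
(1 + 0.76 s)/1.25, so strength 5 sits comfortably above the retention
threshold of 3 and strength ≤ 1 comfortably below.

The `paper-like` profile (500 kb, 30 plants) mirrors the structure of the
real bound-region table: the region-forming plants (strength ≥ 5) are double
boxes at 2/3 bp spacing — consensus pairs and pairs with one 2-mismatch box,
as in the published table — plus one strongly enriched site with no box at
all (the analogue of the bound region for which no double box exists). Weak
plants (strength ≤ 1) comprise spacing mutants of the purH-like arrangement
(7/9 box + perfect box with the spacer widened to 4 bp — the published
spacing-mutant series operates on exactly that site), doubly-mutated
doubles, and isolated consensus boxes, reflecting the observation that most
genomic consensus boxes are not detectably bound. What the generator does
*not* emulate: mappability/repeat artefacts, GC bias, read-level noise,
cooperative occupancy — so passing tests demonstrate correctness of the
computational pipeline under its stated noise model, not performance on real
libraries.

Determinism: one master seed; background, plant realization and each
coverage replicate use fixed substreams, so outputs are bit-reproducible and
adding plants does not reshuffle the background.

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED/bedGraph conversion
  happens only at I/O boundaries. Scanning treats genomes as linear;
  window extraction may wrap only on circular genomes when the caller opts
  in.
- Region centres at half-integer midpoints round half up.
- Degenerate inputs: empty peak lists, no retained regions, or too few
  motif windows end the pipeline cleanly with a manifest, not an error.
- Problem sizes in the validation study (500 kb genomes, 10 replicate
  seeds, width ≤ 6 exhaustive enumeration) were chosen to exercise every
  stage at full fidelity while keeping a complete run in tens of seconds.

## Known limitations

- The spacing-discrimination margin at p ≤ 1e-4 is structurally thin for
  the 2 bp tandem model: `TTATCCACA` matches itself at 3/9 positions under
  a 2 bp shift, so a double box whose spacer is widened to 4 bp still
  matches about 12 of the 2 bp-model's 18 core columns — and for a
  22-column PWM with realistically soft columns the genome-wide 1e-4
  quantile sits near that score. Widened-spacing sites therefore score
  orders of magnitude worse than matched-spacing sites (p ~ 1e-3 vs
  ~ 1e-11) yet occasionally scrape past the permissive 1e-4 reporting
  threshold. The rank-based comparison, not the raw threshold, carries the
  discriminative signal.
- Curve dominance at *every* rank can be broken in the deep tail when a
  chance background hit lands within 100 bp of the boxless region,
  crediting the single-box curve with a region the double-box curve never
  recovers; the acceptance script reports the observed dominance rate.
- Single replicon only; no multi-chromosome support, no FDR/q-values, no
  higher-order background models.
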