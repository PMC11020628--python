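# ltrscout

Signature-based detection of LTR-retrotransposons in genome assemblies.

`ltrscout` scores a genome by bidirectional k-mer match distances (a
forward track of nearest-downstream-copy distances and a backward track of
nearest-upstream-copy distances), groups the scores into stretches with a
statistical merging procedure, finishes assembling candidate LTRs with a
trained linear classifier over repeat-content features, pairs candidate
LTRs in a directed-weighted graph whose connected components resolve
single elements, solo LTRs, recently nested and deeply nested insertions
and sequential same-family runs, and confirms every element with
structural filters: LTR length and similarity, a polypurine tract, a MITE
(terminal-inverted-repeat) exclusion test, and target-site duplications.

Because the repeat profile is learned from the input itself, several
related genomes can be supplied at once: the profile is trained on their
union and predictions are reported per input sequence (cross-species
mode).

## Layout

| module | role |
| --- | --- |
| `ltrscout.sequence_io` | FASTA input, BED/GFF3 output, annotation types |
| `ltrscout.synthetic_data` | synthetic genomes with planted elements + truth; semi-synthetic shuffling |
| `ltrscout.scorer` | forward/backward k-mer match-distance tracks (k=13, window 400–27,000 bp) |
| `ltrscout.merger` | stretch building and the seven-step statistical merge (similarity margin 75 bp) |
| `ltrscout.repeat_profile` | genome-wide repeat scores (fold over a Markov-background expectation) |
| `ltrscout.detector` | 10-feature linear pair-merge classifier; LTR candidate assembly (≥ 200 bp) |
| `ltrscout.identity` | exact global identity (Needleman–Wunsch) with standard/recent operating ranges |
| `ltrscout.matcher` | match graph, hyper-extension trimming, five-case component resolution with recursion for deep nests |
| `ltrscout.extender` | k−1 boundary extension and missing-region extension |
| `ltrscout.filter_postprocess` | length/similarity/PPT/MITE filters, orphan-solo removal, TSD post-processing |
| `ltrscout.evaluation` | 80% reciprocal-overlap TP/FP, recall/precision/F1, coverage |
| `ltrscout.pipeline` | end-to-end orchestration |

A pre-trained pair-merge model (trained on packaged synthetic fixtures)
ships in `src/ltrscout/data/default_model.json`, so `ltrscout detect`
works out of the box; `ltrscout train` regenerates it.

## CLI

```sh
# detect elements in one or more genomes (multi-genome = cross-species mode)
ltrscout detect genome.fa [more.fa ...] --out results/ --bed --gff

# simulate a genome with planted elements and exact truth
ltrscout simulate --spec families.yaml --length 1000000 --seed 1 --out sim

# shuffle inter-element regions, keeping truth elements in place
ltrscout semisynth --fasta sim.fa --truth sim.truth.bed --seed 1 --out semi.fa

# compare predictions with a truth BED (80% reciprocal overlap)
ltrscout eval --pred results/ltrscout.bed --truth sim.truth.bed

# retrain the pair-merge classifier
ltrscout train --seed 1 --out model.json
```

`ltrscout detect --config config.yaml` overrides any numeric constant
(scorer window, merger gap statistics, matcher thresholds, filter
lengths); see `ltrscout.pipeline.PipelineConfig` for the keys.

## Output

BED (0-based half-open, default) and/or GFF3 (1-based inclusive) with the
element span, both LTRs, the polypurine tract (with orientation), the
target-site duplication, the nesting level and parent reference for nested
elements, and a shared-LTR group id for overlapping survivors that share
an LTR. Solo LTRs and complex regions (sequential same-family runs) are
reported as their own feature kinds.
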