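# atacbind

Motif-centric transcription-factor binding-site classification from
paired-end ATAC-seq data.

`atacbind` converts ATAC-seq fragments into a 9-channel per-base signal
window around each motif-predicted binding site (MPBS) and classifies bound
vs. unbound sites with a small multi-kernel 1D convolutional network:

* **Input tensor (9 × 1000 per site):** one footprint-score channel
  (flank-minus-center depletion of pooled Tn5 cut counts), four normalized
  cleavage-signal channels and four slope channels, split by read strand ×
  fragment-size class (≤ / > one nucleosome, 147 bp). No Tn5 sequence-bias
  correction is applied anywhere.
* **Model:** parallel 1D convolutions with kernel sizes 3/5/7 (3 filters
  each, ReLU), cross-filter max-pooling per position, concatenation, two
  fully connected layers, sigmoid output. Implemented in pure numpy
  (hand-derived gradients + Adam) — no deep-learning framework required.
* **Protocol:** MPBSs from PWM scanning at a p-value-derived threshold
  (exact DP over the background score distribution), restricted to ATAC
  peaks, labeled bound/unbound from ChIP-seq summits (closest-within-50-bp
  rule), class-balanced, split 70/20/10. Training uses minibatch 35,
  iterations of 10 shuffled epochs, keeping the 3 lowest-validation-loss
  snapshots; predictions are the ensemble mean, with bound (> 0.5) and
  constitutive (> 0.95) calls.
* **Evaluation:** rank-based AUROC, two baseline scoring procedures
  (mean footprint score per MPBS; PWM score + max-score bonus for
  footprint-region overlap), and Friedman–Nemenyi rank comparison across
  methods.
* **Simulator:** fully self-contained synthetic fixtures (genome + planted
  motifs, fragments with configurable footprint depth, bimodal fragment
  sizes, strand-asymmetric cut patterns, ATAC/ChIP narrowPeak files and a
  truth table), so the whole pipeline is testable without downloads.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(synthetic classification AUROC, null control, baseline ordering, variant
degradation, oracle equivalences, protocol invariants, labeling
correctness).

## CLI

Every subcommand writes a `run_manifest.json` (command, config, seed, input
checksums) next to its outputs. BED fragment input is assumed pre-shifted;
BAM/SAM input gets the +4/−5 Tn5 shift on read.

```sh
atacbind simulate --out sim/ --seed 7 --genome-len 200000 \
    --n-bound 100 --n-unbound 100 --footprint-depth 0.2
atacbind scan    --genome sim/genome.fa --pfm sim/motif.pfm --out mpbs.tsv
atacbind label   --mpbs mpbs.tsv --atac sim/atac_peaks.narrowPeak \
                 --chip sim/chip_peaks.narrowPeak --out labeled.tsv
atacbind dataset --labeled labeled.tsv --fragments sim/fragments.bed \
                 --genome sim/genome.fa --out data/ --seed 7
atacbind train   --data data/ --out model/ --seed 7 --max-iterations 20
atacbind evaluate --data data/ --ensemble model/ensemble.json \
                 --fragments sim/fragments.bed --genome sim/genome.fa --out eval/
atacbind predict --data data/ --ensemble model/ensemble.json --out preds.tsv
atacbind signal  --fragments sim/fragments.bed --genome sim/genome.fa \
                 --out tracks/ --region chrSim:0-5000   # bedGraph export
```

Input layout variants for ablation are available via `dataset --layout`:
`variant1` (no footprint channel), `variant2` (footprint only), `variant3`
(strands pooled), `variant4` (fragment sizes pooled); `--window-half`
shortens the window (e.g. 50/100/250).

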