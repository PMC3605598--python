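# flowdedup

Duplicate-read filtering for 454 pyrosequencing data, operating directly in
flow space. Reads are clustered by a Bayesian distance on raw flow values:
a posterior over homopolymer lengths is computed per flow value, the
probability that two flow values encode the same homopolymer length is
combined across flows into a pairwise flowgram distance, and agglomerative
clustering with per-flow-median consensus flowgrams groups artificial
duplicates. One representative per cluster is emitted (`longest`, `best` or
`consensus` mode). Clusterings can be scored against ground truth with a
pair-counting Jaccard index.

## Command line

```sh
# generate a synthetic dataset with known duplicate structure
flowdedup simulate --output run.sff --truth truth.tsv \
    --templates 800 --rate 0.2 --seed 1

# cluster duplicates and write representatives (.sff or .fasta by extension)
flowdedup dedupe --input run.sff --output reps.sff \
    --membership predicted.tsv --threshold 0.05 --mode longest

# compare a predicted clustering against the truth
flowdedup evaluate --truth truth.tsv --pred predicted.tsv

# duplicate rate and Jaccard index across stringency thresholds
flowdedup sweep --input run.sff --truth truth.tsv \
    --thresholds 0.0,0.01,0.02,0.05,0.1 --output report.tsv
```

A distance threshold of 0.05 is a good starting point; higher thresholds
remove more reads. `dedupe` always writes a `read_id TAB cluster_id`
membership sidecar next to the representative output.

## Probability model

By default a parametric stand-in model is used: a geometric prior over
homopolymer lengths and truncated-normal flow-value likelihoods whose width
grows with homopolymer length and flow cycle. Empirical distributions can be
supplied instead via `--model-table`, a tab-separated file with a prior
section (`prior <TAB> h <TAB> probability`) and binned likelihood rows
(`likelihood <TAB> cycle_bin <TAB> h <TAB> f_low <TAB> f_high <TAB>
density`); `flowdedup.flow_model.export_lookup_table` writes this format.

## Library layout

| module          | contents                                                  |
| --------------- | --------------------------------------------------------- |
| `flowgram_io`   | `Flowgram` record, SFF read/write (via Biopython), FASTA  |
| `flow_model`    | prior/likelihood/posterior, equal-length probability      |
| `distance`      | pairwise flowgram distance over trimmed shared flows      |
| `precluster`    | flow-sign seed binning with recursive seed extension      |
| `cluster`       | agglomerative clustering, median consensus, `dedupe`      |
| `representative`| longest / best / consensus output selection               |
| `evaluate`      | truth from SAM, duplicate rate, Jaccard, threshold sweep  |
| `simulate`      | synthetic flowgram datasets with exact truth partitions   |
| `cli`           | `flowdedup` entry point                                   |

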