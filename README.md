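# repahr

De novo repeat identification from NGS short reads by assembly of
**high-frequency reads**.

Instead of assembling high-frequency k-mers directly, the pipeline

1. counts canonical k-mers from the reads (k = 15 for the spectrum, k = 31
   for filtering),
2. builds the k-mer frequency histogram f(t), locates its main peak p and
   estimates the average read coverage `Cov = p·L / (L − k + 1)` (skipped
   when a known depth is supplied),
3. derives the high-frequency threshold `t1 = ceil(c · Cov)` with
   c ∈ [1.5, 3] (default 2.0) and collects the high-frequency k-mer set
   (count ≥ t1),
4. selects **high-frequency reads**: both the first and last k-mer window
   belong to the set and at least t2 (default 90%) of all windows do,
   preserving read pairing,
5. assembles those reads into contigs (built-in de Bruijn unitig assembler,
   or any external assembler through a command-template adapter) and filters
   contigs by mean k-mer coverage and length into the final repeat library.

A synthetic-data module generates genomes with planted repeat families,
simulated paired-end reads with substitution errors and per-read ground-truth
labels, so the whole pipeline is testable offline; an evaluation module
scores libraries (N50/N90 stats, read recall/FPR, base-level recovery by
exact canonical k-mer anchoring).

## CLI

```bash
# make a fixture: 100 kb genome, one 2 kb x 20-copy family, 40x reads
repahr simulate --out fx --genome-length 100000 --family 2000:20:0.01 \
    --coverage 40 --error-rate 0.005 --seed 1

# full pipeline
repahr run --r1 fx/reads_R1.fastq --r2 fx/reads_R2.fastq --out run1

# score the library against the planted truth
repahr evaluate --library run1/repeats.fasta --genome fx/genome.fasta \
    --truth-bed fx/truth_intervals.bed --out eval.json
```

Stage subcommands `spectrum`, `filter`, `assemble` expose the individual
steps; `repahr run --config config.yaml` reads a YAML config with CLI
overrides. Outputs under the run directory: `histogram_k15.tsv`,
`highfreq_R1/R2.fastq`, `highfreq_singletons.fastq`, `repeats.fasta`,
`report.json`, `run.log`.

To use an external assembler (e.g. SPAdes) instead of the built-in one:

```bash
repahr assemble reads.fastq --assembler external \
    --assembler-cmd 'spades.py -s {reads} -o {workdir}/spades && cp {workdir}/spades/contigs.fasta {output}'
```

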