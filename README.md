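# spikeseq

Quantification of bacterial transcriptome dynamics from RNA-seq **without the
constant-total-RNA assumption**, using whole-cell spike-in normalization.

## The problem

When *E. coli* runs into amino-acid starvation, the stringent response
(orchestrated by the alarmone ppGpp) reshapes the whole transcriptome within
minutes — and the *total* RNA content of the cell falls, because ribosomal
RNA, which dominates the pool, is actively degraded. Conventional RNA-seq
normalization divides by sequencing depth and therefore silently assumes the
total pool is constant. When the pool shrinks, depth normalization inflates
every late sample: genuinely down-regulated genes look flat, and flat genes
look induced.

The fix implemented here is a **whole-cell spike-in**: a reference culture
carrying a plasmid with three marker transcripts (*qrr2*, *bla*,
antisense-*lacI*) is added to each sample at a fixed 1% dose per OD unit of
culture *before* RNA extraction, so extraction efficiency, library yield and
depth all cancel against the spike-in reads.

## The two normalizations

With `reads(g,s)` raw counts, gene length in kb and a sample's spike-in
reads-per-kilobase `RPK_sp(s)` (summed reads over the three plasmid features
divided by their summed length):

```
RPKSP(g,s) = (reads(g,s) / len_kb(g)) / (RPK_sp(s) / 10^4)        # spike anchor
RPKM(g,s)  = (reads(g,s) / total_reads(s) * 10^6) / len_kb(g)     # depth anchor
```

Both are length-corrected; they differ only in the per-sample denominator.
The per-gene difference of log2 fold changes between the two methods is a
per-sample constant, `-log2(total-RNA scale factor)` — the exact, testable
signature of the depth-normalization bias.

Around this core the package provides: the transcript filter cascade (never
sequenced / too low for a computable ratio / ambiguous chromosome-plasmid
genes / no computable fold change at the comparison time points), ≥2-fold
regulation classification, RNA-class pool profiles (16S/23S/5S rRNA, tRNA,
total mRNA) relative to steady state, spike-in read-fraction QC with
trend-based outlier flagging, gene-mean-normalized temporal-profile PCA with
Fisher-exact/BH gene-set enrichment, calculators for the two orthogonal
validation assays (qRT-PCR 2^-ddCT and spike-referenced northern blots), and
a ground-truthed synthetic-data generator that emulates the full experiment
(3 steady-state replicates + 5/10/20/40/80 min starvation series, 89% rRNA
read share, decaying rRNA/mRNA pools, two planted temporal archetypes, a
corrupted mid-series sample, and an optional rifampicin tail).

## Worked example

```python
import spikeseq as sq

matrix, truth = sq.simulate_experiment(seed=1)     # counts, annotation, metadata
qc = sq.spikein_fraction_qc(matrix)                # spike/chromosomal read ratio
print(sq.flag_outliers(qc, 0.2))                   # ['starv_20']

rpksp = sq.normalize_rpksp(matrix)
from spikeseq.pools import pool_profile, class_members
rrna = pool_profile(rpksp, class_members(rpksp.annotation, "rRNA"), "rRNA")
print(round(rrna.relative["starv_80"], 3))         # 0.697
```

The flagged sample is the generator's injected handling artifact (its
spike-in read fraction sits ~28% off the interpolated trend), and the rRNA
pool at 80 min of starvation is recovered at 69.7% of the pre-starvation
level under spike-in normalization — while `sq.normalize_rpkm` would report
~103% for the same genes, because the rRNA decline drags total depth down
with it.

The end-to-end workflow is also scripted: the numbered drivers under
`analysis/` (simulate → normalize/QC → fold-change bias → pool dynamics →
PCA/enrichment → assay cross-check) print what they find and write compact
tables under `results/`. Running `analysis/03_foldchange_bias.py` prints,
among other things:

```
at 80 min, depth normalization misses 43% of the down-regulated genes and
over-calls up-regulation by 107%
```

A `spikeseq` CLI exposes the same steps
(`spikeseq simulate|normalize|qc|filter|foldchange|pools|pca|enrich|ddct|northern|run`).

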