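# wgsmap

Mapping-by-sequencing of challenging mutations: a simulator and analysis
toolkit for pooled-F2 polymorphism mapping in *C. elegans*-style crosses.

Forward genetic screens recover mutations whose causative variant must then
be located. Bulked segregant analysis by whole-genome sequencing does this in
one step: the mutant strain is crossed to a polymorphic mapping strain (the
Hawaiian isolate CB4856 in the classic *C. elegans* workflow, with ~1
annotated SNP per kbp), phenotype-selected F2 recombinants are pooled and
sequenced, and the mapping-strain SNP frequency along each chromosome reveals
linkage. At loci unlinked to the mutation the SNPs sit at ~50% of reads; in
the interval containing a recessively selected mutation they vanish.

Most existing tools assume a single recessive homozygous mutation. `wgsmap`
implements, end to end, the pooling designs that extend the method to harder
cases, together with a forward simulator that generates the pooled sequencing
data each design produces:

| design tag | selection | locus signal | detector |
|---|---|---|---|
| `recessive_hawaiian` | mutant F2s | mapping SNPs absent (0%) | LOESS gap |
| `dominant_reverse` | **wild-type** F2s | mapping SNPs rise to 100% | binned peak |
| `dominant_f3` / `semidominant_f3` | mutant F2s, F3-screened to homozygotes | 0% after screening | LOESS gap |
| `two_gene_hawaiian` | doubly homozygous mutant F2s (~1/16) | two gaps, one per locus | LOESS gap |
| `marked_single` | F2s homozygous for a linked morphological marker + mutation | cluster of novel homozygous variants | chain cluster |
| `marked_reciprocal` | two pools with flanking markers | co-homozygous variants | averaged-fraction LOESS ≥ 0.75 |

The analytic expectations the designs rest on are exposed directly: a
dominant mutant pool is 2:1 het:hom, diluting the mapping allele to 33% and
raising the causative allele to 67%; a heterozygous F2 yields 75% mutant F3s
(so `n` scored F3s misclassify it with probability (3/4)^n) while a
homozygote yields 100%; SNP detection at 20-fold coverage floors at 5%
(1/20); and recovering *k* recombinant homozygotes between loci *d* cM apart
requires screening ~`k / (0.5 · d/100)` F2s — e.g. ~4000 for 50 animals at
2.54 cM.

## Worked example

Generate miniature example configs (3 chromosomes × 2 Mbp, 50 cM each,
1 SNP/kbp panel), simulate a recessive mapping cross (pool of 40 mutant F2s
at 25× coverage), and map it:

```sh
wgsmap fixtures --out fx --seed 5
wgsmap simulate fx/recessive_hawaiian.yaml --out sim
echo '{"I": 2000000, "II": 2000000, "III": 2000000}' > lengths.json
wgsmap map --design recessive_hawaiian --pool sim/pool.vcf \
           --panel sim/panel.tsv --lengths lengths.json --out mapped
```

which prints

```
simulated design 'recessive_hawaiian' (seed 5); wrote 6 files to sim
gap interval I:603162-1789029 (score 7.35e+04)
35 candidate variant(s); report in mapped
```

The simulated mutation sits at chromosome I, 1,100,000 bp (recorded in
`sim/truth.tsv`); the called gap interval I:603,162–1,789,029 contains it.
`mapped/report.json` records the interval, its score (gap length × mean
depression of the LOESS curve below the 0.1 threshold) and every threshold in
force; `mapped/intervals.bed` holds the interval in BED coordinates, and
`mapped/candidates.tsv` lists the novel homozygous variants inside the
interval — the simulated causative lesion plus linked mutagenesis passengers,
which is exactly the candidate shortlist a real experiment yields. Add
`wgsmap plot` to draw the per-chromosome SNP-fraction scatter with the LOESS
overlay and shaded interval.

The same loop runs for all seven designs (`fx/*.yaml`); reverse mapping
additionally writes the parental-strain sample needed for candidate listing,
and the marked designs write the wild-type comparison sample used for
background subtraction.

## Library use

```python
import numpy as np
from wgsmap.cross_sim import (CrossDesign, MutationSpec, f2_generator,
                              select_f2_pool)
from wgsmap.readsim import pool_allele_frequency
from wgsmap.pipeline import tiny_genetic_map

gmap = tiny_genetic_map()
spec = MutationSpec(loci=(("I", 1_100_000),), dominance="dominant")
design = CrossDesign("dominant_f3", pool_size=10_000, n_f3_per_f2=1)
pool = select_f2_pool(f2_generator(gmap, "complete", 61), design, spec,
                      rng=np.random.default_rng(61))
pool_allele_frequency(pool, "I", 1_100_000, "map")   # ~0.333
```

## Layout

- `wgsmap.genome` — genetic maps (piecewise-linear cM↔bp), ancestry-labelled
  haplotypes, diploid genomes
- `wgsmap.cross_sim` — meiosis (complete-interference or Haldane), selfing,
  phenotype assignment, pool selection, F3 screening, design arithmetic
- `wgsmap.readsim` — SNP panels, novel-variant sets, pooled read counts
  (Poisson depth, symmetric error, finite-library duplicate removal), pool
  VCF/TSV I/O
- `wgsmap.mapping` — variant filters (≥3 reads; frequency floor; homozygous
  = ≥15 reads and >80%), LOESS, gap/peak/cluster/reciprocal interval calls,
  candidate listing
- `wgsmap.pipeline`, `wgsmap.cli` — YAML-configured closed-loop runs and the
  `wgsmap` command
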