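# plastdiff

Whole-plastome pairwise divergence analysis for intraspecific chloroplast
genome comparisons.

When two complete chloroplast (cp) genomes of the same species are available
— for example a newly skim-sequenced individual and a previously published
one — their differences are few (on the order of 10⁻³ per site) but highly
informative: they locate mutation hotspots and yield PCR-ready polymorphic
markers (variable cpDNA fragments and cpSSR microsatellites) for population
genetics of species with otherwise scarce genomic resources. `plastdiff`
implements that comparison end to end:

* **Genome model** — a circular plastome with the quadripartite partition
  (LSC, IRb, SSC, IRa; the IRs are exact reverse complements of each other),
  read from FASTA plus GenBank or a simple feature table; IR boundaries can
  be auto-detected as the longest reverse-complement repeat pair.
* **Locus catalog** — genic and intergenic fragments ("geneA-geneB" spacers,
  introns), paired between the two genomes by name; loci inside the inverted
  repeat are analysed once so every mutation is counted a single time.
* **Alignment and event calling** — each homologous locus pair is globally
  aligned (Needleman–Wunsch, affine gaps: match +2, mismatch −3, gap open −5,
  gap extend −2), gaps are left-normalized for stable coordinates inside
  repeats, and each mismatching column becomes one SNP and each maximal gap
  run one indel event, whatever its length.
* **Classification** — transitions vs transversions; synonymous vs
  nonsynonymous for CDS SNPs via strand-aware codon mapping and the
  plastid/bacterial genetic code (translation table 11); large indels
  (> 10 bp) are tested for association with flanking or internal DNA repeats,
  the signature of repeat expansion/contraction.
* **Hotspot statistic and marker selection** — per locus, the proportion of
  variation

  ```
  P = (NS + ID) / L × 100
  ```

  where NS is the SNP count, ID the indel event count and L the aligned
  length (gap columns included). Marker candidates are loci with
  200 ≤ L ≤ 1500 bp and P > 0.25 % (half-up rounding to two decimals),
  ranked by P.
* **cpSSR mining** — microsatellite detection at the standard chloroplast
  thresholds (≥10 units for mono-, ≥6 for di-, ≥5 for tri- through
  hexanucleotide motifs), cross-genome matching by motif and 20-bp flanks,
  and polymorphic cpSSRs called where matched tracts differ in length.
* **Simulator** — `plastdiff.synthetic_plastomes` generates annotated
  quadripartite genome pairs with planted SNPs, indels, repeat-mediated large
  indels and SSR length variants, all recorded in a truth manifest, so the
  entire pipeline is validated against known ground truth (precision and
  recall of event recovery are 1.0 at the default 25-bp event spacing).

## Worked example

Simulate a study-scale pair (160 kb, 75 SNPs, 80 indels, 31 SSR tracts with
8 length-polymorphic) and analyse it:

```python
from plastdiff import SimConfig, simulate_pair, run_compare, run_validate

genome_a, genome_b, truth = simulate_pair(SimConfig(seed=7))
report = run_compare(genome_a, genome_b)   # genome B anchors coordinates
print(report.totals)
print(report.region_kind)
print(run_validate(report, truth)["event_precision"])
```

prints (abridged):

```
n_events: 155          n_snp: 75            n_indel: 80
n_large_indel: 20      n_cds_snp: 40        n_cds_snp_synonymous: 40
n_cds_transition: 34   snp_density_per_kb: 0.47
n_ssr_a: 31            n_ssr_polymorphic: 8
n_loci: 181            n_polymorphic_loci: 103

     SNP  insertion  deletion  indel  total
LSC   47         36        24     60    107
SSC   12          6         1      7     19
IR    16          7         6     13     29

1.0
```

Reading this: the two simulated genomes differ by 155 mutational events —
75 single-base substitutions and 80 indel events — spread over 103
polymorphic loci; all 40 CDS-located SNPs are synonymous (the simulator's
default plants coding SNPs only at four-fold degenerate sites, mirroring
what is observed within plant species), 34 of them transitions; the SNP
density is 0.47 per kb; and every planted event was recovered exactly
(precision = recall = 1.0).

The same analysis runs from the shell on real annotated genomes:

```sh
plastdiff compare --genome-a new.fasta  --annot-a new.gb \
                  --genome-b prior.fasta --annot-b prior.gb --out run/
plastdiff simulate --seed 7 --out sim/
plastdiff validate --sim-dir sim/
```

`compare` writes the full report bundle: the two-column genome summary,
the event table (TSV + VCF), region×kind and category×kind counts, the
large-indel inventory with repeat-association calls, the per-locus
variability table, the ranked marker selection, and the SSR/polymorphic-SSR
tables.

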