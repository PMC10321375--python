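# guidecraft

Reference-free CRISPR sgRNA design for any species with a sequenced genome.

Most guide-design tools ask you to pick a reference species from a fixed
menu before they will evaluate off-target risk; if your organism is not
on the menu — which is true for the large majority of sequenced plant
genomes — the off-target scores are computed against the wrong genome.
`guidecraft` removes the menu: you hand it **your** genome FASTA, it
builds a genome-wide spacer-uniqueness database once, and every
subsequent design run is evaluated against that genome.

## What it computes

For a target sequence and a chosen PAM model (20 Cas9/Cas12 variants
ship in the registry, e.g. SpCas9 `NGG`, Cas12a `TTTV`):

* **Candidates** — every spacer of the model's length adjacent to a PAM
  match, both strands.
* **Uniqueness** — the genome-wide, PAM-adjacent occurrence count of the
  spacer; a count of one is unique, anything else is reported as
  `not_unique` (marked, never dropped).
* **Off-target sites** — every genomic site with Hamming distance
  $d < D$ to the spacer (default $D = 5$, i.e. 0–4 mismatches reported)
  carrying an acceptable PAM, found by pigeonhole seed partitioning:
  split the spacer into $D$ segments, at least one segment of any
  qualifying site must match exactly, locate exact segment hits through
  a k-mer position table, verify in full.
* **CFD score** per site — the cutting-frequency-determination product

  $$\mathrm{CFD} = p_{\mathrm{PAM}} \cdot \prod_{i \in \mathrm{mismatches}} p_i(g_i \rightarrow t_i)$$

  over per-position mismatch penalties, and a per-guide specificity
  aggregate $1 / (1 + \sum_k \mathrm{CFD}_k)$.
* **Quality flags** — GC fraction, a `!` mark for runs of four or more
  T's or A's (the Pol III terminator concern), an inverted-repeat
  hairpin flag, and a pluggable linear activity score.
* **Shared guides** — spacers present (with valid PAM) in *every* member
  of a gene group, for multiplex editing of polygenic traits.

Sequence extraction (promoter / gene / mRNA / CDS / UTR from genome +
GFF3), verification-primer design, and templated insertion of special
sgRNA structures round out the bench workflow.

## Worked example

```sh
# a self-contained toy dataset (synthetic genome + annotation + truth table)
guidecraft fixtures --genome-out toy.fa --gff-out toy.gff3 \
    --truth-out truth.tsv --length 20000 --seed 7

# build the uniqueness database once, reuse it afterwards
guidecraft build-db --genome toy.fa --pam SpCas9-NGG --out toy.db

# pull the CDS of two annotated genes and design guides for both
guidecraft extract --genome toy.fa --gff toy.gff3 \
    --genes gene1,gene2 --kind CDS --out genes.fa
guidecraft design --genome toy.fa --db toy.db --targets genes.fa --out run1
```

The run logs (standard error):

```
guidecraft INFO: indexed 1993 distinct spacers (1993 occurrences) -> toy.db
guidecraft INFO: wrote 2 CDS sequence(s) -> genes.fa
guidecraft INFO: designed 49 guide(s) across 2 target(s) -> run1.*
```

and `run1.guides.tsv` begins (first data row, columns abridged):

```
guide_id                       start  end  strand  spacer                pam  unique  gc        polyTA  hairpin  activity  specificity  n_offtargets
gene1|CDS|chr1:192-491|+_g001  242    261  +       GGTACGGAGAATACTGGTCG  TGG  yes     0.550000          no       0.595230  1.000000     0
```

Reading the row: the top-ranked guide for `gene1`'s CDS sits at bases
242–261 of the target on the plus strand, its spacer occurs exactly
once in the genome (`yes`), has 55 % GC, no poly-T/A run (empty column
rather than `!`), no hairpin, a predicted activity of 0.60 under the
packaged linear model, perfect specificity 1.0, and zero off-target
sites within four mismatches. `run1.offtargets.tsv` lists every off-target site of every
guide with its per-position mismatches and CFD score, and
`run1.<target>.map.svg` draws the guides along the target.

The library mirrors the CLI one-to-one
(`guidecraft.design.design_for_sequence`, `shared_guides`,
`batch_design`, ...) for notebook use.

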