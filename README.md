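# msatclone

Microsatellite analysis of clonal (parthenogenetic) populations of
hybrid origin. The package takes tabular diploid microsatellite
genotype data (allele sizes in bp, species/population labels, missing
calls allowed) and provides:

- **Data model & I/O** (`msatclone.genotype_io`) — wide-CSV and
  GenAlEx-style readers/writers, locus metadata (repeat-motif length /
  flank offset) in TOML, allele-frequency estimation and pooling,
  bp-to-repeat-unit conversion with off-ladder flagging.
- **Diversity statistics** (`msatclone.diversity`) — hypergeometric
  rarefied allelic richness, observed / unbiased expected
  heterozygosity and heterozygote excess, homozygous-call proportion,
  and a clonal genotype-diversity table (distinct multilocus genotype
  counts with the missing-data-is-distinct rule, top genotype
  frequencies, Bruvo distances between most common / most distant
  genotypes).
- **Distances & networks** (`msatclone.distances`) — Bruvo distance
  (`d = 1 − 2^−|x|`, minimal-assignment diploid combination, pairwise
  deletion for missing loci), shared-locus distance
  (`L − #identically-genotyped loci`), minimum spanning networks with
  tie retention, neighbor-joining trees with newick output, TSV/PHYLIP
  matrix export.
- **Shared genotypes** (`msatclone.shared`) — shared-allele
  proportions between individuals and groups, shared k-locus diploid
  genotype proportions (each locus subset treated as one haploid
  marker), maximum shared-locus counts, and discovery of maximal
  cross-species shared multilocus genotypes with carrier frequencies
  and zygosity flags.
- **Coincidence model** (`msatclone.coincidence`) — probability that a
  hybridization event between given parental populations produces a
  multilocus genotype (heterozygous-locus factor `p_i·q_j + p_j·q_i`;
  homozygous loci either by random union `p_i·q_i` or by the
  conservative allelic-conversion mode `(p_i + q_i)/2`), a brute-force
  2^n phase-enumeration oracle, coincidence probabilities across 2–3
  independent origins, theoretical curves vs locus count, and the
  triploid balanced-gamete probability `0.5^(x−1)`.
- **Forward simulator** (`msatclone.simulate`) — bisexual parental
  populations in HWE, F1 hybrid founding, clonal propagation with
  stepwise mutation and allelic conversion (loss of heterozygosity),
  backcross enrichment, missing-call masking, and a replayable
  ground-truth event log.
- **CLI** (`msatclone.cli`) — subcommands `stats`, `shared`,
  `network`, `coincide`, `simulate`, `gamete` and `run` (full pipeline
  from a TOML config with a reproducibility manifest).

## CLI quick start

```bash
# simulate a two-parthenogen scenario and analyse it
msatclone simulate --seed 1 --single-origin --out sim.csv
msatclone stats sim.csv
msatclone shared sim.csv
msatclone network sim.csv
msatclone coincide sim.csv --genotype "L01=104/304,L02=140/340" \
    --paternal paternal_sp --maternal maternal_sp

# full pipeline from a config
msatclone run pipeline.toml --out-dir out/
```

A minimal `pipeline.toml`:

```toml
[input]
table = "genotypes.csv"     # wide CSV: id,species,population,<locus>.1,<locus>.2
loci_meta = "loci.toml"     # optional; motifs inferred by GCD otherwise

[groups]
parth_A = "parthenogen"
parth_B = "parthenogen"
maternal_sp = "maternal"
paternal_sp = "paternal"

[coincidence]
hom_mode = "conversion"
```

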