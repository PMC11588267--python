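# hzkit

Hybrid-zone analysis toolkit for diploid SNP data and bioacoustic traits:

- **`hzkit.syngen`** — seeded generators for genotype transects whose allele
  frequencies follow sigmoid clines (with optional near-zero-width "barrier"
  loci and missing calls), unadmixed reference panels with planted fixed
  differences, and advertisement-call datasets under three scenarios (null,
  character displacement, variance reduction).
- **`hzkit.genio`** — readers/writers for genotype matrices (wide CSV,
  two-row STRUCTURE-like text, minimal VCF), locality tables with haversine
  transect distances, hzar-style allele-frequency CSVs and call tables.
- **`hzkit.diagloci`** — presence/call-rate locus filters, one-SNP-per-locus
  thinning, and species-diagnostic SNP selection by exact rational
  comparison of panel allele frequencies.
- **`hzkit.ancestry`** — K=2 admixture proportions by EM on a binomial
  genotype likelihood (monotone log-likelihood, panel-anchored labels).
- **`hzkit.clines`** — two-parameter sigmoid cline
  `p(x) = (1 + tanh(2(x−c)/w))/2` fitted by maximum likelihood with
  2-log-likelihood-unit profile intervals, multi-locus summaries and
  barrier-locus flagging; mitochondrial, mean-ancestry and per-SNP inputs
  share one fit path.
- **`hzkit.acoustics`** — temperature adjustment of note duration, PCA of
  the four call variables, convex-hull overlap / centroid distance /
  weighted-SD statistics, their allopatric-vs-parapatric Δ differences, and
  a label-permutation significance test with a down-sampled variant.
- **`hzkit.cli`** — `hzkit` command with `simulate`, `diagloci`,
  `ancestry`, `clines`, `acoustics` and `all` subcommands.

## CLI

End-to-end demo on synthetic data (simulate → diagnostic loci → ancestry →
clines → acoustics), deterministic per seed:

```sh
hzkit all --seed 1 --n-loci 200 -B 1000 --scenario variance_reduction --out demo/
```

writes genotype/locality/call CSVs, a diagnostic-locus whitelist, a Q
table, per-locus cline fits plus a summary (center/width in km), the
five-row Δ-test report with permutation P values (plain and down-sampled),
the full permutation null samples, and a `manifest.json` echoing the seed
and configuration. Individual stages are available as subcommands, e.g.

```sh
hzkit simulate --seed 1 --out sim/
hzkit diagloci --panels sim/panel_genotypes.csv --out whitelist.txt
hzkit ancestry --genotypes sim/transect_genotypes.csv --out q.csv
hzkit clines --frequencies sim/snp_frequencies.csv --ci --out clines/
hzkit acoustics --calls sim/calls.csv -B 1000 --out acoustics/
```

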