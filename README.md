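# taxoplace

Rank-normalized taxonomic classification of bacterial/archaeal genomes
against a taxonomy-decorated reference tree. A query genome is attached to
the tree (from a pplacer-style jplace file, or with a built-in naive
placer over the masked concatenated marker alignment), and its taxonomy is
decided by combining three signals:

1. **Topology** — the rank-prefixed taxon labels above and below the
   attachment point often decide the classification outright.
2. **RED** (relative evolutionary divergence) — a [0, 1] node statistic
   (0 at the root, 1 at leaves) whose per-rank medians resolve ambiguous
   rank windows: the query gets the rank whose median RED is nearest its
   attachment RED.
3. **ANI** — fragment-based average nucleotide identity against the
   representative genomes of the candidate genus assigns species when the
   alignment fraction exceeds 65% and the ANI reaches the species'
   circumscription radius (default 95%); otherwise the query is a novel
   species within the genus.

Queries whose taxon is new at some rank are reported with that suffix left
empty and a `novel <rank>` warning — naming is curation, not
classification.

## Command line

```sh
# generate a fully synthetic reference package + queries with known truth
taxoplace synth --seed 7 --out fixture/

# classify queries (jplace placements from the fixture; omit --placements
# to use the naive marker-distance placer instead)
taxoplace classify --ref-dir fixture/ref --genomes fixture/queries \
    --out out/ --placements fixture/placements.jplace \
    --quality fixture/ref/quality.tsv --trace

# inspect RED values / one pairwise ANI
taxoplace red --tree fixture/ref/tree.nwk --out red.tsv
taxoplace ani --query q.fasta --reference ref.fasta
```

`classify` writes `summary.tsv` (user_genome, classification,
closest_reference, ani, af, red_value, method, warnings), a log, and with
`--trace` a per-query JSON decision trace. Exit code is 0 iff every query
produced a result; per-query failures are isolated and listed in
`failures.json`.

A reference package directory contains `tree.nwk` (decorated Newick;
internal labels `'support:taxon[;taxon...]'`), `msa.fasta` (masked
reference alignment rows), `mask.txt` (0/1 column mask), `radii.tsv`
(species_name, representative_genome, radius_pct) and `genomes/` (one
FASTA per representative).

## Layout

| module              | role                                                        |
|---------------------|-------------------------------------------------------------|
| `taxoplace.io`      | decorated Newick, jplace, FASTA, radii TSV, summary report  |
| `taxoplace.red`     | RED per node, per-rank medians, attachment-point RED        |
| `taxoplace.place`   | naive placement and grafting queries onto the tree          |
| `taxoplace.classify`| the ANI / topology / RED decision engine                    |
| `taxoplace.ani`     | fragment ANI (k-mer seeding + ungapped extension), species assignment |
| `taxoplace.profile` | marker tables, domain assignment, concat+mask, QC filter    |
| `taxoplace.synth`   | deterministic synthetic reference packages and truth-labeled queries |
| `taxoplace.cli`     | `taxoplace` command group and batch orchestration           |
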