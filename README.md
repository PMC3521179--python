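# complexkit

Predict protein complexes from integrated protein–protein interaction (PPI)
networks and validate them with independent evidence. The toolkit covers the
full pipeline:

1. **Integration** (`complexkit.network`) — merge tagged PPI edge lists from
   several source databases into one nonredundant undirected network, with
   cross-source overlap statistics.
2. **Prediction** (`complexkit.clustering`) — deterministic density-based
   greedy clustering controlled by two thresholds, *network density* and
   *cluster property*, in overlapping mode with minimum complex size 3.
3. **Benchmarking** (`complexkit.benchmark`) — match predictions to a
   reference complex set (≥ 2 shared proteins), frequency-adjusted
   recall/precision sums, and an exhaustive 0.0–1.0 step-0.1 parameter grid
   search.
4. **Quality annotation** (`complexkit.annotation`) — per-subunit evidence
   categories I/II/III, the complex quality index string `n1.n2.n3/total`,
   complex typing (perfectly matched / partially matched / hypothetical /
   other), curation edits, and a hypothetical-protein report.
5. **Ontology consistency** (`complexkit.ontology`) — depth-5 normalization
   of term annotations, one-sided hypergeometric term enrichment per
   complex, the consistency index (fraction of subunit pairs sharing a
   term), size-matched random controls, and two-sample comparison.
6. **Expression coherence** (`complexkit.expression`) — average pairwise
   cosine over 10-tissue profiles, a cached size-matched Monte-Carlo null,
   Benjamini–Hochberg FDR, tissue-specificity entropy, and the
   size-vs-similarity trend summary.
7. **Paralogy** (`complexkit.paralogs`) — within-complex paralog pairs from
   a precomputed pairwise homology table (strict `E < threshold` by
   default) and complex-level duplication fractions.
8. **Synthetic data** (`complexkit.synthetic`) — seeded generators for
   networks with planted complexes plus matching annotations, expression
   matrices, homology tables, and reference sets, so every stage is
   testable with known ground truth.

## Command-line interface

All functionality is exposed through one umbrella command:

```sh
# generate a synthetic input set with planted truth
complexkit simulate --preset clean --seed 1 --out data/

# integrate tagged edge lists
complexkit integrate --edges bind.tsv:BIND --edges mint.tsv:MINT --out net

# predict complexes
complexkit predict --network net.network.tsv --density 0.6 --cp 0.5 \
    --min-size 3 --out complexes.json

# optimize the two clustering parameters against a reference set
complexkit optimize --network net.network.tsv --reference reference.tsv \
    --step 0.1 --out grid.tsv

# annotate with evidence categories and CQI
complexkit annotate --complexes complexes.json --evidence-i ev1.tsv \
    --curation edits.tsv --out annotated.json

# validation statistics
complexkit validate-go --complexes annotated.json --obo terms.tsv \
    --annotations annotations.tsv --depth 5 --out go
complexkit validate-expression --complexes annotated.json \
    --expression expression.tsv --reps 100000 --seed 17 --out expr
complexkit validate-paralogs --complexes annotated.json \
    --homology homology.tsv --evalue 1e-5 --out par

# or everything at once
complexkit run --config run.json --out results/
```

`complexkit run` accepts a JSON config file mirroring the flags; every
output carries a provenance header with version, seed, and parameters.

## File formats (all plain text)

- **Networks**: TSV `protein_a <TAB> protein_b <TAB> comma-joined source tags`
  (GraphML also written by `integrate`).
- **Complexes**: JSON list of `{id, members, [categories, cqi, type]}`.
- **Reference sets**: TSV `complex_id <TAB> comma-joined members`.
- **Term graph**: minimal OBO (`is_a` only) or `child <TAB> parent` TSV;
  annotations as `protein <TAB> term` TSV.
- **Expression**: TSV `tag_id, locus_id, 10 tissue columns`.
- **Homology**: TSV `gene_a, gene_b, e_value`.

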