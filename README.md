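# metnet

Build disease-associated metabolite networks from disease↔metabolite
association tables, fuse them with text-mining evidence, and prioritize
candidate disease-related metabolites by random walk with restart.

The pipeline:

1. **Vocabulary mapping** — combine an OBO disease ontology with a
   MEDIC-style vocabulary and resolve free-text disease names to ontology
   terms (`metnet.vocab`).
2. **Disease similarity** — functional similarity for every disease pair
   from gene annotations and a weighted gene functional network, normalized
   by the most informative common ancestor in the ontology
   (`metnet.disease_sim`).
3. **Collaborative-filtering profiles** — each metabolite gets a dense
   relevance vector over diseases (1 for direct associations, otherwise the
   best similarity to an associated disease); pairwise cosine similarity,
   thresholded (default 0.01, strict `>`), yields the weighted metabolite
   network (`metnet.cf`).
4. **Evidence fusion** — noisy-OR combination `1 − (1 − a)(1 − b)` of the
   cosine network with text-mining scores (`metnet.fusion`).
5. **Ranking** — random walk with restart (default restart 0.7,
   column-stochastic transitions, L1 convergence) scores every metabolite
   against a seed set (`metnet.rwr`).
6. **Evaluation** — two-snapshot validation: seeds from an earlier
   association table, positives from associations new in a later one,
   Mann–Whitney AUC per disease plus threshold and restart sweeps
   (`metnet.evaluation`).
7. **Synthetic fixtures** — a seeded generator plants module structure
   (shared genes, co-associations, concordant text mining) so every stage is
   testable offline; includes a fixed hand-verifiable worked example
   (`metnet.synth`, `docs/worked_example.md`).

## CLI

Each stage is a subcommand (`metnet --help`):

```sh
metnet synth --seed 7 --out fixtures/              # synthetic bundle
metnet synth --worked-example --out wx/            # tiny fixed instance
metnet map --obo do.obo --medic medic.tsv --raw hmdb_names.tsv --out assoc.tsv
metnet dsim --obo do.obo --genes d2g.tsv --gene-net gnet.tsv \
            --assoc assoc.tsv --out dsim.tsv
metnet build-dmn --assoc assoc.tsv --dsim dsim.tsv --threshold 0.01 --out dmn.tsv
metnet fuse --dmn dmn.tsv --st stitch.tsv --scale 1000 --out fldmn.tsv
metnet rank --network fldmn.tsv --seeds seeds.txt --restart 0.7 --out ranking.tsv
metnet evaluate --network fldmn.tsv --earlier a2017.tsv --later a2018.tsv --out eval.tsv
metnet run --config config.yaml                    # full pipeline from YAML
```

All inputs are plain TSV/OBO; `--scale 1000` divides raw 0–1000 text-mining
scores into [0, 1] on ingest. Exit codes: 0 ok, 2 input error, 3
convergence failure. Every artifact carries a provenance header (tool
version, config hash, input hashes), and identical inputs + config produce
byte-identical outputs.

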