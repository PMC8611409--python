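# bindnet

Analysis toolkit for **bipartite transcription-factor / promoter binding
networks**, of the kind produced by genome-scale yeast one-hybrid (Y1H)
screens of metabolic gene promoters. Given a TF–promoter edge list plus
pathway, TF-family, and subcellular-localization annotations, `bindnet`
answers the questions such a screen raises:

- **Topology** — how many TFs, promoters, and interactions; the per-promoter
  in-degree distribution; what fraction of TFs bind promoters spanning two or
  more metabolic pathways.
- **Pathway cross-talk** — for every pair of pathways, is the number of TFs
  shared between their promoter sets larger than chance? A regional-enrichment
  rank orders a focal pathway's partners by adjusted-p / odds-ratio.
- **Compartmentalized regulation** — within a pathway subnetwork (e.g. the
  TCA cycle, whose enzymes occur as mitochondrial, plastidic, peroxisomal and
  cytosolic isoforms), is a TF family enriched for binding one enzyme-step ×
  compartment isoform group?
- **Conditionality** — across several expression compendia, in which datasets
  is each TF–target pair co-expressed (|Pearson r| ≥ 0.8), and how many edges
  are exclusive to a single compendium?
- **Validation** — are the network's predicted targets over-represented among
  the differentially expressed genes of a TF-induction experiment?

All enrichment questions reduce to Fisher's exact test on a 2×2 table
`a=|A∩B|, b=|A\B|, c=|B\A|, d=U−|A∪B|` against a fixed universe `U` of
screened TFs (or DE-tested genes). The test, the underlying hypergeometric
pmf `P(X=k) = C(K,k)·C(N−K,n−k)/C(N,n)` (computed in log space), and the
Benjamini–Hochberg / Holm adjustments are implemented from first principles
and verified against brute-force enumeration.

A seeded synthetic-data generator (`bindnet.simulate`) emits complete input
bundles with planted structure — excess TF sharing between chosen pathway
pairs, a family×compartment binding bias, dataset-exclusive co-expression,
and a planted DEG-overlap odds ratio — so every stage is testable without
any external download.

## Worked example

```python
from bindnet import (simulate_network, summarize, pathway_multiplicity_fraction,
                     pairwise_pathway_sharing, regional_enrichment_rank)
from bindnet.simulate import NetworkSimSpec

sim = simulate_network(NetworkSimSpec(seed=1))      # quarter-scale screen
s = summarize(sim.network)
print(f"{s.n_edges} interactions between {s.n_tfs} TFs and {s.n_promoters} promoters")
print(f"promoter degree {s.promoter_degree_min}-{s.promoter_degree_max}, "
      f"mean {s.promoter_degree_mean:.1f}")
print(f"{100 * pathway_multiplicity_fraction(sim.network, 2):.0f}% of TFs bind >= 2 pathways")

results = pairwise_pathway_sharing(sim.network, universe=500)
for r in regional_enrichment_rank(results, "ALIPHATIC_GSL")[:3]:
    print(f"rank {r.rank}: {r.partner_of('ALIPHATIC_GSL')} "
          f"(shared TFs {r.n_shared}, OR {r.enrichment.odds_ratio:.2f}, "
          f"adj p {r.enrichment.p_adj:.2e})")
```

prints

```
1613 interactions between 425 TFs and 62 promoters
promoter degree 11-67, mean 26.0
72% of TFs bind >= 2 pathways
rank 1: METHIONINE_BIOSYNTHESIS (shared TFs 49, OR 4.00, adj p 9.17e-07)
rank 2: PENTOSE_PHOSPHATE (shared TFs 50, OR 2.04, adj p 7.56e-03)
rank 3: GLYCOLYSIS_GLUCONEOGENESIS (shared TFs 89, OR 1.80, adj p 9.73e-03)
```

The default generator plants strong co-regulator sharing between the
glucosinolate pathway and the sulfur amino-acid pathways that supply its
precursors; the regional rank recovers methionine biosynthesis first.

## Command line

```sh
bindnet simulate --out data/ --seed 1          # synthetic input bundle
bindnet summarize --edges data/edges.tsv --pathways data/pathways.tsv --out out/
bindnet pairs --edges data/edges.tsv --pathways data/pathways.tsv --universe 500 --out out/
bindnet compartments --edges data/edges.tsv --pathways data/pathways.tsv \
    --localization data/localization.tsv --families data/families.tsv \
    --pathway TCA_CYCLE --out out/
bindnet coexpr --edges data/edges.tsv --manifest data/expression_manifest.yaml --out out/
bindnet validate --deg data/deg_synthetic_contrast.tsv \
    --universe data/deg_universe.txt --targets data/deg_targets.txt --out out/
```

Each subcommand writes TSV outputs plus a JSON run manifest (input hashes,
parameters, counts). Real screen data use the same formats: an edge list
`tf_id<TAB>promoter_id`, annotation tables `promoter_id<TAB>pathway`,
`tf_id<TAB>family`, a SUBA-style localization table, gene×sample expression
matrices with a YAML manifest, and per-contrast DEG tables.

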