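# p2t — pathway-driven target prioritization and drug repurposing

`p2t` turns the output of a signaling-pathway enrichment analysis into
ranked lists of therapeutic targets and repurposable drugs. It is aimed at
computational biologists who already have a table of significantly
perturbed pathways for a disease or condition (from SPIA or enrichr, run
on differential-expression results) and want to know which gene products
inside those pathways are the most promising targets — and which existing
therapeutics hit them.

## The scoring model

Every gene product that belongs to at least one significant pathway is
annotated with attributes from an Open Targets-style data bundle and given
a weighted linear score

```
S = w_pw·(# significant pathways containing the target)
  + w_tr·(tractability count)
  + w_ap·(# approved therapeutics)
  + w_sf·(# safety liabilities)
  + w_ud·(# unique drugs)
  + w_ds·(# associated diseases)
  + w_1·(# phase-1) + w_2·(# phase-2) + w_3·(# phase-3) + w_4·(# phase-4 therapeutics)
```

Two presets ship with the tool. The **default** preset
(1, 1, 1, −2, 1, 1, 0.5, 1, 1.5, 2) rewards clinical maturity — approved
drugs, late-phase trials, broad disease association — and penalizes safety
liabilities; it suits repurposing. The **novel** preset
(0.5, 0.5, 0.5, −2, 0.5, 0.01, 10, 4, 0.5, 0.01) damps everything
late-stage and boosts phase-1/2 counts to surface earlier-stage targets.
Weights are fully user-overridable; no normalization is applied.

Targets are ranked by score (ties: approved count, then unique-drug count,
then symbol). Each drug linked to any scored target inherits the maximum
score among its targets, giving a deduplicated prioritized-therapeutics
table. Ranking quality against a *gold set* (e.g. the approved targets for
an indication) is quantified with a hypergeometric upper-tail test on the
top-k ranks: with N scored targets, K of them gold, the p-value is
P(X ≥ hits) for X ~ Hypergeom(N, K, k).

## Worked example

```sh
p2t fixtures --out fx --seed 3
p2t run --input fx/pathways.tsv --snapshot fx/snapshot.json \
        --gold fx/gold.txt --out results
```

prints

```
wrote snapshot (50 targets, 10 pathways) to fx
scored 41 targets, 67 unique drugs -> results
```

and `results/targets.tsv` begins

```
rank  symbol    ...  n_unique_drugs  n_pathways_with_target  n_approved  ...  score
1     GENE0040  ...  72              2                       2           ...  983.0
2     GENE0038  ...  630             2                       20          ...  845.5
```

41 of the 50 snapshot targets belong to at least one significant pathway,
so 41 are scored; the 67 drugs linked to them each inherit their best
target's score in `results/drugs.tsv`. With the gold set supplied,
`results/enrichment.json` reports the top-15 test —

```
{"K_gold": 5, "N_universe": 41, "k_hits": 4, "n_drawn": 15, "p_value": 0.0514}
```

— 4 of the 5 gold targets landed in the top 15 of 41, an enrichment just
above the conventional 0.05 line for this seed. `results/manifest.json`
echoes the configuration and the per-stage counts; identical configs
reproduce byte-identical tables.

Real inputs work the same way: pass your SPIA (or `--dialect enrichr`)
table and a snapshot built from your own target-annotation pull, and tune
`--alpha`, `--preset`/`--weights`, and `--top-k`.

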