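# seedscreen

Flow-cytometric seed screen (FCSS) analysis toolkit for mixed-ploidy plant
populations. From flow-cytometry peak measurements of seed tissues it
computes genome sizes and ploidy categories, labels each seed's category,
infers reproduction pathways (sexuality, apomeiosis, parthenogenesis,
B_III hybrid formation, pseudogamy, polyspermy, endoreplication),
aggregates per-tree and per-cytotype quantitative summaries, and groups
mother trees by reproductive profile (Bray–Curtis + Ward clustering and a
from-scratch detrended correspondence analysis). A synthetic-data module
generates populations, seed families and noisy cytometry measurements with
hidden ground truth, so the whole pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `seedscreen.fcm_quant` | peak QC, event-list peak fitting, 2C DNA amounts via internal reference standards (Pisum 9.09 pg, Solanum 2.59 pg) |
| `seedscreen.ploidy` | mature-plant ploidy from 2C ranges; seed-tissue ploidy from peak ratios, snapped to a 0.5x grid |
| `seedscreen.pathways` | exhaustive enumeration + ranking of reproduction scenarios consistent with a (maternal, embryo, endosperm) triple |
| `seedscreen.summaries` | category matrices, headline pathway rates, endosperm 2m:1p balance accounting, fruit statistics |
| `seedscreen.ordination` | abundance filter, percent-max transform, Bray–Curtis, Ward clustering, DCA |
| `seedscreen.simdata` | synthetic trees, seed families and measurements with hidden truth |
| `seedscreen.screen` / `seedscreen.io` / `seedscreen.cli` | peak-table screening, CSV/YAML I/O, command-line interface |
| `seedscreen.reference_data` | bundled survey fixtures (per-tree counts, per-category seed counts) |

## CLI

```sh
seedscreen --version
seedscreen quantify --peaks peaks.csv --standard pisum --out 2c.csv
seedscreen call --input 2c.csv --out ploidy.csv
seedscreen classify --seeds seeds.csv --sperm-set 1,1.5,2,2.5,3,4 \
    --tolerance 0.25 --out classified.csv --ties-json ties.json
seedscreen summarize --seeds classified.csv --fruits fruits.csv --out-dir tables/
seedscreen cluster --matrix category_counts.csv --min-count 4 --k 2 \
    --segments 26 --out-dir groups/
seedscreen simulate --config examples/demo.yaml --n-seeds 60 --seed 42 \
    --out peaks.csv --truth truth.csv
seedscreen all --config examples/demo.yaml --out-dir run/
```

`seedscreen all` chains simulate → screen → classify → summarize → cluster
on one YAML configuration (see `examples/demo.yaml`); re-running with the
same config and seed produces byte-identical outputs.

## Library example

```python
from seedscreen import enumerate_explanations, top_explanations

best = top_explanations(enumerate_explanations(maternal=3, embryo=3, endosperm=8))
for x in best:  # ties are preserved: one 2x sperm, or two 1x sperm
    print(x.label.value, x.sperm_to_central, x.mp_ratio_text())
```

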