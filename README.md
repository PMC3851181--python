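# trajex

Scriptable exploratory analysis of short time-series expression data
(bulk or single-cell probe × sample log2 matrices). trajex decomposes the
workflow into small interoperable operators:

- **aggregation** of replicate samples (mean/median) and of consecutive
  time-point segments;
- **equi-width discretization** of each probe's trajectory into integer bins
  (`b = floor(e / w)`, half-open intervals, boundary joins the upper bin);
- a **trajectory graph** — a prefix tree over bin sequences in which every
  node has a single parent and each level partitions the probe universe;
- **clustering** by trajectory shape (successive bin differences, invariant
  to vertical shifts), by exact bin identity, and by k-means on raw profiles
  (Euclidean distance, seeded k-means++ restarts);
- **shape filtering** with per-transition criteria (`up`/`down`/`same`/`any`
  with bin-magnitude bounds), inverse-pattern search, and include/exclude
  set algebra over named probe sets;
- **cross-dataset comparison**: primary/secondary pairing and a
  differentiation operator producing a differential dataset that feeds every
  other operator unchanged;
- **statistics**: hypergeometric association of probe sets with pathways
  (point mass and upper-tail p, optional Benjamini–Hochberg), precision /
  recall, per-trajectory volatility and linear trend;
- a **synthetic fixture generator** with planted co-expression groups,
  pathways and treatment effects, so every operator is testable against a
  known ground truth.

## CLI

The `trajex` command chains operators through files: TSV for matrices and
sample maps, GMT for gene sets, versioned JSON for every intermediate
result. Each invocation appends to `<workdir>/logs/oplog.jsonl`;
`trajex replay --log ...` re-executes a logged chain bit-identically (given
fixed seeds).

A typical control-vs-treatment session:

```sh
trajex simulate --out sim --seed 17                    # or bring your own TSVs
trajex aggregate --matrix sim/treatment.tsv --samples sim/treatment.samples.tsv \
                 --method median --out aggT.json
trajex aggregate --matrix sim/control.tsv --samples sim/control.samples.tsv \
                 --method median --out aggC.json
trajex diff --primary aggT.json --secondary aggC.json --out diff.json
trajex discretize --agg diff.json --width 0.5 --out dset.json
trajex graph --dset dset.json --out graph.json --edges edges.tsv
trajex filter --dset dset.json --criterion "down:2,any,any,any,any,any,any,any" \
              --out hits.json
trajex enrich --selected hits.json --ann sim/annotation.json \
              --universe dset.json --mode tail --out enrichment.json
trajex stats --agg diff.json --metric volatility --out stats.json
```

Other subcommands: `load` (validate matrices / build annotation sets from
GMT + probe tables), `cluster --method shape|identity|kmeans`, `inverse`,
`select`, `annotate`, `export` (static PNG/SVG plots), `replay`. Any flag
can be supplied from a YAML config via `trajex --config cfg.yaml ...`;
explicit flags win.

Expression matrices are TSV with a header row of sample IDs, probe IDs in
the first column, `NA`/`NaN`/empty for missing cells, and `#` comment lines
ignored. The sample map is a TSV with `sample_id`, `timepoint` and an
optional integer `order` column (without it, time points are ordered
lexically with a warning). Values are assumed log2-transformed; pass
`--log2` to transform raw positive values at load.

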