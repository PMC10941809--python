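# ontoburst

Sunburst visualization of ranked drug and disease term lists on their
hierarchical classifications. Annotated term lists (e.g. clinical-trial or
publication counts) are mapped onto the ATC drug classification or the MeSH
disease subtree, counts are optionally up-propagated to parent terms, empty
branches pruned, and wedge colors derived from a configurable color scale.
The result is exported as a self-contained interactive HTML file (inline
SVG, no external resources) and/or a portable JSON plot specification.

## Features

- **Code grammars**: ATC codes (5 levels by code length: 1/3/4/5/7
  characters), MeSH tree numbers (dot-separated segments), and a generic
  dot-separated grammar for arbitrary hierarchies.
- **Ingest**: TSV and XLSX template files (code, label, count, optional
  `#RRGGBB` color and description columns; extra columns are carried
  through), OBO ontologies (is_a graphs unfolded into positional codes),
  NLM MeSH descriptor XML, and flat `(code, name)` ATC tables.
- **Transforms**: bottom-up count propagation with a configurable level
  cap, fixpoint pruning of empty branches, and linear RGB color-scale
  interpolation with manual per-term color overrides.
- **Render**: one sunburst per level-1 branch, tiled summary grids with a
  configurable number of plots per row, label display policies, and border
  styling.

## CLI

```sh
# template with counts -> propagated, pruned, colored summary plot
ontoburst --input drugs.tsv --kind atc --propagate \
    --color-scale "0:#FFFFFF,0.5:#FFFF00,1:#FF0000" \
    --out-html drugs.html --out-json drugs.json

# one plot per level-1 branch instead of the tiled summary
ontoburst --input diseases.tsv --kind mesh --propagate --branches \
    --out-html diseases.html

# MeSH descriptor XML input, subtree C only
ontoburst --input desc2022.xml --mesh-xml --mesh-prefix C --kind mesh \
    --out-html mesh.html
```

Key flags: `--propagate` / `--propagate-level N` (1 = propagate to the
category roots), `--drop-empty/--keep-empty`, `--labels all|none|N`,
`--border/--no-border` with `--border-color` and `--border-width`,
`--summary/--branches` and `--plots-per-row N`, `--config run.toml`
(flags override config values), and `--from-url` to fetch an OBO ontology
(explicit opt-in to network access). See `ontoburst --help`.

## Library

```python
from ontoburst import (
    OntologyKind, build_forest, read_template,
    PropagationConfig, propagate_counts, drop_empty,
    ColorScale, assign_colors,
    PlotConfig, build_plot_spec, layout_summary, export_html,
)

table = read_template("drugs.tsv")
forest = build_forest(table.rows, OntologyKind.ATC)
forest = propagate_counts(forest, PropagationConfig(max_level=1))
forest = drop_empty(forest)
forest = assign_colors(forest, ColorScale.white_to_red())
specs = build_plot_spec(forest, PlotConfig())
export_html(layout_summary(specs, plots_per_row=5), "drugs.html")
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) and an acceptance
module checking propagation against an independent subtree-sum oracle,
pruning against a reachability oracle, exact color-scale interpolation,
lossless I/O round trips and summary-grid arithmetic.

## Data

`data/atc_reference.tsv` is a hand-curated excerpt of the WHO ATC
classification covering all 14 level-1 anatomical main groups plus a
selection of deeper codes. `data/mesh_c_categories.xml` lists the 23
top-level category descriptors of the MeSH disease subtree (2022 release
structure) in NLM DescriptorRecordSet format. Full ontology releases
(complete MeSH XML, ChEMBL ATC extractions) can be substituted directly:
the same parsers handle them.
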