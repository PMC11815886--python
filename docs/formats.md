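# File formats

All tabular files are tab-delimited UTF-8 without quoting. Floats are
written with `%.12g`; every writer/reader pair round-trips to within 1e-9.

## Expression matrix (`read_expression` / `write_expression`)

Genes in rows, samples in columns. First column: gene symbol (header
`gene`); remaining columns: one per sample, named by sample id. Values must
be numeric, finite and non-negative; any `NA` or non-numeric cell is an
error naming the gene and sample. With an alias map, symbols are first
mapped to canonical form; rows mapping to `unknown` (any case) are dropped
and duplicate symbols keep the highest-mean row (both logged).

```
gene	S0001	S0002
EMP3	12.1	3.4
FERMT1	2.0	8.9
```

## Cluster labels (`read_labels` / `write_labels`)

Columns `sample_id`, `cluster`. Each sample at most once. The label order
is taken from `label_order` when given (labels outside it are an error),
else sorted distinct labels. Samples not present in an expression matrix
are allowed and matched later.

## Survival (`read_survival` / `write_survival`)

Columns `sample_id`, `time`, `event`, optional `group`. `time` is days,
strictly positive. `event` is `1` for an observed death and `0` for
censoring; the direction is fixed by the column name.

## Gene-pair feature sets (`read_pairs` / `write_pairs`)

Columns `cluster`, `gene_a`, `gene_b` — one oriented pair per row, grouped
by cluster. The header synonyms `ClusterLabel` / `GeneA` / `GeneB` are
accepted, so published aggregated-feature tables paste in directly. Lines
beginning with `#` are provenance comments (the writer records selection
thresholds there). Within a cluster no gene may appear in two pairs.

## Alias maps (`read_alias_map` / `write_alias_map`)

Columns `alias`, `canonical`. Many aliases may share one canonical symbol;
an alias mapping to two canonicals is an error, as is a map that is not
idempotent (a canonical symbol that is itself an alias of something else).

## Single cell (`read_single_cell` / `write_single_cell`)

Three files: a matrix-market `.mtx` sparse matrix with **cells in rows,
genes in columns**; a plain-text gene list, one symbol per line, in column
order; and a cell-metadata TSV whose first column is the cell id (header
`cell_id`, row order matching the matrix) with at least the columns named
by downstream grouping calls (typically `cell_type` and `condition`,
optionally `donor`).
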