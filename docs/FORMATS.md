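# File formats

All files are plain text; coordinates are μm within the axis-aligned window
[0, width] × [0, height]; densities are cells/mm² (1 mm² = 10⁶ μm²).

## Soma-centre table (CSV)

Required columns `id, x_um, y_um`; optional `diameter_um` (default 10.0) and
`labels` (semicolon-joined tags, e.g. `ON;reference`). Floats are written
with repr-level precision so a save/load round trip is exact.

```
id,x_um,y_um,diameter_um,labels
c0000,45.455995189050526,176.51968827057285,10.0,ON
```

## Arbor territories / clone columns (JSON)

Array of records; `vertices_um` is an ordered ring of a simple
(non-self-intersecting) polygon; `source_field_id` ties an arbor to the
field its reference cell lives in.

```json
[{"reference_id": "c0001", "source_field_id": "f0",
  "vertices_um": [[10.0, 12.0], [40.0, 15.0], [25.0, 44.0]]}]
```

## Dendritic-tip table (CSV)

Columns `tip_id, parent_cell_id, x_um, y_um`.

## Enclosure dataset manifest (JSON)

```json
{"window_um": [353.55, 353.55],
 "fields": [{"id": "f0", "somas_csv": "f0.csv"}, {"id": "f1", "somas_csv": "f1.csv"}],
 "arbors_json": "arbors.json"}
```

## DRP table (TSV)

One annulus per row: `bin_mid_um, count, corrected_area_um2,
density_cells_per_mm2`. Counts are ordered pairs; areas sum every reference
cell's annulus–window intersection.

## Output bundles

Every CLI command writes into its `--out-dir`: `results.json` (the
statistics), any tidy tables as `.tsv`, `config.json` (verbatim parameter
echo plus the pinned RNG algorithm and package version) and `log.txt`.
Failures additionally write `error.json` with a machine-readable record and
exit nonzero.
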