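# On-disk formats

All files are plain TSV; missing values are written `NA`.

## Nucleosome track (BED-like TSV)

One header line, then one row per nucleosome.  Coordinates are 0-based,
half-open (`start < end`); `nucleosome_id` must be unique.

| column | type | meaning |
|---|---|---|
| `chrom` | str | chromosome / contig label |
| `start` | int | interval start, 0-based inclusive |
| `end` | int | interval end, exclusive |
| `nucleosome_id` | str | unique row identifier (joins to matrices) |
| `replication_time_min` | float | minutes after release at which the locus replicates |
| `tss_distance_bp` | float | distance from the transcription start site, bp |
| `gene` | str | associated gene label |
| `induction_class` | str | `none`, `heat`, `alpha`, or `galactose` |
| `heat_induction_log2` | float | expression induction during heat arrest |
| `alpha_induction_log2` | float | expression induction during alpha arrest |

## Time-course matrix TSV

`#key=value` comment lines carry metadata, then a header of time points
(minutes), then one row per nucleosome:

```
#condition=CCA
#channel=H3K4me3
#centered=0
#segments=19
nucleosome_id\t0.0\t5.0\t...
c6_0000\t0.4631\t...
```

- `channel` is `H3K4me3` (log2 enrichment vs midlog) or `occupancy`
  (log2 copies vs panel mean).
- `centered` is 1 after per-row zero-centering.
- `segments` lists cumulative column counts at segment ends for concatenated
  courses (e.g. `19,38`); each segment keeps its own time axis, which is why
  time columns may repeat.
- Values are written with full precision (`repr`) and round-trip bit-exactly.

## Other outputs

Filter reports: TSV with `nucleosome_id`, `status` (`retained`/`removed`),
`reason`.  Truth tables: TSV indexed by `nucleosome_id` with the per-locus
generative parameters (baseline fraction, effective arrest excess, replication
time, effective demethylation rate, class).  Pipeline metrics: JSON, one block
per scenario.
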