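# mirseed

Homology search with covariance models is the standard way to extend the
miRNA repertoire of an under-annotated genome from the families of a
better-annotated relative (e.g. extending rat annotations from mouse).
The raw genome scan, however, returns hundreds of thousands of
"significant" hits, almost all of which are repeat copies, assembly
artifacts, strand shadows or re-discoveries. **mirseed** implements the
post-processing that turns such a hit table into a curated, named set of
novel pre-miRNA annotations, plus the downstream bookkeeping (coordinate
recovery, assembly liftover, short-read expression support) — and a
seeded synthetic-instance generator so the entire pipeline can be tested
end-to-end against planted ground truth without any external data.

## What it does

Given a covariance-model hit table (infernal `--tblout`), a genome FASTA,
repeat annotations (RepeatMasker `.out` or BED) and existing miRNA
annotations (BED/GFF3), the filter cascade applies, in order:

1. **significance** — keep hits with e-value ≤ 0.01 and bit score ≥ *T*,
   where the reporting threshold scales with database size as
   *T* = ⌈log₂(2·G)⌉ bits for a genome of *G* bp (33 bits for a 2.87 Gb
   genome);
2. **known overlap** — drop hits overlapping annotated miRNAs (≥ 1 bp,
   either strand);
3. **unfinished duplicates** — drop scaffold hits whose extracted,
   strand-corrected precursor duplicates a primary-chromosome hit (or a
   better-scoring scaffold hit);
4. **repeat overlap** — drop hits overlapping repeat-masked tracts;
5. **reverse complement** — among opposite-strand overlapping hits at one
   locus, keep only the smallest e-value.

Survivors are then curated: each precursor must fold into a single
hairpin — assessed by exact base-pair maximization (Nussinov-style
dynamic programming over Watson–Crick + G·U pairs, hairpin loop ≥ 3 nt)
with a shape classifier (≥ 14 pairs, ≥ 50 % paired, exactly one
stem-loop) — and its mature and/or mature\* arm must be conserved within
the family alignment (≥ 0.75 identity to the family's modal characters
over the consensus arm columns, after insertion by global alignment to
the family consensus). Accepted candidates are named after their closest
homolog in miRBase style (identical matures at multiple loci get `-1`,
`-2`, … copy indices in genomic order; diverged matures get `a`, `b`, …
letter variants), misassigned existing names are corrected strictly from
a curated rename table, precise coordinates are recovered by ungapped
genome scanning, projected to a newer assembly through UCSC chain files,
and short-read support is counted per sample and tissue (a read counts
when ≥ 50 % of it overlaps the precursor on the same strand).

## Worked example

```python
import tempfile, pathlib
from mirseed import GeneratorParams, RunConfig, generate_instance, run_all

work = pathlib.Path(tempfile.mkdtemp())
paths, manifest = generate_instance(GeneratorParams(), seed=1, out_dir=work)
report = run_all(RunConfig(
    genome=str(paths.genome), tblout=str(paths.tblout),
    repeats=str(paths.repeats), known=str(paths.known),
    families_dir=str(paths.families_dir), chain=str(paths.chain),
    reads_dir=str(paths.reads_dir), sample_sheet=str(paths.sample_sheet),
    out_dir=str(work / "out")))
print(report.n_hits, report.n_candidates, report.n_accepted)
print(sorted(e["name"] for e in report.named))
print(report.support)
```

prints

```
20 9 5
['rno-mir-100', 'rno-mir-101', 'rno-mir-102', 'rno-mir-103', 'rno-mir-104']
{'n_union': 5, 'per_tissue': {'liver': 4, 'thyroid': 4}}
```

The generated instance plants 5 true candidates and 15 decoys; the
cascade removes 3 at significance, 2 at known-overlap, 2 as scaffold
duplicates, 2 in repeats and 2 as reverse-complement shadows
(`out/filter_report.tsv`), curation rejects the 4 planted curation decoys
(`out/decisions.tsv`), and the 5 survivors — exactly the manifest's
`survive_all` set — are named after their mouse homologs, located in the
genome, lifted to the shifted synthetic assembly, and supported by reads
in the planted 3-both / 1-thyroid / 1-liver pattern.

The same stages are available as subcommands of the `mirseed` CLI
(`generate`, `filter`, `curate`, `map`, `liftover`, `support`, `run`);
see `mirseed --help`.

## Layout

- `mirseed.io_formats` — tblout / Stockholm / BED / GFF3 / RepeatMasker /
  UCSC-chain readers and writers; one internal coordinate convention
  (0-based half-open, explicit strand).
- `mirseed.candidate_filter` — the five-stage cascade with per-stage
  accounting (`FilterReport`).
- `mirseed.structure_curation` — folding, hairpin classification,
  conservation scoring, candidate insertion.
- `mirseed.naming` — name grammar, homology naming, rename tables,
  subtype diagnostics.
- `mirseed.genome_mapping` — ungapped sequence location and chain-file
  liftover.
- `mirseed.expression_support` — per-sample read counting and per-tissue
  detection summaries.
- `mirseed.synthetic_data` — seeded instance generator with a
  ground-truth manifest.
- `mirseed.pipeline` / `mirseed.cli` — orchestration and command line.

### Stockholm arm-annotation dialect

Family alignments carry mature/mature\* arm locations as per-sequence
tags of this package's own dialect, in 0-based half-open **alignment
column** coordinates:

```
#=GS mmu-mir-100 MATURE 9-31
#=GS mmu-mir-100 STAR   39-63
```

See `docs/methods.md` for the model, parameter defaults and limitations.
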