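"""End-to-end orchestration: filter -> curate -> name -> map -> liftover -> support.

One :class:`RunConfig` (TOML-loadable) drives a full reproducible run;
:func:`run_all` executes the stages in canonical order, writes every
intermediate artifact, and returns a :class:`RunReport` whose counts are
checked to chain consistently across stages (curation input equals
filter survivors, named set equals curation acceptances, and so on).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .candidate_filter import Candidate, FilterParams, run_cascade
from .errors import ConfigError, MirseedError
from .expression_support import SampleReads, count_overlaps, summarize_support
from .genome_mapping import liftover, locate_sequence
from .io_formats import (
    GenomeStore,
    read_annotations,
    read_chain,
    read_cm_tblout,
    read_repeats,
    read_stockholm,
    write_annotations,
    write_fasta,
)
from .naming import (
    RenameTable,
    apply_renaming,
    assign_names,
    choose_homolog,
    load_packaged_rename_table,
    parse_name,
)
from .structure_curation import (
    CurationParams,
    align_candidate,
    curate,
    family_arm_columns,
    write_decisions,
)
from .io_formats import GAP_CHARS

logger = logging.getLogger("mirseed")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    genome: str
    tblout: str
    repeats: str
    known: str
    families_dir: str
    out_dir: str
    repeats_dialect: str = "bed"
    known_format: str = "bed"
    chain: str | None = None
    reads_dir: str | None = None
    sample_sheet: str | None = None
    rename_table: str | None = None  # path, or "packaged"
    species_prefix: str = "rno"
    filter_params: FilterParams = field(default_factory=FilterParams)
    curation_params: CurationParams = field(default_factory=CurationParams)
    min_read_fraction: float = 0.5
    min_reads: int = 1
    min_samples: int = 1
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = raw.get("paths", {})
        kwargs = dict(paths)
        kwargs.update(raw.get("run", {}))
        filt = raw.get("filter", {})
        cur = raw.get("curation", {})
        support = raw.get("support", {})
        try:
            config = cls(
                **kwargs,
                filter_params=FilterParams(**filt),
                curation_params=CurationParams(**cur),
                **{k: v for k, v in support.items()},
            )
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None
        return config

    def validate(self) -> None:
        required = {
            "genome": self.genome,
            "tblout": self.tblout,
            "repeats": self.repeats,
            "known": self.known,
            "families_dir": self.families_dir,
        }
        for key, value in required.items():
            if not value:
                raise ConfigError(f"config missing required path: {key}")
            if not Path(value).exists():
                raise ConfigError(f"{key} path does not exist: {value}")
        for key in ("chain", "reads_dir", "sample_sheet"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise ConfigError(f"{key} path does not exist: {value}")
        if (self.reads_dir is None) != (self.sample_sheet is None):
            raise ConfigError("reads_dir and sample_sheet must be given together")


@dataclass
class RunReport:
    """Consolidated accounting of one run."""

    filter_stages: list[dict]
    filter_parameters: dict
    n_hits: int
    n_candidates: int
    n_curated_in: int
    n_accepted: int
    named: list[dict]
    n_renamed_existing: int
    n_located: int
    n_multi_hit: int
    n_lifted: int
    n_unmapped: int
    support: dict | None
    config: dict
    version: str = __version__

    def validate(self) -> None:
        if self.filter_stages and self.filter_stages[-1]["n_out"] != self.n_candidates:
            raise MirseedError("report inconsistency: cascade output != candidate count")
        if self.n_curated_in != self.n_candidates:
            raise MirseedError("report inconsistency: curation input != filter survivors")
        if len(self.named) != self.n_accepted:
            raise MirseedError("report inconsistency: named set != curation acceptances")
        if self.n_located != self.n_accepted:
            raise MirseedError("report inconsistency: located != accepted")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _read_sample_sheet(path: str | Path) -> dict[str, str]:
    tissue_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.strip().split("\t")
            if not fields or fields[0] in ("", "sample_id"):
                continue
            tissue_of[fields[0]] = fields[1]
    return tissue_of


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["curation_params"]["allowed_pairs"] = sorted(
        config.curation_params.allowed_pairs
    )
    return echo


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline for one configuration."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = GenomeStore.from_fasta(config.genome)
    hits = read_cm_tblout(config.tblout)
    repeats = read_repeats(config.repeats, config.repeats_dialect)
    known = read_annotations(config.known, config.known_format)
    known_intervals = [iv for _, iv in known]
    families = {}
    for sto in sorted(Path(config.families_dir).glob("*.sto")):
        aln = read_stockholm(sto)
        families[aln.family_id] = aln

    # --- filter cascade ---
    candidates, report = run_cascade(
        hits, genome, repeats, known_intervals, config.filter_params
    )
    logger.info(
        "cascade: %d hits -> %d candidates (thresholds: %s)",
        len(hits),
        len(candidates),
        report.parameters,
    )
    report.to_tsv(out / "filter_report.tsv")
    write_fasta(
        ((c.candidate_id + f" family={c.family_id}", c.sequence) for c in candidates),
        out / "candidates.fa",
    )

    # --- curation ---
    decisions = curate(candidates, families, config.curation_params)
    write_decisions(decisions, out / "decisions.tsv")
    accepted_ids = {d.candidate_id for d in decisions if d.accepted}
    accepted = [c for c in candidates if c.candidate_id in accepted_ids]

    # --- naming ---
    existing_names_raw = [name for name, _ in known if name not in {".", ""}]
    table = None
    if config.rename_table == "packaged":
        table = load_packaged_rename_table()
    elif config.rename_table:
        table = RenameTable.from_tsv(config.rename_table)
    n_renamed = 0
    if table is not None:
        existing_names_raw, n_renamed = apply_renaming(existing_names_raw, table)
    existing_names = []
    for name in existing_names_raw:
        try:
            existing_names.append(parse_name(name))
        except MirseedError:
            logger.warning("unparseable existing annotation name %r", name)

    accepted.sort(key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.strand))
    entries = []
    for cand in accepted:
        family = families[cand.family_id]
        inserted = align_candidate(family, cand.sequence, candidate_name="__candidate__")
        mature_cols = family_arm_columns(inserted, "mature", exclude={"__candidate__"})
        homologs = choose_homolog("__candidate__", inserted, mature_cols)
        row = inserted.get_row("__candidate__")
        mature_seq = "".join(row[c] for c in mature_cols if row[c] not in GAP_CHARS)
        entries.append((cand, homologs[0], mature_seq))
    names = assign_names(entries, existing_names, config.species_prefix)
    for cand, name in zip(accepted, names):
        cand.name = name.render()

    write_annotations(accepted, "gff3", out / "novel_mirnas.gff3")
    write_annotations(accepted, "bed", out / "novel_mirnas.bed")

    # --- coordinate recovery ---
    n_located = n_multi = 0
    for cand in accepted:
        matches = locate_sequence(genome, cand.sequence, query_id=cand.name or "")
        overlapping = [m for m in matches if m.interval.overlaps(cand.interval)]
        if not overlapping:
            raise MirseedError(
                f"{cand.name}: no genome match overlaps the originating hit"
            )
        if len(matches) > 1:
            n_multi += 1
            logger.warning("%s: %d genomic matches; using the originating locus",
                           cand.name, len(matches))
        n_located += 1

    # --- liftover ---
    n_lifted = n_unmapped = 0
    if config.chain:
        chains = read_chain(config.chain)
        lifted, unmapped = [], []
        for cand in accepted:
            result = liftover(cand.interval, chains)
            if result.ok:
                lifted.append((cand.name, result.mapped))
                n_lifted += 1
            else:
                unmapped.append((cand.name, cand.interval, result.reason))
                n_unmapped += 1
        write_annotations(lifted, "bed", out / "novel_mirnas_lifted.bed")
        with open(out / "liftover_unmapped.bed", "w") as fh:
            for name, iv, reason in unmapped:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t{reason}\n")

    # --- read support ---
    support_payload = None
    if config.reads_dir:
        tissue_of = _read_sample_sheet(config.sample_sheet)
        mirnas = [(c.name, c.interval) for c in accepted]
        counts_by_sample = {}
        for sample_id, tissue in tissue_of.items():
            bed = Path(config.reads_dir) / f"{sample_id}.bed"
            reads = [iv for _, iv in read_annotations(bed, "bed")] if bed.exists() else []
            sample = SampleReads(sample_id, tissue, reads)
            counts_by_sample[sample_id] = count_overlaps(
                mirnas, sample, config.min_read_fraction
            )
        summary = summarize_support(
            counts_by_sample, tissue_of, config.min_reads, config.min_samples
        )
        summary.counts.to_csv(out / "support_counts.tsv", sep="\t")
        summary.tissue_summaries.to_csv(out / "support_summary.tsv", sep="\t", index=False)
        support_payload = {
            "n_union": summary.n_union,
            "per_tissue": {t: summary.n_detected(t) for t in summary.tissues},
        }

    run_report = RunReport(
        filter_stages=report.to_frame().to_dict("records"),
        filter_parameters=report.parameters,
        n_hits=len(hits),
        n_candidates=len(candidates),
        n_curated_in=len(decisions),
        n_accepted=len(accepted),
        named=[
            {
                "name": c.name,
                "candidate_id": c.candidate_id,
                "family_id": c.family_id,
                "seq_id": c.interval.seq_id,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
            }
            for c in accepted
        ],
        n_renamed_existing=n_renamed,
        n_located=n_located,
        n_multi_hit=n_multi,
        n_lifted=n_lifted,
        n_unmapped=n_unmapped,
        support=support_payload,
        config=_config_echo(config),
    )
    run_report.validate()
    run_report.save(out / "run_report.json")
    return run_report
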