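"""Short-read expression support for annotated miRNA loci.

Aligned small-RNA reads arrive as BED intervals per sample; a read
supports a miRNA when at least half of the read (configurable) overlaps
the precursor on the same strand. Detection is summarized per tissue —
a miRNA is detected in a tissue when enough samples of that tissue carry
enough reads — together with log-scale count distributions of the kind
shown in small-RNA survey figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import GenomicInterval


@dataclass
class SampleReads:
    """Aligned reads of one sequencing library."""

    sample_id: str
    tissue: str
    reads: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValidationError("tissue must be non-empty")


def count_overlaps(
    mirnas: Sequence[tuple[str, GenomicInterval]],
    sample: SampleReads,
    min_fraction: float = 0.5,
) -> dict[str, int]:
    """Reads per miRNA in one sample.

    A read counts for a miRNA iff ``overlap / read length >=
    min_fraction`` and the strands match; a read may count for several
    overlapping miRNAs. Every miRNA appears in the result (zero counts
    included).
    """
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must be in (0, 1]")
    by_seq: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for name, iv in mirnas:
        by_seq.setdefault(iv.seq_id, []).append((name, iv))
    counts = {name: 0 for name, _ in mirnas}
    for read in sample.reads:
        for name, iv in by_seq.get(read.seq_id, ()):
            if read.strand != iv.strand:
                continue
            if read.overlap_length(iv) / read.length >= min_fraction:
                counts[name] += 1
    return counts


@dataclass
class SupportSummary:
    """Detection flags and count summaries per miRNA and tissue."""

    counts: pd.DataFrame  # miRNAs x samples
    detected: dict[tuple[str, str], bool]
    tissues: list[str]
    min_reads: int
    min_samples: int
    tissue_summaries: pd.DataFrame  # mirna, tissue, log_min, log_median, log_max

    def detected_in(self, tissue: str) -> set[str]:
        return {m for (m, t), flag in self.detected.items() if t == tissue and flag}

    @property
    def detected_union(self) -> set[str]:
        return {m for (m, _), flag in self.detected.items() if flag}

    def n_detected(self, tissue: str) -> int:
        return len(self.detected_in(tissue))

    @property
    def n_union(self) -> int:
        return len(self.detected_union)


def summarize_support(
    counts_by_sample: Mapping[str, Mapping[str, int]],
    tissue_of: Mapping[str, str],
    min_reads: int = 1,
    min_samples: int = 1,
) -> SupportSummary:
    """Fold per-sample counts into per-tissue detection and summaries.

    A miRNA is detected in a tissue iff at least ``min_samples`` samples
    of that tissue each carry at least ``min_reads`` supporting reads.
    Log summaries use ``log(count + 1)`` over the tissue's samples.
    """
    missing = [s for s in counts_by_sample if s not in tissue_of]
    if missing:
        raise ValidationError(f"samples without tissue assignment: {missing}")
    samples = sorted(counts_by_sample)
    mirnas = sorted({m for counts in counts_by_sample.values() for m in counts})
    tissues = sorted(set(tissue_of[s] for s in samples))
    frame = pd.DataFrame(
        [[counts_by_sample[s].get(m, 0) for s in samples] for m in mirnas],
        index=mirnas,
        columns=samples,
        dtype=int,
    )
    detected: dict[tuple[str, str], bool] = {}
    rows = []
    for tissue in tissues:
        cols = [s for s in samples if tissue_of[s] == tissue]
        sub = frame[cols]
        for m in mirnas:
            n_supporting = int((sub.loc[m] >= min_reads).sum())
            detected[(m, tissue)] = n_supporting >= min_samples
            logs = [math.log(c + 1) for c in sub.loc[m]]
            rows.append(
                (
                    m,
                    tissue,
                    detected[(m, tissue)],
                    min(logs) if logs else 0.0,
                    float(pd.Series(logs).median()) if logs else 0.0,
                    max(logs) if logs else 0.0,
                )
            )
    summaries = pd.DataFrame(
        rows, columns=["mirna", "tissue", "detected", "log_min", "log_median", "log_max"]
    )
    return SupportSummary(
        counts=frame,
        detected=detected,
        tissues=tissues,
        min_reads=min_reads,
        min_samples=min_samples,
        tissue_summaries=summaries,
    )


def plot_support(summary: SupportSummary, path: str | None = None):
    """Boxplots of log(count + 1) per miRNA and tissue (survey-figure
    style). Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(summary.tissues), 1, figsize=(10, 3 * len(summary.tissues)), squeeze=False
    )
    for ax, tissue in zip(axes.ravel(), summary.tissues):
        det = sorted(summary.detected_in(tissue))
        data = [
            [math.log(c + 1) for c in summary.counts.loc[m]]
            for m in det
        ]
        if data:
            ax.boxplot(data, tick_labels=det)
            ax.tick_params(axis="x", rotation=90, labelsize=6)
        ax.set_ylabel("log(reads + 1)")
        ax.set_title(tissue)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
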