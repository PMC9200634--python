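"""Per-sample quality control for cfRNA sequencing libraries.

Three metrics proxy the failure modes of plasma RNA libraries:

* ``three_prime_bias`` — fraction of detected genes whose reads all fall on
  the 3'-most exon; high values indicate RNA degradation.
* ``ribosomal_fraction`` — reads mapping to the ribosomal repeat region over
  total reads; high values indicate poor rRNA depletion.
* ``intron_exon_ratio`` — intronic over exonic reads; high values indicate
  genomic DNA contamination.

A sample is excluded when ANY metric is strictly greater than its threshold
(3' bias > 0.4, ribosomal > 0.2, intron/exon > 3); values exactly at a
threshold are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

THREE_PRIME_BIAS_MAX = 0.4
RIBOSOMAL_FRACTION_MAX = 0.2
INTRON_EXON_RATIO_MAX = 3.0

EXON_TABLE_COLUMNS = ("gene_id", "exon_number", "count")


class UndefinedMetricError(ValueError):
    """Raised when a QC metric's denominator is empty or zero."""


@dataclass(frozen=True)
class ReadCategorySummary:
    """Read counts by mapping category for one sample."""

    ribosomal_reads: int
    total_reads: int
    intronic_reads: int
    exonic_reads: int

    def __post_init__(self) -> None:
        for name in ("ribosomal_reads", "total_reads", "intronic_reads", "exonic_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ribosomal_reads > self.total_reads:
            raise ValueError("ribosomal_reads cannot exceed total_reads")


@dataclass(frozen=True)
class QCMetrics:
    """The three quality metrics for one sample, plus pass/fail."""

    sample_id: str
    three_prime_bias: float
    ribosomal_fraction: float
    intron_exon_ratio: float

    @property
    def failures(self) -> list[str]:
        """Names of metrics strictly exceeding their thresholds."""
        out = []
        if self.three_prime_bias > THREE_PRIME_BIAS_MAX:
            out.append("three_prime_bias")
        if self.ribosomal_fraction > RIBOSOMAL_FRACTION_MAX:
            out.append("ribosomal_fraction")
        if self.intron_exon_ratio > INTRON_EXON_RATIO_MAX:
            out.append("intron_exon_ratio")
        return out

    @property
    def passed(self) -> bool:
        return not self.failures


def three_prime_bias(table: pd.DataFrame) -> float:
    """Fraction of detected genes whose reads all map to their 3'-most exon.

    ``table`` has columns (gene_id, exon_number, count), htseq-style. Exon
    numbering is assumed transcript-ordered (strand-aware upstream), so the
    3'-most exon of a gene is the highest exon number present for it.
    Duplicated (gene, exon) rows are summed; genes with zero total reads are
    not "detected" and do not enter either count.
    """
    missing = set(EXON_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"exon table missing columns: {sorted(missing)}")
    counts = (
        table.groupby(["gene_id", "exon_number"], sort=False)["count"].sum().reset_index()
    )
    per_gene = counts.groupby("gene_id", sort=False)
    totals = per_gene["count"].sum()
    detected = totals[totals > 0].index
    if len(detected) == 0:
        raise UndefinedMetricError("no detected genes in exon table")

    def _all_on_last(g: pd.DataFrame) -> bool:
        last = g["exon_number"].max()
        off_last = g.loc[g["exon_number"] != last, "count"].sum()
        return off_last == 0

    flagged = sum(
        _all_on_last(g) for gene, g in counts.groupby("gene_id", sort=False) if gene in set(detected)
    )
    return flagged / len(detected)


def ribosomal_fraction(summary: ReadCategorySummary) -> float:
    """Ribosomal reads over total reads."""
    if summary.total_reads == 0:
        raise UndefinedMetricError("total_reads is zero")
    return summary.ribosomal_reads / summary.total_reads


def intron_exon_ratio(summary: ReadCategorySummary) -> float:
    """Intronic reads over exonic reads (DNA-contamination proxy)."""
    if summary.exonic_reads == 0:
        raise UndefinedMetricError("exonic_reads is zero")
    return summary.intronic_reads / summary.exonic_reads


def evaluate_sample(
    exon_table: pd.DataFrame, summary: ReadCategorySummary, sample_id: str = "sample"
) -> QCMetrics:
    """Compute all three metrics for one sample."""
    return QCMetrics(
        sample_id=sample_id,
        three_prime_bias=three_prime_bias(exon_table),
        ribosomal_fraction=ribosomal_fraction(summary),
        intron_exon_ratio=intron_exon_ratio(summary),
    )


def filter_samples(
    metrics: list[QCMetrics],
) -> tuple[list[QCMetrics], list[tuple[QCMetrics, list[str]]]]:
    """Partition samples into retained and (excluded, violated-metrics) lists."""
    retained = [m for m in metrics if m.passed]
    excluded = [(m, m.failures) for m in metrics if not m.passed]
    return retained, excluded


def report(metrics: list[QCMetrics]) -> pd.DataFrame:
    """Tabular QC report: one row per sample with metrics, pass flag, reasons."""
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metrics],
            "three_prime_bias": [m.three_prime_bias for m in metrics],
            "ribosomal_fraction": [m.ribosomal_fraction for m in metrics],
            "intron_exon_ratio": [m.intron_exon_ratio for m in metrics],
            "pass": [m.passed for m in metrics],
            "failed_metrics": [";".join(m.failures) for m in metrics],
        }
    ).set_index("sample_id")
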