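"""Library representation and sequencing-depth QC.

Pooled lentiviral libraries are judged on how evenly guides are
represented: the standard metric is the fraction of guides whose count
falls within a multiplicative band around the median, here the closed
interval [median/k, median*k] with k = 5 by default and a 90% pass
threshold. Depth is summarized as mean reads per guide (the screen design
targets roughly 1000). QC is advisory only — it never filters guides out
of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RepresentationReport:
    sample_id: str
    median_count: float
    fold_band: float
    fraction_in_band: float  # NaN when the column is all zeros
    zero_count_fraction: float
    mean_reads_per_guide: float
    pass_threshold: float
    passes: bool | None  # None when fraction_in_band is undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CoverageReport:
    sample_id: str
    total_reads: int
    n_guides: int
    mean_reads_per_guide: float
    deciles: dict[int, float] = field(default_factory=dict)


def representation_stats(
    column: pd.Series,
    k: float = 5.0,
    pass_threshold: float = 0.90,
) -> RepresentationReport:
    """Fraction of guides within [median/k, median*k] of the sample median.

    Zero-count guides fall outside the band whenever the median is
    positive. An all-zero column yields median 0 and an undefined
    (NaN-flagged) in-band fraction.
    """
    if len(column) == 0:
        raise ValueError("representation_stats: empty column")
    if k <= 1:
        raise ValueError("fold band k must exceed 1")
    counts = column.to_numpy(dtype=float)
    median = float(np.median(counts))
    mean = float(counts.mean())
    zero_fraction = float((counts == 0).mean())
    if median == 0:
        fraction = float("nan")
        passes = None
    else:
        in_band = (counts >= median / k) & (counts <= median * k)
        fraction = float(in_band.mean())
        passes = fraction >= pass_threshold
    return RepresentationReport(
        sample_id=str(column.name),
        median_count=median,
        fold_band=k,
        fraction_in_band=fraction,
        zero_count_fraction=zero_fraction,
        mean_reads_per_guide=mean,
        pass_threshold=pass_threshold,
        passes=passes,
    )


def coverage_stats(column: pd.Series, library=None) -> CoverageReport:
    """Mean reads per guide with a per-decile count breakdown.

    When a library is given, the denominator is the library size (so
    guides absent from the column still dilute coverage).
    """
    counts = column.to_numpy(dtype=float)
    n_guides = len(library) if library is not None else len(column)
    total = int(counts.sum())
    mean = total / n_guides if n_guides else 0.0
    deciles = {}
    if len(counts):
        qs = np.percentile(counts, np.arange(10, 100, 10))
        deciles = {d: float(v) for d, v in zip(range(10, 100, 10), qs)}
    return CoverageReport(
        sample_id=str(column.name),
        total_reads=total,
        n_guides=n_guides,
        mean_reads_per_guide=mean,
        deciles=deciles,
    )


def qc_table(matrix: pd.DataFrame, k: float = 5.0) -> pd.DataFrame:
    """Per-sample representation report as a tidy table."""
    rows = [representation_stats(matrix[c], k=k).to_dict() for c in matrix.columns]
    return pd.DataFrame(rows).set_index("sample_id")


def format_qc_summary(report: RepresentationReport) -> str:
    status = (
        "undefined (all-zero column)"
        if report.passes is None
        else ("PASS" if report.passes else "FAIL")
    )
    fraction = (
        "n/a"
        if np.isnan(report.fraction_in_band)
        else f"{report.fraction_in_band:.1%}"
    )
    return (
        f"sample {report.sample_id}: median={report.median_count:.1f}, "
        f"{fraction} of guides within {report.fold_band:g}-fold of median "
        f"(threshold {report.pass_threshold:.0%}: {status}), "
        f"{report.zero_count_fraction:.2%} zero-count, "
        f"mean {report.mean_reads_per_guide:.1f} reads/guide"
    )
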