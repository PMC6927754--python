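"""sgRNA library and count-table handling.

The guide library is the reagent universe of a pooled CRISPR screen: one
record per sgRNA with a unique identifier, the targeted gene symbol and the
20-nt spacer sequence. Counts are held as a non-negative integer matrix of
guides x samples, row-aligned to the library.

Read assignment follows the no-mismatch convention: a sequencing read is
credited to a guide only if the guide's exact spacer occurs as a substring
of the read. Reads matching spacers of more than one guide are counted as
ambiguous and assigned to none.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPACER_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: unique id, target gene symbol, spacer sequence."""

    guide_id: str
    gene: str
    spacer: str


class GuideLibrary:
    """Ordered collection of guide records with a gene -> guides index.

    Parameters
    ----------
    frame
        DataFrame with columns ``guide_id``, ``gene``, ``spacer``.
        Row order is preserved and defines the library order.

    Raises
    ------
    ValueError
        On duplicate guide ids or spacers containing characters outside
        ACGT. Duplicate spacers across guides are legal but produce a
        warning (reads matching them become ambiguous).
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["guide_id", "gene", "spacer"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"library table lacks columns: {missing}")
        frame = frame.loc[:, required].reset_index(drop=True)
        frame = frame.astype({"guide_id": str, "gene": str, "spacer": str})
        frame["spacer"] = frame["spacer"].str.upper()

        dup = frame["guide_id"][frame["guide_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate guide_id: {sorted(set(dup))}")
        bad = ~frame["spacer"].map(lambda s: set(s) <= SPACER_ALPHABET)
        if bad.any():
            rows = (np.flatnonzero(bad) + 1).tolist()
            raise ValueError(f"non-ACGT spacer at row(s) {rows}")

        dup_spacers = frame["spacer"][frame["spacer"].duplicated()].unique()
        if len(dup_spacers):
            warnings.warn(
                f"{len(dup_spacers)} spacer sequence(s) shared by multiple "
                "guides; matching reads will be counted as ambiguous",
                stacklevel=2,
            )
        self._frame = frame
        self._shared_spacers = frozenset(dup_spacers)

    @classmethod
    def from_records(cls, records: Iterable[GuideRecord]) -> "GuideLibrary":
        rows = [(r.guide_id, r.gene, r.spacer) for r in records]
        return cls(pd.DataFrame(rows, columns=["guide_id", "gene", "spacer"]))

    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the underlying table (guide_id, gene, spacer)."""
        return self._frame.copy()

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self._frame["guide_id"])

    @property
    def genes(self) -> list[str]:
        return self._frame["gene"].unique().tolist()

    @property
    def n_guides(self) -> int:
        return len(self._frame)

    @property
    def n_genes(self) -> int:
        return self._frame["gene"].nunique()

    @property
    def guide_to_gene(self) -> pd.Series:
        return self._frame.set_index("guide_id")["gene"]

    @property
    def gene_to_guides(self) -> Mapping[str, list[str]]:
        return self._frame.groupby("gene", sort=False)["guide_id"].apply(list).to_dict()

    @property
    def shared_spacers(self) -> frozenset:
        """Spacer sequences carried by more than one guide."""
        return self._shared_spacers

    def spacer_index(self) -> dict[str, str | None]:
        """Map spacer -> guide_id; shared spacers map to ``None``."""
        index: dict[str, str | None] = {}
        for gid, spacer in zip(self._frame["guide_id"], self._frame["spacer"]):
            index[spacer] = None if spacer in self._shared_spacers else gid
        return index

    def __len__(self) -> int:
        return self.n_guides

    def __iter__(self) -> Iterator[GuideRecord]:
        for row in self._frame.itertuples(index=False):
            yield GuideRecord(row.guide_id, row.gene, row.spacer)

    def __repr__(self) -> str:
        return f"GuideLibrary({self.n_guides} guides, {self.n_genes} genes)"


def read_library(
    path: str | Path,
    sep: str = "\t",
    columns: Mapping[str, str] | None = None,
) -> GuideLibrary:
    """Read a guide library table.

    ``columns`` maps the canonical names (guide_id, gene, spacer) to the
    header names used in the file, for tables with non-default headers.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if columns:
        rename = {v: k for k, v in columns.items()}
        frame = frame.rename(columns=rename)
    return GuideLibrary(frame)


def write_library(library: GuideLibrary, path: str | Path, sep: str = "\t") -> None:
    library.frame.to_csv(path, sep=sep, index=False)


def validate_counts(matrix: pd.DataFrame) -> None:
    """Check count-matrix invariants: non-negative integral values."""
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix has non-numeric entries")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at guide {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        frac = np.abs(values - np.round(values)) > 1e-9
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count at guide {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )


def read_counts(
    path: str | Path,
    library: GuideLibrary,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a per-sample count table and align it to the library.

    Guides present in the library but absent from the file become explicit
    zero rows (dropout screens need zeros, not absences); guide rows not in
    the library are dropped. Both events are logged.

    Returns
    -------
    DataFrame indexed by guide_id in library order, one integer column per
    sample.
    """
    frame = pd.read_csv(path, sep=sep)
    if "guide_id" not in frame.columns:
        raise ValueError(f"{path}: counts table lacks a guide_id column")
    frame = frame.set_index("guide_id")
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: counts table has no sample columns")
    validate_counts(frame)

    lib_ids = library.guide_ids
    unknown = frame.index.difference(lib_ids)
    if len(unknown):
        logger.warning(
            "%d guide(s) in counts file but not in library; dropped (e.g. %s)",
            len(unknown),
            list(unknown[:3]),
        )
    missing = lib_ids.difference(frame.index)
    if len(missing):
        logger.warning(
            "%d library guide(s) missing from counts file; filled with 0 (e.g. %s)",
            len(missing),
            list(missing[:3]),
        )
    aligned = frame.reindex(lib_ids, fill_value=0).astype(np.int64)
    aligned.index.name = "guide_id"
    return aligned


def write_counts(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a count matrix; round-trips through :func:`read_counts`."""
    out = matrix.copy()
    out.index.name = "guide_id"
    out.to_csv(path, sep=sep)


@dataclass
class CountingSummary:
    """Read-assignment tally for one sample."""

    sample_id: str
    total_reads: int
    assigned: int
    ambiguous: int
    unassigned: int

    def __post_init__(self) -> None:
        if self.assigned + self.ambiguous + self.unassigned != self.total_reads:
            raise ValueError("read tally does not conserve total reads")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_read_sequences(reads) -> Iterator[str]:
    """Yield uppercase read sequences from a FASTQ path or an iterable."""
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        with _open_maybe_gzip(reads) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                yield str(record.seq).upper()
    else:
        for item in reads:
            yield str(getattr(item, "seq", item)).upper()


def count_spacers(
    reads,
    library: GuideLibrary,
    sample_id: str,
    search_revcomp: bool = False,
) -> tuple[pd.Series, CountingSummary]:
    """Count exact spacer occurrences in single-end reads.

    Every window of each read is looked up in a hash map of the library's
    spacers, so a read is credited to a guide only on an exact,
    mismatch-free occurrence of the full spacer. A read matching the
    spacers of two or more distinct guides — or a spacer shared between
    guides — is ambiguous and assigned to none. By default only the read's
    forward orientation is searched; ``search_revcomp`` also scans the
    reverse complement (amplicon orientation is normally fixed).

    Returns the per-guide count column (library order) and a
    :class:`CountingSummary` whose tallies conserve the total read count.
    """
    index = library.spacer_index()
    lengths = sorted({len(s) for s in index})
    counts: dict[str, int] = dict.fromkeys(library.guide_ids, 0)
    total = assigned = ambiguous = unassigned = 0

    for seq in _iter_read_sequences(reads):
        total += 1
        sequences = (seq, revcomp(seq)) if search_revcomp else (seq,)
        hits: set[str | None] = set()
        for s in sequences:
            for k in lengths:
                for start in range(len(s) - k + 1):
                    window = s[start : start + k]
                    if window in index:
                        hits.add(index[window])
        if not hits:
            unassigned += 1
        elif len(hits) == 1 and None not in hits:
            counts[next(iter(hits))] += 1
            assigned += 1
        else:
            ambiguous += 1

    if total == 0:
        warnings.warn(f"sample {sample_id!r}: empty read stream", stacklevel=2)
    summary = CountingSummary(sample_id, total, assigned, ambiguous, unassigned)
    column = pd.Series(counts, name=sample_id, dtype=np.int64)
    column = column.reindex(library.guide_ids)
    column.index.name = "guide_id"
    return column, summary
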