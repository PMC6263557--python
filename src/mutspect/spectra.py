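"""Accumulation of variant streams into the N x 96 mutation spectra matrix.

The central object is :class:`SpectraMatrix`: integer counts of each of
the 96 SNV subtypes per sample (or per pooled group).  Accumulation is
fully vectorized over samples — for each record the dosage vector is
added to one matrix column in a single operation — so processing time is
independent of sample count and memory holds only the matrix plus one
dosage vector at a time.

Matrices round-trip through a tab-delimited format: first column the row
label, then the 96 canonical subtype columns labeled ``5'[REF>ALT]3'``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import genome as genome_mod
from .subtypes import N_SUBTYPES, classify, subtype_labels
from .variants import SkipCounters, VariantRecord

logger = logging.getLogger(__name__)

#: warn when more than this fraction of records mismatch the reference
REF_MISMATCH_WARN_FRACTION = 0.01


class MatrixFormatError(ValueError):
    pass


class PoolingError(ValueError):
    pass


@dataclass
class SpectraMatrix:
    """Non-negative N x 96 subtype count matrix with row labels."""

    row_labels: list[str]
    counts: np.ndarray  # shape (N, 96), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_SUBTYPES:
            raise MatrixFormatError(
                f"spectra matrix must have {N_SUBTYPES} columns, "
                f"got shape {self.counts.shape}"
            )
        if len(self.row_labels) != self.counts.shape[0]:
            raise MatrixFormatError("row label count does not match matrix rows")
        if (self.counts < 0).any():
            raise MatrixFormatError("spectra counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=list(subtype_labels())
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraMatrix):
            return NotImplemented
        return self.row_labels == other.row_labels and np.array_equal(
            self.counts, other.counts
        )


def accumulate(
    stream: Iterator[VariantRecord],
    genome: genome_mod.GenomeIndex,
    roster: list[str],
    pooling: Mapping[str, str] | None = None,
    counters: SkipCounters | None = None,
    pool_passthrough: bool = False,
) -> SpectraMatrix:
    """Consume a variant stream into a spectra matrix.

    For every record the trinucleotide context at (pos-1 .. pos+1) is
    fetched from the reference, the subtype classified, and the dosage
    vector added to that subtype's column.  Records at sequence edges,
    with ambiguous context, or whose reference base disagrees with the
    FASTA are skipped and counted (a run with >1% reference mismatches
    triggers a warning — the usual sign of a wrong genome build).

    With ``pooling``, dosages are summed into group rows on the fly.
    Roster samples absent from the pooling map are an error unless
    ``pool_passthrough`` makes each its own singleton group.
    """
    if counters is None:
        counters = SkipCounters()
    counters.extra.setdefault("ref_mismatch", 0)
    counters.extra.setdefault("ambiguous_context", 0)
    counters.extra.setdefault("sequence_edge", 0)

    if pooling is not None:
        pooling = dict(pooling)
        unmapped = [s for s in roster if s not in pooling]
        if unmapped and not pool_passthrough:
            raise PoolingError(
                f"samples missing from pooling map: {unmapped[:5]}"
                f"{'...' if len(unmapped) > 5 else ''}"
            )
        for s in unmapped:
            pooling[s] = s
        row_labels: list[str] = []
        for s in roster:
            g = pooling[s]
            if g not in row_labels:
                row_labels.append(g)
        group_row = {g: i for i, g in enumerate(row_labels)}
        proj = np.array([group_row[pooling[s]] for s in roster])
    else:
        row_labels = list(roster)
        proj = None

    M = np.zeros((len(row_labels), N_SUBTYPES), dtype=np.int64)
    n_records = 0
    for rec in stream:
        n_records += 1
        try:
            context = genome_mod.fetch(genome, rec.chrom, rec.pos - 1, rec.pos + 1)
        except genome_mod.RangeError:
            counters.extra["sequence_edge"] += 1
            continue
        if context[1] != rec.ref:
            counters.extra["ref_mismatch"] += 1
            continue
        cls = classify(context, rec.ref, rec.alt)
        if cls is None:
            counters.extra["ambiguous_context"] += 1
            continue
        if proj is None:
            M[:, cls.index] += rec.dosages
        else:
            np.add.at(M[:, cls.index], proj, rec.dosages)

    if n_records and counters.extra["ref_mismatch"] / n_records > REF_MISMATCH_WARN_FRACTION:
        logger.warning(
            "%d/%d records mismatch the reference (middle base != REF); "
            "check that the FASTA matches the variant calls' genome build",
            counters.extra["ref_mismatch"], n_records,
        )
    return SpectraMatrix(row_labels, M)


def merge(matrices: Iterable[SpectraMatrix]) -> SpectraMatrix:
    """Sum matrices over the union of row labels (first-seen order);
    rows absent from an input count as zero.  Associative and
    commutative up to row order, so per-file parallel accumulation
    cannot change results."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to merge")
    row_labels: list[str] = []
    for m in matrices:
        for lbl in m.row_labels:
            if lbl not in row_labels:
                row_labels.append(lbl)
    row_index = {lbl: i for i, lbl in enumerate(row_labels)}
    out = np.zeros((len(row_labels), N_SUBTYPES), dtype=np.int64)
    for m in matrices:
        idx = [row_index[lbl] for lbl in m.row_labels]
        out[idx, :] += m.counts
    return SpectraMatrix(row_labels, out)


def write_matrix(matrix: SpectraMatrix, path: str | os.PathLike) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_matrix(path: str | os.PathLike) -> SpectraMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = list(subtype_labels())
    if list(df.columns) != expected:
        raise MatrixFormatError(
            f"{os.fspath(path)}: header does not match the {N_SUBTYPES} "
            "canonical subtype labels"
        )
    return SpectraMatrix([str(i) for i in df.index], df.to_numpy())
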