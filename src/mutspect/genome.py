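"""Random access to an indexed reference FASTA.

Trinucleotide contexts are fetched one window at a time through a faidx
index (the standard five-column ``.fai`` sidecar: name, length, byte
offset, bases per line, bytes per line), so memory use is independent of
genome size.  Indexing and window reads are delegated to :mod:`pyfaidx`;
this module adds the coordinate conventions and error surface the rest
of the package relies on.

Coordinates are 1-based inclusive throughout, matching VCF ``POS``.
Chromosome names are normalized across the common ``chr`` prefix
disagreement: a query for ``chr22`` resolves against an index entry
``22`` and vice versa (with a one-time warning per run).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from pyfaidx import Faidx, FastaIndexingError, IndexRecord

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    """The FASTA (or its ``.fai`` sidecar) is malformed."""


class UnknownChromosomeError(KeyError):
    """Requested chromosome is absent from the index, even after
    ``chr``-prefix normalization."""


class RangeError(ValueError):
    """Requested window falls outside the sequence bounds."""


@dataclass
class GenomeIndex:
    """Handle to an indexed FASTA.

    ``entries`` maps each sequence name to its ``.fai`` record
    (length, offset, bases per line, bytes per line).  ``fetch`` windows
    are read through the underlying :class:`pyfaidx.Faidx`, which seeks
    directly to the byte offset — the genome is never loaded whole.
    """

    path: str
    entries: dict[str, IndexRecord]
    _faidx: Faidx
    _warned_prefix: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def length(self, chrom: str) -> int:
        return self.entries[self.resolve(chrom)].rlen

    def resolve(self, chrom: str) -> str:
        """Resolve a chromosome name against the index, trying the
        ``chr``-prefixed/stripped alias on a miss."""
        if chrom in self.entries:
            return chrom
        alias = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alias in self.entries:
            if not self._warned_prefix:
                logger.warning(
                    "chromosome %r not in reference; using %r "
                    "(chr-prefix normalization)", chrom, alias,
                )
                self._warned_prefix = True
            return alias
        raise UnknownChromosomeError(
            f"chromosome {chrom!r} not found in {self.path}; "
            f"available: {', '.join(self.entries)}"
        )

    def close(self) -> None:
        self._faidx.file.close()


def load_or_build_index(fasta_path: str | os.PathLike) -> GenomeIndex:
    """Open a FASTA for random access, building the ``.fai`` if absent.

    An existing sidecar ``<fasta>.fai`` is parsed; otherwise the index
    is computed in one pass over the file and written alongside it.
    Raises :class:`FastaFormatError` for an empty file or ragged line
    lengths within a record body.
    """
    fasta_path = os.fspath(fasta_path)
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    if os.path.getsize(fasta_path) == 0:
        raise FastaFormatError(f"{fasta_path} is empty")
    try:
        faidx = Faidx(fasta_path)
    except FastaIndexingError as exc:
        raise FastaFormatError(f"cannot index {fasta_path}: {exc}") from exc
    entries = dict(faidx.index)
    if not entries:
        raise FastaFormatError(f"{fasta_path} contains no sequences")
    for name, rec in entries.items():
        if rec.rlen < 1:
            raise FastaFormatError(f"sequence {name!r} in {fasta_path} is empty")
    return GenomeIndex(path=fasta_path, entries=entries, _faidx=faidx)


def fetch(index: GenomeIndex, chrom: str, start: int, end: int) -> str:
    """Return the uppercase subsequence at 1-based inclusive [start, end].

    Positions beyond either end of the sequence raise :class:`RangeError`
    (callers decide how to treat SNVs at sequence edges); an unknown
    chromosome raises :class:`UnknownChromosomeError`.
    """
    if start < 1 or end < start:
        raise RangeError(f"invalid window [{start}, {end}] (1-based inclusive)")
    name = index.resolve(chrom)
    seqlen = index.entries[name].rlen
    if end > seqlen:
        raise RangeError(
            f"window [{start}, {end}] exceeds length {seqlen} of {name!r}"
        )
    seq = str(index._faidx.fetch(name, start, end))
    return seq.upper()
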