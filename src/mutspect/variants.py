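"""Lazy readers turning VCF or MAF files into a uniform variant stream.

Each reader yields :class:`VariantRecord` values — one per (site,
alt-allele) pair — carrying a per-sample alternate-allele dosage vector
aligned to a fixed sample roster.  Streams are single-pass and bounded:
only the record currently being processed is held in memory, so
arbitrarily large files can be consumed.

Dosage coding follows the diploid genotype: 0/1/2 alternate alleles.
Missing and half-called genotypes contribute only their observed alt
alleles (``./.`` -> 0, ``1/.`` -> 1) and are tallied in the skip
counters.  Phased separators are equivalent to unphased; ploidy above
two counts all alt alleles.  Multiallelic sites are split into one
record per SNV alt allele; indels, symbolic and ``*`` alleles are
skipped and counted.

VCF parsing is delegated to :mod:`cyvcf2` (htslib-backed, handles plain
and bgzip-compressed files).  MAF rows are read with the stdlib
:mod:`csv` module, filtered by allele shape — both alleles single
A/C/G/T — rather than by the producer-dependent ``Variant_Type`` column.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from cyvcf2 import VCF

from .subtypes import BASES


class VcfFormatError(ValueError):
    pass


class MafFormatError(ValueError):
    pass


MAF_REQUIRED_COLUMNS = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
)


@dataclass
class VariantRecord:
    """One SNV (site, alt allele) with per-sample alt-allele dosages."""

    chrom: str
    pos: int  # 1-based, matching VCF POS
    ref: str
    alt: str
    dosages: np.ndarray  # int, length == roster size

    def __post_init__(self) -> None:
        assert self.ref != self.alt and len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SkipCounters:
    """Reconciliation tallies for one streaming run.

    ``sites_read`` counts input site lines (or MAF data rows);
    ``records_emitted`` counts (site, alt) records passed downstream.
    The skip fields account for every input the stream dropped, so the
    run log can reconcile input against output exactly.
    """

    sites_read: int = 0
    records_emitted: int = 0
    non_snv_alleles: int = 0
    filtered: int = 0
    missing_genotypes: int = 0  # sample-site genotypes containing '.'
    extra: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int]:
        d = {
            "sites_read": self.sites_read,
            "records_emitted": self.records_emitted,
            "non_snv_alleles": self.non_snv_alleles,
            "filtered": self.filtered,
            "missing_genotypes": self.missing_genotypes,
        }
        d.update(self.extra)
        return d


def _is_snv_allele(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt


def stream_vcf(
    path: str | os.PathLike,
    keep_samples: Sequence[str] | None = None,
    pass_only: bool = False,
) -> tuple[list[str], Iterator[VariantRecord], SkipCounters]:
    """Stream a multi-sample VCF as (roster, lazy record stream, counters).

    Sites are processed strictly one at a time; the counters object is
    updated as the stream is consumed.  ``pass_only`` restricts to
    records whose FILTER is PASS or '.' (default: use every record).
    """
    path = os.fspath(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError on bad headers
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(
            f"{path} has no sample columns; use the sites-only pseudo-sample "
            "reader for per-file spectra"
        )
    if keep_samples is not None:
        missing = sorted(set(keep_samples) - set(samples))
        if missing:
            raise VcfFormatError(f"samples not in {path}: {missing}")
        vcf.close()
        vcf = VCF(path, samples=list(keep_samples))
        samples = list(vcf.samples)
    if "GT" not in {f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "FORMAT"}:
        raise VcfFormatError(f"{path} has sample columns but no GT FORMAT field")

    counters = SkipCounters()

    def gen() -> Iterator[VariantRecord]:
        n = len(samples)
        for v in vcf:
            counters.sites_read += 1
            if pass_only and v.FILTER is not None:  # None == PASS or '.'
                counters.filtered += 1
                continue
            # allele index matrix: one row per sample, ploidy columns
            gts = np.asarray([g[:-1] for g in v.genotypes], dtype=np.int64)
            if gts.size:
                counters.missing_genotypes += int(np.any(gts < 0, axis=1).sum())
            for ai, alt in enumerate(v.ALT, start=1):
                if not _is_snv_allele(v.REF, alt):
                    counters.non_snv_alleles += 1
                    continue
                dosages = (gts == ai).sum(axis=1) if gts.size else np.zeros(n, dtype=np.int64)
                counters.records_emitted += 1
                yield VariantRecord(v.CHROM, v.POS, v.REF, alt, dosages)

    return samples, gen(), counters


def stream_maf(path: str | os.PathLike) -> tuple[list[str], Iterator[VariantRecord], SkipCounters]:
    """Stream a MAF file as (roster, lazy record stream, counters).

    The roster is the distinct ``Tumor_Sample_Barcode`` values in order
    of first appearance (collected in a cheap pre-scan of that single
    column).  Each qualifying row yields one record with dosage 1 for
    its barcode; rows whose alleles are not single A/C/G/T are skipped
    and counted.
    """
    path = os.fspath(path)

    def open_reader():
        fh = open(path, newline="")
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None:
            fh.close()
            raise MafFormatError(f"{path} is empty")
        for col in MAF_REQUIRED_COLUMNS:
            if col not in reader.fieldnames:
                fh.close()
                raise MafFormatError(f"{path} lacks required MAF column {col!r}")
        return fh, reader

    fh, reader = open_reader()
    roster: list[str] = []
    seen = set()
    with fh:
        for row in reader:
            bc = row["Tumor_Sample_Barcode"]
            if bc not in seen:
                seen.add(bc)
                roster.append(bc)
    if not roster:
        raise MafFormatError(f"{path} contains no data rows")
    index = {s: i for i, s in enumerate(roster)}
    counters = SkipCounters()

    def gen() -> Iterator[VariantRecord]:
        fh, reader = open_reader()
        with fh:
            for row in reader:
                counters.sites_read += 1
                ref = row["Reference_Allele"].upper()
                alt = row["Tumor_Seq_Allele2"].upper()
                if not _is_snv_allele(ref, alt):
                    counters.non_snv_alleles += 1
                    continue
                dosages = np.zeros(len(roster), dtype=np.int64)
                dosages[index[row["Tumor_Sample_Barcode"]]] = 1
                counters.records_emitted += 1
                yield VariantRecord(
                    row["Chromosome"], int(row["Start_Position"]), ref, alt, dosages
                )

    return roster, gen(), counters


def _pseudo_name(path: str) -> str:
    base = os.path.basename(path)
    for suffix in (".gz", ".vcf", ".bcf"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base


def pseudo_sample_stream(
    paths: Iterable[str | os.PathLike],
) -> tuple[list[str], Iterator[VariantRecord], SkipCounters]:
    """Treat each sites-only VCF as one pseudo-sample named from its
    basename; every emitted SNV carries dosage 1 for that sample."""
    paths = [os.fspath(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    roster = [_pseudo_name(p) for p in paths]
    dupes = {n for n in roster if roster.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate pseudo-sample names: {sorted(dupes)}")
    counters = SkipCounters()

    def gen() -> Iterator[VariantRecord]:
        n = len(roster)
        for i, p in enumerate(paths):
            vcf = VCF(p)
            for v in vcf:
                counters.sites_read += 1
                for alt in v.ALT:
                    if not _is_snv_allele(v.REF, alt):
                        counters.non_snv_alleles += 1
                        continue
                    dosages = np.zeros(n, dtype=np.int64)
                    dosages[i] = 1
                    counters.records_emitted += 1
                    yield VariantRecord(v.CHROM, v.POS, v.REF, alt, dosages)
            vcf.close()

    return roster, gen(), counters
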