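import numpy as np
import pytest

import mutspect as ms


@pytest.fixture(scope="session")
def genome_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("genomes")


@pytest.fixture(scope="session")
def small_genome(genome_dir):
    """One 2-chromosome random genome shared across read-only tests."""
    fasta, index = ms.random_genome(2, 600, seed=101, out_dir=genome_dir)
    yield fasta, index
    index.close()


def write_vcf(path, samples, rows, extra_header=""):
    """Hand-rolled VCF writer for crafting edge-case fixtures.

    ``rows`` are (chrom, pos, ref, alt, filter, gt_strings) tuples.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write(extra_header)
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            cols += "\tFORMAT\t" + "\t".join(samples)
        fh.write(cols + "\n")
        for chrom, pos, ref, alt, filt, gts in rows:
            line = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t."
            if samples:
                line += "\tGT\t" + "\t".join(gts)
            fh.write(line + "\n")
    return str(path)


def naive_accumulate(records, index, roster):
    """Brute-force per-record per-sample double loop: the oracle that the
    vectorized accumulator must match integer-exactly."""
    M = np.zeros((len(roster), 96), dtype=np.int64)
    for rec in records:
        try:
            ctx = ms.fetch(index, rec.chrom, rec.pos - 1, rec.pos + 1)
        except Exception:
            continue
        if ctx[1] != rec.ref:
            continue
        cls = ms.classify(ctx, rec.ref, rec.alt)
        if cls is None:
            continue
        for i in range(len(roster)):
            for _ in range(int(rec.dosages[i])):
                M[i, cls.index] += 1
    return M
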