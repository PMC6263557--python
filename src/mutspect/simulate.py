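"""Synthetic reference genomes, variant files, and spectra with known truth.

Everything the rest of the package consumes can be generated here with
a recorded ground truth, enabling exact oracle tests:

* :func:`random_genome` — i.i.d. uniform A/C/G/T FASTA plus ``.fai``;
* :func:`simulate_vcf` / :func:`simulate_maf` — variant files whose true
  per-sample spectra matrix is computed analytically from the same
  draws, so streaming + accumulation must reproduce it integer-exactly;
* :func:`simulate_spectra` — spectra sampled from known signature
  mixtures (multinomial draws from row-normalized ``loadings @
  signatures``), the setting in which NMF recovery is judged;
* :func:`make_separated_signatures` — well-separated synthetic
  signatures (sparse, near-disjoint support plus a small uniform floor)
  so that recovery failures indicate algorithmic defects rather than
  identifiability limits.

All generators are deterministic under their ``seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import genome as genome_mod
from .decompose import LoadingsMatrix, SignatureSet, cosine_similarity_matrix
from .spectra import SpectraMatrix
from .subtypes import BASES, N_SUBTYPES, classify

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class SimulationTruth:
    """Ground truth recorded by a generator.

    For variant-file simulations: the exact expected spectra matrix.
    For mixture simulations: the generating signatures, loadings and
    per-sample depth (expected spectra = depth-scaled mixture).
    """

    spectra: SpectraMatrix
    signatures: SignatureSet | None = None
    loadings: LoadingsMatrix | None = None
    depth: int | None = None


def random_genome(
    n_chroms: int, length: int, seed: int, out_dir: str | os.PathLike,
    line_width: int = 60,
) -> tuple[str, genome_mod.GenomeIndex]:
    """Write a random FASTA (chromosomes ``chr1..chrN``, i.i.d. uniform
    bases) plus its ``.fai``; returns (fasta path, index)."""
    if length < 3:
        raise ValueError("chromosome length must be >= 3")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    path = os.path.join(os.fspath(out_dir), f"genome_{n_chroms}x{length}_s{seed}.fa")
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    with open(path, "w") as fh:
        for c in range(1, n_chroms + 1):
            seq = base_arr[rng.integers(0, 4, size=length)].tobytes().decode()
            fh.write(f">chr{c}\n")
            for i in range(0, length, line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return path, genome_mod.load_or_build_index(path)


def _draw_sites(
    index: genome_mod.GenomeIndex, n_snvs: int, rng: np.random.Generator
) -> list[tuple[str, int, str, str]]:
    """Distinct interior positions (2..L-1) across chromosomes, sorted,
    with an alt drawn uniformly from the three non-reference bases."""
    interior = [(name, rec.rlen - 2) for name, rec in index.entries.items()]
    total = sum(n for _, n in interior)
    if n_snvs > total:
        raise ValueError(
            f"requested {n_snvs} SNVs but genome has only {total} interior positions"
        )
    flat = rng.choice(total, size=n_snvs, replace=False)
    sites = []
    offsets = np.cumsum([0] + [n for _, n in interior])
    for f in np.sort(flat):
        ci = int(np.searchsorted(offsets, f, side="right")) - 1
        chrom = interior[ci][0]
        pos = int(f - offsets[ci]) + 2  # interior: 2 .. L-1
        ref = genome_mod.fetch(index, chrom, pos, pos)
        alt = rng.choice([b for b in BASES if b != ref])
        sites.append((chrom, pos, ref, str(alt)))
    return sites


def _truth_matrix(
    index: genome_mod.GenomeIndex,
    roster: list[str],
    events: list[tuple[str, int, str, str, np.ndarray]],
) -> SpectraMatrix:
    M = np.zeros((len(roster), N_SUBTYPES), dtype=np.int64)
    for chrom, pos, ref, alt, dosages in events:
        context = genome_mod.fetch(index, chrom, pos - 1, pos + 1)
        cls = classify(context, ref, alt)
        assert cls is not None  # sites are drawn from an unambiguous genome
        M[:, cls.index] += dosages
    return SpectraMatrix(list(roster), M)


def simulate_vcf(
    index: genome_mod.GenomeIndex,
    n_samples: int,
    n_snvs: int,
    seed: int,
    out_path: str | os.PathLike,
    alt_freq: float = 0.3,
) -> tuple[str, SimulationTruth]:
    """Write a multi-sample diploid VCF with known per-sample spectra.

    Sites are distinct interior positions; each sample's genotype at
    each site carries Binomial(2, ``alt_freq``) alternate alleles.  The
    truth matrix is accumulated analytically from the same draws, so
    ``accumulate(stream_vcf(...))`` must equal it exactly.
    """
    rng = np.random.default_rng(seed)
    roster = [f"sample{i + 1}" for i in range(n_samples)]
    sites = _draw_sites(index, n_snvs, rng)
    events = []
    out_path = os.fspath(out_path)
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, rec in index.entries.items():
            fh.write(f"##contig=<ID={name},length={rec.rlen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(roster)
            + "\n"
        )
        for chrom, pos, ref, alt in sites:
            dosages = rng.binomial(2, alt_freq, size=n_samples).astype(np.int64)
            gts = "\t".join(_GT_STRINGS[int(d)] for d in dosages)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
            events.append((chrom, pos, ref, alt, dosages))
    return out_path, SimulationTruth(spectra=_truth_matrix(index, roster, events))


def simulate_maf(
    index: genome_mod.GenomeIndex,
    n_samples: int,
    n_snvs: int,
    seed: int,
    out_path: str | os.PathLike,
) -> tuple[str, SimulationTruth]:
    """Write a MAF with known truth: each row is one somatic SNV in one
    tumor sample (dosage 1), barcodes cycling through the roster so every
    sample appears."""
    rng = np.random.default_rng(seed)
    roster = [f"TUMOR-{i + 1:03d}" for i in range(n_samples)]
    sites = _draw_sites(index, n_snvs, rng)
    events = []
    out_path = os.fspath(out_path)
    columns = (
        "Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
        "Variant_Type", "Reference_Allele", "Tumor_Seq_Allele2",
        "Tumor_Sample_Barcode",
    )
    with open(out_path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for i, (chrom, pos, ref, alt) in enumerate(sites):
            si = i % n_samples if i < n_samples else int(rng.integers(n_samples))
            fh.write(
                f"Unknown\t{chrom}\t{pos}\t{pos}\tSNP\t{ref}\t{alt}\t{roster[si]}\n"
            )
            dosages = np.zeros(n_samples, dtype=np.int64)
            dosages[si] = 1
            events.append((chrom, pos, ref, alt, dosages))
    return out_path, SimulationTruth(spectra=_truth_matrix(index, roster, events))


def make_separated_signatures(
    k: int, seed: int, floor: float = 0.01, max_pairwise_cosine: float = 0.3
) -> SignatureSet:
    """Build K well-separated synthetic signatures.

    The 96 subtypes are split into K disjoint blocks; each signature
    concentrates its mass on its own block (Dirichlet within the block)
    plus a small uniform floor over all subtypes.  Pairwise cosine
    similarity is verified <= ``max_pairwise_cosine`` so that signature
    recovery tests probe the algorithm, not identifiability.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8] for disjoint-support construction")
    rng = np.random.default_rng(seed)
    blocks = np.array_split(rng.permutation(N_SUBTYPES), k)
    H = np.full((k, N_SUBTYPES), floor / N_SUBTYPES)
    for i, block in enumerate(blocks):
        H[i, block] += (1.0 - floor) * rng.dirichlet(np.ones(len(block)))
    H /= H.sum(axis=1, keepdims=True)
    if k > 1:
        sims = cosine_similarity_matrix(H, H)
        off = sims[~np.eye(k, dtype=bool)]
        assert off.max() <= max_pairwise_cosine, (
            f"constructed signatures insufficiently separated "
            f"(max pairwise cosine {off.max():.3f})"
        )
    return SignatureSet([f"true{i + 1}" for i in range(k)], H)


def random_loadings(
    n_samples: int, k: int, seed: int, sparsity: float = 0.0
) -> LoadingsMatrix:
    """Random non-negative mixture weights, each row summing to 1."""
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.ones(k), size=n_samples)
    if sparsity > 0:
        mask = rng.random((n_samples, k)) < sparsity
        mask[np.arange(n_samples), W.argmax(axis=1)] = False  # keep one active
        W[mask] = 0.0
        W /= W.sum(axis=1, keepdims=True)
    return LoadingsMatrix(
        [f"sim{i + 1}" for i in range(n_samples)],
        [f"true{j + 1}" for j in range(k)],
        W,
    )


def simulate_spectra(
    signatures: SignatureSet,
    loadings: LoadingsMatrix,
    depth: int,
    seed: int,
) -> tuple[SpectraMatrix, SimulationTruth]:
    """Sample per-sample spectra from known signature mixtures.

    Each sample's mixture distribution is its row of the row-normalized
    ``loadings @ signatures``; ``depth`` mutations are drawn
    multinomially from it.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    W = loadings.matrix
    if W.shape[1] != signatures.k:
        raise ValueError("loadings and signatures disagree on K")
    row_sums = W.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("loadings contain an all-zero row (degenerate sample)")
    P = (W / row_sums[:, None]) @ signatures.matrix
    P /= P.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    counts = np.vstack([rng.multinomial(depth, p) for p in P]).astype(np.int64)
    M = SpectraMatrix(list(loadings.row_labels), counts)
    return M, SimulationTruth(
        spectra=M, signatures=signatures, loadings=loadings, depth=depth
    )
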