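# Methods

## Subtype model

An SNV is classified by its base change and trinucleotide context.
Because a mutation observed on the reverse strand is the same event,
purine-reference records (A or G) are collapsed onto the pyrimidine
strand: the context is reverse-complemented and both alleles
complemented before lookup. This makes `classify` strand-symmetric and
exactly 2-to-1 — the 64 × 3 = 192 unambiguous (trinucleotide, alt)
inputs cover the 96 classes twice each, which the test suite verifies
by enumeration.

The canonical column order is change-major (C>A, C>G, C>T, T>A, T>C,
T>G), then 5' base, then 3' base, bases in A, C, G, T order, labeled
with the COSMIC-style bracket grammar `5'[REF>ALT]3'`. No authority
mandates a particular order, so this package fixes one and uses it in
every reader and writer; it matches the convention of widely used
signature catalogs so matrices are directly comparable.

Soft-masked (lowercase) bases are uppercased before classification —
masking is annotation, not ambiguity. `N` and every other non-ACGT
IUPAC code cannot be assigned a class; such records return a null
classification (skipped and counted), distinct from the errors raised
for structurally malformed input.

## Streaming contract

The VCF reader (cyvcf2/htslib) and MAF reader (stdlib `csv`) yield one
record per (site, alt allele) with a length-N integer dosage vector.
The accumulator fetches the context window `pos−1..pos+1` through a
faidx index (pyfaidx), classifies, and adds the dosage vector to one
matrix column. Retained state is exactly one dosage vector plus the
N × 96 matrix; a test drives the accumulator with a generator that
raises if records are ever buffered. Consequences: time linear in
records and independent of N per record; memory independent of record
count.

Decisions where formats are underspecified:

- **Dosage coding.** Diploid genotypes code 0/1/2 alternate alleles.
  Missing and half-calls count observed alt alleles only (`./.` → 0,
  `1/.` → 1) — the least biased completion — and are tallied. Phased
  `|` equals `/`; ploidy > 2 counts all alt alleles.
- **Multiallelic sites** split into one record per SNV alt allele, each
  with that allele's count per sample. Non-SNV alleles (indels,
  symbolic, `*`) are skipped and counted.
- **FILTER** is ignored by default (call sets differ on its semantics);
  `--pass-only` restricts to PASS/`.`.
- **MAF** rows are filtered by allele shape (both single A/C/G/T), not
  the unreliable `Variant_Type` column; each row contributes dosage 1
  to its `Tumor_Sample_Barcode`. The roster (barcodes in first-seen
  order) is collected in a cheap pre-scan of that one column so the
  stream itself stays single-pass and bounded.
- **Reference mismatches** (FASTA middle base ≠ record REF) are skipped
  and counted; above 1% of records a warning flags a probable
  genome-build mismatch. Sequence-edge SNVs (no flank) are likewise
  skipped and counted. Duplicate site lines all count: the matrix holds
  observed-event frequencies, not distinct sites.
- **Chromosome naming**: `chr22` resolves against `22` and vice versa,
  with a one-time warning.

Every skip path increments a named counter written to the run log, so
`sum(M)` plus skipped dosages reconciles exactly against the input.

Pooling maps samples to groups during accumulation (dosages scattered
into group rows via one indexed add). Samples absent from the pooling
map are an error unless explicitly passed through as singleton groups —
silent dropping never happens. Multi-file inputs are accumulated by
independent workers and merged; merge aligns rows by label over the
union (first-seen order, missing rows zero) and is associative and
commutative, so worker scheduling cannot affect results.

## NMF

Factorization minimizes the Frobenius reconstruction error with the
classic multiplicative updates, chosen because the objective is
provably non-increasing under them — a property the diagnostics record
per iteration and tests assert on every run. Initialization is seeded
uniform on (0,1]; a 1e-9 floor in the update denominators prevents
absorbing zeros. Convergence: relative objective change < `tol`
(default 1e-6) or `max_iter` (default 2000). Because the updates find
local minima, `restarts` independent runs (seeds derived from the user
seed via `SeedSequence` spawn keys) keep the best final objective;
default 1. After convergence each signature row is normalized to sum 1
and the corresponding loading column rescaled, leaving the product
unchanged, so signatures are depth-free probability distributions and
loadings carry the mutation burden.

K is user-supplied; `rank_scan` reports relative reconstruction error
per candidate K to guide the choice, but no automatic selection is
attempted (Bayesian/rank-estimating NMF is the province of the
downstream tools the codegen path targets). An independent cross-check
test confirms the fit reaches reconstruction error comparable to
scikit-learn's NMF on the same matrix.

PCA (scikit-learn, full SVD, column-centered) operates on raw counts by
default with an optional per-row proportion normalization; components
lack non-negativity and hence the mechanistic interpretation of NMF
signatures, but expose sample-similarity structure. A matrix with zero
total variance reports all explained-variance fractions as 0.

Signature matching is greedy assignment by descending cosine
similarity without replacement, ties broken by (inferred, reference)
index for determinism. On well-separated instances greedy agrees with
the exhaustive optimal assignment, verified against a brute-force
K!-enumeration oracle for K ≤ 5.

## Synthetic data

The generators define the study conditions for every oracle test:

- `random_genome`: i.i.d. uniform A/C/G/T, written as FASTA + `.fai`.
  Uniform composition means all 64 trinucleotides occur; real genomes'
  composition bias (e.g. CpG depletion) is deliberately absent, so
  passing tests certify counting/classification machinery, not
  biological realism of the spectra themselves.
- `simulate_vcf`: distinct interior positions, alt uniform over the
  three non-reference bases, diploid genotypes with Binomial(2, 0.3)
  alt dosage. The 0.3 frequency gives substantial mass to all three
  dosage codes (0.49/0.42/0.09), exercising the full coding path; the
  truth matrix is computed analytically from the same draws, making
  `accumulate ∘ stream` an integer-exact equality test.
- `simulate_maf`: one somatic event per row, barcodes cycling so every
  sample appears.
- `simulate_spectra`: per-sample multinomial draws of `depth` mutations
  from the row-normalized mixture `loadings @ signatures`.
- `make_separated_signatures`: K sparse near-disjoint-support
  signatures plus a 1% uniform floor, constructed (and asserted) to
  have pairwise cosine ≤ 0.3. Recovery tests use separated signatures
  on purpose: recoverability degrades with signature correlation for
  any NMF method, and these tests are meant to detect implementation
  defects, not to map the identifiability frontier.

All generators are deterministic under their seed; fixtures are created
at test time, never stored.

## Problem sizes

The shipped tests and acceptance script run at desk scale, chosen to
finish in seconds while still exercising every code path: genomes of
300–900 bp (100 kb for composition checks), 20 random 500-SNV ×
20-sample accumulation fixtures, 20 end-to-end truth-recovery seeds,
one 2504-sample × 100-SNV VCF for the population-scale matrix shape,
and the NMF recovery experiment at 100 samples × depth 5000 from K = 3
signatures. Streaming behavior is size-independent by construction, so
these sizes probe the same code that handles cohort-scale files.

## Known limitations

- 96 subtypes only: no 192-type transcription-strand spectra, no
  extended (5-mer/7-mer) contexts, no indel or doublet classes.
- No normalization by genomic trinucleotide content; counts are raw.
- bgzip-compressed FASTA is not supported (VCFs may be bgzipped).
- Genotype-likelihood-based dosages (GL/PL) are not used; GT only.
- The generated R scripts target the package versions noted in their
  headers and are validated structurally, not executed against R.
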