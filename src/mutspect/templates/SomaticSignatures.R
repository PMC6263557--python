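# Load a mutspect spectra matrix for SomaticSignatures (de novo NMF
# signature extraction). Targets SomaticSignatures 2.x: the motif matrix
# has rows = 96 motifs named like "CA A.A" and columns = samples.
library(SomaticSignatures)

m <- read.table("$matrix_path", header = TRUE, sep = "\t",
                row.names = 1, check.names = FALSE)
stopifnot(ncol(m) == 96)

# "A[C>A]A" -> "CA A.A" motif naming
cols <- colnames(m)
ref  <- substr(cols, 3, 3)
alt  <- substr(cols, 5, 5)
fivep  <- substr(cols, 1, 1)
threep <- substr(cols, 7, 7)
motifs <- paste0(ref, alt, " ", fivep, ".", threep)

sca_mm <- t(as.matrix(m))
rownames(sca_mm) <- motifs

n_sigs <- 5  # choose the number of signatures to extract
sigs_nmf <- identifySignatures(sca_mm, n_sigs, nmfDecomposition)
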