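# Load a mutspect spectra matrix for signeR (Bayesian NMF with
# automatic rank estimation). Targets signeR 1.x: a samples x 96
# integer count matrix.
library(signeR)

m <- read.table("$matrix_path", header = TRUE, sep = "\t",
                row.names = 1, check.names = FALSE)
M <- as.matrix(m)
stopifnot(ncol(M) == 96)
storage.mode(M) <- "integer"

signatures <- signeR(M = M, nlim = c(2, 8))
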