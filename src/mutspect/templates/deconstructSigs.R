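# Load a mutspect spectra matrix for deconstructSigs (supervised
# signature refitting). Targets deconstructSigs 1.8.x: sigs.input is a
# data.frame of samples x 96 trinucleotide contexts labeled "A[C>A]A".
library(deconstructSigs)

m <- read.table("$matrix_path", header = TRUE, sep = "\t",
                row.names = 1, check.names = FALSE)
sigs.input <- as.data.frame(m)
stopifnot(ncol(sigs.input) == 96)

# Per-sample refit against the COSMIC catalog:
results <- lapply(rownames(sigs.input), function(s) {
  whichSignatures(tumor.ref = sigs.input,
                  signatures.ref = signatures.cosmic,
                  sample.id = s,
                  contexts.needed = TRUE)
})
names(results) <- rownames(sigs.input)
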