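"""Counts -> RPKM -> TPM -> log2, with below-minimum imputation.

Uses a hand-sized matrix so every number can be checked on paper.
"""

import pandas as pd

from panelqc import ExpressionMatrix, compute_rpkm, log_transform, rpkm_to_tpm

counts = ExpressionMatrix(
    values=pd.DataFrame(
        {"sampleA": [100.0, 100.0, 0.0], "sampleB": [10.0, 30.0, 60.0]},
        index=["geneX", "geneY", "geneZ"],
    ),
    unit="counts",
    gene_lengths=pd.Series([1000.0, 2000.0, 500.0],
                           index=["geneX", "geneY", "geneZ"]),
)

rpkm = compute_rpkm(counts)
tpm = rpkm_to_tpm(rpkm)
log = log_transform(tpm)

print("RPKM (counts / kb of gene / million mapped reads):")
print(rpkm.values.round(1), "\n")
print("TPM (RPKM rescaled so each sample sums to 1e6):")
print(tpm.values.round(1))
print("column sums:", tpm.values.sum(axis=0).round(6).to_dict(), "\n")
print(f"log2(TPM); zeros imputed at {log.attrs['log_impute_value']:.1f} "
      "(half the smallest positive TPM, so absent genes stay below every "
      "measured value):")
print(log.values.round(3))
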