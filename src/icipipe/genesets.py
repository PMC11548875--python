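"""Built-in gene lists.

Functional T cell scores use the regulatory and cytotoxic panels; the
cell-cycle S and G2/M lists (standard single-cell phase markers) feed the
scaling step's covariate regression. All lists are plain data and may be
replaced by the caller.
"""

REGULATORY_GENES = (
    "ICOS", "FOXP3", "IKZF2", "LAYN", "TNFRSF18", "CTLA4",
    "IL21R", "BATF", "CCR8", "IL2RA", "TNFRSF4",
)

CYTOTOXIC_GENES = (
    "CX3CR1", "PRF1", "GZMA", "GZMB", "GZMH", "GNLY", "KLRG1", "NKG7",
)

# Abridged canonical S / G2M phase marker lists; the synthetic generator
# plants a shared cycling factor on these genes so the regression covariates
# have signal to remove.
S_PHASE_GENES = (
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG",
    "GINS2", "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1",
)

G2M_GENES = (
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF",
)
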