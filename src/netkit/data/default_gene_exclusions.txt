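# Default gene exclusion list applied before any analysis.
# One gene symbol or glob-style pattern per line; '#' starts a comment.

# Genes with discordant quantification between poly(A)-selected and
# total-RNA library protocols (fixed list; lower/missing in poly(A) data:
# CCR2..ZNF460; lower/missing in total-RNA data: CCN1..SNCG).
CCR2
CD28
CD84
MALAT1
PLCG2
RMRP
TERC
WDR74
ZNF460
CCN1
S100A14
SAA1
SAA2-SAA4
SNCG

# Histone genes (protocol-dependent quantification; both current and
# legacy HGNC symbol schemes).
HIST*
H1-[0-9]*
H2A[A-Z]*
H2B[A-Z]*
H3-[0-9]*
H3C[0-9]*
H4C[0-9]*

# Mitochondrially encoded genes.
MT-*

# Mitochondrial ribosomal proteins.
MRPL*
MRPS*

# Cytosolic ribosomal (40S/60S) proteins.  NOTE: the glob also catches
# RPS6K* kinases; see docs/methods.md.
RPL[0-9]*
RPLP[0-9]*
RPS[0-9]*
RPSA

# Non-protein-coding gene families.
MIR[0-9]*
LINC[0-9]*
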