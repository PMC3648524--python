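VEGFA
VEGFB
VEGFC
PGF
FLT1
KDR
FLT4
NRP1
NRP2
SEMA3A
SEMA3B
SEMA3C
SEMA3E
SEMA3F
SEMA3G
SEMA4A
SEMA4D
SEMA4F
SEMA4G
SEMA5A
SEMA5B
SEMA6A
SEMA6B
SEMA7A
PLXNA1
PLXNA3
PLXNB1
PLXNB2
PLXNB3
PLXNC1
PLXND1
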