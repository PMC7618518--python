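# Common contaminant gene symbols: human keratins and frequent
# adventitious proteins (cRAP-style), matched case-insensitively.
KRT1
KRT2
KRT3
KRT4
KRT5
KRT6A
KRT6B
KRT7
KRT8
KRT9
KRT10
KRT12
KRT13
KRT14
KRT15
KRT16
KRT17
KRT18
KRT19
KRT20
KRT23
KRT24
KRT25
KRT26
KRT27
KRT28
KRT31
KRT32
KRT33A
KRT33B
KRT34
KRT35
KRT36
KRT37
KRT38
KRT71
KRT72
KRT73
KRT74
KRT75
KRT76
KRT77
KRT78
KRT79
KRT80
KRT81
KRT82
KRT83
KRT84
KRT85
KRT86
ALB
TRYP1
PRSS1
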