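# SYNTHETIC stand-in table of per-gene RNA->protein rate constants.
# The published per-gene pulse-labeling constants are not redistributed here;
# these are plausible-scale placeholder values (translation rates ~10-100
# protein mRNA^-1 h^-1, protein half-lives ~10-100 h) generated for testing
# and for the packaged default wiring.  Replace the rows with measured
# constants (and fill the provenance column) for real analyses.
# columns: gene, k_sp (protein mRNA^-1 h^-1), k_dp (h^-1), k_sr (h^-1),
#          k_dr (h^-1), provenance
gene	k_sp	k_dp	k_sr	k_dr	provenance
NQO1	61.0	0.026
GLUD1	48.0	0.019
G6PD	55.0	0.031
POR	33.0	0.024
SOD1	86.0	0.012
GSR	27.0	0.022
TXNRD1	38.0	0.035
GPX1	72.0	0.017
CAT	64.0	0.015
PRDX1	95.0	0.014
PRDX2	81.0	0.016
TXN	90.0	0.021
GLRX	42.0	0.028
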