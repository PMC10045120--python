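# Default gene -> model wiring for the 14 mapped redox genes.
# Gene groups joined with "+" act additively on a single multiplier.
# AQP3 scales aquaporin-mediated H2O2 permeation by default; add k34 to its
# list to let it also scale drug permeation.
rate_scaled:
  NQO1: [k29]
  SOD1: [k32]
  POR: [k33]
  AQP3: [k_aqp_h2o2]
  GSR: [k_gsr]
  TXNRD1: [k_trxr]
  G6PD+GLUD1: [k_nadph]
abundance_set:
  GPX1: GPX
  CAT: CAT
  PRDX1+PRDX2: PrxSH
  TXN: TrxSH
  GLRX: Grx
epsilon: 1.0e-3
abundance_mode: equilibrium
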