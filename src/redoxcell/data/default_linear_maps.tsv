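# SYNTHETIC stand-in linear RNA->protein maps for genes lacking
# synthesis/degradation rate constants (the AQP3-style fallback).
# columns: gene, slope (protein copies per RNA unit), intercept (copies)
gene	slope	intercept
AQP3	1200.0	0.0
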