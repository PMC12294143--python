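# Domain lexicon: maps endolysin domain names to their functional class
# (EAD = enzymatically active domain, CBD = cell-wall-binding domain) and,
# for EADs, the catalytic activity. Extend for additional Pfam/SMART/CDD
# models; unknown domain names are kept by the parser with role "unknown".
domains:
  Amidase_5:       {role: EAD, activity: amidase}
  Amidase_2:       {role: EAD, activity: amidase}
  NLPC_P60:        {role: EAD, activity: endopeptidase}
  CHAP:            {role: EAD, activity: CHAP}
  Glucosaminidase: {role: EAD, activity: glucosaminidase}
  Glyco_hydro_25:  {role: EAD, activity: lysozyme}
  PGRP:            {role: EAD, activity: amidase}
  PlyCA:           {role: EAD, activity: unknown}
  pneumo_PspA:     {role: CBD, activity: unknown}
  CW_7:            {role: CBD, activity: unknown}
  ZoocinA_TRD:     {role: CBD, activity: unknown}
  SH3_5:           {role: CBD, activity: unknown}
  LysM:            {role: CBD, activity: unknown}
  PlyCB:           {role: CBD, activity: unknown}
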