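# Reference endolysin architecture list (25 ordered EAD/CBD layouts).
#
# SYNTHETIC RECONSTRUCTION: frequency-ranked architecture labels are
# panel-relative, and only a handful of layouts are pinned by published text
# (A1 = Amidase_5 & NLPC_P60 & ZoocinA_TRD; A2 = ZoocinA_TRD only; A10 with a
# central CW_7 interrupting Amidase_5/NLPC_P60 and Glucosaminidase;
# A20 = CHAP & PlyCA; A21 = PlyCB; no-CBD set {A4,A5,A7,A11,A15,A20,A25};
# no-EAD set {A2,A19,A21}). The remaining layouts here are plausible fillers
# over the shipped domain lexicon that respect those constraints. Use
# rank_architectures(label_map=...) to pin labels to your own reference.
architectures:
  A1:  [Amidase_5, NLPC_P60, ZoocinA_TRD]
  A2:  [ZoocinA_TRD]
  A3:  [Amidase_5, ZoocinA_TRD]
  A4:  [Amidase_5, NLPC_P60]
  A5:  [CHAP]
  A6:  [CHAP, SH3_5]
  A7:  [Glyco_hydro_25]
  A8:  [Glyco_hydro_25, LysM]
  A9:  [Amidase_5, CW_7]
  A10: [Amidase_5, NLPC_P60, CW_7, Glucosaminidase]
  A11: [Glucosaminidase]
  A12: [CHAP, LysM]
  A13: [Glyco_hydro_25, CW_7]
  A14: [Amidase_5, SH3_5]
  A15: [NLPC_P60]
  A16: [Glucosaminidase, ZoocinA_TRD]
  A17: [PGRP, pneumo_PspA]
  A18: [CHAP, ZoocinA_TRD]
  A19: [CW_7]
  A20: [CHAP, PlyCA]
  A21: [PlyCB]
  A22: [Amidase_5, LysM]
  A23: [NLPC_P60, ZoocinA_TRD]
  A24: [Glyco_hydro_25, SH3_5]
  A25: [Amidase_5]
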