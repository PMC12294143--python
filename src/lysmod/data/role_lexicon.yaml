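# Role lexicon: product-string keywords and domain names used to assign lysis
# roles to annotated ORFs. Keywords are matched case-insensitively as whole
# tokens ("lysin" never matches inside "holin"). Edit freely: annotation
# vocabularies differ between RefSeq and automated annotators, so this default
# is a reconstruction of common product strings, not a fixed standard.
keywords:
  holin: holin
  endolysin: endolysin
  lysin: endolysin
  lysozyme: endolysin
  amidase: endolysin
  muramidase: endolysin
  endonuclease: endonuclease
  hypothetical: hypothetical
# Domain evidence: any EAD/CBD domain from the domain lexicon implies
# endolysin; the families below imply holin.
holin_domains:
  - Phage_holin_1
  - Phage_holin_2
  - Phage_holin_3
  - Phage_holin_4
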