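# Organization catalogue: ordered patterns over module role signatures.
# Tokens: H = holin, E = endolysin, N = endonuclease; [N] marks an optional
# endonuclease intercalated at that position. Signatures are matched after
# stripping X (other/hypothetical intercalations); the first matching entry
# (catalogue order) wins. A-C are holin-first, D-E endolysin-first.
#
# NOTE: the per-label gene counts encode one defensible reading of the
# five-way organization scheme for Streptococcus-phage lysis cassettes
# (<=2 ORFs per role, holin-first for A-C, optional endonuclease in C).
# They live in config, not code, precisely so they can be reconciled
# against any reference drawing. Edit to match your own catalogue.
catalogue:
  - label: A
    pattern: H E
  - label: B
    pattern: H H E
  - label: C
    pattern: H [N] E
  - label: D
    pattern: E H
  - label: E
    pattern: E E H
max_per_role: 2
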