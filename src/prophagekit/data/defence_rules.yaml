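# Keyword rules for anti-phage defence system screening. Each system lists its
# required components; a component matches a gene whose product matches the
# (case-insensitive) regular expression. A system is called when one gene per
# component co-occurs within the proximity window (in genes).
#
# This is a lightweight screen, not a profile (HMM) search: PADLOC remains the
# authoritative tool for defence-system annotation.
Thoeris_type1:
  ThsA-like: "ThsA|SIR2|NAD"
  ThsB-like: "ThsB|TIR"
RM_type_II:
  MTase-like: "methyltransferase|modification methylase"
  REase-like: "restriction endonuclease|REase"
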