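# Ordered product-keyword rules mapping annotation text to phage gene roles.
# Patterns are case-insensitive regular expressions; the first matching rule
# wins, so more specific patterns must come first. Edit freely: the detector
# loads this file at import time (or any user-supplied copy).
- pattern: "tail sheath"
  role: tail_sheath
- pattern: "tape measure"
  role: tape_measure
- pattern: "baseplate|tail tip"
  role: baseplate
- pattern: "tail fib(er|re)"
  role: tail_fibre
- pattern: "head[-/ ]tail (joining|adaptor|connector)|head closure|neck protein"
  role: head_tail_joining
- pattern: "major capsid|major head|coat protein|capsid protein"
  role: major_capsid
- pattern: "scaffold"
  role: scaffold
- pattern: "prohead protease|head maturation protease|capsid.*protease|protease.*(phage|capsid|prohead)"
  role: protease
- pattern: "portal"
  role: portal
- pattern: "terminase"
  role: terminase
- pattern: "integrase|recombinase xerc|site-specific recombinase"
  role: integrase
- pattern: "tail shaft|major tail protein|tail tube"
  role: tail_shaft
- pattern: "\\b(holin|endolysin|lysin|lysozyme)\\b"
  role: lysis
- pattern: "phage|virion|prophage|capsid"
  role: other_phage
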