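# Default vinculin domain partition (residue ranges, inclusive).
# Follows the 1TR2 deposition's domain annotations; override with your own
# file for other numbering schemes.  D1-D4 form the head (Vh); the tail (Vt)
# is the fifth helix bundle.  The metavinculin splice insert sits between the
# hinge and the tail and shifts tail numbering by +68.
domains:
  D1: [[1, 252]]
  D2: [[253, 485]]
  D3: [[486, 717]]
  D4: [[718, 835]]
  hinge: [[836, 895]]
  Vt: [[896, 1066]]
  insert: [[916, 983]]
metavinculin_tail_offset: 68
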