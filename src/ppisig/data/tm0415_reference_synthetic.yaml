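# Synthetic stand-in reference annotation (TM0415-style author numbering).
# The sequence is GENERATED: it carries the key donor-site residues
# (K171, F221, R229, R232, M266), the GRGD motif context (231-234) with
# the upstream arginine (R229), the DXXE magnesium motif (173-176) and
# the acceptor-site residues at the correct author positions over a
# random background. It is NOT the real protein sequence; supply your
# own file in the same layout to screen against a real reference.
offset: 1
donor_domain: [169, 286]
key_positions: [171, 221, 229, 232, 266]
acceptor_site:
  11: D
  76: I
  78: N
  89: S
  116: L
  141: Q
  145: R
sequence: |-
  WPQVNSTFCHDVWALTDSDLTHHGRGYKLMNNMYTSRPHYLFTEVPDAKADMYLTWTPKM
  GLIFYACEYQVFRILIPNQEMGYVEMWTSPARLCFMRMPVQIPNDCQINHFEITKLNYIN
  KPKPMQYENKIFCKTCKYYFQQAHRVCQMDTTLWPWYNGDNESWFNAEIVKPDNCEYKFF
  RAYVNLSMLHKSCARITAWDKYDTRKCMKVQHCNGQVIWMFSSWYEKWRAGRGDPDTKTT
  YAVPLSYMCRFFEEWIDEIHHWVNYMDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMY
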