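# Typed-contact rules applied to Delaunay edges between annotated atoms.
# A pair fires a rule when one atom carries class_a, the other class_b,
# and the heavy-atom distance is at most max_dist (Angstrom).
# type	class_a	class_b	max_dist
charged_attractive	positive	negative	6.0
charged_repulsive	positive	positive	6.0
charged_repulsive	negative	negative	6.0
aromatic	aromatic	aromatic	6.0
hydrophobic	hydrophobic	hydrophobic	4.5
hydrogen_bond	donor	acceptor	3.5
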