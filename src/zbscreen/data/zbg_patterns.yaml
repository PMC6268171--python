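# Zinc-binding-group substructure dictionary, v1.
#
# Eight allowed classes of zinc-coordinating functional groups, plus
# exclusion patterns for groups deliberately kept out of the dictionary
# (hydroxamates and thiols) on absorption/metabolism/tolerability grounds.
#
# Each allowed pattern gives a SMARTS and how to find the coordinating
# atoms (the N/O atoms presented to the metal):
#   coordinating: [i, j, ...]  -> indices into the SMARTS atom order
#   coordinating: pyridine-n   -> all pyridine-type ring nitrogens of the
#                                 match (aromatic N, no H, two ring bonds)
# Azole ring patterns are written without NH placement so either tautomer
# of the drawn input matches.  Deprotonated forms (carboxylate,
# tetrazolate, phosphate anions) match their parent class.
#
# The 1-hydroxy-2-oxo class covers enol/phenol hydroxyls adjacent or
# conjugated (incl. peri-fused flavonoid 4-keto-5-OH) to a carbonyl.
# Catechols (two hydroxyls, no carbonyl) are intentionally NOT covered.
version: 1
allowed:
  carboxyl:
    - smarts: "[CX3](=[OX1])[OX2H1]"
      coordinating: [1, 2]
    - smarts: "[CX3](=[OX1])[OX1-]"
      coordinating: [1, 2]
  phosphate:
    - smarts: "[PX4](=[OX1])([OX2,OX1-])[OX2,OX1-]"
      coordinating: [1, 2, 3]
  imidazole:
    - smarts: "c1cncn1"
      coordinating: pyridine-n
  triazole-123:
    - smarts: "c1cnnn1"
      coordinating: pyridine-n
  triazole-124:
    - smarts: "c1ncnn1"
      coordinating: pyridine-n
  tetrazole:
    - smarts: "c1nnnn1"
      coordinating: pyridine-n
  thiadiazole:
    # both the 1,3,4- and 1,2,5-isomers are accepted
    - smarts: "c1nncs1"
      coordinating: pyridine-n
    - smarts: "c1cnsn1"
      coordinating: pyridine-n
  hydroxy-oxo-12:
    # enol/phenol O-H adjacent (1,2) to a carbonyl, or one conjugated bond
    # away (covers the peri-fused flavonoid 4-keto-5-OH chelator and
    # beta-diketone enols such as curcumin)
    - smarts: "[OX2H1][#6]~[#6X3]=[OX1]"
      coordinating: [0, 3]
    - smarts: "[OX2H1][#6]~[#6]~[#6X3]=[OX1]"
      coordinating: [0, 4]
excluded:
  hydroxamate:
    - "[CX3](=[OX1])[NX3][OX2H1]"
    - "[CX3](=[OX1])[NX3][OX1-]"
    - "[NX3]([OX2H1])[CX3]=[OX1]"
  thiol:
    - "[SX2H1]"
    - "[SX1-]"
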