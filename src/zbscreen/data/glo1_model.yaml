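# Packaged Glo-1 structure-based pharmacophore model, v1.
#
# Seven features describing the glyoxalase-1 active site: a zinc-binder
# (ZB) oriented to the catalytic zinc at the bottom of the site, two
# hydrophobic spheres (HY) filling the pocket formed by Leu92/Phe71/
# Met179/Leu160/Leu69/Phe62, two donors (HBD) toward Asn103 and Thr101 at
# the mouth, one acceptor (HBA) toward Lys156 and one negative-ionizable
# (NI) complementary to Arg122/Arg37.  A match requires at least four of
# the seven features and must always include the ZB and its adjacent HY.
#
# Coordinates are SYNTHETIC fixture data: a plausible layout of the
# 1QIN-type active site (zinc at the origin, pocket on +x, polar mouth on
# +y) constructed for this package.  They are not crystallographic
# coordinates; consumers should assert feature composition, not absolute
# positions.
schema: zbscreen-pharmacophore-1
metadata:
  name: glo1
  source_structure: 1QIN
  coordinates: synthetic
  zinc: [0.0, 0.0, 0.0]
min_required: 4
mandatory: [ZB1, HY1]
features:
  - id: ZB1
    kind: ZB
    center: [0.0, 0.0, 2.1]
    tolerance: 1.6
    projection: {target: [0.0, 0.0, 0.0], angle_tol: 30.0}
    annotation: Zn
  - id: HY1
    kind: HY
    center: [3.4, 1.2, 3.2]
    tolerance: 2.2
    annotation: hydrophobic pocket (Leu92/Phe71/Met179/Leu160/Leu69/Phe62)
  - id: HY2
    kind: HY
    center: [6.3, 2.4, 4.0]
    tolerance: 2.2
    annotation: hydrophobic pocket (Leu92/Phe71/Met179/Leu160/Leu69/Phe62)
  - id: HBD1
    kind: HBD
    center: [-2.6, 4.1, 4.4]
    tolerance: 1.6
    projection: {target: [-4.6, 5.6, 5.2], angle_tol: 30.0}
    annotation: Asn103
  - id: HBD2
    kind: HBD
    center: [-4.2, 1.8, 5.6]
    tolerance: 1.6
    projection: {target: [-6.2, 2.2, 6.8], angle_tol: 30.0}
    annotation: Thr101
  - id: HBA1
    kind: HBA
    center: [-0.8, 6.4, 2.2]
    tolerance: 1.6
    projection: {target: [-1.5, 8.9, 1.4], angle_tol: 30.0}
    annotation: Lys156
  - id: NI1
    kind: NI
    center: [2.2, 6.1, 5.8]
    tolerance: 1.6
    annotation: Arg122/Arg37
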