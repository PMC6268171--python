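# Methods

## The screening model

The toolkit encodes a two-criterion selection of zinc-metalloenzyme
inhibitor candidates: a candidate must be 2D-similar to known actives
(fingerprint similarity over a large library) *and* satisfy the 3D
geometry of the target's active site (pharmacophore match), with external
docking scores aggregated at the end as an orthogonal ranking.  The
package assumes a rigid receptor summarized as a pharmacophore model; all
ligand flexibility is handled by conformer enumeration.

## Fingerprints and similarity

Circular environments are grown to a maximum topological *diameter* of 6
bonds (radius 3) and hashed with RDKit's Morgan generator; the hash is
deterministic within an RDKit release and collisions are tolerated.  Two
atom abstractions are exposed: *functional-class* (pharmacophoric role
flags; compared in bit mode, duplicates removed) and *atom-type* (element,
charge, hybridization, connectivity; compared in count mode, duplicates
retained).  Both modes are overridable per call.  Overlap components are
SA/SB/SC (shared / target-only / reference-only); in count mode SA is the
summed per-feature minimum.  Tanimoto, Dice and Cosine are evaluated
exactly as printed in the package docstrings; two empty fingerprints score
0 by convention, avoiding 0/0.  Top-k search is an exhaustive scan with
stable tie-breaking by database input order, so results are reproducible
and equal to a brute-force oracle by construction.

## Drug-likeness and ADMET proxies

The Lipinski/Veber stage uses HBD ≤ 5, HBA ≤ 10, cLogP ≤ 5, MW **strictly
< 500**, rotatable bonds ≤ 10, TPSA ≤ 140 Å²; the molecular-weight bound
is deliberately strict while the others are inclusive, and the default
violation budget is zero (one violation can be tolerated by
configuration).  Donors/acceptors use the Lipinski convention (N-H/O-H
groups; N+O atoms), distinct from the perception rules of the 3D engine.
cLogP is the Crippen atom-contribution estimate and TPSA the Ertl
topological PSA, both fixed by the pinned RDKit version; absolute values
from other descriptor implementations will differ, so thresholds are
meaningful only within this package.

ADMET filtration uses transparent rule-based surrogates with documented
constants: solubility cLogP ≤ 6; absorption TPSA ≤ 131.6 Å² and cLogP
≤ 5.88 (Egan-style bounds); BBB window TPSA ≤ 90 Å² and 1 ≤ cLogP ≤ 4.
BBB is informational by default (`bbb_excluding` opts in) because
peripheral targets do not require CNS penetration; the overall verdict is
solubility AND absorption.

## Ligand preparation

Ionization is rule-table driven: substructure pattern → literature pKa →
toggle action.  A group is toggled whenever its pKa falls within the
physiological window [6.5, 8.5] widened by ±2 units; a group whose pKa
lies entirely below (acids) or above (bases) the widened window is emitted
only in its dominant form, and the input form is always retained.  The
table (v1) covers carboxylic acids (4.2), phosphate OH (2.0), tetrazole NH
(4.9), phenols (10.0), thiophenols (6.6), aliphatic amines (10.5),
imidazoles (7.0) and amidines (12.5).  Tautomers come from RDKit's
transform-rule enumerator (keto-enol, lactam-lactim, azole shifts), capped
at 16; unassigned stereocenters are enumerated up to 2⁴ isomers.  Output
is capped with deterministic priority ionization > tautomer > stereo and
every form carries its parent id.  Deduplication keys on canonical
isomeric SMILES including charges, keep-first, so it is idempotent and
order-stable.

## The zinc-binding-group dictionary

Patterns live in `data/zbg_patterns.yaml` (versioned data).  Azole classes
are written without NH placement so any drawn tautomer matches, and
deprotonated forms (carboxylate, tetrazolate) match their parent class.
Coordinating atoms are either explicit SMARTS indices or "all
pyridine-type ring nitrogens" for azoles.  The 1-hydroxy-2-oxo class
covers enol/phenol hydroxyls adjacent to a carbonyl or one conjugated bond
away, which captures both beta-diketone enols (curcumin-like) and the
peri-fused flavonoid 4-keto-5-OH chelator; catechols (two hydroxyls, no
carbonyl) are deliberately not covered.  Exclusion patterns (hydroxamates
including the reverse N-hydroxy forms, thiols/thiolates) veto only their
own atoms: a molecule carrying both a thiol and a carboxyl still reports
the carboxyl.  Overlapping allowed matches are resolved greedily in fixed
class order, so a tetrazole is never double-reported as a triazole.

The chelation geometry check accepts two coordinating atoms separated by
2.5 ± 0.5 Å, both bounds inclusive — the bidentate hydroxyl/ketone
spacing required for zinc chelation in the flavonoid series.

## Pharmacophore engine

**Perception.**  Ligand-side rules (documented in
`pharmacophore/perceive.py`): donors are N/O bearing hydrogens; acceptors
are oxygens, pyridine-type aromatic nitrogens and non-amide neutral
amines; hydrophobics are centroids of all-carbon rings and of ≥3-carbon
aliphatic chains without heteroatom substituents; negative/positive
ionizables are acid-group/basic-amine centroids; aromatic rings contribute
centroid + normal; ZB points are the coordinating-atom centroids of
dictionary matches.  Complex perception emits one feature per detected
interaction: hydrogen bonds at donor–acceptor distance ≤ 3.5 Å with a
D-H···A angle ≥ 120° when an explicit hydrogen is present (distance-only
otherwise); hydrophobic contacts at ≤ 4.5 Å clustered by ligand
connectivity; charge pairs at ≤ 5.5 Å; and zinc coordination at ligand
N/O to Zn ≤ 2.8 Å, reported as an HBD candidate annotated `Zn`.  The
customization step re-types the single nearest zinc-proximal HBD to the ZB
kind (position and tolerance retained, idempotent), restricting its
chemistry to the dictionary classes at match time.

**The packaged Glo-1 model** carries seven features — ZB×1, HY×2, HBD×2
(Asn103/Thr101), HBA×1 (Lys156), NI×1 (Arg122/Arg37) — with min_required
4 and mandatory {ZB, adjacent HY}, where "adjacent" designates the HY
whose center is nearest the ZB.  Its coordinates are *synthetic* fixture
data: a plausible layout of the 1QIN-type active site (zinc at the origin,
pocket on +x, polar mouth on +y) constructed for this package, since no
crystallographic feature coordinates are published.  Tests assert
composition, never absolute positions.  Default tolerances are 1.6 Å
(2.2 Å for HY), overridable per feature in the model file.

**Matching.**  A match is an injective kind-compatible assignment (ZB
features accept only ZB points) covering all mandatory features and at
least max(min_required, 3) features — three mapped points being the
minimum for a determined rigid transform, which is why the mandatory pair
alone can never constitute a match.  Each candidate assignment is scored
under its own least-squares (Kabsch) superposition of ligand points onto
feature centers; it is accepted iff every displacement is within its
feature's tolerance, and the accepted assignment maximizing
fit = Σ(1 − d/tol) wins, ties broken by mapped count then lexicographic
assignment.  The fit formula is this package's own transparent surrogate:
a perfect 5-feature map scores exactly 5.0, and commercial fit values are
not reproduced.  Note the transform is the least-squares optimum, not a
fit-maximizing one; with unequal tolerances the reported fit can sit below
the naive per-point bound, so tests bound it via Cauchy-Schwarz
(fit ≥ k − √(k·Σjitter²)/min tolerance for a k-point toy).

**Screening** embeds up to 255 ETKDG conformers per molecule
(deterministic per-molecule seeds derived from the run seed), estimates
strain with MMFF94 single-point energies (UFF fallback), drops conformers
more than 20 kcal/mol above the per-molecule minimum, and keeps the best
match per molecule.  Embedding failures are logged skips, never fatal.

## Consensus scoring

Docking itself is out of scope; the module ingests long-form score tables.
The direction map is explicit, versioned configuration: the four GOLD
fitness functions and LibDock are higher-better, CDOCKER energies
lower-better and negated before raw summation.  Candidates missing any of
the six scores are excluded rather than imputed.  `raw_sum` is invariant
to constant shifts of any score; `rank_sum` (per-score ranks, min method)
is additionally invariant to monotone rescaling of any single score.
Ties break by candidate id for determinism.

## Synthetic data: what it does and does not emulate

`synth_library` assembles molecules from a closed fragment grammar (seven
ring scaffolds × substituent lists), giving exact ground truth: which ZBG
class a molecule carries, whether it bears an excluded group, and whether
it violates a drug-likeness rule (hexadecyl chains violate cLogP and
rotatable bonds; hexaol arms violate the donor count).  At n = 10,000 the
grammar yields roughly 2,400 unique structures, so the deduplication stage
works hard, as in a real similarity-search funnel.  The generator makes no
attempt to emulate a real vendor library's property or scaffold
distribution — passing funnel tests demonstrates correct plumbing and
arithmetic, not real-world hit rates.  `toy_conformer` builds "feature
skeletons": minimal chemical fragments (imidazole for ZB, propane for HY,
water for HBD, ether for HBA, methanesulfonate for NI) placed at feature
centers, so k-feature ground truth is exact; they are not realistic
molecules.  `mini_complex` is a fixed ~20-atom SER/LEU/Zn fragment with a
pentane-1,5-diol ligand realizing exactly one hydrogen bond, one
hydrophobic contact and one zinc coordination.  The engineered binder
fixtures (tetrazole/thiadiazole cores with biphenyl and short polar arms)
are real, embeddable molecules with at least one conformer that maps ≥ 4
model features.

## Numerical choices and determinism

All randomness flows from explicit integer seeds; per-molecule embedding
seeds are derived arithmetically and kept below 2³¹.  Funnel reports are
byte-identical across reruns once wall-clock timings are stripped.
Candidate counts are non-increasing from the merge stage onward except at
ligand enumeration; the similarity battery itself maps a library into
hit *rows* (n_ref × n_measures × n_schemes × min(k, library size)), which
at desk scale (10⁴ molecules, k = 500) exceeds the library size even
though it is a massive reduction at vendor-library scale.

## Problem sizes

The default test suite runs libraries of 200–800 molecules with 4–8
conformers per molecule; the acceptance script runs the full funnel on a
10,000-molecule synthetic library with k = 500 and 8 conformers per
prepared form (about two minutes on one CPU), plus a 100-conformer screen
of the binder fixtures.  These sizes were chosen so every stage count is
large enough to exercise the arithmetic while the whole reproduction stays
interactive.

## Known limitations

* Descriptor absolute values (cLogP, TPSA) are implementation-specific;
  filter outcomes near a boundary can differ from other toolkits.
* The perception rules are deliberately compact; subtle donor/acceptor
  contexts (tautomer-dependent acceptors, thione sulfur) are out of scope.
* Receptor perception reads typed atoms and residue labels only; no
  protonation of the receptor is performed.
* The matcher's assignment search is exhaustive with pruning — exact for
  pharmacophore-sized models (≤ ~8 features) but not intended for dense
  feature clouds.
* Selectivity scoring of perceived models, excluded-volume features and
  the docking engines themselves are out of scope; scores are ingested.
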