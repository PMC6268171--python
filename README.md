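# zbscreen

A structure-based virtual-screening toolkit for zinc-metalloenzyme
inhibitor discovery, built around glyoxalase-1 (Glo-1) — a zinc enzyme
whose inhibition starves tumor cells of methylglyoxal detoxification.
Effective Glo-1 inhibitors must coordinate the catalytic zinc at the bottom
of the active site, fill the adjacent hydrophobic pocket, and engage the
polar residues at the site's mouth.

The toolkit implements the full screening funnel:

1. **2D similarity search** — extended-connectivity fingerprints in two
   abstractions (functional-class with duplicates removed; atom-type with
   duplicate counts, both grown to topological diameter 6) scored by the
   three classic overlap measures over shared (SA), target-only (SB) and
   reference-only (SC) features:

   * Tanimoto `SA/(SA+SB+SC)`
   * Dice `2·SA/(2·SA+SB+SC)`
   * Cosine `SA/√((SA+SB)(SA+SC))`

   with top-k search (default k = 500 per run) and the full battery of
   references × measures × schemes.
2. **Drug-likeness filtration** — strict Lipinski + Veber rules
   (HBD ≤ 5, HBA ≤ 10, cLogP ≤ 5, MW < 500, rotatable bonds ≤ 10,
   TPSA ≤ 140 Å²; zero violations by default) plus rule-based ADMET
   proxies for solubility, intestinal absorption and blood-brain-barrier
   penetration.
3. **Ligand preparation** — ionization at pH 6.5–8.5 from a versioned
   pKa rule table, tautomer and stereoisomer enumeration, canonical
   deduplication.
4. **Zinc-binding-group (ZBG) dictionary** — the toolkit's distinctive
   chemistry: a closed list of eight group classes allowed to coordinate
   the zinc (carboxyl, phosphate, imidazole, 1,2,3- and 1,2,4-triazole,
   tetrazole, thiadiazole, 1-hydroxy-2-oxo chelators), with hydroxamates
   and thiols deliberately excluded on absorption, metabolism and
   tolerability grounds, plus the 2.5 ± 0.5 Å bidentate chelation
   geometry check.
5. **3D pharmacophore screening** — a packaged seven-feature Glo-1 model
   (ZB, 2×HY, 2×HBD, HBA, NI), rule-based receptor–ligand perception with
   a zinc-binder customization step, conformer ensembles (up to 255 per
   molecule within a 20 kcal/mol window), and partial matching: at least
   4/7 features, always including the ZB and its adjacent HY, scored by

   `fit = Σ over mapped features (1 − displacement/tolerance)`

   under a least-squares rigid superposition.
6. **Consensus scoring** — ingestion of external docking score tables
   (GoldScore, ChemScore, ASP, CHEMPLP, CDOCKER, LibDock), sign-normalized
   raw-sum or rank-sum aggregation, joined with pharmacophore fit values.

Every stage is testable offline through deterministic synthetic
generators: a labeled fragment-grammar library, exact-k pharmacophore
"feature skeletons", a miniature zinc-site receptor complex, and dominated
docking-score tables.

## Worked example

```python
from zbscreen.chem import records_from_smiles
from zbscreen.zbg import detect_zbg
from zbscreen.pharmacophore import glo1_model, screen
from zbscreen.synth import fixture_binders

rec = records_from_smiles([("O=c1cc(-c2ccccc2)oc2cccc(O)c12", "5-hydroxyflavone")])[0]
for m in detect_zbg(rec):
    print(f"{rec.id}: class={m.zbg_class} coordinating_atoms={m.coordinating}")

model = glo1_model()
print(f"model: {len(model.features)} features, min_required={model.min_required}, "
      f"mandatory={model.mandatory_ids}")

hits = screen(fixture_binders()[:1], model, max_confs=100, seed=7)
for h in hits.hits:
    print(f"{h.record.id}: mapped={h.result.mapped_count} fit={h.result.fit:.2f} "
          f"features={sorted(h.result.assignment)}")
```

prints

```
5-hydroxyflavone: class=hydroxy-oxo-12 coordinating_atoms=(0, 16)
model: 7 features, min_required=4, mandatory=['ZB1', 'HY1']
binder-tetrazole: mapped=4 fit=2.64 features=['HBD1', 'HY1', 'HY2', 'ZB1']
```

The flavonoid's 5-hydroxy/4-keto oxygen pair is recognized as a bidentate
zinc chelator (atom indices 0 and 16 are the two oxygens).  The engineered
tetrazole binder maps four of the seven model features — the mandatory
zinc binder and adjacent hydrophobic sphere, the second hydrophobic
sphere, and one donor — with a fit of 2.64 out of a possible 4.0 for that
mapping (displacements cost `d/tolerance` per feature).

The same funnel runs end to end from a YAML config:

```bash
zbscreen run config.yaml        # writes per-stage artifacts + report.json
zbscreen zbg --in panel.smi     # ZBG matches as CSV
zbscreen make-fixtures --outdir fixtures --n 1000 --seed 1
```

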