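"""End-to-end screening funnel orchestration.

Stages run in a fixed order mirroring the screening narrative:

    similarity_battery -> merge -> deduplicate -> lipinski_veber -> admet
    -> enumerate_forms -> pharmacophore_screen -> consensus

Candidate counts are non-increasing from deduplication onward, except at
the ligand-enumeration stage, which is the only stage permitted to increase
the record count.  Every stage's input count equals the previous stage's
output count; all randomness flows from the single config seed.  Per-stage
artifacts are persisted to the run directory and a JSON funnel report is
written at the end.

Config schema (YAML)::

    seed: 1
    output_dir: runs/demo
    references: {file: refs.smi} | {synthetic: {n: 5}}
    library:    {file: lib.smi}  | {synthetic: {n: 10000, zbg_fraction: 0.5,
                                                violation_fraction: 0.2}}
    similarity: {k: 500, measures: [...], schemes: [...]}
    filters:    {max_violations: 0, bbb_excluding: false}
    ligprep:    {ph_low: 6.5, ph_high: 8.5, max_forms: 8}
    pharmacophore: {model: glo1 | path.yaml, max_confs: 10, energy_window: 20.0}
    consensus:  {score_table: synthetic | path.csv, method: raw_sum, top_n: 9}
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import synth
from .consensus import consensus as consensus_rank
from .consensus import load_scores, select_candidates
from .chem import MoleculeRecord, compute_descriptors, read_molecules, write_molecules
from .filters import admet_proxy, lipinski_veber, reports_to_frame
from .fingerprints import MEASURES, SCHEMES, run_similarity_battery
from .ligprep import deduplicate, prepare_library
from .pharmacophore import glo1_model, load_model, screen

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "similarity_battery", "merge", "deduplicate", "lipinski_veber", "admet",
    "enumerate_forms", "pharmacophore_screen", "consensus",
]

__all__ = ["FunnelReport", "run_pipeline", "STAGE_ORDER"]


@dataclass
class FunnelReport:
    """Ordered per-stage counts, parameters and timing for one run."""

    stages: list[dict] = field(default_factory=list)
    seed: int = 0
    incomplete: bool = False

    def add(self, name: str, n_in: int, n_out: int, params: dict, wall: float):
        self.stages.append({
            "stage": name, "input": int(n_in), "output": int(n_out),
            "params": params, "wall_clock_s": round(wall, 3),
        })

    def validate(self) -> None:
        """Chain and monotonicity invariants; raises on violation."""
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur["input"] != prev["output"]:
                raise ValueError(
                    f"stage {cur['stage']} input {cur['input']} != "
                    f"previous output {prev['output']}")
        for st in self.stages:
            if st["stage"] in ("similarity_battery", "enumerate_forms"):
                continue  # the battery maps molecules to hit rows; ligprep may grow
            if st["output"] > st["input"]:
                raise ValueError(f"stage {st['stage']} increased the candidate count")

    def to_dict(self) -> dict:
        return {"seed": self.seed, "incomplete": self.incomplete, "stages": self.stages}

    def to_json(self, drop_timing: bool = False) -> str:
        doc = self.to_dict()
        if drop_timing:
            doc = json.loads(json.dumps(doc))
            for st in doc["stages"]:
                st.pop("wall_clock_s", None)
        return json.dumps(doc, indent=2, sort_keys=True)

    def counts(self) -> dict[str, int]:
        return {st["stage"]: st["output"] for st in self.stages}


def _load_records(section: dict, seed: int, default_n: int) -> list[MoleculeRecord]:
    if "file" in section:
        return read_molecules(section["file"])
    spec = section.get("synthetic", {}) or {}
    return synth.synth_library(
        n=int(spec.get("n", default_n)), seed=seed,
        zbg_fraction=float(spec.get("zbg_fraction", 0.5)),
        violation_fraction=float(spec.get("violation_fraction", 0.2)),
    )


def run_pipeline(config: str | Path | dict) -> FunnelReport:
    """Execute the full funnel from a config file or dict; returns the report.

    Stage artifacts (CSV/SMILES) and ``report.json`` are written to the
    configured output directory.  A fatal stage error aborts the run and
    writes the partial report flagged incomplete.
    """
    cfg = yaml.safe_load(Path(config).read_text()) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "zbscreen_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = FunnelReport(seed=seed)

    try:
        _run_stages(cfg, seed, outdir, report)
    except Exception:
        report.incomplete = True
        (outdir / "report.json").write_text(report.to_json())
        raise
    report.validate()
    (outdir / "report.json").write_text(report.to_json())
    return report


def _run_stages(cfg: dict, seed: int, outdir: Path, report: FunnelReport) -> None:
    references = _load_records(cfg.get("references", {}), seed=seed + 1, default_n=5)
    library = _load_records(cfg.get("library", {}), seed=seed, default_n=1000)
    by_id = {rec.id: rec for rec in library}

    sim = cfg.get("similarity", {}) or {}
    k = int(sim.get("k", 500))
    measures = sim.get("measures", list(MEASURES))
    schemes = sim.get("schemes", list(SCHEMES))

    t0 = time.perf_counter()
    if library:
        hits = run_similarity_battery(references, library, k=k,
                                      measures=measures, schemes=schemes)
        rows = hits.rows
    else:
        import pandas as pd
        from .fingerprints import HitList
        rows = HitList.empty().rows
    report.add("similarity_battery", len(library), len(rows),
               {"k": k, "measures": measures, "schemes": schemes,
                "n_references": len(references)}, time.perf_counter() - t0)

    t0 = time.perf_counter()
    rows.to_csv(outdir / "battery.csv", index=False)
    report.add("merge", len(rows), len(rows), {}, time.perf_counter() - t0)

    t0 = time.perf_counter()
    seen_ids: list[str] = []
    seen: set[str] = set()
    for tid in rows["target_id"]:
        if tid not in seen:
            seen.add(tid)
            seen_ids.append(tid)
    unique = deduplicate([by_id[tid] for tid in seen_ids])
    if unique:
        write_molecules(unique, outdir / "deduplicated.smi")
    report.add("deduplicate", len(rows), len(unique), {}, time.perf_counter() - t0)

    filt = cfg.get("filters", {}) or {}
    max_violations = int(filt.get("max_violations", 0))
    t0 = time.perf_counter()
    lv_reports = []
    lv_pass = []
    for rec in unique:
        rep = lipinski_veber(compute_descriptors(rec), max_violations=max_violations,
                             record_id=rec.id)
        lv_reports.append(rep)
        if rep.verdict:
            lv_pass.append(rec)
    if lv_reports:
        reports_to_frame(lv_reports).to_csv(outdir / "lipinski_veber.csv", index=False)
    report.add("lipinski_veber", len(unique), len(lv_pass),
               {"max_violations": max_violations}, time.perf_counter() - t0)

    bbb_excluding = bool(filt.get("bbb_excluding", False))
    t0 = time.perf_counter()
    admet_reports = []
    admet_pass = []
    for rec in lv_pass:
        rep = admet_proxy(compute_descriptors(rec), record_id=rec.id,
                          bbb_excluding=bbb_excluding)
        admet_reports.append(rep)
        if rep.verdict:
            admet_pass.append(rec)
    if admet_reports:
        reports_to_frame(admet_reports).to_csv(outdir / "admet.csv", index=False)
    report.add("admet", len(lv_pass), len(admet_pass),
               {"bbb_excluding": bbb_excluding}, time.perf_counter() - t0)

    lp = cfg.get("ligprep", {}) or {}
    t0 = time.perf_counter()
    prepared = prepare_library(admet_pass, ph_low=float(lp.get("ph_low", 6.5)),
                               ph_high=float(lp.get("ph_high", 8.5)),
                               max_forms=int(lp.get("max_forms", 8)))
    if prepared:
        write_molecules(prepared, outdir / "prepared.smi")
    report.add("enumerate_forms", len(admet_pass), len(prepared),
               {"ph_low": lp.get("ph_low", 6.5), "ph_high": lp.get("ph_high", 8.5),
                "max_forms": lp.get("max_forms", 8)}, time.perf_counter() - t0)

    ph = cfg.get("pharmacophore", {}) or {}
    model_name = ph.get("model", "glo1")
    model = glo1_model() if model_name == "glo1" else load_model(model_name)
    max_confs = int(ph.get("max_confs", 10))
    energy_window = float(ph.get("energy_window", 20.0))
    t0 = time.perf_counter()
    screened = screen(prepared, model, max_confs=max_confs,
                      energy_window=energy_window, seed=seed)
    # best form per parent: the funnel counts candidate structures
    best_by_parent: dict[str, object] = {}
    for h in screened.hits:
        key = h.record.parent_id or h.record.id
        prev = best_by_parent.get(key)
        if prev is None or h.result.fit > prev.result.fit:
            best_by_parent[key] = h
    import pandas as pd
    hit_rows = pd.DataFrame([
        {"candidate_id": (h.record.parent_id or h.record.id), "form_id": h.record.id,
         "conformer": h.result.conformer_id, "mapped": h.result.mapped_count,
         "fit": h.result.fit,
         "mapped_features": " ".join(sorted(h.result.assignment))}
        for h in best_by_parent.values()
    ])
    hit_rows = hit_rows.sort_values(["fit", "candidate_id"], ascending=[False, True],
                                    kind="mergesort") if len(hit_rows) else hit_rows
    hit_rows.to_csv(outdir / "screen_hits.csv", index=False)
    report.add("pharmacophore_screen", len(prepared), len(best_by_parent),
               {"model": model_name, "max_confs": max_confs,
                "energy_window": energy_window,
                "min_required": model.min_required,
                "mandatory": list(model.mandatory_ids),
                "screen_counts": screened.counts}, time.perf_counter() - t0)

    cons = cfg.get("consensus", {}) or {}
    t0 = time.perf_counter()
    n_final = 0
    params = {}
    if best_by_parent and cons:
        source = cons.get("score_table", "synthetic")
        candidate_ids = sorted(best_by_parent)
        if source == "synthetic":
            table_df, _plant = synth.synth_score_table(candidate_ids, seed=seed + 2)
        else:
            table_df = source
        score_table = load_scores(table_df)
        method = cons.get("method", "raw_sum")
        ranking = consensus_rank(score_table, method=method)
        fits = {cid: best_by_parent[cid].result.fit for cid in candidate_ids}
        top_n = int(cons.get("top_n", 9))
        final = select_candidates(ranking, fits, top_n=top_n)
        final.to_csv(outdir / "consensus.csv", index=False)
        n_final = len(final)
        params = {"method": method, "top_n": top_n,
                  "score_table": "synthetic" if source == "synthetic" else str(source)}
    report.add("consensus", len(best_by_parent), n_final, params,
               time.perf_counter() - t0)
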