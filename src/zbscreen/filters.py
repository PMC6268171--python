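"""Drug-likeness and ADMET-proxy filtration.

Lipinski + Veber rules with the strict boundaries used throughout this
package: HBD <= 5, HBA <= 10, cLogP <= 5, MW strictly < 500 g/mol,
rotatable bonds <= 10, TPSA <= 140 A^2.  The default tolerance is zero
violations; a single violation may be tolerated by configuration.

The ADMET stage uses transparent rule-based proxies in three named
dimensions (constants documented here, fixed for reproducibility):

* solubility    — cLogP <= 6;
* absorption    — TPSA <= 131.6 A^2 and cLogP <= 5.88 (Egan-style bounds);
* BBB           — TPSA <= 90 A^2 and 1 <= cLogP <= 4, reported as an
  informational flag, non-excluding by default.

The overall ADMET verdict is solubility AND absorption (AND BBB only when
``bbb_excluding`` is set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .chem import DescriptorSet

__all__ = ["RuleOutcome", "FilterReport", "lipinski_veber", "admet_proxy", "reports_to_frame"]


@dataclass(frozen=True)
class RuleOutcome:
    rule: str
    threshold: str
    observed: float
    passed: bool


@dataclass
class FilterReport:
    """Per-molecule filtration outcome for one stage."""

    record_id: str
    stage: Literal["lipinski_veber", "admet"]
    outcomes: list[RuleOutcome] = field(default_factory=list)
    violations: int = 0
    verdict: bool = True

    def outcome(self, rule: str) -> RuleOutcome:
        for o in self.outcomes:
            if o.rule == rule:
                return o
        raise KeyError(rule)


# (rule name, threshold text, descriptor attribute, predicate)
_LIPINSKI_VEBER_RULES = [
    ("hbd", "<= 5", "hbd", lambda v: v <= 5),
    ("hba", "<= 10", "hba", lambda v: v <= 10),
    ("clogp", "<= 5", "clogp", lambda v: v <= 5),
    ("mw", "< 500", "mw", lambda v: v < 500),
    ("rotb", "<= 10", "rotb", lambda v: v <= 10),
    ("tpsa", "<= 140", "tpsa", lambda v: v <= 140),
]

# ADMET proxy constants; fixed, documented values.
SOLUBILITY_CLOGP_MAX = 6.0
ABSORPTION_TPSA_MAX = 131.6
ABSORPTION_CLOGP_MAX = 5.88
BBB_TPSA_MAX = 90.0
BBB_CLOGP_MIN = 1.0
BBB_CLOGP_MAX = 4.0


def lipinski_veber(desc: DescriptorSet, max_violations: int = 0,
                   record_id: str = "") -> FilterReport:
    """Evaluate the six Lipinski/Veber rules on one descriptor set.

    The molecular-weight bound is strict (< 500); all other bounds are
    inclusive.  The verdict passes iff the violation count does not exceed
    ``max_violations`` (default 0: strict selection, no violation allowed).
    """
    outcomes = []
    for rule, threshold, attr, pred in _LIPINSKI_VEBER_RULES:
        value = getattr(desc, attr)
        outcomes.append(RuleOutcome(rule=rule, threshold=threshold,
                                    observed=float(value), passed=bool(pred(value))))
    violations = sum(1 for o in outcomes if not o.passed)
    return FilterReport(
        record_id=record_id,
        stage="lipinski_veber",
        outcomes=outcomes,
        violations=violations,
        verdict=violations <= max_violations,
    )


def admet_proxy(desc: DescriptorSet, record_id: str = "",
                bbb_excluding: bool = False) -> FilterReport:
    """Evaluate the three ADMET proxy rules on one descriptor set.

    BBB penetration is reported as a flag; it only affects the verdict when
    ``bbb_excluding`` is True.
    """
    sol = desc.clogp <= SOLUBILITY_CLOGP_MAX
    absn = desc.tpsa <= ABSORPTION_TPSA_MAX and desc.clogp <= ABSORPTION_CLOGP_MAX
    bbb = desc.tpsa <= BBB_TPSA_MAX and BBB_CLOGP_MIN <= desc.clogp <= BBB_CLOGP_MAX
    outcomes = [
        RuleOutcome("solubility", f"clogp <= {SOLUBILITY_CLOGP_MAX}", desc.clogp, sol),
        RuleOutcome("absorption",
                    f"tpsa <= {ABSORPTION_TPSA_MAX} and clogp <= {ABSORPTION_CLOGP_MAX}",
                    desc.tpsa, absn),
        RuleOutcome("bbb",
                    f"tpsa <= {BBB_TPSA_MAX} and {BBB_CLOGP_MIN} <= clogp <= {BBB_CLOGP_MAX}",
                    desc.tpsa, bbb),
    ]
    verdict = sol and absn and (bbb or not bbb_excluding)
    excluding = [sol, absn] + ([bbb] if bbb_excluding else [])
    violations = sum(1 for ok in excluding if not ok)
    return FilterReport(record_id=record_id, stage="admet", outcomes=outcomes,
                        violations=violations, verdict=verdict)


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Long-form DataFrame: one row per (molecule, rule)."""
    rows = []
    for rep in reports:
        for o in rep.outcomes:
            rows.append({
                "record_id": rep.record_id, "stage": rep.stage, "rule": o.rule,
                "threshold": o.threshold, "observed": o.observed, "passed": o.passed,
                "violations": rep.violations, "verdict": rep.verdict,
            })
    return pd.DataFrame(rows)
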