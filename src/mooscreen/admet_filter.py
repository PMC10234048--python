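"""Ten-rule ADMET / physicochemical screen for potential active compounds.

A compound is certified "potentially active" only if it satisfies all ten
rules simultaneously: the five Lipinski-style physicochemical bounds
(MW <= 500 g/mol, nHD <= 5, nHA <= 10, logP <= 5, nRot <= 10) and five
predicted ADMET model outputs (F20, BBB, hERG, HHT each <= 0.7, TPSA
<= 140 A^2). All comparators are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CompoundTable, PROPERTY_COLUMNS

#: (property, comparator, threshold) — the default screen.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "MW": 500.0,
    "nHD": 5.0,
    "nHA": 10.0,
    "logP": 5.0,
    "nRot": 10.0,
    "F20": 0.7,
    "BBB": 0.7,
    "hERG": 0.7,
    "HHT": 0.7,
    "TPSA": 140.0,
}


@dataclass(frozen=True)
class FilterRuleSet:
    """Ten inclusive upper-bound rules plus a policy for missing properties.

    missing_policy: "fail" rejects a compound whose property is absent
    (conservative default), "pass" treats the rule as satisfied,
    "ignore-rule" drops the rule for that compound only.
    """

    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    missing_policy: str = "fail"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("fail", "pass", "ignore-rule"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        for prop, thr in self.thresholds.items():
            if not (thr == thr and abs(thr) != float("inf")):
                raise ValueError(f"non-finite threshold for {prop}")


def apply_filter(
    table: CompoundTable, rules: FilterRuleSet | None = None
) -> tuple[CompoundTable, pd.DataFrame]:
    """Screen a compound table; returns (passed subset, per-compound audit).

    The audit has one row per input compound with a boolean verdict per
    rule (True = satisfied), the overall ``passed`` flag, the
    ``first_failed`` rule name and the ``;``-joined ``failed_rules`` list.
    A rule on a missing property yields the verdict dictated by
    ``missing_policy`` and is annotated ``missing`` in ``failed_rules``
    when it causes rejection.
    """
    rules = rules or FilterRuleSet()
    audit_rows = []
    passed = []
    for rec in table:
        verdicts: dict[str, object] = {"compound_id": rec.compound_id}
        failed: list[str] = []
        for prop, thr in rules.thresholds.items():
            value = rec.properties.get(prop)
            if value is None:
                if rules.missing_policy == "fail":
                    ok = False
                    failed.append(f"{prop}(missing)")
                else:  # "pass" and "ignore-rule" both let the compound through
                    ok = True
            else:
                ok = value <= thr
                if not ok:
                    failed.append(prop)
            verdicts[prop] = ok
        verdicts["passed"] = not failed
        verdicts["first_failed"] = failed[0] if failed else ""
        verdicts["failed_rules"] = ";".join(failed)
        audit_rows.append(verdicts)
        if not failed:
            passed.append(rec)
    cols = ["compound_id", *rules.thresholds, "passed", "first_failed", "failed_rules"]
    audit = pd.DataFrame(audit_rows, columns=cols)
    return CompoundTable(passed), audit


def summarize_by_herb(passed: CompoundTable) -> pd.DataFrame:
    """Per-herb pass counts; compounds shared by k herbs count once in each.

    Returns a frame with one row per herb plus a final ``__unique__`` row
    carrying the deduplicated total.
    """
    counts: dict[str, int] = {}
    for rec in passed:
        for herb in rec.herbs:
            counts[herb] = counts.get(herb, 0) + 1
    rows = [{"herb": h, "n_compounds": counts[h]} for h in sorted(counts)]
    rows.append({"herb": "__unique__", "n_compounds": len(passed)})
    return pd.DataFrame(rows, columns=["herb", "n_compounds"])
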