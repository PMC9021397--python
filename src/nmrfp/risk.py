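"""Clinical risk classifiers and the metabolomics x LVEF combined score.

LVEF classes follow the ESC heart-failure convention: reduced (<40%,
high risk), mid-range (40-49%, intermediate), preserved (>=50%, low).
NT-proBNP above 400 pg/ml marks high risk.  The combined score starts
from the metabolomic class and lets extreme LVEF values override it:
predicted survivors with LVEF < 35% become high risk, predicted deceased
with LVEF > 50% become low risk; in between, metabolomics governs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plsda import DECEASED, SURVIVOR

__all__ = [
    "RiskAssignment",
    "lvef_classify",
    "ntprobnp_classify",
    "combine_met_lvef",
    "combine_met_ntprobnp",
    "risk_table",
    "covariate_matrix",
    "DICHOTOMIES",
]

LOW, HIGH = "low", "high"
LR, IR, HIR = "LR", "IR", "HiR"


@dataclass(frozen=True)
class RiskAssignment:
    """One patient's risk class from one source, with rule provenance."""

    patient_id: str
    source: str
    risk_class: str
    provenance: str

    _LEGAL = {
        "metabolomics": {LOW, HIGH},
        "lvef": {LR, IR, HIR},
        "ntprobnp": {LOW, HIGH},
        "combined_met_lvef": {LOW, HIGH},
        "combined_met_ntprobnp": {LOW, HIGH},
    }

    def __post_init__(self):
        legal = self._LEGAL.get(self.source)
        if legal is None:
            raise ValueError(f"unknown risk source {self.source!r}")
        if self.risk_class not in legal:
            raise ValueError(
                f"risk class {self.risk_class!r} not legal for source "
                f"{self.source!r} (legal: {sorted(legal)})")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


def lvef_classify(lvef: float) -> str:
    """ESC LVEF risk class: HiR if <40, IR if 40-49, LR if >=50."""
    if not 0 < lvef < 100:
        raise ValueError(f"LVEF {lvef} out of range (0, 100)")
    if lvef < 40:
        return HIR
    if lvef < 50:
        return IR
    return LR


def ntprobnp_classify(value: float, threshold: float = 400.0) -> str:
    """High risk iff NT-proBNP strictly above ``threshold`` pg/ml."""
    if value < 0:
        raise ValueError(f"NT-proBNP {value} must be non-negative")
    return HIGH if value > threshold else LOW


def combine_met_lvef(metab_class: str, lvef: float) -> tuple[str, str]:
    """Combined metabolomics x LVEF score; returns (risk, provenance).

    Metabolomics screens first (survivor -> low, deceased -> high);
    LVEF overrides only at its prognostically-extreme values:
    survivor-predicted patients with LVEF < 35% are reclassified high
    risk, deceased-predicted patients with LVEF > 50% low risk.
    """
    if metab_class not in (SURVIVOR, DECEASED):
        raise ValueError(f"unknown metabolomic class {metab_class!r}")
    if not 0 < lvef < 100:
        raise ValueError(f"LVEF {lvef} out of range (0, 100)")
    if metab_class == SURVIVOR and lvef < 35:
        return HIGH, "LVEF<35 override"
    if metab_class == DECEASED and lvef > 50:
        return LOW, "LVEF>50 override"
    risk = HIGH if metab_class == DECEASED else LOW
    return risk, "metabolomics"


def combine_met_ntprobnp(metab_class: str, ntprobnp_class: str,
                         rule: str = "either_high") -> str:
    """Combine metabolomics with the NT-proBNP threshold class.

    Strategies: ``either_high`` (high iff either source is high, default),
    ``both_high``, ``met_only``.
    """
    if metab_class not in (SURVIVOR, DECEASED):
        raise ValueError(f"unknown metabolomic class {metab_class!r}")
    if ntprobnp_class not in (LOW, HIGH):
        raise ValueError(f"unknown NT-proBNP class {ntprobnp_class!r}")
    met_high = metab_class == DECEASED
    bnp_high = ntprobnp_class == HIGH
    if rule == "either_high":
        return HIGH if (met_high or bnp_high) else LOW
    if rule == "both_high":
        return HIGH if (met_high and bnp_high) else LOW
    if rule == "met_only":
        return HIGH if met_high else LOW
    raise ValueError(f"unknown combination rule {rule!r}")


def risk_table(cohort: pd.DataFrame, metab_class,
               ntprobnp_rule: str = "either_high") -> pd.DataFrame:
    """Per-patient risk classes from every source, one column per source.

    ``cohort`` needs ``patient_id``, ``lvef`` and ``nt_probnp`` columns;
    ``metab_class`` is the per-patient metabolomic class aligned with the
    cohort rows.
    """
    metab = np.asarray(metab_class)
    if metab.size != len(cohort):
        raise ValueError("metab_class length must match cohort")
    rows = []
    for (_, pat), met in zip(cohort.iterrows(), metab):
        lv = lvef_classify(float(pat["lvef"]))
        bnp = ntprobnp_classify(float(pat["nt_probnp"]))
        comb_lv, prov = combine_met_lvef(met, float(pat["lvef"]))
        comb_bnp = combine_met_ntprobnp(met, bnp, rule=ntprobnp_rule)
        rows.append({"patient_id": pat["patient_id"],
                     "metabolomics": HIGH if met == DECEASED else LOW,
                     "lvef": lv,
                     "ntprobnp": bnp,
                     "combined_met_lvef": comb_lv,
                     "combined_met_lvef_provenance": prov,
                     "combined_met_ntprobnp": comb_bnp})
    return pd.DataFrame(rows)


#: Table-style dichotomizations of the continuous clinical covariates
#: (strict ">" at each boundary).
DICHOTOMIES: dict[str, tuple[str, float]] = {
    "age_gt_60": ("age_at_diagnosis", 60.0),
    "time_gt_15": ("time_from_diagnosis", 15.0),
    "ntprobnp_gt_400": ("nt_probnp", 400.0),
    "sbp_gt_130": ("sbp", 130.0),
    "eddi_gt_30": ("eddi", 30.0),
    "lavi_gt_40": ("lavi", 40.0),
}


def covariate_matrix(cohort: pd.DataFrame,
                     include: list[str] | None = None) -> pd.DataFrame:
    """Adjusted-model covariate matrix with declared reference levels.

    Continuous covariates are dichotomized per :data:`DICHOTOMIES`; sex is
    coded male = 1 (reference female); NYHA enters as indicators for class
    II and III-IV against reference I; LVEF as indicators for reduced and
    mid-range against preserved.
    """
    cols = {}
    cols["sex_male"] = (cohort["sex"].astype(str) == "M").astype(float)
    for name, (src, cut) in DICHOTOMIES.items():
        cols[name] = (cohort[src].astype(float) > cut).astype(float)
    nyha = cohort["nyha"].astype(str)
    cols["nyha_II"] = (nyha == "II").astype(float)
    cols["nyha_III_IV"] = nyha.isin(["III", "IV"]).astype(float)
    lvef_cls = cohort["lvef"].astype(float).map(lvef_classify)
    cols["lvef_reduced"] = (lvef_cls == HIR).astype(float)
    cols["lvef_midrange"] = (lvef_cls == IR).astype(float)
    out = pd.DataFrame(cols, index=cohort.index)
    if include is not None:
        missing = set(include) - set(out.columns)
        if missing:
            raise KeyError(f"unknown covariates requested: {sorted(missing)}")
        out = out[include]
    return out
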