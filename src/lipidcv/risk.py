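"""Declarative 10-year cardiovascular risk equation evaluator.

Published 10-year coronary heart disease risk scores (Framingham-,
Reynolds- and D:A:D-style) share a common structure: a linear predictor
over transformed risk factors, mapped to an absolute risk either through
a Cox baseline survival (risk = 1 - S0^exp(L - L_ref)) or through a
Poisson-type rate (risk = 1 - exp(-exp(L) * t)). This module evaluates
any equation of that structure from a declarative description; the
published coefficient values themselves are data, shipped as editable
YAML templates with citation fields rather than hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .crossval import auc_rank

__all__ = [
    "RiskTerm",
    "RiskEquation",
    "linear_predictor",
    "ten_year_risk",
    "score_cohort",
    "load_equation",
    "save_equation",
    "equation_template_dir",
]

TRANSFORMS = ("identity", "natural_log", "binary")
FORMS = ("cox_survival", "log_rate")


@dataclass(frozen=True)
class RiskTerm:
    variable: str
    transform: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}")


@dataclass
class RiskEquation:
    """A 10-year risk equation: terms, functional form, and baseline.

    ``centering`` maps variables to reference values subtracted on the
    transformed scale (log-transformed variables are centered at
    ``ln(reference)``), the convention of Cox-form published scores.
    ``baseline_survival`` is S0 at the horizon for the cox_survival form;
    ``horizon_years`` is t for the log_rate form.
    """

    name: str
    form: str
    terms: Sequence[RiskTerm]
    baseline_survival: float | None = None
    horizon_years: float | None = None
    centering: Mapping[str, float] = field(default_factory=dict)
    citation: str = ""

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if self.form == "cox_survival":
            if self.baseline_survival is None or not (0 < self.baseline_survival <= 1):
                raise ValueError("cox_survival form needs baseline_survival in (0, 1]")
        else:
            if self.horizon_years is None or not (self.horizon_years > 0):
                raise ValueError("log_rate form needs horizon_years > 0")

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "form": self.form,
            "terms": [
                {"variable": t.variable, "transform": t.transform, "coefficient": t.coefficient}
                for t in self.terms
            ],
            "centering": dict(self.centering),
            "citation": self.citation,
        }
        if self.baseline_survival is not None:
            d["baseline_survival"] = self.baseline_survival
        if self.horizon_years is not None:
            d["horizon_years"] = self.horizon_years
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskEquation":
        return cls(
            name=d["name"],
            form=d["form"],
            terms=[RiskTerm(t["variable"], t["transform"], float(t["coefficient"])) for t in d["terms"]],
            baseline_survival=d.get("baseline_survival"),
            horizon_years=d.get("horizon_years"),
            centering={k: float(v) for k, v in (d.get("centering") or {}).items()},
            citation=d.get("citation", ""),
        )


def linear_predictor(eq: RiskEquation, row: Mapping[str, float]) -> float:
    """Linear predictor L = sum coefficient * (transform(value) - center)."""
    total = 0.0
    for term in eq.terms:
        if term.variable not in row:
            raise KeyError(f"risk equation {eq.name!r} needs variable {term.variable!r}")
        v = float(row[term.variable])
        if not math.isfinite(v):
            raise ValueError(f"variable {term.variable!r} is not finite")
        center = eq.centering.get(term.variable)
        if term.transform == "natural_log":
            if v <= 0:
                raise ValueError(f"variable {term.variable!r} must be > 0 for log transform")
            x = math.log(v)
            if center is not None:
                x -= math.log(center)
        elif term.transform == "binary":
            if v not in (0.0, 1.0):
                raise ValueError(f"binary variable {term.variable!r} must be 0/1, got {v}")
            x = v - (center or 0.0)
        else:
            x = v - (center or 0.0)
        total += term.coefficient * x
    return total


def ten_year_risk(eq: RiskEquation, L: float, L_ref: float = 0.0) -> float:
    """Absolute risk over the horizon; monotone increasing in L.

    Cox form: 1 - S0^exp(L - L_ref). Rate form: 1 - exp(-exp(L) * t)
    (L_ref ignored; rate-form scores are absolute already).
    """
    if eq.form == "cox_survival":
        risk = 1.0 - eq.baseline_survival ** math.exp(L - L_ref)
    else:
        risk = 1.0 - math.exp(-math.exp(L) * eq.horizon_years)
    return min(max(risk, 0.0), 1.0)


def score_cohort(
    eq: RiskEquation,
    samples: pd.DataFrame,
    outcome: Sequence[int] | str,
) -> tuple[pd.DataFrame, float, int]:
    """Per-sample risks plus the (non-cross-validated) discrimination AUC.

    ``outcome`` is a binary vector aligned with ``samples`` or the name
    of a binary column. Samples with missing or invalid covariates are
    excluded (listed in the returned frame with NaN risk); the returned
    count is the number excluded. For the Cox form the cohort reference
    predictor is the mean linear predictor of the scored samples.
    """
    if isinstance(outcome, str):
        y = samples[outcome].to_numpy(dtype=int)
    else:
        y = np.asarray(outcome, dtype=int)
    if len(y) != len(samples):
        raise ValueError("outcome length must match sample table")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")

    Ls = np.full(len(samples), np.nan)
    errors: list[str] = []
    for i, (_sid, row) in enumerate(samples.iterrows()):
        try:
            Ls[i] = linear_predictor(eq, row)
        except (KeyError, ValueError) as exc:
            errors.append(str(exc))
    ok = np.isfinite(Ls)
    n_excluded = int((~ok).sum())
    L_ref = float(Ls[ok].mean()) if eq.form == "cox_survival" else 0.0
    risks = np.full(len(samples), np.nan)
    for i in np.flatnonzero(ok):
        risks[i] = ten_year_risk(eq, Ls[i], L_ref)
    result = pd.DataFrame({"risk": risks, "excluded": ~ok}, index=samples.index)
    y_ok = y[ok]
    auc = auc_rank(risks[ok], y_ok) if 0 < y_ok.sum() < len(y_ok) else float("nan")
    return result, auc, n_excluded


def equation_template_dir() -> Path:
    """Directory of the shipped equation YAML templates."""
    return Path(__file__).parent / "equations"


def load_equation(path: str | Path) -> RiskEquation:
    with open(path) as fh:
        return RiskEquation.from_dict(yaml.safe_load(fh))


def save_equation(eq: RiskEquation, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(eq.to_dict(), fh, sort_keys=False)
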