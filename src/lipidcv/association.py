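"""Case-control association scans and cohort characteristic statistics.

Implements the statistical core of the case-control lipidomic analysis:

* multiple binary logistic regression of outcome on each lipid feature
  (plus adjustment covariates), reported as odds ratios per interquartile
  range (OR per IQR) with 95% Wald confidence intervals;
* Benjamini-Hochberg false-discovery-rate adjustment across each feature
  family (species and classes corrected separately within a contrast);
* Mann-Whitney U and Fisher's exact tests for the cohort characteristics
  comparison table.

Features are analysed on the log10 concentration scale by default; the
IQR used to scale each odds ratio is computed on the same scale over the
samples entering that fit, so OR-per-IQR is self-consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import BINARY_COVARIATES, CONTINUOUS_COVARIATES, LipidMatrix

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = [
    "AssociationRecord",
    "AssociationScanResult",
    "ContrastSpec",
    "LogisticFit",
    "fit_logistic",
    "or_per_iqr",
    "bh_adjust",
    "class_totals",
    "association_scan",
    "mann_whitney_u",
    "fisher_exact",
    "cohort_table",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison with optional adjustment covariates."""

    case_group: str
    control_group: str
    adjust_covariates: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ValueError("case and control groups must differ")


#: The two contrasts of the study design: HIV infection (HIV controls vs
#: healthy controls, adjusted for the characteristics that differ between
#: them) and future cardiovascular events within HIV (cases vs HIV
#: controls, adjusted for statin treatment).
HIV_INFECTION_CONTRAST = ContrastSpec(
    "HIV_CONTROL", "HEALTHY", ("family_history_chd", "smoker", "hscrp"), name="HIV_vs_HEALTHY"
)
CVD_EVENT_CONTRAST = ContrastSpec("HIV_CASE", "HIV_CONTROL", ("statin",), name="CASE_vs_CONTROL")


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    separation: bool = False


@dataclass
class AssociationRecord:
    """One feature's association result (one output table row)."""

    feature_id: str
    level: str
    contrast: str
    beta: float
    se: float
    or_per_iqr: float
    ci95_low: float
    ci95_high: float
    p_raw: float
    p_adj: float
    iqr_used: float
    n_used: int
    status: str = "ok"  # ok | unconverged | skipped_constant


@dataclass
class AssociationScanResult:
    records: list[AssociationRecord]
    contrast: ContrastSpec
    level: str
    scale: str
    iqr_basis: str = "samples_in_fit"
    dropped_covariates: tuple[str, ...] = ()

    @property
    def unconverged(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.status == "unconverged"]

    @property
    def skipped(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.status == "skipped_constant"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _q, _r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    return [names[i] for i in sorted(piv[rank:])]


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood binary logistic fit (Newton / IRLS).

    ``design`` must contain the intercept column explicitly and be of
    full column rank. Returns coefficient estimates, the inverse observed
    information as covariance, and a convergence flag that is False under
    perfect separation (diverging coefficients) or iteration exhaustion.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    bad = _collinear_columns(X, names)
    if bad:
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.Logit(y.astype(float), X).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=0
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(np.full(k, np.nan), np.full((k, k), np.nan), False, separation=True)
    beta = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    separation = bool(np.abs(beta).max() > 1e4)
    return LogisticFit(beta, cov, converged and not separation, separation=separation)


def or_per_iqr(beta_j: float, se_j: float, iqr_j: float) -> tuple[float, float, float]:
    """Odds ratio (with 95% Wald CI) for an IQR-sized predictor increase."""
    if not (iqr_j > 0):
        raise ValueError("iqr must be > 0 (constant features are skipped upstream)")
    if se_j < 0:
        raise ValueError("se must be >= 0")
    or_ = float(np.exp(beta_j * iqr_j))
    lo = float(np.exp((beta_j - Z_95 * se_j) * iqr_j))
    hi = float(np.exp((beta_j + Z_95 * se_j) * iqr_j))
    return or_, min(lo, hi), max(lo, hi)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def class_totals(matrix: LipidMatrix) -> LipidMatrix:
    """Aggregate a species-level matrix to class level (per-sample sums).

    Aggregation is defined on the concentration scale; a log-scale matrix
    cannot be summed meaningfully and is rejected.
    """
    if matrix.scale != "raw":
        raise ValueError("class totals are sums of concentrations; pass a raw-scale matrix")
    classes = matrix.classes
    cols = {c: [] for c in classes}
    for s in matrix.species_ids:
        cols[matrix.class_map[s]].append(s)
    data = pd.DataFrame(
        {c: matrix.data[members].sum(axis=1) for c, members in cols.items()},
        index=matrix.data.index,
    )
    return LipidMatrix(data, {c: c for c in classes}, scale="raw")


def _analysis_frame(matrix: LipidMatrix, level: str, scale: str) -> pd.DataFrame:
    m = matrix if level == "species" else class_totals(matrix)
    if scale == "log10":
        m = m.to_log10()
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'log10'")
    return m.data


def association_scan(
    matrix: LipidMatrix,
    samples: pd.DataFrame,
    contrast: ContrastSpec,
    level: str = "species",
    scale: str = "log10",
) -> AssociationScanResult:
    """Per-feature logistic association scan with BH-adjusted p-values.

    Each feature is fit in its own model (intercept + feature +
    adjustment covariates) on the samples of the two contrast groups;
    the feature IQR is computed on the analysis scale over those same
    samples. BH adjustment is applied across all converged features of
    the requested level; unconverged or constant features keep a record
    (status flagged) but do not enter the BH family.
    """
    if level not in ("species", "class"):
        raise ValueError("level must be 'species' or 'class'")
    for cov in contrast.adjust_covariates:
        if cov not in samples.columns:
            raise ValueError(f"adjustment covariate {cov!r} missing from sample table")
    mask = samples["group"].isin([contrast.case_group, contrast.control_group])
    sub = samples.loc[mask]
    for g in (contrast.case_group, contrast.control_group):
        if (sub["group"] == g).sum() < 2:
            raise ValueError(f"contrast group {g!r} has fewer than 2 samples")
    feats = _analysis_frame(matrix, level, scale).loc[sub.index]
    if feats.shape[1] == 0:
        raise ValueError("empty feature set")
    y = (sub["group"] == contrast.case_group).to_numpy(dtype=int)
    # A binary adjustment covariate whose levels never co-occur with one
    # outcome level makes every fit quasi-separated (its coefficient
    # diverges regardless of the lipid feature), so it cannot be adjusted
    # for by maximum likelihood and is dropped scan-wide with a warning.
    kept_covariates: list[str] = []
    dropped: list[str] = []
    for cov in contrast.adjust_covariates:
        cvals = sub[cov].to_numpy(dtype=float)
        if set(np.unique(cvals)) <= {0.0, 1.0}:
            cells = [((cvals == a) & (y == b)).sum() for a in (0, 1) for b in (0, 1)]
            if 0 in cells:
                logger.warning(
                    "adjustment covariate %r quasi-separates the outcome in this "
                    "contrast; dropped from all fits",
                    cov,
                )
                dropped.append(cov)
                continue
        kept_covariates.append(cov)
    covs = sub[kept_covariates].to_numpy(dtype=float)
    n = len(sub)

    records: list[AssociationRecord] = []
    contrast_name = contrast.name or f"{contrast.case_group}_vs_{contrast.control_group}"
    for fid in feats.columns:
        x = feats[fid].to_numpy(dtype=float)
        q75, q25 = np.quantile(x, [0.75, 0.25])  # type-7 linear interpolation
        iqr = float(q75 - q25)
        rec = AssociationRecord(
            feature_id=fid,
            level=level,
            contrast=contrast_name,
            beta=np.nan,
            se=np.nan,
            or_per_iqr=np.nan,
            ci95_low=np.nan,
            ci95_high=np.nan,
            p_raw=np.nan,
            p_adj=np.nan,
            iqr_used=iqr,
            n_used=n,
        )
        if iqr == 0:
            logger.warning("feature %s is constant in contrast %s; skipped", fid, contrast_name)
            rec.status = "skipped_constant"
            records.append(rec)
            continue
        X = np.column_stack([np.ones(n), x, covs])
        names = ["intercept", fid, *kept_covariates]
        fit = fit_logistic(pd.DataFrame(X, columns=names), y)
        if not fit.converged:
            rec.status = "unconverged"
            records.append(rec)
            continue
        beta = float(fit.beta[1])
        se = float(np.sqrt(fit.cov[1, 1]))
        or_, lo, hi = or_per_iqr(beta, se, iqr)
        z = beta / se if se > 0 else np.inf
        rec.beta, rec.se = beta, se
        rec.or_per_iqr, rec.ci95_low, rec.ci95_high = or_, lo, hi
        rec.p_raw = float(2 * scipy.stats.norm.sf(abs(z)))
        records.append(rec)

    ok = [r for r in records if r.status == "ok"]
    if ok:
        adj = bh_adjust([r.p_raw for r in ok])
        for r, a in zip(ok, adj):
            r.p_adj = float(a)
    return AssociationScanResult(records, contrast, level, scale, dropped_covariates=tuple(dropped))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U statistic (for ``x``) and two-sided p-value.

    Uses exact enumeration for small tie-free samples
    (``len(x)+len(y) <= 12``) and the tie-corrected normal approximation
    with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = (x.size + y.size) <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


#: Cohort characteristics table variable registry: name -> kind.
COHORT_VARIABLES: dict[str, str] = {
    **{v: "binary" for v in BINARY_COVARIATES},
    **{v: "continuous" for v in CONTINUOUS_COVARIATES},
}


def cohort_table(
    samples: pd.DataFrame,
    group_pairs: Iterable[tuple[str, str]],
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Participant characteristics comparison table.

    Continuous variables are summarised as median (IQR) and compared
    pairwise by Mann-Whitney U tests; binary variables as % (x/n) with
    Fisher's exact tests.
    """
    group_pairs = list(group_pairs)
    groups_needed = sorted({g for pair in group_pairs for g in pair})
    for g in groups_needed:
        if not (samples["group"] == g).any():
            raise ValueError(f"group {g!r} absent from sample table")
    if variables is None:
        variables = [v for v in COHORT_VARIABLES if v in samples.columns]
    rows = []
    for var in variables:
        if var not in COHORT_VARIABLES:
            raise ValueError(f"unknown variable {var!r}")
        if var not in samples.columns:
            raise ValueError(f"variable {var!r} missing from sample table")
        kind = COHORT_VARIABLES[var]
        row: dict[str, object] = {"variable": var, "kind": kind}
        for g in groups_needed:
            vals = samples.loc[samples["group"] == g, var]
            if kind == "continuous":
                med = vals.median()
                q25, q75 = vals.quantile([0.25, 0.75])
                row[g] = f"{med:.2f} ({q25:.2f}-{q75:.2f})"
            else:
                k, n = int(vals.sum()), len(vals)
                pct = 100.0 * k / n if n else np.nan
                row[g] = f"{pct:.1f} ({k}/{n})"
        for ga, gb in group_pairs:
            va = samples.loc[samples["group"] == ga, var]
            vb = samples.loc[samples["group"] == gb, var]
            if kind == "continuous":
                _u, p = mann_whitney_u(va.to_numpy(), vb.to_numpy())
            else:
                p = fisher_exact(
                    int(va.sum()), int(len(va) - va.sum()), int(vb.sum()), int(len(vb) - vb.sum())
                )
            row[f"p_{ga}_vs_{gb}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
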