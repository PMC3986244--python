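"""Synthetic case-control lipidomic cohort generator.

Generates sample-by-species lipid concentration matrices with a known
correlation structure and known injected group effects, together with a
clinical covariate table, so that every downstream estimator in this
package can be exercised against a ground truth.

The cohort emulates a three-group HIV cardiovascular case-control design:
HIV-positive individuals who went on to have a coronary event (cases),
HIV-positive controls without an event, and HIV-negative healthy controls.
Lipid species concentrations are log10-normal; species within a lipid
class share a single latent factor so that class members co-vary, while
different classes are independent. Group effects are specified as target
odds ratios per interquartile range (OR per IQR) — the effect scale on
which the association scan reports — and are converted into log-scale
mean shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "GAUSSIAN_IQR_PER_SD",
    "GROUPS",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_COVARIATE_MODELS",
    "DEFAULT_EFFECTS",
    "EffectSpec",
    "GeneratorConfig",
    "LipidMatrix",
    "shift_from_target_or",
    "generate_covariates",
    "generate_cohort",
    "validate_sample_table",
]

#: IQR of a Gaussian in units of its SD: 2 * Phi^-1(0.75).
GAUSSIAN_IQR_PER_SD = 2.0 * norm.ppf(0.75)

GROUPS = ("HIV_CASE", "HIV_CONTROL", "HEALTHY")

CONTRASTS = ("HIV_vs_HEALTHY", "CASE_vs_CONTROL")

# 24 lipid classes with plausible species counts per class, summing to 316.
# Class abbreviations follow lipidomics convention: Cer ceramide, HexCer
# monohexosylceramide, SM sphingomyelin, PC/PE phosphatidyl-choline/
# -ethanolamine (O = alkyl ether, P = alkenyl/plasmalogen), LPC/LPE lyso
# forms, PI/PS/PG glycerophospholipids, CE cholesteryl ester, FC free
# cholesterol, DG/TG di-/tri-acylglycerol.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "dhCer": 8,
    "Cer": 22,
    "HexCer": 10,
    "Hex2Cer": 8,
    "Hex3Cer": 6,
    "GM3": 6,
    "SM": 24,
    "PC": 40,
    "PC_O": 16,
    "PC_P": 18,
    "LPC": 14,
    "LPC_O": 6,
    "PE": 20,
    "PE_O": 8,
    "PE_P": 12,
    "LPE": 8,
    "PI": 14,
    "LPI": 5,
    "PS": 6,
    "PG": 6,
    "CE": 22,
    "FC": 1,
    "DG": 12,
    "TG": 24,
}

BINARY_COVARIATES = (
    "male",
    "smoker",
    "diabetes",
    "family_history_chd",
    "statin",
    "art",
    "detectable_vl",
)

CONTINUOUS_COVARIATES = (
    "age",
    "bmi",
    "sbp",
    "cd4",
    "hscrp",
    "hdl",
    "ldl",
    "tc",
    "tg",
)

# Per-group covariate distributions. Binary covariates are Bernoulli with
# the given per-group proportion; continuous covariates are normal or
# log-normal parameterised by (median, IQR) so the generated medians and
# spreads match a typical treated-HIV case-control cohort (cases enriched
# for smoking, statin use, family history and dyslipidaemia; healthy
# controls with higher HDL and low hsCRP). Order: (HIV_CASE, HIV_CONTROL,
# HEALTHY).
DEFAULT_COVARIATE_MODELS: dict[str, dict] = {
    "male": {"dist": "bernoulli", "p": {"HIV_CASE": 0.913, "HIV_CONTROL": 0.911, "HEALTHY": 0.933}},
    "smoker": {"dist": "bernoulli", "p": {"HIV_CASE": 0.522, "HIV_CONTROL": 0.422, "HEALTHY": 0.067}},
    # healthy-group rates for traits that exist in any population are a
    # small positive number (an observed 0/45 is compatible with these),
    # so adjusted logistic fits are almost surely identifiable
    "diabetes": {"dist": "bernoulli", "p": {"HIV_CASE": 0.174, "HIV_CONTROL": 0.067, "HEALTHY": 0.02}},
    "family_history_chd": {"dist": "bernoulli", "p": {"HIV_CASE": 0.522, "HIV_CONTROL": 0.20, "HEALTHY": 0.06}},
    "statin": {"dist": "bernoulli", "p": {"HIV_CASE": 0.348, "HIV_CONTROL": 0.067, "HEALTHY": 0.02}},
    "art": {"dist": "bernoulli", "p": {"HIV_CASE": 1.0, "HIV_CONTROL": 0.889, "HEALTHY": 0.0}},
    "detectable_vl": {"dist": "bernoulli", "p": {"HIV_CASE": 0.391, "HIV_CONTROL": 0.422, "HEALTHY": 0.0}},
    "age": {
        "dist": "normal",
        "median": {"HIV_CASE": 51.1, "HIV_CONTROL": 51.2, "HEALTHY": 54.0},
        "iqr": {"HIV_CASE": 20.5, "HIV_CONTROL": 18.4, "HEALTHY": 9.3},
        "min": 18.0,
    },
    "bmi": {
        "dist": "normal",
        "median": {"HIV_CASE": 22.6, "HIV_CONTROL": 24.3, "HEALTHY": 23.6},
        "iqr": {"HIV_CASE": 6.1, "HIV_CONTROL": 5.9, "HEALTHY": 4.5},
        "min": 15.0,
    },
    "sbp": {
        "dist": "normal",
        "median": {"HIV_CASE": 120.0, "HIV_CONTROL": 120.0, "HEALTHY": 121.0},
        "iqr": {"HIV_CASE": 20.0, "HIV_CONTROL": 20.0, "HEALTHY": 20.25},
        "min": 80.0,
    },
    # Healthy-control CD4 drawn from an HIV-negative reference range.
    "cd4": {
        "dist": "normal",
        "median": {"HIV_CASE": 452.0, "HIV_CONTROL": 320.0, "HEALTHY": 900.0},
        "iqr": {"HIV_CASE": 390.0, "HIV_CONTROL": 312.0, "HEALTHY": 400.0},
        "min": 10.0,
    },
    "hscrp": {
        "dist": "lognormal",
        "median": {"HIV_CASE": 2.78, "HIV_CONTROL": 2.26, "HEALTHY": 0.64},
        "iqr": {"HIV_CASE": 4.70, "HIV_CONTROL": 3.08, "HEALTHY": 1.12},
    },
    "hdl": {
        "dist": "normal",
        "median": {"HIV_CASE": 0.74, "HIV_CONTROL": 0.95, "HEALTHY": 1.50},
        "iqr": {"HIV_CASE": 0.41, "HIV_CONTROL": 0.35, "HEALTHY": 0.60},
        "min": 0.3,
    },
    "ldl": {
        "dist": "normal",
        "median": {"HIV_CASE": 3.60, "HIV_CONTROL": 3.30, "HEALTHY": 2.97},
        "iqr": {"HIV_CASE": 1.30, "HIV_CONTROL": 1.30, "HEALTHY": 1.03},
        "min": 0.5,
    },
    "tc": {
        "dist": "normal",
        "median": {"HIV_CASE": 5.89, "HIV_CONTROL": 5.20, "HEALTHY": 5.00},
        "iqr": {"HIV_CASE": 1.65, "HIV_CONTROL": 1.57, "HEALTHY": 1.15},
        "min": 2.0,
    },
    "tg": {
        "dist": "lognormal",
        "median": {"HIV_CASE": 3.67, "HIV_CONTROL": 1.77, "HEALTHY": 1.00},
        "iqr": {"HIV_CASE": 2.06, "HIV_CONTROL": 1.29, "HEALTHY": 1.06},
    },
}


@dataclass(frozen=True)
class EffectSpec:
    """A group effect on one lipid feature, sized as an OR per IQR.

    ``feature_id`` may name a species or a whole class (then every member
    species is shifted by the same log-scale amount so the class total
    carries the effect). ``contrast`` decides which groups are shifted:
    ``HIV_vs_HEALTHY`` shifts both HIV groups relative to healthy
    controls; ``CASE_vs_CONTROL`` shifts HIV cases relative to HIV
    controls. ``target_or_per_iqr`` is the odds ratio an IQR-scaled
    logistic association scan of that contrast should approximately
    recover.
    """

    feature_id: str
    contrast: str
    target_or_per_iqr: float

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}; expected one of {CONTRASTS}")
        if not (self.target_or_per_iqr > 0):
            raise ValueError("target_or_per_iqr must be > 0")


# Default injected effects: class-level ORs per IQR reflecting the
# direction and size of the HIV- and CVD-associated lipid class shifts
# the analyses are designed to detect (sphingolipid / plasmalogen
# depletion with HIV infection; glycerolipid and ceramide elevation
# ahead of cardiovascular events).
DEFAULT_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec("HexCer", "HIV_vs_HEALTHY", 0.17),
    EffectSpec("Hex2Cer", "HIV_vs_HEALTHY", 0.31),
    EffectSpec("GM3", "HIV_vs_HEALTHY", 0.30),
    EffectSpec("SM", "HIV_vs_HEALTHY", 0.14),
    EffectSpec("PC", "HIV_vs_HEALTHY", 0.43),
    EffectSpec("PC_P", "HIV_vs_HEALTHY", 0.12),
    EffectSpec("DG", "HIV_vs_HEALTHY", 5.42),
    EffectSpec("Cer", "CASE_vs_CONTROL", 3.44),
    EffectSpec("PE", "CASE_vs_CONTROL", 4.42),
    EffectSpec("LPE", "CASE_vs_CONTROL", 3.07),
    EffectSpec("PI", "CASE_vs_CONTROL", 3.03),
    EffectSpec("PG", "CASE_vs_CONTROL", 2.73),
    EffectSpec("CE", "CASE_vs_CONTROL", 3.62),
    EffectSpec("DG", "CASE_vs_CONTROL", 3.72),
    EffectSpec("TG", "CASE_vs_CONTROL", 5.94),
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    group_sizes
        Samples per group. Defaults to the 23 / 45 / 45 case-control
        design the package's analyses are sized for.
    species_per_class
        Mapping class name -> number of member species (24 classes, 316
        species by default).
    log_mu, log_sigma
        Location and scale of per-species log10 concentration (units:
        log10 pmol/mL). Scalars broadcast to all species; arrays give
        per-species values in catalogue order.
    within_class_loading
        Loading of the shared per-class latent factor, in [0, 1). The
        within-class Pearson correlation of log concentrations is the
        loading squared.
    covariate_models
        Per-variable distribution specs (see DEFAULT_COVARIATE_MODELS).
    effects
        Injected group effects (see EffectSpec).
    confounders
        Optional list of ``(covariate, feature_id, slope)`` triples adding
        ``slope * standardized covariate`` to the species' log10
        concentration; empty by default so association ground truth is
        purely the injected group effects.
    export_scale
        ``"raw"`` (concentrations) or ``"log10"``; recorded so downstream
        consumers know which scale a written matrix is on. Generation is
        always on the log10 scale internally; export defaults to raw.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HIV_CASE": 23, "HIV_CONTROL": 45, "HEALTHY": 45}
    )
    species_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    log_mu: float | Sequence[float] = 2.0
    log_sigma: float | Sequence[float] = 0.25
    within_class_loading: float = 0.6
    covariate_models: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MODELS.items()})
    effects: Sequence[EffectSpec] = DEFAULT_EFFECTS
    confounders: Sequence[tuple[str, str, float]] = ()
    export_scale: str = "raw"
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.species_per_class)

    @property
    def n_species(self) -> int:
        return int(sum(self.species_per_class.values()))

    def species_catalogue(self) -> tuple[list[str], dict[str, str]]:
        """Species ids in generation order and the species -> class map."""
        species: list[str] = []
        class_map: dict[str, str] = {}
        for cls, count in self.species_per_class.items():
            for i in range(1, count + 1):
                sid = f"{cls}_{i:02d}"
                species.append(sid)
                class_map[sid] = cls
        return species, class_map

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 0:
                raise ValueError(f"group size for {g} must be >= 0, got {n}")
        for cls, count in self.species_per_class.items():
            if count < 1:
                raise ValueError(f"class {cls!r} must have >= 1 species")
        if not (0.0 <= self.within_class_loading < 1.0):
            raise ValueError("within_class_loading must be in [0, 1)")
        sigma = np.broadcast_to(np.asarray(self.log_sigma, dtype=float), (self.n_species,))
        if not np.all(sigma > 0):
            raise ValueError("log_sigma must be > 0")
        if self.export_scale not in ("raw", "log10"):
            raise ValueError("export_scale must be 'raw' or 'log10'")
        species, class_map = self.species_catalogue()
        known = set(species) | set(self.species_per_class)
        for eff in self.effects:
            if eff.feature_id not in known:
                raise ValueError(
                    f"effect names unknown feature {eff.feature_id!r} "
                    "(not a species or class in the catalogue)"
                )
        for cov, feat, _slope in self.confounders:
            if cov not in self.covariate_models:
                raise ValueError(f"confounder names unknown covariate {cov!r}")
            if feat not in known:
                raise ValueError(f"confounder names unknown feature {feat!r}")


class LipidMatrix:
    """Sample-by-species lipid concentration matrix plus species->class map.

    ``data`` is a pandas DataFrame indexed by sample_id with one column
    per species; values are finite and non-negative concentrations
    (arbitrary units) or, if ``scale == "log10"``, their base-10 logs.
    """

    def __init__(self, data: pd.DataFrame, class_map: Mapping[str, str], scale: str = "raw"):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dupes}")
        missing = [s for s in data.columns if s not in class_map]
        if missing:
            raise ValueError(f"species missing from class map: {missing}")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {data.index[bad[0]]!r}, species {data.columns[bad[1]]!r}"
            )
        if scale == "raw" and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative concentration at sample {data.index[bad[0]]!r}, "
                f"species {data.columns[bad[1]]!r}"
            )
        self.data = data
        self.class_map = {s: class_map[s] for s in data.columns}
        self.scale = scale

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.class_map[s], None)
        return list(seen)

    def to_log10(self) -> "LipidMatrix":
        """Return the matrix on the log10 scale (identity if already there)."""
        if self.scale == "log10":
            return self
        values = self.data.to_numpy(dtype=float)
        if (values <= 0).any():
            bad = np.argwhere(values <= 0)[0]
            raise ValueError(
                "cannot log-transform non-positive concentration at sample "
                f"{self.data.index[bad[0]]!r}, species {self.data.columns[bad[1]]!r}"
            )
        return LipidMatrix(np.log10(self.data), self.class_map, scale="log10")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LipidMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.class_map == other.class_map
            and self.data.equals(other.data)
        )


def shift_from_target_or(theta: float, sigma: float, iqr: float) -> float:
    """Log-scale mean shift realizing a target OR per IQR.

    For two equal-variance Gaussian log-concentration populations whose
    means differ by ``delta``, the population logistic slope per unit is
    ``delta / sigma**2``. Setting that slope to ``ln(theta) / iqr`` —
    the per-unit coefficient whose IQR-scaled odds ratio is ``theta`` —
    gives ``delta = ln(theta) * sigma**2 / iqr``.
    """
    if not (theta > 0):
        raise ValueError("theta (OR per IQR) must be > 0")
    if not (sigma > 0):
        raise ValueError("sigma must be > 0")
    if not (iqr > 0):
        raise ValueError("iqr must be > 0")
    return math.log(theta) * sigma * sigma / iqr


def _mixture_iqr(delta: float, sigma: float, w_shifted: float) -> float:
    """IQR of the two-group pooled distribution w*N(delta,s^2)+(1-w)*N(0,s^2)."""

    def cdf(x: float) -> float:
        return w_shifted * norm.cdf((x - delta) / sigma) + (1 - w_shifted) * norm.cdf(x / sigma)

    lo = min(0.0, delta) - 8 * sigma
    hi = max(0.0, delta) + 8 * sigma
    q25 = brentq(lambda x: cdf(x) - 0.25, lo, hi)
    q75 = brentq(lambda x: cdf(x) - 0.75, lo, hi)
    return q75 - q25


def _calibrated_shift(theta: float, sigma: float, w_shifted: float, n_iter: int = 25) -> float:
    """Fixed-point shift so the *pooled* contrast-sample IQR scaling
    reproduces the target OR.

    The association scan computes each feature's IQR over the samples
    entering the fit, i.e. over the two contrast groups pooled. The shift
    itself widens that pooled IQR, so the shift solving
    ``delta = ln(theta) * sigma^2 / IQR_pooled(delta)`` is found by
    iteration (a contraction; a handful of steps suffice).
    """
    delta = shift_from_target_or(theta, sigma, GAUSSIAN_IQR_PER_SD * sigma)
    for _ in range(n_iter):
        new = shift_from_target_or(theta, sigma, _mixture_iqr(delta, sigma, w_shifted))
        if abs(new - delta) < 1e-12:
            delta = new
            break
        delta = new
    return delta


def _class_log_sigma(mus: np.ndarray, sigmas: np.ndarray, loading: float) -> float:
    # Delta-method SD of log10(sum of member concentrations): weights are
    # expected concentrations; within-class correlation is loading^2.
    ln10 = math.log(10.0)
    means = np.power(10.0, mus) * np.exp(0.5 * (sigmas * ln10) ** 2)
    w = means / means.sum()
    rho = loading * loading
    cov = rho * np.outer(sigmas, sigmas)
    np.fill_diagonal(cov, sigmas * sigmas)
    var = float(w @ cov @ w)
    return math.sqrt(var)


def _contrast_weight(contrast: str, group_sizes: Mapping[str, int]) -> float:
    """Fraction of samples in the shifted arm among the two scanned groups."""
    if contrast == "HIV_vs_HEALTHY":
        n_shift = group_sizes.get("HIV_CONTROL", 0)
        n_ref = group_sizes.get("HEALTHY", 0)
    else:
        n_shift = group_sizes.get("HIV_CASE", 0)
        n_ref = group_sizes.get("HIV_CONTROL", 0)
    total = n_shift + n_ref
    return 0.5 if total == 0 else n_shift / total


def _shifted_groups(contrast: str) -> tuple[str, ...]:
    if contrast == "HIV_vs_HEALTHY":
        # an HIV-infection effect is present in every HIV-positive arm
        return ("HIV_CASE", "HIV_CONTROL")
    return ("HIV_CASE",)


def _effect_deltas(config: GeneratorConfig) -> dict[str, dict[str, float]]:
    """Resolve EffectSpecs into per-species, per-group log10 shifts."""
    species, class_map = config.species_catalogue()
    idx = {s: i for i, s in enumerate(species)}
    members: dict[str, list[str]] = {}
    for s, c in class_map.items():
        members.setdefault(c, []).append(s)
    mus = np.broadcast_to(np.asarray(config.log_mu, dtype=float), (config.n_species,)).copy()
    sigmas = np.broadcast_to(np.asarray(config.log_sigma, dtype=float), (config.n_species,)).copy()

    deltas: dict[str, dict[str, float]] = {s: {} for s in species}
    for eff in config.effects:
        w = _contrast_weight(eff.contrast, config.group_sizes)
        if eff.feature_id in members:  # class-level effect
            ids = members[eff.feature_id]
            rows = [idx[s] for s in ids]
            sigma_eff = _class_log_sigma(mus[rows], sigmas[rows], config.within_class_loading)
            delta = _calibrated_shift(eff.target_or_per_iqr, sigma_eff, w)
            targets = ids
        else:
            sigma_eff = float(sigmas[idx[eff.feature_id]])
            delta = _calibrated_shift(eff.target_or_per_iqr, sigma_eff, w)
            targets = [eff.feature_id]
        for g in _shifted_groups(eff.contrast):
            for s in targets:
                deltas[s][g] = deltas[s].get(g, 0.0) + delta
    return deltas


def generate_covariates(
    config: GeneratorConfig, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` covariate rows for one group from the configured models."""
    if group not in config.group_sizes and group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    cols: dict[str, np.ndarray] = {}
    for var, spec in config.covariate_models.items():
        dist = spec["dist"]
        if dist == "bernoulli":
            p = spec["p"][group]
            cols[var] = (rng.random(n) < p).astype(int)
        elif dist in ("normal", "lognormal"):
            med = spec["median"][group]
            iqr = spec["iqr"][group]
            sd = iqr / GAUSSIAN_IQR_PER_SD
            if dist == "normal":
                x = rng.normal(med, sd, size=n)
                if "min" in spec:
                    x = np.maximum(x, spec["min"])
            else:
                # log-normal parameterised by median and IQR on the raw scale
                log_med = math.log(med)
                log_sd = math.log((med + iqr / 2) / max(med - iqr / 2, 1e-12)) / GAUSSIAN_IQR_PER_SD
                x = np.exp(rng.normal(log_med, log_sd, size=n))
            cols[var] = x
        else:
            raise ValueError(f"unknown covariate distribution {dist!r} for {var!r}")
    frame = pd.DataFrame(cols, columns=list(config.covariate_models))
    frame.insert(0, "group", group)
    return frame


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check group vocabulary, binary columns and finiteness; return input."""
    if "group" not in samples.columns:
        raise ValueError("sample table must have a 'group' column")
    bad_groups = sorted(set(samples["group"]) - set(GROUPS))
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups}; expected {GROUPS}")
    for col in BINARY_COVARIATES:
        if col in samples.columns:
            vals = samples[col]
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = samples.index[bad][0]
                raise ValueError(
                    f"binary column {col!r} has non-0/1 value {vals[row]!r} at row {row!r}"
                )
    for col in CONTINUOUS_COVARIATES:
        if col in samples.columns:
            arr = samples[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                row = samples.index[~np.isfinite(arr)][0]
                raise ValueError(f"non-finite value in column {col!r} at row {row!r}")
    return samples


def generate_cohort(config: GeneratorConfig) -> tuple[LipidMatrix, pd.DataFrame]:
    """Generate a (LipidMatrix, sample table) pair from the config.

    Log10 concentrations follow a one-factor-per-class Gaussian model:
    ``z = mu + delta_group + sigma * (loading * F_class + sqrt(1-loading^2) * eps)``
    with ``F_class`` shared by all members of a class within a sample and
    independent across classes, so the within-class Pearson correlation
    is ``loading**2``. Injected effects enter as group-conditional mean
    shifts calibrated so the association scan approximately recovers the
    target ORs per IQR. Deterministic given the config (seed included).
    """
    config.validate()
    species, class_map = config.species_catalogue()
    n_species = config.n_species
    mus = np.broadcast_to(np.asarray(config.log_mu, dtype=float), (n_species,))
    sigmas = np.broadcast_to(np.asarray(config.log_sigma, dtype=float), (n_species,))
    deltas = _effect_deltas(config)  # validates effects before sampling

    ss = np.random.SeedSequence(config.seed)
    ss_lipid, ss_cov = ss.spawn(2)
    rng = np.random.default_rng(ss_lipid)

    groups_per_sample: list[str] = []
    sample_ids: list[str] = []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        for i in range(1, n + 1):
            groups_per_sample.append(g)
            sample_ids.append(f"{g}_{i:03d}")
    n_samples = len(sample_ids)

    loading = config.within_class_loading
    resid = math.sqrt(1.0 - loading * loading)
    z = np.empty((n_samples, n_species))
    col = 0
    for cls, count in config.species_per_class.items():
        factor = rng.standard_normal((n_samples, 1))
        eps = rng.standard_normal((n_samples, count))
        block = loading * factor + resid * eps
        z[:, col : col + count] = block
        col += count
    z = mus[None, :] + sigmas[None, :] * z

    group_arr = np.array(groups_per_sample)
    for j, s in enumerate(species):
        for g, d in deltas[s].items():
            z[group_arr == g, j] += d

    # covariates (drawn after lipids from an independent substream)
    cov_rng = np.random.default_rng(ss_cov)
    blocks = []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        blocks.append(generate_covariates(config, g, n, cov_rng))
    samples = pd.concat(blocks, ignore_index=True)
    samples.insert(0, "sample_id", sample_ids)
    samples = samples.set_index("sample_id")

    # optional covariate -> lipid links (confounding), standardized slope
    for cov, feat, slope in config.confounders:
        x = samples[cov].to_numpy(dtype=float)
        sd = x.std()
        xs = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        if feat in config.species_per_class:
            targets = [s for s, c in class_map.items() if c == feat]
        else:
            targets = [feat]
        for s in targets:
            z[:, species.index(s)] += slope * xs

    frame = pd.DataFrame(z, index=pd.Index(sample_ids, name="sample_id"), columns=species)
    if config.export_scale == "raw":
        matrix = LipidMatrix(np.power(10.0, frame), class_map, scale="raw")
    else:
        matrix = LipidMatrix(frame, class_map, scale="log10")
    validate_sample_table(samples)
    return matrix, samples


def null_config(**overrides) -> GeneratorConfig:
    """A GeneratorConfig with no injected effects (convenience for
    calibration studies); keyword overrides are applied on top."""
    cfg = GeneratorConfig(effects=())
    return replace(cfg, **overrides) if overrides else cfg
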