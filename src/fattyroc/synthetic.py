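"""Synthetic case-control cohorts with the statistical structure the
analysis assumes.

Samples are drawn through a Gaussian copula: a latent multivariate
normal supplies the between-analyte dependence, and each latent
coordinate is transformed to the analyte's marginal family (normal or
lognormal) with a target mean and coefficient of variation.  Case (ASD)
means are shifted from control (NEU) means by ``cohens_d`` pooled
standard deviations on the raw scale; an integer seafood-meals-per-month
covariate shares the copula layer so it correlates with the DHA and EPA
latents.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from .core_data import MEASURED_ANALYTES, CohortTable, SubjectRecord, compute_derived_table

__all__ = [
    "AnalyteSpec",
    "SeafoodModel",
    "SyntheticPanelSpec",
    "default_paper_spec",
    "generate_cohort",
]


@dataclass
class AnalyteSpec:
    """Marginal recipe for one measured analyte.

    ``neu_mean`` is the control-group mean in percent of total fatty
    acids; ``neu_cv`` its coefficient of variation; ``cohens_d`` the
    standardized ASD-NEU mean shift (0 for a null analyte, negative for
    lower-in-ASD); ``family`` the marginal shape.
    """

    neu_mean: float
    neu_cv: float
    cohens_d: float = 0.0
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.neu_mean <= 0:
            raise ValueError("neu_mean must be positive")
        if self.neu_cv <= 0:
            raise ValueError("neu_cv must be positive")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"family must be normal|lognormal, got {self.family!r}")


@dataclass
class SeafoodModel:
    """Poisson seafood-meals-per-month covariate coupled to DHA and EPA."""

    rate: float = 3.0
    rho_dha: float = 0.374
    rho_epa: float = 0.393

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for r in (self.rho_dha, self.rho_epa):
            if not -1 < r < 1:
                raise ValueError("|rho| must be < 1")


@dataclass
class SyntheticPanelSpec:
    """Full distributional recipe for one synthetic two-cohort study."""

    n_asd: int = 63
    n_neu: int = 49
    analytes: dict[str, AnalyteSpec] = field(default_factory=dict)
    copula_correlation: np.ndarray | None = None  # 11x11, MEASURED_ANALYTES order
    seafood: SeafoodModel = field(default_factory=SeafoodModel)
    subtype_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 1 or self.n_neu < 1:
            raise ValueError("cohort sizes must be positive")
        unknown = set(self.analytes) - set(MEASURED_ANALYTES)
        if unknown:
            raise ValueError(f"unknown analyte(s) in spec: {sorted(unknown)}")
        if self.copula_correlation is None:
            self.copula_correlation = np.eye(len(MEASURED_ANALYTES))
        self.copula_correlation = np.asarray(self.copula_correlation, dtype=float)
        k = len(MEASURED_ANALYTES)
        if self.copula_correlation.shape != (k, k):
            raise ValueError(f"copula_correlation must be {k}x{k}")
        if not np.allclose(self.copula_correlation, self.copula_correlation.T):
            raise ValueError("copula_correlation must be symmetric")
        if not np.allclose(np.diag(self.copula_correlation), 1.0):
            raise ValueError("copula_correlation must have unit diagonal")
        if sum(self.subtype_counts.values()) > self.n_asd:
            raise ValueError("subtype counts exceed n_asd")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_asd": self.n_asd,
            "n_neu": self.n_neu,
            "seed": self.seed,
            "analytes": {
                a: {
                    "neu_mean": s.neu_mean,
                    "neu_cv": s.neu_cv,
                    "cohens_d": s.cohens_d,
                    "family": s.family,
                }
                for a, s in self.analytes.items()
            },
            "copula_correlation": self.copula_correlation.tolist(),
            "seafood": {
                "rate": self.seafood.rate,
                "rho_dha": self.seafood.rho_dha,
                "rho_epa": self.seafood.rho_epa,
            },
            "subtype_counts": dict(self.subtype_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticPanelSpec":
        return cls(
            n_asd=d.get("n_asd", 63),
            n_neu=d.get("n_neu", 49),
            analytes={a: AnalyteSpec(**s) for a, s in d.get("analytes", {}).items()},
            copula_correlation=(
                np.asarray(d["copula_correlation"])
                if d.get("copula_correlation") is not None
                else None
            ),
            seafood=SeafoodModel(**d.get("seafood", {})),
            subtype_counts=d.get("subtype_counts", {}),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticPanelSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _extended_correlation(spec: SyntheticPanelSpec) -> np.ndarray:
    """Analyte correlation augmented with the seafood latent row."""
    k = len(MEASURED_ANALYTES)
    r = np.eye(k + 1)
    r[:k, :k] = spec.copula_correlation
    i_dha = MEASURED_ANALYTES.index("DHA")
    i_epa = MEASURED_ANALYTES.index("EPA")
    r[k, i_dha] = r[i_dha, k] = spec.seafood.rho_dha
    r[k, i_epa] = r[i_epa, k] = spec.seafood.rho_epa
    return r


def _check_psd(r: np.ndarray) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigvals.min():.3e})"
        )
    return r


def _marginal_transform(z: np.ndarray, mean: float, sd: float, family: str) -> np.ndarray:
    """Map standard-normal latents to the target marginal (mean, sd).

    Normal draws are clipped at zero to respect the nonnegativity of
    relative concentrations; with realistic CVs the clipped mass is
    negligible (means sit several SDs above zero).
    """
    if family == "normal":
        return np.maximum(mean + sd * z, 0.0)
    # lognormal matched by moments: E=mean, SD=sd
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - sigma**2 / 2
    return np.exp(mu + sigma * z)


def _draw_cohort(
    spec: SyntheticPanelSpec, cohort: str, n: int, rng: np.random.Generator
) -> list[SubjectRecord]:
    k = len(MEASURED_ANALYTES)
    r = _check_psd(_extended_correlation(spec))
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(k + 1))
    z = rng.standard_normal((n, k + 1)) @ chol.T
    values = np.empty((n, k))
    for j, analyte in enumerate(MEASURED_ANALYTES):
        a = spec.analytes[analyte]
        sd = a.neu_cv * a.neu_mean  # pooled SD on the raw scale
        mean = a.neu_mean + (a.cohens_d * sd if cohort == "ASD" else 0.0)
        if mean <= 0:
            raise ValueError(f"{analyte}: shifted ASD mean is nonpositive ({mean:.4g})")
        values[:, j] = _marginal_transform(z[:, j], mean, sd, a.family)
    seafood = stats.poisson.ppf(stats.norm.cdf(z[:, k]), spec.seafood.rate)
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"{cohort}-{i + 1:03d}",
                cohort=cohort,
                concentrations={
                    a: float(values[i, j]) for j, a in enumerate(MEASURED_ANALYTES)
                },
                seafood_meals_per_month=float(seafood[i]),
            )
        )
    return records


def generate_cohort(spec: SyntheticPanelSpec, seed: int | None = None) -> CohortTable:
    """Draw one synthetic study (both cohorts) from ``spec``.

    ``seed`` overrides ``spec.seed`` when given.  ASD diagnosis subtypes
    are assigned at random according to ``spec.subtype_counts`` (the
    remainder are labelled ``autism``); the four derived measures are
    filled in before returning.
    """
    missing = set(MEASURED_ANALYTES) - set(spec.analytes)
    if missing:
        raise ValueError(f"spec missing analyte(s): {sorted(missing)}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    asd = _draw_cohort(spec, "ASD", spec.n_asd, rng)
    neu = _draw_cohort(spec, "NEU", spec.n_neu, rng)
    if spec.subtype_counts:
        order = rng.permutation(len(asd))
        labels = []
        for subtype, count in spec.subtype_counts.items():
            labels.extend([subtype] * count)
        labels.extend(["autism"] * (len(asd) - len(labels)))
        for idx, lab in zip(order, labels):
            asd[idx].diagnosis_subtype = lab
    else:
        for r in asd:
            r.diagnosis_subtype = "autism"
    table = CohortTable(records=asd + neu, provenance=f"synthetic(seed={spec.seed if seed is None else seed})")
    return compute_derived_table(table)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Control-group central value, 95% interval, and case central value for
# each measured analyte (percent of total fatty acids), plus the marginal
# family used to emulate the observed distribution shape (normal where a
# t-family test applied, lognormal for the right-skewed analytes).
_PANEL: dict[str, tuple[float, float, float, float, str]] = {
    #            neu_mean  neu_lo   neu_hi   asd_mean  family
    "AA":            (20.16, 18.12,  22.03,  20.05, "normal"),
    "DGLA":          (2.226, 1.548,  3.110,  2.045, "normal"),
    "DHA":           (3.816, 2.721,  5.347,  3.707, "lognormal"),
    "EPA":           (0.344, 0.225,  0.569,  0.349, "lognormal"),
    "elaidic":       (0.176, 0.120,  0.253,  0.177, "lognormal"),
    "LA":            (14.00, 12.43,  15.61,  14.18, "normal"),
    "oleic":         (13.94, 11.86,  15.55,  13.90, "lognormal"),
    "palmitelaidic": (0.0201, 0.0105, 0.0282, 0.0198, "normal"),
    "palmitic":      (25.44, 24.04,  27.15,  25.50, "lognormal"),
    "palmitoleic":   (0.205, 0.0147, 0.306,  0.229, "lognormal"),
    "stearic":       (19.51, 18.24,  20.49,  19.27, "lognormal"),
}

# Modest physiological correlations between analytes sharing a pathway
# (same family or diet source); everything else independent.
_CORRELATED_PAIRS = (
    ("DHA", "EPA", 0.5),
    ("AA", "DGLA", 0.3),
    ("AA", "LA", 0.3),
    ("DGLA", "LA", 0.2),
    ("palmitic", "stearic", 0.3),
    ("oleic", "palmitoleic", 0.3),
)


def back_solved_cv(mean: float, lo: float, hi: float) -> float:
    """CV implied by a central 95% interval: ``(hi - lo)/(2*1.96*mean)``."""
    return (hi - lo) / (2 * 1.96 * mean)


def default_paper_spec(seed: int = 0) -> SyntheticPanelSpec:
    """Study conditions emulating the reference case-control cohorts.

    Control means are the published control central values; CVs are
    back-solved so the central 95% range matches the published interval
    widths; effect sizes are implied by the published case central
    values; cohort sizes are 63 cases and 49 controls with 8 Asperger's
    and 7 PDD-NOS subtype flags among the cases.
    """
    analytes = {}
    for name, (neu_mean, lo, hi, asd_mean, family) in _PANEL.items():
        cv = back_solved_cv(neu_mean, lo, hi)
        sd = cv * neu_mean
        analytes[name] = AnalyteSpec(
            neu_mean=neu_mean,
            neu_cv=cv,
            cohens_d=(asd_mean - neu_mean) / sd,
            family=family,
        )
    k = len(MEASURED_ANALYTES)
    corr = np.eye(k)
    for a, b, rho in _CORRELATED_PAIRS:
        i, j = MEASURED_ANALYTES.index(a), MEASURED_ANALYTES.index(b)
        corr[i, j] = corr[j, i] = rho
    return SyntheticPanelSpec(
        n_asd=63,
        n_neu=49,
        analytes=analytes,
        copula_correlation=corr,
        seafood=SeafoodModel(rate=3.0, rho_dha=0.374, rho_epa=0.393),
        subtype_counts={"Aspergers": 8, "PDD_NOS": 7},
        seed=seed,
    )
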