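"""Synthetic cohorts with the statistical structure cPCA assumes.

The generator produces (a) a correlated multivariate-normal biomarker panel,
(b) a binary disease status from a logistic liability on a weighted trait
sum, with the intercept solved so the realized prevalence matches a target,
(c) Hardy-Weinberg biallelic genotypes with per-variant additive effects on
one or several traits (pleiotropic and single-trait "biomarker" variants),
and (d) missing-completely-at-random masking.  Every output is a pure
function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import BiomarkerPanel

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "repair_correlation",
    "simulate_trait_panel",
    "simulate_disease",
    "simulate_genotypes",
    "apply_genetic_effects",
    "inject_missingness",
    "simulate_cohort",
]

_REPAIR_EIG_FLOOR = 1e-8
_REPAIR_MAX_FROBENIUS = 0.05


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort.

    genetic_effects maps variant id -> list of (trait name, per-allele
    effect in trait SD units); a variant with several entries is
    pleiotropic.  disease_weights are on the liability log-odds scale.
    """

    n_samples: int
    trait_names: list[str]
    trait_correlation: np.ndarray
    disease_weights: dict[str, float] = field(default_factory=dict)
    target_prevalence: float = 0.1
    missing_rate: float = 0.0
    n_variants: int = 0
    variant_mafs: list[float] = field(default_factory=list)
    genetic_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("duplicate trait names")
        self.trait_correlation = np.asarray(self.trait_correlation, dtype=float)
        k = len(self.trait_names)
        if self.trait_correlation.shape != (k, k):
            raise ValueError("trait_correlation shape mismatch")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie in (0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0,1)")
        if len(self.variant_mafs) != self.n_variants:
            raise ValueError("variant_mafs length must equal n_variants")
        for m in self.variant_mafs:
            if not (0.0 < m <= 0.5):
                raise ValueError(f"MAF {m} outside (0, 0.5]")
        for t in self.disease_weights:
            if t not in self.trait_names:
                raise ValueError(f"disease weight for unknown trait {t!r}")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["trait_correlation"] = np.asarray(raw["trait_correlation"], float)
        eff = {
            v: [(t, float(e)) for t, e in entries]
            for v, entries in raw.get("genetic_effects", {}).items()
        }
        raw["genetic_effects"] = eff
        return cls(**raw)


@dataclass
class SimulatedCohort:
    panel: BiomarkerPanel
    disease_status: np.ndarray
    genotypes: np.ndarray
    variant_meta: pd.DataFrame
    age: np.ndarray
    sex: np.ndarray
    liability_intercept: float

    def __post_init__(self) -> None:
        status = np.asarray(self.disease_status)
        if status.sum() < 1 or (1 - status).sum() < 1:
            raise ValueError("cohort must contain at least one case and one non-case")
        if self.genotypes.size and not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotype dosages must be 0/1/2")

    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "sex": self.sex},
            index=pd.Index(self.panel.sample_ids, name="sample_id"),
        )

    def write(self, out_dir, sep: str = "\t") -> dict[str, str]:
        """Write panel, status+covariates, genotype dosages and variant
        metadata as TSVs; returns the path map."""
        import os

        paths = {}
        os.makedirs(out_dir, exist_ok=True)
        p = os.path.join(out_dir, "panel.tsv")
        self.panel.write_table(p, sep=sep)
        paths["panel"] = p
        idx = pd.Index(self.panel.sample_ids, name="sample_id")
        p = os.path.join(out_dir, "status.tsv")
        pd.DataFrame({"disease_status": self.disease_status.astype(int)}, index=idx).to_csv(p, sep=sep)
        paths["status"] = p
        p = os.path.join(out_dir, "covariates.tsv")
        self.covariates().to_csv(p, sep=sep)
        paths["covariates"] = p
        if self.genotypes.size:
            p = os.path.join(out_dir, "genotypes.tsv")
            pd.DataFrame(self.genotypes, index=idx, columns=self.variant_meta["id"]).to_csv(p, sep=sep)
            paths["genotypes"] = p
            p = os.path.join(out_dir, "variants.tsv")
            self.variant_meta.to_csv(p, sep=sep, index=False)
            paths["variants"] = p
        return paths


# ---------------------------------------------------------------------------
# Correlation repair + panel
# ---------------------------------------------------------------------------

def repair_correlation(R: np.ndarray, max_frobenius: float = _REPAIR_MAX_FROBENIUS) -> np.ndarray:
    """Project a nearly-valid correlation matrix to a PSD one.

    Negative eigenvalues are clipped to a small positive floor and the
    matrix renormalized to unit diagonal.  Rejects asymmetric input and
    repairs whose Frobenius-norm change exceeds ``max_frobenius``.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(R) > 1 + 1e-10):
        raise ValueError("correlation entries must lie in [-1, 1]")
    w, V = np.linalg.eigh(R)
    if w[0] >= _REPAIR_EIG_FLOOR:
        out = R.copy()
        np.fill_diagonal(out, 1.0)
        return out
    w = np.clip(w, _REPAIR_EIG_FLOOR, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    if np.linalg.norm(S - R, "fro") > max_frobenius:
        raise ValueError("correlation matrix too far from PSD to repair")
    return S


def simulate_trait_panel(config: CohortConfig) -> BiomarkerPanel:
    """Draw n_samples rows from N(0, R) with R the (repaired) requested
    trait correlation; no genetic effects or missingness yet."""
    R = repair_correlation(config.trait_correlation)
    rng = np.random.default_rng(config.rng_seed)
    L = np.linalg.cholesky(R + np.eye(R.shape[0]) * 1e-12)
    Z = rng.standard_normal((config.n_samples, R.shape[0]))
    values = Z @ L.T
    ids = np.array([f"S{i:07d}" for i in range(config.n_samples)])
    return BiomarkerPanel(ids, list(config.trait_names), values,
                          np.zeros_like(values, dtype=bool))


# ---------------------------------------------------------------------------
# Disease model
# ---------------------------------------------------------------------------

def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def solve_liability_intercept(
    linear: np.ndarray, target_prevalence: float, tol: float = 1e-4
) -> float:
    """Bisection for the logistic intercept b with
    mean(expit(b + linear)) = target_prevalence, over b in [-20, 20]."""
    lo, hi = -20.0, 20.0
    f = lambda b: float(np.mean(_expit(b + linear))) - target_prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target prevalence unreachable on [-20, 20]")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v) < tol:
            return mid
        if v < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_disease(
    panel: BiomarkerPanel,
    weights: Mapping[str, float],
    target_prevalence: float,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Bernoulli disease status from a logistic liability on the weighted
    trait sum; the intercept is solved so expected prevalence matches the
    target.  Returns (status, intercept)."""
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must lie in (0,1)")
    linear = np.zeros(panel.n_samples)
    for trait, w in weights.items():
        linear += w * panel.values[:, panel.trait_index(trait)]
    b = solve_liability_intercept(linear, target_prevalence)
    rng = np.random.default_rng(seed)
    status = (rng.random(panel.n_samples) < _expit(b + linear)).astype(np.int8)
    return status, b


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n_samples: int, mafs: Sequence[float], seed: int) -> np.ndarray:
    """HWE biallelic dosages: per variant, Binomial(2, maf) per sample."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n_samples, mafs.size)).astype(np.int8)


def apply_genetic_effects(
    panel: BiomarkerPanel,
    genotypes: np.ndarray,
    effects: Mapping[str, Sequence[tuple[str, float]]],
    variant_ids: Sequence[str],
) -> BiomarkerPanel:
    """Add per-allele additive effects to traits; traits without an effect
    are untouched (bit-identical)."""
    vindex = {v: j for j, v in enumerate(variant_ids)}
    out = panel.copy()
    for variant, entries in effects.items():
        if variant not in vindex:
            raise ValueError(f"effect references unknown variant {variant!r}")
        dosage = genotypes[:, vindex[variant]].astype(float)
        for trait, eff in entries:
            out.values[:, out.trait_index(trait)] += eff * dosage
    return out


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def inject_missingness(panel: BiomarkerPanel, rate: float, seed: int) -> BiomarkerPanel:
    """MCAR: each cell masked independently with probability ``rate``;
    masked cells are flagged in missing_mask and set to NaN, never zeroed."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0,1)")
    out = panel.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.values.shape) < rate
    # never create a fully-missing trait on small panels
    for j in range(mask.shape[1]):
        if mask[:, j].all():
            mask[rng.integers(mask.shape[0]), j] = False
    out.missing_mask = out.missing_mask | mask
    out.values = out.values.copy()
    out.values[out.missing_mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# One-call cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Run the full generative recipe with stage seeds derived from
    ``config.rng_seed`` so each stage is independently reproducible."""
    ss = np.random.SeedSequence(config.rng_seed)
    s_panel, s_geno, s_disease, s_miss, s_cov, s_meta = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(6)
    ]
    cfg = CohortConfig(**{**config.__dict__, "rng_seed": s_panel,
                          "trait_correlation": config.trait_correlation})
    panel = simulate_trait_panel(cfg)
    if config.n_variants:
        genotypes = simulate_genotypes(config.n_samples, config.variant_mafs, s_geno)
        rng_meta = np.random.default_rng(s_meta)
        ids = [f"rs{i + 1:05d}" for i in range(config.n_variants)]
        chrom = np.repeat(1, config.n_variants)
        # spread variants >= 2 Mb apart so each is its own locus by default
        pos = 1_000_000 + 2_000_000 * np.arange(config.n_variants)
        alleles = rng_meta.choice(["A", "C", "G", "T"], size=(config.n_variants, 2))
        for row in alleles:  # avoid identical ref/alt
            if row[0] == row[1]:
                row[1] = {"A": "G", "G": "A", "C": "T", "T": "C"}[row[0]]
        meta = pd.DataFrame({
            "id": ids, "chrom": chrom, "pos": pos,
            "A1": alleles[:, 0], "A2": alleles[:, 1],
            "maf": config.variant_mafs,
        })
        panel = apply_genetic_effects(panel, genotypes, config.genetic_effects, ids)
    else:
        genotypes = np.zeros((config.n_samples, 0), dtype=np.int8)
        meta = pd.DataFrame(columns=["id", "chrom", "pos", "A1", "A2", "maf"])
    status, intercept = simulate_disease(
        panel, config.disease_weights, config.target_prevalence, s_disease)
    panel = inject_missingness(panel, config.missing_rate, s_miss)
    rng_cov = np.random.default_rng(s_cov)
    age = rng_cov.uniform(40.0, 70.0, config.n_samples)
    sex = rng_cov.integers(0, 2, config.n_samples).astype(np.int8)
    return SimulatedCohort(panel, status, genotypes, meta, age, sex, intercept)
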