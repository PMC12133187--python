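"""Composite-phenotype construction over biomarker subsets.

A composite phenotype (CP) is the first principal component of the
correlation matrix of a chosen subset of quantitative biomarkers,
re-expressed as a scoring rule that can be applied to any cohort carrying
those biomarkers.  This module owns the panel container, the exhaustive
subset enumeration, the missing-data handling that precedes PCA, and the
PC1 extraction / orientation / scoring rules.

Conventions
-----------
* Subsets are emitted in deterministic order: size ascending, then
  lexicographically by member names.  Members within a subset keep the
  panel's canonical trait order.
* Eigenvector signs are fixed so the canonically-first member trait has a
  non-negative loading (first nonzero loading positive if it is zero).
* ``orientation`` flips the score so that, on training data, non-cases
  score at least as high as cases ("protective" direction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "PhenotypeSubset",
    "CompositePhenotype",
    "count_combinations",
    "enumerate_subsets",
    "filter_samples_by_missingness",
    "impute_iterative_lowrank",
    "correlation_matrix",
    "pc1",
    "fit_cp",
    "score_cp",
    "orient_cp",
]

_EIGEN_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerPanel:
    """Samples x traits quantitative panel with an explicit missingness mask.

    ``values[i, j]`` is undefined wherever ``missing_mask[i, j]`` is True;
    masked cells are stored as NaN but the mask is authoritative.
    """

    sample_ids: np.ndarray
    trait_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.sample_ids), len(self.trait_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("duplicate trait names")
        fully = self.missing_mask.all(axis=0)
        if self.values.shape[0] > 0 and fully.any():
            names = [t for t, m in zip(self.trait_names, fully) if m]
            raise ValueError(f"traits entirely missing: {names}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait_index(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError:
            raise KeyError(f"trait {name!r} not in panel") from None

    def copy(self) -> "BiomarkerPanel":
        return BiomarkerPanel(
            self.sample_ids.copy(), list(self.trait_names),
            self.values.copy(), self.missing_mask.copy(), dict(self.meta),
        )

    def subset_samples(self, row_idx: np.ndarray) -> "BiomarkerPanel":
        return BiomarkerPanel(
            self.sample_ids[row_idx], list(self.trait_names),
            self.values[row_idx], self.missing_mask[row_idx], dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.trait_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BiomarkerPanel":
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(df.index.to_numpy(), list(map(str, df.columns)), values, mask)

    @classmethod
    def read_table(cls, path, sep: str = "\t") -> "BiomarkerPanel":
        """Read a TSV/CSV panel: header row, first column = sample id,
        missing cells empty or 'NA'."""
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
        return cls.from_dataframe(df)

    def write_table(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, na_rep="NA")


@dataclass(frozen=True)
class PhenotypeSubset:
    """An ordered subset of 2..k trait names in canonical panel order."""

    member_traits: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.member_traits)) != len(self.member_traits):
            raise ValueError("duplicate members in subset")
        if len(self.member_traits) < 2:
            raise ValueError("subset needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.member_traits)

    def __str__(self) -> str:
        return "|".join(self.member_traits)


@dataclass
class CompositePhenotype:
    """A fitted CP: subset, unit-norm PC1 loadings of the training
    correlation submatrix, top eigenvalue, protective orientation, and the
    training standardization constants needed to score new samples."""

    subset: PhenotypeSubset
    loadings: np.ndarray
    eigenvalue: float
    orientation: int
    train_means: np.ndarray
    train_sds: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-10:
            raise ValueError("loadings must be unit-norm")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "members": list(self.subset.member_traits),
            "loadings": self.loadings.tolist(),
            "eigenvalue": float(self.eigenvalue),
            "orientation": int(self.orientation),
            "train_means": np.asarray(self.train_means, float).tolist(),
            "train_sds": np.asarray(self.train_sds, float).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositePhenotype":
        return cls(
            PhenotypeSubset(tuple(d["members"])),
            np.asarray(d["loadings"], float),
            float(d["eigenvalue"]),
            int(d["orientation"]),
            np.asarray(d["train_means"], float),
            np.asarray(d["train_sds"], float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "CompositePhenotype":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def count_combinations(k: int, min_size: int = 2) -> int:
    """Number of subsets of size >= min_size out of k traits.

    For min_size=2 this is 2**k - k - 1 (21 traits -> 2,097,130).
    """
    if k < min_size:
        raise ValueError(f"panel size {k} below minimum subset size {min_size}")
    return sum(math.comb(k, i) for i in range(min_size, k + 1))


def enumerate_subsets(trait_names: Sequence[str], min_size: int = 2) -> Iterator[PhenotypeSubset]:
    """Yield every subset of >= min_size traits exactly once.

    Order: size ascending, then lexicographic by member names.  Members of
    each subset keep the canonical order of ``trait_names``.
    """
    names = list(trait_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names")
    if len(names) < min_size:
        raise ValueError("fewer traits than min_size")
    order = {t: i for i, t in enumerate(names)}
    for size in range(min_size, len(names) + 1):
        subs = [tuple(sorted(c, key=order.__getitem__))
                for c in combinations(names, size)]
        for members in sorted(subs):
            yield PhenotypeSubset(members)


# ---------------------------------------------------------------------------
# Missing-data handling
# ---------------------------------------------------------------------------

def filter_samples_by_missingness(
    panel: BiomarkerPanel, max_missing_fraction: float = 0.30
) -> tuple[BiomarkerPanel, np.ndarray]:
    """Drop samples missing more than ``max_missing_fraction`` of traits.

    Returns the filtered panel and the removed sample ids.  A sample with
    exactly the threshold fraction missing is retained.
    """
    frac = panel.missing_mask.mean(axis=1)
    keep = frac <= max_missing_fraction
    removed = panel.sample_ids[~keep]
    return panel.subset_samples(np.flatnonzero(keep)), removed


def impute_iterative_lowrank(
    panel: BiomarkerPanel,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> BiomarkerPanel:
    """Iterative low-rank (truncated-SVD) imputation of missing cells.

    Traits are standardized on observed cells, missing cells initialized at
    the trait mean, then alternately reconstructed from the leading
    ``n_components`` singular vectors until the largest missing-cell change
    falls below ``tol``.  Observed cells are never altered.  On
    non-convergence the result carries ``meta['imputation_converged']=False``
    instead of failing.
    """
    mask = panel.missing_mask
    out = panel.copy()
    if not mask.any():
        return out
    X = panel.values.copy()
    obs = ~mask
    # start missing cells at the observed trait means
    mu0 = np.array([X[obs[:, j], j].mean() for j in range(X.shape[1])])
    X[mask] = np.broadcast_to(mu0, X.shape)[mask]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # moments re-estimated from the completed matrix each pass, as in
        # iterative PCA imputation
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        low = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
        filled = low * sd + mu
        delta = np.max(np.abs(filled[mask] - X[mask]))
        X[mask] = filled[mask]
        if delta < tol:
            converged = True
            break
    out.values = X
    out.values[obs] = panel.values[obs]
    out.missing_mask = np.zeros_like(mask)
    out.meta["imputation_converged"] = converged
    out.meta["imputation_iterations"] = n_iter
    return out


# ---------------------------------------------------------------------------
# Correlation + PC1
# ---------------------------------------------------------------------------

def correlation_matrix(panel: BiomarkerPanel) -> np.ndarray:
    """Pearson correlation of a complete panel; computed once and reused
    for every subset's PC1 (correlation-based PCA only needs submatrices)."""
    if panel.missing_mask.any():
        raise ValueError("panel has missing cells; impute first")
    sds = panel.values.std(axis=0, ddof=1)
    const = np.flatnonzero(sds == 0)
    if const.size:
        names = [panel.trait_names[j] for j in const]
        raise ValueError(f"constant traits have no correlation: {names}")
    R = np.corrcoef(panel.values, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Canonical eigenvector sign: first nonzero loading positive."""
    for v in vec:
        if v != 0.0:
            return vec if v > 0 else -vec
    return vec


def pc1(correlation_submatrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Top eigenpair of a correlation submatrix.

    Returns unit-norm loadings (sign-fixed) and the top eigenvalue, which
    for a correlation matrix is always >= 1.  Near-degenerate top
    eigenvalues (gap < 1e-12) fall back to the basis vector of the
    canonically-first trait so degenerate inputs stay deterministic.
    """
    R = np.asarray(correlation_submatrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 2:
        raise ValueError("need a square matrix of size >= 2")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    w, V = np.linalg.eigh(R)
    lam = float(w[-1])
    if R.shape[0] > 1 and lam - float(w[-2]) < _EIGEN_TIE_TOL:
        vec = np.zeros(R.shape[0])
        vec[0] = 1.0
        return vec, lam
    vec = V[:, -1]
    vec = vec / np.linalg.norm(vec)
    return _fix_sign(vec), lam


def orient_cp(scores: np.ndarray, disease_status: np.ndarray) -> int:
    """Protective orientation sign: -1 when cases outscore non-cases on
    the training data, else +1 (ties -> +1)."""
    scores = np.asarray(scores, float)
    status = np.asarray(disease_status).astype(bool)
    case_mean = scores[status].mean()
    ctrl_mean = scores[~status].mean()
    return -1 if case_mean > ctrl_mean else 1


def fit_cp(
    train_panel: BiomarkerPanel,
    subset: PhenotypeSubset,
    corr: np.ndarray,
    disease_status: np.ndarray | None = None,
) -> CompositePhenotype:
    """Fit a CP for ``subset`` from the cached training correlation matrix
    ``corr`` and the training panel's moments; orient on training labels
    when provided."""
    idx = np.array([train_panel.trait_index(t) for t in subset.member_traits])
    loadings, lam = pc1(corr[np.ix_(idx, idx)])
    means = train_panel.values[:, idx].mean(axis=0)
    sds = train_panel.values[:, idx].std(axis=0, ddof=1)
    cp = CompositePhenotype(subset, loadings, lam, 1, means, sds)
    if disease_status is not None:
        cp.orientation = orient_cp(score_cp(train_panel, cp), disease_status)
    return cp


def score_cp(panel: BiomarkerPanel, cp: CompositePhenotype) -> np.ndarray:
    """Score samples: orientation * sum_j loading_j * (x_j - mean_j)/sd_j,
    with means/sds frozen from the training split."""
    idx = np.array([panel.trait_index(t) for t in cp.subset.member_traits])
    Z = (panel.values[:, idx] - cp.train_means) / cp.train_sds
    return cp.orientation * (Z @ cp.loadings)
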