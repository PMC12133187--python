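"""Per-variant association scans and multi-trait consensus loci.

Phenotypes are rank-based inverse-normal transformed (Blom offset), then
regressed on each variant's dosage with age, sex and optional genetic PCs
as covariates.  The covariates are projected out of phenotype and dosages
once (QR residualization); each variant then needs only a simple
regression on residuals, with the degrees of freedom of the full joint
model.  This is algebraically identical to the per-variant multiple
regression (Frisch-Waugh-Lovell) and is enforced against that oracle in
the test suite.

Loci are distance-clumped around lead variants; a consensus locus is one
whose window is genome-wide significant in EVERY composite phenotype's
scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssoc",
    "Locus",
    "inverse_normal_transform",
    "ols_gwas",
    "genome_wide_hits",
    "clump_loci",
    "consensus_loci",
    "read_sumstats",
    "write_sumstats",
]

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW = 500_000

_SUMSTAT_COLS = ["id", "chrom", "pos", "A1", "A2", "beta", "se", "p", "n"]


@dataclass
class VariantAssoc:
    id: str
    chrom: str
    pos: int
    A1: str
    A2: str
    beta: float
    se: float
    p: float
    n: int
    failed: bool = False


@dataclass
class Locus:
    lead_id: str
    chrom: str
    lead_pos: int
    window: tuple[int, int]
    member_ids: list[str] = field(default_factory=list)
    lead_p: float = np.nan


# ---------------------------------------------------------------------------
# Inverse-normal transform
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Blom rank-based INT: Phi^{-1}((rank - 3/8) / (n + 1/4)) with
    midranks for ties; strictly monotone in the input."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("constant vector cannot be transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# Residual-projection GWAS
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def ols_gwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant linear model phenotype ~ dosage + covariates.

    Returns a summary-statistics frame (id, chrom, pos, A1, A2, beta, se,
    p, n).  Monomorphic variants (zero residual dosage variance) are kept
    with beta=0, p=1 and ``failed=True``.  ``variant_meta`` supplies id /
    chrom / pos / alleles; positional defaults are generated otherwise.
    """
    D = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = D.shape
    if y.shape[0] != n:
        raise ValueError("phenotype length mismatch")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    q = C.shape[1]
    if n <= q + 1:
        raise ValueError("too few samples for the covariate model")
    Q, _ = np.linalg.qr(C)
    y_r = _residualize(y[:, None], Q)[:, 0]
    D_r = _residualize(D, Q)

    dd = np.einsum("ij,ij->j", D_r, D_r)
    dy = D_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - q - 1
    ok = dd > 1e-12
    beta = np.zeros(m)
    se = np.zeros(m)
    p = np.ones(m)
    beta[ok] = dy[ok] / dd[ok]
    sse = np.maximum(yy - beta[ok] ** 2 * dd[ok], 0.0)
    sigma2 = sse / df
    se[ok] = np.sqrt(sigma2 / dd[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf)
    p[ok] = np.clip(2 * stats.t.sf(np.abs(tvals), df), np.nextafter(0, 1), 1.0)

    if variant_meta is None:
        variant_meta = pd.DataFrame({
            "id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "A1": "A", "A2": "G",
        })
    out = variant_meta.loc[:, ["id", "chrom", "pos", "A1", "A2"]].copy().reset_index(drop=True)
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["failed"] = ~ok
    return out


# ---------------------------------------------------------------------------
# Hits, clumping, consensus
# ---------------------------------------------------------------------------

def genome_wide_hits(assocs: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> list[str]:
    """Variant ids with p strictly below the genome-wide threshold."""
    if assocs.empty:
        return []
    return assocs.loc[assocs["p"] < threshold, "id"].tolist()


def clump_loci(
    assocs: pd.DataFrame,
    window_halfwidth: int = DEFAULT_WINDOW,
    threshold: float | None = None,
) -> list[Locus]:
    """Greedy distance clumping: the smallest-p unassigned variant becomes
    a lead; all unassigned variants on its chromosome within +- window join
    its locus.  Ties on p resolve to the lower (chrom, pos).  With
    ``threshold`` set, only variants below it seed/join loci."""
    df = assocs.copy()
    if threshold is not None:
        df = df[df["p"] < threshold]
    if df.empty:
        return []
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(df)):
        if assigned[i]:
            continue
        lead = df.iloc[i]
        same = (~assigned) & (df["chrom"].to_numpy() == lead["chrom"]) \
            & (np.abs(df["pos"].to_numpy() - lead["pos"]) <= window_halfwidth)
        members = df.loc[same, "id"].tolist()
        assigned |= same.to_numpy() if hasattr(same, "to_numpy") else same
        loci.append(Locus(
            lead_id=str(lead["id"]), chrom=str(lead["chrom"]),
            lead_pos=int(lead["pos"]),
            window=(int(lead["pos"]) - window_halfwidth,
                    int(lead["pos"]) + window_halfwidth),
            member_ids=members, lead_p=float(lead["p"]),
        ))
    return sorted(loci, key=lambda L: (L.chrom, L.lead_pos))


def _windows_overlap(a: Locus, b: Locus) -> bool:
    return a.chrom == b.chrom and a.window[0] <= b.window[1] and b.window[0] <= a.window[1]


def consensus_loci(
    assoc_sets: Sequence[pd.DataFrame],
    threshold: float = GENOME_WIDE_P,
    window_halfwidth: int = DEFAULT_WINDOW,
) -> list[Locus]:
    """Loci genome-wide significant in EVERY association set.

    Each set is clumped at the threshold; a locus from the first set
    survives only if an overlapping significant locus exists in all other
    sets.  The reported lead is the best-p variant over all overlapping
    loci across sets.  All sets must share the variant universe (matching
    id/chrom/pos metadata).
    """
    if not assoc_sets:
        raise ValueError("need at least one association set")
    base = assoc_sets[0][["id", "chrom", "pos"]].sort_values("id").reset_index(drop=True)
    for other in assoc_sets[1:]:
        o = other[["id", "chrom", "pos"]].sort_values("id").reset_index(drop=True)
        if not base.equals(o):
            raise ValueError("variant metadata differs between association sets")
    clumped = [clump_loci(a, window_halfwidth, threshold) for a in assoc_sets]
    out: list[Locus] = []
    for locus in clumped[0]:
        partners = [locus]
        ok = True
        for other in clumped[1:]:
            hits = [L for L in other if _windows_overlap(locus, L)]
            if not hits:
                ok = False
                break
            partners.extend(hits)
        if not ok:
            continue
        best = min(partners, key=lambda L: (L.lead_p, L.chrom, L.lead_pos))
        members = sorted({m for L in partners for m in L.member_ids})
        out.append(Locus(best.lead_id, best.chrom, best.lead_pos,
                         (best.lead_pos - window_halfwidth,
                          best.lead_pos + window_halfwidth),
                         members, best.lead_p))
    return sorted(out, key=lambda L: (L.chrom, L.lead_pos))


# ---------------------------------------------------------------------------
# Summary-statistics I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _SUMSTAT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return df


def write_sumstats(df: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = [c for c in _SUMSTAT_COLS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep=sep, index=False)
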