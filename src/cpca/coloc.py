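"""Approximate-Bayes-factor colocalization of two association signals.

Within a locus window, each variant's evidence for association with each
trait is summarized by a Wakefield log approximate Bayes factor computed
from (beta, se) with a Gaussian prior of variance W on the true effect.
Under the single-causal-variant assumption per trait, posterior mass is
apportioned across five hypotheses:

  H0 no causal variant for either trait
  H1 causal variant for trait 1 only
  H2 causal variant for trait 2 only
  H3 distinct causal variants for the two traits
  H4 one shared causal variant

All accumulation is in log space (z^2 terms overflow naive exponentials);
a locus is called colocalized when PP4 exceeds a strict threshold
(default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "RegionStats",
    "ColocPriors",
    "ColocResult",
    "extract_window",
    "harmonize_regions",
    "wakefield_labf",
    "coloc_abf",
    "classify_coloc",
]

DEFAULT_W = 0.04  # prior variance of the true effect (SD 0.2, standardized trait)
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class RegionStats:
    """Per-variant summary statistics for one trait in one window."""

    variant_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.variant_ids.size == self.beta.size == self.se.size):
            raise ValueError("ragged region stats")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")


@dataclass
class ColocPriors:
    """Per-variant prior probabilities of causality.

    p1/p2: causal for trait 1/2 only; p12: causal for both.  The defaults
    are the canonical single-variant ABF colocalization priors.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum below 1")


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    labf1: np.ndarray = field(default_factory=lambda: np.array([]))
    labf2: np.ndarray = field(default_factory=lambda: np.array([]))
    n_variants: int = 0
    h3_defined: bool = True

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


# ---------------------------------------------------------------------------
# Window extraction + harmonization
# ---------------------------------------------------------------------------

def extract_window(
    assocs: pd.DataFrame, lead_id: str, halfwidth: int = 500_000
) -> pd.DataFrame:
    """All variants on the lead's chromosome with |pos - lead pos| <=
    halfwidth (boundary inclusive)."""
    lead = assocs.loc[assocs["id"] == lead_id]
    if lead.empty:
        raise ValueError(f"lead variant {lead_id!r} not in summary statistics")
    chrom = lead["chrom"].iloc[0]
    pos = int(lead["pos"].iloc[0])
    sel = (assocs["chrom"] == chrom) & (np.abs(assocs["pos"] - pos) <= halfwidth)
    return assocs.loc[sel].reset_index(drop=True)


def harmonize_regions(
    stats1: pd.DataFrame, stats2: pd.DataFrame
) -> tuple[RegionStats, RegionStats, dict]:
    """Match two summary-stat slices on (chrom, pos, allele pair), flip the
    second trait's beta where A1/A2 are swapped, and drop strand-ambiguous
    palindromic variants.  Returns both RegionStats plus a log of counts."""
    a = stats1.set_index(["chrom", "pos"])
    b = stats2.set_index(["chrom", "pos"])
    common = a.index.intersection(b.index)
    ids, b1, s1, b2, s2 = [], [], [], [], []
    n_flipped = n_palindromic = n_mismatch = 0
    for key in common:
        ra, rb = a.loc[key], b.loc[key]
        if isinstance(ra, pd.DataFrame) or isinstance(rb, pd.DataFrame):
            continue  # duplicated position: skip defensively
        if (str(ra["A1"]).upper(), str(ra["A2"]).upper()) in _PALINDROMES:
            n_palindromic += 1
            continue
        pair_a = (str(ra["A1"]).upper(), str(ra["A2"]).upper())
        pair_b = (str(rb["A1"]).upper(), str(rb["A2"]).upper())
        if pair_a == pair_b:
            flip = 1.0
        elif pair_a == pair_b[::-1]:
            flip = -1.0
            n_flipped += 1
        else:
            n_mismatch += 1
            continue
        ids.append(str(ra["id"]))
        b1.append(float(ra["beta"]))
        s1.append(float(ra["se"]))
        b2.append(flip * float(rb["beta"]))
        s2.append(float(rb["se"]))
    if not ids:
        raise ValueError("no shared variants after harmonization")
    log = {"n_shared": len(ids), "n_flipped": n_flipped,
           "n_palindromic_dropped": n_palindromic, "n_allele_mismatch": n_mismatch}
    n1 = int(stats1["n"].max()) if "n" in stats1 else 0
    n2 = int(stats2["n"].max()) if "n" in stats2 else 0
    return (RegionStats(np.array(ids), np.array(b1), np.array(s1), n1),
            RegionStats(np.array(ids), np.array(b2), np.array(s2), n2), log)


# ---------------------------------------------------------------------------
# Bayes factors + posteriors
# ---------------------------------------------------------------------------

def wakefield_labf(beta, se, prior_effect_variance: float = DEFAULT_W):
    """Wakefield log approximate Bayes factor.

    With V = se^2, r = W/(V+W), z = beta/se:
        lABF = 1/2 (log(1 - r) + r z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_effect_variance <= 0:
        raise ValueError("prior effect variance must be positive")
    V = se**2
    r = prior_effect_variance / (V + prior_effect_variance)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal within rounding."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    region1: RegionStats,
    region2: RegionStats,
    priors: ColocPriors | None = None,
    prior_effect_variance: float = DEFAULT_W,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Per-variant lABFs feed log-sum-exp accumulators: S1 = logsum(l1),
    S2 = logsum(l2), S12 = logsum(l1 + l2); the H3 sum over ordered
    distinct pairs is log(exp(S1 + S2) - exp(S12)).  With fewer than two
    shared variants H3 is undefined and carries zero mass (flagged).
    """
    if priors is None:
        priors = ColocPriors()
    if not np.array_equal(region1.variant_ids, region2.variant_ids):
        order1 = np.argsort(region1.variant_ids)
        order2 = np.argsort(region2.variant_ids)
        if not np.array_equal(region1.variant_ids[order1], region2.variant_ids[order2]):
            raise ValueError("regions do not share a variant list; harmonize first")
        region1 = RegionStats(region1.variant_ids[order1], region1.beta[order1],
                              region1.se[order1], region1.n)
        region2 = RegionStats(region2.variant_ids[order2], region2.beta[order2],
                              region2.se[order2], region2.n)
    l1 = wakefield_labf(region1.beta, region1.se, prior_effect_variance)
    l2 = wakefield_labf(region2.beta, region2.se, prior_effect_variance)
    m = l1.size
    S1 = logsumexp(l1)
    S2 = logsumexp(l2)
    S12 = logsumexp(l1 + l2)
    h3_defined = m >= 2
    # unnormalized log posteriors (H0 configuration has likelihood 1)
    lp = np.full(5, -np.inf)
    lp[0] = 0.0
    lp[1] = np.log(priors.p1) + S1
    lp[2] = np.log(priors.p2) + S2
    if h3_defined:
        cross = _log_diff_exp(S1 + S2, S12)
        if np.isfinite(cross):
            lp[3] = np.log(priors.p1) + np.log(priors.p2) + cross
    lp[4] = np.log(priors.p12) + S12
    post = np.exp(lp - logsumexp(lp))
    post /= post.sum()
    return ColocResult(*map(float, post), labf1=l1, labf2=l2,
                       n_variants=m, h3_defined=h3_defined)


def classify_coloc(result: ColocResult, pp4_threshold: float = 0.7) -> str:
    """'colocalized' when PP4 strictly exceeds the threshold (default 0.7),
    else 'not_colocalized'."""
    return "colocalized" if result.pp4 > pp4_threshold else "not_colocalized"
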