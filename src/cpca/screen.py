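"""Exhaustive composite-phenotype screen.

Orchestrates the full combinatorial scan: enumerate every trait subset,
fit its CP on the training split (from the cached training correlation
matrix), score train and test, compare the CP's training ROC against a
reference single biomarker, Bonferroni-select, and validate winners on the
held-out test split.  Per-subset bootstrap seeds are derived from
(master seed, subset index) so chunked or parallel execution cannot change
any result.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BiomarkerPanel,
    CompositePhenotype,
    PhenotypeSubset,
    correlation_matrix,
    count_combinations,
    enumerate_subsets,
    fit_cp,
    score_cp,
)
from .evaluate import (
    auc,
    bootstrap_auc_ci,
    compare_paired_roc,
    delong_test,
    orient_marker,
    train_test_split,
)

__all__ = [
    "ScreenConfig",
    "bonferroni_threshold",
    "run_screen",
    "component_frequency",
    "top_candidates",
]


@dataclass
class ScreenConfig:
    """Knobs of one screen run.

    n_tests_for_correction defaults to the exact enumerated subset count;
    set it to a rounded value (e.g. 2e6) to reproduce published thresholds
    derived from approximate test counts.  delong_screen_alpha, when set,
    gates the expensive bootstrap comparison behind a cheap DeLong test:
    only subsets with DeLong p below the gate (and positive delta) get the
    n_boot-replicate bootstrap; gated-out subsets keep their DeLong p,
    flagged in the ``method`` column, and can never be selected.
    """

    reference_trait: str
    alpha: float = 0.05
    n_tests_for_correction: int | None = None
    min_subset_size: int = 2
    n_boot: int = 2000
    train_fraction: float = 0.70
    delong_screen_alpha: float | None = None
    ci_boot: bool = False
    seed: int = 0


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests
    (0.05 / 2,000,000 = 2.5e-8; 0.05 / 5 = 0.01)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _subset_seed(master_seed: int, subset_index: int) -> int:
    return int(np.random.SeedSequence([master_seed, subset_index])
               .generate_state(1)[0] % (2**31 - 1))


_COLUMNS = [
    "subset", "size", "train_auc", "train_ci_low", "train_ci_high",
    "test_auc", "test_ci_low", "test_ci_high", "delta_train",
    "p_vs_reference", "method", "failed", "selected",
]


def run_screen(
    panel: BiomarkerPanel,
    disease_status: np.ndarray,
    config: ScreenConfig,
    chunk_size: int = 10000,
    checkpoint_path: str | None = None,
) -> pd.DataFrame:
    """Run the full cPCA screen; returns the candidate table.

    The panel must be complete (filtered + imputed).  CPs are fit on the
    training split only; the reference biomarker is auto-oriented on the
    same training data.  Selection requires a comparison p-value below the
    Bonferroni threshold, a positive training AUC difference over the
    reference, and a test AUC strictly above the reference's test AUC.
    Degenerate subsets are retained with ``failed=True`` and never
    selected.  With ``checkpoint_path`` set, completed chunks are appended
    to a TSV and a rerun resumes after the last full chunk.
    """
    if panel.missing_mask.any():
        raise ValueError("panel has missing cells; filter and impute first")
    if config.reference_trait not in panel.trait_names:
        raise ValueError(f"reference trait {config.reference_trait!r} not in panel")
    status = np.asarray(disease_status).astype(np.int8)
    train_idx, test_idx = train_test_split(status, config.train_fraction, config.seed)
    train_panel = panel.subset_samples(train_idx)
    test_panel = panel.subset_samples(test_idx)
    y_train = status[train_idx]
    y_test = status[test_idx]

    corr = correlation_matrix(train_panel)

    ref_col = panel.trait_index(config.reference_trait)
    ref_sign = orient_marker(train_panel.values[:, ref_col], y_train)
    ref_train = ref_sign * train_panel.values[:, ref_col]
    ref_test = ref_sign * test_panel.values[:, ref_col]
    ref_test_auc = auc(ref_test, y_test)
    ref_train_auc = auc(ref_train, y_train)

    n_total = count_combinations(panel.n_traits, config.min_subset_size)
    n_tests = config.n_tests_for_correction or n_total
    threshold = bonferroni_threshold(config.alpha, n_tests)

    done_rows: list[pd.DataFrame] = []
    start_index = 0
    if checkpoint_path and os.path.exists(checkpoint_path):
        prev = pd.read_csv(checkpoint_path, sep="\t")
        n_prev = (len(prev) // chunk_size) * chunk_size  # only whole chunks trusted
        if n_prev:
            done_rows.append(prev.iloc[:n_prev])
            start_index = n_prev
            if n_prev < len(prev):  # drop the partial tail before appending
                prev.iloc[:n_prev].to_csv(checkpoint_path, sep="\t", index=False)
        else:
            os.remove(checkpoint_path)

    records: list[dict] = []
    chunk: list[dict] = []

    def flush_chunk():
        nonlocal chunk
        if checkpoint_path and chunk:
            df = pd.DataFrame(chunk, columns=_COLUMNS)
            header = not os.path.exists(checkpoint_path)
            df.to_csv(checkpoint_path, sep="\t", index=False, mode="a", header=header)
        records.extend(chunk)
        chunk = []

    for i, subset in enumerate(enumerate_subsets(panel.trait_names, config.min_subset_size)):
        if i < start_index:
            continue
        row = _evaluate_subset(
            subset, i, train_panel, test_panel, y_train, y_test,
            corr, ref_train, ref_test, ref_test_auc, threshold, config,
        )
        chunk.append(row)
        if len(chunk) >= chunk_size:
            flush_chunk()
    flush_chunk()

    table = pd.concat(done_rows + [pd.DataFrame(records, columns=_COLUMNS)],
                      ignore_index=True) if done_rows or records else \
        pd.DataFrame(columns=_COLUMNS)
    table.attrs["threshold"] = threshold
    table.attrs["reference_trait"] = config.reference_trait
    table.attrs["reference_test_auc"] = ref_test_auc
    table.attrs["reference_train_auc"] = ref_train_auc
    table.attrs["n_tests"] = n_tests
    return table


def _evaluate_subset(
    subset: PhenotypeSubset,
    index: int,
    train_panel: BiomarkerPanel,
    test_panel: BiomarkerPanel,
    y_train: np.ndarray,
    y_test: np.ndarray,
    corr: np.ndarray,
    ref_train: np.ndarray,
    ref_test: np.ndarray,
    ref_test_auc: float,
    threshold: float,
    config: ScreenConfig,
) -> dict:
    row = {
        "subset": str(subset), "size": subset.size,
        "train_auc": np.nan, "train_ci_low": np.nan, "train_ci_high": np.nan,
        "test_auc": np.nan, "test_ci_low": np.nan, "test_ci_high": np.nan,
        "delta_train": np.nan, "p_vs_reference": np.nan,
        "method": "", "failed": False, "selected": False,
    }
    seed_i = _subset_seed(config.seed, index)
    try:
        cp = fit_cp(train_panel, subset, corr, y_train)
        s_train = score_cp(train_panel, cp)
        s_test = score_cp(test_panel, cp)
    except Exception:
        row["failed"] = True
        return row
    row["train_auc"] = auc(s_train, y_train)
    row["test_auc"] = auc(s_test, y_test)
    if config.ci_boot:
        ci_tr = bootstrap_auc_ci(s_train, y_train, config.n_boot, seed=seed_i)
        ci_te = bootstrap_auc_ci(s_test, y_test, config.n_boot, seed=seed_i + 1)
        row["train_ci_low"], row["train_ci_high"] = ci_tr.ci_low, ci_tr.ci_high
        row["test_ci_low"], row["test_ci_high"] = ci_te.ci_low, ci_te.ci_high

    gate = config.delong_screen_alpha
    if gate is not None:
        dl = delong_test(s_train, ref_train, y_train)
        if not (dl.delta > 0 and dl.p_value < gate):
            row["delta_train"] = dl.delta
            row["p_vs_reference"] = dl.p_value
            row["method"] = "delong_screen"
            return row
    cmp_ = compare_paired_roc(s_train, ref_train, y_train,
                              method="bootstrap", n_boot=config.n_boot, seed=seed_i)
    row["delta_train"] = cmp_.delta
    row["p_vs_reference"] = cmp_.p_value
    row["method"] = "bootstrap"
    row["selected"] = bool(
        cmp_.delta > 0
        and cmp_.p_value < threshold
        and row["test_auc"] > ref_test_auc
    )
    return row


# ---------------------------------------------------------------------------
# Post-screen characterization
# ---------------------------------------------------------------------------

def component_frequency(
    selected_subsets: Iterable[Sequence[str] | PhenotypeSubset | str],
    order: int = 1,
) -> pd.DataFrame:
    """Count how often each trait (order 1), unordered pair (2) or triple
    (3) appears across the selected subsets; fractions are out of the
    number of selected subsets, sorted descending."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    subsets = []
    for s in selected_subsets:
        if isinstance(s, PhenotypeSubset):
            subsets.append(tuple(s.member_traits))
        elif isinstance(s, str):
            subsets.append(tuple(s.split("|")))
        else:
            subsets.append(tuple(s))
    if not subsets:
        return pd.DataFrame(columns=["members", "count", "fraction"])
    counts: dict[tuple[str, ...], int] = {}
    for members in subsets:
        for combo in _combinations(sorted(members), order):
            counts[combo] = counts.get(combo, 0) + 1
    n = len(subsets)
    df = pd.DataFrame(
        {"members": ["|".join(c) for c in counts],
         "count": list(counts.values())}
    )
    df["fraction"] = df["count"] / n
    return df.sort_values(["count", "members"], ascending=[False, True],
                          ignore_index=True)


def top_candidates(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Rank candidates by test AUC descending; ties prefer fewer member
    traits, then lexicographic subset name.  Returns the top k rows with a
    ``rank`` column."""
    if table.empty:
        out = table.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = table.sort_values(
        ["test_auc", "size", "subset"], ascending=[False, True, True],
        ignore_index=True,
    ).head(k).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
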