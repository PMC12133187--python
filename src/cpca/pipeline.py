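"""End-to-end orchestration: simulate -> filter -> impute -> split ->
screen -> report -> GWAS -> consensus -> colocalization.

Every stage's RNG seed is derived deterministically from the master seed
and the stage name, so a rerun with the same configuration is
bit-identical, and the run manifest records input checksums, the
configuration echo and every stage output so silent input changes are
detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    BiomarkerPanel,
    PhenotypeSubset,
    correlation_matrix,
    fit_cp,
    filter_samples_by_missingness,
    impute_iterative_lowrank,
    score_cp,
)
from .coloc import ColocPriors, classify_coloc, coloc_abf, extract_window, harmonize_regions
from .evaluate import bootstrap_auc_ci, train_test_split
from .gwas import (
    DEFAULT_WINDOW,
    GENOME_WIDE_P,
    consensus_loci,
    inverse_normal_transform,
    ols_gwas,
    write_sumstats,
)
from .screen import ScreenConfig, component_frequency, run_screen, top_candidates

logger = logging.getLogger("cpca")

__all__ = ["RunConfig", "run_pipeline", "report", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    h = zlib.crc32(f"{master_seed}:{stage}".encode())
    return int(h % (2**31 - 1))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Paths + stage settings for one pipeline run."""

    panel_path: str
    status_path: str
    out_dir: str
    covariates_path: str | None = None
    genotypes_path: str | None = None
    variants_path: str | None = None
    reference_trait: str = "eGFR"
    alpha: float = 0.05
    n_tests_for_correction: int | None = None
    min_subset_size: int = 2
    n_boot: int = 2000
    train_fraction: float = 0.70
    delong_screen_alpha: float | None = None
    max_missing_fraction: float = 0.30
    impute_rank: int = 2
    gwas_threshold: float = GENOME_WIDE_P
    clump_window: int = DEFAULT_WINDOW
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w: float = 0.04
    max_gwas_cps: int | None = None
    chunk_size: int = 10000
    seed: int = 0
    log_level: str = "INFO"


def _load_inputs(config: RunConfig):
    for attr in ("panel_path", "status_path"):
        path = getattr(config, attr)
        if not os.path.exists(path):
            raise FileNotFoundError(f"{attr.replace('_path', '')} file not found: {path}")
    panel = BiomarkerPanel.read_table(config.panel_path)
    status_df = pd.read_csv(config.status_path, sep="\t", index_col=0)
    status = status_df.iloc[:, 0].reindex(panel.sample_ids).to_numpy()
    if np.isnan(status.astype(float)).any():
        raise ValueError("disease status missing for some panel samples")
    covars = None
    if config.covariates_path:
        covars = pd.read_csv(config.covariates_path, sep="\t", index_col=0)
        covars = covars.reindex(panel.sample_ids)
    genos = meta = None
    if config.genotypes_path:
        gdf = pd.read_csv(config.genotypes_path, sep="\t", index_col=0)
        genos = gdf.reindex(panel.sample_ids).to_numpy(dtype=float)
        meta = pd.read_csv(config.variants_path, sep="\t",
                           dtype={"chrom": str}) if config.variants_path else None
        if meta is None:
            raise ValueError("genotypes given without variant metadata")
    return panel, status.astype(np.int8), covars, genos, meta


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
        "completed": False,
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")

    def record(stage: str, **info):
        manifest["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3), **info}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        logger.info("stage=%s %s", stage, info)

    try:
        for attr in ("panel_path", "status_path", "covariates_path",
                     "genotypes_path", "variants_path"):
            path = getattr(config, attr)
            if path and os.path.exists(path):
                manifest["inputs"][path] = _sha256(path)
        panel, status, covars, genos, vmeta = _load_inputs(config)
        record("load", n_samples=panel.n_samples, n_traits=panel.n_traits)

        # filter + impute
        all_ids = panel.sample_ids
        panel, removed = filter_samples_by_missingness(panel, config.max_missing_fraction)
        if removed.size:
            keep_mask = ~np.isin(all_ids, removed)
            status = status[keep_mask]
            if covars is not None:
                covars = covars.loc[panel.sample_ids]
            if genos is not None:
                genos = genos[keep_mask]
        record("filter", removed=int(removed.size), retained=panel.n_samples)
        panel = impute_iterative_lowrank(panel, n_components=config.impute_rank)
        record("impute", converged=bool(panel.meta.get("imputation_converged", True)),
               iterations=int(panel.meta.get("imputation_iterations", 0)))

        # screen (train/test split happens inside, seeded)
        scfg = ScreenConfig(
            reference_trait=config.reference_trait,
            alpha=config.alpha,
            n_tests_for_correction=config.n_tests_for_correction,
            min_subset_size=config.min_subset_size,
            n_boot=config.n_boot,
            train_fraction=config.train_fraction,
            delong_screen_alpha=config.delong_screen_alpha,
            seed=stage_seed(config.seed, "screen"),
        )
        ckpt = os.path.join(config.out_dir, "screen_checkpoint.tsv")
        table = run_screen(panel, status, scfg, chunk_size=config.chunk_size,
                           checkpoint_path=ckpt)
        table_path = os.path.join(config.out_dir, "candidates.tsv")
        table.to_csv(table_path, sep="\t", index=False)
        summary = {
            "n_subsets": int(len(table)),
            "n_selected": int(table["selected"].sum()),
            "threshold": table.attrs["threshold"],
            "reference_trait": table.attrs["reference_trait"],
            "reference_test_auc": table.attrs["reference_test_auc"],
        }
        with open(os.path.join(config.out_dir, "screen_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
        record("screen", path=table_path, **summary)

        # report
        rep = report(table, table[table["selected"]],
                     {o: component_frequency(table.loc[table["selected"], "subset"], o)
                      for o in (1, 2, 3)})
        rep_path = os.path.join(config.out_dir, "report.txt")
        with open(rep_path, "w") as fh:
            fh.write(rep)
        record("report", path=rep_path)

        # GWAS per selected CP + reference trait
        if genos is not None and genos.shape[1]:
            train_idx, _ = train_test_split(status, config.train_fraction, scfg.seed)
            train_panel = panel.subset_samples(train_idx)
            y_train = status[train_idx]
            corr = correlation_matrix(train_panel)
            sel = table[table["selected"] & ~table["failed"]]
            if config.max_gwas_cps is not None:
                sel = sel.head(config.max_gwas_cps)
            cov_mat = covars.to_numpy(dtype=float) if covars is not None else None
            gwas_dir = os.path.join(config.out_dir, "gwas")
            os.makedirs(gwas_dir, exist_ok=True)
            assoc_sets = []
            for _, row in sel.iterrows():
                subset = PhenotypeSubset(tuple(str(row["subset"]).split("|")))
                cp = fit_cp(train_panel, subset, corr, y_train)
                scores = score_cp(panel, cp)
                assoc = ols_gwas(genos, inverse_normal_transform(scores),
                                 cov_mat, vmeta)
                assoc_sets.append(assoc)
                write_sumstats(assoc, os.path.join(
                    gwas_dir, f"cp_{row['subset'].replace('|', '-')}.tsv"))
            ref_vals = panel.values[:, panel.trait_index(config.reference_trait)]
            ref_assoc = ols_gwas(genos, inverse_normal_transform(ref_vals),
                                 cov_mat, vmeta)
            ref_path = os.path.join(gwas_dir, "reference.tsv")
            write_sumstats(ref_assoc, ref_path)
            record("gwas", n_cps=len(assoc_sets), dir=gwas_dir)

            loci = consensus_loci(assoc_sets, config.gwas_threshold,
                                  config.clump_window) if assoc_sets else []
            loci_df = pd.DataFrame([{
                "lead_id": L.lead_id, "chrom": L.chrom, "lead_pos": L.lead_pos,
                "window_start": L.window[0], "window_end": L.window[1],
                "lead_p": L.lead_p, "n_members": len(L.member_ids),
            } for L in loci])
            loci_path = os.path.join(config.out_dir, "consensus_loci.tsv")
            loci_df.to_csv(loci_path, sep="\t", index=False)
            record("consensus", n_loci=len(loci), path=loci_path)

            # coloc each consensus locus: best CP vs reference trait
            coloc_rows = []
            if assoc_sets and loci:
                best_assoc = assoc_sets[0]
                priors = ColocPriors(config.coloc_p1, config.coloc_p2, config.coloc_p12)
                for L in loci:
                    w1 = extract_window(best_assoc, L.lead_id, config.clump_window)
                    w2 = extract_window(ref_assoc, L.lead_id, config.clump_window)
                    r1, r2, _ = harmonize_regions(w1, w2)
                    res = coloc_abf(r1, r2, priors, config.coloc_w)
                    coloc_rows.append({
                        "lead_id": L.lead_id, "n_variants": res.n_variants,
                        "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                        "pp3": res.pp3, "pp4": res.pp4,
                        "call": classify_coloc(res),
                    })
            coloc_path = os.path.join(config.out_dir, "coloc.tsv")
            pd.DataFrame(coloc_rows).to_csv(coloc_path, sep="\t", index=False)
            record("coloc", n_loci=len(coloc_rows), path=coloc_path)

        manifest["completed"] = True
        record("done", ok=True)
    except Exception as exc:
        record("error", error=str(exc))
        raise
    return manifest


def report(
    candidate_table: pd.DataFrame,
    selected: pd.DataFrame,
    frequencies: dict[int, pd.DataFrame],
    k: int = 10,
) -> str:
    """Deterministic human-readable screen report: top-k candidates,
    reference comparison, component frequencies, and the top CP's
    loadings-bearing subset."""
    lines = []
    ref = candidate_table.attrs.get("reference_trait", "reference")
    ref_auc = candidate_table.attrs.get("reference_test_auc", float("nan"))
    lines.append("Composite-phenotype screen report")
    lines.append("=" * 40)
    lines.append(f"subsets evaluated : {len(candidate_table)}")
    lines.append(f"selected          : {len(selected)}")
    lines.append(f"threshold         : {candidate_table.attrs.get('threshold', float('nan')):.3g}")
    lines.append(f"reference marker  : {ref} (test AUC {ref_auc:.3f})")
    lines.append("")
    if selected.empty:
        lines.append("Zero composite phenotypes selected; no frequency tables.")
        return "\n".join(lines) + "\n"
    top = top_candidates(candidate_table, k)
    lines.append(f"Top {min(k, len(top))} composite phenotypes (test AUC, size, p vs {ref}):")
    for _, row in top.iterrows():
        lines.append(
            f"  {int(row['rank']):2d}. {row['subset']}  "
            f"AUC={row['test_auc']:.3f}  size={int(row['size'])}  "
            f"p={row['p_vs_reference']:.3g}"
        )
    lines.append("")
    labels = {1: "traits", 2: "pairs", 3: "triples"}
    for order, freq in sorted(frequencies.items()):
        lines.append(f"Most frequent {labels.get(order, order)} among selected subsets:")
        for _, row in freq.head(10).iterrows():
            lines.append(f"  {row['members']}: {int(row['count'])} ({row['fraction']:.1%})")
        lines.append("")
    lines.append(f"#1 composite phenotype: {top.iloc[0]['subset']}")
    return "\n".join(lines) + "\n"
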