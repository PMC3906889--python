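"""End-to-end orchestration: simulate -> fit -> reference -> score ->
classify/QC -> rank -> select -> cluster, with all tables written as TSV.

The pipeline is deterministic for a fixed (config, seed): rerunning it
produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, interaction, simulate, tables
from .growth import FitConfig, fit_logistic
from .interaction import (
    DoseResponse,
    QCConfig,
    Thresholds,
    WILDTYPE_THRESHOLDS,
)

log = logging.getLogger("qhtcp")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; the seed is recorded in every output."""

    out_dir: str = "qhtcp_out"
    screen: simulate.ScreenConfig = field(default_factory=simulate.ScreenConfig)
    fit: FitConfig = FitConfig(tol=1e-10)
    thresholds: Thresholds = Thresholds()
    wildtype_thresholds: Thresholds = WILDTYPE_THRESHOLDS
    qc: QCConfig = QCConfig()
    remc: clustering.REMcConfig = clustering.REMcConfig()
    reference_stat: str = "median"
    k_min_fraction: float = 0.05  # no-growth K cut as fraction of median K
    seed: int = 0


@dataclass
class PipelineReport:
    """Counts and tables produced by one pipeline run."""

    interactions: pd.DataFrame
    n_enhancers: int
    n_suppressors: int
    tier_counts: dict[int, int]
    n_selected: int
    cluster_summary: pd.DataFrame | None
    out_dir: Path


def fit_screen(
    screen: simulate.SyntheticScreen, cfg: FitConfig, k_min_fraction: float
):
    """Fit every rendered culture and rebuild dose responses from the
    fitted L values.

    The no-growth K cut is set plate-wide to ``k_min_fraction`` times the
    median fitted K over all cultures, then all series are re-flagged.
    """
    # first pass with the configured absolute cut to get the K landscape
    gene_fits = {key: fit_logistic(ts, cfg) for key, ts in screen.series.items()}
    ref_fits = {key: fit_logistic(ts, cfg) for key, ts in screen.reference_series.items()}
    all_K = np.array(
        [f.K for f in list(gene_fits.values()) + list(ref_fits.values()) if f.grew]
    )
    if all_K.size:
        k_min = max(k_min_fraction * float(np.median(all_K)), 1e-9)
        cfg = dataclasses.replace(cfg, k_min=k_min)

    doses = np.asarray(screen.config.doses)
    dose_responses: dict[str, DoseResponse] = {}
    genes = sorted({g for g, _ in gene_fits})
    for gene in genes:
        L = np.full(doses.size, np.nan)
        grew = np.zeros(doses.size, dtype=bool)
        for j, d in enumerate(doses):
            f = gene_fits[(gene, float(d))]
            ok = f.grew and f.K >= cfg.k_min and f.r_squared >= cfg.r2_min
            if ok:
                L[j] = f.L
                grew[j] = True
        dose_responses[gene] = DoseResponse(gene, doses.copy(), L, grew)

    ref_by_dose: dict[float, np.ndarray] = {}
    for d in doses:
        vals = [
            f.L
            for (i, dd), f in sorted(ref_fits.items())
            if dd == float(d) and f.grew
        ]
        ref_by_dose[float(d)] = np.asarray(vals)
    return dose_responses, ref_by_dose, gene_fits


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full analysis on a seeded synthetic screen and write all
    output tables under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating screen (seed=%d, n_genes=%d)", cfg.seed, cfg.screen.n_genes)
    screen_cfg = dataclasses.replace(cfg.screen, seed=cfg.seed)
    screen = simulate.generate_screen(screen_cfg)

    log.info("fitting %d culture series", len(screen.series) + len(screen.reference_series))
    dose_responses, ref_by_dose, gene_fits = fit_screen(
        screen, cfg.fit, cfg.k_min_fraction
    )

    screen_table = tables.fits_to_screen_table(
        {"dose": d, "orf": g, "fit": gene_fits[(g, d)]}
        for (g, d) in sorted(gene_fits)
    )
    tables.write_table(screen_table, out / "screen_fits.tsv", seed=cfg.seed, config=cfg.screen)

    ref = interaction.build_reference(ref_by_dose, stat=cfg.reference_stat)

    log.info("scoring %d strains", len(dose_responses))
    results = []
    for gene in sorted(dose_responses):
        dr = dose_responses[gene]
        if not dr.grew[0]:
            log.warning("skipping %s: no growth at dose 0", gene)
            continue
        res = interaction.score_interaction(dr, ref)
        res = dataclasses.replace(
            res,
            interaction_class=interaction.classify(res, cfg.thresholds),
        )
        res = dataclasses.replace(
            res, qc_flags=interaction.qc_flags(res, cfg=cfg.qc)
        )
        results.append(res)
    ranked = interaction.rank_interactions(results)

    int_table = tables.results_to_interaction_table(ranked)
    int_table["class"] = [r.interaction_class for r in ranked]
    int_table["qc_flags"] = [";".join(sorted(r.qc_flags)) for r in ranked]
    tables.write_table(int_table, out / "interactions.tsv", seed=cfg.seed, config=cfg.screen)

    n_enh = sum(r.interaction_class == interaction.DELETION_ENHANCER for r in ranked)
    n_sup = sum(r.interaction_class == interaction.DELETION_SUPPRESSOR for r in ranked)
    tier_counts: dict[int, int] = {}
    for r in ranked:
        tier_counts[r.tier] = tier_counts.get(r.tier, 0) + 1

    # gene selection for clustering: here the single screen stands in for
    # both contexts (a companion wild-type screen table can be supplied to
    # the library functions directly)
    by_gene = {r.strain_id: r for r in ranked}
    selected = clustering.select_genes(
        by_gene, {}, cfg.thresholds, cfg.wildtype_thresholds
    )

    summary = None
    selected_scored = sorted(
        g for g in selected if not np.isnan(by_gene[g].INT)
    )
    if len(selected_scored) >= 2:
        profs = [
            clustering.InteractionProfile(
                g,
                np.array([by_gene[g].INT, by_gene[g].K0]),
                np.zeros(2, dtype=bool),
            )
            for g in selected_scored
        ]
        remc_cfg = dataclasses.replace(cfg.remc, seed=cfg.seed)
        tree = clustering.remc(profs, remc_cfg)
        summary = clustering.cluster_summary(tree, {p.gene_id: p for p in profs})
        tables.write_table(summary, out / "cluster_summary.tsv", seed=cfg.seed, config=cfg.screen)
        membership = pd.DataFrame(
            [
                {"cluster": leaf.name, "gene": g}
                for leaf in tree.leaves()
                for g in leaf.members
            ]
        )
        tables.write_table(membership, out / "cluster_members.tsv", seed=cfg.seed, config=cfg.screen)

    summary_rows = pd.DataFrame(
        [
            {
                "n_strains": len(ranked),
                "n_enhancers": n_enh,
                "n_suppressors": n_sup,
                "n_selected": len(selected),
                "max_tier": max(tier_counts) if tier_counts else 0,
            }
        ]
    )
    tables.write_table(summary_rows, out / "run_summary.tsv", seed=cfg.seed, config=cfg.screen)

    return PipelineReport(
        interactions=int_table,
        n_enhancers=n_enh,
        n_suppressors=n_sup,
        tier_counts=tier_counts,
        n_selected=len(selected),
        cluster_summary=summary,
        out_dir=out,
    )
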