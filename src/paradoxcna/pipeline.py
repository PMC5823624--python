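"""End-to-end orchestration: simulate -> CNA -> meta -> paradox -> miRNA.

The pipeline reproduces the integrative workflow on a synthetic study:

1. generate the multi-cohort fixtures with planted truth;
2. integrate the aCGH cohorts onto anchors, permutation-test per-anchor
   gain/loss frequencies and merge significant runs into aberrant regions;
3. robust-rank-aggregate per-cohort differential-expression rankings into
   the consensus deregulated gene set, and the per-study miRNA lists into
   the consensus deregulated miRNA set;
4. overlap deregulated genes with aberrant regions, test the association
   (chi-square), classify paradoxical genes and validate them sample-wise
   on the matched cohort (z vs log2 CNA co-occurrence, randomization test);
5. test miRNA-target enrichment among the validated paradoxical genes,
   CNA-controlled partial correlations with an empirical random-pair null,
   explanatory classification, and per-gene multiple-correlation
   percentiles.

Every random stage draws from a seed derived from the single configured
seed; the report lists them all, and a rerun with the same configuration is
identical.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cna_integration, mirna_assoc, paradox, rank_meta, synthetic_cohort
from .formats_io import fmt_float
from .mirna_assoc import TargetNetwork
from .paradox import AnalysisThresholds
from .synthetic_cohort import SimulationConfig

__all__ = ["PipelineConfig", "SummaryReport", "run"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One configuration object for the whole analysis."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    alpha_genes: float = 0.01        # RRA corrected-p cutoff, genes
    alpha_mirnas: float = 0.05       # RRA corrected-p cutoff, miRNAs
    alpha_pairs: float = 0.05        # empirical pair-test cutoff
    anchor_alpha: float = 0.05       # per-anchor permutation cutoff
    n_perm: int = 10_000             # anchor permutations
    n_rand: int = 100_000            # per-gene validation randomizations
    n_null: int = 10_000             # random pairs in the empirical null
    max_gap: int = 500_000           # anchor-run merge gap, bases
    min_target_score: float = 0.0    # target-network load filters
    min_target_sources: int = 2
    exclude_genes: frozenset = frozenset()   # e.g. non-protein-coding ids

    def __post_init__(self):
        for name in ("alpha_genes", "alpha_mirnas", "alpha_pairs", "anchor_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """A per-stage 31-bit seed derived from the configured seed."""
        tag = zlib.crc32(stage.encode())
        h = np.random.SeedSequence([self.sim.seed, tag])
        return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class SummaryReport:
    """Per-stage counts and statistics of one pipeline run."""

    n_anchors: int = 0
    n_significant_anchors: int = 0
    n_regions: int = 0
    n_de_genes_up: int = 0
    n_de_genes_down: int = 0
    n_de_in_region: int = 0
    chi2: float = float("nan")
    chi2_p: float = float("nan")
    quadrants: dict = field(default_factory=dict)     # up-gain/up-loss/...
    n_paradoxical: int = 0
    n_validated: int = 0
    n_deregulated_mirnas: int = 0
    n_validated_mirnas: int = 0
    target_overlap: int = 0
    target_overlap_p: float = float("nan")
    n_pairs_tested: int = 0
    n_pairs_significant: int = 0
    n_pairs_explanatory: int = 0
    pct_significant_explanatory: float = float("nan")
    n_top5_cmc: int = 0
    top5_cmc_p: float = float("nan")
    median_freq_paradoxical: float = float("nan")
    mean_freq_paradoxical: float = float("nan")
    seeds: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    # planted-truth recovery (synthetic runs only)
    paradox_sensitivity: float = float("nan")
    paradox_precision: float = float("nan")
    mirna_sensitivity: float = float("nan")
    explanatory_edge_fraction: float = float("nan")
    nonedge_explanatory_fraction: float = float("nan")

    def check_consistency(self) -> None:
        assert self.n_validated <= self.n_paradoxical <= self.n_de_in_region
        assert self.n_pairs_explanatory <= self.n_pairs_significant <= self.n_pairs_tested

    def as_text(self) -> str:
        lines = ["paradoxcna pipeline summary", "=" * 30]
        for k, v in asdict(self).items():
            if isinstance(v, float):
                v = fmt_float(v)
            lines.append(f"{k}: {v}")
        return "\n".join(lines) + "\n"


def run(config: PipelineConfig, outdir=None) -> SummaryReport:
    """Execute the full synthetic-cohort analysis and report it."""
    report = SummaryReport()
    t0 = time.perf_counter()

    def tic(stage):
        report.timings[stage] = round(time.perf_counter() - t0, 3)

    # -- stage 0: simulation ------------------------------------------------
    sim = config.sim
    report.seeds["simulation"] = sim.seed
    cna_truth = synthetic_cohort.simulate_genome(sim)
    mirna_truth = synthetic_cohort.simulate_mirna_truth(sim)
    datasets, _ = synthetic_cohort.simulate_cna_datasets(sim, truth=cna_truth)
    gene_cohorts, _, truth = synthetic_cohort.simulate_expression(
        sim, cna_truth, mirna_truth)
    study_lists = synthetic_cohort.simulate_mirna_study_rankings(sim, mirna_truth)
    matched, _ = synthetic_cohort.simulate_matched_cohort(sim, cna_truth, mirna_truth)
    net_edges, _, _ = synthetic_cohort.simulate_target_network(
        sim, cna_truth, mirna_truth)
    tic("simulate")

    # -- stage 1: CNA integration ------------------------------------------
    table = cna_integration.build_anchor_table(datasets)
    seed_perm = config.stage_seed("anchor_permutation")
    report.seeds["anchor_permutation"] = seed_perm
    cna_integration.anchor_frequency_test(table, n_perm=config.n_perm,
                                          seed=seed_perm)
    regions = cna_integration.merge_significant_anchors(
        table, max_gap=config.max_gap, alpha=config.anchor_alpha)
    report.n_anchors = table.n_anchors
    report.n_significant_anchors = int(
        ((table.p_gain < config.anchor_alpha)
         | (table.p_loss < config.anchor_alpha)).sum())
    report.n_regions = len(regions)
    tic("cna")

    # -- stage 2: gene meta-analysis ---------------------------------------
    gene_lists = [rank_meta.rank_differential(m) for m in gene_cohorts]
    gene_meta = rank_meta.aggregate(gene_lists, alpha=config.alpha_genes)
    de_table = {r.id: (1 if r.direction == "up" else -1)
                for r in gene_meta if r.significant
                and r.id not in config.exclude_genes}
    report.n_de_genes_up = sum(1 for d in de_table.values() if d == 1)
    report.n_de_genes_down = sum(1 for d in de_table.values() if d == -1)
    tic("meta_genes")

    # -- stage 3: miRNA meta-analysis + cohort validation -------------------
    mirna_meta = rank_meta.aggregate(study_lists, alpha=config.alpha_mirnas)
    mirna_dirs = {r.id: (1 if r.direction == "up" else -1)
                  for r in mirna_meta if r.significant}
    report.n_deregulated_mirnas = len(mirna_dirs)
    # matched-cohort confirmation: BH < 0.05 in the same direction
    conf_up, conf_down = _confirmed_features(matched.mirna_expr)
    validated_mirnas = {m: d for m, d in mirna_dirs.items()
                        if (m in conf_up if d == 1 else m in conf_down)}
    report.n_validated_mirnas = len(validated_mirnas)
    tic("meta_mirnas")

    # -- stage 4: paradox classification + validation -----------------------
    region_map = paradox.assign_genes_to_regions(cna_truth.genes, regions)
    records = paradox.identify_paradoxical(de_table, region_map)
    report.n_de_in_region = len(records)
    try:
        report.chi2, report.chi2_p, tab = paradox.association_chi_square(
            de_table, region_map)
        report.quadrants = {"up_gain": int(tab[0, 0]), "up_loss": int(tab[0, 1]),
                            "down_gain": int(tab[1, 0]), "down_loss": int(tab[1, 1])}
    except ValueError as exc:
        log.warning("chi-square skipped: %s", exc)

    z = paradox.zscore_expression(matched.gene_expr)
    seed_rand = config.stage_seed("validation_randomization")
    report.seeds["validation_randomization"] = seed_rand
    paradox_records = [r for r in records if r.is_paradoxical]
    for i, rec in enumerate(paradox_records):
        if rec.gene not in z.index or rec.gene not in matched.gene_cna.index:
            continue
        zr = z.loc[rec.gene].to_numpy()
        cr = matched.gene_cna.loc[rec.gene].reindex(z.columns).to_numpy()
        paradox.sample_paradox_frequencies(zr, cr, rec, config.thresholds)
        paradox.validate_gene_randomization(
            zr, cr, rec, n_rand=config.n_rand,
            seed=np.random.SeedSequence([seed_rand, i]), th=config.thresholds)
    validated = [r for r in paradox_records if r.validated]
    report.n_paradoxical = len(paradox_records)
    report.n_validated = len(validated)
    freqs = [r.freq_paradoxical for r in validated if np.isfinite(r.freq_paradoxical)]
    if freqs:
        report.median_freq_paradoxical = float(np.median(freqs))
        report.mean_freq_paradoxical = float(np.mean(freqs))
    tic("paradox")

    # -- stage 5: miRNA association ----------------------------------------
    validated_genes = {r.gene: r.de_direction for r in validated}
    universe_genes = {r.id for r in gene_meta}
    network = TargetNetwork(
        edges={(m, g) for m, g in net_edges
               if g in universe_genes and m in validated_mirnas},
        population_genes=len(universe_genes))
    if validated_genes and network.edges:
        report.target_overlap, report.target_overlap_p = \
            mirna_assoc.target_overlap_test(set(validated_genes), network)
    if validated_genes and validated_mirnas:
        seed_null = config.stage_seed("pair_null")
        report.seeds["pair_null"] = seed_null
        tumors = matched.gene_expr.tumor_samples
        pairs = mirna_assoc.test_pairs(
            validated_mirnas, validated_genes,
            matched.gene_expr.values[tumors], matched.mirna_expr.values[tumors],
            matched.gene_cna[tumors], n_null=config.n_null,
            alpha=config.alpha_pairs, seed=seed_null)
        report.n_pairs_tested = len(pairs)
        report.n_pairs_significant = sum(p.significant for p in pairs)
        report.n_pairs_explanatory = sum(p.explanatory for p in pairs)
        if report.n_pairs_significant:
            report.pct_significant_explanatory = (
                100.0 * report.n_pairs_explanatory / report.n_pairs_significant)

        mir_expr_t = matched.mirna_expr.values.loc[
            sorted(validated_mirnas), tumors]
        cmcs = {g: mirna_assoc.gene_cmc_profile(
            matched.gene_expr.values.loc[g, tumors].to_numpy(), mir_expr_t)
            for g in sorted(validated_genes)}
        background = np.array([
            mirna_assoc.gene_cmc_profile(
                matched.gene_expr.values.loc[g, tumors].to_numpy(), mir_expr_t)
            for g in matched.gene_expr.feature_ids])
        _, report.n_top5_cmc, report.top5_cmc_p = mirna_assoc.cmc_percentile(
            cmcs, background)
    else:
        pairs = []
    tic("mirna_assoc")

    _recovery_metrics(report, truth, validated_genes, validated_mirnas, pairs)
    report.check_consistency()

    if outdir is not None:
        _write_artifacts(outdir, table, regions, gene_meta, mirna_meta,
                         paradox_records, pairs, report)
    return report


def _confirmed_features(matrix) -> tuple[set, set]:
    """Features confirmed deregulated in a cohort at BH < 0.05, by direction."""
    from scipy import stats as sstats
    from statsmodels.stats.multitest import multipletests
    t = matrix.tumors().to_numpy()
    n = matrix.normals().to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sstats.ttest_ind(t, n, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    sig = multipletests(p, method="fdr_bh")[1] < 0.05
    diff = t.mean(axis=1) - n.mean(axis=1)
    ids = np.asarray(matrix.feature_ids)
    return set(ids[sig & (diff > 0)]), set(ids[sig & (diff < 0)])


def _recovery_metrics(report, truth, validated_genes, validated_mirnas, pairs):
    planted = truth.paradox_gene_ids
    found = set(validated_genes)
    if planted:
        report.paradox_sensitivity = len(found & planted) / len(planted)
    if found:
        report.paradox_precision = len(found & planted) / len(found)
    if truth.deregulated_mirnas:
        report.mirna_sensitivity = (
            len(set(validated_mirnas) & set(truth.deregulated_mirnas))
            / len(truth.deregulated_mirnas))
    tested_edges = [p for p in pairs if (p.mirna, p.gene) in truth.regulator_edges]
    non_edges = [p for p in pairs if (p.mirna, p.gene) not in truth.regulator_edges]
    if tested_edges:
        report.explanatory_edge_fraction = (
            sum(p.explanatory for p in tested_edges) / len(tested_edges))
    if non_edges:
        report.nonedge_explanatory_fraction = (
            sum(p.explanatory for p in non_edges) / len(non_edges))


def _write_artifacts(outdir, table, regions, gene_meta, mirna_meta,
                     records, pairs, report):
    from pathlib import Path

    from .formats_io import write_bed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    anchors = pd.DataFrame({
        "chrom": table.chroms, "pos": table.positions,
        "gain_freq": table.gain_freq, "loss_freq": table.loss_freq,
        "p_gain": table.p_gain, "p_loss": table.p_loss,
    })
    anchors.to_csv(out / "anchors.tsv", sep="\t", index=False,
                   float_format="%.6g")
    write_bed(out / "regions.bed",
              [r.interval for r in regions],
              scores=[r.peak_frequency for r in regions])

    def meta_frame(results):
        return pd.DataFrame([{
            "id": r.id, "direction": r.direction, "rho": r.rho, "p": r.p,
            "p_loo": r.p_loo, "n_lists_used": r.n_lists_used,
            "significant": int(r.significant)} for r in results])

    meta_frame(gene_meta).to_csv(out / "genes_meta.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    meta_frame(mirna_meta).to_csv(out / "mirna_meta.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    pd.DataFrame([{
        "gene": r.gene, "de_direction": r.de_direction,
        "region_direction": r.region_direction,
        "is_paradoxical": int(r.is_paradoxical),
        "freq_paradoxical": r.freq_paradoxical,
        "freq_regular": r.freq_regular, "freq_up": r.freq_up,
        "freq_down": r.freq_down, "freq_gain": r.freq_gain,
        "freq_loss": r.freq_loss, "validation_p": r.validation_p,
        "validated": int(r.validated)} for r in records]).to_csv(
        out / "paradox.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame([{
        "mirna": p.mirna, "gene": p.gene, "r_partial": p.r_partial,
        "empirical_p": p.empirical_p, "significant": int(p.significant),
        "explanatory": int(p.explanatory)} for p in pairs]).to_csv(
        out / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "summary.txt").write_text(report.as_text())
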