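"""Synthetic multi-cohort fixtures with planted ground truth.

Emulates the study design the pipeline targets: several aCGH cohorts with
heterogeneous probe grids and recurrent gain/loss regions, several
tumor/normal expression cohorts with a gene-dosage effect, a panel of
deregulated miRNAs whose repression inverts the dosage effect for a set of
planted "paradoxical" genes, noisy truncated per-study miRNA rankings, a
miRNA->gene target network, and one matched multi-omics cohort (expression
+ per-gene copy number + miRNA expression on the same tumor samples) that
stands in for the homogeneous validation cohort.

Generative model (log-scale expression), tumor sample s, gene g:

    x[g,s] = baseline_g + alpha * call[g,s]
             - sum_{m targets g} beta[g,m] * dmir[m,s] * (1 + kappa * ab[g,s])
             + Normal(0, noise_sd)

where ``call`` is the discrete copy call (region carriers at rate
``aberration_frequency`` plus a small background), ``dmir`` the per-sample
miRNA deregulation (shift +/- ``mirna_shift`` plus sample noise) and ``ab``
indicates that the sample carries the gene's region aberration.  The
interaction term (``kappa``, paradox genes only) makes repression strongest
in aberration-carrying samples — the clonal compensation that keeps a
paradoxical gene's expression defying its copy number.  For planted paradox
genes ``beta`` is solved so the expected tumor-vs-normal shift is
``paradox_shift_sds`` noise-SDs in the direction opposite to the region
(spec floor: at least 2).  Normals have call = 0 and no miRNA deregulation.

Every generator is a pure function of (config, seed): each draws from its
own named substream, so outputs are reproducible per-operation and
independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_integration import ProbeCallDataset
from .formats_io import ExpressionMatrix, GenomicInterval, RankedList

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "CnaTruth",
    "SyntheticTruth",
    "MatchedCohort",
    "simulate_genome",
    "simulate_cna_datasets",
    "simulate_mirna_truth",
    "simulate_expression",
    "simulate_matched_cohort",
    "simulate_mirna_study_rankings",
    "simulate_target_network",
]

#: log2-ratio class means for loss / neutral / gain (single-copy change in
#: a diploid background: log2(1/2) rounded, log2(3/2))
RATIO_CLASS_MEANS = {-1: -0.5, 0: 0.0, 1: 0.58}

_SLOTS_PER_CHROM = 4            # non-overlapping region slots per chromosome

# named rng substreams
_S_GENOME, _S_CNA, _S_TRUTH, _S_EXPR, _S_LISTS, _S_MATCHED, _S_NETWORK = range(7)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Cohort sizes follow a desk-scale version of the published design (10
    expression cohorts of ~75 samples, 3 aCGH cohorts, 9 miRNA studies, one
    large matched validation cohort); ``aberration_frequency`` sits at the
    top of the reported 0.07-0.45 per-region range so that planted regions
    are recurrent, and effect sizes are in log2-expression units.
    """

    n_genes: int = 2000
    n_mirnas: int = 40
    n_cna_datasets: int = 3
    n_expr_datasets: int = 4
    samples_per_dataset: int = 60       # tumors per cohort
    normals_per_dataset: int = 15
    n_chromosomes: int = 5
    aberrant_region_count: int = 8
    aberration_frequency: float = 0.4
    dosage_effect: float = 0.5          # alpha, log2 units per call unit
    mirna_repression: float = 1.0       # beta for ordinary (decoy) targets
    noise_sd: float = 0.5
    n_paradox_genes: int = 60
    seed: int = 0

    # secondary knobs
    background_rate: float = 0.01       # per-cell background aberration rate
    mirna_shift: float = 1.5            # log2 shift of a deregulated miRNA
    mirna_sample_sd: float = 0.5        # per-sample spread of the deregulation
    n_deregulated_mirnas: int = 10
    n_mirna_studies: int = 9
    detection_rate: float = 0.8         # P(a study reports a true miRNA)
    gene_dropout: float = 0.05          # per-cohort missing-gene fraction
    compensation: float = 4.0           # kappa: clonal repression boost
    paradox_shift_sds: float = 3.0      # net paradox shift, in noise-SD units
    decoy_targets_per_mirna: int = 8
    matched_tumors: int = 150
    matched_normals: int = 40
    cna_ratio_sd: float = 0.1           # log2-ratio noise around class means
    probes_per_chromosome: int = 100    # per CNA dataset
    chrom_length: int = 10_000_000
    gene_length: int = 5_000

    def __post_init__(self):
        counts = dict(
            n_genes=self.n_genes, n_mirnas=self.n_mirnas,
            n_cna_datasets=self.n_cna_datasets,
            n_expr_datasets=self.n_expr_datasets,
            samples_per_dataset=self.samples_per_dataset,
            normals_per_dataset=self.normals_per_dataset,
            n_chromosomes=self.n_chromosomes,
            aberrant_region_count=self.aberrant_region_count,
            n_mirna_studies=self.n_mirna_studies,
            probes_per_chromosome=self.probes_per_chromosome,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        for name in ("aberration_frequency", "background_rate",
                     "detection_rate", "gene_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_paradox_genes < 0 or self.n_deregulated_mirnas < 0:
            raise ConfigurationError("planted counts must be >= 0")
        if self.aberrant_region_count > self.n_chromosomes * _SLOTS_PER_CHROM:
            raise ConfigurationError(
                f"{self.aberrant_region_count} regions exceed genome capacity "
                f"({self.n_chromosomes * _SLOTS_PER_CHROM} slots)")
        if self.n_deregulated_mirnas > self.n_mirnas:
            raise ConfigurationError("more deregulated miRNAs than miRNAs")

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class CnaTruth:
    """Planted genome: gene coordinates and aberrant regions."""

    genes: list[GenomicInterval]
    regions: list[tuple[GenomicInterval, int]]       # (interval, +/-1)
    gene_region_direction: dict[str, int]            # genes inside a region
    baseline: dict[str, float]                       # per-gene log2 baseline


@dataclass
class MirnaTruth:
    mirna_ids: list[str]
    deregulated: dict[str, int]                      # miRNA -> +/-1
    baseline: dict[str, float]


@dataclass
class SyntheticTruth:
    """Planted ground truth consumed by the recovery tests."""

    paradox_gene_ids: set[str]
    gene_region_direction: dict[str, int]
    de_direction: dict[str, int]
    deregulated_mirnas: dict[str, int]
    regulator_edges: set[tuple[str, str]]            # (miRNA, paradox gene)

    def __post_init__(self):
        for g in self.paradox_gene_ids:
            if self.de_direction[g] * self.gene_region_direction[g] != -1:
                raise ValueError(f"paradox gene {g} does not oppose its region")
            mirs = {m for m, gg in self.regulator_edges if gg == g}
            if not any(self.deregulated_mirnas[m] == -self.de_direction[g]
                       for m in mirs):
                raise ValueError(f"paradox gene {g} lacks an opposing regulator")


@dataclass
class MatchedCohort:
    """Expression + per-gene copy number + miRNA expression, same tumors."""

    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    gene_cna: pd.DataFrame                           # genes x tumor samples, log2


# ---------------------------------------------------------------------------
# genome and truth
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> CnaTruth:
    """Place genes and aberrant regions on the synthetic genome.

    Genes tile each chromosome evenly; regions occupy the middle half of
    randomly chosen non-overlapping chromosome slots, directions
    alternating gain/loss so both kinds exist.
    """
    rng = config.rng(_S_GENOME)
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    genes: list[GenomicInterval] = []
    for gi in range(config.n_genes):
        ci, slot = divmod(gi, per_chrom)
        spacing = config.chrom_length // (per_chrom + 1)
        start = spacing * (slot + 1)
        genes.append(GenomicInterval(f"chr{ci + 1}", start,
                                     start + config.gene_length, f"G{gi:04d}"))

    slot_len = config.chrom_length // _SLOTS_PER_CHROM
    all_slots = [(c, s) for c in range(config.n_chromosomes)
                 for s in range(_SLOTS_PER_CHROM)]
    chosen = rng.permutation(len(all_slots))[:config.aberrant_region_count]
    regions = []
    for k, idx in enumerate(sorted(chosen)):
        c, s = all_slots[idx]
        lo = s * slot_len + slot_len // 4
        hi = lo + slot_len // 2
        direction = 1 if k % 2 == 0 else -1
        regions.append((GenomicInterval(f"chr{c + 1}", lo, hi,
                                        f"region_{k}"), direction))

    gene_region = {}
    for g in genes:
        for interval, direction in regions:
            if g.overlap(interval) > 0:
                gene_region[g.id] = direction
                break
    baseline = {g.id: float(b) for g, b in
                zip(genes, rng.normal(7.0, 1.0, size=len(genes)))}
    return CnaTruth(genes=genes, regions=regions,
                    gene_region_direction=gene_region, baseline=baseline)


def simulate_mirna_truth(config: SimulationConfig) -> MirnaTruth:
    """Name the miRNA universe and plant the deregulated panel (half up)."""
    rng = config.rng(_S_TRUTH, 0)
    ids = [f"hsa-mir-{i + 1:03d}" for i in range(config.n_mirnas)]
    chosen = sorted(rng.permutation(config.n_mirnas)[:config.n_deregulated_mirnas])
    deregulated = {ids[m]: (1 if j < (config.n_deregulated_mirnas + 1) // 2 else -1)
                   for j, m in enumerate(chosen)}
    baseline = {mid: float(b) for mid, b in
                zip(ids, rng.normal(5.0, 1.0, size=len(ids)))}
    return MirnaTruth(mirna_ids=ids, deregulated=deregulated, baseline=baseline)


def _plant_regulation(config: SimulationConfig, cna: CnaTruth,
                      mirna: MirnaTruth) -> tuple[SyntheticTruth, dict]:
    """Choose paradox genes, regulator edges and per-edge repression betas.

    Returns the truth plus a dict gene -> list of (miRNA, beta) covering
    every gene with any miRNA effect (paradox regulators and decoy targets
    of the deregulated miRNAs).
    """
    rng = config.rng(_S_TRUTH, 1)
    up_mirs = sorted(m for m, d in mirna.deregulated.items() if d == 1)
    down_mirs = sorted(m for m, d in mirna.deregulated.items() if d == -1)

    region_genes = sorted(cna.gene_region_direction)
    # a paradox gene in a gain needs an up miRNA (repressor), and vice versa
    eligible = [g for g in region_genes
                if (up_mirs if cna.gene_region_direction[g] == 1 else down_mirs)]
    if config.n_paradox_genes > len(eligible):
        raise ConfigurationError(
            f"cannot plant {config.n_paradox_genes} paradox genes: only "
            f"{len(eligible)} region genes have a matching deregulated miRNA")
    gain_pool = [g for g in eligible if cna.gene_region_direction[g] == 1]
    loss_pool = [g for g in eligible if cna.gene_region_direction[g] == -1]
    n_gain = min(len(gain_pool), config.n_paradox_genes - min(
        len(loss_pool), config.n_paradox_genes // 2))
    paradox = (list(rng.choice(gain_pool, size=n_gain, replace=False))
               if n_gain else [])
    paradox += list(rng.choice(loss_pool, size=config.n_paradox_genes - n_gain,
                               replace=False)) if config.n_paradox_genes - n_gain else []
    paradox = sorted(map(str, paradox))

    f = config.aberration_frequency
    kappa = config.compensation
    target_shift = config.paradox_shift_sds * config.noise_sd
    effects: dict[str, list[tuple[str, float]]] = {}
    edges: set[tuple[str, str]] = set()
    de_direction: dict[str, int] = {}

    for g in paradox:
        rdir = cna.gene_region_direction[g]
        pool = up_mirs if rdir == 1 else down_mirs
        k = int(rng.integers(1, min(2, len(pool)) + 1))
        regs = sorted(rng.choice(pool, size=k, replace=False))
        beta = ((config.dosage_effect * f + target_shift)
                / (k * config.mirna_shift * (1.0 + kappa * f)))
        effects[g] = [(m, beta) for m in regs]
        edges.update((m, g) for m in regs)
        de_direction[g] = -rdir

    # decoy targets of the deregulated miRNAs, outside aberrant regions
    free = [g.id for g in cna.genes
            if g.id not in cna.gene_region_direction and g.id not in effects]
    free = list(rng.permutation(free))
    for m in sorted(mirna.deregulated):
        take, free = free[:config.decoy_targets_per_mirna], \
            free[config.decoy_targets_per_mirna:]
        for g in take:
            effects[g] = [(m, config.mirna_repression)]
            de_direction[g] = -mirna.deregulated[m]

    # regular region genes follow their dosage
    for g, rdir in cna.gene_region_direction.items():
        de_direction.setdefault(g, rdir)

    truth = SyntheticTruth(
        paradox_gene_ids=set(paradox),
        gene_region_direction=dict(cna.gene_region_direction),
        de_direction=de_direction,
        deregulated_mirnas=dict(mirna.deregulated),
        regulator_edges=edges,
    )
    return truth, effects


# ---------------------------------------------------------------------------
# CNA datasets
# ---------------------------------------------------------------------------

def _probe_grid(config: SimulationConfig, rng) -> list[GenomicInterval]:
    """One dataset's probe tiling: uniform per-chromosome tiles with
    jittered boundaries, so probe sets differ across datasets."""
    probes = []
    n = config.probes_per_chromosome
    step = config.chrom_length / n
    for c in range(config.n_chromosomes):
        edges = np.arange(n + 1) * step
        jitter = rng.uniform(-0.3, 0.3, size=n - 1) * step
        edges[1:-1] = edges[1:-1] + jitter
        edges = np.round(edges).astype(np.int64)
        for i in range(n):
            if edges[i + 1] > edges[i]:
                probes.append(GenomicInterval(
                    f"chr{c + 1}", int(edges[i]), int(edges[i + 1]),
                    f"p{c}_{i}"))
    return probes


def _call_matrix(config: SimulationConfig, rng, positions_chrom, positions_mid,
                 regions, n_samples: int) -> np.ndarray:
    """Discrete calls for items (probes or genes) located at midpoints.

    Region carriers are drawn per sample per region (whole-region events);
    background aberrations are independent per cell with random sign.
    """
    n_items = len(positions_mid)
    calls = np.zeros((n_items, n_samples), dtype=np.int8)
    for interval, direction in regions:
        inside = np.array([
            (positions_chrom[i] == interval.chrom
             and interval.start <= positions_mid[i] < interval.end)
            for i in range(n_items)])
        if not inside.any():
            continue
        carrier = rng.random(n_samples) < config.aberration_frequency
        calls[np.ix_(inside, carrier)] = direction
    if config.background_rate > 0:
        bg = rng.random((n_items, n_samples)) < config.background_rate
        signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_items, n_samples))
        calls = np.where(bg & (calls == 0), signs, calls)
    return calls


def simulate_cna_datasets(config: SimulationConfig, mode: str = "calls",
                          truth: CnaTruth | None = None
                          ) -> tuple[list[ProbeCallDataset], CnaTruth]:
    """Generate the aCGH cohorts on distinct jittered probe grids."""
    if mode not in ("calls", "ratios"):
        raise ValueError(f"mode must be 'calls' or 'ratios', got {mode!r}")
    if truth is None:
        truth = simulate_genome(config)
    datasets = []
    for d in range(config.n_cna_datasets):
        rng = config.rng(_S_CNA, d)
        probes = _probe_grid(config, rng)
        chroms = [p.chrom for p in probes]
        mids = [(p.start + p.end) // 2 for p in probes]
        calls = _call_matrix(config, rng, chroms, mids, truth.regions,
                             config.samples_per_dataset)
        sample_ids = [f"cna{d}_s{j}" for j in range(config.samples_per_dataset)]
        if mode == "calls":
            datasets.append(ProbeCallDataset(probes=probes, sample_ids=sample_ids,
                                             calls=calls))
        else:
            means = np.vectorize(RATIO_CLASS_MEANS.get)(calls.astype(int))
            ratios = means + rng.normal(0.0, config.cna_ratio_sd, size=calls.shape)
            datasets.append(ProbeCallDataset(probes=probes, sample_ids=sample_ids,
                                             log_ratios=ratios))
    return datasets, truth


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def _tumor_expression(config: SimulationConfig, rng, cna: CnaTruth,
                      mirna: MirnaTruth, truth: SyntheticTruth, effects: dict,
                      gene_ids: list[str], n_tumors: int):
    """Draw (gene tumor expr, miRNA tumor expr, gene calls, dmir) blocks."""
    chroms = {g.id: g.chrom for g in cna.genes}
    mids = {g.id: (g.start + g.end) // 2 for g in cna.genes}
    calls = _call_matrix(config, rng,
                         [chroms[g] for g in gene_ids],
                         [mids[g] for g in gene_ids],
                         cna.regions, n_tumors)

    dmir = np.zeros((len(mirna.mirna_ids), n_tumors))
    mexpr = np.zeros_like(dmir)
    for i, m in enumerate(mirna.mirna_ids):
        noise = rng.normal(0.0, config.mirna_sample_sd, size=n_tumors)
        if m in mirna.deregulated:
            dmir[i] = mirna.deregulated[m] * config.mirna_shift + noise
            mexpr[i] = mirna.baseline[m] + dmir[i]
        else:
            mexpr[i] = mirna.baseline[m] + noise

    midx = {m: i for i, m in enumerate(mirna.mirna_ids)}
    gexpr = np.empty((len(gene_ids), n_tumors))
    for i, g in enumerate(gene_ids):
        x = cna.baseline[g] + config.dosage_effect * calls[i].astype(float)
        for m, beta in effects.get(g, ()):
            mult = 1.0
            if g in truth.paradox_gene_ids:
                ab = calls[i] == truth.gene_region_direction[g]
                mult = 1.0 + config.compensation * ab
            x = x - beta * dmir[midx[m]] * mult
        gexpr[i] = x + rng.normal(0.0, config.noise_sd, size=n_tumors)
    return gexpr, mexpr, calls


def simulate_expression(config: SimulationConfig,
                        cna_truth: CnaTruth | None = None,
                        mirna_truth: MirnaTruth | None = None):
    """Generate the tumor/normal expression cohorts (genes and miRNAs).

    Returns (gene cohorts, miRNA cohorts, SyntheticTruth).  Each cohort
    drops a random ``gene_dropout`` fraction of genes to exercise
    missing-feature handling downstream.
    """
    if cna_truth is None:
        cna_truth = simulate_genome(config)
    if mirna_truth is None:
        mirna_truth = simulate_mirna_truth(config)
    if not set(cna_truth.baseline) == {g.id for g in cna_truth.genes}:
        raise ValueError("inconsistent gene universe in CNA truth")
    truth, effects = _plant_regulation(config, cna_truth, mirna_truth)

    gene_cohorts, mirna_cohorts = [], []
    for d in range(config.n_expr_datasets):
        rng = config.rng(_S_EXPR, d)
        all_ids = [g.id for g in cna_truth.genes]
        n_drop = int(round(config.gene_dropout * len(all_ids)))
        dropped = set(rng.permutation(all_ids)[:n_drop]) if n_drop else set()
        gene_ids = [g for g in all_ids if g not in dropped]

        nt, nn = config.samples_per_dataset, config.normals_per_dataset
        gexpr, mexpr, _ = _tumor_expression(
            config, rng, cna_truth, mirna_truth, truth, effects, gene_ids, nt)
        gnorm = (np.array([cna_truth.baseline[g] for g in gene_ids])[:, None]
                 + rng.normal(0.0, config.noise_sd, size=(len(gene_ids), nn)))
        mnorm = (np.array([mirna_truth.baseline[m] for m in mirna_truth.mirna_ids])[:, None]
                 + rng.normal(0.0, config.mirna_sample_sd,
                              size=(len(mirna_truth.mirna_ids), nn)))

        tum = [f"e{d}_t{j}" for j in range(nt)]
        nor = [f"e{d}_n{j}" for j in range(nn)]
        classes = {**{s: "tumor" for s in tum}, **{s: "normal" for s in nor}}
        gene_cohorts.append(ExpressionMatrix(
            values=pd.DataFrame(np.hstack([gexpr, gnorm]), index=gene_ids,
                                columns=tum + nor),
            sample_class=classes))
        mirna_cohorts.append(ExpressionMatrix(
            values=pd.DataFrame(np.hstack([mexpr, mnorm]),
                                index=mirna_truth.mirna_ids, columns=tum + nor),
            sample_class=classes))
    return gene_cohorts, mirna_cohorts, truth


def simulate_matched_cohort(config: SimulationConfig,
                            cna_truth: CnaTruth | None = None,
                            mirna_truth: MirnaTruth | None = None
                            ) -> tuple[MatchedCohort, SyntheticTruth]:
    """Generate the matched validation cohort (TCGA-like).

    Gene expression, per-gene log2 copy number and miRNA expression share
    the same tumor samples, with class-mean log2 ratios around the discrete
    calls.
    """
    if cna_truth is None:
        cna_truth = simulate_genome(config)
    if mirna_truth is None:
        mirna_truth = simulate_mirna_truth(config)
    truth, effects = _plant_regulation(config, cna_truth, mirna_truth)
    rng = config.rng(_S_MATCHED)
    gene_ids = [g.id for g in cna_truth.genes]
    nt, nn = config.matched_tumors, config.matched_normals

    gexpr, mexpr, calls = _tumor_expression(
        config, rng, cna_truth, mirna_truth, truth, effects, gene_ids, nt)
    means = np.vectorize(RATIO_CLASS_MEANS.get)(calls.astype(int))
    log2cna = means + rng.normal(0.0, config.cna_ratio_sd, size=calls.shape)

    gnorm = (np.array([cna_truth.baseline[g] for g in gene_ids])[:, None]
             + rng.normal(0.0, config.noise_sd, size=(len(gene_ids), nn)))
    mnorm = (np.array([mirna_truth.baseline[m] for m in mirna_truth.mirna_ids])[:, None]
             + rng.normal(0.0, config.mirna_sample_sd,
                          size=(len(mirna_truth.mirna_ids), nn)))

    tum = [f"v_t{j}" for j in range(nt)]
    nor = [f"v_n{j}" for j in range(nn)]
    classes = {**{s: "tumor" for s in tum}, **{s: "normal" for s in nor}}
    cohort = MatchedCohort(
        gene_expr=ExpressionMatrix(
            values=pd.DataFrame(np.hstack([gexpr, gnorm]), index=gene_ids,
                                columns=tum + nor),
            sample_class=classes),
        mirna_expr=ExpressionMatrix(
            values=pd.DataFrame(np.hstack([mexpr, mnorm]),
                                index=mirna_truth.mirna_ids, columns=tum + nor),
            sample_class=classes),
        gene_cna=pd.DataFrame(log2cna, index=gene_ids, columns=tum),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# miRNA study rankings and target network
# ---------------------------------------------------------------------------

def simulate_mirna_study_rankings(config: SimulationConfig,
                                  mirna_truth: MirnaTruth | None = None,
                                  ) -> list[tuple[RankedList, RankedList]]:
    """Noisy truncated per-study rankings of the deregulated miRNAs.

    Each study reports every truly deregulated miRNA with probability
    ``detection_rate`` (in randomized order, i.e. good but noisy ranks)
    padded with a random number of false positives; list lengths vary.
    """
    if mirna_truth is None:
        mirna_truth = simulate_mirna_truth(config)
    studies = []
    others = sorted(set(mirna_truth.mirna_ids) - set(mirna_truth.deregulated))
    for s in range(config.n_mirna_studies):
        rng = config.rng(_S_LISTS, s)
        lists: dict[str, list[str]] = {"up": [], "down": []}
        true_mirs = sorted(mirna_truth.deregulated)
        detected = [m for m in true_mirs if rng.random() < config.detection_rate]
        for m in rng.permutation(detected):
            lists["up" if mirna_truth.deregulated[m] == 1 else "down"].append(str(m))
        n_fp = int(rng.integers(0, 5)) if others else 0
        for m in rng.choice(others, size=min(n_fp, len(others)), replace=False):
            lists[("up", "down")[int(rng.integers(0, 2))]].append(str(m))
        studies.append((
            RankedList("up", lists["up"], config.n_mirnas),
            RankedList("down", lists["down"], config.n_mirnas)))
    return studies


def simulate_target_network(config: SimulationConfig,
                            cna_truth: CnaTruth | None = None,
                            mirna_truth: MirnaTruth | None = None):
    """The miRNA->gene target table: planted edges plus random bystanders.

    Returns (edges, scores, sources) where edges include every planted
    regulator/decoy edge and random edges from non-deregulated miRNAs, with
    confidence scores passing the default load-time filter.
    """
    if cna_truth is None:
        cna_truth = simulate_genome(config)
    if mirna_truth is None:
        mirna_truth = simulate_mirna_truth(config)
    truth, effects = _plant_regulation(config, cna_truth, mirna_truth)
    rng = config.rng(_S_NETWORK)
    edges = {(m, g) for g, pairs in effects.items() for m, _ in pairs}
    others = sorted(set(mirna_truth.mirna_ids) - set(mirna_truth.deregulated))
    gene_ids = [g.id for g in cna_truth.genes]
    for m in others:
        targets = rng.choice(gene_ids, size=config.decoy_targets_per_mirna,
                             replace=False)
        edges.update((str(m), str(g)) for g in targets)
    edges = sorted(edges)
    scores = rng.uniform(0.5, 1.0, size=len(edges))
    sources = rng.integers(2, 6, size=len(edges))
    return edges, list(scores), list(sources)
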