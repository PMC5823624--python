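"""Paradoxical-gene classification and sample-wise validation.

A "paradoxical" gene is one whose consensus differential-expression
direction (tumor vs normal) is opposite to the consensus copy-number
direction of the chromosomal region it resides in — e.g. a consistently
downregulated gene inside a recurrent gain.  The stages:

1. :func:`assign_genes_to_regions` — overlap deregulated genes with the
   aberrant regions from the CNA stage.
2. :func:`association_chi_square` — 2x2 test of up/down deregulation
   against in-gain/in-loss residence.
3. :func:`identify_paradoxical` — flag genes whose DE direction opposes
   their region's direction.
4. :func:`zscore_expression` / :func:`sample_paradox_frequencies` — on a
   matched cohort with per-sample expression and copy number, count the
   samples where deregulation (|z| beyond 1.647 on the gene's DE side)
   co-occurs with a copy-number change beyond |log2| 0.2, on the opposite
   (paradoxical) or same (regular) side.
5. :func:`validate_gene_randomization` — permutation test of the
   paradoxical-minus-regular frequency excess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna_integration import AberrantRegion
from .formats_io import ExpressionMatrix, GenomicInterval

__all__ = [
    "AnalysisThresholds",
    "ParadoxRecord",
    "assign_genes_to_regions",
    "association_chi_square",
    "identify_paradoxical",
    "zscore_expression",
    "sample_paradox_frequencies",
    "validate_gene_randomization",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisThresholds:
    """Cutoffs for the sample-wise validation.

    ``z_cut`` follows the source convention of 1.647 (not the textbook
    1.645); ``cna_cut`` is on the log2 copy-ratio scale.
    """

    z_cut: float = 1.647
    cna_cut: float = 0.2
    validation_alpha: float = 1e-4
    gene_alpha: float = 0.01

    def __post_init__(self):
        if self.z_cut <= 0 or self.cna_cut <= 0:
            raise ValueError("cutoffs must be positive")
        for a in (self.validation_alpha, self.gene_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alphas must lie in (0, 1)")


@dataclass
class ParadoxRecord:
    """One deregulated gene residing in an aberrant region."""

    gene: str
    de_direction: int             # +1 up, -1 down
    region_direction: int         # +1 gain, -1 loss
    is_paradoxical: bool = False
    freq_paradoxical: float = float("nan")
    freq_regular: float = float("nan")
    freq_up: float = float("nan")
    freq_down: float = float("nan")
    freq_gain: float = float("nan")
    freq_loss: float = float("nan")
    n_informative: int = 0
    validation_p: float = float("nan")
    validated: bool = False

    def __post_init__(self):
        if self.de_direction not in (-1, 1) or self.region_direction not in (-1, 1):
            raise ValueError("directions must be +/-1")
        self.is_paradoxical = self.de_direction * self.region_direction == -1


def assign_genes_to_regions(genes: list[GenomicInterval],
                            regions: list[AberrantRegion]) -> dict[str, int]:
    """Map each gene to the direction of the aberrant region it overlaps.

    Overlap of >= 1 base counts.  A gene overlapping regions of both
    directions maps to the side with the larger total overlap; exact ties
    are dropped (logged).  Genes overlapping no region are absent from the
    result.
    """
    out: dict[str, int] = {}
    for gene in genes:
        gain_bp = loss_bp = 0
        for region in regions:
            ov = gene.overlap(region.interval)
            if ov > 0:
                if region.direction == 1:
                    gain_bp += ov
                else:
                    loss_bp += ov
        if gain_bp == 0 and loss_bp == 0:
            continue
        if gain_bp > loss_bp:
            out[gene.id] = 1
        elif loss_bp > gain_bp:
            out[gene.id] = -1
        else:
            log.warning("gene %s: equal overlap with gain and loss regions, dropped",
                        gene.id)
    return out


def association_chi_square(de_table: dict[str, int],
                           region_map: dict[str, int]):
    """Chi-square association between DE direction and region direction.

    Builds the 2x2 table (rows up/down, columns in-gain/in-loss) over
    deregulated genes residing in aberrant regions; Pearson chi-square with
    1 df, no continuity correction.  Returns (chi2, p, table) with the
    table as a 2x2 ndarray [[up-gain, up-loss], [down-gain, down-loss]].
    """
    table = np.zeros((2, 2), dtype=int)
    for gene, de in de_table.items():
        region = region_map.get(gene)
        if region is None:
            continue
        table[0 if de == 1 else 1, 0 if region == 1 else 1] += 1
    if table.sum() == 0:
        raise ValueError("no deregulated gene resides in an aberrant region")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "zero marginal in the 2x2 table; use an exact test instead")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table


def identify_paradoxical(de_table: dict[str, int],
                         region_map: dict[str, int]) -> list[ParadoxRecord]:
    """One record per deregulated gene in an aberrant region."""
    out = []
    for gene in sorted(de_table):
        region = region_map.get(gene)
        if region is None:
            continue
        out.append(ParadoxRecord(gene=gene, de_direction=de_table[gene],
                                 region_direction=region))
    return out


def zscore_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Standardize tumor expression against the normal-sample distribution.

    z[g, s] = (x[g, s] - mean_normals(g)) / sd_normals(g), sample sd with
    ddof=1.  Genes with zero normal sd get NaN (logged).
    """
    normals = matrix.normals()
    if normals.shape[1] < 2:
        raise ValueError("need >= 2 normal samples for the reference distribution")
    mu = normals.mean(axis=1)
    sd = normals.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d genes with constant normals: z set to missing",
                    int(degenerate.sum()))
    sd = sd.replace(0.0, np.nan)
    return matrix.tumors().sub(mu, axis=0).div(sd, axis=0)


def _event_counts(z: np.ndarray, cna: np.ndarray, de: int, region: int,
                  th: AnalysisThresholds):
    """Per-sample event indicators for one gene over its informative samples."""
    ok = np.isfinite(z) & np.isfinite(cna)
    z, cna = z[ok], cna[ok]
    dereg = z * de > th.z_cut                     # deregulated on the DE side
    gainish = cna * region > th.cna_cut           # CNA on the region side
    lossish = cna * region < -th.cna_cut          # CNA on the DE side
    paradox = dereg & gainish
    regular = dereg & lossish
    return z, cna, dereg, paradox, regular, int(ok.sum())


def sample_paradox_frequencies(z_row, cna_row, record: ParadoxRecord,
                               th: AnalysisThresholds = AnalysisThresholds()) -> ParadoxRecord:
    """Fill a record's per-sample co-occurrence frequencies.

    Over samples with both z and CNA present: a *paradoxical* event is
    deregulation on the gene's DE side together with a copy-number change
    beyond the cutoff on the opposite (region) side; a *regular* event has
    the copy-number change on the DE side.  Marginal up/down/gain/loss
    frequencies are reported alongside.
    """
    z = np.asarray(z_row, dtype=float)
    cna = np.asarray(cna_row, dtype=float)
    if z.shape != cna.shape:
        raise ValueError("z and cna vectors must be sample-matched")
    zi, ci, dereg, paradox, regular, n = _event_counts(
        z, cna, record.de_direction, record.region_direction, th)
    if n == 0:
        log.warning("gene %s: no informative samples", record.gene)
        return record
    record.n_informative = n
    record.freq_paradoxical = paradox.sum() / n
    record.freq_regular = regular.sum() / n
    record.freq_up = (zi > th.z_cut).sum() / n
    record.freq_down = (zi < -th.z_cut).sum() / n
    record.freq_gain = (ci > th.cna_cut).sum() / n
    record.freq_loss = (ci < -th.cna_cut).sum() / n
    return record


def validate_gene_randomization(z_row, cna_row, record: ParadoxRecord,
                                n_rand: int = 100_000,
                                seed: int | np.random.SeedSequence = 0,
                                th: AnalysisThresholds = AnalysisThresholds()) -> ParadoxRecord:
    """Randomization test of the paradoxical co-occurrence excess.

    Statistic T = freq_paradoxical - freq_regular.  Null: the gene's CNA
    vector is permuted against its z vector.  Because T depends on the
    permuted labels only through how many deregulated samples receive a
    region-side (and DE-side) copy-number change, the null is sampled
    exactly from the corresponding multivariate hypergeometric law rather
    than by materialising shuffles.  p = (#T_perm >= T_obs + 1)/(n_rand+1);
    validated requires p < validation_alpha and a positive excess.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    z = np.asarray(z_row, dtype=float)
    cna = np.asarray(cna_row, dtype=float)
    _, _, dereg, paradox, regular, n = _event_counts(
        z, cna, record.de_direction, record.region_direction, th)
    if n == 0:
        record.validation_p = float("nan")
        record.validated = False
        return record

    n_dereg = int(dereg.sum())
    ok = np.isfinite(z) & np.isfinite(cna)
    side = cna[ok] * record.region_direction
    n_gainish = int((side > th.cna_cut).sum())     # CNA on the region side
    n_lossish = int((side < -th.cna_cut).sum())    # CNA on the DE side
    t_obs = int(paradox.sum()) - int(regular.sum())

    rng = np.random.default_rng(seed)
    if n_dereg == 0:
        g_d = l_d = np.zeros(n_rand, dtype=np.int64)
    else:
        g_d = (rng.hypergeometric(n_gainish, n - n_gainish, n_dereg, size=n_rand)
               if n_gainish > 0 else np.zeros(n_rand, dtype=np.int64))
        # losses among the deregulated, given how many region-side labels they took
        remaining = n_dereg - g_d
        if n_lossish > 0:
            l_d = np.where(remaining > 0,
                           rng.hypergeometric(n_lossish, n - n_gainish - n_lossish,
                                              np.maximum(remaining, 1)), 0)
        else:
            l_d = np.zeros(n_rand, dtype=np.int64)
    t_perm = g_d - l_d

    record.validation_p = float(((t_perm >= t_obs).sum() + 1.0) / (n_rand + 1.0))
    record.validated = bool(
        record.validation_p < th.validation_alpha
        and record.freq_paradoxical > record.freq_regular)
    return record
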