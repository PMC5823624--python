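"""miRNA : paradoxical-gene association analysis.

Tests whether consistently deregulated miRNAs can account for paradoxical
gene expression:

* :func:`target_overlap_test` — hypergeometric enrichment of miRNA targets
  among the paradoxical genes (strict upper tail, P(X > observed)).
* :func:`partial_correlation` — first-order Pearson partial correlation of
  miRNA and gene expression, controlling for the gene's copy number (the
  dosage confounder).
* :func:`empirical_pair_test` — empirical two-sided significance against
  the same measure over random miRNA:gene pairs.
* :func:`classify_explanatory` — a significant pair is *explanatory* when
  the correlation sign matches the deregulation directions (positive for
  same-direction pairs, negative for opposite).
* :func:`multiple_correlation` — per-gene coefficient of multiple
  correlation C = sqrt(c' R^-1 c) with the full deregulated-miRNA panel,
  i.e. the correlation between the gene and its best linear prediction from
  the miRNAs.
* :func:`cmc_percentile` — placement of each paradoxical gene's C in the
  background distribution over all genes, plus top-5% enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetNetwork",
    "PairAssociation",
    "GeneCmc",
    "target_overlap_test",
    "partial_correlation",
    "empirical_pair_test",
    "sample_null_partials",
    "classify_explanatory",
    "test_pairs",
    "multiple_correlation",
    "gene_cmc_profile",
    "cmc_percentile",
]


@dataclass
class TargetNetwork:
    """miRNA -> gene edges restricted to a declared gene universe."""

    edges: set[tuple[str, str]]
    population_genes: int
    targeted_genes: int = field(init=False)

    def __post_init__(self):
        self.targeted_genes = len({g for _, g in self.edges})
        if self.targeted_genes > self.population_genes:
            raise ValueError("more targeted genes than population genes")

    def targets_of(self, mirnas) -> set[str]:
        mirnas = set(mirnas)
        return {g for m, g in self.edges if m in mirnas}


@dataclass
class PairAssociation:
    """One miRNA:gene pair's CNA-controlled association."""

    mirna: str
    gene: str
    r_partial: float
    empirical_p: float = float("nan")
    significant: bool = False
    explanatory: bool = False

    def __post_init__(self):
        if np.isfinite(self.r_partial) and abs(self.r_partial) > 1 + 1e-12:
            raise ValueError(f"|r_partial| > 1: {self.r_partial}")


@dataclass
class GeneCmc:
    """Per-gene multiple correlation with the deregulated miRNA panel."""

    gene: str
    C: float
    percentile: float = float("nan")


def hypergeom_strict_upper(overlap: int, population: int, successes: int,
                           draws: int) -> float:
    """P(X > overlap) for X ~ Hypergeometric(population, successes, draws)."""
    if successes > population or draws > population or overlap > draws:
        raise ValueError(
            f"inconsistent hypergeometric parameters: N={population}, "
            f"K={successes}, n={draws}, k={overlap}")
    return float(stats.hypergeom.sf(overlap, population, successes, draws))


def target_overlap_test(paradox_genes: set[str],
                        network: TargetNetwork,
                        targeted: set[str] | None = None) -> tuple[int, float]:
    """Enrichment of miRNA-targeted genes among the paradoxical genes.

    Population N = network.population_genes, successes K = targeted genes,
    draws n = |paradox set|; returns (overlap, strict upper-tail p).
    """
    if targeted is None:
        targeted = {g for _, g in network.edges}
    overlap = len(paradox_genes & targeted)
    p = hypergeom_strict_upper(overlap, network.population_genes,
                               network.targeted_genes, len(paradox_genes))
    return overlap, p


def partial_correlation(x, y, z) -> float:
    """First-order Pearson partial correlation r_xy.z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    Returns NaN when a controlling correlation is +/-1 (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need >= 4 observations")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
    if denom <= 0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def sample_null_partials(gene_expr: pd.DataFrame, mirna_expr: pd.DataFrame,
                         gene_cna: pd.DataFrame, n_null: int,
                         seed: int | np.random.SeedSequence = 0,
                         exclude: set[tuple[str, str]] | None = None) -> np.ndarray:
    """Null distribution of r_partial over random (miRNA, gene) pairs.

    Pairs are drawn uniformly with replacement from the full gene x miRNA
    universes (excluding any pair in *exclude*, e.g. the tested pairs); the
    controlling variable is each drawn gene's own copy number.  Matrices
    must share sample columns.
    """
    if gene_expr.shape[0] < 2 or mirna_expr.shape[0] < 2:
        raise ValueError("universes must contain >= 2 features each")
    genes = list(gene_expr.index)
    mirnas = list(mirna_expr.index)
    exclude = exclude or set()
    rng = np.random.default_rng(seed)
    out = np.empty(n_null)
    filled = 0
    while filled < n_null:
        gi = rng.integers(0, len(genes), size=n_null - filled)
        mi = rng.integers(0, len(mirnas), size=n_null - filled)
        for g_idx, m_idx in zip(gi, mi):
            g, m = genes[g_idx], mirnas[m_idx]
            if (m, g) in exclude:
                continue
            try:
                r = partial_correlation(mirna_expr.loc[m].to_numpy(),
                                        gene_expr.loc[g].to_numpy(),
                                        gene_cna.loc[g].to_numpy())
            except ValueError:
                continue
            if np.isfinite(r):
                out[filled] = r
                filled += 1
                if filled == n_null:
                    break
    return out


def empirical_pair_test(r_values: np.ndarray, null_r: np.ndarray,
                        alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided empirical p-values against a null sample of r_partial.

    p = min(1, 2 * min(lower tail, upper tail)) with the add-one
    correction, so a value beyond every null draw gets p = 2/(n_null+1).
    Returns (p, significant-at-alpha).
    """
    null_r = np.sort(np.asarray(null_r, dtype=float))
    n = null_r.size
    if n < 100:
        raise ValueError("null sample too small (need >= 100 draws)")
    r = np.asarray(r_values, dtype=float)
    upper = n - np.searchsorted(null_r, r, side="left")   # null >= r
    lower = np.searchsorted(null_r, r, side="right")      # null <= r
    p = np.minimum(1.0, 2.0 * (np.minimum(lower, upper) + 1.0) / (n + 1.0))
    p = np.where(np.isfinite(r), p, np.nan)
    return p, np.where(np.isfinite(r), p < alpha, False)


def classify_explanatory(mirna_direction: int, gene_direction: int,
                         r_partial: float, significant: bool) -> bool:
    """A pair is explanatory iff significant and sign(r) matches directions.

    Same-direction deregulation requires positive correlation; inverse
    deregulation requires negative correlation (consistent with repression
    through the miRNA).  r exactly 0 is never explanatory.
    """
    if mirna_direction not in (-1, 1) or gene_direction not in (-1, 1):
        raise ValueError("directions must be +/-1")
    if not significant or not np.isfinite(r_partial) or r_partial == 0:
        return False
    return bool(np.sign(r_partial) == mirna_direction * gene_direction)


def test_pairs(mirna_dirs: dict[str, int], gene_dirs: dict[str, int],
               gene_expr: pd.DataFrame, mirna_expr: pd.DataFrame,
               gene_cna: pd.DataFrame, edges: set[tuple[str, str]] | None = None,
               n_null: int = 10_000, alpha: float = 0.05,
               seed: int | np.random.SeedSequence = 0) -> list[PairAssociation]:
    """Full pair analysis for all (deregulated miRNA, paradoxical gene) pairs.

    When *edges* is given, only targeting pairs are tested (the published
    workflow tests target pairs); otherwise the full cross product.
    """
    pairs = [(m, g) for m in sorted(mirna_dirs) for g in sorted(gene_dirs)
             if edges is None or (m, g) in edges]
    r_vals = []
    for m, g in pairs:
        try:
            r = partial_correlation(mirna_expr.loc[m].to_numpy(),
                                    gene_expr.loc[g].to_numpy(),
                                    gene_cna.loc[g].to_numpy())
        except ValueError:
            r = float("nan")
        r_vals.append(r)
    null_r = sample_null_partials(gene_expr, mirna_expr, gene_cna, n_null,
                                  seed=seed, exclude=set(pairs))
    p, sig = empirical_pair_test(np.asarray(r_vals), null_r, alpha=alpha)
    out = []
    for (m, g), r, pv, s in zip(pairs, r_vals, p, sig):
        pa = PairAssociation(mirna=m, gene=g, r_partial=float(r),
                             empirical_p=float(pv), significant=bool(s))
        pa.explanatory = classify_explanatory(mirna_dirs[m], gene_dirs[g],
                                              pa.r_partial, pa.significant)
        out.append(pa)
    return out


def multiple_correlation(c_vector, r_matrix) -> float:
    """Coefficient of multiple correlation C = sqrt(c' R^-1 c).

    *c_vector* holds the gene's Pearson correlations with each miRNA and
    *r_matrix* the miRNA x miRNA correlation matrix.  If R is singular, or
    C^2 falls outside [0, 1] by more than 1e-8, the least-squares
    pseudo-solution is used and the result clipped (with a warning).
    """
    c = np.asarray(c_vector, dtype=float).ravel()
    R = np.asarray(r_matrix, dtype=float)
    if R.shape != (c.size, c.size):
        raise ValueError(f"dimension mismatch: c has {c.size}, R is {R.shape}")
    if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must be symmetric with unit diagonal")
    try:
        c2 = float(c @ np.linalg.solve(R, c))
        ok = True
    except np.linalg.LinAlgError:
        ok = False
        c2 = float("nan")
    if not ok or c2 < -1e-8 or c2 > 1 + 1e-8:
        warnings.warn(
            f"ill-conditioned miRNA correlation matrix (cond={np.linalg.cond(R):.3g}); "
            "using least-squares pseudo-solution and clipping C^2 to [0, 1]")
        c2 = float(c @ np.linalg.lstsq(R, c, rcond=None)[0])
    return float(np.sqrt(np.clip(c2, 0.0, 1.0)))


def gene_cmc_profile(gene_row, mirna_expr: pd.DataFrame) -> float:
    """C between one gene's expression and the full miRNA panel."""
    g = np.asarray(gene_row, dtype=float)
    M = mirna_expr.to_numpy()
    c = np.array([np.corrcoef(g, M[i])[0, 1] for i in range(M.shape[0])])
    R = np.corrcoef(M)
    return multiple_correlation(c, R)


def cmc_percentile(paradox_cmcs: dict[str, float],
                   background_cmcs: np.ndarray,
                   top_fraction: float = 0.05):
    """Placement of paradoxical-gene CMCs in the background distribution.

    percentile = fraction of background strictly below the gene's C.
    Returns (per-gene GeneCmc list, count in the top ``top_fraction``,
    hypergeometric enrichment p of that count: population = background
    size, successes = floor(top_fraction * background size), draws =
    number of paradoxical genes, strict upper tail).
    """
    bg = np.sort(np.asarray(background_cmcs, dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    out = []
    n_top = 0
    for gene in sorted(paradox_cmcs):
        C = paradox_cmcs[gene]
        pct = float(np.searchsorted(bg, C, side="left") / bg.size)
        out.append(GeneCmc(gene=gene, C=C, percentile=pct))
        if pct >= 1.0 - top_fraction:
            n_top += 1
    successes = int(np.floor(top_fraction * bg.size))
    p = hypergeom_strict_upper(n_top, bg.size, successes, len(out)) if out else 1.0
    return out, n_top, p
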