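"""Per-cohort differential ranking and robust rank aggregation.

The same machinery serves the gene meta-analysis (ranked lists computed
from expression matrices with :func:`rank_differential`) and the miRNA
meta-analysis (ranked lists supplied by the source studies).

Robust rank aggregation scores a feature by order statistics of uniforms:
with normalized ranks r(1) <= ... <= r(n) across n lists, the score is

    rho = min_k P(at least k of n independent U(0,1) <= r(k))
        = min_k sum_{j=k..n} C(n,j) r(k)^j (1 - r(k))^(n-j)

and p = min(1, n * rho) (Bonferroni over the n order statistics).  The
leave-one-out correction re-aggregates with each list excluded in turn and
averages the resulting p-values, guarding against single-study dominance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionMatrix, RankedList

__all__ = [
    "AggregationResult",
    "rank_differential",
    "rra_rho",
    "aggregate",
    "loo_correct",
]

log = logging.getLogger(__name__)


@dataclass
class AggregationResult:
    """Consensus direction and significance of one feature across lists."""

    id: str
    direction: str                # "up" or "down"
    rho: float
    p: float
    p_loo: float
    n_lists_used: int
    significant: bool = False

    def __post_init__(self):
        for name in ("rho", "p", "p_loo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_lists_used < 1:
            raise ValueError("n_lists_used must be >= 1")


def rank_differential(matrix: ExpressionMatrix) -> tuple[RankedList, RankedList]:
    """Rank a cohort's features by tumor-vs-normal differential expression.

    Welch's two-sample t statistic per feature, Benjamini-Hochberg adjusted;
    features split by the sign of the tumor-normal mean difference
    (non-positive differences go to the "down" list) and ranked by adjusted
    p ascending, ties broken by |mean difference| descending then id.
    """
    tumors = matrix.tumors().to_numpy()
    normals = matrix.normals().to_numpy()
    if tumors.shape[1] < 2 or normals.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples per class, got {tumors.shape[1]} tumors / "
            f"{normals.shape[1]} normals")

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumors, normals, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)   # zero-variance features: no evidence
    p_adj = multipletests(p, method="fdr_bh")[1]
    diff = tumors.mean(axis=1) - normals.mean(axis=1)

    ids = np.asarray(matrix.feature_ids)
    order = np.lexsort((ids, -np.abs(diff), p_adj))
    universe = len(ids)
    up_ids = [str(ids[i]) for i in order if diff[i] > 0]
    down_ids = [str(ids[i]) for i in order if diff[i] <= 0]
    measured = frozenset(map(str, ids))
    return (RankedList("up", up_ids, universe, measured),
            RankedList("down", down_ids, universe, measured))


def rra_rho(normalized_ranks, n_lists: int | None = None) -> tuple[float, float]:
    """Robust-rank-aggregation score for one feature.

    ``normalized_ranks`` are the feature's ranks divided by each list's
    universe size, one entry per list where the feature is measured; each
    must lie in (0, 1].  Returns (rho, p) with p = min(1, n * rho).
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    n = int(n_lists) if n_lists is not None else r.size
    if n < r.size:
        raise ValueError("n_lists smaller than the number of ranks")
    k = np.arange(1, r.size + 1)
    beta = stats.binom.sf(k - 1, n, r)     # P(at least k of n uniforms <= r(k))
    rho = float(beta.min())
    return rho, float(min(1.0, n * rho))


def _rank_matrix(lists: list[RankedList], features: list[str],
                 universe_override: int | None = None) -> np.ndarray:
    """Features x lists matrix of normalized ranks; NaN where unmeasured.

    Listed features get position / universe_size; measured-but-unlisted get
    1 (worst); unmeasured get NaN and do not count toward n_lists.
    """
    fidx = {f: i for i, f in enumerate(features)}
    mat = np.full((len(features), len(lists)), np.nan)
    for j, lst in enumerate(lists):
        universe = universe_override if universe_override is not None else lst.universe_size
        if lst.measured_ids is None:
            mat[:, j] = 1.0                 # whole universe assumed measured
        else:
            for f in lst.measured_ids:
                if f in fidx:
                    mat[fidx[f], j] = 1.0
        for pos, f in enumerate(lst.ids, start=1):
            if f in fidx:
                mat[fidx[f], j] = min(1.0, pos / universe)
    return mat


def _aggregate_matrix(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised rho/p over a features x lists normalized-rank matrix."""
    n_feat, n_lists = mat.shape
    n_used = (~np.isnan(mat)).sum(axis=1)
    r = np.sort(np.where(np.isnan(mat), np.inf, mat), axis=1)
    k = np.arange(1, n_lists + 1)[None, :]
    with np.errstate(invalid="ignore"):
        beta = stats.binom.sf(k - 1, n_used[:, None],
                              np.where(np.isfinite(r), r, 1.0))
    beta = np.where(k <= n_used[:, None], beta, np.inf)
    rho = np.where(n_used > 0, beta.min(axis=1), np.nan)
    p = np.minimum(1.0, n_used * rho)
    return rho, p, n_used


def loo_correct(mat: np.ndarray) -> np.ndarray:
    """Leave-one-out corrected p per feature for a normalized-rank matrix.

    Re-aggregates with each of the N lists excluded and averages the N
    p-values; rounds where a feature has no measured list contribute p = 1.
    """
    n_feat, n_lists = mat.shape
    if n_lists < 2:
        raise ValueError("leave-one-out needs >= 2 lists")
    acc = np.zeros(n_feat)
    for j in range(n_lists):
        sub = np.delete(mat, j, axis=1)
        _, p, n_used = _aggregate_matrix(sub)
        acc += np.where(n_used > 0, p, 1.0)
    return acc / n_lists


def aggregate(list_pairs: list[tuple[RankedList, RankedList]],
              alpha: float = 0.05,
              universe: str = "per-list") -> list[AggregationResult]:
    """Aggregate per-study (up, down) ranked-list pairs across studies.

    ``universe="per-list"`` normalizes each list's ranks by its own
    universe size (expression cohorts, where the measured feature set is
    known); ``universe="union"`` uses the union of all studies' reported
    features (published miRNA lists, where per-study platforms are unknown).

    Per direction, features measured but unlisted in a study receive the
    worst normalized rank (1); unmeasured features contribute no entry.  A
    feature significant in both directions keeps the direction with the
    smaller leave-one-out p; exact ties are excluded and logged.
    """
    if len(list_pairs) < 2:
        raise ValueError("need >= 2 list pairs to aggregate")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    ups = [p[0] for p in list_pairs]
    downs = [p[1] for p in list_pairs]

    feats: set[str] = set()
    for lst in ups + downs:
        feats.update(lst.ids)
        if lst.measured_ids is not None:
            feats.update(lst.measured_ids)
    if not feats:
        raise ValueError("empty feature universe")
    features = sorted(feats)

    override = len(features) if universe == "union" else None
    per_dir: dict[str, tuple] = {}
    for direction, lists in (("up", ups), ("down", downs)):
        mat = _rank_matrix(lists, features, universe_override=override)
        rho, p, n_used = _aggregate_matrix(mat)
        p_loo = loo_correct(mat)
        per_dir[direction] = (rho, p, p_loo, n_used)

    out: list[AggregationResult] = []
    for i, f in enumerate(features):
        rho_u, p_u, ploo_u, n_u = (per_dir["up"][j][i] for j in range(4))
        rho_d, p_d, ploo_d, n_d = (per_dir["down"][j][i] for j in range(4))
        if n_u == 0 and n_d == 0:
            continue                      # unmeasured everywhere
        if n_d == 0 or (n_u > 0 and ploo_u < ploo_d):
            direction, rho, p, p_loo, n = "up", rho_u, p_u, ploo_u, n_u
        elif n_u == 0 or ploo_d < ploo_u:
            direction, rho, p, p_loo, n = "down", rho_d, p_d, ploo_d, n_d
        else:                             # exact tie
            if ploo_u < alpha:
                log.warning("feature %s: direction tie at p_loo=%g, excluded", f, ploo_u)
                continue
            direction, rho, p, p_loo, n = "up", rho_u, p_u, ploo_u, n_u
        out.append(AggregationResult(
            id=f, direction=direction, rho=float(rho), p=float(p),
            p_loo=float(p_loo), n_lists_used=int(n),
            significant=bool(p_loo < alpha)))
    out.sort(key=lambda r: (r.p_loo, r.id))
    return out
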