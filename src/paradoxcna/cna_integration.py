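"""Copy-number aberration integration across heterogeneous probe sets.

The stages, in pipeline order:

1. :func:`call_from_log_ratios` — threshold the continuous log2 ratios into
   discrete calls (loss -1 / neutral 0 / gain +1).  Pre-called input is the
   first-class path; the threshold caller serves data that arrives as ratios.
2. :func:`build_anchor_table` — place every dataset on a common grid of
   "anchors", the sorted union of all probe start/end positions, so cohorts
   profiled on different arrays become directly comparable.
3. :func:`anchor_frequency_test` — per-anchor permutation p-values for the
   pooled gain and loss counts, under a null that shuffles each sample's
   calls across its informative anchors (preserving per-sample aberration
   burden, the dominant confounder).
4. :func:`merge_significant_anchors` — merge runs of same-direction
   significant anchors into aberrant regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import MISSING_CALL, GenomicInterval

__all__ = [
    "ProbeCallDataset",
    "AnchorTable",
    "AberrantRegion",
    "call_from_log_ratios",
    "build_anchor_table",
    "anchor_frequency_test",
    "merge_significant_anchors",
]


@dataclass
class ProbeCallDataset:
    """One cohort's CNA data: probe intervals x samples.

    Either ``calls`` (int8, values in {-1, 0, +1} with ``MISSING_CALL`` for
    missing) or ``log_ratios`` (float with NaN for missing) is present,
    depending on the input mode.
    """

    probes: list[GenomicInterval]
    sample_ids: list[str]
    calls: np.ndarray | None = None
    log_ratios: np.ndarray | None = None

    def __post_init__(self):
        mat = self.calls if self.calls is not None else self.log_ratios
        if mat is None:
            raise ValueError("one of calls/log_ratios must be provided")
        if mat.shape != (len(self.probes), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.probes)} probes x {len(self.sample_ids)} samples")
        if self.calls is not None:
            ok = np.isin(self.calls, [-1, 0, 1, MISSING_CALL])
            if not ok.all():
                bad = np.unique(self.calls[~ok])
                raise ValueError(f"calls contain invalid symbols {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_calls_from_ratios(self, loss_cut: float = -0.2,
                               gain_cut: float = 0.2) -> "ProbeCallDataset":
        """Return a called copy of a ratios-mode dataset."""
        if self.log_ratios is None:
            return self
        return ProbeCallDataset(
            probes=self.probes, sample_ids=self.sample_ids,
            calls=call_from_log_ratios(self.log_ratios, loss_cut, gain_cut))


@dataclass
class AnchorTable:
    """Genome-wide anchors with pooled per-anchor call statistics.

    ``calls`` is an anchors x pooled-samples int8 matrix (missing =
    ``MISSING_CALL``); ``sample_dataset`` records which input dataset each
    pooled sample column came from.
    """

    chroms: np.ndarray            # anchor chromosome, object array
    positions: np.ndarray         # anchor position, int
    calls: np.ndarray             # anchors x samples, int8
    sample_ids: list[str]
    sample_dataset: np.ndarray    # dataset index per sample column
    gain_count: np.ndarray = field(default=None)
    loss_count: np.ndarray = field(default=None)
    n_informative: np.ndarray = field(default=None)
    p_gain: np.ndarray | None = None
    p_loss: np.ndarray | None = None

    def __post_init__(self):
        if self.gain_count is None:
            informative = self.calls != MISSING_CALL
            self.gain_count = (self.calls == 1).sum(axis=1)
            self.loss_count = (self.calls == -1).sum(axis=1)
            self.n_informative = informative.sum(axis=1)

    @property
    def n_anchors(self) -> int:
        return len(self.positions)

    @property
    def gain_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_informative > 0,
                            self.gain_count / np.maximum(self.n_informative, 1), 0.0)

    @property
    def loss_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_informative > 0,
                            self.loss_count / np.maximum(self.n_informative, 1), 0.0)


@dataclass(frozen=True)
class AberrantRegion:
    """A merged run of significant same-direction anchors."""

    interval: GenomicInterval
    direction: int                # +1 gain, -1 loss
    peak_frequency: float
    peak_p: float

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +/-1, got {self.direction}")
        if not (0.0 <= self.peak_frequency <= 1.0):
            raise ValueError("peak frequency outside [0, 1]")


def call_from_log_ratios(values: np.ndarray, loss_cut: float = -0.2,
                         gain_cut: float = 0.2) -> np.ndarray:
    """Discretize log2 ratios into calls with strict-inequality cutoffs.

    value < loss_cut -> -1, value > gain_cut -> +1, else 0; a value exactly
    at a cutoff is neutral.  NaN stays missing.
    """
    if not (np.isfinite(loss_cut) and np.isfinite(gain_cut)):
        raise ValueError("thresholds must be finite")
    if not loss_cut < 0 < gain_cut:
        raise ValueError(f"need loss_cut < 0 < gain_cut, got {loss_cut}, {gain_cut}")
    values = np.asarray(values, dtype=float)
    calls = np.zeros(values.shape, dtype=np.int8)
    calls[values < loss_cut] = -1
    calls[values > gain_cut] = 1
    calls[~np.isfinite(values)] = MISSING_CALL
    return calls


def _assign_dataset_to_anchors(chrom: str, positions: np.ndarray,
                               ds: ProbeCallDataset) -> np.ndarray:
    """Map each anchor position to a probe row of *ds* (-1 = uncovered).

    Half-open containment: probe [s, e) covers positions s..e-1.  If two
    probes of the dataset cover the same anchor, the smaller-span probe
    wins; ties go to the leftmost start (deterministic, favors resolution).
    """
    idx = [i for i, p in enumerate(ds.probes) if p.chrom == chrom]
    assignment = np.full(len(positions), -1, dtype=np.int64)
    if not idx:
        return assignment
    best_span = np.full(len(positions), np.iinfo(np.int64).max, dtype=np.int64)
    best_start = np.full(len(positions), np.iinfo(np.int64).max, dtype=np.int64)
    for i in idx:
        p = ds.probes[i]
        lo = np.searchsorted(positions, p.start, side="left")
        hi = np.searchsorted(positions, p.end, side="left")  # end excluded
        if lo >= hi:
            continue
        span = p.end - p.start
        sl = slice(lo, hi)
        better = (span < best_span[sl]) | (
            (span == best_span[sl]) & (p.start < best_start[sl]))
        assignment[sl] = np.where(better, i, assignment[sl])
        best_span[sl] = np.where(better, span, best_span[sl])
        best_start[sl] = np.where(better, p.start, best_start[sl])
    return assignment


def build_anchor_table(datasets: list[ProbeCallDataset],
                       max_missing_datasets: int = 1) -> AnchorTable:
    """Integrate heterogeneous probe sets onto a common anchor grid.

    Anchors are the sorted unique starts and ends of all probes, per
    chromosome.  For each anchor and dataset, the covering probe's call
    vector is assigned (half-open containment); uncovered anchors get a
    missing vector.  Anchors with missing vectors from more than
    ``max_missing_datasets`` datasets are dropped.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    called = [ds.with_calls_from_ratios() for ds in datasets]
    chrom_sets = [set(p.chrom for p in ds.probes) for ds in called]
    shared = set.intersection(*chrom_sets) if chrom_sets else set()
    if len(called) > 1 and not shared:
        raise ValueError("datasets share no chromosome: disjoint genomes")

    all_chroms = sorted(set.union(*chrom_sets))
    n_datasets = len(called)
    sample_ids: list[str] = []
    sample_dataset: list[int] = []
    for d, ds in enumerate(called):
        sample_ids.extend(f"d{d}:{s}" for s in ds.sample_ids)
        sample_dataset.extend([d] * ds.n_samples)
    sample_dataset = np.asarray(sample_dataset)

    chrom_out, pos_out, call_rows = [], [], []
    for chrom in all_chroms:
        bounds = sorted({b for ds in called for p in ds.probes
                         if p.chrom == chrom for b in (p.start, p.end)})
        positions = np.asarray(bounds, dtype=np.int64)
        if positions.size == 0:
            continue
        assignments = [_assign_dataset_to_anchors(chrom, positions, ds)
                       for ds in called]
        covered = np.stack([a >= 0 for a in assignments])    # datasets x anchors
        keep = (n_datasets - covered.sum(axis=0)) <= max_missing_datasets
        if not keep.any():
            continue
        block = np.full((int(keep.sum()), len(sample_ids)), MISSING_CALL, dtype=np.int8)
        col = 0
        for d, ds in enumerate(called):
            a = assignments[d][keep]
            hit = a >= 0
            block[hit, col:col + ds.n_samples] = ds.calls[a[hit], :]
            col += ds.n_samples
        chrom_out.extend([chrom] * int(keep.sum()))
        pos_out.append(positions[keep])
        call_rows.append(block)

    if not pos_out:
        raise ValueError("no anchors retained")
    return AnchorTable(
        chroms=np.asarray(chrom_out, dtype=object),
        positions=np.concatenate(pos_out),
        calls=np.vstack(call_rows),
        sample_ids=sample_ids,
        sample_dataset=sample_dataset,
    )


def anchor_frequency_test(table: AnchorTable, n_perm: int = 10_000,
                          seed: int | np.random.SeedSequence = 0) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for pooled per-anchor gain and loss counts.

    Null: each sample's calls are shuffled independently across that
    sample's informative anchors, preserving its aberration burden.  At any
    fixed anchor the shuffled call of sample *s* is uniform over its
    informative calls, so the null count is simulated directly from those
    marginals, grouped by the anchors' missing-sample pattern (identical in
    distribution to materialised permutations, at a fraction of the cost).

    p = (#permutation counts >= observed + 1) / (n_perm + 1), separately
    for gains and losses; results are stored on the table and returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    informative = table.calls != MISSING_CALL          # anchors x samples
    n_anchors, n_samples = table.calls.shape

    a_s = informative.sum(axis=0).astype(float)        # informative anchors per sample
    g_s = (table.calls == 1).sum(axis=0)
    l_s = (table.calls == -1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_gain_s = np.where(a_s > 0, g_s / np.maximum(a_s, 1), 0.0)
        p_loss_s = np.where(a_s > 0, l_s / np.maximum(a_s, 1), 0.0)

    p_gain = np.ones(n_anchors)
    p_loss = np.ones(n_anchors)
    # group anchors by their informative-sample pattern
    patterns, inverse = np.unique(informative, axis=0, return_inverse=True)
    for k in range(patterns.shape[0]):
        members = np.flatnonzero(inverse == k)
        cols = np.flatnonzero(patterns[k])
        if cols.size == 0:
            continue
        null_gain = np.zeros(n_perm, dtype=np.int32)
        null_loss = np.zeros(n_perm, dtype=np.int32)
        for s in cols:
            u = rng.random(n_perm)
            null_gain += u < p_gain_s[s]
            null_loss += (u >= p_gain_s[s]) & (u < p_gain_s[s] + p_loss_s[s])
        max_count = cols.size
        tail_gain = np.zeros(max_count + 2)
        tail_loss = np.zeros(max_count + 2)
        bc = np.bincount(null_gain, minlength=max_count + 1)
        tail_gain[:max_count + 1] = bc[::-1].cumsum()[::-1]
        bc = np.bincount(null_loss, minlength=max_count + 1)
        tail_loss[:max_count + 1] = bc[::-1].cumsum()[::-1]
        og = table.gain_count[members]
        ol = table.loss_count[members]
        p_gain[members] = (tail_gain[og] + 1.0) / (n_perm + 1.0)
        p_loss[members] = (tail_loss[ol] + 1.0) / (n_perm + 1.0)

    table.p_gain, table.p_loss = p_gain, p_loss
    return p_gain, p_loss


def merge_significant_anchors(table: AnchorTable, max_gap: int = 1_000_000,
                              alpha: float = 0.05) -> list[AberrantRegion]:
    """Merge runs of same-direction significant anchors into regions.

    An anchor is significant for gain if p_gain < alpha (likewise loss); if
    both sides are significant the smaller p wins.  Maximal same-direction
    runs with inter-anchor gaps <= max_gap become one region spanning
    [first anchor, last anchor + 1); region frequency is the peak anchor
    frequency in the run.
    """
    if table.p_gain is None or table.p_loss is None:
        raise ValueError("run anchor_frequency_test first")
    direction = np.zeros(table.n_anchors, dtype=np.int8)
    sig_gain = table.p_gain < alpha
    sig_loss = table.p_loss < alpha
    both = sig_gain & sig_loss
    direction[sig_gain & ~both] = 1
    direction[sig_loss & ~both] = -1
    direction[both] = np.where(table.p_gain[both] <= table.p_loss[both], 1, -1)

    freq = np.where(direction == 1, table.gain_freq, table.loss_freq)
    pval = np.where(direction == 1, table.p_gain, table.p_loss)

    regions: list[AberrantRegion] = []
    run: list[int] = []

    def flush(run):
        if not run:
            return
        first, last = run[0], run[-1]
        d = int(direction[first])
        name = ("gain" if d == 1 else "loss") + f"_{len(regions) + 1}"
        regions.append(AberrantRegion(
            interval=GenomicInterval(str(table.chroms[first]),
                                     int(table.positions[first]),
                                     int(table.positions[last]) + 1, name),
            direction=d,
            peak_frequency=float(freq[run].max()
                                 if isinstance(run, np.ndarray) else
                                 max(freq[i] for i in run)),
            peak_p=float(min(pval[i] for i in run)),
        ))

    for i in range(table.n_anchors):
        if direction[i] == 0:
            continue
        if run and (direction[i] != direction[run[-1]]
                    or table.chroms[i] != table.chroms[run[-1]]
                    or table.positions[i] - table.positions[run[-1]] > max_gap):
            flush(run)
            run = []
        run.append(i)
    flush(run)
    return regions
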