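"""Readers and writers for the project's file formats.

All formats are plain TSV dialects: tab-separated, UTF-8, ``#`` comment
lines, no quoting.  Genomic coordinates are 0-based half-open everywhere
(BED-native); SEG-like files carry a header comment declaring this so the
files are self-describing.  Floats are written with 6 significant digits,
which makes write -> read round trips byte-stable.

Formats
-------
BED4                 gene / probe annotations (chrom, start, end, id)
SEG-like TSV         per-sample copy-number segments or probe calls
matrix TSV           features x samples, first column ``id``; tumor/normal
                     labels live in a ``<stem>.classes.tsv`` sidecar
ranked-list TSV      columns id, direction in {up, down}, rank (1-based)
target-network TSV   columns mirna, gene, score, sources
truth TSV            planted ground truth of a synthetic cohort
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ExpressionMatrix",
    "RankedList",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_seg_calls",
    "write_seg_calls",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ranked_list",
    "write_ranked_list",
    "read_target_network",
    "write_target_network",
    "normalize_mirna_name",
    "fmt_float",
]

#: integer code for a missing call in probe/call matrices
MISSING_CALL = np.int8(-9)

FLOAT_FMT = "%.6g"


def fmt_float(x: float) -> str:
    """Format a float with the package-wide 6-significant-digit convention."""
    return FLOAT_FMT % x


class ParseError(ValueError):
    """Raised on malformed input; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with *other* (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix with tumor/normal labels.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids
    as columns; ``sample_class`` maps each sample id to ``"tumor"`` or
    ``"normal"``.
    """

    values: pd.DataFrame
    sample_class: Mapping[str, str]

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.sample_class)
        if missing:
            raise ValueError(f"samples without class label: {sorted(missing)[:5]}")
        bad = {c for c in self.sample_class.values() if c not in ("tumor", "normal")}
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        if not self.tumor_samples:
            raise ValueError("matrix must contain at least one tumor sample")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_class[s] == "tumor"]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_class[s] == "normal"]

    def tumors(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    def normals(self) -> pd.DataFrame:
        return self.values[self.normal_samples]


@dataclass
class RankedList:
    """An ordered list of feature ids (best rank first) for one direction.

    ``universe_size`` is the number of features that were eligible in the
    producing study; ``measured_ids`` (optional) is the full set of features
    the study measured, used by the aggregator to distinguish
    measured-but-unlisted (worst rank) from unmeasured (no entry).
    """

    direction: str
    ids: list[str]
    universe_size: int
    measured_ids: frozenset[str] | None = None

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")
        if len(self.ids) > self.universe_size:
            raise ValueError("list longer than its universe")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_bed(path) -> list[GenomicInterval]:
    """Read a 4+-column BED file as a list of intervals, in file order."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected >=4 BED columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        try:
            out.append(GenomicInterval(chrom, start, end, name))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval],
              scores: Iterable[float] | None = None) -> None:
    intervals = list(intervals)
    scores = list(scores) if scores is not None else None
    with open(path, "wt", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.id]
            if scores is not None:
                row.append(fmt_float(scores[i]))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# SEG-like probe/call files
# ---------------------------------------------------------------------------

SEG_HEADER = "# coords=0-based-half-open"
_SEG_COLUMNS = ("sample", "chrom", "start", "end", "value")


def read_seg_calls(path, mode: str = "calls"):
    """Read a SEG-like TSV into a :class:`~paradoxcna.cna_integration.ProbeCallDataset`.

    Columns: sample, chrom, start, end, value.  In ``calls`` mode the value
    must be one of -1, 0, 1; in ``ratios`` mode any finite float (a log2
    ratio).  Probes are the unique (chrom, start, end) triples; sample x
    probe cells without a row are recorded as missing.
    """
    from .cna_integration import ProbeCallDataset  # local import to avoid a cycle

    if mode not in ("calls", "ratios"):
        raise ValueError(f"mode must be 'calls' or 'ratios', got {mode!r}")
    rows = []
    for lineno, fields in _data_lines(path):
        if fields[:5] == list(_SEG_COLUMNS):
            continue  # header row
        if len(fields) < 5:
            raise ParseError(path, lineno, f"expected 5 columns, got {len(fields)}")
        sample, chrom, start_s, end_s, val_s = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        if start >= end:
            raise ParseError(path, lineno, f"start {start} >= end {end}")
        try:
            value = float(val_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value {val_s!r}")
        if mode == "calls" and value not in (-1.0, 0.0, 1.0):
            raise ParseError(path, lineno,
                             f"value {val_s!r} is not a call in {{-1,0,1}} (calls mode)")
        rows.append((sample, chrom, start, end, value))

    probes_seen: dict[tuple, int] = {}
    samples_seen: dict[str, int] = {}
    for sample, chrom, start, end, _ in rows:
        probes_seen.setdefault((chrom, start, end), len(probes_seen))
        samples_seen.setdefault(sample, len(samples_seen))
    probe_keys = sorted(probes_seen, key=lambda k: (k[0], k[1], k[2]))
    probe_index = {k: i for i, k in enumerate(probe_keys)}
    sample_ids = list(samples_seen)

    if mode == "calls":
        calls = np.full((len(probe_keys), len(sample_ids)), MISSING_CALL, dtype=np.int8)
        for sample, chrom, start, end, value in rows:
            calls[probe_index[(chrom, start, end)], samples_seen[sample]] = int(value)
        values = None
    else:
        values = np.full((len(probe_keys), len(sample_ids)), np.nan)
        for sample, chrom, start, end, value in rows:
            values[probe_index[(chrom, start, end)], samples_seen[sample]] = value
        calls = None

    probes = [GenomicInterval(c, s, e, f"{c}:{s}-{e}") for c, s, e in probe_keys]
    return ProbeCallDataset(probes=probes, sample_ids=sample_ids,
                            calls=calls, log_ratios=values)


def write_seg_calls(path, dataset, mode: str = "calls") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(SEG_HEADER + f" mode={mode}\n")
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        mat = dataset.calls if mode == "calls" else dataset.log_ratios
        for j, sample in enumerate(dataset.sample_ids):
            for i, probe in enumerate(dataset.probes):
                v = mat[i, j]
                if mode == "calls":
                    if v == MISSING_CALL:
                        continue
                    val_s = str(int(v))
                else:
                    if not math.isfinite(v):
                        continue
                    val_s = fmt_float(v)
                fh.write(f"{sample}\t{probe.chrom}\t{probe.start}\t{probe.end}\t{val_s}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _classes_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".classes.tsv")


def read_expression_matrix(path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", comment="#", index_col="id")
    classes = pd.read_csv(_classes_path(path), sep="\t", comment="#")
    sample_class = dict(zip(classes["sample"].astype(str), classes["class"]))
    values.columns = values.columns.astype(str)
    values.index = values.index.astype(str)
    return ExpressionMatrix(values=values, sample_class=sample_class)


def write_expression_matrix(path, matrix: ExpressionMatrix) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        arr = matrix.values.to_numpy()
        for i, fid in enumerate(matrix.feature_ids):
            fh.write(str(fid) + "\t" + "\t".join(fmt_float(v) for v in arr[i]) + "\n")
    with open(_classes_path(path), "wt", encoding="utf-8") as fh:
        fh.write("sample\tclass\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.sample_class[s]}\n")


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------

def normalize_mirna_name(name: str, strip_arm: bool = True) -> str:
    """Lowercase a miRNA name and (optionally) strip a trailing -3p/-5p arm."""
    name = name.strip().lower()
    if strip_arm and (name.endswith("-3p") or name.endswith("-5p")):
        name = name[:-3]
    return name


def read_ranked_list(path, universe_size: int | None = None,
                     normalize: bool = False) -> tuple[RankedList, RankedList]:
    """Read a ranked-list TSV into an (up, down) pair of :class:`RankedList`.

    Columns: id, direction in {up, down}, rank (1-based within direction).
    Rows may appear in any order; output lists are sorted by rank.
    """
    entries: dict[str, list[tuple[int, str]]] = {"up": [], "down": []}
    for lineno, fields in _data_lines(path):
        if fields[:3] == ["id", "direction", "rank"]:
            continue
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        fid, direction, rank_s = fields[:3]
        if direction not in ("up", "down"):
            raise ParseError(path, lineno, f"direction {direction!r} not in {{up,down}}")
        try:
            rank = int(rank_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer rank {rank_s!r}")
        if normalize:
            fid = normalize_mirna_name(fid)
        if fid in (x for _, x in entries[direction]):
            raise ParseError(path, lineno, f"duplicate id {fid!r} in direction {direction}")
        entries[direction].append((rank, fid))

    def build(direction: str) -> RankedList:
        ids = [fid for _, fid in sorted(entries[direction])]
        n = universe_size if universe_size is not None else max(
            1, len(entries["up"]) + len(entries["down"]))
        return RankedList(direction=direction, ids=ids, universe_size=n)

    return build("up"), build("down")


def write_ranked_list(path, up: RankedList, down: RankedList) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("id\tdirection\trank\n")
        for lst in (up, down):
            for rank, fid in enumerate(lst.ids, start=1):
                fh.write(f"{fid}\t{lst.direction}\t{rank}\n")


# ---------------------------------------------------------------------------
# Target network
# ---------------------------------------------------------------------------

def read_target_network(path, min_score: float = 0.0,
                        min_sources: int = 1) -> set[tuple[str, str]]:
    """Read a miRNA->gene target table, filtered by prediction confidence.

    Columns: mirna, gene, score, sources.  Rows with score below
    ``min_score`` or fewer than ``min_sources`` supporting sources are
    dropped at load time (the stand-in for a confidence-filtered database
    query).
    """
    edges = set()
    for lineno, fields in _data_lines(path):
        if fields[:2] == ["mirna", "gene"]:
            continue
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        mirna, gene, score_s, sources_s = fields[:4]
        try:
            score, sources = float(score_s), int(sources_s)
        except ValueError:
            raise ParseError(path, lineno, f"bad score/sources {score_s!r}/{sources_s!r}")
        if score >= min_score and sources >= min_sources:
            edges.add((mirna, gene))
    return edges


def write_target_network(path, edges, scores=None, sources=None) -> None:
    edges = sorted(edges)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("mirna\tgene\tscore\tsources\n")
        for k, (m, g) in enumerate(edges):
            sc = scores[k] if scores is not None else 1.0
            so = sources[k] if sources is not None else 2
            fh.write(f"{m}\t{g}\t{fmt_float(sc)}\t{so}\n")
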