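"""Stranded-coverage evidence for mitochondrial transcription.

Three products come out of a per-base stranded coverage track:

* the single-strand transcription test (fraction of depth on the sense
  strand, with rRNA loci excludable because non-polyA rRNA contamination
  aligns antisense there without being evidence of antisense transcription);
* transcribed intergenic regions longer than 100 bp — candidate
  mitochondrial long noncoding RNAs (lncmtRNAs);
* abrupt coverage drop-offs, read as transcript cleavage/start boundaries,
  which can corroborate refined start codons.

All vectors are genome-length and circular: windows and region merging wrap
the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (AnnotationTable, FormatError, ValidationError,
                      circular_distance, circular_length, circular_overlap)

__all__ = [
    "CoverageTrack", "TranscribedRegion", "DropoffSite",
    "read_coverage_tsv", "write_coverage_tsv", "read_bedgraph_pair",
    "strand_fraction", "call_transcribed_regions", "detect_dropoffs",
    "annotate_starts_with_dropoffs",
]


@dataclass
class CoverageTrack:
    """Per-base sense and antisense read depth for one circular genome."""

    genome_id: str
    sense: np.ndarray
    antisense: np.ndarray

    def __post_init__(self):
        self.sense = np.asarray(self.sense, dtype=float)
        self.antisense = np.asarray(self.antisense, dtype=float)
        if self.sense.shape != self.antisense.shape or self.sense.ndim != 1:
            raise ValidationError("sense/antisense vectors must be equal-length 1-D")
        if (self.sense < 0).any() or (self.antisense < 0).any():
            raise ValidationError("coverage depths must be non-negative")

    def __len__(self) -> int:
        return self.sense.size


@dataclass(frozen=True)
class TranscribedRegion:
    """A called transcribed interval (1-based inclusive, circular)."""

    start: int
    end: int
    mean_depth: float
    max_depth: float
    label: str  # "intergenic" or "genic-overlap"


@dataclass(frozen=True)
class DropoffSite:
    """A sharp coverage step at the boundary between ``position`` and
    ``position + 1`` (circular).  ``direction`` is "down" when depth falls
    5'->3' across the boundary and "up" when it rises."""

    position: int
    log2_ratio: float
    direction: str


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_coverage_tsv(path, genome_id: str | None = None) -> CoverageTrack:
    """Read a 3-column TSV (pos, sense, antisense), 1-based, full length."""
    df = pd.read_csv(path, sep="\t")
    need = {"pos", "sense", "antisense"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    df = df.sort_values("pos")
    L = len(df)
    if not (df["pos"].to_numpy() == np.arange(1, L + 1)).all():
        raise FormatError(f"{path}: positions must be exactly 1..{L}")
    return CoverageTrack(genome_id=genome_id or str(path),
                         sense=df["sense"].to_numpy(float),
                         antisense=df["antisense"].to_numpy(float))


def write_coverage_tsv(track: CoverageTrack, path) -> None:
    pd.DataFrame({
        "pos": np.arange(1, len(track) + 1),
        "sense": track.sense,
        "antisense": track.antisense,
    }).to_csv(path, sep="\t", index=False)


def read_bedgraph_pair(sense_path, antisense_path, genome_length: int,
                       genome_id: str = "") -> CoverageTrack:
    """Build a track from two bedGraph files (0-based half-open intervals)."""
    vecs = []
    for path in (sense_path, antisense_path):
        v = np.zeros(genome_length)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                _, s, e, d = line.split()[:4]
                s, e = int(s), int(e)
                if e > genome_length:
                    raise ValidationError(
                        f"{path}: interval end {e} exceeds genome length")
                v[s:e] = float(d)
        vecs.append(v)
    return CoverageTrack(genome_id=genome_id or str(sense_path),
                         sense=vecs[0], antisense=vecs[1])


# ---------------------------------------------------------------------------
# single-strand transcription test
# ---------------------------------------------------------------------------

def strand_fraction(track: CoverageTrack, annotations: AnnotationTable,
                    exclude_rrna: bool = True) -> float:
    """Fraction of total depth on the sense strand.

    With ``exclude_rrna`` (default), positions inside rRNA features are left
    out of both sums, so that antisense rRNA contamination cannot dilute the
    single-strand signal.  Returns NaN when no coverage remains (a
    zero-coverage track supports neither conclusion).
    """
    mask = np.ones(len(track), dtype=bool)
    if exclude_rrna:
        for f in annotations.of_type("rRNA"):
            if f.end >= f.start:
                mask[f.start - 1 : f.end] = False
            else:
                mask[f.start - 1 :] = False
                mask[: f.end] = False
    s = float(track.sense[mask].sum())
    a = float(track.antisense[mask].sum())
    if s + a == 0:
        return math.nan
    return s / (s + a)


# ---------------------------------------------------------------------------
# transcribed-region calling
# ---------------------------------------------------------------------------

def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based inclusive circular intervals."""
    n = mask.size
    if mask.all():
        return [(1, n)]
    if not mask.any():
        return []
    # rotate so the array starts on a False; runs then never wrap mid-array
    first_false = int(np.argmin(mask))
    rot = np.roll(mask, -first_false)
    runs = []
    diffs = np.flatnonzero(np.diff(rot.astype(int)))
    starts = [i + 1 for i in diffs if not rot[i]]
    ends = [i for i in diffs if rot[i]]
    if rot[-1]:
        ends.append(n - 1)
    for s, e in zip(starts, ends):
        runs.append((((s + first_false) % n) + 1, ((e + first_false) % n) + 1))
    runs.sort(key=lambda r: r[0])
    return runs


def call_transcribed_regions(track: CoverageTrack,
                             annotations: AnnotationTable,
                             min_len: int = 100,
                             min_mean_depth: float = 15.0,
                             merge_gap: int = 50,
                             per_base_floor: float | None = None,
                             ) -> list[TranscribedRegion]:
    """Segment the sense track into transcribed regions.

    Positions with sense depth at or above ``per_base_floor`` (default
    ``min_mean_depth / 2``) are segmented into maximal circular runs;
    runs separated by fewer than ``merge_gap`` uncovered bases are merged;
    surviving regions must span at least ``min_len`` bases and average at
    least ``min_mean_depth``.  A region is labelled "intergenic" when less
    than 10% of it overlaps any annotated feature, else "genic-overlap".
    """
    if min_mean_depth <= 0:
        raise ValidationError("min_mean_depth must be positive")
    floor = min_mean_depth / 2 if per_base_floor is None else per_base_floor
    L = len(track)
    mask = track.sense >= floor
    runs = _circular_runs(mask)
    if not runs:
        return []

    # merge circularly adjacent runs separated by < merge_gap
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        prev = merged[-1]
        gap = (s - prev[1] - 1) % L
        if gap < merge_gap:
            prev[1] = e
        else:
            merged.append([s, e])
    if len(merged) > 1:
        # wrap-around: last run vs first run
        gap = (merged[0][0] - merged[-1][1] - 1) % L
        if gap < merge_gap:
            merged[0][0] = merged[-1][0]
            merged.pop()

    regions = []
    for s, e in merged:
        n = circular_length(s, e, L)
        if n >= L:
            idx = np.arange(L)
        else:
            idx = (np.arange(s - 1, s - 1 + n)) % L
        depths = track.sense[idx]
        mean_d, max_d = float(depths.mean()), float(depths.max())
        if n < min_len or mean_d < min_mean_depth:
            continue
        ov = sum(circular_overlap(s, e, f.start, f.end, L)
                 for f in annotations.features)
        label = "intergenic" if ov < 0.10 * n else "genic-overlap"
        regions.append(TranscribedRegion(start=s, end=e, mean_depth=mean_d,
                                         max_depth=max_d, label=label))
    regions.sort(key=lambda r: r.start)
    return regions


# ---------------------------------------------------------------------------
# drop-off detection
# ---------------------------------------------------------------------------

def _window_means(depth: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Circular trailing/leading window means at every boundary p|p+1.

    left[p-1]  = mean depth over [p-window+1, p]
    right[p-1] = mean depth over [p+1, p+window]
    """
    L = depth.size
    ext = np.concatenate([depth, depth, depth])  # slice window ends freely
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    p = np.arange(L) + L  # boundary index into ext for positions 1..L
    left = (csum[p + 1] - csum[p + 1 - window]) / window
    right = (csum[p + 1 + window] - csum[p + 1]) / window
    return left, right


def detect_dropoffs(track: CoverageTrack, window: int = 50,
                    min_log2: float = 2.0,
                    min_separation: int = 100) -> list[DropoffSite]:
    """Find sharp coverage steps on the sense strand.

    Every circular boundary p|p+1 is scored log2((left+1)/(right+1)) with
    ``window``-base flanking means and a +1 pseudocount.  Boundaries whose
    |score| clears ``min_log2`` and is a local extremum are kept, then
    greedily thinned so that sites of the same direction are at least
    ``min_separation`` bases apart.  Down and up steps are thinned
    separately: a cleavage produces one step of each sign and the two may
    legitimately sit close together.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    L = len(track)
    left, right = _window_means(track.sense, window)
    score = np.log2((left + 1.0) / (right + 1.0))

    sites: list[DropoffSite] = []
    for direction, signed in (("down", score), ("up", -score)):
        prev_s = np.roll(signed, 1)
        next_s = np.roll(signed, -1)
        # local maximum of the signed score; ties resolved to the earliest
        is_peak = (signed >= min_log2) & (signed > prev_s) & (signed >= next_s)
        cand = np.flatnonzero(is_peak)
        order = cand[np.argsort(-signed[cand], kind="stable")]
        kept: list[int] = []
        for p in order:
            if all(circular_distance(p + 1, q + 1, L) >= min_separation
                   for q in kept):
                kept.append(int(p))
        for p in kept:
            sites.append(DropoffSite(position=p + 1,
                                     log2_ratio=float(score[p]),
                                     direction=direction))
    sites.sort(key=lambda s: s.position)
    return sites


def annotate_starts_with_dropoffs(calls, sites, genome_length: int,
                                  tolerance: int = 10):
    """Match each start call to the nearest "up" drop-off within tolerance.

    Returns a list of (StartCall, DropoffSite-or-None) pairs: a coverage
    rise near a chosen start codon corroborates it as a transcript 5' end.
    """
    ups = [s for s in sites if s.direction == "up"]
    out = []
    for call in calls:
        best, best_d = None, None
        for s in ups:
            d = circular_distance(call.position, s.position, genome_length)
            if d <= tolerance and (best_d is None or d < best_d):
                best, best_d = s, d
        out.append((call, best))
    return out
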