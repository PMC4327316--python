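"""Read-versus-design judgement and perfect-clone selection.

Every sequenced bead is judged against the intended design pool: reads are
adapter-trimmed, matched to their closest design by global alignment (unit
edit costs), and classified as ``perfect`` (zero edits), ``sub_only``
(substitutions but no indels), ``has_indel`` or ``unmatched``.  The
distinction matters because on a pyrosequencing platform most indel
mismatches are sequencing artefacts of homopolymer runs rather than real
synthesis errors, so the substitution-only ("red") correctness criterion
tracks the true molecule quality more closely than the strict ("blue") one.

Perfect, confidently mapped beads are then collected per design into an
ordered retrieval candidate list with a minimum-replication policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .simulate import DesignPool

__all__ = [
    "ReadClassification", "TargetSelection", "PoolIndex", "ErrorRateEstimate",
    "trim_adapters", "classify_read", "classify_reads", "select_targets",
    "quality_group_analysis", "estimate_error_rate", "fold_improvement",
]

#: Reads farther than this edit distance from every design are unmatched
#: (~12.5% of a 120-nt insert; beyond that, assignment is guesswork).
DEFAULT_MAX_EDIT_DISTANCE = 15

#: Seed length of the k-mer pre-filter that narrows alignment candidates.
SEED_K = 12

CLASS_PERFECT = "perfect"
CLASS_SUB_ONLY = "sub_only"
CLASS_HAS_INDEL = "has_indel"
CLASS_UNMATCHED = "unmatched"


# ---------------------------------------------------------------------------
# adapter trimming

@dataclass(frozen=True)
class TrimResult:
    insert: str
    trimmed_prefix: bool
    trimmed_suffix: bool
    usable: bool


def _hamming_le1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return True


def trim_adapters(sequence: str, adaptors: Sequence[str]) -> TrimResult:
    """Strip adaptor occurrences (<= 1 mismatch) from both read ends.

    The longest adaptor matching the read prefix is removed, then likewise
    for the suffix.  Reads without a recognisable adaptor pass through
    unchanged but flagged untrimmed; a read trimmed down to nothing is
    flagged unusable.
    """
    if not adaptors:
        raise ValueError("adaptor set must be provided")
    seq = sequence
    trimmed5 = trimmed3 = False
    for a in sorted(adaptors, key=len, reverse=True):
        if len(a) <= len(seq) and _hamming_le1(seq[:len(a)], a):
            seq = seq[len(a):]
            trimmed5 = True
            break
    for a in sorted(adaptors, key=len, reverse=True):
        if len(a) <= len(seq) and _hamming_le1(seq[-len(a):], a):
            seq = seq[:-len(a)]
            trimmed3 = True
            break
    return TrimResult(insert=seq, trimmed_prefix=trimmed5, trimmed_suffix=trimmed3,
                      usable=len(seq) > 0)


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    design_id: Optional[str]
    n_sub: int
    n_ins: int
    n_del: int
    distance: int
    cls: str
    mean_quality: float


class PoolIndex:
    """Exact-match hash plus k-mer seed index over a design pool.

    The exact lookup short-circuits the common (error-free) case; the seed
    index restricts full alignment to designs sharing at least one k-mer
    with the read, which is essentially always true for reads within the
    maximum accepted edit distance of their design.
    """

    def __init__(self, pool: DesignPool, k: int = SEED_K):
        self.pool = pool
        self.k = k
        self.exact: dict[str, str] = {}
        for did, seq in zip(pool.ids, pool.sequences):
            self.exact.setdefault(seq, did)
        self.seeds: dict[str, set[int]] = {}
        for i, seq in enumerate(pool.sequences):
            for j in range(0, max(1, len(seq) - k + 1)):
                self.seeds.setdefault(seq[j:j + k], set()).add(i)

    def candidates(self, read: str) -> list[int]:
        hits: dict[int, int] = {}
        for j in range(0, max(1, len(read) - self.k + 1), self.k):
            for i in self.seeds.get(read[j:j + self.k], ()):
                hits[i] = hits.get(i, 0) + 1
        return sorted(hits, key=lambda i: (-hits[i], self.pool.ids[i]))


# edlib cigar operation -> (read-edit kind); 'I'/'D' orientation is fixed by
# the _cigar_counts regression test against hand-built alignments.
def _cigar_counts(cigar: str) -> tuple[int, int, int]:
    """(substitutions, insertions-in-read, deletions-from-design) from a cigar."""
    n_sub = n_ins = n_del = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        count = int(num)
        num = ""
        if ch == "X":
            n_sub += count
        elif ch == "I":
            n_ins += count  # edlib 'I': base present in query(read), absent in design
        elif ch == "D":
            n_del += count  # edlib 'D': design base absent from the read
    return n_sub, n_ins, n_del


def _classify_counts(n_sub: int, n_ins: int, n_del: int) -> str:
    if n_sub == 0 and n_ins == 0 and n_del == 0:
        return CLASS_PERFECT
    if n_ins == 0 and n_del == 0:
        return CLASS_SUB_ONLY
    return CLASS_HAS_INDEL


def _mean_quality(quality: str) -> float:
    if not quality:
        return float("nan")
    return float(np.mean([ord(c) - 33 for c in quality]))


def classify_read(insert: str, pool: DesignPool,
                  max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
                  index: Optional[PoolIndex] = None,
                  read_id: str = "", quality: str = "") -> ReadClassification:
    """Match one insert to its closest design and decompose the edits.

    Exact matches are resolved by hash lookup; otherwise the insert is
    globally aligned (Needleman-Wunsch, unit costs) against seed-sharing
    candidate designs, falling back to the whole pool when no seed hits.
    Distance ties break toward the smallest design id.  Reads beyond
    ``max_edit_distance`` of every design are ``unmatched``.
    """
    if len(pool) == 0:
        raise ValueError("design pool is empty")
    if not insert:
        raise ValueError("insert sequence is empty")
    idx = index if index is not None else PoolIndex(pool)
    mq = _mean_quality(quality)
    exact = idx.exact.get(insert)
    if exact is not None:
        return ReadClassification(read_id, exact, 0, 0, 0, 0, CLASS_PERFECT, mq)
    cand = idx.candidates(insert)
    if not cand:
        cand = list(range(len(pool)))
    best_dist = max_edit_distance + 1
    best_i = None
    for i in cand:
        res = edlib.align(insert, pool.sequences[i], mode="NW", task="distance",
                          k=min(best_dist, max_edit_distance))
        d = res["editDistance"]
        if d == -1:
            continue
        if d < best_dist or (d == best_dist and best_i is not None
                             and pool.ids[i] < pool.ids[best_i]):
            best_dist, best_i = d, i
    if best_i is None:
        return ReadClassification(read_id, None, 0, 0, 0, -1, CLASS_UNMATCHED, mq)
    res = edlib.align(insert, pool.sequences[best_i], mode="NW", task="path")
    n_sub, n_ins, n_del = _cigar_counts(res["cigar"])
    cls = _classify_counts(n_sub, n_ins, n_del)
    return ReadClassification(read_id, pool.ids[best_i], n_sub, n_ins, n_del,
                              best_dist, cls, mq)


def classify_reads(reads: pd.DataFrame, pool: DesignPool,
                   max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
                   adaptors: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Classify a whole read table (columns read_id, sequence[, quality]).

    Returns one row per read: read_id, design_id (NA if unmatched), n_sub,
    n_ins, n_del, distance, cls, mean_quality.
    """
    idx = PoolIndex(pool)
    rows = []
    has_q = "quality" in reads.columns
    for rec in reads.itertuples(index=False):
        seq = rec.sequence
        if adaptors:
            tr = trim_adapters(seq, adaptors)
            if not tr.usable:
                rows.append((rec.read_id, None, 0, 0, 0, -1, CLASS_UNMATCHED,
                             _mean_quality(rec.quality if has_q else "")))
                continue
            seq = tr.insert
        rc = classify_read(seq, pool, max_edit_distance, index=idx,
                           read_id=rec.read_id,
                           quality=rec.quality if has_q else "")
        rows.append((rc.read_id, rc.design_id, rc.n_sub, rc.n_ins, rc.n_del,
                     rc.distance, rc.cls, rc.mean_quality))
    return pd.DataFrame(rows, columns=["read_id", "design_id", "n_sub", "n_ins",
                                       "n_del", "distance", "cls", "mean_quality"])


# ---------------------------------------------------------------------------
# target selection

@dataclass(frozen=True)
class TargetSelection:
    """Ordered retrieval candidates per design plus the not-recovered list."""

    frame: pd.DataFrame        # design_id, rank, well_id, read_id, residual_px, flag
    missing: tuple             # designs with zero perfect ok-mapped beads
    k: int


def select_targets(mapping_frame: pd.DataFrame, classifications: pd.DataFrame,
                   k: int = 1,
                   design_ids: Optional[Iterable[str]] = None) -> TargetSelection:
    """Pick up to ``k`` wells per design among perfect, ok-mapped beads.

    Wells are ranked by ascending mapping residual (most trustworthy
    location first).  Designs with at least one but fewer than ``k`` perfect
    beads are kept and flagged ``under_replicated``; designs with none go to
    the missing list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    merged = classifications.merge(mapping_frame[["read_id", "well_id",
                                                  "residual_px", "flag"]],
                                   on="read_id")
    good = merged[(merged["cls"] == CLASS_PERFECT) & (merged["flag"] == "ok")]
    good = good.sort_values(["design_id", "residual_px", "read_id"])
    rows = []
    seen = set()
    for did, grp in good.groupby("design_id", sort=True):
        seen.add(did)
        n_avail = len(grp)
        status = "ok" if n_avail >= k else "under_replicated"
        for rank, rec in enumerate(grp.head(k).itertuples(index=False), start=1):
            rows.append((did, rank, rec.well_id, rec.read_id,
                         float(rec.residual_px), status))
    universe = (sorted(set(design_ids)) if design_ids is not None
                else sorted(set(classifications["design_id"].dropna())))
    missing = tuple(d for d in universe if d not in seen)
    frame = pd.DataFrame(rows, columns=["design_id", "rank", "well_id",
                                        "read_id", "residual_px", "flag"])
    return TargetSelection(frame=frame, missing=missing, k=k)


# ---------------------------------------------------------------------------
# quality and error-rate analytics

def quality_group_analysis(classifications: pd.DataFrame, n_groups: int = 3) -> pd.DataFrame:
    """Correct-read fractions per mean-quality group.

    Matched reads are split into ``n_groups`` equal-count groups by ascending
    mean quality.  Per group, the ``red`` fraction counts reads with no
    substitutions (indels forgiven — the pyrosequencing-error view) and the
    ``blue`` fraction counts strictly perfect reads; blue <= red always.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    matched = classifications[classifications["cls"] != CLASS_UNMATCHED]
    if len(matched) < n_groups:
        raise ValueError(f"only {len(matched)} matched reads for {n_groups} groups")
    matched = matched.sort_values(["mean_quality", "read_id"]).reset_index(drop=True)
    groups = np.array_split(np.arange(len(matched)), n_groups)
    rows = []
    for g, idx in enumerate(groups, start=1):
        sub = matched.iloc[idx]
        red = float((sub["n_sub"] == 0).mean())
        blue = float(((sub["n_sub"] == 0) & (sub["n_ins"] == 0)
                      & (sub["n_del"] == 0)).mean())
        rows.append((g, len(sub), float(sub["mean_quality"].mean()), red, blue))
    return pd.DataFrame(rows, columns=["group", "n_reads", "mean_quality",
                                       "red_fraction", "blue_fraction"])


@dataclass(frozen=True)
class ErrorRateEstimate:
    rate: float
    n_errors: int
    n_bases: int
    text: str


def estimate_error_rate(classifications: pd.DataFrame, total_bases: int) -> ErrorRateEstimate:
    """Per-base error rate over matched reads, rendered as "1 in X bp"."""
    if total_bases <= 0:
        raise ValueError("total_bases must be > 0")
    matched = classifications[classifications["cls"] != CLASS_UNMATCHED]
    n_err = int((matched["n_sub"] + matched["n_ins"] + matched["n_del"]).sum())
    rate = n_err / total_bases
    if n_err == 0:
        text = f"0 errors in {total_bases:,} bp"
    else:
        text = f"1 in {round(1.0 / rate):,} bp"
    return ErrorRateEstimate(rate=rate, n_errors=n_err, n_bases=int(total_bases),
                             text=text)


def fold_improvement(rate_before: float, rate_after: float) -> float:
    """Quality gain as the ratio of per-base error rates (before / after).

    ``rate_after == 0`` yields ``math.inf`` (flag with ``math.isinf``).
    """
    if rate_before <= 0:
        raise ValueError("rate_before must be > 0")
    if rate_after < 0:
        raise ValueError("rate_after must be >= 0")
    if rate_after == 0:
        return math.inf
    return rate_before / rate_after
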