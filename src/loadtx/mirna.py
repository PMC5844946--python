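"""Small-RNA read processing: adapter trimming, exact-overlap assignment of
reads to mature miRNAs, counting, and the expression filter.

Assignment model
----------------
A read is compared against every mature miRNA at every ungapped offset. The
overlap at an offset is the intersection of the read span and the miRNA span;
a candidate hit requires an overlap of at least ``min_overlap`` nucleotides
(default 17) containing zero mismatches. The score of a hit is its overlap
length. A read is assigned iff a unique miRNA achieves the maximal score;
a tie between two or more distinct miRNAs leaves the read unassigned
(``unassigned_ambiguous``) so no read is ever double-counted.

Bases of the read overhanging either miRNA terminus are ignored, not scored
as mismatches: isomiRs with shifted or untemplated ends still match over
their templated core. The search is strand-specific (small-RNA libraries are
stranded); ``search_reverse_complement=True`` adds the reverse-complemented
read as a second query for unstranded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SmallRNARead

ASSIGNED = "assigned"
UNASSIGNED_SHORT = "unassigned_short"
UNASSIGNED_NO_HIT = "unassigned_no_hit"
UNASSIGNED_AMBIGUOUS = "unassigned_ambiguous"
UNASSIGNED_STATUSES = (UNASSIGNED_SHORT, UNASSIGNED_NO_HIT, UNASSIGNED_AMBIGUOUS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# adapter trimming


@dataclass(frozen=True)
class TrimResult:
    read: SmallRNARead | None
    status: str  # trimmed | no_adapter | too_short
    insert_len: int


def trim_adapter(
    read: SmallRNARead,
    adapter: str,
    seed_len: int = 8,
    min_len: int = 17,
) -> TrimResult:
    """Trim a 3' adapter by exact match of its first ``seed_len`` bases.

    The sequence is truncated at the first occurrence of the adapter seed.
    Reads without the seed are kept unmodified and flagged ``no_adapter``;
    trimmed inserts shorter than ``min_len`` (the assignment overlap floor)
    are discarded with status ``too_short``.
    """
    if len(adapter) < seed_len:
        raise ValueError(f"adapter ({len(adapter)} nt) shorter than seed_len={seed_len}")
    seed = adapter[:seed_len].upper()
    idx = read.sequence.find(seed)
    if idx < 0:
        return TrimResult(read=read, status="no_adapter", insert_len=len(read))
    if idx < min_len:
        return TrimResult(read=None, status="too_short", insert_len=idx)
    quals = read.qualities[:idx] if read.qualities is not None else None
    return TrimResult(
        read=SmallRNARead(read.read_id, read.sequence[:idx], quals),
        status="trimmed",
        insert_len=idx,
    )


# ---------------------------------------------------------------------------
# assignment


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of assigning one read to the mature-miRNA reference.

    ``offset`` is the read start relative to the miRNA start (may be
    negative for 5'-overhanging reads). ``best_mirnas`` lists every miRNA
    achieving the maximal score; it has one element when assigned.
    """

    read_id: str
    status: str
    mirna: str | None = None
    overlap_len: int = 0
    offset: int | None = None
    best_mirnas: tuple[str, ...] = field(default_factory=tuple)


def _best_hit(seq: str, ref_seq: str, min_overlap: int) -> tuple[int, int] | None:
    """Best (overlap, offset) of ``seq`` against one miRNA, or None.

    Scans every ungapped offset; the overlap must be >= min_overlap and
    mismatch-free. Ties between offsets of equal overlap keep the smallest
    offset (immaterial for scoring, deterministic for reporting).
    """
    n, m = len(seq), len(ref_seq)
    best: tuple[int, int] | None = None
    for off in range(-(n - min_overlap), m - min_overlap + 1):
        lo = max(0, -off)            # first read index inside the miRNA
        hi = min(n, m - off)         # one past the last such index
        ov = hi - lo
        if ov < min_overlap:
            continue
        if best is not None and ov <= best[0]:
            continue
        if seq[lo:hi] == ref_seq[lo + off:hi + off]:
            best = (ov, off)
    return best


def assign_read(
    read: SmallRNARead | str,
    reference: Mapping[str, str],
    min_overlap: int = 17,
    search_reverse_complement: bool = False,
) -> AssignmentResult:
    """Assign one trimmed read to its best-matching mature miRNA.

    See the module docstring for the scoring model. Raises on an empty
    reference.
    """
    if not reference:
        raise ValueError("empty miRNA reference")
    if isinstance(read, str):
        read = SmallRNARead("read", read)
    queries = [read.sequence]
    if search_reverse_complement:
        queries.append(read.sequence.translate(_COMPLEMENT)[::-1])

    # a read shorter than min_overlap admits no candidate and falls through
    # to unassigned_no_hit; unassigned_short is reserved for trim-stage discards
    hits: dict[str, tuple[int, int]] = {}
    for name, ref_seq in reference.items():
        cand = None
        for q in queries:
            h = _best_hit(q, ref_seq, min_overlap)
            if h is not None and (cand is None or h[0] > cand[0]):
                cand = h
        if cand is not None:
            hits[name] = cand
    if not hits:
        return AssignmentResult(read.read_id, UNASSIGNED_NO_HIT)

    top = max(ov for ov, _ in hits.values())
    best = sorted(name for name, (ov, _) in hits.items() if ov == top)
    if len(best) > 1:
        return AssignmentResult(
            read.read_id, UNASSIGNED_AMBIGUOUS, overlap_len=top, best_mirnas=tuple(best)
        )
    name = best[0]
    return AssignmentResult(
        read.read_id, ASSIGNED, mirna=name, overlap_len=top,
        offset=hits[name][1], best_mirnas=(name,),
    )


# ---------------------------------------------------------------------------
# counting and filtering


@dataclass
class MiRNACountMatrix:
    """Integer read counts per mature miRNA per sample, with provenance.

    Invariant (default ambiguous handling): each column sum equals the
    number of assigned reads in that sample.
    """

    counts: pd.DataFrame                 # miRNA x sample
    unassigned: pd.DataFrame             # status x sample tallies
    provenance: str = ""

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def count_mirnas(
    assignments_by_sample: Mapping[str, Iterable[AssignmentResult]],
    mirna_names: Sequence[str] | None = None,
    ambiguous_mode: str = "drop",
    provenance: str = "",
) -> MiRNACountMatrix:
    """Tally assignments into a miRNA x sample count matrix.

    ``ambiguous_mode='drop'`` (default) leaves ambiguous reads uncounted;
    ``'count_all_best'`` credits every tied-best miRNA (breaks the
    column-sum invariant, intended for sensitivity analysis only).
    """
    if ambiguous_mode not in ("drop", "count_all_best"):
        raise ValueError(f"unknown ambiguous_mode {ambiguous_mode!r}")
    samples = list(assignments_by_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("sample labels must be unique")
    names = set(mirna_names or ())
    tallies: dict[str, dict[str, int]] = {s: {} for s in samples}
    unassigned = pd.DataFrame(0, index=list(UNASSIGNED_STATUSES), columns=samples)
    for s, results in assignments_by_sample.items():
        for r in results:
            if r.status == ASSIGNED:
                tallies[s][r.mirna] = tallies[s].get(r.mirna, 0) + 1
                names.add(r.mirna)
            else:
                unassigned.loc[r.status, s] += 1
                if r.status == UNASSIGNED_AMBIGUOUS and ambiguous_mode == "count_all_best":
                    for m in r.best_mirnas:
                        tallies[s][m] = tallies[s].get(m, 0) + 1
                        names.add(m)
    counts = pd.DataFrame(
        {s: pd.Series(tallies[s], dtype="int64") for s in samples},
        index=sorted(names),
    ).fillna(0).astype(int)
    counts.index.name = "feature"
    return MiRNACountMatrix(counts=counts, unassigned=unassigned, provenance=provenance)


def filter_expressed(
    counts: pd.DataFrame,
    min_count: int = 10,
    mode: str = "max_per_sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the expression filter; returns (filtered matrix, report).

    Modes: ``max_per_sample`` (default) keeps a miRNA iff its maximum
    per-sample count is >= min_count; ``total`` applies the bound to the
    row total; ``strict_gt`` requires the per-sample maximum to be
    strictly > min_count. The report lists each miRNA's statistic and
    keep/drop decision.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if mode == "max_per_sample":
        stat, keep = counts.max(axis=1), counts.max(axis=1) >= min_count
    elif mode == "total":
        stat, keep = counts.sum(axis=1), counts.sum(axis=1) >= min_count
    elif mode == "strict_gt":
        stat, keep = counts.max(axis=1), counts.max(axis=1) > min_count
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    report = pd.DataFrame({"statistic": stat, "kept": keep})
    return counts.loc[keep], report
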