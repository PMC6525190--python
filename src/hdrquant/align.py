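"""Global read-to-amplicon alignment and outcome classification.

Each read is aligned to its reference amplicon with an affine-gap
Needleman-Wunsch/Gotoh algorithm (numba-accelerated) and assigned one of
four outcome classes:

* ``DISCARDED`` — the aligned span covers too little of the amplicon
  (the in-silico analogue of size selection, which removes short
  donor-oligo contamination fragments);
* ``INDEL``     — the read carries an insertion or deletion anchored in the
  10-bp quantification window.  Reads carrying both an indel and donor SNPs
  are counted as indels, never as HDR;
* ``HDR``       — no window indel, and every target SNP matches the donor
  allele (PAM-block incorporation is reported but not required);
* ``UNMODIFIED`` — everything else; substitution-only reads (sequencing
  errors) land here.

Indel placement inside repeats is ambiguous: score-equivalent alignments can
anchor the same indel at different positions.  Window membership is therefore
decided over the full range of score-equivalent placements (left- and
right-shifted through local repeats): an indel is "in the window" if any
equivalent placement intersects the half-open window interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .locus import (
    AmpliconLocus,
    DonorTemplate,
    apply_hdr,
    rebase_donor,
    trim_to_read_length,
)

__all__ = [
    "Scoring",
    "Alignment",
    "AlignmentOp",
    "SnpCall",
    "ReadCall",
    "OUTCOMES",
    "global_align",
    "detect_window_indels",
    "detect_donor_snps",
    "classify_read",
    "classify_sample",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("UNMODIFIED", "HDR", "INDEL", "DISCARDED")

# base encoding: A C G T = 0..3, N = 4 (N mismatches everything, incl. N)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scores; a gap of length L costs
    ``gap_open + L * gap_extend``.

    Defaults (+2/−3/−5/−2) make a single-SNP HDR read score far better as a
    mismatch than as gaps at amplicon read lengths, so HDR reads never
    misalign as indels.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentOp:
    kind: str  # 'match' | 'mismatch' | 'insertion' | 'deletion'
    ref_start: int  # reference anchor (inter-base coordinate for insertions)
    length: int
    inserted: str = ""  # read bases for insertions


@dataclass(frozen=True)
class Alignment:
    """A global alignment; gaps are ``-``.  Removing gaps from the aligned
    strings reproduces the input read and reference."""

    aligned_read: str
    aligned_ref: str
    score: int
    ops: tuple[AlignmentOp, ...]

    @property
    def reference(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def read(self) -> str:
        return self.aligned_read.replace("-", "")


@njit(cache=True)
def _gotoh(a, b, match, mismatch, go, ge):  # pragma: no cover - numba kernel
    """Affine-gap global alignment of read ``a`` vs reference ``b``.

    Returns (score, path, path_len) where path holds one state per alignment
    column from the start: 0 = diagonal (match/mismatch), 1 = deletion
    (gap in read, consumes reference), 2 = insertion (gap in reference,
    consumes read).  Ties prefer diagonal over deletion over insertion.
    """
    n, m = len(a), len(b)
    NEG = np.int64(-(10**12))
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # deletion state
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # insertion state
    tM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    M[0, 0] = 0
    for j in range(1, m + 1):
        X[0, j] = go + ge * j
        tX[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        Y[i, 0] = go + ge * i
        tY[i, 0] = 2 if i > 1 else 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            # diagonal: predecessor preference M > X > Y at equal score
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + s
            tM[i, j] = src
            # deletion: consume reference base j-1
            best = M[i, j - 1] + go
            src = 0
            if X[i, j - 1] > best:
                best = X[i, j - 1]
                src = 1
            if Y[i, j - 1] + go > best:
                best = Y[i, j - 1] + go
                src = 2
            X[i, j] = best + ge
            tX[i, j] = src
            # insertion: consume read base i-1
            best = M[i - 1, j] + go
            src = 0
            if X[i - 1, j] + go > best:
                best = X[i - 1, j] + go
                src = 1
            if Y[i - 1, j] > best:
                best = Y[i - 1, j]
                src = 2
            Y[i, j] = best + ge
            tY[i, j] = src

    # final state preference: M > X > Y
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    path = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        path[k] = state
        if state == 0:
            state = tM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = tX[i, j]
            j -= 1
        else:
            state = tY[i, j]
            i -= 1
    return score, path, k


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def global_align(
    read: str, reference: str, scoring: Scoring = DEFAULT_SCORING
) -> Alignment:
    """Optimal affine-gap global alignment of ``read`` against ``reference``.

    Deterministic tie-breaking prefers match/mismatch over deletion over
    insertion at equal score.
    """
    if not read or not reference:
        raise ValueError("global_align requires nonempty read and reference")
    score, path, start = _gotoh(
        _encode(read),
        _encode(reference),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    aread: list[str] = []
    aref: list[str] = []
    ops: list[AlignmentOp] = []
    i = j = 0
    run_kind: Optional[str] = None
    run_start = run_len = 0
    run_ins: list[str] = []

    def flush() -> None:
        if run_kind is not None:
            ops.append(
                AlignmentOp(run_kind, run_start, run_len, "".join(run_ins))
            )

    for state in path[start:]:
        if state == 0:
            kind = "match" if read[i] == reference[j] and read[i] != "N" else "mismatch"
            aread.append(read[i])
            aref.append(reference[j])
            anchor = j
            i += 1
            j += 1
            ins = ""
        elif state == 1:
            kind = "deletion"
            aread.append("-")
            aref.append(reference[j])
            anchor = j
            j += 1
            ins = ""
        else:
            kind = "insertion"
            aread.append(read[i])
            aref.append("-")
            anchor = j  # inter-base: inserted before reference[j]
            ins = read[i]
            i += 1
        if kind == run_kind and (kind != "insertion" or anchor == run_start):
            run_len += 1
            if ins:
                run_ins.append(ins)
        else:
            flush()
            run_kind, run_start, run_len = kind, anchor, 1
            run_ins = [ins] if ins else []
    flush()
    return Alignment("".join(aread), "".join(aref), int(score), tuple(ops))


def _deletion_anchor_range(ref: str, start: int, length: int) -> tuple[int, int]:
    """Leftmost/rightmost score-equivalent start of a deletion of
    ``ref[start:start+length]``."""
    lo = start
    while lo > 0 and ref[lo - 1] == ref[lo + length - 1]:
        lo -= 1
    hi = start
    while hi + length < len(ref) and ref[hi] == ref[hi + length]:
        hi += 1
    return lo, hi


def _insertion_anchor_range(ref: str, anchor: int, inserted: str) -> tuple[int, int]:
    """Leftmost/rightmost score-equivalent inter-base anchor of an insertion."""
    lo, seq = anchor, inserted
    while lo > 0 and ref[lo - 1] == seq[-1]:
        seq = ref[lo - 1] + seq[:-1]
        lo -= 1
    hi, seq = anchor, inserted
    while hi < len(ref) and ref[hi] == seq[0]:
        seq = seq[1:] + ref[hi]
        hi += 1
    return lo, hi


def detect_window_indels(
    alignment: Alignment, window: tuple[int, int]
) -> tuple[bool, list[AlignmentOp]]:
    """Report indel operations anchored inside the half-open window.

    A deletion hits the window when any score-equivalent placement of its
    deleted reference interval intersects it; an insertion hits when any
    equivalent inter-base anchor lies in ``[start, end)``.
    """
    w_start, w_end = window
    ref = alignment.reference
    events: list[AlignmentOp] = []
    for op in alignment.ops:
        if op.kind == "deletion":
            lo, hi = _deletion_anchor_range(ref, op.ref_start, op.length)
            if lo < w_end and hi + op.length > w_start:
                events.append(op)
        elif op.kind == "insertion":
            lo, hi = _insertion_anchor_range(ref, op.ref_start, op.inserted)
            if lo < w_end and hi >= w_start:
                events.append(op)
    return bool(events), events


@dataclass(frozen=True)
class SnpCall:
    position: int  # reference coordinate
    ref_allele: str
    donor_allele: str
    observed: Optional[str]  # None when the position is deleted in the read
    matches_donor: bool
    is_target: bool  # target SNP (True) vs PAM-block position (False)


def detect_donor_snps(alignment: Alignment, donor: DonorTemplate) -> list[SnpCall]:
    """Observed allele at every donor-edited position, with donor-match flags.

    Positions covered by a gap in the read are undetermined
    (``observed=None``, ``matches_donor=False``).
    """
    wanted = {p: (r, a, True) for p, r, a in donor.target_snps}
    wanted.update({p: (r, a, False) for p, r, a in donor.pam_block})
    observed: dict[int, Optional[str]] = {}
    j = 0
    for cr, cf in zip(alignment.aligned_read, alignment.aligned_ref):
        if cf == "-":
            continue
        if j in wanted:
            observed[j] = None if cr == "-" else cr
        j += 1
    calls = []
    for pos in sorted(wanted):
        ref_allele, donor_allele, is_target = wanted[pos]
        obs = observed.get(pos)
        calls.append(
            SnpCall(pos, ref_allele, donor_allele, obs, obs == donor_allele, is_target)
        )
    return calls


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    outcome: str
    window_indel: bool = False
    snp_calls: tuple[SnpCall, ...] = ()
    indel_events: tuple[AlignmentOp, ...] = ()
    reason: str = ""


def _aligned_span(alignment: Alignment) -> tuple[int, int]:
    """Half-open reference interval between the first and last read base."""
    first = last = -1
    j = 0
    for cr, cf in zip(alignment.aligned_read, alignment.aligned_ref):
        if cf == "-":
            continue
        if cr != "-":
            if first < 0:
                first = j
            last = j
        j += 1
    return (0, 0) if first < 0 else (first, last + 1)


def _clean_at(aln: Alignment, donor: DonorTemplate) -> bool:
    """True when the reference alignment is gapless and the read carries the
    reference base at every donor-edited position — in that case the optimal
    HDR-allele alignment can only score worse and need not be computed."""
    if any(op.kind in ("insertion", "deletion") for op in aln.ops):
        return False
    # gapless: aligned strings are the raw sequences
    return all(
        aln.aligned_read[pos] == ref_allele for pos, ref_allele, _ in
        donor.target_snps + donor.pam_block
    )


def classify_read(
    read,
    locus: AmpliconLocus,
    donor: Optional[DonorTemplate] = None,
    scoring: Scoring = DEFAULT_SCORING,
    min_coverage_fraction: float = 0.9,
) -> ReadCall:
    """Assign one outcome class to a read.

    ``read`` is either a bare sequence or a ``(id, sequence, quality)``
    record.  Decision order: DISCARDED when the aligned span covers less
    than ``min_coverage_fraction`` of the amplicon (size-selection analogue),
    else INDEL when any indel anchors in the quantification window (reads
    with both an indel and donor SNPs count as indels), else HDR when every
    target SNP matches the donor, else UNMODIFIED.

    When a donor is given, reads that do not align cleanly to the reference
    are additionally aligned to the expected HDR allele (reference with the
    donor substitutions applied) and classified on the better-scoring
    alignment, ties favouring the reference.  Without this, the optimal
    reference alignment of a read carrying both donor SNPs and an adjacent
    indel can absorb the SNPs into the indel and misplace its anchor.  Both
    alleles have identical length, so window and SNP coordinates agree.
    """
    if isinstance(read, str):
        read_id, seq = "read", read
    else:
        read_id, seq = read[0], read[1]

    try:
        aln = global_align(seq, locus.reference, scoring)
    except ValueError as exc:
        logger.debug("read %s: alignment failed (%s); discarded", read_id, exc)
        return ReadCall(read_id, "DISCARDED", reason=f"alignment failed: {exc}")

    if donor is not None and not _clean_at(aln, donor):
        hdr_aln = global_align(seq, apply_hdr(locus.reference, donor), scoring)
        if hdr_aln.score > aln.score:
            aln = hdr_aln

    span = _aligned_span(aln)
    coverage = (span[1] - span[0]) / len(locus.reference)
    if coverage < min_coverage_fraction:
        return ReadCall(
            read_id,
            "DISCARDED",
            reason=f"aligned span covers {coverage:.2f} < {min_coverage_fraction} of amplicon",
        )

    window_indel, events = detect_window_indels(aln, locus.window)
    snp_calls = tuple(detect_donor_snps(aln, donor)) if donor is not None else ()
    if window_indel:
        outcome = "INDEL"
    else:
        targets = [c for c in snp_calls if c.is_target]
        if targets and all(c.matches_donor for c in targets):
            outcome = "HDR"
        else:
            outcome = "UNMODIFIED"
    return ReadCall(read_id, outcome, window_indel, snp_calls, tuple(events))


def classify_sample(
    reads: Iterable,
    locus: AmpliconLocus,
    donor: Optional[DonorTemplate] = None,
    scoring: Scoring = DEFAULT_SCORING,
    min_coverage_fraction: float = 0.9,
) -> list[ReadCall]:
    """Classify every read against the effective (read-length) amplicon.

    Applies the same amplicon trimming rule as the simulator so reads and
    reference agree on coordinates for over-long amplicons.
    """
    eff = trim_to_read_length(locus)
    donor_eff = rebase_donor(donor, locus, eff) if donor is not None else None
    return [
        classify_read(r, eff, donor_eff, scoring, min_coverage_fraction)
        for r in reads
    ]
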