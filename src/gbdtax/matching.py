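"""Local ungapped matching between genome pairs.

This module finds high-scoring segment pairs (HSPs) between two genomes with
a deterministic seeded matcher — exact k-mer seeds, merged along diagonals,
extended ungapped with an X-drop criterion — and resolves overlaps with the
greedy-with-trimming procedure, so that the accepted HSP set is
footprint-disjoint on both genomes.  The trimmed set is what the GBDP
distance formulas consume.

The matcher is ungapped by design: trimming an ungapped HSP is exact
coordinate slicing, and identities can be re-counted on any slice directly
from the sequences.  Coordinates are 0-based half-open on the concatenation
of each genome's replicons (replicons are joined with a spacer of 2k N's so
seeds cannot span a join); ``len_a``/``len_b`` in :class:`HSPSet` are the
true genome lengths without spacers, as used by the distance formulas.

Results are bit-reproducible: all tie-breaks are fully specified
(score desc, length desc, a_start, b_start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genomes import GenomeRecord, encode_sequence, reverse_complement_codes

__all__ = [
    "MatchParams",
    "HSP",
    "HSPSet",
    "find_hsps",
    "greedy_with_trimming",
]


@dataclass(frozen=True)
class MatchParams:
    """Seeding/extension/filter parameters of the built-in matcher.

    word_size: exact-seed length k.
    match / mismatch: ungapped alignment scores (+1 / -2 by default, the
        classic megablast-like scheme under which a positive-scoring segment
        is at least two-thirds identical).
    xdrop: stop extension once the running score falls this far below the
        best score seen.
    min_length / min_identity: HSP acceptance filters.
    max_kmer_hits: seeds from k-mers occurring more often than this in the
        indexed genome are skipped (guards against low-complexity blowup).
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20
    min_length: int = 100
    min_identity: float = 0.70
    max_kmer_hits: int = 64


@dataclass(frozen=True)
class HSP:
    """An ungapped locally aligned segment pair.

    Coordinates are 0-based half-open on the concatenated sequences.  For
    strand '-', a[a_start:a_end] aligns to the reverse complement of
    b[b_start:b_end]; offset o on A corresponds to B position b_end-1-o.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    identities: int
    score: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("ungapped HSP must have equal spans on A and B")
        if not 0 <= self.identities <= self.length:
            raise ValueError("identities must lie in [0, length]")

    def b_pos(self, offset: int) -> int:
        """B coordinate aligned to A position a_start+offset."""
        if self.strand == "+":
            return self.b_start + offset
        return self.b_end - 1 - offset


_SORT_KEY = lambda h: (-h.score, -(h.a_end - h.a_start), h.a_start, h.b_start)


@dataclass
class HSPSet:
    """All HSPs between one genome pair, plus the data needed to re-slice them."""

    pair: tuple[str, str]
    hsps: list[HSP]
    len_a: int
    len_b: int
    # encoded concatenated sequences (with spacers); kept so trimming can
    # re-count identities on slices.  None for HSP sets imported from
    # tabular alignment output.
    a_codes: np.ndarray | None = field(default=None, repr=False)
    b_codes: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_length(self) -> int:
        return sum(h.length for h in self.hsps)

    @property
    def total_identities(self) -> int:
        return sum(h.identities for h in self.hsps)

    def sorted(self) -> "HSPSet":
        return replace(self, hsps=sorted(self.hsps, key=_SORT_KEY))

    def is_footprint_disjoint(self) -> bool:
        for axis in ("a", "b"):
            ivals = sorted(
                (getattr(h, f"{axis}_start"), getattr(h, f"{axis}_end"))
                for h in self.hsps
            )
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    return False
        return True


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and integer values of all valid (ACGT-only) k-mers."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.int64)
    for j in range(k):
        vals = (vals << 2) | codes[j : j + m].astype(np.int64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    pos = np.flatnonzero(valid)
    return pos, vals[pos]


def _seed_pairs(
    a_codes: np.ndarray, b_codes: np.ndarray, k: int, max_hits: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (a_pos, b_pos) with identical k-mers, repeat-capped on A."""
    a_pos, a_val = _kmer_values(a_codes, k)
    b_pos, b_val = _kmer_values(b_codes, k)
    if a_pos.size == 0 or b_pos.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(a_val, kind="stable")
    a_val_sorted = a_val[order]
    a_pos_sorted = a_pos[order]
    lo = np.searchsorted(a_val_sorted, b_val, side="left")
    hi = np.searchsorted(a_val_sorted, b_val, side="right")
    counts = hi - lo
    counts[counts > max_hits] = 0
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    keep = counts > 0
    lo_k, cnt_k, bpos_k = lo[keep], counts[keep], b_pos[keep]
    offsets = np.cumsum(cnt_k) - cnt_k
    flat = np.arange(total) - np.repeat(offsets, cnt_k) + np.repeat(lo_k, cnt_k)
    return a_pos_sorted[flat], np.repeat(bpos_k, cnt_k)


def _merge_seed_runs(
    b_seeds: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Merge sorted same-diagonal seed starts into maximal exact-match runs."""
    runs: list[tuple[int, int]] = []
    start = prev = int(b_seeds[0])
    for b in b_seeds[1:]:
        b = int(b)
        if b <= prev + k:
            prev = b
        else:
            runs.append((start, prev + k))
            start = prev = b
    runs.append((start, prev + k))
    return runs


def _xdrop_segment(
    mm_pos: np.ndarray,
    w0: int,
    w1: int,
    s0: int,
    e0: int,
    params: MatchParams,
) -> tuple[int, int]:
    """Extend the all-match run [s0,e0) left/right within window [w0,w1).

    ``mm_pos`` holds the absolute positions of mismatches along the
    diagonal within the window.  Scores walk +match at a
    match, +mismatch at a mismatch; each direction stops when the running
    score drops more than xdrop below its best.  Returns the half-open
    segment bounds.  Only mismatch positions are visited, so runtime is
    proportional to the local divergence, not the window size.
    """
    ms, mm, X = params.match, params.mismatch, params.xdrop

    # right extension from e0
    cur = best = 0
    best_end = e0
    prev = e0
    i = int(np.searchsorted(mm_pos, e0))
    while i < mm_pos.size:
        t = int(mm_pos[i])
        cur += (t - prev) * ms
        if cur > best:
            best, best_end = cur, t
        cur += mm
        prev = t + 1
        if best - cur > X:
            break
        i += 1
    else:
        cur += (w1 - prev) * ms
        if cur > best:
            best, best_end = cur, w1

    # left extension from s0 (mirror walk over mismatches below s0)
    cur = best = 0
    best_start = s0
    prev = s0
    i = int(np.searchsorted(mm_pos, s0)) - 1
    while i >= 0:
        t = int(mm_pos[i])
        cur += (prev - t - 1) * ms
        if cur > best:
            best, best_start = cur, t + 1
        cur += mm
        prev = t
        if best - cur > X:
            break
        i -= 1
    else:
        cur += (prev - w0) * ms
        if cur > best:
            best, best_start = cur, w0

    return best_start, best_end


def _scan_strand(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    params: MatchParams,
) -> list[tuple[int, int, int, int]]:
    """HSPs of one strand as (a_start, a_end, b_start, b_end) on b_codes."""
    k = params.word_size
    a_seed, b_seed = _seed_pairs(a_codes, b_codes, k, params.max_kmer_hits)
    if a_seed.size == 0:
        return []
    diag = a_seed - b_seed
    order = np.lexsort((b_seed, diag))
    diag, b_seed = diag[order], b_seed[order]
    boundaries = np.flatnonzero(np.diff(diag) != 0) + 1
    groups = np.split(np.arange(diag.size), boundaries)

    n_a, n_b = a_codes.size, b_codes.size
    out: list[tuple[int, int, int, int]] = []
    margin = 4 * params.xdrop + 2 * k
    for g in groups:
        d = int(diag[g[0]])
        runs = _merge_seed_runs(b_seed[g], k)
        # valid b-range of this diagonal
        lo_b = max(0, -d)
        hi_b = min(n_b, n_a - d)
        w0 = max(lo_b, runs[0][0] - margin)
        w1 = min(hi_b, runs[-1][1] + margin)
        while True:
            window_match = a_codes[w0 + d : w1 + d] == b_codes[w0:w1]
            # positions with ambiguity codes never match (255 == 255 would)
            window_match &= b_codes[w0:w1] < 4
            mm_pos = w0 + np.flatnonzero(~window_match)
            segs = []
            touched = False
            covered_end = -1
            for s0, e0 in runs:
                if e0 <= covered_end:
                    continue
                s, e = _xdrop_segment(mm_pos, w0, w1, s0, e0, params)
                if (s == w0 and w0 > lo_b) or (e == w1 and w1 < hi_b):
                    touched = True  # hit the extraction edge: widen and redo
                    break
                segs.append((s, e))
                covered_end = max(covered_end, e)
            if not touched:
                break
            w0 = max(lo_b, w0 - 4 * margin)
            w1 = min(hi_b, w1 + 4 * margin)
        for s, e in segs:
            out.append((s + d, e + d, s, e))
    return out


def find_hsps(
    a: GenomeRecord, b: GenomeRecord, params: MatchParams | None = None
) -> HSPSet:
    """Find ungapped HSPs between two genomes on both strands.

    Deterministic: exact k-mer seeds, diagonal-merged, X-drop extended,
    filtered by ``min_length`` and ``min_identity``, sorted by
    (score desc, length desc, a_start, b_start).
    """
    params = params or MatchParams()
    k = params.word_size
    a_codes = encode_sequence(a.concatenated(spacer=2 * k))
    b_codes = encode_sequence(b.concatenated(spacer=2 * k))
    if k > a_codes.size or k > b_codes.size:
        warnings.warn(
            f"word size {k} exceeds a genome length for pair "
            f"({a.strain_id}, {b.strain_id}); no HSPs found"
        )
        return HSPSet((a.strain_id, b.strain_id), [], a.total_length, b.total_length)

    hsps: list[HSP] = []
    seen: set[tuple[int, int, int, str]] = set()
    n_b = b_codes.size
    for strand, b_arr in (("+", b_codes), ("-", reverse_complement_codes(b_codes))):
        for a_s, a_e, b_s, b_e in _scan_strand(a_codes, b_arr, params):
            length = a_e - a_s
            if length < params.min_length:
                continue
            ident = int(np.count_nonzero(a_codes[a_s:a_e] == b_arr[b_s:b_e]))
            if ident / length < params.min_identity:
                continue
            if strand == "-":
                b_s, b_e = n_b - b_e, n_b - b_s
            key = (a_s, b_s, length, strand)
            if key in seen:
                continue
            seen.add(key)
            score = ident * params.match + (length - ident) * params.mismatch
            hsps.append(HSP(a_s, a_e, b_s, b_e, strand, ident, score))

    return HSPSet(
        (a.strain_id, b.strain_id),
        sorted(hsps, key=_SORT_KEY),
        a.total_length,
        b.total_length,
        a_codes=a_codes,
        b_codes=b_codes,
    ).sorted()


# ---------------------------------------------------------------------------
# greedy-with-trimming overlap resolution


def _subtract(
    span: tuple[int, int], blocks: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Subtract sorted disjoint blocks from one interval."""
    s, e = span
    out = []
    cur = s
    for bs, be in blocks:
        if be <= cur or bs >= e:
            continue
        if bs > cur:
            out.append((cur, min(bs, e)))
        cur = max(cur, be)
        if cur >= e:
            break
    if cur < e:
        out.append((cur, e))
    return out


class _IntervalSet:
    """Sorted disjoint half-open intervals with insertion and subtraction."""

    def __init__(self) -> None:
        self._ivals: list[tuple[int, int]] = []

    def add(self, s: int, e: int) -> None:
        ivals = self._ivals + [(s, e)]
        ivals.sort()
        merged = [ivals[0]]
        for cs, ce in ivals[1:]:
            ps, pe = merged[-1]
            if cs <= pe:
                merged[-1] = (ps, max(pe, ce))
            else:
                merged.append((cs, ce))
        self._ivals = merged

    def subtract_from(self, span: tuple[int, int]) -> list[tuple[int, int]]:
        return _subtract(span, self._ivals)


def _recount(
    hspset: HSPSet, h: HSP, o_start: int, o_end: int, params_score: tuple[int, int]
) -> HSP:
    """Build the fragment of ``h`` covering A-offsets [o_start, o_end)."""
    a_s = h.a_start + o_start
    a_e = h.a_start + o_end
    length = o_end - o_start
    if h.strand == "+":
        b_s = h.b_start + o_start
        b_e = h.b_start + o_end
    else:
        b_e = h.b_end - o_start
        b_s = h.b_end - o_end
    if hspset.a_codes is not None and hspset.b_codes is not None:
        a_slice = hspset.a_codes[a_s:a_e]
        if h.strand == "+":
            b_slice = hspset.b_codes[b_s:b_e]
        else:
            b_slice = reverse_complement_codes(hspset.b_codes[b_s:b_e])
        ident = int(np.count_nonzero((a_slice == b_slice) & (a_slice < 4)))
    else:
        # no sequences available (imported HSPs): apportion identities
        ident = min(length, round(h.identities * length / h.length))
    match, mismatch = params_score
    score = ident * match + (length - ident) * mismatch
    return HSP(a_s, a_e, b_s, b_e, h.strand, ident, score)


def greedy_with_trimming(
    raw: HSPSet,
    min_length: int = 100,
    score_params: tuple[int, int] = (1, -2),
) -> HSPSet:
    """Resolve HSP overlaps greedily so the result is footprint-disjoint.

    HSPs are visited by descending score (ties: longer first, then smaller
    a_start, then smaller b_start).  The first is accepted whole; each later
    HSP has the sub-spans overlapping any accepted footprint on either
    genome removed (exact coordinate slicing for ungapped HSPs, identities
    re-counted on each kept slice) and surviving fragments shorter than
    ``min_length`` are discarded.
    """
    foot_a = _IntervalSet()
    foot_b = _IntervalSet()
    accepted: list[HSP] = []
    for h in sorted(raw.hsps, key=_SORT_KEY):
        # kept A-offsets after removing the A-footprint overlap
        kept_a = [
            (s - h.a_start, e - h.a_start)
            for s, e in foot_a.subtract_from((h.a_start, h.a_end))
        ]
        # kept A-offsets after removing the B-footprint overlap
        kept_b_coords = foot_b.subtract_from((h.b_start, h.b_end))
        if h.strand == "+":
            kept_b = [
                (s - h.b_start, e - h.b_start) for s, e in kept_b_coords
            ]
        else:
            kept_b = sorted((h.b_end - e, h.b_end - s) for s, e in kept_b_coords)
        # intersect the two kept-offset sets
        frags: list[tuple[int, int]] = []
        for s1, e1 in kept_a:
            for s2, e2 in kept_b:
                s, e = max(s1, s2), min(e1, e2)
                if e > s:
                    frags.append((s, e))
        for s, e in sorted(frags):
            if e - s < min_length:
                continue
            frag = _recount(raw, h, s, e, score_params)
            accepted.append(frag)
            foot_a.add(frag.a_start, frag.a_end)
            foot_b.add(frag.b_start, frag.b_end)
    out = HSPSet(
        raw.pair,
        sorted(accepted, key=_SORT_KEY),
        raw.len_a,
        raw.len_b,
        a_codes=raw.a_codes,
        b_codes=raw.b_codes,
    )
    assert out.is_footprint_disjoint()
    return out
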