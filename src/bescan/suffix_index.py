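"""Suffix-array index over a genome (both strands) with mismatch search.

The index concatenates every contig's forward sequence and its reverse
complement, each terminated by a unique sentinel symbol ordered below the
DNA alphabet.  The suffix array is built with induced sorting (SA-IS) in
linear time.  Queries are answered by binary search over the array:

* exact lookup of an anchor in O(|anchor| * log |text|), and
* bounded-Hamming-distance lookup of a window of length w with up to d
  substitutions, bounded by O((s*w)^d * log |text|) array-interval
  narrowings for alphabet size s = 4.

Mismatch search walks the pattern left to right keeping the suffix-array
interval of suffixes matching the variant prefix built so far, branching
over the four bases while a mismatch budget remains and pruning empty
intervals.  Every surviving leaf corresponds to one distinct length-w
variant, so each text occurrence is reported exactly once with its exact
(hence minimal) Hamming distance.  N in the text is a distinct symbol that
never matches a pattern base; patterns must be N-free.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .errors import BescanError
from .genome_io import GenomeRecord, reverse_complement

# Base ranks above the per-segment sentinels; order is arbitrary but fixed.
_BASE_RANK = {"A": 0, "C": 1, "G": 2, "N": 3, "T": 4}
DNA = "ACGT"


def build_suffix_array(s: list[int], alphabet_size: int) -> list[int]:
    """SA-IS: linear-time suffix array of an integer string.

    ``s`` must end with a unique smallest symbol (sentinel).  Returns the
    permutation ``sa`` with ``suffix(sa[i]) < suffix(sa[i+1])``.
    """
    n = len(s)
    if n == 0:
        return []
    if n == 1:
        return [0]
    if n == 2:
        return [1, 0] if s[0] > s[1] else [0, 1]

    # Classify suffixes: True = S-type (suffix smaller than its successor).
    is_s = [False] * n
    is_s[n - 1] = True
    for i in range(n - 2, -1, -1):
        if s[i] < s[i + 1] or (s[i] == s[i + 1] and is_s[i + 1]):
            is_s[i] = True

    def is_lms(i: int) -> bool:
        return i > 0 and is_s[i] and not is_s[i - 1]

    lms = [i for i in range(1, n) if is_lms(i)]

    # Bucket boundaries by symbol.
    counts = [0] * alphabet_size
    for c in s:
        counts[c] += 1
    bucket_heads = [0] * alphabet_size
    bucket_tails = [0] * alphabet_size
    total = 0
    for c in range(alphabet_size):
        bucket_heads[c] = total
        total += counts[c]
        bucket_tails[c] = total

    def induced_sort(lms_order: list[int]) -> list[int]:
        sa = [-1] * n
        tails = bucket_tails[:]
        for i in reversed(lms_order):
            c = s[i]
            tails[c] -= 1
            sa[tails[c]] = i
        heads = bucket_heads[:]
        for pos in range(n):
            i = sa[pos]
            if i > 0 and not is_s[i - 1]:
                c = s[i - 1]
                sa[heads[c]] = i - 1
                heads[c] += 1
        tails = bucket_tails[:]
        for pos in range(n - 1, -1, -1):
            i = sa[pos]
            if i > 0 and is_s[i - 1]:
                c = s[i - 1]
                tails[c] -= 1
                sa[tails[c]] = i - 1
        return sa

    sa = induced_sort(lms)

    # Name LMS substrings in sorted order; equal substrings share a name.
    def lms_equal(a: int, b: int) -> bool:
        if a == n - 1 or b == n - 1:
            return a == b  # the sentinel LMS substring is unique
        off = 0
        while True:
            a_lms, b_lms = is_lms(a + off), is_lms(b + off)
            if off > 0 and a_lms and b_lms:
                return True
            if a_lms != b_lms or s[a + off] != s[b + off]:
                return False
            off += 1

    lms_sorted = [i for i in sa if is_lms(i)]
    names = [-1] * n
    current = 0
    for prev, i in zip([None] + lms_sorted, lms_sorted):
        if prev is not None and not lms_equal(prev, i):
            current += 1
        names[i] = current
    reduced = [names[i] for i in lms]

    if current + 1 == len(lms):
        order = [0] * len(lms)
        for idx, name in enumerate(reduced):
            order[name] = idx
        lms_order = [lms[i] for i in order]
    else:
        sub_sa = build_suffix_array(reduced, current + 1)
        lms_order = [lms[i] for i in sub_sa]

    return induced_sort(lms_order)


@dataclass(frozen=True)
class _Segment:
    text_start: int  # offset of first base in the concatenated text
    text_end: int  # offset one past last base (sentinel sits at text_end)
    contig_id: str
    strand: str
    contig_len: int


@dataclass(frozen=True)
class MismatchQuery:
    """A bounded-Hamming window query: ``pattern`` within ``max_mismatches``."""

    pattern: str
    max_mismatches: int

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set(DNA):
            raise ValueError("pattern must be non-empty and A/C/G/T only")
        if not 0 <= self.max_mismatches <= 3:
            raise ValueError("max_mismatches must be in 0..3")


@dataclass(frozen=True, order=True)
class MatchHit:
    """One match: contig, strand, forward 0-based start, mismatch count."""

    contig_id: str
    strand: str
    start: int
    mismatches: int = 0


class SuffixIndex:
    """Queryable double-strand suffix array over a set of contigs."""

    def __init__(self, records: list[GenomeRecord]):
        if not records or all(r.length == 0 for r in records):
            raise BescanError("cannot index an empty genome")
        segments: list[_Segment] = []
        pieces: list[str] = []
        offset = 0
        for rec in records:
            if rec.length == 0:
                continue
            for strand, seq in (
                ("+", rec.sequence),
                ("-", reverse_complement(rec.sequence)),
            ):
                segments.append(
                    _Segment(offset, offset + len(seq), rec.contig_id, strand, rec.length)
                )
                pieces.append(seq)
                offset += len(seq) + 1  # +1 for the sentinel

        n_sent = len(segments)
        self._n_sent = n_sent
        text: list[int] = []
        for idx, piece in enumerate(pieces):
            text.extend(n_sent + _BASE_RANK[b] for b in piece)
            text.append(idx)
        # SA-IS needs the globally smallest symbol last: sentinel 0 is the
        # first segment's terminator, so append one below everything instead.
        self._text = [t + 1 for t in text]
        self._text.append(0)
        self._sa = build_suffix_array(self._text, n_sent + 5 + 1)
        self._segments = segments
        self._seg_starts = [seg.text_start for seg in segments]
        self._base_symbols = {b: n_sent + _BASE_RANK[b] + 1 for b in DNA}

    # -- coordinate mapping -------------------------------------------------

    def _map_offset(self, text_pos: int, length: int) -> MatchHit | None:
        idx = bisect_right(self._seg_starts, text_pos) - 1
        if idx < 0:
            return None
        seg = self._segments[idx]
        if text_pos + length > seg.text_end:
            return None  # would span the sentinel
        rel = text_pos - seg.text_start
        if seg.strand == "+":
            start = rel
        else:
            start = seg.contig_len - rel - length
        return MatchHit(seg.contig_id, seg.strand, start)

    # -- interval narrowing -------------------------------------------------

    def _narrow(self, lo: int, hi: int, depth: int, symbol: int) -> tuple[int, int]:
        """Restrict sa[lo:hi] (all sharing a depth-long prefix) to suffixes
        whose next symbol equals ``symbol``."""
        text, sa = self._text, self._sa
        n = len(text)

        def char_at(i: int) -> int:
            p = sa[i] + depth
            return text[p] if p < n else -1

        # leftmost index with char >= symbol
        a, b = lo, hi
        while a < b:
            mid = (a + b) // 2
            if char_at(mid) < symbol:
                a = mid + 1
            else:
                b = mid
        new_lo = a
        # leftmost index with char > symbol
        b = hi
        while a < b:
            mid = (a + b) // 2
            if char_at(mid) <= symbol:
                a = mid + 1
            else:
                b = mid
        return new_lo, a

    # -- queries ------------------------------------------------------------

    def find_exact(self, pattern: str) -> list[MatchHit]:
        """All occurrences of ``pattern`` on both strands (forward coords)."""
        if not pattern or set(pattern) - set(DNA):
            raise ValueError("pattern must be non-empty and A/C/G/T only")
        lo, hi = 0, len(self._sa)
        for depth, base in enumerate(pattern):
            lo, hi = self._narrow(lo, hi, depth, self._base_symbols[base])
            if lo >= hi:
                return []
        hits = []
        for i in range(lo, hi):
            hit = self._map_offset(self._sa[i], len(pattern))
            if hit is not None:
                hits.append(hit)
        hits.sort()
        return hits

    def find_with_mismatches(self, query: MismatchQuery) -> list[MatchHit]:
        """All occurrences within Hamming distance ``max_mismatches``.

        Equivalent to enumerating every substitution variant of the pattern
        and looking each one up exactly, with hits deduplicated at their
        minimal distance; implemented as a pruned walk over suffix-array
        intervals so absent variant prefixes cost one narrowing.
        """
        pattern = query.pattern
        d_max = query.max_mismatches
        w = len(pattern)
        hits: list[MatchHit] = []
        symbols = self._base_symbols

        stack = [(0, len(self._sa), 0, 0)]  # lo, hi, depth, mismatches used
        while stack:
            lo, hi, depth, mm = stack.pop()
            if depth == w:
                for i in range(lo, hi):
                    hit = self._map_offset(self._sa[i], w)
                    if hit is not None:
                        hits.append(
                            MatchHit(hit.contig_id, hit.strand, hit.start, mm)
                        )
                continue
            want = pattern[depth]
            for base in DNA:
                cost = 0 if base == want else 1
                if mm + cost > d_max:
                    continue
                nlo, nhi = self._narrow(lo, hi, depth, symbols[base])
                if nlo < nhi:
                    stack.append((nlo, nhi, depth + 1, mm + cost))
        hits.sort()
        return hits

    def mismatch_histogram(self, pattern: str, d_max: int) -> list[int]:
        """counts[k] = positions (both strands) at minimal distance exactly k."""
        hits = self.find_with_mismatches(MismatchQuery(pattern, d_max))
        counts = [0] * (d_max + 1)
        for hit in hits:
            counts[hit.mismatches] += 1
        return counts

    # -- introspection (used by tests) --------------------------------------

    @property
    def suffix_array(self) -> list[int]:
        return self._sa

    @property
    def text_symbols(self) -> list[int]:
        return self._text


def build_suffix_index(records: list[GenomeRecord]) -> SuffixIndex:
    """Build the double-strand index; errors on an empty genome."""
    return SuffixIndex(records)
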