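"""Spacer+PAM candidate enumeration and seed off-target counting.

PAM sites are located by exact anchor lookup (the longest non-degenerate
suffix of the PAM pattern) in the suffix index, then validated against the
degenerate positions of the IUPAC pattern.  Off-target specificity is
measured on the PAM-proximal seed (default 13 bp): the seed is matched
genome-wide on both strands at 0-3 mismatches and the candidate's own
occurrence is removed from the 0-mismatch bin exactly once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ConsistencyError
from .genome_io import GenomeRecord, TargetRegion, reverse_complement
from .suffix_index import DNA, MatchHit, MismatchQuery, SuffixIndex

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class PamSpec:
    """PAM pattern (IUPAC) plus spacer length; anchor drives index lookup."""

    pattern: str = "NGG"
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set(IUPAC):
            raise ValueError(f"invalid IUPAC PAM pattern {self.pattern!r}")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be positive")

    @property
    def anchor(self) -> str:
        """Longest suffix of the pattern made only of A/C/G/T."""
        suffix = ""
        for ch in reversed(self.pattern):
            if ch in DNA:
                suffix = ch + suffix
            else:
                break
        return suffix

    def matches(self, seq: str) -> bool:
        """IUPAC match against a genome slice; N in the genome matches nothing."""
        if len(seq) != len(self.pattern):
            return False
        return all(b in IUPAC[p] for p, b in zip(self.pattern, seq))


@dataclass
class GuideCandidate:
    """One spacer+PAM occurrence.

    All coordinates are forward-strand 0-based half-open.  ``spacer_seq``,
    ``pam_seq`` and ``seed_seq`` are written 5'->3' on the protospacer
    strand; ``seed_seq`` is the ``seed length`` PAM-proximal (3') end of
    the spacer.  ``offtargets[k]`` counts genome-wide seed matches at
    minimal Hamming distance k after self-exclusion.
    """

    contig_id: str
    strand: str
    spacer_start: int
    spacer_end: int
    pam_start: int
    pam_end: int
    spacer_seq: str
    pam_seq: str
    seed_seq: str
    offtargets: list[int] = field(default_factory=list)

    @property
    def seed_start(self) -> int:
        """Forward start of the seed occurrence (for self-exclusion)."""
        if self.strand == "+":
            return self.pam_start - len(self.seed_seq)
        return self.pam_end

    def key(self) -> tuple[str, str, int]:
        return (self.contig_id, self.strand, self.pam_start)


def find_pam_sites(
    index: SuffixIndex,
    records: list[GenomeRecord],
    pam: PamSpec,
    region: TargetRegion,
) -> list[tuple[str, int]]:
    """(strand, pam_start) for every full-pattern PAM inside the region.

    ``pam_start`` is the forward 0-based start of the PAM interval on both
    strands.  Anchor hits from the index are extended to the full pattern
    and validated; an all-degenerate pattern falls back to a full scan.
    """
    seqs = {rec.contig_id: rec.sequence for rec in records}
    contig_seq = seqs[region.contig_id]
    lp = len(pam.pattern)
    anchor = pam.anchor
    sites: set[tuple[str, int]] = set()

    def consider(strand: str, pam_start: int) -> None:
        pam_end = pam_start + lp
        if pam_start < region.start or pam_end > region.end:
            return
        window = contig_seq[pam_start:pam_end]
        if strand == "-":
            window = reverse_complement(window)
        if pam.matches(window):
            sites.add((strand, pam_start))

    if anchor:
        offset = lp - len(anchor)
        for hit in index.find_exact(anchor):
            if hit.contig_id != region.contig_id:
                continue
            if hit.strand == "+":
                consider("+", hit.start - offset)
            else:
                consider("-", hit.start)
    else:  # fully degenerate pattern: scan every position in the region
        for pos in range(region.start, region.end - lp + 1):
            consider("+", pos)
            consider("-", pos)
    return sorted(sites, key=lambda site: (site[1], site[0]))


def extract_candidates(
    records: list[GenomeRecord],
    pam_sites: list[tuple[str, int]],
    pam: PamSpec,
    contig_id: str,
    seed_length: int = 13,
) -> list[GuideCandidate]:
    """Build GuideCandidates for PAM sites with a full N-free spacer."""
    seq = {rec.contig_id: rec.sequence for rec in records}[contig_id]
    n = len(seq)
    lp = len(pam.pattern)
    sl = pam.spacer_length
    out: list[GuideCandidate] = []
    for strand, pam_start in pam_sites:
        pam_end = pam_start + lp
        if strand == "+":
            spacer_start, spacer_end = pam_start - sl, pam_start
            if spacer_start < 0:
                continue
            spacer_seq = seq[spacer_start:spacer_end]
            pam_seq = seq[pam_start:pam_end]
        else:
            spacer_start, spacer_end = pam_end, pam_end + sl
            if spacer_end > n:
                continue
            spacer_seq = reverse_complement(seq[spacer_start:spacer_end])
            pam_seq = reverse_complement(seq[pam_start:pam_end])
        if "N" in spacer_seq:
            continue
        out.append(
            GuideCandidate(
                contig_id=contig_id,
                strand=strand,
                spacer_start=spacer_start,
                spacer_end=spacer_end,
                pam_start=pam_start,
                pam_end=pam_end,
                spacer_seq=spacer_seq,
                pam_seq=pam_seq,
                seed_seq=spacer_seq[-seed_length:],
            )
        )
    return out


def _has_adjacent_pam(
    seqs: dict[str, str], pam: PamSpec, hit: MatchHit, seed_len: int
) -> bool:
    """Does a seed hit have a PAM immediately 3' on its own strand?"""
    seq = seqs[hit.contig_id]
    lp = len(pam.pattern)
    if hit.strand == "+":
        pam_start = hit.start + seed_len
        if pam_start + lp > len(seq):
            return False
        return pam.matches(seq[pam_start : pam_start + lp])
    pam_start = hit.start - lp
    if pam_start < 0:
        return False
    return pam.matches(reverse_complement(seq[pam_start : pam_start + lp]))


def attach_offtargets(
    index: SuffixIndex,
    candidates: list[GuideCandidate],
    d_max: int = 3,
    records: list[GenomeRecord] | None = None,
    pam: PamSpec | None = None,
    require_pam: bool = False,
) -> list[GuideCandidate]:
    """Fill each candidate's off-target histogram with self-exclusion.

    With ``require_pam`` the count keeps only seed hits that have an
    adjacent PAM at the off-target locus (needs ``records`` and ``pam``).
    """
    if require_pam and (records is None or pam is None):
        raise ValueError("require_pam needs records and a PamSpec")
    seqs = {rec.contig_id: rec.sequence for rec in records} if records else {}
    out = []
    for cand in candidates:
        seed_len = len(cand.seed_seq)
        hits = index.find_with_mismatches(MismatchQuery(cand.seed_seq, d_max))
        self_hit = MatchHit(cand.contig_id, cand.strand, cand.seed_start, 0)
        if self_hit not in hits:
            raise ConsistencyError(
                f"guide at {cand.contig_id}:{cand.pam_start}{cand.strand} "
                "did not find its own seed occurrence"
            )
        counts = [0] * (d_max + 1)
        removed_self = False
        for hit in hits:
            if not removed_self and hit == self_hit:
                removed_self = True
                continue
            if require_pam and not _has_adjacent_pam(seqs, pam, hit, seed_len):
                continue
            counts[hit.mismatches] += 1
        cand.offtargets = counts
        out.append(cand)
    return out


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern to a regex over A/C/G/T (N never matches)."""
    return re.compile("".join(f"[{IUPAC[ch]}]" for ch in pattern))
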