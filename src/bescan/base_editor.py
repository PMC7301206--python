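"""Deaminase edit-window simulation and codon-consequence classification.

The editor converts every source base inside the edit window at once:
C->T (cytidine deaminase) or A->G (adenine deaminase) on the protospacer
strand, observed as G->A / T->C on the complementary strand.  Each CDS
overlapping an edited base contributes one outcome per changed codon,
translated under the standard genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from Bio.Data.CodonTable import standard_dna_table

from .genome_io import GeneFeature, GenomeRecord
from .guide_finder import GuideCandidate

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Codon -> one-letter amino acid, '*' for stop; standard code (tables 1/11
# agree on all sense codons).
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid or '*'; None for codons with N/invalid length."""
    return CODON_TABLE.get(codon)


class Conversion(str, Enum):
    C_TO_T = "C_to_T"
    A_TO_G = "A_to_G"

    @property
    def source(self) -> str:
        return "C" if self is Conversion.C_TO_T else "A"

    @property
    def product(self) -> str:
        return "T" if self is Conversion.C_TO_T else "G"


@dataclass(frozen=True)
class EditorSpec:
    """Conversion chemistry plus window geometry.

    ``window_min``/``window_max`` are distances in bases upstream of the
    PAM, inclusive on both ends (base 1 = the spacer base adjacent to the
    PAM).  Defaults cover bases 13-20 upstream, i.e. spacer positions 1-8
    from the 5' end of a 20-nt spacer.
    """

    conversion: Conversion = Conversion.C_TO_T
    window_min: int = 13
    window_max: int = 20

    def __post_init__(self) -> None:
        if not 1 <= self.window_min <= self.window_max:
            raise ValueError("need 1 <= window_min <= window_max")

    def validate_against(self, spacer_length: int) -> None:
        if self.window_max > spacer_length:
            raise ValueError(
                f"edit window extends {self.window_max} bases upstream but "
                f"the spacer is only {spacer_length} nt"
            )


@dataclass(frozen=True)
class EditOutcome:
    """One changed codon in one CDS."""

    feature_ref: str
    codon_index: int  # 0-based within the CDS
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_aa == "*" and self.ref_aa != "*"

    @property
    def is_synonymous(self) -> bool:
        return self.alt_aa == self.ref_aa

    def notation(self) -> str:
        """1-based variant-style string, e.g. ``Q74*`` or ``P12L``."""
        return f"{self.ref_aa}{self.codon_index + 1}{self.alt_aa}"


@dataclass
class AnnotatedGuide:
    """A candidate plus its simulated base-editing consequences."""

    candidate: GuideCandidate
    window_start: int
    window_end: int
    editable_positions: list[int] = field(default_factory=list)
    outcomes: list[EditOutcome] = field(default_factory=list)

    @property
    def can_edit(self) -> bool:
        return any(not o.is_synonymous for o in self.outcomes)

    @property
    def introduces_stop(self) -> bool:
        return any(o.is_stop_gain for o in self.outcomes)

    @property
    def edited_features(self) -> list[str]:
        seen: list[str] = []
        for o in self.outcomes:
            if o.feature_ref not in seen:
                seen.append(o.feature_ref)
        return seen


def compute_edit_window(
    candidate: GuideCandidate, editor: EditorSpec
) -> tuple[int, int]:
    """Forward half-open genomic interval of the edit window."""
    editor.validate_against(len(candidate.spacer_seq))
    if candidate.strand == "+":
        # base k upstream of the PAM sits at pam_start - k
        return (
            candidate.pam_start - editor.window_max,
            candidate.pam_start - editor.window_min + 1,
        )
    return (
        candidate.pam_end + editor.window_min - 1,
        candidate.pam_end + editor.window_max,
    )


def editable_positions(
    candidate: GuideCandidate,
    editor: EditorSpec,
    records: list[GenomeRecord],
) -> list[int]:
    """Forward positions in the window whose protospacer-strand base is the
    conversion source (complement rule on the - strand)."""
    seq = next(
        r.sequence for r in records if r.contig_id == candidate.contig_id
    )
    w_start, w_end = compute_edit_window(candidate, editor)
    source = editor.conversion.source
    forward_source = source if candidate.strand == "+" else _COMPLEMENT[source]
    return [
        pos
        for pos in range(max(w_start, 0), min(w_end, len(seq)))
        if seq[pos] == forward_source
    ]


def simulate_edits(
    guide: AnnotatedGuide, records: list[GenomeRecord]
) -> list[EditOutcome]:
    """Apply all window edits simultaneously and report every changed codon.

    Positions outside any CDS contribute nothing; a codon truncated by the
    CDS end is skipped with a warning.
    """
    cand = guide.candidate
    record = next(r for r in records if r.contig_id == cand.contig_id)
    if not guide.editable_positions:
        return []

    outcomes: list[EditOutcome] = []
    for feat in record.features:
        hit_positions = [
            pos
            for pos in guide.editable_positions
            if feat.overlaps(pos, pos + 1)
        ]
        if not hit_positions:
            continue
        outcomes.extend(_edits_in_feature(cand, feat, record, hit_positions))
    return outcomes


def _edits_in_feature(
    cand: GuideCandidate,
    feat: GeneFeature,
    record: GenomeRecord,
    positions: list[int],
) -> list[EditOutcome]:
    ref_cds = feat.spliced_sequence(record.sequence)
    alt = list(ref_cds)
    # Protospacer-strand conversion observed on the coding strand: same
    # letters when guide and CDS share a strand, complemented otherwise.
    # Either way the coding-strand ref base determines the substitution.
    edited_offsets = []
    for pos in positions:
        spliced = feat.genomic_to_spliced(pos)
        if spliced is None:
            continue
        ref_base = ref_cds[spliced]
        alt[spliced] = _edited_base(ref_base)
        edited_offsets.append(spliced)

    alt_cds = "".join(alt)
    off = feat.codon_start_offset
    n_codons = (len(ref_cds) - off) // 3
    outcomes = []
    for codon_idx in sorted({(o - off) // 3 for o in edited_offsets if o >= off}):
        start = off + codon_idx * 3
        if codon_idx >= n_codons:
            logger.warning(
                "feature %s: edit in incomplete terminal codon skipped",
                feat.label(),
            )
            continue
        ref_codon = ref_cds[start : start + 3]
        alt_codon = alt_cds[start : start + 3]
        if ref_codon == alt_codon:
            continue
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        if ref_aa is None or alt_aa is None:
            logger.warning(
                "feature %s: ambiguous codon %s skipped", feat.label(), ref_codon
            )
            continue
        outcomes.append(
            EditOutcome(
                feature_ref=feat.label(),
                codon_index=codon_idx,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    return outcomes


def _edited_base(base: str) -> str:
    # C->T / A->G on one strand is G->A / T->C on the other; both directions
    # of both chemistries map uniquely, so the coding-strand base suffices.
    return {"C": "T", "G": "A", "A": "G", "T": "C"}[base]


def annotate_guide(
    candidate: GuideCandidate,
    editor: EditorSpec,
    records: list[GenomeRecord],
) -> AnnotatedGuide:
    """Full per-guide pipeline: window, editable bases, simulated outcomes."""
    w_start, w_end = compute_edit_window(candidate, editor)
    guide = AnnotatedGuide(candidate, w_start, w_end)
    guide.editable_positions = editable_positions(candidate, editor, records)
    guide.outcomes = simulate_edits(guide, records)
    return guide
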