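"""Genome input: GenBank/FASTA readers, feature model, target resolution.

Internal coordinates are 0-based half-open everywhere.  All user-facing
coordinates (CLI queries, CSV output) are 1-based inclusive, matching the
GenBank convention; the conversion happens only at the module boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AmbiguousTargetError,
    BoundsError,
    FormatError,
    TargetNotFoundError,
)

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A CDS annotation: strand, (possibly multi-interval) coordinates, ids.

    ``intervals`` are non-overlapping (start, end) pairs in 0-based
    half-open contig coordinates, ordered 5'->3' in *genomic* orientation
    (ascending start).  ``codon_start_offset`` is the number of leading
    bases of the spliced sequence to skip before the first codon
    (GenBank ``codon_start`` minus one).
    """

    locus_tag: str | None = None
    gene_name: str | None = None
    protein_id: str | None = None
    strand: str = "+"
    intervals: tuple[tuple[int, int], ...] = ()
    codon_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.codon_start_offset not in (0, 1, 2):
            raise ValueError("codon_start_offset must be 0, 1 or 2")
        prev_end = -1
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be ordered and non-overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def label(self) -> str:
        return self.locus_tag or self.gene_name or self.protein_id or "?"

    def names(self) -> tuple[str, ...]:
        return tuple(
            n for n in (self.locus_tag, self.gene_name, self.protein_id) if n
        )

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) intersects any interval of this feature."""
        return any(s < end and start < e for s, e in self.intervals)

    def spliced_sequence(self, contig_seq: str) -> str:
        """Coding-strand sequence: spliced exons, reverse-complemented for -."""
        parts = "".join(contig_seq[s:e] for s, e in self.intervals)
        if self.strand == "-":
            parts = reverse_complement(parts)
        return parts

    def genomic_to_spliced(self, pos: int) -> int | None:
        """Map a genomic position to a coding-strand spliced offset.

        Returns None when the position falls outside every interval.
        The returned offset does NOT account for codon_start_offset.
        """
        offset = 0
        for s, e in self.intervals:
            if s <= pos < e:
                fwd = offset + (pos - s)
                if self.strand == "+":
                    return fwd
                return self.spliced_length - 1 - fwd
            offset += e - s
        return None


@dataclass
class GenomeRecord:
    """One contig: uppercase A/C/G/T/N sequence plus CDS features."""

    contig_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"sequence contains invalid symbols {sorted(bad)}")
        for feat in self.features:
            if feat.end > self.length:
                raise ValueError(
                    f"feature {feat.label()} extends past contig end"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetRegion:
    """A resolved target: 0-based half-open slice of one contig."""

    contig_id: str
    start: int
    end: int
    source_query: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")


def normalise_sequence(raw: str, contig_id: str) -> str:
    """Uppercase and map non-ACGTN IUPAC letters to N (one warning/contig)."""
    seq = raw.upper()
    if _NON_ACGTN.search(seq):
        logger.warning(
            "contig %s: non-ACGTN symbols normalised to N", contig_id
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def _feature_from_seqfeature(sf) -> GeneFeature | None:
    quals = sf.qualifiers
    strand = "-" if sf.location.strand == -1 else "+"
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    intervals = tuple((int(p.start), int(p.end)) for p in parts)
    if any(s >= e for s, e in intervals):
        return None
    codon_start = int(quals.get("codon_start", ["1"])[0]) - 1

    def first(key: str) -> str | None:
        vals = quals.get(key)
        return vals[0] if vals else None

    return GeneFeature(
        locus_tag=first("locus_tag"),
        gene_name=first("gene"),
        protein_id=first("protein_id"),
        strand=strand,
        intervals=intervals,
        codon_start_offset=codon_start,
    )


def read_genbank(path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecords with CDS features.

    Fuzzy location bounds (``<``/``>``) are truncated to their concrete
    coordinates with a warning; sequences are uppercased and non-ACGTN
    letters mapped to N.
    """
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not seqrecords:
        raise FormatError(f"no GenBank records found in {path}")

    records = []
    for sr in seqrecords:
        try:
            raw = str(sr.seq)
        except Exception as exc:  # undefined sequence (e.g. CONTIG stub)
            raise FormatError(f"record {sr.id} has no sequence: {exc}") from exc
        if not raw:
            raise FormatError(f"record {sr.id} has an empty sequence")
        seq = normalise_sequence(raw, sr.id)
        features = []
        for sf in sr.features:
            if sf.type != "CDS":
                continue
            loc_str = str(sf.location)
            if "<" in loc_str or ">" in loc_str:
                logger.warning(
                    "contig %s: fuzzy CDS location %s truncated to concrete bounds",
                    sr.id,
                    loc_str,
                )
            feat = _feature_from_seqfeature(sf)
            if feat is not None and feat.end <= len(seq):
                features.append(feat)
        records.append(GenomeRecord(sr.id, seq, features))
    return records


def read_fasta(path) -> list[GenomeRecord]:
    """Parse FASTA into featureless GenomeRecords (sequence-only mode)."""
    try:
        seqrecords = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA file {path}: {exc}") from exc
    if not seqrecords:
        raise FormatError(f"no FASTA records found in {path}")
    records = []
    for sr in seqrecords:
        if len(sr.seq) == 0:
            raise FormatError(f"record {sr.id} has an empty sequence")
        records.append(
            GenomeRecord(sr.id, normalise_sequence(str(sr.seq), sr.id))
        )
    return records


_RANGE_RE = re.compile(r"^\s*(\d[\d,]*)\s*-\s*(\d[\d,]*)\s*$")


def resolve_target(records: list[GenomeRecord], query: str) -> TargetRegion:
    """Resolve a user query to a TargetRegion.

    Accepted forms: ``START-END`` (1-based inclusive, thousands separators
    allowed, on the first contig), or an exact match against one feature's
    gene name, locus tag, or protein ID.  ``START == END`` denotes a single
    base.
    """
    m = _RANGE_RE.match(query)
    if m:
        lo = int(m.group(1).replace(",", ""))
        hi = int(m.group(2).replace(",", ""))
        if lo < 1 or hi < lo:
            raise BoundsError(f"invalid range {query!r}: need 1 <= start <= end")
        contig = records[0]
        if hi > contig.length:
            raise BoundsError(
                f"range {query!r} exceeds contig {contig.contig_id} "
                f"length {contig.length}"
            )
        return TargetRegion(contig.contig_id, lo - 1, hi, source_query=query)

    matches: list[tuple[GenomeRecord, GeneFeature]] = []
    for rec in records:
        for feat in rec.features:
            if query in feat.names():
                matches.append((rec, feat))
    if not matches:
        raise TargetNotFoundError(f"no feature matches query {query!r}")
    if len(matches) > 1:
        raise AmbiguousTargetError(
            query, [f"{r.contig_id}:{f.label()}" for r, f in matches]
        )
    rec, feat = matches[0]
    return TargetRegion(rec.contig_id, feat.start, feat.end, source_query=query)


def find_feature(
    records: list[GenomeRecord], query: str
) -> tuple[GenomeRecord, GeneFeature]:
    """Look up exactly one feature by gene name / locus tag / protein ID."""
    matches = [
        (rec, feat)
        for rec in records
        for feat in rec.features
        if query in feat.names()
    ]
    if not matches:
        raise TargetNotFoundError(f"no feature matches {query!r}")
    if len(matches) > 1:
        raise AmbiguousTargetError(
            query, [f"{r.contig_id}:{f.label()}" for r, f in matches]
        )
    return matches[0]


def write_genbank(records: list[GenomeRecord], path) -> None:
    """Write GenomeRecords back to GenBank (used by the fixture generator)."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    seqrecords = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.contig_id,
            name=rec.contig_id[:16],
            description="synthetic fixture",
            annotations={"molecule_type": "DNA", "date": "01-JAN-2000"},
        )
        for feat in rec.features:
            strand = 1 if feat.strand == "+" else -1
            parts = [FeatureLocation(s, e, strand) for s, e in feat.intervals]
            if strand == -1:
                parts = parts[::-1]
            location = parts[0] if len(parts) == 1 else sum(parts[1:], parts[0])
            quals: dict[str, list[str]] = {
                "codon_start": [str(feat.codon_start_offset + 1)]
            }
            if feat.locus_tag:
                quals["locus_tag"] = [feat.locus_tag]
            if feat.gene_name:
                quals["gene"] = [feat.gene_name]
            if feat.protein_id:
                quals["protein_id"] = [feat.protein_id]
            sr.features.append(SeqFeature(location, type="CDS", qualifiers=quals))
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "genbank")
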