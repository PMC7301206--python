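"""Filtering, sorting, CSV export, and the end-to-end design pipeline."""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .base_editor import AnnotatedGuide, EditorSpec, annotate_guide
from .errors import TargetNotFoundError
from .genome_io import GenomeRecord, TargetRegion, find_feature
from .guide_finder import (
    GuideCandidate,
    PamSpec,
    attach_offtargets,
    extract_candidates,
    find_pam_sites,
)
from .suffix_index import SuffixIndex, build_suffix_index

CSV_COLUMNS = [
    "contig",
    "start",
    "end",
    "strand",
    "spacer",
    "pam",
    "offtargets_0",
    "offtargets_1",
    "offtargets_2",
    "offtargets_3",
    "genes",
    "aa_changes",
    "introduces_stop",
]

FILTER_MODES = ("all", "edit", "stop")


def filter_guides(guides: list[AnnotatedGuide], mode: str) -> list[AnnotatedGuide]:
    """all -> identity; edit -> non-synonymous editors; stop -> stop-gainers."""
    if mode == "all":
        return list(guides)
    if mode == "edit":
        return [g for g in guides if g.can_edit]
    if mode == "stop":
        return [g for g in guides if g.introduces_stop]
    raise ValueError(f"unknown filter mode {mode!r}; expected one of {FILTER_MODES}")


def restrict_to_gene(
    guides: list[AnnotatedGuide],
    records: list[GenomeRecord],
    feature_ref: str,
) -> list[AnnotatedGuide]:
    """Keep guides whose edit window overlaps the named feature."""
    rec, feat = find_feature(records, feature_ref)
    return [
        g
        for g in guides
        if g.candidate.contig_id == rec.contig_id
        and feat.overlaps(g.window_start, g.window_end)
    ]


def sort_guides(guides: list[AnnotatedGuide]) -> list[AnnotatedGuide]:
    """Ascending by off-target histogram, ties by genomic position."""
    return sorted(
        guides,
        key=lambda g: (
            tuple(g.candidate.offtargets),
            g.candidate.contig_id,
            g.candidate.spacer_start,
            g.candidate.strand,
        ),
    )


@dataclass(frozen=True)
class ReportRow:
    """One CSV line; coordinates are 1-based inclusive spacer bounds."""

    contig_id: str
    strand: str
    start: int
    end: int
    spacer_seq: str
    pam_seq: str
    offtargets: tuple[int, int, int, int]
    genes: str
    aa_changes: str
    introduces_stop: bool

    def as_list(self) -> list[str]:
        return [
            self.contig_id,
            str(self.start),
            str(self.end),
            self.strand,
            self.spacer_seq,
            self.pam_seq,
            *(str(c) for c in self.offtargets),
            self.genes,
            self.aa_changes,
            "yes" if self.introduces_stop else "no",
        ]


def to_report_rows(guides: list[AnnotatedGuide]) -> list[ReportRow]:
    rows = []
    for g in guides:
        cand = g.candidate
        rows.append(
            ReportRow(
                contig_id=cand.contig_id,
                strand=cand.strand,
                start=cand.spacer_start + 1,
                end=cand.spacer_end,
                spacer_seq=cand.spacer_seq,
                pam_seq=cand.pam_seq,
                offtargets=tuple(cand.offtargets),
                genes=";".join(g.edited_features),
                aa_changes=";".join(o.notation() for o in g.outcomes),
                introduces_stop=g.introduces_stop,
            )
        )
    return rows


def render_csv(rows: list[ReportRow]) -> str:
    """RFC 4180 text (CRLF line endings, header line, deterministic)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(CSV_COLUMNS)
    for row in rows:
        writer.writerow(row.as_list())
    return buf.getvalue()


def write_csv(rows: list[ReportRow], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(render_csv(rows))


def design_guides(
    records: list[GenomeRecord],
    region: TargetRegion,
    pam: PamSpec = PamSpec(),
    editor: EditorSpec | None = EditorSpec(),
    seed_length: int = 13,
    d_max: int = 3,
    offtarget_require_pam: bool = False,
    index: SuffixIndex | None = None,
) -> list[AnnotatedGuide]:
    """Run the whole pipeline for one target region, sorted output.

    With ``editor=None`` (classic sgRNA design) guides carry empty outcome
    lists, so only ``mode='all'`` is meaningful downstream.
    """
    if index is None:
        index = build_suffix_index(records)
    sites = find_pam_sites(index, records, pam, region)
    candidates = extract_candidates(
        records, sites, pam, region.contig_id, seed_length
    )
    candidates = attach_offtargets(
        index,
        candidates,
        d_max=d_max,
        records=records,
        pam=pam,
        require_pam=offtarget_require_pam,
    )
    guides = []
    for cand in candidates:
        if editor is None:
            # classic mode: no simulation; gene restriction falls back to
            # spacer overlap
            guides.append(
                AnnotatedGuide(cand, cand.spacer_start, cand.spacer_end)
            )
        else:
            guides.append(annotate_guide(cand, editor, records))
    return sort_guides(guides)
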