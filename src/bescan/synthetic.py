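"""Synthetic genome fixtures with planted guides and machine-readable truth.

Fixtures are built by writing controlled cassettes (genes, guide sites,
off-target seed copies, stop-codon layouts) into an i.i.d. random
background.  Every planted fact is verified at build time by the naive
oracles in this module — quadratic regex/Hamming scans and direct codon
translation written independently of the suffix-array pipeline — so the
truth tables are sound before any test uses them.

All generation is a pure function of ``rng_seed``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from random import Random

import numpy as np

from .genome_io import GeneFeature, GenomeRecord, reverse_complement, write_genbank
from .guide_finder import IUPAC, PamSpec
from .suffix_index import MatchHit

DNA = "ACGT"

# Planted loci keep this much clearance from contig ends and each other so
# boundary effects never leak into truth tables unless a test asks for them.
PAD = 25

# ---------------------------------------------------------------------------
# naive oracles (intentionally simple; independent of the suffix-array path)
# ---------------------------------------------------------------------------


def naive_hamming_hits(
    records: list[GenomeRecord], pattern: str, d_max: int
) -> list[MatchHit]:
    """Brute-force double-strand scan: every window within Hamming d_max.

    N in the genome matches nothing (always a mismatch).
    """
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    w = len(pattern)
    hits: list[MatchHit] = []
    for rec in records:
        for strand, seq in (
            ("+", rec.sequence),
            ("-", reverse_complement(rec.sequence)),
        ):
            if len(seq) < w:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, w)
            dists = (windows != pat).sum(axis=1)
            for pos in np.nonzero(dists <= d_max)[0]:
                start = int(pos) if strand == "+" else rec.length - int(pos) - w
                hits.append(MatchHit(rec.contig_id, strand, start, int(dists[pos])))
    hits.sort()
    return hits


def naive_histogram(
    records: list[GenomeRecord], pattern: str, d_max: int
) -> list[int]:
    counts = [0] * (d_max + 1)
    for hit in naive_hamming_hits(records, pattern, d_max):
        counts[hit.mismatches] += 1
    return counts


def naive_pam_sites(
    records: list[GenomeRecord], pam: PamSpec, contig_id: str,
    start: int, end: int,
) -> list[tuple[str, int]]:
    """Overlapping IUPAC regex scan of both strands; forward pam_start."""
    rec = next(r for r in records if r.contig_id == contig_id)
    lp = len(pam.pattern)
    rx = re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in pam.pattern) + "))")
    sites: list[tuple[str, int]] = []
    for m in rx.finditer(rec.sequence):
        p = m.start()
        if start <= p and p + lp <= end:
            sites.append(("+", p))
    for m in rx.finditer(reverse_complement(rec.sequence)):
        p = rec.length - m.start() - lp
        if start <= p and p + lp <= end:
            sites.append(("-", p))
    return sorted(sites, key=lambda s: (s[1], s[0]))


_COMP = str.maketrans("ACGTN", "TGCAN")


def mirror_records(records: list[GenomeRecord]) -> list[GenomeRecord]:
    """Reverse-complement every contig, re-stranding and mirroring features."""
    out = []
    for rec in records:
        n = rec.length
        feats = [
            GeneFeature(
                locus_tag=f.locus_tag,
                gene_name=f.gene_name,
                protein_id=f.protein_id,
                strand="-" if f.strand == "+" else "+",
                intervals=tuple(sorted((n - e, n - s) for s, e in f.intervals)),
                codon_start_offset=f.codon_start_offset,
            )
            for f in rec.features
        ]
        out.append(
            GenomeRecord(rec.contig_id, reverse_complement(rec.sequence), feats)
        )
    return out


def naive_annotate(
    records: list[GenomeRecord],
    contig_id: str,
    start: int,
    end: int,
    pam: PamSpec | None = None,
    seed_length: int = 13,
    conversion: str = "C_to_T",
    window_min: int = 13,
    window_max: int = 20,
) -> list[dict]:
    """Naive end-to-end guide classification (full truth table for a region).

    Everything is recomputed with quadratic scans and direct slicing: regex
    PAM detection, sliding-window Hamming histograms, whole-genome edit
    application, and codon-by-codon retranslation with the local table.
    Returns one dict per guide: key, seed, offtargets, can_edit,
    introduces_stop.
    """
    pam = pam or PamSpec()
    rec = next(r for r in records if r.contig_id == contig_id)
    seq = rec.sequence
    sl = pam.spacer_length
    lp = len(pam.pattern)
    source, product = (
        ("C", "T") if conversion == "C_to_T" else ("A", "G")
    )
    out = []
    for strand, pam_start in naive_pam_sites(records, pam, contig_id, start, end):
        pam_end = pam_start + lp
        if strand == "+":
            sp_start, sp_end = pam_start - sl, pam_start
            if sp_start < 0:
                continue
            spacer = seq[sp_start:sp_end]
            w_lo, w_hi = pam_start - window_max, pam_start - window_min + 1
            fwd_source = source
        else:
            sp_start, sp_end = pam_end, pam_end + sl
            if sp_end > len(seq):
                continue
            spacer = reverse_complement(seq[sp_start:sp_end])
            w_lo, w_hi = pam_end + window_min - 1, pam_end + window_max
            fwd_source = source.translate(_COMP)
        if "N" in spacer:
            continue
        seed = spacer[-seed_length:]
        hist = naive_histogram(records, seed, 3)
        hist[0] -= 1  # self

        edited = [
            p for p in range(max(w_lo, 0), min(w_hi, len(seq)))
            if seq[p] == fwd_source
        ]
        fwd_product = product if strand == "+" else product.translate(_COMP)
        alt_seq = list(seq)
        for p in edited:
            alt_seq[p] = fwd_product
        alt_seq = "".join(alt_seq)

        can_edit = False
        introduces_stop = False
        for feat in rec.features:
            if not any(feat.overlaps(p, p + 1) for p in edited):
                continue
            ref_cds = feat.spliced_sequence(seq)
            alt_cds = feat.spliced_sequence(alt_seq)
            off = feat.codon_start_offset
            ref_aa = translate_naive(ref_cds[off:])
            alt_aa = translate_naive(alt_cds[off:])
            for ra, aa in zip(ref_aa, alt_aa):
                if ra != aa:
                    can_edit = True
                    if aa == "*":
                        introduces_stop = True
        out.append(
            {
                "key": (contig_id, strand, pam_start),
                "seed": seed,
                "offtargets": hist,
                "can_edit": can_edit,
                "introduces_stop": introduces_stop,
            }
        )
    return out


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------


@dataclass
class PlantedGuide:
    """One planted spacer+PAM site and what the pipeline must report for it."""

    contig_id: str
    strand: str
    pam_start: int
    seed_seq: str
    expected_offtargets: list[int] | None = None
    expect_stop: bool | None = None
    expect_can_edit: bool | None = None
    label: str = ""

    def key(self) -> tuple[str, str, int]:
        return (self.contig_id, self.strand, self.pam_start)


@dataclass
class FixtureTruth:
    rng_seed: int
    planted_guides: list[PlantedGuide] = field(default_factory=list)
    planted_features: list[GeneFeature] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rng_seed": self.rng_seed,
                "planted_guides": [vars(g).copy() for g in self.planted_guides],
                "planted_features": [
                    {
                        "locus_tag": f.locus_tag,
                        "gene_name": f.gene_name,
                        "strand": f.strand,
                        "intervals": list(f.intervals),
                    }
                    for f in self.planted_features
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

# Sense codons with no C anywhere / no C visible on the forward strand of a
# minus-strand gene; used as window filler so cytidine editing stays confined
# to the planted codon.
_FWD_FILLER = "GAT"  # Asp, no C
_FWD_NEUTRAL = "GGT"  # Gly, no C
_REV_FILLER = "AAT"  # forward bases; coding revcomp ATT = Ile, no forward C


class FixtureBuilder:
    """Mutable single-contig genome under construction.

    Build order matters: genes first, then planted guides/off-targets, then
    ``finalize()`` to freeze records and fill verified truth histograms.
    """

    def __init__(
        self,
        rng_seed: int,
        length: int,
        gc_content: float = 0.5,
        contig_id: str = "synth_1",
    ):
        if length < 200:
            raise ValueError("fixture genomes must be at least 200 bp")
        if not 0 < gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        self.rng = Random(rng_seed)
        self.rng_seed = rng_seed
        self.contig_id = contig_id
        half_gc = gc_content / 2
        half_at = (1 - gc_content) / 2
        self.seq = list(
            self.rng.choices(
                "ACGT", weights=[half_at, half_gc, half_gc, half_at], k=length
            )
        )
        self.features: list[GeneFeature] = []
        self.reserved: list[tuple[int, int]] = []
        self.truth = FixtureTruth(rng_seed=rng_seed)

    # -- placement ----------------------------------------------------------

    def _is_free(self, start: int, end: int) -> bool:
        if start < PAD or end > len(self.seq) - PAD:
            return False
        return all(
            end + PAD <= s or e + PAD <= start for s, e in self.reserved
        )

    def _find_free(self, size: int, align3_from: int | None = None) -> int:
        for _ in range(500):
            start = self.rng.randrange(PAD, len(self.seq) - size - PAD + 1)
            if align3_from is not None:
                start -= (start - align3_from) % 3
                if start < PAD:
                    continue
            if self._is_free(start, start + size):
                return start
        raise ValueError(
            f"cannot place a {size} bp element in a {len(self.seq)} bp fixture"
        )

    def _write(self, start: int, bases: str) -> None:
        self.seq[start : start + len(bases)] = list(bases)

    def _snapshot(self, start: int, end: int) -> list[str]:
        return self.seq[start:end]

    # -- genes --------------------------------------------------------------

    def add_gene(
        self,
        n_codons: int = 40,
        strand: str = "+",
        locus_tag: str | None = None,
    ) -> GeneFeature:
        """Plant a CDS: ATG + random sense codons + stop, length 3*(n_codons+2)."""
        sense = [c for c in CODON_LIST if CODON_TABLE_LOCAL[c] != "*"]
        body = "".join(self.rng.choice(sense) for _ in range(n_codons))
        coding = "ATG" + body + self.rng.choice(("TAA", "TAG", "TGA"))
        genomic = coding if strand == "+" else reverse_complement(coding)
        start = self._find_free(len(genomic))
        self._write(start, genomic)
        self.reserved.append((start, start + len(genomic)))
        feat = GeneFeature(
            locus_tag=locus_tag or f"SYN_{len(self.features) + 1:04d}",
            gene_name=None,
            strand=strand,
            intervals=((start, start + len(genomic)),),
        )
        self.features.append(feat)
        self.truth.planted_features.append(feat)
        return feat

    # -- guides -------------------------------------------------------------

    def plant_guide_site(
        self,
        strand: str = "+",
        spacer_length: int = 20,
        seed_length: int = 13,
        label: str = "",
    ) -> PlantedGuide:
        """Plant a bare NGG guide site in free (intergenic) space."""
        size = spacer_length + 3
        start = self._find_free(size)
        if strand == "+":
            pam_start = start + spacer_length
            self._write(pam_start + 1, "GG")
            seed = "".join(self.seq[pam_start - seed_length : pam_start])
        else:
            pam_start = start
            self._write(pam_start, "CC")  # forward CC = GG on the - strand
            seed = reverse_complement(
                "".join(self.seq[pam_start + 3 : pam_start + 3 + seed_length])
            )
        self.reserved.append((start, start + size))
        guide = PlantedGuide(
            self.contig_id, strand, pam_start, seed, label=label or "bare"
        )
        self.truth.planted_guides.append(guide)
        return guide

    def _mutate(self, seed: str, n_subs: int) -> str:
        out = list(seed)
        for pos in self.rng.sample(range(len(seed)), n_subs):
            out[pos] = self.rng.choice([b for b in DNA if b != out[pos]])
        return "".join(out)

    def plant_offtarget(
        self, guide: PlantedGuide, n_copies: int, mismatches: int,
        strand: str = "+",
    ) -> list[int]:
        """Plant seed copies at exactly ``mismatches`` substitutions.

        Each copy is verified with the naive scanner: planting must add
        exactly one position in the requested bin and disturb nothing else,
        otherwise the locus/variant is regenerated.  Returns the copies'
        start positions.
        """
        if not 0 <= mismatches <= 3:
            raise ValueError("mismatches must be in 0..3")
        seed = guide.seed_seq
        placed = []
        for _ in range(n_copies):
            before = self._current_histogram(seed)
            for _attempt in range(80):
                variant = self._mutate(seed, mismatches)
                written = variant if strand == "+" else reverse_complement(variant)
                start = self._find_free(len(written))
                saved = self._snapshot(start, start + len(written))
                self._write(start, written)
                after = self._current_histogram(seed)
                want = list(before)
                want[mismatches] += 1
                if after == want:
                    self.reserved.append((start, start + len(written)))
                    placed.append(start)
                    break
                self.seq[start : start + len(written)] = saved  # revert
            else:
                raise ValueError(
                    "could not plant an off-target copy without collisions"
                )
        return placed

    def plant_stop_site(self, codon: str, label: str = "") -> PlantedGuide:
        """Plant a gene + guide whose edit window hits the given codon.

        ``codon`` in {CAA, CAG, CGA} plants a forward gene with a C->T
        stop-gain layout; ``TGG`` plants a minus-strand gene edited through
        the opposite strand; ``CTG`` plants a synonymous-only (L->L) site.
        The codon sits 18 bases upstream of a plus-strand NGG PAM, inside
        the default 13-20 window, with every other window base non-C on the
        protospacer strand.
        """
        if codon not in ("CAA", "CAG", "CGA", "CTG", "TGG"):
            raise ValueError(f"unsupported planted codon {codon!r}")
        expect_stop = codon in ("CAA", "CAG", "CGA", "TGG")
        expect_edit = expect_stop  # CTG -> TTG is synonymous

        sense = [
            c for c in CODON_LIST
            if CODON_TABLE_LOCAL[c] != "*" and c not in ("TAA", "TAG", "TGA")
        ]
        spacer_codons = "".join(self.rng.choice(sense) for _ in range(4))
        if codon == "TGG":
            gene_strand = "-"
            planted_genomic = "CCA"  # coding TGG on the - strand
            window_filler = _REV_FILLER
            neutral = _REV_FILLER
            pam_codon = "AGG"  # coding CCT (Pro) on the - strand
            spacer_fill = reverse_complement(spacer_codons)
        else:
            gene_strand = "+"
            planted_genomic = codon
            window_filler = _FWD_FILLER
            neutral = _FWD_NEUTRAL
            pam_codon = "AGG"
            spacer_fill = spacer_codons

        # Cassette layout relative to the + strand PAM start p (frame-aligned):
        #   [p-21, p-18) filler whose last two bases pad the window start
        #   [p-18, p-15) the planted codon (18 bases upstream of the PAM)
        #   [p-15, p-12) neutral codon finishing the window
        #   [p-12, p)    four spacer codons outside the window
        #   [p,    p+3)  NGG PAM codon
        cassette = (
            window_filler
            + planted_genomic
            + neutral
            + spacer_fill
            + pam_codon
        )
        n_codons_interior = 12
        coding_len = 3 * (n_codons_interior + 2)

        # Gene: ATG + 2 leading codons + 8-codon cassette + 2 trailing + stop
        lead = "".join(self.rng.choice(sense) for _ in range(2))
        trail = "".join(self.rng.choice(sense) for _ in range(2))
        cassette_coding = (
            cassette if gene_strand == "+" else reverse_complement(cassette)
        )
        coding = "ATG" + lead + cassette_coding + trail + self.rng.choice(("TAA", "TAG"))
        assert len(coding) == coding_len
        genomic = coding if gene_strand == "+" else reverse_complement(coding)
        g_start = self._find_free(len(genomic))
        self._write(g_start, genomic)
        self.reserved.append((g_start, g_start + len(genomic)))
        # Forward-strand offset of the cassette within the genomic slice.
        lead_len = 3 + len(lead)
        if gene_strand == "+":
            cassette_start = g_start + lead_len
        else:
            cassette_start = g_start + (coding_len - lead_len - len(cassette))
        pam_start = cassette_start + 21

        feat = GeneFeature(
            locus_tag=f"SYN_{len(self.features) + 1:04d}",
            strand=gene_strand,
            intervals=((g_start, g_start + len(genomic)),),
        )
        self.features.append(feat)
        self.truth.planted_features.append(feat)

        seed = "".join(self.seq[pam_start - 13 : pam_start])
        guide = PlantedGuide(
            self.contig_id,
            "+",
            pam_start,
            seed,
            expect_stop=expect_stop,
            expect_can_edit=expect_edit,
            label=label or f"stop_site_{codon}",
        )
        self.truth.planted_guides.append(guide)
        return guide

    # -- assembly -----------------------------------------------------------

    def _current_histogram(self, seed: str) -> list[int]:
        rec = GenomeRecord(self.contig_id, "".join(self.seq), [])
        return naive_histogram([rec], seed, 3)

    def finalize(self) -> tuple[list[GenomeRecord], FixtureTruth]:
        """Freeze records and fill each planted guide's verified histogram.

        Expected off-target counts come from the naive scanner with the
        guide's own seed occurrence removed from the 0-mismatch bin.
        """
        record = GenomeRecord(self.contig_id, "".join(self.seq), self.features)
        for guide in self.truth.planted_guides:
            hist = naive_histogram([record], guide.seed_seq, 3)
            if hist[0] < 1:
                raise ValueError("planted guide lost its own seed occurrence")
            hist[0] -= 1
            guide.expected_offtargets = hist
        return [record], self.truth


# Local codon table for gene construction (kept independent of base_editor).
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_LIST = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
CODON_TABLE_LOCAL = dict(zip(CODON_LIST, _AAS))


def translate_naive(cds: str) -> str:
    """Direct codon-by-codon translation (oracle for the genetic code)."""
    return "".join(
        CODON_TABLE_LOCAL[cds[i : i + 3]]
        for i in range(0, len(cds) - len(cds) % 3, 3)
    )


# ---------------------------------------------------------------------------
# public fixture operations
# ---------------------------------------------------------------------------


def make_genome(
    rng_seed: int,
    length: int = 5000,
    gc_content: float = 0.5,
    n_genes: int = 3,
    path=None,
) -> tuple[list[GenomeRecord], FixtureTruth]:
    """Random background + ``n_genes`` planted CDSs; optional GenBank output."""
    builder = FixtureBuilder(rng_seed, length, gc_content)
    for _ in range(n_genes):
        builder.add_gene(n_codons=builder.rng.randint(20, 50))
    records, truth = builder.finalize()
    if path is not None:
        write_genbank(records, path)
    return records, truth
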