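"""Per-ORF genomic feature annotation.

Conservation statistic over a per-base track, nearest upstream promoter,
RNA-seq read support, genomic-context classification against a gene model
set, and a descriptive polyadenylation-hexamer scan of the region
downstream of the stop codon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    GenomicInterval,
    OrfRecord,
    SpeciesLocus,
    reverse_complement,
)

POLYA_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass
class ConservationTrack:
    """Per-base conservation scores in [0, 1] over a locus.

    ``scores[i]`` is the score of genome position ``offset + i``; NaN
    marks bases with no score.
    """

    scores: np.ndarray
    offset: int = 0
    chrom: str = "locus"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("conservation scores must lie in [0, 1]")

    @property
    def end(self) -> int:
        return self.offset + len(self.scores)

    @classmethod
    def from_bedgraph(cls, path, chrom: str, offset: int, length: int
                      ) -> "ConservationTrack":
        """Build a track from a bedGraph file (chrom, start, end, value)."""
        scores = np.full(length, np.nan)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                c, s, e, v = line.split()[:4]
                if c != chrom:
                    continue
                lo = max(int(s) - offset, 0)
                hi = min(int(e) - offset, length)
                if lo < hi:
                    scores[lo:hi] = float(v)
        return cls(scores=scores, offset=offset, chrom=chrom)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            scores = self.scores
            i = 0
            while i < len(scores):
                if not np.isfinite(scores[i]):
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(scores)
                    and np.isfinite(scores[j + 1])
                    and scores[j + 1] == scores[i]
                ):
                    j += 1
                fh.write(
                    f"{self.chrom}\t{self.offset + i}\t{self.offset + j + 1}"
                    f"\t{scores[i]:.4f}\n"
                )
                i = j + 1


def mean_conservation(track: ConservationTrack, interval: GenomicInterval
                      ) -> float:
    """Arithmetic mean of per-base scores over *interval*.

    Bases without a score are ignored; NaN is returned when no base of
    the interval has a score.
    """
    if interval.start < track.offset or interval.end > track.end:
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) outside track "
            f"extent [{track.offset}, {track.end})"
        )
    window = track.scores[interval.start - track.offset : interval.end - track.offset]
    if not np.isfinite(window).any():
        return float("nan")
    return float(np.nanmean(window))


@dataclass(frozen=True)
class PromoterCall:
    """A predicted transcription start site with a confidence score."""

    position: int
    score: float
    strand: str
    chrom: str = "locus"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("promoter score must lie in [0, 1]")


def read_promoter_bed(path) -> list[PromoterCall]:
    """Read promoter calls from BED6 (TSS = start for +, end-1 for -)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            chrom, start, end, _name, score, strand = f[:6]
            pos = int(start) if strand == "+" else int(end) - 1
            calls.append(
                PromoterCall(position=pos, score=float(score), strand=strand,
                             chrom=chrom)
            )
    return calls


def nearest_upstream_promoter(
    promoters: Sequence[PromoterCall], orf: OrfRecord
) -> tuple[int, float] | None:
    """Distance and score of the closest same-strand upstream promoter.

    Upstream means at or 5' of the ORF's ATG on the ORF strand; the
    distance is the non-negative nucleotide separation. Ties on distance
    are broken by the higher score. Returns None when no same-strand
    upstream promoter exists.
    """
    atg = orf.start_codon_position
    best: tuple[int, float] | None = None
    for p in promoters:
        if p.strand != orf.strand or p.chrom != orf.interval.chrom:
            continue
        dist = atg - p.position if orf.strand == "+" else p.position - atg
        if dist < 0:
            continue
        if best is None or dist < best[0] or (dist == best[0] and p.score > best[1]):
            best = (dist, p.score)
    return best


@dataclass
class ReadSupport:
    n_reads: int
    breadth_pct: float  # % of ORF bases covered by >= 1 read

    def __post_init__(self) -> None:
        if self.n_reads == 0 and self.breadth_pct != 0.0:
            raise ValueError("zero reads implies zero breadth")


def read_support(reads: Sequence[GenomicInterval], orf: OrfRecord) -> ReadSupport:
    """Count reads overlapping an ORF and the breadth of >=1x coverage."""
    iv = orf.interval
    covered = np.zeros(len(iv), dtype=bool)
    n = 0
    for r in reads:
        if r.chrom != iv.chrom:
            continue
        lo = max(r.start, iv.start) - iv.start
        hi = min(r.end, iv.end) - iv.start
        if lo < hi:
            n += 1
            covered[lo:hi] = True
    breadth = 100.0 * covered.sum() / len(iv) if n else 0.0
    return ReadSupport(n_reads=n, breadth_pct=float(breadth))


def read_bed_intervals(path, default_strand: str = "+") -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            strand = f[5] if len(f) > 5 else default_strand
            intervals.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), strand)
            )
    return intervals


# ---------------------------------------------------------------------------
# genomic context classification

CONTEXT_CATEGORIES = (
    "cds_overlap_same_frame",
    "cds_overlap_diff_frame",
    "utr5",
    "utr3",
    "lncRNA",
    "intergenic",
)


@dataclass(frozen=True)
class ContextLabel:
    category: str
    orientation: str  # sense | antisense
    host_feature_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CONTEXT_CATEGORIES:
            raise ValueError(f"unknown context category {self.category!r}")


@dataclass(frozen=True)
class GeneFeature:
    """One feature of a gene model (GFF3-style)."""

    feature_id: str
    feature_type: str  # CDS | five_prime_UTR | three_prime_UTR | lncRNA | exon
    interval: GenomicInterval
    phase: int = 0  # for CDS: bases to skip before the first full codon


_LNCRNA_TYPES = {"lncRNA", "lnc_RNA", "ncRNA"}
_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}


def read_gff3_features(path) -> list[GeneFeature]:
    """Read CDS/UTR/lncRNA/exon features from a GFF3 file."""
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, phase, attrs = f[:9]
            m = re.search(r"ID=([^;]+)", attrs)
            fid = m.group(1) if m else f"{ftype}:{start}-{end}"
            features.append(
                GeneFeature(
                    feature_id=fid,
                    feature_type=ftype,
                    interval=GenomicInterval(chrom, int(start) - 1, int(end),
                                             strand if strand in "+-" else "+"),
                    phase=int(phase) if phase.isdigit() else 0,
                )
            )
    return features


def _frame_congruent(orf: OrfRecord, cds: GeneFeature) -> bool:
    """True when the ORF reads in the same frame as the host CDS."""
    if orf.strand == "+":
        orf_first = orf.interval.start
        cds_first = cds.interval.start + cds.phase
        return (orf_first - cds_first) % 3 == 0
    orf_first = orf.interval.end - 1  # first base read on '-'
    cds_first = cds.interval.end - 1 - cds.phase
    return (cds_first - orf_first) % 3 == 0


def classify_context(orf: OrfRecord, features: Sequence[GeneFeature]
                     ) -> ContextLabel:
    """Assign one genomic-context category to an ORF.

    Priority when features overlap: CDS > UTR > lncRNA > intergenic.
    Among equal-priority overlaps the one with the largest overlap wins.
    Orientation is sense when the ORF and host strands agree.
    """
    def best_overlap(types: set[str]) -> GeneFeature | None:
        hits = [
            ft for ft in features
            if ft.feature_type in types and ft.interval.overlaps(orf.interval)
        ]
        if not hits:
            return None
        return max(hits, key=lambda ft: ft.interval.overlap_length(orf.interval))

    cds = best_overlap({"CDS"})
    if cds is not None:
        orientation = "sense" if cds.interval.strand == orf.strand else "antisense"
        if orientation == "sense" and _frame_congruent(orf, cds):
            cat = "cds_overlap_same_frame"
        else:
            cat = "cds_overlap_diff_frame"
        return ContextLabel(cat, orientation, cds.feature_id)
    utr5 = best_overlap(_UTR5_TYPES)
    utr3 = best_overlap(_UTR3_TYPES)
    utr = None
    if utr5 and utr3:
        utr = max(
            (utr5, utr3), key=lambda ft: ft.interval.overlap_length(orf.interval)
        )
    else:
        utr = utr5 or utr3
    if utr is not None:
        cat = "utr5" if utr.feature_type in _UTR5_TYPES else "utr3"
        orientation = "sense" if utr.interval.strand == orf.strand else "antisense"
        return ContextLabel(cat, orientation, utr.feature_id)
    lnc = best_overlap(_LNCRNA_TYPES)
    if lnc is not None:
        orientation = "sense" if lnc.interval.strand == orf.strand else "antisense"
        return ContextLabel("lncRNA", orientation, lnc.feature_id)
    return ContextLabel("intergenic", "sense", None)


# ---------------------------------------------------------------------------
# polyadenylation signal scan (descriptive only; not a cascade filter)


def polya_scan(locus: SpeciesLocus, orf: OrfRecord, window_nt: int = 150
               ) -> list[int]:
    """Offsets of polyA hexamers (AATAAA/ATTAAA) downstream of the stop.

    The window starts at the first base after the ORF interval on the ORF
    strand; offsets are 0-based within the window. Descriptive annotation
    only — the filter cascade never uses it.
    """
    if window_nt < 6:
        raise ValueError("window_nt must be >= 6")
    seq = locus.sequence
    if orf.strand == "+":
        lo = orf.interval.end - locus.genome_offset
        window = seq[lo : lo + window_nt]
    else:
        hi = orf.interval.start - locus.genome_offset
        window = reverse_complement(seq[max(0, hi - window_nt) : hi])
    hits = []
    for i in range(len(window) - 5):
        if window[i : i + 6] in POLYA_HEXAMERS:
            hits.append(i)
    return hits
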