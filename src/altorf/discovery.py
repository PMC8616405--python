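"""ATG-initiated ORF discovery on both strands of a genomic locus.

The scanner enumerates candidate altORFs: open reading frames that begin
with ATG, run uninterrupted to a stop codon, and encode at least
``min_aa`` residues (30 by default, the conventional altORF minimum).
Each candidate is annotated with its Kozak context and a PWM-based
translation-initiation strength score, and candidates matching canonical
Hox proteins can be removed to avoid re-discovering known isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    STOP_CODONS,
    GenomicInterval,
    OrfRecord,
    SpeciesLocus,
    reverse_complement,
    translate_codons,
)

logger = logging.getLogger(__name__)

# Kozak context layout: 6 bases upstream, the ATG, one base downstream.
KOZAK_POSITIONS = (-6, -5, -4, -3, -2, -1, 4)
KOZAK_CONTEXT_LENGTH = 10


@dataclass
class KozakModel:
    """Position-weight model for translation-initiation context strength.

    ``weights`` maps each scored position (-6..-1 and +4; the ATG itself is
    fixed) to per-nucleotide weights. Scores are min-max normalized so the
    consensus context scores 1 and the anti-consensus context scores 0.
    An N contributes the position minimum (no evidence of a good context).
    """

    weights: dict[int, dict[str, float]]

    def __post_init__(self) -> None:
        missing = set(KOZAK_POSITIONS) - set(self.weights)
        if missing:
            raise ValueError(f"Kozak model missing positions: {sorted(missing)}")
        self.min_score = sum(min(w.values()) for w in self.weights.values())
        self.max_score = sum(max(w.values()) for w in self.weights.values())
        if not self.max_score > self.min_score:
            raise ValueError("degenerate Kozak model: max_score <= min_score")

    @property
    def consensus_context(self) -> str:
        up = "".join(
            max(self.weights[p], key=self.weights[p].get) for p in range(-6, 0)
        )
        down = max(self.weights[4], key=self.weights[4].get)
        return up + "ATG" + down

    @property
    def anti_consensus_context(self) -> str:
        up = "".join(
            min(self.weights[p], key=self.weights[p].get) for p in range(-6, 0)
        )
        down = min(self.weights[4], key=self.weights[4].get)
        return up + "ATG" + down

    @classmethod
    def from_tsv(cls, path) -> "KozakModel":
        """Load a PWM from a TSV with columns position, A, C, G, T."""
        df = pd.read_csv(path, sep="\t")
        weights = {
            int(row["position"]): {nt: float(row[nt]) for nt in "ACGT"}
            for _, row in df.iterrows()
        }
        return cls(weights)

    @classmethod
    def default(cls) -> "KozakModel":
        """Drosophila-style consensus PWM shipped with the package."""
        with resources.as_file(
            resources.files("altorf.data") / "kozak_pwm.tsv"
        ) as path:
            return cls.from_tsv(path)


def score_kozak(context: str, model: KozakModel) -> float:
    """Score a 10-mer Kozak context in [0, 1] under *model*.

    The raw score is the sum of position weights over the scored positions
    (the three ATG bases are skipped), min-max normalized by the model's
    best and worst achievable contexts.
    """
    context = context.upper()
    if len(context) != KOZAK_CONTEXT_LENGTH:
        raise ValueError(
            f"Kozak context must be {KOZAK_CONTEXT_LENGTH} nt, got {len(context)}"
        )
    raw = 0.0
    for pos in KOZAK_POSITIONS:
        idx = pos + 6 if pos < 0 else 9  # +4 is the final base
        nt = context[idx]
        w = model.weights[pos]
        raw += w.get(nt, min(w.values())) if nt != "N" else min(w.values())
    return (raw - model.min_score) / (model.max_score - model.min_score)


def extract_kozak(locus: SpeciesLocus, orf: OrfRecord) -> str:
    """Strand-oriented 10-mer context around an ORF's start codon.

    Covers positions -6..-1, the ATG and +4 read 5'->3' on the ORF strand;
    positions outside the locus are padded with N.
    """
    seq = locus.sequence
    n = len(seq)
    if orf.strand == "+":
        a = orf.interval.start - locus.genome_offset
        lo, hi = a - 6, a + 4
        window = seq[max(lo, 0) : min(hi, n)]
        return "N" * max(0, -lo) + window + "N" * max(0, hi - n)
    rc = reverse_complement(seq)
    a = n - (orf.interval.end - locus.genome_offset)
    lo, hi = a - 6, a + 4
    window = rc[max(lo, 0) : min(hi, n)]
    return "N" * max(0, -lo) + window + "N" * max(0, hi - n)


def _scan_strand(
    seq: str, min_aa: int, require_stop: bool, atg_policy: str
) -> list[tuple[int, int, int, str, bool]]:
    """Scan the three frames of one strand of *seq*.

    Returns tuples of (start, end, frame, peptide, has_terminal_stop) in
    the coordinates of *seq* (which is the reverse complement for the
    minus strand). ``end`` includes the stop codon when present.
    """
    results = []
    n = len(seq)
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, n - 2, 3)]
        seg_start = 0  # codon index of current stop-to-stop segment
        ncod = len(codons)
        while seg_start < ncod:
            # find the closing stop of this segment
            stop_idx = None
            for j in range(seg_start, ncod):
                if codons[j] in STOP_CODONS:
                    stop_idx = j
                    break
            seg_end = stop_idx if stop_idx is not None else ncod
            if stop_idx is None and require_stop:
                break  # open segment at locus edge: excluded
            for i in range(seg_start, seg_end):
                if codons[i] != "ATG":
                    continue
                aa_len = seg_end - i
                if aa_len < min_aa:
                    break  # later ATGs in the segment are shorter still
                span = codons[i:seg_end]
                if any("N" in c for c in span):
                    logger.debug(
                        "discarding candidate at codon %d frame %d: N in codon",
                        i,
                        frame,
                    )
                    continue
                start = frame + 3 * i
                end = frame + 3 * (seg_end + (1 if stop_idx is not None else 0))
                peptide = translate_codons("".join(span))
                results.append((start, end, frame, peptide, stop_idx is not None))
                if atg_policy == "first":
                    break
            if stop_idx is None:
                break
            seg_start = stop_idx + 1
    return results


def scan_orfs(
    locus: SpeciesLocus,
    min_aa: int = 30,
    require_stop: bool = True,
    atg_policy: str = "first",
    kozak_model: KozakModel | None = None,
) -> list[OrfRecord]:
    """Enumerate ATG-initiated ORFs of >= *min_aa* codons on both strands.

    One ORF is reported per (strand, frame, stop-to-stop segment): the
    5'-most qualifying ATG in the segment (``atg_policy='first'``), or
    every qualifying ATG (``atg_policy='all'``). Antisense ORF ids carry
    an ``as`` prefix. Codons containing N are neither start nor stop and
    invalidate any candidate that spans them. With ``require_stop`` the
    ORF must terminate in a stop codon within the locus and the reported
    interval includes that stop.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if atg_policy not in ("first", "all"):
        raise ValueError("atg_policy must be 'first' or 'all'")
    seq = locus.sequence
    n = len(seq)
    if n == 0:
        raise ValueError("locus sequence is empty")

    raw: list[tuple[GenomicInterval, int, str, bool]] = []
    for start, end, frame, pep, has_stop in _scan_strand(
        seq, min_aa, require_stop, atg_policy
    ):
        iv = GenomicInterval(
            locus.chrom,
            locus.genome_offset + start,
            locus.genome_offset + end,
            "+",
        )
        raw.append((iv, frame, pep, has_stop))
    rc = reverse_complement(seq)
    for start, end, frame, pep, has_stop in _scan_strand(
        rc, min_aa, require_stop, atg_policy
    ):
        iv = GenomicInterval(
            locus.chrom,
            locus.genome_offset + n - end,
            locus.genome_offset + n - start,
            "-",
        )
        raw.append((iv, frame, pep, has_stop))

    records: list[OrfRecord] = []
    counters = {"+": 0, "-": 0}
    raw.sort(key=lambda r: (r[0].start, r[0].end, r[0].strand))
    for iv, frame, pep, has_stop in raw:
        counters[iv.strand] += 1
        prefix = "ORF" if iv.strand == "+" else "ORFas"
        orf = OrfRecord(
            orf_id=f"{prefix}{counters[iv.strand]}",
            species_id=locus.species_id,
            interval=iv,
            frame=frame,
            aa_length=len(pep),
            peptide=pep,
            has_terminal_stop=has_stop,
            nt_sequence=_orf_nt(locus, iv, has_stop),
        )
        orf.kozak_context = extract_kozak(locus, orf)
        if kozak_model is not None:
            orf.kozak_score = score_kozak(orf.kozak_context, kozak_model)
        records.append(orf)
    return records


def _orf_nt(locus: SpeciesLocus, iv: GenomicInterval, has_stop: bool) -> str:
    lo = iv.start - locus.genome_offset
    hi = iv.end - locus.genome_offset
    nt = locus.sequence[lo:hi]
    if iv.strand == "-":
        nt = reverse_complement(nt)
    return nt[:-3] if has_stop else nt  # coding part only, stop dropped


def filter_hox_matches(
    orfs: Sequence[OrfRecord],
    hox_proteins: Iterable[str],
    min_identity: float = 0.95,
    min_span_aa: int = 30,
) -> tuple[list[OrfRecord], list[OrfRecord]]:
    """Partition ORFs into (kept, removed) by similarity to Hox proteins.

    An ORF is removed when its peptide has a local alignment to any of
    the supplied Hox protein sequences with identity >= *min_identity*
    over >= *min_span_aa* aligned residues — a stand-in for the BLASTP
    screen used to drop candidates that are fragments of conventional
    Hox isoforms.
    """
    from .comparative import align_peptides

    hox = [p.upper() for p in hox_proteins]
    if not hox:
        raise ValueError("hox_proteins must be non-empty")
    kept, removed = [], []
    for orf in orfs:
        hit = False
        for protein in hox:
            aln = align_peptides(orf.peptide, protein)
            if aln.aligned_span >= min_span_aa and aln.identity >= min_identity:
                hit = True
                break
        (removed if hit else kept).append(orf)
    return kept, removed


def orfs_to_frame(orfs: Sequence[OrfRecord]) -> pd.DataFrame:
    """Tabulate ORF records (one row per ORF) for TSV export."""
    return pd.DataFrame(
        {
            "orf_id": [o.orf_id for o in orfs],
            "species": [o.species_id for o in orfs],
            "chrom": [o.interval.chrom for o in orfs],
            "start": [o.interval.start for o in orfs],
            "end": [o.interval.end for o in orfs],
            "strand": [o.strand for o in orfs],
            "frame": [o.frame for o in orfs],
            "aa_length": [o.aa_length for o in orfs],
            "kozak_context": [o.kozak_context for o in orfs],
            "kozak_score": [o.kozak_score for o in orfs],
        }
    )
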