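"""Cross-species comparison of ORF peptides.

Implements local peptide alignment (Smith-Waterman with BLOSUM62 and
affine gaps, via Biopython's pairwise aligner), Karlin-Altschul E-values,
single-linkage ortholog grouping seeded by shared k-mers, evolutionary age
assignment from a species divergence-time table, and pairwise dN/dS by
the Nei-Gojobori (1986) counting method with Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .core import STOP_CODONS, OrfRecord, translate_codons

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# BLAST-style affine gap cost: a gap of length g costs open + g * extend.
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters for converting raw scores to E-values.

    Defaults are the standard gapped BLOSUM62 constants; ``m`` and ``n``
    are the effective query and database lengths.
    """

    K: float = 0.041
    lam: float = 0.267
    m: int = 100
    n: int = 100

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    aligned_span: int


def _make_aligner(gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gapped residue costs open+extend, each further residue extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner(DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)


def _validate_peptide(p: str) -> str:
    p = p.upper()
    bad = set(p) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid symbols in peptide: {sorted(bad)}")
    return p


def evalue(score: float, params: EvalueParams) -> float:
    """Karlin-Altschul expected number of hits: E = K*m*n*exp(-lambda*S)."""
    return params.K * params.m * params.n * math.exp(-params.lam * score)


def align_peptides(
    a: str,
    b: str,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    params: EvalueParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal local alignment of two peptides under BLOSUM62 affine gaps.

    Identity is the fraction of identical residue pairs over all alignment
    columns (gap columns included in the span). A best score <= 0 is
    reported as a no-hit: zero score, zero span, E-value infinity.
    """
    a, b = _validate_peptide(a), _validate_peptide(b)
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if (gap_open, gap_extend) == (DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND):
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    params = params or EvalueParams(m=len(a), n=len(b))
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, math.inf, 0.0, 0)
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = span = 0
    prev_a = prev_b = None
    for (qs, qe), (ts, te) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            span += (qs - prev_a) + (ts - prev_b)  # gap columns
        span += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
        prev_a, prev_b = qe, te
    bits = (params.lam * score - math.log(params.K)) / math.log(2)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bits,
        evalue=evalue(score, params),
        identity=matches / span if span else 0.0,
        aligned_span=span,
    )


# ---------------------------------------------------------------------------
# ortholog grouping


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str]]  # (species_id, orf_id)
    age_my: float = float("nan")

    @property
    def species_count(self) -> int:
        return len({sp for sp, _ in self.members})


def _kmer_set(peptide: str, k: int) -> set[str]:
    return {peptide[i : i + k] for i in range(len(peptide) - k + 1)}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_ortholog_groups(
    per_species_orfs: Mapping[str, Sequence[OrfRecord]],
    e_max: float = 1e-5,
    seed_k: int = 4,
) -> list[OrthologGroup]:
    """Cluster ORFs across species into single-linkage ortholog groups.

    Cross-species peptide pairs sharing at least one length-``seed_k``
    word are aligned; pairs with E <= *e_max* become edges and connected
    components become groups. Every ORF lands in exactly one group
    (singletons included). Pairs without a shared seed word cannot reach
    E <= 1e-5 for peptides of this size and are skipped.
    """
    if not per_species_orfs:
        raise ValueError("need at least one species")
    entries: list[tuple[str, OrfRecord]] = []
    for sp, orfs in per_species_orfs.items():
        entries.extend((sp, o) for o in orfs)
    uf = _UnionFind(len(entries))

    kmer_index: dict[str, list[int]] = {}
    for idx, (_, orf) in enumerate(entries):
        for kmer in _kmer_set(orf.peptide, seed_k):
            kmer_index.setdefault(kmer, []).append(idx)

    candidate_pairs: set[tuple[int, int]] = set()
    for idxs in kmer_index.values():
        for i, j in itertools.combinations(idxs, 2):
            if entries[i][0] != entries[j][0]:  # cross-species only
                candidate_pairs.add((i, j) if i < j else (j, i))

    for i, j in candidate_pairs:
        if uf.find(i) == uf.find(j):
            continue
        a, b = entries[i][1].peptide, entries[j][1].peptide
        hit = align_peptides(a, b, params=EvalueParams(m=len(a), n=len(b)))
        if hit.evalue <= e_max:
            uf.union(i, j)

    components: dict[int, list[int]] = {}
    for idx in range(len(entries)):
        components.setdefault(uf.find(idx), []).append(idx)
    groups = []
    for gid, idxs in enumerate(sorted(components.values(), key=min), start=1):
        members = [(entries[i][0], entries[i][1].orf_id) for i in idxs]
        groups.append(OrthologGroup(group_id=f"OG{gid:04d}", members=members))
    return groups


# ---------------------------------------------------------------------------
# divergence times and group age


@dataclass
class DivergenceTable:
    """Symmetric species divergence times in million years (My)."""

    times: dict[frozenset, float] = field(default_factory=dict)

    def set(self, a: str, b: str, my: float) -> None:
        if my < 0:
            raise ValueError("divergence time must be >= 0")
        self.times[frozenset((a, b))] = my

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = frozenset((a, b))
        if key not in self.times:
            raise KeyError(f"no divergence time for species pair ({a}, {b})")
        return self.times[key]

    @classmethod
    def from_tsv(cls, path) -> "DivergenceTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for _, row in df.iterrows():
            table.set(str(row["species_a"]), str(row["species_b"]), float(row["my"]))
        return table

    @classmethod
    def default(cls) -> "DivergenceTable":
        """Drosophila 11-species divergence fixture shipped with the package."""
        with resources.as_file(
            resources.files("altorf.data") / "divergence_my.tsv"
        ) as path:
            return cls.from_tsv(path)


def group_age(group: OrthologGroup, table: DivergenceTable) -> float:
    """Minimal evolutionary age of a group in My.

    The age is the divergence time of the two most distant species that
    contain a member; a single-species group has age 0.
    """
    species = sorted({sp for sp, _ in group.members})
    if len(species) < 2:
        return 0.0
    return max(table.get(a, b) for a, b in itertools.combinations(species, 2))


# ---------------------------------------------------------------------------
# codon alignment and NG86 dN/dS

_GLOBAL_ALIGNER = PairwiseAligner(mode="global")
_GLOBAL_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_GLOBAL_ALIGNER.open_gap_score = -12
_GLOBAL_ALIGNER.extend_gap_score = -1


def codon_align(nt_a: str, nt_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment of two coding sequences.

    The peptides are aligned globally (Needleman-Wunsch, BLOSUM62) and the
    protein alignment is back-threaded onto the codons, so gaps come in
    whole-codon units. Input sequences are the coding parts only (no
    terminal stop); lengths must be multiples of 3.
    """
    pep_a, pep_b = translate_codons(nt_a), translate_codons(nt_b)
    aln = _GLOBAL_ALIGNER.align(pep_a, pep_b)[0]
    col_a, col_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(col_a, col_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(nt_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(nt_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


@dataclass
class DndsResult:
    dN: float
    dS: float
    omega: float | None
    caution_flag: str  # ok | dS_too_small | dS_too_large

    @property
    def reliable(self) -> bool:
        return self.caution_flag == "ok"


_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_AA[_stop] = "*"
_NT = "ACGT"


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at *pos* that are synonymous.

    Changes creating a stop codon count as nonsynonymous.
    """
    aa = _CODON_AA[codon]
    syn = 0
    for nt in _NT:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if _CODON_AA[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon."""
    s = sum(_syn_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways.

    For codons differing at k positions all k! orderings of the single-nt
    steps are considered; pathways passing through a stop codon are
    excluded (unless every pathway does, in which case all are used).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_AA[nxt] == "*":
                via_stop = True
            if _CODON_AA[nxt] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, via_stop))
    usable = [(s, n) for s, n, stop in paths if not stop]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def dnds_ng86(
    aligned_a: str, aligned_b: str, min_codons: int = 10
) -> DndsResult:
    """Pairwise dN/dS by Nei-Gojobori (1986) counting with JC correction.

    Takes a codon alignment (gaps as ``---``); columns with a gap or a
    stop codon in either sequence are skipped. Flags the result when dS
    is outside the trustworthy range: ``dS_too_small`` below 0.01
    (sequences too close), ``dS_too_large`` above 2 or when the JC
    correction diverges (sequences too divergent).
    """
    if len(aligned_a) != len(aligned_b) or len(aligned_a) % 3 != 0:
        raise ValueError("aligned sequences must have equal length, multiple of 3")
    S = N = Sd = Nd = 0.0
    n_pairs = 0
    for i in range(0, len(aligned_a), 3):
        c1, c2 = aligned_a[i : i + 3], aligned_b[i : i + 3]
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        if _CODON_AA[c1] == "*" or _CODON_AA[c2] == "*":
            continue
        n_pairs += 1
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_pairs < min_codons:
        raise ValueError(
            f"only {n_pairs} ungapped codon pairs; need >= {min_codons}"
        )
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if math.isinf(dS) or dS > 2.0:
        flag = "dS_too_large"
    elif dS < 0.01:
        flag = "dS_too_small"
    else:
        flag = "ok"
    omega = None
    if dS > 0 and math.isfinite(dS) and math.isfinite(dN):
        omega = dN / dS
    return DndsResult(dN=dN, dS=dS, omega=omega, caution_flag=flag)


def mean_pairwise_omega(
    ref: OrfRecord,
    partners: Iterable[OrfRecord],
    min_codons: int = 10,
) -> DndsResult | None:
    """Mean NG86 result over pairwise comparisons of *ref* with partners.

    Pairs whose dS falls outside the trustworthy range are kept in the
    flag bookkeeping but omega is averaged over reliable pairs only.
    Returns None when there are no partners.
    """
    results = []
    for other in partners:
        try:
            aln = codon_align(ref.nt_sequence, other.nt_sequence)
            results.append(dnds_ng86(*aln, min_codons=min_codons))
        except ValueError:
            continue
    if not results:
        return None
    reliable = [r for r in results if r.reliable and r.omega is not None]
    if reliable:
        return DndsResult(
            dN=float(np.mean([r.dN for r in reliable])),
            dS=float(np.mean([r.dS for r in reliable])),
            omega=float(np.mean([r.omega for r in reliable])),
            caution_flag="ok",
        )
    flags = [r.caution_flag for r in results]
    flag = max(set(flags), key=flags.count)
    return DndsResult(
        dN=float(np.mean([r.dN for r in results if math.isfinite(r.dN)] or [0.0])),
        dS=float(np.mean([r.dS for r in results if math.isfinite(r.dS)] or [0.0])),
        omega=None,
        caution_flag=flag,
    )
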