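"""Short linear motif (ELM/SLiM) scanning and the per-ORF ELM score.

ELM classes are regular expressions over the amino-acid alphabet. The
scan counts every distinct match start position (overlapping matches
included). The ELM score of an ORF normalizes its motif content by how
common each motif class is across the whole initial prediction set and
by peptide length:

    score_i = 1e6 * ( sum_j  n_{j,i} / n_{j,all} ) / L_i

where n_{j,i} is the count of motif class j in ORF i, n_{j,all} its
total count over all initially predicted ORFs, and L_i the peptide
length in residues. Restricting the class set to motifs present in the
Hox proteins Ubx/AbdA/AbdB focuses the scan on interaction motifs these
proteins could share with candidate altORF peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .comparative import AA_ALPHABET


@dataclass
class MotifPattern:
    """One ELM class: an identifier, a functional class and a regex."""

    elm_id: str
    elm_class: str
    pattern: str
    _compiled: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # Wrap in a lookahead so finditer yields every (overlapping) start.
        self._compiled = re.compile(f"(?=({self.pattern}))")

    def count_matches(self, peptide: str) -> int:
        return sum(1 for _ in self._compiled.finditer(peptide))

    def match_positions(self, peptide: str) -> list[int]:
        return [m.start() for m in self._compiled.finditer(peptide)]


def read_patterns_tsv(path) -> list[MotifPattern]:
    """Load motif classes from a TSV (elm_id, elm_class, regex)."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifPattern(str(r["elm_id"]), str(r["elm_class"]), str(r["regex"]))
        for _, r in df.iterrows()
    ]


def default_patterns() -> list[MotifPattern]:
    """ELM-style demonstration pattern set shipped with the package."""
    with resources.as_file(
        resources.files("altorf.data") / "elm_patterns_demo.tsv"
    ) as path:
        return read_patterns_tsv(path)


@dataclass
class MotifSummary:
    orf_id: str
    counts: dict[str, int]

    @property
    def total_elms(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_types(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


def select_hox_elms(
    patterns: Sequence[MotifPattern], hox_proteins: Iterable[str]
) -> list[MotifPattern]:
    """Keep motif classes with at least one match in a Hox protein."""
    hox = [p.upper() for p in hox_proteins]
    return [pat for pat in patterns if any(pat.count_matches(h) for h in hox)]


def scan_motifs(peptide: str, patterns: Sequence[MotifPattern]) -> MotifSummary:
    """Count matches of every pattern in *peptide* (overlaps included)."""
    peptide = peptide.upper()
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residues in peptide: {sorted(bad)}")
    return MotifSummary(
        orf_id="", counts={p.elm_id: p.count_matches(peptide) for p in patterns}
    )


def global_motif_counts(summaries: Iterable[MotifSummary]) -> dict[str, int]:
    """Total occurrences of each motif class over the initial ORF set.

    Must be computed over the full pre-filter prediction set: the ELM
    score's denominator is defined against that population.
    """
    totals: dict[str, int] = {}
    for s in summaries:
        for elm_id, c in s.counts.items():
            totals[elm_id] = totals.get(elm_id, 0) + c
    return totals


def elm_score(
    summary: MotifSummary, globals_: Mapping[str, int], aa_length: int
) -> float:
    """The ELM density score of one ORF (full precision).

    Reports use ``round(score)``; keep this value for computation.
    """
    if aa_length <= 0:
        raise ValueError("aa_length must be positive")
    total = 0.0
    for elm_id, count in summary.counts.items():
        if count == 0:
            continue
        if elm_id not in globals_ or globals_[elm_id] < count:
            raise ValueError(
                f"global count missing or smaller than ORF count for {elm_id}"
            )
        total += count / globals_[elm_id]
    return 1e6 * total / aa_length
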