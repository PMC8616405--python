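"""Multi-species synthetic locus bundles with planted altORFs.

The generator builds an ancestral locus containing planted ORFs inside
insulated neighborhoods, evolves it into each simulated species under a
per-My substitution probability with purifying selection on planted
coding regions, and emits the full input set the annotation pipeline
consumes: per-species FASTA, a conservation track, promoter calls, read
alignments, a gene-model stub, reference flags and a truth table.

Every planted ORF carries an ``intended_fate``: ``none`` for a
pass-everything plant, or the name of the cascade step designed to
remove it (a single-fault decoy). Neighborhood construction keeps the
regions around planted starts free of spurious start codons so a plant
is always recovered exactly by the scanner; the filler between
neighborhoods is unconstrained random sequence and yields background
ORFs with background-level conservation, no promoter support and no
reads.

Sequence layout per neighborhood (in plant-strand orientation)::

    [stop-insulator][upstream pad][Kozak 6-mer][ATG][body][TAA][pad][stop-insulator]

The insulator ``TTAATTAATTAA`` contains stop codons in all six frames,
so no reading frame crosses a neighborhood boundary. Pads are drawn from
{A,C,G} (no T), which excludes start and stop codons on both strands;
bodies encode random peptides over a diverse alphabet with codons chosen
to avoid ATG (and where possible CAT) at every offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .comparative import DivergenceTable
from .core import GenomicInterval, SpeciesLocus, reverse_complement, STOP_CODONS
from .discovery import KozakModel
from .features import ConservationTrack, PromoterCall

INSULATOR = "TTAATTAATTAA"  # stop codons in all 6 frames; self-revcomp
CHROM = "simlocus"

from Bio.Seq import Seq as _Seq  # noqa: E402

_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_AA_TO_ANY: dict[str, list[str]] = {}
for _c in _ALL_CODONS:
    _a = str(_Seq(_c).translate())
    if _a != "*":
        _AA_TO_ANY.setdefault(_a, []).append(_c)

FATES = (
    "none", "hox_removal", "min_species", "min_age",
    "conservation", "promoter", "kozak", "read_support",
)


@dataclass
class PlantSpec:
    """Blueprint of one planted ORF and its intended cascade fate."""

    plant_id: str
    aa_length: int = 40
    strand: str = "+"
    target_species: tuple[str, ...] = ()
    omega: float = 0.1
    kozak_strength: str = "strong"  # strong | weak
    promoter_distance: int = 100
    promoter_score: float = 0.92
    conservation_level: float = 0.85
    expressed: bool = True
    hox_peptide: str | None = None  # force peptide to a Hox fragment
    ref_flagged: bool = False
    intended_fate: str = "none"

    def __post_init__(self) -> None:
        if self.aa_length < 10:
            raise ValueError("aa_length must be >= 10")
        if self.intended_fate not in FATES:
            raise ValueError(f"unknown intended_fate {self.intended_fate!r}")


@dataclass
class SimulationConfig:
    seed: int = 42
    species: tuple[str, ...] = ("simA", "simB", "simC", "simD", "simE")
    ref_species: str = "simA"
    divergence: DivergenceTable | None = None
    rate_per_my: float = 0.002
    plants: list[PlantSpec] = field(default_factory=list)
    filler_gap: int = 60
    background_conservation: float = 0.08
    conservation_noise_sd: float = 0.02
    read_length: int = 75
    read_depth: int = 12
    n_noise_promoters: int = 30

    def __post_init__(self) -> None:
        if self.divergence is None:
            self.divergence = _default_divergence(self.species)
        for sp in self.plants:
            if not sp.target_species:
                sp.target_species = tuple(self.species)
            if self.ref_species not in sp.target_species:
                raise ValueError(
                    f"{sp.plant_id}: reference species must be a target"
                )


def _default_divergence(species: Sequence[str]) -> DivergenceTable:
    """Ladder divergence: species i splits from the rest at fixed times."""
    times = [0, 5, 12, 25, 40]
    table = DivergenceTable()
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i < j:
                table.set(a, b, times[min(max(i, j), len(times) - 1)])
    return table


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequence(
    ancestral: str,
    divergence_my: float,
    rate: float,
    rng: np.random.Generator,
    constrained: Sequence[tuple[int, int, float]] = (),
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Evolve *ancestral* by i.i.d. per-site substitution.

    Each site mutates with probability ``p = rate * divergence_my`` to a
    uniformly chosen different base. Inside a ``constrained``
    ``(start, end, omega)`` interval — a planted coding region read in
    frame from ``start`` — a substitution that changes the encoded amino
    acid is accepted with probability *omega* and one creating a stop
    codon is always rejected. ``protected`` positions never change
    (planted start/stop codons).
    """
    p = rate * divergence_my
    if p > 0.75:
        raise ValueError("rate * divergence_my must be <= 0.75")
    if p == 0:
        return ancestral
    seq = list(ancestral)
    n = len(seq)
    protected_mask = np.zeros(n, dtype=bool)
    for lo, hi in protected:
        protected_mask[lo:hi] = True
    sites = np.flatnonzero(rng.random(n) < p)
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for site in sites:
        if protected_mask[site]:
            continue
        old = seq[site]
        if old == "N":
            continue
        new = others[old][rng.integers(3)]
        constraint = None
        for lo, hi, omega in constrained:
            if lo <= site < hi:
                constraint = (lo, omega)
                break
        if constraint is None:
            seq[site] = new
            continue
        lo, omega = constraint
        cstart = lo + 3 * ((site - lo) // 3)
        codon = seq[cstart : cstart + 3]
        newcodon = list(codon)
        newcodon[site - cstart] = new
        newcodon = "".join(newcodon)
        if newcodon in STOP_CODONS:
            continue
        if str(_Seq(newcodon).translate()) != str(_Seq("".join(codon)).translate()):
            if rng.random() >= omega:
                continue
        seq[site] = new
    return "".join(seq)


# ---------------------------------------------------------------------------
# neighborhood construction


def _tless_run(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACG"))[rng.integers(0, 3, size=length)])


# body peptides avoid Met (would force ATG) and Trp (high BLOSUM
# self-score inflates chance local-alignment hits between unrelated plants)
_BODY_ALPHABET = "ACDEFGHIKLNPQRSTVY"

# residues with a synonymous codon starting with the given +4 base
_PLUS4_RESIDUES = {"G": "ADEGV", "C": "HLPQR", "A": "IKNRST", "T": "CFLSY"}


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    """Random peptide over a diverse 18-residue alphabet (no Met/Trp)."""
    idx = rng.integers(0, len(_BODY_ALPHABET), size=length)
    return "".join(_BODY_ALPHABET[i] for i in idx)


def _encode_body(peptide: str, rng: np.random.Generator, plus4: str) -> str:
    """Encode *peptide* avoiding spurious start codons in the body.

    The first codon must start with ``plus4`` (the Kozak +4 base). For
    T-less-codable residues a T-less codon is used (structurally safe);
    other residues (Hox fragments) fall back to any synonymous codon that
    creates no ATG — and, when possible, no CAT (a reverse-strand ATG) —
    across the trailing window. Residue pairs like His-Ile force a CAT;
    the rare reverse-strand ORFs this can seed carry background-level
    context scores and never survive the cascade.
    """
    for ban in (("ATG", "CAT"), ("ATG",)):
        for _ in range(40):  # randomized restarts on junction dead-ends
            body = _try_encode(peptide, rng, plus4, ban)
            if body is not None:
                return body
    raise ValueError(f"cannot encode peptide {peptide!r} safely")


def _try_encode(
    peptide: str, rng: np.random.Generator, plus4: str, ban: tuple[str, ...]
) -> str | None:
    """One greedy pass with single-step repair; None on a dead end.

    Conflicts are local (a 5-nt window across the codon junction), so
    when position *i* has no fitting codon it usually suffices to
    re-choose the codon at *i - 1*.
    """
    last = len(peptide) - 1

    def options(i: int) -> list[str]:
        opts = list(_AA_TO_ANY[peptide[i]])
        rng.shuffle(opts)
        if i == 0:
            opts = [c for c in opts if c[0] == plus4] or opts
        if i == last:
            # avoid CAT across the body|stop junction
            opts = [c for c in opts if c[2] != "A"] or opts
        return opts

    def fits(tail: str, codon: str) -> bool:
        window = tail + codon
        return not any(b in window for b in ban)

    out: list[str] = []
    i = 0
    while i <= last:
        tail = "".join(out[-1:])[-2:]
        pick = next((c for c in options(i) if fits(tail, c)), None)
        if pick is None and i > 0:
            # repair: re-choose the previous codon so that i has a fit
            prev_tail = "".join(out[-2:-1])[-2:]
            for alt in options(i - 1):
                if not fits(prev_tail, alt):
                    continue
                pick = next(
                    (c for c in options(i) if fits(alt[-2:], c)), None
                )
                if pick is not None:
                    out[-1] = alt
                    break
        if pick is None:
            return None
        out.append(pick)
        i += 1
    return "".join(out)


@dataclass
class _Neighborhood:
    spec: PlantSpec
    local_seq: str  # plant-strand orientation
    atg_local: int  # offset of ATG within local_seq
    body_end_local: int  # end of stop codon within local_seq
    genome_start: int = -1  # filled at assembly time

    @property
    def length(self) -> int:
        return len(self.local_seq)


def _build_neighborhood(
    spec: PlantSpec, rng: np.random.Generator, kozak: KozakModel
) -> _Neighborhood:
    if spec.kozak_strength == "strong":
        context = kozak.consensus_context
    else:
        context = kozak.anti_consensus_context
    up6, plus4 = context[:6], context[9]
    pad_len = max(spec.promoter_distance + 50, 40)
    pad_u = _tless_run(rng, pad_len)
    if "T" in up6:  # guard junction: no ATG/CAT across pad|context
        pad_u = pad_u[:-2] + "GG"
    if spec.hox_peptide is not None:
        peptide = spec.hox_peptide
    else:
        peptide = _random_peptide(rng, spec.aa_length - 1)
        first = _PLUS4_RESIDUES[plus4]
        peptide = first[rng.integers(len(first))] + peptide[1:]
    body = _encode_body(peptide, rng, plus4)
    pad_d = _tless_run(rng, 15)[:-2] + "GG"
    local = INSULATOR + pad_u + up6 + "ATG" + body + "TAA" + pad_d + INSULATOR
    atg_local = len(INSULATOR) + len(pad_u) + 6
    body_end = atg_local + 3 + len(body) + 3
    return _Neighborhood(spec=spec, local_seq=local, atg_local=atg_local,
                         body_end_local=body_end)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class LocusBundle:
    """All inputs the annotation pipeline needs, plus the truth table."""

    config: SimulationConfig
    loci: dict[str, SpeciesLocus]
    conservation: ConservationTrack
    promoters: list[PromoterCall]
    reads: list[GenomicInterval]
    hox_proteins: dict[str, str]
    truth: pd.DataFrame
    flags: pd.DataFrame
    gene_features_gff: str  # GFF3 text stub

    @property
    def ref_locus(self) -> SpeciesLocus:
        return self.loci[self.config.ref_species]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sp, locus in self.loci.items():
            with open(out / f"{sp}.fa", "w") as fh:
                fh.write(f">{sp} {CHROM}\n")
                for i in range(0, len(locus.sequence), 70):
                    fh.write(locus.sequence[i : i + 70] + "\n")
        self.conservation.to_bedgraph(out / "conservation.bedgraph")
        with open(out / "promoters.bed", "w") as fh:
            for i, p in enumerate(self.promoters):
                fh.write(
                    f"{p.chrom}\t{p.position}\t{p.position + 1}\tprom{i}"
                    f"\t{p.score:.3f}\t{p.strand}\n"
                )
        with open(out / "reads.bed", "w") as fh:
            for i, r in enumerate(self.reads):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")
        with open(out / "hox_synthetic.fa", "w") as fh:
            for name, seq in self.hox_proteins.items():
                fh.write(f">{name}\n{seq}\n")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.flags.to_csv(out / "ref_flags.tsv", sep="\t", index=False)
        with open(out / "genes.gff3", "w") as fh:
            fh.write(self.gene_features_gff)
        with open(out / "divergence.tsv", "w") as fh:
            fh.write("species_a\tspecies_b\tmy\n")
            for key, my in sorted(
                self.config.divergence.times.items(), key=lambda kv: sorted(kv[0])
            ):
                a, b = sorted(key)
                fh.write(f"{a}\t{b}\t{my}\n")
        meta = {
            "seed": self.config.seed,
            "ref_species": self.config.ref_species,
            "species": list(self.config.species),
        }
        with open(out / "bundle.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)


def load_bundle(bundle_dir) -> LocusBundle:
    """Reload a bundle previously written with :meth:`LocusBundle.write`."""
    from .features import read_bed_intervals, read_promoter_bed

    d = Path(bundle_dir)
    with open(d / "bundle.yaml") as fh:
        meta = yaml.safe_load(fh)
    loci = {}
    for sp in meta["species"]:
        rec = next(SeqIO.parse(str(d / f"{sp}.fa"), "fasta"))
        loci[sp] = SpeciesLocus(species_id=sp, sequence=str(rec.seq), chrom=CHROM)
    div = DivergenceTable.from_tsv(d / "divergence.tsv")
    config = SimulationConfig(
        seed=int(meta["seed"]),
        species=tuple(meta["species"]),
        ref_species=meta["ref_species"],
        divergence=div,
    )
    n = len(loci[meta["ref_species"]].sequence)
    track = ConservationTrack.from_bedgraph(
        d / "conservation.bedgraph", chrom=CHROM, offset=0, length=n
    )
    hox = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(d / "hox_synthetic.fa"), "fasta")
    }
    return LocusBundle(
        config=config,
        loci=loci,
        conservation=track,
        promoters=read_promoter_bed(d / "promoters.bed"),
        reads=read_bed_intervals(d / "reads.bed"),
        hox_proteins=hox,
        truth=pd.read_csv(d / "truth.tsv", sep="\t"),
        flags=pd.read_csv(d / "ref_flags.tsv", sep="\t"),
        gene_features_gff=(d / "genes.gff3").read_text(),
    )


def load_hox_fixture() -> dict[str, str]:
    """Synthetic stand-in Hox proteins shipped with the package."""
    with resources.as_file(
        resources.files("altorf.data") / "hox_synthetic.fasta"
    ) as path:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def make_bundle(config: SimulationConfig,
                kozak_model: KozakModel | None = None) -> LocusBundle:
    """Generate a deterministic locus bundle from *config*.

    The same config and seed always produce byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    kozak = kozak_model or KozakModel.default()
    hox = load_hox_fixture()

    neighborhoods = [
        _build_neighborhood(spec, rng, kozak) for spec in config.plants
    ]

    # --- assemble the reference (ancestral) locus -------------------------
    pieces: list[str] = []
    pos = 0
    leading = _filler(rng, 400)
    pieces.append(leading)
    pos += len(leading)
    filler_spans: list[tuple[int, int]] = [(0, pos)]
    for nb in neighborhoods:
        nb.genome_start = pos
        seq = nb.local_seq
        if nb.spec.strand == "-":
            seq = reverse_complement(seq)
        pieces.append(seq)
        pos += len(seq)
        gap = _filler(rng, config.filler_gap)
        filler_spans.append((pos, pos + len(gap)))
        pieces.append(gap)
        pos += len(gap)
    trailing = _filler(rng, 700)
    filler_spans.append((pos, pos + len(trailing)))
    pieces.append(trailing)
    pos += len(trailing)
    ref_seq = "".join(pieces)
    n = len(ref_seq)

    truth_rows = []
    for nb in neighborhoods:
        start, end = _plant_genome_interval(nb)
        truth_rows.append(
            {
                "plant_id": nb.spec.plant_id,
                "chrom": CHROM,
                "start": start,
                "end": end,
                "strand": nb.spec.strand,
                "aa_length": nb.spec.aa_length,
                "intended_fate": nb.spec.intended_fate,
                "ref_flagged": nb.spec.ref_flagged,
                "expressed": nb.spec.expressed,
                "target_species": ",".join(nb.spec.target_species),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["plant_id", "chrom", "start", "end", "strand", "aa_length",
                 "intended_fate", "ref_flagged", "expressed", "target_species"],
    )

    # --- evolve into each species ----------------------------------------
    loci = {config.ref_species: SpeciesLocus(
        species_id=config.ref_species, sequence=ref_seq, chrom=CHROM)}
    div = config.divergence
    for sp in config.species:
        if sp == config.ref_species:
            continue
        t = div.get(config.ref_species, sp)
        out_pieces = []
        cursor = 0
        for nb in neighborhoods:
            g0 = nb.genome_start
            g1 = g0 + nb.length
            gap_seq = ref_seq[cursor:g0]
            out_pieces.append(
                evolve_sequence(gap_seq, t, config.rate_per_my, rng)
            )
            local = nb.local_seq
            if sp not in nb.spec.target_species:
                # plant absent in this species: scramble the neighborhood
                out_pieces.append(
                    INSULATOR
                    + _filler(rng, nb.length - 2 * len(INSULATOR))
                    + INSULATOR
                )
            else:
                atg = nb.atg_local
                body_lo, body_hi = atg + 3, nb.body_end_local - 3
                evolved = evolve_sequence(
                    local,
                    t,
                    config.rate_per_my,
                    rng,
                    constrained=[(body_lo, body_hi, nb.spec.omega)],
                    protected=[(atg, atg + 3),
                               (nb.body_end_local - 3, nb.body_end_local),
                               (0, len(INSULATOR)),
                               (nb.length - len(INSULATOR), nb.length)],
                )
                if nb.spec.strand == "-":
                    evolved = reverse_complement(evolved)
                out_pieces.append(evolved)
            cursor = g1
        out_pieces.append(
            evolve_sequence(ref_seq[cursor:], t, config.rate_per_my, rng)
        )
        loci[sp] = SpeciesLocus(species_id=sp, sequence="".join(out_pieces),
                                chrom=CHROM)

    # --- conservation track (reference coordinates) -----------------------
    scores = np.clip(
        rng.normal(config.background_conservation,
                   config.conservation_noise_sd, size=n),
        0.0, 1.0,
    )
    for nb in neighborhoods:
        start, end = _plant_genome_interval(nb)
        scores[start:end] = np.clip(
            rng.normal(nb.spec.conservation_level,
                       config.conservation_noise_sd, size=end - start),
            0.0, 1.0,
        )
    track = ConservationTrack(scores=scores, offset=0, chrom=CHROM)

    # --- promoters ---------------------------------------------------------
    promoters = []
    for nb in neighborhoods:
        start, end = _plant_genome_interval(nb)
        atg = start if nb.spec.strand == "+" else end - 1
        d = nb.spec.promoter_distance
        tss = atg - d if nb.spec.strand == "+" else atg + d
        promoters.append(
            PromoterCall(position=tss, score=nb.spec.promoter_score,
                         strand=nb.spec.strand, chrom=CHROM)
        )
    for _ in range(config.n_noise_promoters):
        span = filler_spans[rng.integers(len(filler_spans))]
        tss = int(rng.integers(span[0], span[1]))
        promoters.append(
            PromoterCall(position=tss,
                         score=float(rng.uniform(0.1, 0.5)),
                         strand="+" if rng.random() < 0.5 else "-",
                         chrom=CHROM)
        )

    # --- reads --------------------------------------------------------------
    reads = []
    rl = config.read_length
    for nb in neighborhoods:
        if not nb.spec.expressed:
            continue
        start, end = _plant_genome_interval(nb)
        lo = max(0, start - 10)
        hi = min(n, end + 10)
        n_reads = max(config.read_depth, 5)
        span = max(hi - lo - rl, 1)
        for k in range(n_reads):
            s = lo + int(round(k * span / max(n_reads - 1, 1)))
            reads.append(GenomicInterval(CHROM, s, min(s + rl, n),
                                         nb.spec.strand))

    # --- flags and gene-model stub ------------------------------------------
    flags = truth.loc[truth["ref_flagged"], ["plant_id"]].copy()
    flags["source"] = "polyriboseq"
    gff = _gff_stub(n)

    bundle = LocusBundle(
        config=config,
        loci=loci,
        conservation=track,
        promoters=promoters,
        reads=reads,
        hox_proteins=hox,
        truth=truth,
        flags=flags,
        gene_features_gff=gff,
    )
    _self_check(bundle, kozak)
    return bundle


def _plant_genome_interval(nb: _Neighborhood) -> tuple[int, int]:
    """Genome interval of the planted ORF (ATG..stop inclusive)."""
    if nb.spec.strand == "+":
        start = nb.genome_start + nb.atg_local
        return start, start + (nb.body_end_local - nb.atg_local)
    end = nb.genome_start + nb.length - nb.atg_local
    return end - (nb.body_end_local - nb.atg_local), end


def _filler(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _gff_stub(locus_length: int) -> str:
    """Minimal synthetic gene-model GFF3 for context classification."""
    third = locus_length // 3
    lines = [
        "##gff-version 3",
        f"{CHROM}\tsim\tgene\t1\t{third}\t.\t+\t.\tID=gene1",
        f"{CHROM}\tsim\tmRNA\t1\t{third}\t.\t+\t.\tID=mRNA1;Parent=gene1",
        f"{CHROM}\tsim\tfive_prime_UTR\t1\t200\t.\t+\t.\tID=utr5_1;Parent=mRNA1",
        f"{CHROM}\tsim\tCDS\t201\t{third - 300}\t.\t+\t0\tID=cds1;Parent=mRNA1",
        f"{CHROM}\tsim\tthree_prime_UTR\t{third - 299}\t{third}\t.\t+\t.\t"
        "ID=utr3_1;Parent=mRNA1",
        f"{CHROM}\tsim\tlnc_RNA\t{third + 100}\t{2 * third}\t.\t-\t.\tID=lnc1",
    ]
    return "\n".join(lines) + "\n"


def _self_check(bundle: LocusBundle, kozak: KozakModel) -> None:
    """Assert every plant is recovered by the scanner in the reference."""
    from .discovery import scan_orfs

    orfs = scan_orfs(bundle.ref_locus, min_aa=10, kozak_model=None)
    found = {(o.interval.start, o.interval.end, o.strand) for o in orfs}
    for _, row in bundle.truth.iterrows():
        key = (row["start"], row["end"], row["strand"])
        if key not in found:
            raise AssertionError(
                f"planted ORF {row['plant_id']} not recovered at {key}"
            )


# ---------------------------------------------------------------------------
# the default study bundle


def default_config(seed: int = 42) -> SimulationConfig:
    """The standard test bundle: 20 pass-all plants and 80 one-fault decoys.

    Six of the pass-all plants are reference-flagged and anchor threshold
    calibration: their conservation, promoter and Kozak values are drawn
    from the low end of the passing range so that every other pass-all
    plant clears the calibrated cutoffs.
    """
    rng = np.random.default_rng(seed + 101)
    species = ("simA", "simB", "simC", "simD", "simE")
    plants: list[PlantSpec] = []

    def aa() -> int:
        return int(rng.integers(30, 61))

    def strand(i: int) -> str:
        return "+" if i % 2 == 0 else "-"

    k = 0
    for i in range(20):
        flagged = i < 6
        plants.append(
            PlantSpec(
                plant_id=f"pass{i:02d}",
                aa_length=aa(),
                strand=strand(k),
                conservation_level=(
                    float(rng.uniform(0.55, 0.62)) if flagged
                    else float(rng.uniform(0.75, 0.95))
                ),
                promoter_distance=(
                    int(rng.integers(200, 261)) if flagged
                    else int(rng.integers(20, 181))
                ),
                promoter_score=(
                    float(rng.uniform(0.82, 0.88)) if flagged
                    else float(rng.uniform(0.90, 0.99))
                ),
                ref_flagged=flagged,
                intended_fate="none",
            )
        )
        k += 1

    hox = load_hox_fixture()
    hox_names = sorted(hox)
    for i in range(10):
        protein = hox[hox_names[i % len(hox_names)]]
        off = 30 + 17 * i
        # start the fragment on a residue with a G-initial codon so the
        # Kozak +4 consensus base is preserved (single-fault decoy)
        while protein[off] not in "ADEGV":
            off += 1
        frag = protein[off : off + 40]
        plants.append(
            PlantSpec(
                plant_id=f"hox{i:02d}", aa_length=41, strand=strand(k),
                hox_peptide=frag, intended_fate="hox_removal",
            )
        )
        k += 1
    for i in range(14):
        plants.append(
            PlantSpec(
                plant_id=f"spec{i:02d}", aa_length=aa(), strand=strand(k),
                target_species=("simA",), intended_fate="min_species",
            )
        )
        k += 1
    for i in range(14):
        plants.append(
            PlantSpec(
                plant_id=f"age{i:02d}", aa_length=aa(), strand=strand(k),
                target_species=("simA", "simB"), intended_fate="min_age",
            )
        )
        k += 1
    for i in range(14):
        plants.append(
            PlantSpec(
                plant_id=f"cons{i:02d}", aa_length=aa(), strand=strand(k),
                conservation_level=0.12, intended_fate="conservation",
            )
        )
        k += 1
    for i in range(14):
        if i % 2 == 0:
            spec = PlantSpec(
                plant_id=f"prom{i:02d}", aa_length=aa(), strand=strand(k),
                promoter_distance=600, intended_fate="promoter",
            )
        else:
            spec = PlantSpec(
                plant_id=f"prom{i:02d}", aa_length=aa(), strand=strand(k),
                promoter_distance=20, promoter_score=0.30,
                intended_fate="promoter",
            )
        plants.append(spec)
        k += 1
    for i in range(7):
        plants.append(
            PlantSpec(
                plant_id=f"koz{i:02d}", aa_length=aa(), strand=strand(k),
                kozak_strength="weak", intended_fate="kozak",
            )
        )
        k += 1
    for i in range(7):
        plants.append(
            PlantSpec(
                plant_id=f"read{i:02d}", aa_length=aa(), strand=strand(k),
                expressed=False, intended_fate="read_support",
            )
        )
        k += 1
    return SimulationConfig(seed=seed, species=species, plants=plants)
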