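"""End-to-end annotation pipeline over a locus bundle.

Glues the per-module operations together: scan the reference locus,
screen against Hox proteins, build cross-species ortholog groups, attach
conservation/promoter/read/Kozak/motif features to every reference ORF,
and run calibration plus the 9-step cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cascade as _cascade
from .comparative import (
    DivergenceTable,
    OrthologGroup,
    build_ortholog_groups,
    group_age,
    mean_pairwise_omega,
)
from .core import OrfRecord, SpeciesLocus
from .discovery import KozakModel, filter_hox_matches, scan_orfs
from .features import (
    ConservationTrack,
    mean_conservation,
    nearest_upstream_promoter,
    read_support,
)
from .motifs import (
    MotifPattern,
    elm_score,
    global_motif_counts,
    scan_motifs,
    select_hox_elms,
)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    thresholds: _cascade.CascadeThresholds
    funnel: _cascade.FunnelReport
    final: pd.DataFrame
    ref_orfs: list[OrfRecord]
    groups: list[OrthologGroup]


def annotate_features(
    bundle,
    kozak_model: KozakModel | None = None,
    patterns: list[MotifPattern] | None = None,
    min_aa: int = 30,
    e_max: float = 1e-5,
) -> tuple[pd.DataFrame, list[OrfRecord], list[OrthologGroup], dict]:
    """Build the per-ORF feature table for a bundle's reference species.

    Returns (features, reference ORFs, ortholog groups, ortholog-partner
    map). The motif denominator population is the full initial reference
    prediction set, fixed before any filtering.
    """
    from .motifs import default_patterns

    kozak_model = kozak_model or KozakModel.default()
    patterns = patterns if patterns is not None else default_patterns()
    hox_seqs = list(bundle.hox_proteins.values())

    per_species: dict[str, list[OrfRecord]] = {}
    for sp, locus in bundle.loci.items():
        per_species[sp] = scan_orfs(locus, min_aa=min_aa, kozak_model=kozak_model)
    ref_sp = bundle.config.ref_species
    ref_orfs = per_species[ref_sp]

    _, removed = filter_hox_matches(ref_orfs, hox_seqs)
    hox_ids = {o.orf_id for o in removed}

    groups = build_ortholog_groups(per_species, e_max=e_max)
    div: DivergenceTable = bundle.config.divergence
    orf_group: dict[str, OrthologGroup] = {}
    for g in groups:
        g.age_my = group_age(g, div)
        for sp, oid in g.members:
            if sp == ref_sp:
                orf_group[oid] = g
    orf_by_key = {
        (sp, o.orf_id): o for sp, orfs in per_species.items() for o in orfs
    }
    partners = {
        oid: [
            orf_by_key[(sp, member_id)]
            for sp, member_id in g.members
            if sp != ref_sp
        ]
        for oid, g in orf_group.items()
    }

    hox_patterns = select_hox_elms(patterns, hox_seqs)
    summaries = {}
    for o in ref_orfs:
        s = scan_motifs(o.peptide, hox_patterns)
        s.orf_id = o.orf_id
        summaries[o.orf_id] = s
    globals_ = global_motif_counts(summaries.values())

    flagged_keys = set()
    if len(bundle.truth):
        flagged = bundle.truth[bundle.truth["ref_flagged"].astype(bool)]
        flagged_keys = {
            (r["start"], r["end"], r["strand"]) for _, r in flagged.iterrows()
        }

    rows = []
    for o in ref_orfs:
        g = orf_group.get(o.orf_id)
        prom = nearest_upstream_promoter(bundle.promoters, o)
        rs = read_support(bundle.reads, o)
        summ = summaries[o.orf_id]
        rows.append(
            {
                "orf_id": o.orf_id,
                "start": o.interval.start,
                "end": o.interval.end,
                "strand": o.strand,
                "aa_length": o.aa_length,
                "hox_match": o.orf_id in hox_ids,
                "species_count": g.species_count if g else 1,
                "age_my": g.age_my if g else 0.0,
                "phastcons": mean_conservation(bundle.conservation, o.interval),
                # upstream distances are reported with a negative sign;
                # the cascade compares magnitudes
                "prom_dist": -prom[0] if prom else pd.NA,
                "prom_score": prom[1] if prom else pd.NA,
                "kozak_score": o.kozak_score,
                "n_reads": rs.n_reads,
                "breadth_pct": rs.breadth_pct,
                "total_elms": summ.total_elms,
                "distinct_types": summ.distinct_types,
                "elm_score": elm_score(summ, globals_, o.aa_length),
                "ref_flagged": (
                    (o.interval.start, o.interval.end, o.strand) in flagged_keys
                ),
            }
        )
    features = pd.DataFrame(rows)
    return features, ref_orfs, groups, partners


def run_pipeline(
    bundle,
    kozak_model: KozakModel | None = None,
    patterns: list[MotifPattern] | None = None,
    min_aa: int = 30,
    min_kozak: float | None = None,
) -> PipelineResult:
    """Annotate a bundle, calibrate thresholds and run the cascade."""
    features, ref_orfs, groups, partners = annotate_features(
        bundle, kozak_model=kozak_model, patterns=patterns, min_aa=min_aa
    )
    thresholds = _cascade.calibrate_thresholds(features, min_kozak=min_kozak)
    orf_by_id = {o.orf_id: o for o in ref_orfs}

    def annotate_dnds(surviving: pd.DataFrame) -> pd.DataFrame:
        dn, ds, omega, flag = [], [], [], []
        for oid in surviving["orf_id"]:
            res = mean_pairwise_omega(orf_by_id[oid], partners.get(oid, []))
            dn.append(res.dN if res else pd.NA)
            ds.append(res.dS if res else pd.NA)
            omega.append(res.omega if res else pd.NA)
            flag.append(res.caution_flag if res else "no_orthologs")
        return surviving.assign(dN=dn, dS=ds, omega=omega, dnds_flag=flag)

    funnel, final = _cascade.run_cascade(features, thresholds,
                                         annotate_dnds=annotate_dnds)
    return PipelineResult(
        features=features,
        thresholds=thresholds,
        funnel=funnel,
        final=final,
        ref_orfs=ref_orfs,
        groups=groups,
    )
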