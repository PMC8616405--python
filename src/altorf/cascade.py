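"""Threshold calibration and the 9-step altORF filter cascade.

The cascade starts from the full prediction set and applies, in fixed
order: (1) prediction itself, (2) removal of candidates matching
conventional Hox proteins, (3) presence in at least ``min_species``
species, (4) minimal evolutionary age, (5) conservation score,
(6) upstream promoter distance and score, (7) Kozak strength,
(8) RNA-seq read support, and (9) dN/dS annotation of the survivors
(which removes nothing). The conservation, promoter and Kozak cutoffs
are calibrated as the extreme values observed among reference-flagged
candidates — ORFs matching previously published altORF peptide sets —
so that every flagged candidate with complete features survives the
calibrated steps by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import math

import pandas as pd

# Columns a feature table must carry for the corresponding cascade step.
FEATURE_COLUMNS = {
    "hox": ["hox_match"],
    "species": ["species_count"],
    "age": ["age_my"],
    "conservation": ["phastcons"],
    "promoter": ["prom_dist", "prom_score"],
    "kozak": ["kozak_score"],
    "reads": ["n_reads", "breadth_pct"],
}

STEP_NAMES = [
    "prediction",
    "hox_removal",
    "min_species",
    "min_age",
    "conservation",
    "promoter",
    "kozak",
    "read_support",
    "final_dnds",
]


@dataclass
class CascadeThresholds:
    """Cutoffs applied by the cascade, with per-field provenance.

    ``provenance`` maps each field to ``"calibrated"`` (derived from
    reference-flagged rows) or ``"config"`` (supplied).
    """

    min_species: int = 2
    min_age_my: float = 10.0
    min_phastcons: float = 0.0
    max_prom_dist: int = 10**9
    min_prom_score: float = 0.0
    min_kozak: float = 0.0
    min_reads: int = 5
    min_breadth_pct: float = 40.0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "min_species": self.min_species,
            "min_age_my": self.min_age_my,
            "min_phastcons": self.min_phastcons,
            "max_prom_dist": self.max_prom_dist,
            "min_prom_score": self.min_prom_score,
            "min_kozak": self.min_kozak,
            "min_reads": self.min_reads,
            "min_breadth_pct": self.min_breadth_pct,
            "provenance": dict(self.provenance),
        }


def calibrate_thresholds(
    rows: pd.DataFrame,
    min_species: int = 2,
    min_age_my: float = 10.0,
    min_reads: int = 5,
    min_breadth_pct: float = 40.0,
    min_kozak: float | None = None,
    phastcons_decimals: int = 2,
) -> CascadeThresholds:
    """Derive cascade cutoffs from the reference-flagged rows of *rows*.

    Calibrated fields are the extreme values among flagged rows: the
    minimum conservation score (rounded to ``phastcons_decimals``), the
    maximum absolute promoter distance, the minimum promoter score and —
    unless overridden — the minimum Kozak score. Species/age/read-support
    cutoffs are configuration values, not calibrated (the read-support
    reference data lie outside the locus under study).
    """
    flagged = rows[rows["ref_flagged"].astype(bool)]
    if flagged.empty:
        raise ValueError("calibration requires at least one reference-flagged row")
    # floor rather than round: the reported cutoff must not exceed the
    # flagged minimum, or the anchoring reference rows would be dropped
    scale = 10 ** phastcons_decimals
    thr = CascadeThresholds(
        min_species=min_species,
        min_age_my=min_age_my,
        min_phastcons=math.floor(float(flagged["phastcons"].min()) * scale) / scale,
        max_prom_dist=int(flagged["prom_dist"].abs().max()),
        min_prom_score=float(flagged["prom_score"].min()),
        min_kozak=(
            float(flagged["kozak_score"].min()) if min_kozak is None else min_kozak
        ),
        min_reads=min_reads,
        min_breadth_pct=min_breadth_pct,
    )
    thr.provenance = {
        "min_species": "config",
        "min_age_my": "config",
        "min_phastcons": "calibrated",
        "max_prom_dist": "calibrated",
        "min_prom_score": "calibrated",
        "min_kozak": "config" if min_kozak is not None else "calibrated",
        "min_reads": "config",
        "min_breadth_pct": "config",
    }
    return thr


@dataclass
class FunnelStep:
    step_name: str
    survivors: int
    ref_flagged_survivors: int


@dataclass
class FunnelReport:
    steps: list[FunnelStep]
    removal_log: dict = field(default_factory=dict)  # step -> removed orf_ids

    def counts(self) -> list[int]:
        return [s.survivors for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.step_name for s in self.steps],
                "survivors": [s.survivors for s in self.steps],
                "ref_flagged_survivors": [
                    s.ref_flagged_survivors for s in self.steps
                ],
            }
        )


def step_predicates(thr: CascadeThresholds) -> dict[str, Callable[[pd.Series], bool]]:
    """Per-step keep-predicates over one feature row.

    Exposed so tests can replay every row against every predicate
    independently of the vectorized cascade.
    """
    return {
        "hox_removal": lambda r: not bool(r["hox_match"]),
        "min_species": lambda r: r["species_count"] >= thr.min_species,
        "min_age": lambda r: r["age_my"] >= thr.min_age_my,
        "conservation": lambda r: r["phastcons"] >= thr.min_phastcons,
        "promoter": lambda r: (
            pd.notna(r["prom_dist"])
            and abs(r["prom_dist"]) <= thr.max_prom_dist
            and r["prom_score"] >= thr.min_prom_score
        ),
        "kozak": lambda r: r["kozak_score"] >= thr.min_kozak,
        "read_support": lambda r: (
            r["n_reads"] >= thr.min_reads
            and r["breadth_pct"] >= thr.min_breadth_pct
        ),
    }


def _check_columns(rows: pd.DataFrame, step: str, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"step {step!r} needs missing feature columns {missing}")


def run_cascade(
    rows: pd.DataFrame,
    thr: CascadeThresholds,
    annotate_dnds: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> tuple[FunnelReport, pd.DataFrame]:
    """Apply the 9-step cascade to a feature table.

    Returns the funnel report (survivor and flagged-survivor counts after
    every step) and the final survivor table. ``annotate_dnds`` is called
    on the survivors in step 9 to add dN/dS columns; the step removes
    nothing.
    """
    if "ref_flagged" not in rows.columns:
        rows = rows.assign(ref_flagged=False)
    surviving = rows.copy()
    steps = [FunnelStep("prediction", len(surviving),
                        int(surviving["ref_flagged"].sum()))]
    preds = step_predicates(thr)
    needed = {
        "hox_removal": FEATURE_COLUMNS["hox"],
        "min_species": FEATURE_COLUMNS["species"],
        "min_age": FEATURE_COLUMNS["age"],
        "conservation": FEATURE_COLUMNS["conservation"],
        "promoter": FEATURE_COLUMNS["promoter"],
        "kozak": FEATURE_COLUMNS["kozak"],
        "read_support": FEATURE_COLUMNS["reads"],
    }
    removal_log = {}
    for step in STEP_NAMES[1:-1]:
        if len(surviving):
            _check_columns(surviving, step, needed[step])
            keep = surviving.apply(preds[step], axis=1).astype(bool)
        else:
            keep = pd.Series(dtype=bool)
        removal_log[step] = list(surviving.loc[~keep, "orf_id"]) if len(
            surviving) else []
        surviving = surviving[keep] if len(surviving) else surviving
        steps.append(
            FunnelStep(step, len(surviving), int(surviving["ref_flagged"].sum())
                       if len(surviving) else 0)
        )
    if annotate_dnds is not None and len(surviving):
        surviving = annotate_dnds(surviving)
    steps.append(
        FunnelStep("final_dnds", len(surviving),
                   int(surviving["ref_flagged"].sum()) if len(surviving) else 0)
    )
    report = FunnelReport(steps=steps)
    report.removal_log = removal_log
    return report, surviving


# ---------------------------------------------------------------------------
# reporting


def elm_score_bins(rows: pd.DataFrame) -> tuple[int, int, int]:
    """Bin ELM scores at <100, [100, 200] and >200 (inclusive bounds)."""
    if "elm_score" not in rows.columns:
        raise ValueError("rows lack an elm_score column")
    s = rows["elm_score"].astype(float)
    low = int((s < 100).sum())
    mid = int(((s >= 100) & (s <= 200)).sum())
    high = int((s > 200).sum())
    return low, mid, high


REPORT_COLUMNS = [
    "orf_id", "aa_length", "strand", "age_my", "species_count", "phastcons",
    "prom_score", "prom_dist", "kozak_score", "n_reads", "breadth_pct",
    "ref_flagged", "total_elms", "distinct_types", "elm_score",
]


def report_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Final survivor table in report formatting.

    Scores are rounded to report precision (conservation to 3 decimals,
    promoter/Kozak to 2/3, ELM score to integer); the promoter distance
    keeps its upstream sign; rows are ordered by genomic position when
    coordinates are present, else by orf_id.
    """
    df = rows.copy()
    if "start" in df.columns:
        df = df.sort_values(["start", "orf_id"])
    else:
        df = df.sort_values("orf_id")
    out = pd.DataFrame()
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            continue
        out[col] = df[col].values
    for col, decimals in (
        ("phastcons", 3), ("prom_score", 2), ("kozak_score", 3),
        ("breadth_pct", 1),
    ):
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce").round(decimals)
    if "elm_score" in out:
        out["elm_score"] = (
            pd.to_numeric(out["elm_score"], errors="coerce")
            .round(0)
            .astype("Int64")
        )
    return out.reset_index(drop=True)


def load_bxc48_features() -> pd.DataFrame:
    """The published 48-candidate altORF feature table for the BX-C locus.

    One row per selected altORF with conservation, promoter, Kozak,
    read-support and motif columns; ``ref_flagged`` marks candidates that
    match previously published altORF peptide sets (Poly-ribo-seq or
    proteogenomic re-annotation) and anchors threshold calibration.
    """
    with resources.as_file(
        resources.files("altorf.data") / "bxc48_features.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t")
    df["ref_flagged"] = (
        df["flag_polyriboseq"].fillna("").str.lower().eq("yes")
        | df["flag_proteomics"].fillna("").str.lower().eq("yes")
    )
    return df
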