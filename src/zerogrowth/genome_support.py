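"""SIP differential-coverage binning support, homology calls, and
rrn-corrected population quantification.

Sequencing a CsCl-fractionated stable-isotope-probing (SIP) sample skews
apparent scaffold coverage with G+C content; the transform
(coverage / GC^9) * 1e15 (GC on the 0-100 percent scale) flattens that
skew so a rectangular gate in (native coverage, transformed SIP
coverage) space can extract a population bin. Homology calls follow
amino-acid identity/coverage thresholds (>=40%/>=80% against curated
evidence for true homologs; >=25%/>=80% for putative ones). 16S rRNA
gene copies are converted to cell numbers by dividing by the genus's
average rrn operons per genome (9.3 for the focal genus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CURATED_TIERS = frozenset({"curated_db", "curated_annotation", "literature"})
ALL_TIERS = CURATED_TIERS | {"general_db"}

TRUE_IDENTITY_MIN = 40.0
PUTATIVE_IDENTITY_MIN = 25.0
COVERAGE_MIN = 80.0


def gc_transform_coverage(coverage, gc_percent, constant: float = 1e15):
    """t = (coverage / gc_percent^9) * constant, GC on the 0-100 scale.

    Strictly decreasing in GC at fixed coverage, linear in coverage.
    Accepts scalars or arrays; raises on GC <= 0 or negative coverage.
    """
    cov = np.asarray(coverage, dtype=float)
    gc = np.asarray(gc_percent, dtype=float)
    if (gc <= 0).any() if gc.ndim else gc <= 0:
        raise ValueError("gc_percent must be positive")
    if (cov < 0).any() if cov.ndim else cov < 0:
        raise ValueError("coverage must be >= 0")
    out = cov / gc**9 * constant
    return out if out.ndim else float(out)


def select_bin(
    scaffolds: pd.DataFrame,
    cov_a_range: tuple[float, float],
    cov_b_transformed_range: tuple[float, float],
    gc_range: tuple[float, float] | None = None,
    constant: float = 1e15,
) -> tuple[pd.DataFrame, dict]:
    """Extract the scaffold bin inside rectangular coverage/GC gates.

    ``scaffolds`` needs columns scaffold_id, length_nt, gc_percent,
    coverage_a, coverage_b. Gate bounds are inclusive; the coverage_b
    gate applies to the GC-transformed coverage, which is added as column
    ``coverage_b_transformed``. Returns (subset, summary).
    """
    for name, rng in [("cov_a_range", cov_a_range), ("cov_b_transformed_range", cov_b_transformed_range)] + (
        [("gc_range", gc_range)] if gc_range is not None else []
    ):
        if rng[0] > rng[1]:
            raise ValueError(f"empty gate range {name}: {rng}")
    df = scaffolds.copy()
    df["coverage_b_transformed"] = gc_transform_coverage(
        df["coverage_b"].to_numpy(), df["gc_percent"].to_numpy(), constant
    )
    mask = (
        df["coverage_a"].between(*cov_a_range)
        & df["coverage_b_transformed"].between(*cov_b_transformed_range)
    )
    if gc_range is not None:
        mask &= df["gc_percent"].between(*gc_range)
    subset = df[mask].reset_index(drop=True)
    summary = {
        "n_scaffolds": int(len(subset)),
        "total_bp": int(subset["length_nt"].sum()) if len(subset) else 0,
        "mean_gc_percent": float(subset["gc_percent"].mean()) if len(subset) else 0.0,
        "mean_coverage_a": float(subset["coverage_a"].mean()) if len(subset) else 0.0,
        "mean_coverage_b": float(subset["coverage_b"].mean()) if len(subset) else 0.0,
    }
    return subset, summary


@dataclass
class HomologyHit:
    """One protein homology search hit with its evidence tier."""

    query_id: str
    subject_id: str
    percent_identity: float
    percent_query_coverage: float
    evidence_tier: str = "general_db"

    def __post_init__(self) -> None:
        for name in ("percent_identity", "percent_query_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.evidence_tier not in ALL_TIERS:
            raise ValueError(f"unknown evidence tier: {self.evidence_tier!r}")


def call_homology(hit: HomologyHit, synteny_support: bool = False) -> str:
    """Classify a hit as true_homolog, putative_homolog, or no_call.

    true: identity >= 40 and coverage >= 80 with curated-tier evidence
    (curated database, curated platform annotation, or literature);
    putative: identity >= 25 and coverage >= 80 with any evidence;
    synteny support (operon membership) promotes a putative call with
    true-level identity to a true homolog. All thresholds inclusive.
    """
    if hit.percent_query_coverage < COVERAGE_MIN:
        return "no_call"
    curated = hit.evidence_tier in CURATED_TIERS
    if hit.percent_identity >= TRUE_IDENTITY_MIN and (curated or synteny_support):
        return "true_homolog"
    if hit.percent_identity >= PUTATIVE_IDENTITY_MIN:
        return "putative_homolog"
    return "no_call"


def call_homology_table(hits: pd.DataFrame, synteny_col: str | None = None) -> pd.DataFrame:
    """Vector version of :func:`call_homology` over a hit table."""
    calls = []
    for _, row in hits.iterrows():
        hit = HomologyHit(
            query_id=str(row["query_id"]),
            subject_id=str(row["subject_id"]),
            percent_identity=float(row["percent_identity"]),
            percent_query_coverage=float(row["percent_query_coverage"]),
            evidence_tier=str(row.get("evidence_tier", "general_db")),
        )
        synteny = bool(row[synteny_col]) if synteny_col else False
        calls.append(call_homology(hit, synteny_support=synteny))
    out = hits.copy()
    out["call"] = calls
    return out


@dataclass
class AbundanceRecord:
    """rrn-corrected population quantification."""

    copies_per_cm3: float
    rrn_per_genome: float
    cells_per_cm3: float
    relative_abundance_percent: float | None


def rrn_correct_relative_abundance(
    copies: float,
    rrn: float = 9.3,
    total_community_cells: float | None = None,
) -> AbundanceRecord:
    """cells = 16S copies / rrn; optional % of the total community.

    The 9.3 default is the genus-average rrn operon copy number used to
    correct 16S qPCR counts of the focal population.
    """
    if copies <= 0 or rrn <= 0:
        raise ValueError("copies and rrn must be positive")
    cells = copies / rrn
    rel = None
    if total_community_cells is not None:
        if total_community_cells <= 0:
            raise ValueError("total_community_cells must be positive")
        rel = 100.0 * cells / total_community_cells
    return AbundanceRecord(
        copies_per_cm3=float(copies),
        rrn_per_genome=float(rrn),
        cells_per_cm3=float(cells),
        relative_abundance_percent=rel,
    )
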