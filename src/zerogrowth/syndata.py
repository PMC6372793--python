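"""Synthetic gene catalogs, transcript count matrices, and qPCR series.

The generator emulates the data layout of a genome-centric peat-soil
microcosm experiment: a single low-abundance sulfate-reducer genome
(~6,500 CDS) whose transcripts are counted across a 6-substrate x
{+/- sulfate} x multi-day x 3-replicate incubation design, together with
a qPCR time series of 16S rRNA gene copies that stays flat around
1.2e6 copies cm^-3 while transcription responds to the treatments.

Counts follow a negative-binomial model

    K_ij ~ NB(mean = mu_ij, Var = mu_ij + phi * mu_ij^2)
    mu_ij = (length_i / 1000) * (N_j / 1e6) * b_i * a_j^gamma(cat_i)

where ``b_i`` is a log-normal per-gene baseline (its scale is the gene's
control-condition FPKM), ``N_j`` the whole-library sequencing depth,
``a_j`` a per-sample activity multiplier, and ``gamma`` a per-category
coupling exponent in [0, 1]. Categories with gamma = 1 (ribosomal
proteins, energy metabolism, sulfate reduction) covary fully with the
activity factor; growth-associated categories (cell division, DNA
replication, envelope biogenesis) have gamma = 0 and stay flat — the
planted structure the downstream activity screen is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES: tuple[str, ...] = (
    "sulfate_reduction",
    "ribosomal",
    "central_energy",
    "growth_division",
    "growth_replication",
    "growth_envelope",
    "stress",
    "sporulation",
    "phage_response",
    "other",
)

SUBSTRATES: tuple[str, ...] = (
    "none",
    "formate",
    "acetate",
    "propionate",
    "lactate",
    "butyrate",
)

SULFATE_LEVELS: tuple[str, ...] = ("plusS", "minusS")

#: sampling days of the microcosm experiment (day 0 = initial soil)
DAYS: tuple[int, ...] = (0, 5, 8, 15, 26, 36, 50)

# representative locus tags per category; cycled, then suffixed
_PATHWAY_TAGS: dict[str, tuple[str, ...]] = {
    "sulfate_reduction": ("dsrA", "dsrB", "dsrC", "sat", "aprA", "aprB", "qmoA", "qmoB"),
    "ribosomal": ("rplA", "rpsC", "rplB", "rpsD", "rplC"),
    "central_energy": ("atpA", "atpB", "nuoA", "nuoB", "rnfC"),
    "growth_division": ("ftsZ", "ftsA", "minE", "ftsK"),
    "growth_replication": ("gyrB", "gyrA", "dnaG", "dnaC", "priA"),
    "growth_envelope": ("murA", "murB", "murC", "ddl", "mraY"),
    "stress": ("uspA", "groL", "groS", "dnaK", "clpP"),
    "sporulation": ("spo0A", "spoIIE", "spoIIIAD", "spoVT"),
    "phage_response": ("nrdE", "nrdF", "gatC", "gatA"),
    "other": ("hyp",),
}

#: per-category counts mirroring the focal genome's annotated gene sets,
#: expressed as fractions of 6,440 CDS (COG D/L/M = 73/280/215; 72
#: ribosomal/complex genes; 5 stress, 22 sporulation, 4 phage markers)
DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "sulfate_reduction": 20,
    "ribosomal": 72,
    "central_energy": 50,
    "growth_division": 73,
    "growth_replication": 280,
    "growth_envelope": 215,
    "stress": 5,
    "sporulation": 22,
    "phage_response": 4,
}

#: activity-coupling exponents: the genome-wide bulk of transcription
#: scales with overall activity (total mRNA rises 56-188-fold in the
#: stimulated incubations), while growth machinery stays flat — the
#: zero-growth contrast
DEFAULT_COUPLING: dict[str, float] = {
    "sulfate_reduction": 1.0,
    "ribosomal": 1.0,
    "central_energy": 1.0,
    "stress": 1.0,
    "growth_division": 0.0,
    "growth_replication": 0.0,
    "growth_envelope": 0.0,
    "sporulation": 0.0,
    "phage_response": 0.0,
    "other": 1.0,
}

#: day-36 total-mRNA fold changes of the sulfate-stimulated incubations
#: relative to the no-substrate control (acetate/propionate/lactate/
#: butyrate = 56/80/62/188)
DEFAULT_ACTIVITY_FOLDS: dict[tuple[str, str], float] = {
    ("acetate", "plusS"): 56.0,
    ("propionate", "plusS"): 80.0,
    ("lactate", "plusS"): 62.0,
    ("butyrate", "plusS"): 188.0,
}


def default_category_weights(n_reference: int = 6440) -> dict[str, float]:
    """Category weights scaled from the annotated focal-genome gene sets."""
    w = {c: n / n_reference for c, n in DEFAULT_CATEGORY_COUNTS.items()}
    w["other"] = 1.0 - sum(w.values())
    return w


def default_design(
    substrates: Sequence[str] = SUBSTRATES,
    sulfates: Sequence[str] = SULFATE_LEVELS,
    days: Sequence[int] = (0, 8, 36),
    replicates: int = 3,
) -> pd.DataFrame:
    """Full-factorial sample sheet for the microcosm experiment.

    Returns a DataFrame with columns sample_id, substrate, sulfate, day,
    replicate; day 0 denotes the initial soil.
    """
    bad_days = set(days) - set(DAYS)
    if bad_days:
        raise ValueError(f"days not in the sampling schedule {DAYS}: {sorted(bad_days)}")
    rows = []
    for substrate in substrates:
        if substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate: {substrate!r}")
        for sulfate in sulfates:
            if sulfate not in SULFATE_LEVELS:
                raise ValueError(f"unknown sulfate level: {sulfate!r}")
            for day in days:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{substrate}_{sulfate}_d{day}_r{rep}",
                            "substrate": substrate,
                            "sulfate": sulfate,
                            "day": int(day),
                            "replicate": rep,
                        }
                    )
    design = pd.DataFrame(rows)
    if design.duplicated(["substrate", "sulfate", "day", "replicate"]).any():
        raise ValueError("duplicate (substrate, sulfate, day, replicate) in design")
    return design


@dataclass
class SimulationParams:
    """Knobs of the count simulator; defaults emulate the study conditions.

    baseline_log_mean/baseline_log_sd parameterize the natural-log normal
    baseline b_i (control-condition FPKM scale). dispersion is the NB phi
    with Var = mu + phi*mu^2. library_size_range spans the 27-188 million
    fragments per metatranscriptome of the experiment. activity_factor
    maps (substrate, sulfate) -> a > 0 for the treatment's day-36 plateau;
    before day 36 the factor ramps (day 0 -> 1, day 8 -> sqrt(a)).
    """

    n_genes: int = 2000
    baseline_log_mean: float = -3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (2.7e7, 1.88e8)
    activity_factor: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_FOLDS)
    )
    #: natural-log SD of the per-microcosm realized activity multiplier;
    #: replicate microcosms of the same condition differ strongly in
    #: realized activity (replicate SDs of total-transcript fractions are
    #: of the order of the mean), which this emulates
    activity_replicate_sd: float = 0.5
    coupling_exponent: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.activity_replicate_sd < 0:
            raise ValueError("activity_replicate_sd must be >= 0")
        for key, a in self.activity_factor.items():
            if a <= 0:
                raise ValueError(f"activity factor must be > 0 for {key}")
        for cat, g in self.coupling_exponent.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"coupling exponent out of [0, 1] for {cat!r}")


@dataclass
class CountMatrix:
    """Gene x sample fragment counts plus the sample design.

    library_sizes holds the whole-metatranscriptome fragment totals per
    sample (of which the focal genome's counts are a small part); needed
    for library-depth FPKM normalization.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count columns must match design sample_ids in order")


def generate_gene_catalog(
    n_genes: int,
    category_weights: Mapping[str, float] | None = None,
    length_range: tuple[int, int] = (300, 3000),
    seed: int = 0,
    genes_per_scaffold: int = 20,
) -> pd.DataFrame:
    """Draw a synthetic CDS catalog with category labels.

    Categories are assigned multinomially from ``category_weights`` (must
    sum to 1 within 1e-9); lengths are uniform over ``length_range``
    (within [100, 10000] nt). Genes are laid head-to-tail on scaffolds of
    ``genes_per_scaffold`` genes with 200-nt spacers.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if category_weights is None:
        category_weights = default_category_weights()
    unknown = set(category_weights) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in weights: {sorted(unknown)}")
    cats = [c for c in CATEGORIES if c in category_weights]
    probs = np.array([category_weights[c] for c in cats], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category weights must sum to 1, got {probs.sum()!r}")
    lo, hi = length_range
    if lo < 100 or hi > 10000 or lo > hi:
        raise ValueError("length_range must lie within [100, 10000] nt")

    rng = np.random.default_rng(seed)
    categories = rng.choice(cats, size=n_genes, p=probs)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)

    tag_counter: dict[str, int] = {c: 0 for c in CATEGORIES}
    records = []
    pos = 1
    for i in range(n_genes):
        scaffold_idx = i // genes_per_scaffold
        if i % genes_per_scaffold == 0:
            pos = 1
        cat = str(categories[i])
        tags = _PATHWAY_TAGS[cat]
        k = tag_counter[cat]
        tag = tags[k] if k < len(tags) else f"{tags[k % len(tags)]}_{k // len(tags)}"
        tag_counter[cat] = k + 1
        length = int(lengths[i])
        records.append(
            {
                "gene_id": f"gene_{i + 1:05d}",
                "scaffold_id": f"scaffold_{scaffold_idx + 1:04d}",
                "start": pos,
                "end": pos + length - 1,
                "strand": str(strands[i]),
                "length_nt": length,
                "category": cat,
                "pathway_tag": tag,
            }
        )
        pos += length + 200
    return pd.DataFrame(records)


def _resolve_activity(
    design: pd.DataFrame, activity_factor: Mapping, ramp_with_day: bool = True
) -> np.ndarray:
    """Per-sample activity multipliers a_j from a condition -> a map.

    Keys may be (substrate, sulfate) or (substrate, sulfate, day); the
    triple, when present, wins. Conditions absent from the map default to
    a = 1 only if a (substrate, sulfate) double exists for some condition;
    a fully empty map is an error. With two-key maps the factor ramps with
    incubation day: a^0 at day 0, a^0.5 at day 8, a^1 from day 36 on.
    """
    if not activity_factor:
        raise ValueError("activity_factor map is empty")
    ramp = {0: 0.0, 5: 0.4, 8: 0.5, 15: 0.7, 26: 0.9, 36: 1.0, 50: 1.0}
    out = np.empty(len(design), dtype=float)
    for idx, row in enumerate(design.itertuples(index=False)):
        triple = (row.substrate, row.sulfate, row.day)
        double = (row.substrate, row.sulfate)
        if triple in activity_factor:
            out[idx] = float(activity_factor[triple])
        elif double in activity_factor:
            a = float(activity_factor[double])
            out[idx] = a ** ramp[row.day] if ramp_with_day else a
        else:
            out[idx] = 1.0
    return out


def simulate_counts(
    catalog: pd.DataFrame,
    design: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
) -> CountMatrix:
    """Draw the gene x sample NB count matrix with planted activity coupling.

    Reproducible for a fixed seed (defaults to ``params.seed``). Raises if
    a category in the catalog has no coupling exponent.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if params.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    missing = set(catalog["category"]) - set(params.coupling_exponent)
    if missing:
        raise ValueError(f"no coupling exponent for categories: {sorted(missing)}")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    n_genes = len(catalog)
    n_samples = len(design)
    b = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, size=n_genes)
    lo, hi = params.library_size_range
    library_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    a = _resolve_activity(design, params.activity_factor)
    if params.activity_replicate_sd > 0:
        a = a * np.exp(rng.normal(0.0, params.activity_replicate_sd, size=n_samples))
    gamma = catalog["category"].map(params.coupling_exponent).to_numpy(float)
    lengths = catalog["length_nt"].to_numpy(float)

    # mu_ij = (L_i/1000) * (N_j/1e6) * b_i * a_j^gamma_i
    mu = (
        (lengths / 1000.0)[:, None]
        * b[:, None]
        * (library_sizes / 1e6)[None, :]
        * np.power(a[None, :], gamma[:, None])
    )
    if params.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(
        counts, index=catalog["gene_id"].to_numpy(), columns=design["sample_id"].to_numpy()
    )
    lib = pd.Series(np.round(library_sizes), index=design["sample_id"].to_numpy())
    return CountMatrix(counts=counts_df, design=design.reset_index(drop=True), library_sizes=lib)


def simulate_qpcr(
    design: pd.DataFrame,
    mean_copies: float = 1.2e6,
    cv: float = 0.2,
    fold_map: Mapping | None = None,
    seed: int = 0,
    target: str = "focal_population",
) -> pd.DataFrame:
    """16S rRNA gene copy series with log-normal noise around a stable mean.

    The geometric mean of draws at a condition equals
    ``mean_copies * fold_map(condition)``; fold_map defaults to 1
    everywhere (the stable low-abundance population). cv is the
    coefficient of variation of the log-normal noise.
    """
    if mean_copies <= 0:
        raise ValueError("mean_copies must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    folds = (
        _resolve_activity(design, fold_map, ramp_with_day=False)
        if fold_map
        else np.ones(len(design))
    )
    noise = rng.normal(0.0, sigma, size=len(design)) if cv > 0 else np.zeros(len(design))
    series = design.copy()
    series["copies_per_cm3"] = mean_copies * folds * np.exp(noise)
    series["target"] = target
    return series


def write_gff3(catalog: pd.DataFrame, path) -> None:
    """Write the catalog as GFF3 (one CDS feature per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in catalog.itertuples(index=False):
            attrs = (
                f"ID={row.gene_id};category={row.category};pathway_tag={row.pathway_tag}"
            )
            fh.write(
                f"{row.scaffold_id}\tzerogrowth\tCDS\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t0\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read a catalog written by :func:`write_gff3` back into a DataFrame."""
    cols = [
        "scaffold_id", "source", "type", "start", "end", "score", "strand",
        "frame", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    attr = df["attributes"].str.extract(
        r"ID=(?P<gene_id>[^;]+);category=(?P<category>[^;]+);pathway_tag=(?P<pathway_tag>[^;]+)"
    )
    out = pd.concat([attr, df[["scaffold_id", "start", "end", "strand"]]], axis=1)
    out["length_nt"] = out["end"] - out["start"] + 1
    return out[
        ["gene_id", "scaffold_id", "start", "end", "strand", "length_nt", "category", "pathway_tag"]
    ]
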