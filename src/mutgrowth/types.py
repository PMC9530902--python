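"""Domain types shared across the package.

The study system is a panel of *Escherichia coli* strains drawn from three
collections — MDS (mismatch-repair / proofreading deletion mutators built on
the genome-reduced MDS42), KHK (reduced-genome derivatives of W3110), and MG
(MG1655 and derivative mutators) — phenotyped in three media of decreasing
nutritional richness (LB, MAA, M63). Each strain x medium condition carries a
growth rate mu (h^-1) and a mutation rate M (per bp per division) estimated
from fluctuation assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MEDIA = ("LB", "MAA", "M63")

#: Ordinal coding of nutritional richness used by the regression layer.
MEDIUM_CODES = {"LB": 1, "MAA": 0, "M63": -1}

COLLECTIONS = ("MDS", "KHK", "MG")

GENOTYPE_CLASSES = (
    "wild type",
    "reduced genome",
    "mutator",
    "genome-reduced mutator",
)


class ConfigurationError(ValueError):
    """Invalid configuration (unknown collection, empty panel, bad rate...)."""


class QualityError(RuntimeError):
    """Data fail a quality gate (too few points, no reliable plate...)."""


def genotype_class(genome_reduced: int, mmr_deficient: int) -> str:
    """Map the two binary disturbance flags to the four-level genotype label."""
    return GENOTYPE_CLASSES[int(genome_reduced) + 2 * int(mmr_deficient)]


@dataclass(frozen=True)
class StrainRecord:
    """One strain: collection membership plus binary genotype flags."""

    strain_id: str
    collection: str
    genome_reduced: int
    mmr_deficient: int

    def __post_init__(self) -> None:
        if self.collection not in COLLECTIONS:
            raise ConfigurationError(f"unknown collection {self.collection!r}")
        for flag in (self.genome_reduced, self.mmr_deficient):
            if flag not in (0, 1):
                raise ConfigurationError("genotype flags must be 0 or 1")

    @property
    def genotype_class(self) -> str:
        return genotype_class(self.genome_reduced, self.mmr_deficient)


@dataclass(frozen=True)
class MediumSpec:
    """A growth medium with its trade-off law parameters.

    alpha_true is the slope of log10(mutation rate) per unit growth rate
    (negative: faster growth, lower mutation rate); m_inf_true is the maximal
    mutation rate (per bp per division) as growth rate approaches zero;
    mu_range bounds the growth rates (h^-1) the medium supports.
    """

    name: str
    alpha_true: float
    m_inf_true: float
    mu_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name not in MEDIA:
            raise ConfigurationError(f"unknown medium {self.name!r}")
        if self.m_inf_true <= 0:
            raise ConfigurationError("m_inf_true must be positive")
        if self.alpha_true >= 0:
            raise ConfigurationError("alpha_true must be negative")
        lo, hi = self.mu_range
        if not (0 <= lo < hi):
            raise ConfigurationError("mu_range must satisfy 0 <= lo < hi")

    @property
    def code(self) -> int:
        return MEDIUM_CODES[self.name]


def default_media() -> list[MediumSpec]:
    """The three study media with the fitted trade-off parameters.

    Slopes and maximal rates follow the fitted per-medium law
    (LB: -9.5 / 1e-3, MAA: -12.6 / 4e-4, M63: -12.8 / 7e-6); growth-rate
    ranges are chosen so generated mutation rates span ~1e-10..1e-7.
    """
    return [
        MediumSpec("LB", alpha_true=-9.5, m_inf_true=1e-3, mu_range=(0.4, 0.8)),
        MediumSpec("MAA", alpha_true=-12.6, m_inf_true=4e-4, mu_range=(0.25, 0.6)),
        MediumSpec("M63", alpha_true=-12.8, m_inf_true=7e-6, mu_range=(0.1, 0.45)),
    ]


@dataclass(frozen=True)
class TrueRates:
    """Ground-truth rates for one strain in one medium (generator output)."""

    strain_id: str
    medium: str
    mu_true: float   # growth rate, h^-1
    m_true: float    # mutation rate, per bp per division

    def __post_init__(self) -> None:
        if self.m_true <= 0:
            raise ConfigurationError("m_true must be positive")
        if self.mu_true < 0:
            raise ConfigurationError("mu_true must be non-negative")


@dataclass(frozen=True)
class PlateCounts:
    """CFU plating record: per-plate dilution factors and colony counts."""

    dilutions: tuple[float, ...]
    colony_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dilutions) == 0:
            raise ConfigurationError("at least one plate required")
        if len(self.dilutions) != len(self.colony_counts):
            raise ConfigurationError("dilutions and counts differ in length")
        if any(d <= 0 for d in self.dilutions):
            raise ConfigurationError("dilution factors must be positive")
        if any(c < 0 for c in self.colony_counts):
            raise ConfigurationError("colony counts must be non-negative")

    def __len__(self) -> int:
        return len(self.dilutions)


@dataclass
class FluctuationAssay:
    """One fluctuation test: mutant counts across parallel cultures.

    plate_counts may be attached later (the CFU assay is a separate plating
    step); target_size_bp is the effective mutational target conferring the
    selected resistance.
    """

    assay_id: str
    mutant_counts: np.ndarray
    target_size_bp: int
    plate_counts: PlateCounts | None = None
    n_final_true: float | None = None  # generator truth, if synthetic

    def __post_init__(self) -> None:
        self.mutant_counts = np.asarray(self.mutant_counts, dtype=np.int64)
        if self.mutant_counts.size < 2:
            raise ConfigurationError("need >= 2 parallel cultures")
        if (self.mutant_counts < 0).any():
            raise ConfigurationError("mutant counts must be non-negative")
        if self.target_size_bp <= 0:
            raise ConfigurationError("target_size_bp must be positive")


@dataclass
class GrowthCurve:
    """OD595 time series for a single well."""

    well_id: str
    times: np.ndarray   # hours, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ConfigurationError("times and od differ in length")
        if self.times.size < 5:
            raise QualityError("growth curve needs >= 5 points")
        if not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ConfigurationError("od values must be finite")


@dataclass(frozen=True)
class GrowthFit:
    """Estimated growth rate (h^-1) from windowed log-linear fitting."""

    rate: float
    window: tuple[int, int]
    r2: float
    se: float = float("nan")
    n_replicates: int = 1


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate estimate from one or more fluctuation assays."""

    m_hat: float                 # expected mutations per culture
    mutation_rate: float         # per bp per division
    ci_low: float
    ci_high: float
    n_final_hat: float
    method: str                  # "MSS-MLE" or "P0"
    all_zero: bool = False


@dataclass(frozen=True)
class TradeoffFit:
    """Per-medium fit of log10(mutation rate) = log10(m_inf) + alpha * mu."""

    medium: str
    alpha: float
    m_inf: float
    pearson_r: float
    p_value: float
    n_points: int
    alpha_se: float = float("nan")
    intercept_se: float = float("nan")


RATE_TABLE_COLUMNS = [
    "collection",
    "strain",
    "genome_reduced",
    "mmr_deficient",
    "medium",
    "growth_rate",
    "growth_se",
    "mutation_rate",
    "mutation_se",
    "n_replicates",
]


def validate_rate_table(table) -> None:
    """Check the tidy rate-table contract (one row per strain x medium,
    positive mutation rates, known media)."""
    missing = [c for c in RATE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"rate table missing columns: {missing}")
    if not set(table["medium"]).issubset(MEDIA):
        bad = sorted(set(table["medium"]) - set(MEDIA))
        raise ConfigurationError(f"unknown media in rate table: {bad}")
    if (table["mutation_rate"] <= 0).any():
        raise ConfigurationError("mutation rates must be positive")
    if table.duplicated(subset=["strain", "medium"]).any():
        raise ConfigurationError("duplicate (strain, medium) rows")


def subseed(seed: int, *tags: str | int) -> int:
    """Derive a stage-specific seed (< 2^31) from a global seed.

    Stable across runs and platforms; decouples stages so editing one stage's
    configuration does not shift another stage's random stream.
    """
    import zlib

    label = ":".join(str(t) for t in (seed, *tags))
    return zlib.crc32(label.encode("utf-8")) % (2**31 - 1)
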