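"""Seeded synthetic data: strain panels, trade-off-law rates, fluctuation
assays, CFU plates, and plate-reader growth curves.

The generator emulates the study conditions: three strain collections (MDS
mutators on the genome-reduced MDS42 background, KHK reduced genomes on
W3110, MG mutators on MG1655), three media (LB, MAA, M63), mutation rates
following the per-medium log-linear trade-off law
``log10(M) = log10(M_inf) + alpha * mu`` with log10-normal noise, ~30
parallel cultures per fluctuation assay, Poisson CFU plating, and logistic
OD curves with Gaussian read noise.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    FluctuationAssay,
    GrowthCurve,
    MediumSpec,
    PlateCounts,
    RATE_TABLE_COLUMNS,
    StrainRecord,
    TrueRates,
    subseed,
)

#: Parent strain of each collection (no mutation-machinery deletion).
PARENT_IDS = {"MDS": "MDS42", "KHK": "W3110", "MG": "MG1655"}

#: Growth handicap of each disturbance, as a fraction of the within-medium
#: growth-rate range (mutators and reduced genomes grow slower than parents).
_GROWTH_PENALTY = {"genome_reduced": 0.25, "mmr_deficient": 0.35}


def make_strain_panel(
    sizes: Mapping[str, int], seed: int = 0
) -> list[StrainRecord]:
    """Build a strain panel with the collections' genotype structure.

    Each requested collection contributes its parent strain (disturbance
    flags of the newly deleted machinery set to 0) plus derivatives carrying
    the collection's characteristic disturbance: MDS derivatives are
    genome-reduced mutators (MMR/proofreading genes deleted from MDS42), KHK
    derivatives are reduced genomes, MG derivatives are mutators. The panel
    is deterministic for a given (sizes, seed).
    """
    panel: list[StrainRecord] = []
    for collection, n in sizes.items():
        if collection not in PARENT_IDS:
            raise ConfigurationError(f"unknown collection {collection!r}")
        if n < 1:
            raise ConfigurationError(f"collection {collection} needs >= 1 strain")
        parent_gr = 1 if collection == "MDS" else 0
        panel.append(
            StrainRecord(PARENT_IDS[collection], collection, parent_gr, 0)
        )
        for i in range(1, n):
            if collection == "MDS":
                gr, md = 1, 1
            elif collection == "KHK":
                gr, md = 1, 0
            else:  # MG
                gr, md = 0, 1
            panel.append(
                StrainRecord(f"{collection}-d{i:02d}", collection, gr, md)
            )
    return panel


def parent_map(panel: Sequence[StrainRecord]) -> dict[str, str]:
    """Derivative -> parent strain id, per collection."""
    return {
        s.strain_id: PARENT_IDS[s.collection]
        for s in panel
        if s.strain_id != PARENT_IDS[s.collection]
    }


def sample_true_rates(
    panel: Sequence[StrainRecord],
    media: Sequence[MediumSpec],
    sigma_log10: float = 0.2,
    seed: int = 0,
) -> list[TrueRates]:
    """Draw ground-truth (mu, M) pairs obeying each medium's trade-off law.

    Each strain carries a latent vigor u in (0, 1) mapped affinely into
    every medium's growth-rate range. The collection parent draws its vigor
    from the upper part of the range; each derivative inherits the parent's
    vigor scaled by a sub-unity jitter and by multiplicative handicaps for
    its genome-reduction and MMR-deficiency flags, so derivatives always
    grow slower than their parent (the disturbance costs fitness). Reusing
    one u per strain across media preserves the per-strain growth ordering
    LB >= MAA >= M63 and yields the positive cross-media rate correlations
    seen in real panels. Mutation rates follow
    log10(M) = log10(M_inf) + alpha * mu + Normal(0, sigma_log10).
    """
    if len(panel) == 0:
        raise ConfigurationError("empty strain panel")
    if len(media) == 0:
        raise ConfigurationError("empty media list")
    if sigma_log10 < 0:
        raise ConfigurationError("sigma_log10 must be >= 0")

    rng = np.random.default_rng(subseed(seed, "true-rates"))
    parent_vigor: dict[str, float] = {}
    out: list[TrueRates] = []
    for strain in panel:
        if strain.collection not in parent_vigor:
            parent_vigor[strain.collection] = rng.uniform(0.6, 1.0)
        v = parent_vigor[strain.collection]
        if strain.strain_id != PARENT_IDS[strain.collection]:
            v *= rng.uniform(0.5, 1.0)
        u = (
            v
            * (1 - _GROWTH_PENALTY["genome_reduced"] * strain.genome_reduced)
            * (1 - _GROWTH_PENALTY["mmr_deficient"] * strain.mmr_deficient)
        )
        for medium in media:
            lo, hi = medium.mu_range
            mu = lo + u * (hi - lo)
            log10_m = (
                math.log10(medium.m_inf_true)
                + medium.alpha_true * mu
                + (rng.normal(0.0, sigma_log10) if sigma_log10 > 0 else 0.0)
            )
            out.append(TrueRates(strain.strain_id, medium.name, mu, 10.0**log10_m))
    return out


def sample_rates_on_law(
    medium: MediumSpec,
    n: int,
    sigma_log10: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (mu, M) pairs directly from one medium's trade-off law.

    Growth rates are uniform over the medium's supported range;
    log10(M) = log10(M_inf) + alpha * mu + Normal(0, sigma_log10). This is
    the generative law without the strain-panel machinery — the fixture for
    law-recovery exercises.
    """
    if n < 2:
        raise ConfigurationError("need n >= 2 pairs")
    rng = np.random.default_rng(subseed(seed, "law", medium.name))
    lo, hi = medium.mu_range
    mu = rng.uniform(lo, hi, size=n)
    log10_m = (
        math.log10(medium.m_inf_true)
        + medium.alpha_true * mu
        + (rng.normal(0.0, sigma_log10, size=n) if sigma_log10 > 0 else 0.0)
    )
    return mu, 10.0**log10_m


def law_rate_table(
    medium: MediumSpec, mu: np.ndarray, m: np.ndarray
) -> pd.DataFrame:
    """Wrap raw law samples as a rate table of anonymous wild-type strains."""
    rows = [
        {
            "collection": "MG",
            "strain": f"law-{i:03d}",
            "genome_reduced": 0,
            "mmr_deficient": 0,
            "medium": medium.name,
            "growth_rate": float(mu_i),
            "growth_se": 0.0,
            "mutation_rate": float(m_i),
            "mutation_se": 0.0,
            "n_replicates": 1,
        }
        for i, (mu_i, m_i) in enumerate(zip(mu, m))
    ]
    return pd.DataFrame(rows, columns=RATE_TABLE_COLUMNS)


def true_rate_table(
    panel: Sequence[StrainRecord], rates: Sequence[TrueRates]
) -> pd.DataFrame:
    """Assemble ground-truth rates into the tidy rate-table schema
    (SEs zero, single replicate) — the noiseless end of the pipeline."""
    by_id = {s.strain_id: s for s in panel}
    rows = [
        {
            "collection": by_id[r.strain_id].collection,
            "strain": r.strain_id,
            "genome_reduced": by_id[r.strain_id].genome_reduced,
            "mmr_deficient": by_id[r.strain_id].mmr_deficient,
            "medium": r.medium,
            "growth_rate": r.mu_true,
            "growth_se": 0.0,
            "mutation_rate": r.m_true,
            "mutation_se": 0.0,
            "n_replicates": 1,
        }
        for r in rates
    ]
    return pd.DataFrame(rows, columns=RATE_TABLE_COLUMNS)


def simulate_fluctuation_assay(
    m_true: float,
    n_final: float,
    target_size_bp: int,
    n_cultures: int = 30,
    seed: int = 0,
    assay_id: str = "assay",
) -> FluctuationAssay:
    """Simulate one fluctuation test by the stochastic clone-size process.

    The expected number of mutation events per culture is
    m = m_true * target_size_bp * n_final. Events per culture are Poisson(m);
    each event occurs at a time uniform in population growth, so its clone
    expands to floor(n_final / x) cells with x ~ Uniform(1, n_final) — the
    classic 1/x^2 clone-size law producing jackpot cultures. This is a
    process simulation, deliberately independent of the analytic pmf used by
    the estimators.
    """
    if n_cultures < 2:
        raise ConfigurationError("need >= 2 cultures")
    if n_final < 1e3:
        raise ConfigurationError("n_final must be >= 1e3")
    m = m_true * target_size_bp * n_final
    if not math.isfinite(m) or m < 0:
        raise ConfigurationError(f"expected mutations per culture m={m} invalid")

    rng = np.random.default_rng(subseed(seed, "fluctuation", assay_id))
    counts = np.zeros(n_cultures, dtype=np.int64)
    if m > 0:
        events = rng.poisson(m, size=n_cultures)
        total = int(events.sum())
        if total > 0:
            x = rng.uniform(1.0, n_final, size=total)
            clone_sizes = np.floor(n_final / x).astype(np.int64)
            culture_idx = np.repeat(np.arange(n_cultures), events)
            counts = np.bincount(
                culture_idx, weights=clone_sizes, minlength=n_cultures
            ).astype(np.int64)
    return FluctuationAssay(
        assay_id=assay_id,
        mutant_counts=counts,
        target_size_bp=target_size_bp,
        n_final_true=float(n_final),
    )


def simulate_cfu_plates(
    n_final: float,
    dilution_factors: Sequence[float],
    n_plates: int = 2,
    seed: int = 0,
) -> PlateCounts:
    """Simulate the CFU assay: n_plates plates per dilution factor, colony
    counts Poisson(n_final * dilution)."""
    if any(d <= 0 for d in dilution_factors):
        raise ConfigurationError("dilution factors must be positive")
    rng = np.random.default_rng(subseed(seed, "cfu"))
    dilutions: list[float] = []
    counts: list[int] = []
    for d in dilution_factors:
        lam = n_final * d
        draws = rng.poisson(lam, size=n_plates)
        dilutions.extend([d] * n_plates)
        counts.extend(int(c) for c in draws)
    return PlateCounts(tuple(dilutions), tuple(counts))


def simulate_growth_curves(
    mu_true: float,
    od0: float = 0.01,
    capacity: float = 1.0,
    interval_h: float = 0.5,
    duration_h: float = 48.0,
    noise_sd: float = 0.002,
    n_wells: int = 6,
    seed: int = 0,
    well_prefix: str = "well",
) -> list[GrowthCurve]:
    """Simulate plate-reader wells: logistic growth plus Gaussian read noise.

    OD(t) = capacity * od0 * e^(mu t) / (capacity + od0 * (e^(mu t) - 1)),
    readings every interval_h hours for duration_h, noise truncated at 0.
    """
    if not (0 < od0 < capacity):
        raise ConfigurationError("need 0 < od0 < capacity")
    if interval_h <= 0:
        raise ConfigurationError("interval_h must be positive")
    rng = np.random.default_rng(subseed(seed, "growth"))
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    growth = np.exp(mu_true * times)
    clean = capacity * od0 * growth / (capacity + od0 * (growth - 1.0))
    curves = []
    for w in range(n_wells):
        od = clean.copy()
        if noise_sd > 0:
            od = np.maximum(od + rng.normal(0.0, noise_sd, size=od.size), 0.0)
        curves.append(GrowthCurve(f"{well_prefix}{w + 1}", times, od))
    return curves


def curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Plate-reader layout: first column time (hours), one column per well."""
    data = {"time_h": curves[0].times}
    for c in curves:
        data[c.well_id] = c.od
    return pd.DataFrame(data)
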