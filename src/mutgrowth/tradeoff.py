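"""The mutation-rate / growth-rate trade-off analysis.

Within each medium, strains of every genotype fall on a common log-linear
trajectory

    log10(M_i) = log10(M_inf) + alpha * mu_i

where M_i is the mutation rate (per bp per division), mu_i the growth rate
(h^-1), M_inf the maximal mutation rate as growth approaches zero, and
alpha < 0 the slope coupling mutability to fitness. The fit pools all
collections: M_inf and alpha are medium properties, not genotype
properties. Companion statistics: per-medium Pearson correlation, paired
distribution-shift tests between media, cross-media rate correlations, and
per-strain fold changes relative to the parent strain.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigurationError, TradeoffFit, validate_rate_table


def fit_tradeoff(table: pd.DataFrame, medium: str) -> TradeoffFit:
    """OLS fit of log10(mutation rate) on growth rate for one medium.

    Pools every collection/genotype present. Returns the slope (alpha), the
    back-transformed intercept (m_inf = 10^intercept), and the Pearson
    correlation of log10(M) with mu on the same pairs.
    """
    validate_rate_table(table)
    sub = table[table["medium"] == medium]
    if len(sub) < 3:
        raise ConfigurationError(
            f"need >= 3 strains with rates in {medium}, got {len(sub)}"
        )
    mu = sub["growth_rate"].to_numpy(dtype=float)
    log_m = np.log10(sub["mutation_rate"].to_numpy(dtype=float))
    if np.ptp(mu) == 0:
        raise ConfigurationError(f"degenerate fit: constant growth rate in {medium}")
    res = stats.linregress(mu, log_m)
    return TradeoffFit(
        medium=medium,
        alpha=float(res.slope),
        m_inf=float(10.0**res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(sub),
        alpha_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def predict_mutation_rate(fit: TradeoffFit, mu: float) -> float:
    """Mutation rate predicted by the trade-off law at growth rate mu.

    At mu = 0 this is m_inf, the maximal mutation rate.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return float(10.0 ** (math.log10(fit.m_inf) + fit.alpha * mu))


def growth_rate_for_mutation_rate(fit: TradeoffFit, m: float) -> float:
    """Inverse of the trade-off law: growth rate at which the fitted line
    reaches mutation rate m."""
    if m <= 0:
        raise ValueError("m must be positive")
    return float((math.log10(m) - math.log10(fit.m_inf)) / fit.alpha)


def mutations_per_genome(m_inf: float, genome_size_bp: float = 4e6) -> float:
    """Expected mutations per genome per division at mutation rate m_inf.

    With a ~4 Mb genome, the rich-medium maximal rate corresponds to over a
    thousand mutations per genome, while the poor-medium one allows only a
    few.
    """
    if m_inf < 0 or genome_size_bp < 0:
        raise ValueError("arguments must be non-negative")
    return float(m_inf * genome_size_bp)


def compare_media_distributions(
    table: pd.DataFrame, medium_a: str, medium_b: str
) -> dict:
    """Paired shift of per-strain log10 mutation rates between two media.

    Wilcoxon signed-rank test (two-sided) on log10(M) of strains measured in
    both media; the shift is the median per-strain log10 difference
    (medium_a minus medium_b, in decades). Identical rates short-circuit to
    shift 0, p = 1.
    """
    validate_rate_table(table)
    a = table[table["medium"] == medium_a].set_index("strain")["mutation_rate"]
    b = table[table["medium"] == medium_b].set_index("strain")["mutation_rate"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ConfigurationError(
            f"need >= 3 strains in both {medium_a} and {medium_b}, "
            f"got {len(shared)}"
        )
    diff = np.log10(a[shared].to_numpy()) - np.log10(b[shared].to_numpy())
    if np.allclose(diff, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diff, alternative="two-sided")
    return {
        "medium_a": medium_a,
        "medium_b": medium_b,
        "median_log10_shift": float(np.median(diff)),
        "statistic": float(stat),
        "p_value": float(p),
        "n_pairs": int(len(shared)),
        "test": "wilcoxon-signed-rank (paired, two-sided, log10 rates)",
    }


def cross_media_correlation(
    table: pd.DataFrame,
    rate_kind: str = "mutation",
    per_collection: bool = True,
    log_scale: bool | None = None,
) -> pd.DataFrame:
    """Pearson correlation of per-strain rates between every media pair.

    Mutation rates correlate on the log10 scale (the plotted scale) unless
    log_scale is overridden; growth rates on the raw scale. Pairs with fewer
    than 3 shared strains are skipped with a warning. Returns one row per
    (collection or 'pooled', media pair).
    """
    validate_rate_table(table)
    if rate_kind not in ("mutation", "growth"):
        raise ConfigurationError("rate_kind must be 'mutation' or 'growth'")
    column = f"{rate_kind}_rate"
    use_log = rate_kind == "mutation" if log_scale is None else log_scale

    groups = [("pooled", table)]
    if per_collection:
        groups += [(c, g) for c, g in table.groupby("collection")]

    media = [m for m in ("LB", "MAA", "M63") if m in set(table["medium"])]
    rows = []
    for label, sub in groups:
        wide = sub.pivot(index="strain", columns="medium", values=column)
        for ma, mb in itertools.combinations(media, 2):
            pair = wide[[ma, mb]].dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"skipping {label} {ma}/{mb}: only {len(pair)} shared strains"
                )
                continue
            x, y = pair[ma].to_numpy(), pair[mb].to_numpy()
            if use_log:
                x, y = np.log10(x), np.log10(y)
            r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "group": label,
                    "medium_a": ma,
                    "medium_b": mb,
                    "rate_kind": rate_kind,
                    "pearson_r": float(r),
                    "p_value": float(p),
                    "n": int(len(pair)),
                }
            )
    return pd.DataFrame(rows)


def disturbance_fold_changes(
    table: pd.DataFrame, parent_map: Mapping[str, str]
) -> pd.DataFrame:
    """log10 rate ratios of each derivative strain to its parent, per medium.

    Positive mutation-rate ratios with negative growth-rate ratios are the
    signature of the trade-off: the genetic disturbance raises mutability at
    a growth cost. Returned tidy: one row per (strain, medium) with both
    ratios.
    """
    validate_rate_table(table)
    indexed = table.set_index(["strain", "medium"])
    rows = []
    for strain, parent in parent_map.items():
        for medium in sorted(set(table["medium"])):
            if (strain, medium) not in indexed.index:
                continue
            if (parent, medium) not in indexed.index:
                raise ConfigurationError(
                    f"parent {parent!r} of {strain!r} missing in medium {medium}"
                )
            d = indexed.loc[(strain, medium)]
            p = indexed.loc[(parent, medium)]
            rows.append(
                {
                    "strain": strain,
                    "parent": parent,
                    "medium": medium,
                    "log10_mutation_ratio": math.log10(
                        d["mutation_rate"] / p["mutation_rate"]
                    ),
                    "log10_growth_ratio": math.log10(
                        d["growth_rate"] / p["growth_rate"]
                    )
                    if d["growth_rate"] > 0 and p["growth_rate"] > 0
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
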