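"""End-to-end orchestration: simulate -> estimate -> fit -> predict -> report.

Stage order mirrors the analysis: ground-truth rates are drawn from the
per-medium trade-off law, raw fluctuation assays and growth curves are
simulated from them, the estimators recover a tidy rate table, the
trade-off is refit per medium, and the regression/classification layer runs
on the recovered table. Recovery diagnostics (true vs estimated alpha and
M_inf) close the loop.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluctuation, growth, io, models, synthetic, tradeoff
from .types import (
    ConfigurationError,
    MediumSpec,
    RATE_TABLE_COLUMNS,
    TradeoffFit,
    default_media,
    subseed,
)

logger = logging.getLogger("mutgrowth")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage. Outputs written
    by earlier stages are retained."""


class _StageGuard:
    """Context manager attributing a stage failure to its stage name and
    logging one structured line on success."""

    def __init__(self, name: str):
        self.name = name
        self.rows_in = 0
        self.rows_out = 0

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(f"stage '{self.name}' failed: {exc}") from exc
        logger.info(
            "stage=%s elapsed=%.2fs rows_in=%d rows_out=%d",
            self.name, time.perf_counter() - self.t0, self.rows_in, self.rows_out,
        )
        return False


@dataclass
class RunConfig:
    """Every knob of the end-to-end run; all randomness derives from seed."""

    # panel
    n_mds: int = 14
    n_khk: int = 10
    n_mg: int = 10
    media: tuple[str, ...] = ("LB", "MAA", "M63")
    sigma_log10: float = 0.2
    # per-medium overrides {name: {"alpha_true":..., "m_inf_true":..., "mu_range":...}}
    media_params: dict = field(default_factory=dict)
    # fluctuation assay design
    n_cultures: int = 30
    n_assay_replicates: int = 3
    target_size_bp: int = 30
    m_design: float = 2.0          # intended expected mutations per culture
    n_final_bounds: tuple[float, float] = (1e5, 5e9)
    estimator: str = "mle"
    # CFU plating
    cfu_plates_per_dilution: int = 2
    # growth assay
    od0: float = 0.01
    capacity: float = 1.0
    interval_h: float = 0.5
    duration_h: float = 48.0
    od_noise_sd: float = 0.002
    n_wells: int = 6
    window_points: int = 5
    r2_gate: float = 0.95
    # prediction layer
    n_classifier_repeats: int = 5
    test_fraction: float = 0.4
    # bookkeeping
    outdir: str | None = None
    seed: int = 0

    def medium_specs(self) -> list[MediumSpec]:
        specs = []
        for spec in default_media():
            if spec.name not in self.media:
                continue
            override = self.media_params.get(spec.name, {})
            specs.append(
                dataclasses.replace(
                    spec,
                    **{
                        k: tuple(v) if k == "mu_range" else v
                        for k, v in override.items()
                    },
                )
            )
        if not specs:
            raise ConfigurationError(f"no known media among {self.media}")
        return specs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["media"] = list(self.media)
        d["n_final_bounds"] = list(self.n_final_bounds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "media" in kwargs:
            kwargs["media"] = tuple(kwargs["media"])
        if "n_final_bounds" in kwargs:
            kwargs["n_final_bounds"] = tuple(kwargs["n_final_bounds"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RunReport:
    config: RunConfig
    rate_table: pd.DataFrame
    true_table: pd.DataFrame
    tradeoff_fits: list[TradeoffFit]
    regressions: list[models.RegressionReport]
    classifications: list[models.ClassificationReport]
    skipped: dict[str, str]  # stage/option combinations refused, with reasons
    diagnostics: pd.DataFrame        # true vs recovered alpha / m_inf
    mutations_per_genome: dict[str, float]
    manifest: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline for one config; deterministic for a fixed
    (config, seed). Any stage failure aborts naming the stage; files already
    written are retained."""
    seed = config.seed
    media = config.medium_specs()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    with _StageGuard("simulate") as g:
        panel = synthetic.make_strain_panel(
            {"MDS": config.n_mds, "KHK": config.n_khk, "MG": config.n_mg},
            seed=subseed(seed, "panel"),
        )
        truths = synthetic.sample_true_rates(
            panel, media, sigma_log10=config.sigma_log10,
            seed=subseed(seed, "rates"),
        )
        true_table = synthetic.true_rate_table(panel, truths)
        g.rows_in, g.rows_out = len(panel), len(true_table)

    with _StageGuard("estimate") as g:
        strain_by_id = {s.strain_id: s for s in panel}
        rows = []
        all_assays, all_plates = [], {}
        lo_n, hi_n = config.n_final_bounds
        for truth in truths:
            strain = strain_by_id[truth.strain_id]
            # assay design: choose the culture size that puts the expected
            # number of mutations per culture near m_design, as at the bench
            n_final = float(
                np.clip(
                    config.m_design / (truth.m_true * config.target_size_bp),
                    lo_n, hi_n,
                )
            )
            estimates = []
            for rep in range(config.n_assay_replicates):
                assay_id = f"{truth.strain_id}:{truth.medium}:r{rep}"
                assay = synthetic.simulate_fluctuation_assay(
                    truth.m_true,
                    n_final,
                    config.target_size_bp,
                    n_cultures=config.n_cultures,
                    seed=seed,
                    assay_id=assay_id,
                )
                plates = synthetic.simulate_cfu_plates(
                    n_final,
                    dilution_factors=[150.0 / n_final, 40.0 / n_final],
                    n_plates=config.cfu_plates_per_dilution,
                    seed=subseed(seed, "plates", assay_id),
                )
                assay.plate_counts = plates
                all_assays.append(assay)
                all_plates[assay_id] = plates
                estimates.append(
                    fluctuation.mutation_rate_from_assay(
                        assay, method=config.estimator
                    )
                )
            mut_rate, mut_se = fluctuation.combine_rate_estimates(estimates)
            if mut_rate <= 0:  # every replicate all-zero: report the CI bound
                mut_rate = max(e.ci_high for e in estimates)

            curves = synthetic.simulate_growth_curves(
                truth.mu_true,
                od0=config.od0,
                capacity=config.capacity,
                interval_h=config.interval_h,
                duration_h=config.duration_h,
                noise_sd=config.od_noise_sd,
                n_wells=config.n_wells,
                seed=subseed(seed, "curves", truth.strain_id, truth.medium),
                well_prefix=f"{truth.strain_id}:{truth.medium}:w",
            )
            gfit = growth.rate_from_curves(
                curves,
                window_points=config.window_points,
                r2_gate=config.r2_gate,
            )
            rows.append(
                {
                    "collection": strain.collection,
                    "strain": strain.strain_id,
                    "genome_reduced": strain.genome_reduced,
                    "mmr_deficient": strain.mmr_deficient,
                    "medium": truth.medium,
                    "growth_rate": gfit.rate,
                    "growth_se": gfit.se,
                    "mutation_rate": mut_rate,
                    "mutation_se": mut_se,
                    "n_replicates": config.n_assay_replicates,
                }
            )
        rate_table = pd.DataFrame(rows, columns=RATE_TABLE_COLUMNS)
        g.rows_in, g.rows_out = len(truths), len(rate_table)

        if outdir:
            for name, writer in [
                ("rate_table.csv", lambda p: io.write_rate_table(rate_table, p)),
                ("true_rates.csv", lambda p: io.write_rate_table(true_table, p)),
                ("assays.csv", lambda p: io.write_assays(all_assays, p)),
                ("plates.csv", lambda p: io.write_plates(all_plates, p)),
            ]:
                path = outdir / name
                writer(path)
                manifest.append(str(path))

    with _StageGuard("tradeoff") as g:
        fits = [tradeoff.fit_tradeoff(rate_table, m.name) for m in media]
        diag_rows = []
        for spec, fit in zip(media, fits):
            diag_rows.append(
                {
                    "medium": spec.name,
                    "alpha_true": spec.alpha_true,
                    "alpha_hat": fit.alpha,
                    "alpha_rel_err": abs(fit.alpha - spec.alpha_true)
                    / abs(spec.alpha_true),
                    "log10_m_inf_true": np.log10(spec.m_inf_true),
                    "log10_m_inf_hat": np.log10(fit.m_inf),
                    "pearson_r": fit.pearson_r,
                    "p_value": fit.p_value,
                }
            )
        diagnostics = pd.DataFrame(diag_rows)
        mpg = {f.medium: tradeoff.mutations_per_genome(f.m_inf) for f in fits}
        g.rows_in, g.rows_out = len(rate_table), len(fits)

    with _StageGuard("predict") as g:
        regressions, errors = [], {}
        for mode in ("interactive", "additive"):
            encoded = models.encode_features(rate_table, mode=mode)
            for response in ("mutation", "growth"):
                try:
                    regressions.append(models.fit_mlr(encoded, response, mode))
                except ConfigurationError as err:
                    errors[f"mlr/{response}/{mode}"] = str(err)
        encoded = models.encode_features(rate_table, mode="interactive")
        classifications = []
        for target in ("medium", "genotype"):
            for kernel in ("linear", "rbf"):
                try:
                    classifications.append(
                        models.classify(
                            encoded,
                            target=target,
                            kernel=kernel,
                            test_fraction=config.test_fraction,
                            n_repeats=config.n_classifier_repeats,
                            # kernel excluded: both kernels are compared on
                            # identical train/test divisions (paired design)
                            seed=subseed(seed, "svm", target),
                        )
                    )
                except ConfigurationError as err:
                    errors[f"{target}/{kernel}"] = str(err)
        g.rows_in = len(encoded)
        g.rows_out = len(regressions) + len(classifications)

    report = RunReport(
        config=config,
        rate_table=rate_table,
        true_table=true_table,
        tradeoff_fits=fits,
        regressions=regressions,
        classifications=classifications,
        skipped=errors,
        diagnostics=diagnostics,
        mutations_per_genome=mpg,
        manifest=manifest,
    )
    if outdir:
        with _StageGuard("report"):
            fit_path = outdir / "tradeoff_fits.csv"
            pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
                fit_path, index=False
            )
            manifest.append(str(fit_path))
            summary_path = outdir / "summary.txt"
            summary_path.write_text(summarize(report) + "\n")
            manifest.append(str(summary_path))
    return report


def summarize(report: RunReport) -> str:
    """Human-readable run summary; a pure function of the report."""
    lines = ["== mutation/growth trade-off pipeline =="]
    lines.append(
        f"strains: {report.rate_table['strain'].nunique()}  "
        f"conditions: {len(report.rate_table)}"
    )
    lines.append("")
    lines.append("Trade-off law per medium (true -> recovered):")
    for _, d in report.diagnostics.iterrows():
        lines.append(
            f"  {d['medium']:>4}: alpha {d['alpha_true']:+.2f} -> "
            f"{d['alpha_hat']:+.2f} ({100 * d['alpha_rel_err']:.1f}% err), "
            f"log10 M_inf {d['log10_m_inf_true']:+.2f} -> "
            f"{d['log10_m_inf_hat']:+.2f}, r = {d['pearson_r']:.3f}"
        )
    lines.append("")
    lines.append("Mutations per genome per division at M_inf (4 Mb genome):")
    for medium, v in report.mutations_per_genome.items():
        lines.append(f"  {medium:>4}: {v:,.1f}")
    lines.append("")
    lines.append("Multiple linear regression (adjusted R^2):")
    for r in report.regressions:
        flag = f" [dropped: {', '.join(r.dropped)}]" if r.dropped else ""
        lines.append(
            f"  {r.response:>8} ~ ({r.mode}): adj R2 = {r.adj_r2:.3f}, "
            f"n = {r.n}{flag}"
        )
    lines.append("")
    lines.append("SVM classification (mean test accuracy over repeats):")
    if not report.classifications and not report.skipped:
        lines.append("  skipped")
    for c in report.classifications:
        accs = ", ".join(f"{a:.2f}" for a in c.accuracies)
        lines.append(
            f"  {c.target:>8} / {c.kernel:<6}: mean {c.mean_accuracy:.3f} "
            f"[{accs}]"
        )
    for key, msg in report.skipped.items():
        lines.append(f"  {key}: skipped ({msg})")
    return "\n".join(lines)
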