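"""End-to-end orchestration: ingest -> screening -> sufficiency gate -> AFT fits
-> thresholds -> report.

One configuration drives the whole analysis on either a real necropsy CSV or
a synthetic dataset, and the report mirrors the published analysis shape:
an ingestion/mortality-rate table, per-combination sufficiency verdicts,
fitted-model summaries, a threshold table (50%/90% lethal loads with
bootstrap CIs) and per-species absolute thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import screening
from .aft import AFTFit, AFTModelSpec, bootstrap_fits, fit_aft, select_best_model
from .core import LoadMetric, PlasticCategory, Taxon
from .necropsy import (
    NecropsyDataset,
    SpeciesReference,
    derive_load_observations,
    filter_detection_limit,
    impute_body_size,
    load_necropsy_table,
)
from .simulate import SimulationConfig
from .thresholds import absolute_threshold, invert_threshold, mortality_curve, threshold_with_ci

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "species_absolute_table",
           "EXIT_OK", "EXIT_NO_SUFFICIENT", "EXIT_CRASH"]

EXIT_OK = 0
EXIT_CRASH = 1
EXIT_NO_SUFFICIENT = 2


@dataclass(frozen=True)
class Combination:
    """One taxon x category-subset x metric to attempt."""

    taxon: Taxon
    category: PlasticCategory | None  # None = TOTAL
    metric: LoadMetric


@dataclass
class PipelineConfig:
    necropsy_csv: str | None = None
    species_reference_csv: str | None = None
    simulation: SimulationConfig | None = None
    combinations: list[Combination] = field(default_factory=list)
    candidate_covariates: tuple[str, ...] = ("individual_length", "species_mean_length")
    q_values: tuple[float, ...] = (0.5, 0.9)
    n_boot: int = 1000
    seed: int = 0
    min_size_mm: float = 5.0
    out_dir: str | None = None
    species_lengths: dict[str, float] = field(default_factory=dict)  # for absolute thresholds

    def __post_init__(self) -> None:
        if any(not 0 < q < 1 for q in self.q_values):
            raise ValueError("q values must lie in (0, 1)")
        if self.n_boot < 0:
            raise ValueError("n_boot must be nonnegative")
        if self.necropsy_csv is None and self.simulation is None:
            raise ValueError("either a necropsy CSV or a simulation config is required")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None and not isinstance(
            d["simulation"], SimulationConfig
        ):
            from .simulate import Law, TrueParameters

            sim = dict(d["simulation"])
            if "true_params" in sim:
                tp = dict(sim["true_params"])
                for law_key in ("censor_law", "species_mean_length_law"):
                    if law_key in tp and not isinstance(tp[law_key], Law):
                        tp[law_key] = Law(tp[law_key]["name"], tuple(tp[law_key]["params"]))
                if "beta" in tp:
                    tp["beta"] = tuple(tp["beta"])
                if "covariate_names" in tp:
                    tp["covariate_names"] = tuple(tp["covariate_names"])
                if "metric" in tp:
                    tp["metric"] = LoadMetric(tp["metric"])
                sim["true_params"] = TrueParameters(**tp)
            if "taxon" in sim:
                sim["taxon"] = Taxon(sim["taxon"])
            if "category_mix" in sim:
                sim["category_mix"] = {
                    PlasticCategory(k): v for k, v in sim["category_mix"].items()
                }
            if "mean_piece_volume_cm3" in sim:
                sim["mean_piece_volume_cm3"] = {
                    PlasticCategory(k): v for k, v in sim["mean_piece_volume_cm3"].items()
                }
            d["simulation"] = SimulationConfig(**sim)
        combos = []
        for c in d.get("combinations", []):
            if isinstance(c, Combination):
                combos.append(c)
            else:
                combos.append(
                    Combination(
                        taxon=Taxon(c["taxon"]),
                        category=None
                        if c.get("category") in (None, "TOTAL", "total")
                        else PlasticCategory(c["category"]),
                        metric=LoadMetric(c.get("metric", "piece_count")),
                    )
                )
        d["combinations"] = combos
        for key in ("candidate_covariates", "q_values"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunReport:
    table1: pd.DataFrame  # frequency of occurrence + KD%/PD% per taxon/category
    verdicts: list[screening.SufficiencyVerdict]
    fits: list[AFTFit]
    thresholds: pd.DataFrame  # Table-2 analogue
    absolute: pd.DataFrame  # Table-3 analogue
    curves: dict[str, pd.DataFrame]
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        """Deterministic JSON summary (no timestamps)."""
        return json.dumps(
            {
                "table1": self.table1.reset_index().to_dict(orient="records"),
                "verdicts": [
                    {
                        "taxon": v.taxon.value,
                        "category": v.category.value if v.category else "TOTAL",
                        "n_deaths": v.n_deaths,
                        "kw_p": None if np.isnan(v.kw_p) else v.kw_p,
                        "dunn_p_kd_vs_knd": None
                        if np.isnan(v.dunn_p_kd_vs_knd)
                        else v.dunn_p_kd_vs_knd,
                        "ordered_medians": v.ordered_medians,
                        "sufficient": v.sufficient,
                        "reasons": v.reasons,
                    }
                    for v in self.verdicts
                ],
                "fits": [json.loads(f.to_json()) for f in self.fits],
                "thresholds": self.thresholds.to_dict(orient="records"),
                "absolute": self.absolute.to_dict(orient="records"),
                "log": self.log,
            },
            sort_keys=True,
            default=float,
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.table1.to_csv(out / "table1_rates.csv")
        self.thresholds.to_csv(out / "table2_thresholds.csv", index=False)
        self.absolute.to_csv(out / "table3_absolute.csv", index=False)
        for name, curve in self.curves.items():
            curve.to_csv(out / f"curve_{name}.csv", index=False)


def _load_input(config: PipelineConfig) -> NecropsyDataset:
    if config.necropsy_csv is not None:
        return load_necropsy_table(config.necropsy_csv)
    from .simulate import generate_dataset

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    return generate_dataset(sim)


def _candidate_specs(combo: Combination, covariates: tuple[str, ...]) -> list[AFTModelSpec]:
    cats = None if combo.category is None else frozenset({combo.category})
    specs = [AFTModelSpec(combo.taxon, cats, combo.metric, ())]
    for cov in covariates:
        specs.append(AFTModelSpec(combo.taxon, cats, combo.metric, (cov,)))
    if len(covariates) >= 2:
        specs.append(AFTModelSpec(combo.taxon, cats, combo.metric, tuple(covariates[:2])))
    return specs


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and assemble the report.  Deterministic given the seed."""
    log: list[str] = []
    dataset = _load_input(config)
    log.append(f"loaded {len(dataset)} records ({dataset.provenance})")

    filtered = filter_detection_limit(dataset, config.min_size_mm)
    log.append(f"detection-limit filter (>= {config.min_size_mm} mm): {len(filtered)} records")

    if config.species_reference_csv:
        ref = SpeciesReference.from_csv(config.species_reference_csv)
        filtered = NecropsyDataset(
            [impute_body_size(r, ref) for r in filtered.records],
            provenance=filtered.provenance,
        )
        n_imp = sum(r.imputed for r in filtered.records)
        log.append(f"body-size imputation: {n_imp} records imputed")

    taxa = sorted({c.taxon for c in config.combinations}, key=lambda t: t.value) or sorted(
        {r.taxon for r in filtered.records}, key=lambda t: t.value
    )
    t1_rows = []
    for taxon in taxa:
        try:
            fo = frequency = screening.frequency_of_occurrence(filtered, taxon)
            mort = screening.mortality_given_ingestion(filtered, taxon)
        except ValueError as exc:
            log.append(f"table1 skipped for {taxon.value}: {exc}")
            continue
        for key in fo.index:
            t1_rows.append(
                {
                    "taxon": taxon.value,
                    "category": key,
                    "fo_pct": fo[key],
                    "kd_pct": mort.kd_pct.get(key, np.nan),
                    "pd_pct": mort.pd_pct.get(key, np.nan),
                }
            )
    table1 = pd.DataFrame(t1_rows).set_index(["taxon", "category"]) if t1_rows else pd.DataFrame()

    verdicts: list[screening.SufficiencyVerdict] = []
    fits: list[AFTFit] = []
    threshold_rows: list[dict] = []
    curves: dict[str, pd.DataFrame] = {}
    gate_cache: dict[tuple[Taxon, PlasticCategory | None], screening.SufficiencyVerdict] = {}

    for combo in config.combinations:
        key = (combo.taxon, combo.category)
        if key not in gate_cache:
            gate_cache[key] = screening.data_sufficiency(filtered, combo.taxon, combo.category)
            verdicts.append(gate_cache[key])
        verdict = gate_cache[key]
        cat_label = combo.category.value if combo.category else "TOTAL"
        if not verdict.sufficient:
            log.append(
                f"skipped {combo.taxon.value}/{cat_label}/{combo.metric.value}: "
                + "; ".join(verdict.reasons)
            )
            continue

        candidates = []
        for spec in _candidate_specs(combo, config.candidate_covariates):
            try:
                obs = derive_load_observations(filtered, spec)
                candidates.append((spec, obs, fit_aft(obs, spec=spec)))
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.append(f"fit failed for {spec.label}: {exc}")
        converged = [(s, o, f) for s, o, f in candidates if f.converged]
        if not converged:
            log.append(f"no converged fit for {combo.taxon.value}/{cat_label}/{combo.metric.value}")
            continue
        best = select_best_model([f for _, _, f in converged])
        spec, obs, _ = next(c for c in converged if c[2] is best)
        fits.append(best)
        log.append(
            f"fit {spec.label}: N={best.n_events + best.n_censored} "
            f"({best.n_events} events, {best.n_censored} censored), "
            f"sigma={best.sigma:.3f}, AIC={best.aic:.1f}"
        )

        boots = (
            bootstrap_fits(obs, spec=spec, n_boot=config.n_boot, seed=config.seed + 1)
            if config.n_boot
            else []
        )
        x_prof = best.covariate_profile
        row = {
            "taxon": combo.taxon.value,
            "category": cat_label,
            "metric": combo.metric.value,
            "covariates": ",".join(spec.covariates),
            "n_events": best.n_events,
            "n_censored": best.n_censored,
            "covariate_profile": ";".join(f"{v:g}" for v in x_prof),
            "ci_available": bool(boots),
        }
        for q in config.q_values:
            tag = f"q{int(round(q * 100))}"
            if boots:
                est = threshold_with_ci(best, boots, q, x_prof)
                row[f"{tag}_threshold"] = est.point
                row[f"{tag}_ci_low"] = est.ci_low
                row[f"{tag}_ci_high"] = est.ci_high
            else:
                row[f"{tag}_threshold"] = invert_threshold(best, q, x_prof)
                row[f"{tag}_ci_low"] = np.nan
                row[f"{tag}_ci_high"] = np.nan
        threshold_rows.append(row)

        grid_max = invert_threshold(best, 0.99, x_prof)
        grid = np.linspace(0.0, grid_max, 101)
        curve = mortality_curve(best, boots, grid, x_prof)
        curves[f"{combo.taxon.value}_{cat_label}_{combo.metric.value}"] = pd.DataFrame(
            {
                "load": curve.load,
                "probability": curve.probability,
                "ci_low": curve.band_low,
                "ci_high": curve.band_high,
            }
        )

    thresholds_df = pd.DataFrame(threshold_rows)
    absolute_df = (
        species_absolute_table(thresholds_df, config.species_lengths)
        if len(thresholds_df)
        else pd.DataFrame()
    )
    report = RunReport(
        table1=table1,
        verdicts=verdicts,
        fits=fits,
        thresholds=thresholds_df,
        absolute=absolute_df,
        curves=curves,
        log=log,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def species_absolute_table(
    thresholds: pd.DataFrame, species_length_table: dict[str, float]
) -> pd.DataFrame:
    """Scale per-length thresholds to absolute amounts for named animals.

    Cross-product of species x (q, taxon-category) rows restricted to
    per-length metrics; piece-count thresholds are not scalable and are
    excluded with a note column left implicit in the log.
    """
    rows = []
    if thresholds is None or not len(thresholds) or not species_length_table:
        return pd.DataFrame(
            columns=["species", "body_length_cm", "taxon", "category", "q", "absolute_threshold"]
        )
    per_length = thresholds[
        thresholds.metric.isin(
            [LoadMetric.VOLUME_PER_LENGTH.value, LoadMetric.LENGTH_PER_LENGTH.value]
        )
    ]
    n_excluded = len(thresholds) - len(per_length)
    if n_excluded:
        logger.info("%d piece-count threshold rows excluded (not scalable by length)", n_excluded)
    q_cols = [c for c in thresholds.columns if c.endswith("_threshold") and c.startswith("q")]
    for species, length in species_length_table.items():
        if length <= 0:
            raise ValueError(f"species length must be positive ({species})")
        for _, trow in per_length.iterrows():
            for col in q_cols:
                q = int(col[1 : col.index("_")]) / 100.0
                rows.append(
                    {
                        "species": species,
                        "body_length_cm": length,
                        "taxon": trow["taxon"],
                        "category": trow["category"],
                        "metric": trow["metric"],
                        "q": q,
                        "absolute_threshold": absolute_threshold(float(trow[col]), length),
                    }
                )
    return pd.DataFrame(rows)
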