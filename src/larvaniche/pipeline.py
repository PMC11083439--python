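"""End-to-end orchestration: preprocess → growth → maternal → trophic → niche → stats.

Every stage persists its output as CSV in the run directory so the run is
inspectable and restartable; a JSON manifest records the configuration
snapshot, seed, stage order, SHA-256 digests of every output file, and all
warnings raised along the way.  For a fixed (config, seed, inputs) triple the
table files are byte-identical across runs (the manifest carries timestamps
and is the one file excluded from that guarantee).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth as growth_mod
from . import maternal as maternal_mod
from . import niche as niche_mod
from . import stats as stats_mod
from . import trophic as trophic_mod
from .config import AnalysisConfig
from .dataio import (
    CohortDataset,
    STAGE_POST,
    STAGE_PRE,
    read_larvae,
    read_stations,
    validate_dataset,
    write_table,
)
from .maternal import EggIsotopeParams
from .preprocess import preprocess_dataset
from .synthetic import SimulationConfig, default_cohort_configs, simulate_two_cohorts

logger = logging.getLogger(__name__)

STAGE_ORDER = ("preprocess", "growth", "maternal", "trophic", "niche", "stats")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    started: float = 0.0
    finished: float = 0.0
    warnings: list[str] = field(default_factory=list)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df_or_records, path: Path, manifest: RunManifest) -> None:
    if isinstance(df_or_records, pd.DataFrame):
        if df_or_records.empty:
            return
    elif not df_or_records:
        return
    write_table(df_or_records, path)
    manifest.files[path.name] = _digest(path)


def load_dataset(larvae_path: str | Path, stations_path: str | Path) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from the two input CSVs."""
    larvae, rej_l = read_larvae(larvae_path)
    stations, rej_s = read_stations(stations_path)
    if rej_l or rej_s:
        logger.warning("rejected rows: %d larvae, %d stations", len(rej_l), len(rej_s))
    return CohortDataset(larvae=larvae, stations=stations, provenance=str(larvae_path))


def _summary_rows(values_by_group: dict, variable: str, stage: str) -> list[dict]:
    rows = []
    for group, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        rows.append(
            {
                "stage": stage,
                "variable": variable,
                "group": group,
                "n": len(v),
                "min": float(v.min()) if len(v) else float("nan"),
                "max": float(v.max()) if len(v) else float("nan"),
                "mean": float(v.mean()) if len(v) else float("nan"),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            }
        )
    return rows


_GROWTH_VARS = {"SL": "sl_mm", "DW": "dw_mg", "RADIUS": "radius_um", "MIW": "miw_um"}
_LOG_VARS = {"SL", "DW"}  # log-transformed before ANCOVA for linearity


def run_pipeline(
    config: AnalysisConfig | None = None,
    out_dir: str | Path = "run",
    dataset: CohortDataset | None = None,
    larvae_path: str | Path | None = None,
    stations_path: str | Path | None = None,
    simulate: bool = False,
    sim_configs: tuple[SimulationConfig, SimulationConfig] | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Run the full analysis and write the report directory.

    Inputs come from one of: an in-memory ``dataset``, CSV paths, or
    ``simulate=True`` (two synthetic cohorts; defaults to
    :func:`~larvaniche.synthetic.default_cohort_configs`).  Returns the
    manifest; all tables live in ``out_dir``.
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config), seed=seed, started=time.time())

    egg_params: dict[str, EggIsotopeParams] = dict(config.egg or {})

    if simulate:
        sim_configs = sim_configs or default_cohort_configs()
        dataset, truth = simulate_two_cohorts(sim_configs[0], sim_configs[1], seed=seed)
        _write(dataset.larvae, out / "larvae.csv", manifest)
        _write(dataset.stations, out / "stations.csv", manifest)
        _write(truth, out / "truth.csv", manifest)
        for cfg in sim_configs:
            egg_params.setdefault(
                cfg.cohort,
                EggIsotopeParams(
                    mean_d15n_egg=cfg.maternal_d15n_mean,
                    sd_d15n_egg=cfg.maternal_d15n_sd,
                    mean_d13c_egg=cfg.maternal_d13c_mean,
                    sd_d13c_egg=cfg.maternal_d13c_sd,
                ),
            )
    elif dataset is None:
        if larvae_path is None or stations_path is None:
            raise PipelineError(
                "preprocess", ValueError("need a dataset, CSV paths, or simulate=True")
            )
        try:
            dataset = load_dataset(larvae_path, stations_path)
        except FileNotFoundError as exc:
            raise PipelineError("preprocess", exc) from exc

    report = validate_dataset(dataset)
    manifest.warnings.extend(report.warnings)
    if not report.is_clean:
        manifest.warnings.extend(
            report.unresolved_stations + report.duplicate_ids + report.range_violations
        )

    # ---- preprocess -------------------------------------------------------
    try:
        dataset = preprocess_dataset(dataset, config.lipid_larva, config.lipid_zoo)
        _write(dataset.larvae, out / "preprocessed_larvae.csv", manifest)
        _write(dataset.stations, out / "preprocessed_stations.csv", manifest)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc
    manifest.stages.append("preprocess")

    cohorts = dataset.cohorts()

    # ---- growth -----------------------------------------------------------
    try:
        fit_sl, fit_dw, labels = growth_mod.fit_and_classify(
            dataset, config.log_base, config.growth_scope
        )
        fits = [fit_sl, fit_dw] if not isinstance(fit_sl, dict) else (
            list(fit_sl.values()) + list(fit_dw.values())
        )
        fit_rows = [
            {
                "response": f.response,
                "scope": f.scope,
                "log_base": f.log_base,
                "intercept": f.intercept,
                "slope": f.slope,
                "r2": f.r2,
                "n": f.n,
                "resid_sd": f.resid_sd,
            }
            for f in fits
        ]
        _write(pd.DataFrame(fit_rows), out / "growth_fits.csv", manifest)
        _write(labels, out / "growth_labels.csv", manifest)
    except Exception as exc:
        raise PipelineError("growth", exc) from exc
    manifest.stages.append("growth")
    label_of = {l.larva_id: l.label for l in labels}

    # ---- maternal ---------------------------------------------------------
    try:
        rng_egg = np.random.default_rng(np.random.SeedSequence((seed, 1)))
        factor_rows = []
        estimates_by_cohort: dict[str, list] = {}
        for cohort in cohorts:
            pre = dataset.subset(cohort=cohort, stage=STAGE_PRE).larvae
            if len(pre) < 3:
                manifest.warnings.append(f"maternal: cohort {cohort} has < 3 pre-flexion larvae")
                continue
            if cohort not in egg_params:
                raise ValueError(
                    f"no egg isotope parameters configured for cohort {cohort!r}"
                )
            eggs15, eggs13 = maternal_mod.draw_egg_values(egg_params[cohort], len(pre), rng_egg)
            reg15 = maternal_mod.fit_factor_regression(pre, eggs15, "d15n")
            reg13 = maternal_mod.fit_factor_regression(pre, eggs13, "d13c")
            for reg in (reg15, reg13):
                factor_rows.append(
                    {
                        "cohort": cohort,
                        "isotope": reg.isotope,
                        "n": reg.n,
                        "intercept_c0": reg.intercept,
                        "slope_c1": reg.slope,
                        "p": reg.p_value,
                        "r2": reg.r2,
                    }
                )
                if reg.p_value >= config.alpha:
                    manifest.warnings.append(
                        f"maternal: {cohort} {reg.isotope} factor regression NS "
                        f"(p = {reg.p_value:.3f}); applied anyway"
                    )
            estimates_by_cohort[cohort] = maternal_mod.estimate_maternal_dataset(pre, reg15, reg13)
        _write(pd.DataFrame(factor_rows), out / "factor_regressions.csv", manifest)
        all_estimates = [e for ests in estimates_by_cohort.values() for e in ests]
        _write(all_estimates, out / "maternal_estimates.csv", manifest)

        cohort_of = {l.larva_id: l.cohort for l in dataset.larvae}
        summary = maternal_mod.maternal_group_summary(all_estimates, cohort_of)
        _write(summary, out / "maternal_summary.csv", manifest)
    except Exception as exc:
        raise PipelineError("maternal", exc) from exc
    manifest.stages.append("maternal")

    # ---- trophic ----------------------------------------------------------
    try:
        if not dataset.stations:
            raise ValueError("no stations available (missing stations input?)")
        tp_results = trophic_mod.tp_for_dataset(dataset, config.tp)
        _write(tp_results, out / "tp_results.csv", manifest)
        tp_of = {r.larva_id: r.tp for r in tp_results}
        rows = []
        for cohort in cohorts:
            for stage in (STAGE_PRE, STAGE_POST, "TOTAL"):
                sub = dataset.subset(cohort=cohort, stage=None if stage == "TOTAL" else stage)
                vals = [tp_of[l.larva_id] for l in sub.larvae]
                rows.extend(_summary_rows({cohort: vals}, "TP", stage))
        _write(pd.DataFrame(rows), out / "tp_summary.csv", manifest)
    except Exception as exc:
        raise PipelineError("trophic", exc) from exc
    manifest.stages.append("trophic")

    # ---- niche ------------------------------------------------------------
    try:
        niche_tables = _niche_stage(dataset, estimates_by_cohort, label_of, config, seed)
        for name, df in niche_tables.items():
            _write(df, out / f"{name}.csv", manifest)
    except Exception as exc:
        raise PipelineError("niche", exc) from exc
    manifest.stages.append("niche")

    # ---- stats ------------------------------------------------------------
    try:
        tables = report_tables(dataset, labels, estimates_by_cohort, tp_results, config)
        for name, df in tables.items():
            _write(df, out / f"{name}.csv", manifest)
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    manifest.stages.append("stats")

    manifest.finished = time.time()
    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest


def _config_snapshot(config: AnalysisConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


def _niche_points(
    dataset: CohortDataset,
    estimates_by_cohort: dict,
    label_of: dict[str, str],
) -> dict[tuple[str, str], np.ndarray]:
    """(group, niche_type) -> (n, 2) array of (δ13C, δ15N).

    Maternal niches use back-calculated pre-flexion maternal pairs; larval
    trophic niches use raw post-flexion pairs (no maternal influence).
    Groups: each cohort, and each cohort×OPT/DEF class.
    """
    points: dict[tuple[str, str], list] = {}
    for cohort, ests in estimates_by_cohort.items():
        for est in ests:
            pair = (est.d13c_maternal, est.d15n_maternal)
            points.setdefault((cohort, "maternal"), []).append(pair)
            lab = label_of.get(est.larva_id)
            if lab in (growth_mod.OPT, growth_mod.DEF):
                points.setdefault((f"{cohort}/{lab}", "maternal"), []).append(pair)
    for larva in dataset.larvae:
        if larva.stage != STAGE_POST:
            continue
        pair = (larva.d13c, larva.d15n)
        points.setdefault((larva.cohort, "larval"), []).append(pair)
        lab = label_of.get(larva.larva_id)
        if lab in (growth_mod.OPT, growth_mod.DEF):
            points.setdefault((f"{larva.cohort}/{lab}", "larval"), []).append(pair)
    return {k: np.asarray(v, dtype=float) for k, v in points.items()}


def _niche_stage(dataset, estimates_by_cohort, label_of, config: AnalysisConfig, seed: int):
    groups = _niche_points(dataset, estimates_by_cohort, label_of)
    fits = {}
    ellipse_rows, posterior_rows, overlap_rows = [], [], []
    for i, ((group, ntype), pts) in enumerate(sorted(groups.items())):
        if len(pts) < 3:
            continue
        try:
            fit = niche_mod.fit_standard_ellipse(pts)
        except ValueError:
            continue
        fits[(group, ntype)] = fit
        ellipse_rows.append(
            {
                "group": group,
                "niche": ntype,
                "n": fit.n,
                "mean_d13c": fit.mean[0],
                "mean_d15n": fit.mean[1],
                "var_d13c": fit.cov[0, 0],
                "var_d15n": fit.cov[1, 1],
                "cov": fit.cov[0, 1],
                "sea": fit.sea,
                "seac": fit.seac,
            }
        )
        post = niche_mod.bayesian_sea(
            pts,
            n_draws=config.niche.n_draws,
            prior=config.niche.prior,
            seed=np.random.default_rng(np.random.SeedSequence((seed, 2, i))),
        )
        posterior_rows.append(
            {
                "group": group,
                "niche": ntype,
                "sea_median": post.median,
                "ci50_lo": post.ci50[0],
                "ci50_hi": post.ci50[1],
                "ci75_lo": post.ci75[0],
                "ci75_hi": post.ci75[1],
                "ci95_lo": post.ci95[0],
                "ci95_hi": post.ci95[1],
            }
        )

    keys = sorted(fits)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            if ka[1] != kb[1]:
                continue  # only compare like niches
            # compare cohorts to each other and OPT vs DEF within a cohort
            same_family = ("/" not in ka[0]) == ("/" not in kb[0])
            if "/" in ka[0] and ka[0].split("/")[0] != kb[0].split("/")[0]:
                continue
            if not same_family:
                continue
            ov = niche_mod.overlap(
                fits[ka],
                fits[kb],
                k=config.niche.boundary_k,
                corrected=config.niche.corrected_overlap,
            )
            overlap_rows.append(
                {
                    "group_a": ka[0],
                    "group_b": kb[0],
                    "niche": ka[1],
                    "area_a": ov.area_a,
                    "area_b": ov.area_b,
                    "area_intersection": ov.area_intersection,
                    "prop_a": ov.prop_a,
                    "prop_b": ov.prop_b,
                    "prop_union": ov.prop_union,
                }
            )
    out = {
        "ellipses": pd.DataFrame(ellipse_rows),
        "posterior_sea": pd.DataFrame(posterior_rows),
        "overlaps": pd.DataFrame(overlap_rows),
    }
    return {k: v for k, v in out.items() if not v.empty}


def _test_row(result, extra: dict) -> dict:
    row = dict(extra)
    row.update(
        {
            "test": result.test,
            "statistic": result.statistic,
            "df1": result.df[0] if result.df else "",
            "df2": result.df[1] if result.df else "",
            "p": result.p,
            "sig": result.stars,
        }
    )
    for label, gs in result.groups.items():
        row[f"mean_{label}"] = gs.mean
        row[f"sd_{label}"] = gs.sd
        row[f"n_{label}"] = gs.n
    return row


def report_tables(dataset, labels, estimates_by_cohort, tp_results, config: AnalysisConfig):
    """Assemble the six report tables from persisted stage outputs.

    1. factor regressions (written by the maternal stage);
    2. environment/baseline Mann–Whitney contrasts between cohorts;
    3. inter-cohort growth ANCOVA by stage;
    4. intra-cohort OPT vs DEF growth ANCOVA by stage;
    5. maternal isotope Mann–Whitney between cohorts;
    6. maternal isotope Mann–Whitney OPT vs DEF within cohorts;
    plus a trophic-variable comparison table (δ15N, δ13C, C:N, TP).
    """
    cohorts = dataset.cohorts()
    label_of = {l.larva_id: l.label for l in labels}
    tp_of = {r.larva_id: r.tp for r in tp_results}
    tables: dict[str, pd.DataFrame] = {}

    # Table 2 shape: environment + baselines, MW between the two cohorts
    env_rows = []
    if len(cohorts) == 2 and dataset.stations:
        ca, cb = cohorts
        for var, attr in (
            ("TEMP", "temp_c"),
            ("SAL", "sal_psu"),
            ("d15N_micro", "d15n_micro"),
            ("d13C_micro", "d13c_micro"),
            ("d15N_meso", "d15n_meso"),
            ("d13C_meso", "d13c_meso"),
        ):
            a = [getattr(s, attr) for s in dataset.stations if s.cohort == ca]
            b = [getattr(s, attr) for s in dataset.stations if s.cohort == cb]
            if not a or not b:
                continue
            try:
                res = stats_mod.mann_whitney_z(a, b, labels=(ca, cb))
            except ValueError:
                continue
            env_rows.append(_test_row(res, {"variable": var}))
    tables["environment_tests"] = pd.DataFrame(env_rows)

    # Tables 3 shape: inter-cohort growth comparisons per stage
    growth_rows = []
    if len(cohorts) == 2:
        ca, cb = cohorts
        for stage in ("TOTAL", STAGE_PRE, STAGE_POST):
            sub = dataset.subset(stage=None if stage == "TOTAL" else stage)
            grp = np.array([l.cohort for l in sub.larvae])
            age = np.array([l.age_days for l in sub.larvae], dtype=float)
            for var, attr in _GROWTH_VARS.items():
                y = np.array([getattr(l, attr) for l in sub.larvae], dtype=float)
                try:
                    res = stats_mod.ancova_group_effect(y, age, grp, log_transform=var in _LOG_VARS)
                except ValueError:
                    continue
                growth_rows.append(_test_row(res, {"stage": stage, "variable": var}))
    tables["growth_tests"] = pd.DataFrame(growth_rows)

    # Table 4 shape: OPT vs DEF within each cohort, per stage
    intra_rows = []
    for cohort in cohorts:
        for stage in ("TOTAL", STAGE_PRE, STAGE_POST):
            sub = dataset.subset(cohort=cohort, stage=None if stage == "TOTAL" else stage)
            chosen = [l for l in sub.larvae if label_of.get(l.larva_id) in ("OPT", "DEF")]
            if len(chosen) < 6:
                continue
            grp = np.array([label_of[l.larva_id] for l in chosen])
            age = np.array([l.age_days for l in chosen], dtype=float)
            for var, attr in _GROWTH_VARS.items():
                y = np.array([getattr(l, attr) for l in chosen], dtype=float)
                try:
                    res = stats_mod.select_test(
                        y, age, grp, alpha=config.alpha, log_transform=var in _LOG_VARS
                    )
                except ValueError:
                    continue
                intra_rows.append(_test_row(res, {"cohort": cohort, "stage": stage, "variable": var}))
    tables["growth_class_tests"] = pd.DataFrame(intra_rows)

    # Table 5 shape: maternal isotopes between cohorts (MW)
    mat_rows = []
    if len(estimates_by_cohort) == 2:
        (ca, ea), (cb, eb) = sorted(estimates_by_cohort.items())
        for iso, attr in (("d15N_maternal", "d15n_maternal"), ("d13C_maternal", "d13c_maternal")):
            a = [getattr(e, attr) for e in ea]
            b = [getattr(e, attr) for e in eb]
            try:
                res = stats_mod.mann_whitney_z(a, b, labels=(ca, cb))
            except ValueError:
                continue
            mat_rows.append(_test_row(res, {"variable": iso}))
    tables["maternal_tests"] = pd.DataFrame(mat_rows)

    # Table 6 shape: maternal isotopes OPT vs DEF within cohorts (MW)
    mat_class_rows = []
    for cohort, ests in sorted(estimates_by_cohort.items()):
        for iso, attr in (("d15N_maternal", "d15n_maternal"), ("d13C_maternal", "d13c_maternal")):
            a = [getattr(e, attr) for e in ests if label_of.get(e.larva_id) == "OPT"]
            b = [getattr(e, attr) for e in ests if label_of.get(e.larva_id) == "DEF"]
            if not a or not b:
                continue
            try:
                res = stats_mod.mann_whitney_z(a, b, labels=("OPT", "DEF"))
            except ValueError:
                continue
            mat_class_rows.append(_test_row(res, {"cohort": cohort, "variable": iso}))
    tables["maternal_class_tests"] = pd.DataFrame(mat_class_rows)

    # Trophic-variable contrasts between cohorts (δ15N, δ13C, C:N, TP)
    troph_rows = []
    if len(cohorts) == 2:
        for stage in ("TOTAL", STAGE_PRE, STAGE_POST):
            sub = dataset.subset(stage=None if stage == "TOTAL" else stage)
            grp = np.array([l.cohort for l in sub.larvae])
            age = np.array([l.age_days for l in sub.larvae], dtype=float)
            for var, getter in (
                ("d15N", lambda l: l.d15n),
                ("d13C", lambda l: l.d13c),
                ("CN", lambda l: l.cn),
                ("TP", lambda l: tp_of[l.larva_id]),
            ):
                y = np.array([getter(l) for l in sub.larvae], dtype=float)
                try:
                    res = stats_mod.select_test(y, age, grp, alpha=config.alpha)
                except ValueError:
                    continue
                troph_rows.append(_test_row(res, {"stage": stage, "variable": var}))
    tables["trophic_tests"] = pd.DataFrame(troph_rows)

    return {k: v for k, v in tables.items() if not v.empty}
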