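"""End-to-end orchestration: generate/load -> process -> summarise -> infer -> test.

Stages operate on a :class:`~thermomorph.synthetic.Cohort` (either freshly
generated or loaded from the input CSVs) and produce tidy data frames:
brightness summaries, physiology summaries, preferred temperatures,
bootstrap results (summary contrasts, covariate correlations and
time-resolved curves) and the classical-test table, for all six
species x sex subsets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CHANNELS, SEXES, SPECIES, AnalysisConfig, PipelineConfig
from .gradient import attach_temperatures, preferred_temperature
from .hypotests import check_assumptions, correlation_test, multi_group_test, two_group_test
from .inference import (
    AnalysisSubset,
    bootstrap_ci,
    correlation_curve,
    difference_curve,
    difference_of_means,
    spearman_rho,
)
from .io import write_cohort
from .physiology import summarise_trace, truncate_trace
from .spectra import process_individual
from .synthetic import Cohort, generate_cohort

logger = logging.getLogger("thermomorph")

SUMMARY_RESPONSES = (
    "heatup_internal",
    "heatup_external",
    "equilibrium_internal",
    "equilibrium_external",
    "preferred",
)
COVARIATES = ("brightness", "mass")

_BOOT_TAG = 0xB007
_SUBSTRATE = "substrate"


@dataclass
class PipelineResult:
    config: PipelineConfig
    brightness: pd.DataFrame
    physiology: pd.DataFrame
    preferred: pd.DataFrame
    bootstrap: pd.DataFrame
    curves: pd.DataFrame
    tests: pd.DataFrame
    subsets: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def process_spectra(cohort: Cohort) -> pd.DataFrame:
    """Artefact-correct, aggregate and summarise brightness per individual."""
    rows = []
    for ind in cohort.individuals:
        specs = cohort.spectra.get(ind.id)
        if not specs:
            continue
        _, summary = process_individual(specs)
        ind.brightness_pct = summary.brightness_pct
        rows.append(
            {
                "individual_id": ind.id,
                "brightness_pct": summary.brightness_pct,
                "n_spectra_used": summary.n_spectra_used,
            }
        )
    return pd.DataFrame(rows, columns=["individual_id", "brightness_pct", "n_spectra_used"])


def process_physiology(cohort: Cohort, cfg: AnalysisConfig) -> pd.DataFrame:
    """Truncate every trace and derive heat-up speed + equilibrium temperature."""
    not_reached = {tuple(g) for g in cfg.equilibrium_not_reached}
    by_id = {ind.id: ind for ind in cohort.individuals}
    rows = []
    for (ind_id, channel), trace in cohort.traces.items():
        ind = by_id.get(ind_id)
        flag = ind is not None and (ind.species, ind.sex) in not_reached
        summary = summarise_trace(
            trace,
            truncate_s=cfg.truncate_s,
            heatup_window_s=cfg.heatup_window_s,
            equilibrium_window_s=cfg.equilibrium_window_s,
            heatup_method=cfg.heatup_method,
            equilibrium_not_reached=flag,
        )
        rows.append(
            {
                "individual_id": ind_id,
                "channel": channel,
                "heatup_speed_c_per_min": summary.heatup_speed_c_per_min,
                "equilibrium_c": summary.equilibrium_c,
                "flags": ";".join(summary.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "channel",
            "heatup_speed_c_per_min",
            "equilibrium_c",
            "flags",
        ],
    )


def process_gradient(cohort: Cohort, cfg: AnalysisConfig) -> pd.DataFrame:
    """Convert positions to substrate temperatures and derive preferences."""
    rows = []
    n_sightings = n_missing = 0
    for ind_id, track in cohort.tracks.items():
        calibration = cohort.calibrations[track.runway_id]
        if calibration.residual_rms_c > cfg.calibration_max_rms_c:
            raise ValueError(
                f"calibration {track.runway_id} residual RMS "
                f"{calibration.residual_rms_c:.2f} exceeds tolerance"
            )
        attach_temperatures(track, calibration)
        value, n_used = preferred_temperature(track, window_min=cfg.preferred_window_min)
        n_sightings += track.positions_cm.size
        n_missing += int(np.isnan(track.positions_cm).sum())
        rows.append(
            {
                "individual_id": ind_id,
                "preferred_c": value,
                "n_sightings_used": n_used,
                "flags": ";".join(track.flags),
            }
        )
    if n_sightings:
        logger.info(
            "gradient: %d sightings, %.2f%% missing",
            n_sightings,
            100.0 * n_missing / n_sightings,
        )
    return pd.DataFrame(
        rows, columns=["individual_id", "preferred_c", "n_sightings_used", "flags"]
    )


def build_subsets(
    cohort: Cohort,
    brightness: pd.DataFrame,
    physiology: pd.DataFrame,
    preferred: pd.DataFrame,
    cfg: AnalysisConfig,
) -> list[AnalysisSubset]:
    """Partition the cohort into the six species x sex analysis subsets."""
    bright = brightness.set_index("individual_id")["brightness_pct"]
    pref = preferred.set_index("individual_id")["preferred_c"]
    phys = physiology.set_index(["individual_id", "channel"])
    subsets = []
    for species in SPECIES:
        for sex in SEXES:
            members = [
                i for i in cohort.individuals if i.species == species and i.sex == sex
            ]
            if not members:
                continue
            ids = [i.id for i in members]
            summaries = {
                "mass": np.array([i.mass_g for i in members]),
                "brightness": np.array(
                    [bright.get(i, np.nan) for i in ids], dtype=float
                ),
                "preferred": np.array([pref.get(i, np.nan) for i in ids], dtype=float),
            }
            for channel in CHANNELS:
                speeds, equils = [], []
                for i in ids:
                    try:
                        row = phys.loc[(i, channel)]
                        speeds.append(float(row["heatup_speed_c_per_min"]))
                        equils.append(float(row["equilibrium_c"]))
                    except KeyError:
                        speeds.append(np.nan)
                        equils.append(np.nan)
                summaries[f"heatup_{channel}"] = np.array(speeds)
                summaries[f"equilibrium_{channel}"] = np.array(equils)
            series = {}
            for channel in CHANNELS:
                mats, times = [], None
                complete = True
                for i in ids:
                    trace = cohort.traces.get((i, channel))
                    if trace is None:
                        complete = False
                        break
                    truncated = truncate_trace(trace, cutoff_s=cfg.truncate_s)
                    if times is None:
                        times = truncated.times_s
                    elif not np.array_equal(times, truncated.times_s):
                        raise ValueError(
                            f"time grid mismatch in {species}/{sex} {channel} traces"
                        )
                    mats.append(truncated.temperatures_c)
                if complete and mats:
                    series[channel] = (times, np.vstack(mats))
            sub_tracks = [cohort.tracks.get(i) for i in ids]
            if all(t is not None and t.substrate_c is not None for t in sub_tracks):
                t0 = sub_tracks[0].times_min
                if all(np.array_equal(t.times_min, t0) for t in sub_tracks):
                    series[_SUBSTRATE] = (
                        t0,
                        np.vstack([t.substrate_c for t in sub_tracks]),
                    )
            subset = AnalysisSubset(
                species=species,
                sex=sex,
                ids=np.array(ids, dtype=object),
                morph=np.array([i.morph for i in members], dtype=object),
                summaries=summaries,
                series=series,
            )
            logger.info(
                "subset %s/%s: n=%d, morphs=%s", species, sex, subset.n,
                subset.morph_counts(),
            )
            subsets.append(subset)
    return subsets


def _spearman_stat(covariate: str, response: str):
    def stat(subset: AnalysisSubset) -> float:
        x = subset.summaries[covariate]
        y = subset.summaries[response]
        valid = np.isfinite(x) & np.isfinite(y)
        if valid.sum() < 3:
            return float("nan")
        return spearman_rho(x[valid], y[valid])

    return stat


def _contrast_pairs(subset: AnalysisSubset, all_pairwise: bool) -> list:
    morphs = subset.morphs_present()
    if all_pairwise and len(morphs) > 2:
        return [(a, b) for i, a in enumerate(morphs) for b in morphs[i + 1 :]]
    if "green" in morphs and "brown" in morphs:
        return [("green", "brown")]
    if len(morphs) == 2:
        return [(morphs[0], morphs[1])]
    return []


def run_bootstrap(
    subsets: list,
    cfg: AnalysisConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap summary contrasts, covariate correlations and curves."""
    summary_rows, curve_rows = [], []
    stream = 0
    for subset in subsets:
        base = [int(seed), _BOOT_TAG]
        pairs = _contrast_pairs(subset, cfg.all_pairwise_contrasts)
        for pair in pairs:
            a, b = pair
            for response in SUMMARY_RESPONSES:
                if response not in subset.summaries:
                    continue
                stream += 1
                values = subset.summaries[response]
                if not np.any(np.isfinite(values)):
                    continue
                rng = np.random.default_rng(np.random.SeedSequence(base + [stream]))
                res = bootstrap_ci(
                    subset,
                    difference_of_means(response, a, b),
                    B=cfg.n_bootstrap,
                    level=cfg.ci_level,
                    seed=rng,
                    label=f"{a}-{b}",
                    max_missing_frac=cfg.max_missing_frac,
                    quantile_method=cfg.quantile_method,
                )
                summary_rows.append(
                    _summary_row(subset, "contrast", f"{a}-{b}", response, res)
                )
            for channel, (times, _) in subset.series.items():
                stream += 1
                rng = np.random.default_rng(np.random.SeedSequence(base + [stream]))
                curve = difference_curve(
                    subset, a, b, channel,
                    B=cfg.n_bootstrap, level=cfg.ci_level, seed=rng,
                    quantile_method=cfg.quantile_method,
                )
                curve_rows.extend(
                    _curve_rows(subset, "contrast", f"{a}-{b}", channel, curve)
                )
        for covariate in COVARIATES:
            cov = subset.summaries.get(covariate)
            if cov is None or not np.all(np.isfinite(cov)):
                continue
            for response in SUMMARY_RESPONSES:
                if response not in subset.summaries:
                    continue
                stream += 1
                if not np.any(np.isfinite(subset.summaries[response])):
                    continue
                rng = np.random.default_rng(np.random.SeedSequence(base + [stream]))
                res = bootstrap_ci(
                    subset,
                    _spearman_stat(covariate, response),
                    B=cfg.n_bootstrap,
                    level=cfg.ci_level,
                    seed=rng,
                    label=f"rho({covariate})",
                    max_missing_frac=cfg.max_missing_frac,
                    quantile_method=cfg.quantile_method,
                )
                summary_rows.append(
                    _summary_row(subset, "correlation", covariate, response, res)
                )
            for channel in subset.series:
                stream += 1
                rng = np.random.default_rng(np.random.SeedSequence(base + [stream]))
                curve = correlation_curve(
                    subset, covariate, channel,
                    B=cfg.n_bootstrap, level=cfg.ci_level, seed=rng,
                    quantile_method=cfg.quantile_method,
                )
                curve_rows.extend(
                    _curve_rows(subset, "correlation", covariate, channel, curve)
                )
    summary_cols = [
        "species", "sex", "kind", "label", "response",
        "estimate", "ci_low", "ci_high", "excludes_zero", "valid",
    ]
    curve_cols = [
        "species", "sex", "kind", "label", "channel", "time",
        "estimate", "ci_low", "ci_high", "excludes_zero",
    ]
    return (
        pd.DataFrame(summary_rows, columns=summary_cols),
        pd.DataFrame(curve_rows, columns=curve_cols),
    )


def _summary_row(subset, kind, label, response, res) -> dict:
    return {
        "species": subset.species,
        "sex": subset.sex,
        "kind": kind,
        "label": label,
        "response": response,
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "excludes_zero": res.excludes_zero,
        "valid": res.valid,
    }


def _curve_rows(subset, kind, label, channel, curve) -> list:
    excl = curve.excludes_zero()
    return [
        {
            "species": subset.species,
            "sex": subset.sex,
            "kind": kind,
            "label": label,
            "channel": channel,
            "time": float(t),
            "estimate": float(e),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "excludes_zero": bool(x),
        }
        for t, e, lo, hi, x in zip(
            curve.times, curve.estimate, curve.ci_low, curve.ci_high, excl
        )
    ]


def run_classical_tests(subsets: list, cfg: AnalysisConfig) -> pd.DataFrame:
    """Assumption-checked classical tests: morph, covariates, and sex effects."""
    rows = []
    for subset in subsets:
        for response in SUMMARY_RESPONSES:
            values = subset.summaries.get(response)
            if values is None or not np.any(np.isfinite(values)):
                continue
            groups, labels = [], []
            for morph in subset.morphs_present():
                g = values[subset.morph == morph]
                g = g[np.isfinite(g)]
                if g.size:
                    groups.append(g)
                    labels.append(morph)
            if len(groups) >= 2 and all(g.size >= 3 for g in groups):
                try:
                    assumptions = check_assumptions(groups, alpha=cfg.alpha)
                    if len(groups) == 2:
                        res = two_group_test(groups, assumptions)
                    else:
                        res = multi_group_test(groups, assumptions, labels=labels)
                    rows.append(_test_row(subset.species, subset.sex, response, "morph", res))
                    for pair, pres in res.pairwise.items():
                        rows.append(
                            _test_row(
                                subset.species, subset.sex, response,
                                f"morph:{pair[0]}-{pair[1]}", pres,
                            )
                        )
                except ValueError as exc:
                    logger.warning(
                        "skipping morph test %s/%s %s: %s",
                        subset.species, subset.sex, response, exc,
                    )
            for covariate in COVARIATES:
                x = subset.summaries.get(covariate)
                if x is None:
                    continue
                valid = np.isfinite(x) & np.isfinite(values)
                if valid.sum() < 4:
                    continue
                xv, yv = x[valid], values[valid]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                bivariate_normal = _normal_proxy(xv, cfg.alpha) and _normal_proxy(
                    yv, cfg.alpha
                )
                res = correlation_test(xv, yv, bivariate_normal=bivariate_normal)
                rows.append(
                    _test_row(subset.species, subset.sex, response, covariate, res)
                )
    # sex effect: within species, compare females vs males
    by_species: dict = {}
    for subset in subsets:
        by_species.setdefault(subset.species, {})[subset.sex] = subset
    for species, by_sex in by_species.items():
        if "F" not in by_sex or "M" not in by_sex:
            continue
        for response in SUMMARY_RESPONSES:
            gf = by_sex["F"].summaries.get(response)
            gm = by_sex["M"].summaries.get(response)
            if gf is None or gm is None:
                continue
            gf = gf[np.isfinite(gf)]
            gm = gm[np.isfinite(gm)]
            if gf.size < 3 or gm.size < 3:
                continue
            assumptions = check_assumptions([gf, gm], alpha=cfg.alpha)
            res = two_group_test([gf, gm], assumptions)
            rows.append(_test_row(species, "F+M", response, "sex", res))
    return pd.DataFrame(
        rows,
        columns=[
            "species", "sex", "response", "factor",
            "test", "statistic", "df", "p", "transform",
        ],
    )


def _normal_proxy(values: np.ndarray, alpha: float) -> bool:
    from scipy.stats import shapiro

    if values.size < 3:
        return False
    return shapiro(values).pvalue > alpha


def _test_row(species, sex, response, factor, res) -> dict:
    df = res.df
    if isinstance(df, tuple):
        df = "/".join(str(d) for d in df)
    return {
        "species": species,
        "sex": sex,
        "response": response,
        "factor": factor,
        "test": res.name,
        "statistic": res.statistic,
        "df": df,
        "p": res.pvalue,
        "transform": res.transform,
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir=None,
    seed: int | None = None,
    cohort: Cohort | None = None,
    write_inputs: bool = False,
) -> PipelineResult:
    """Full pipeline; ``seed`` overrides the config's simulation seed.

    When ``cohort`` is given, the simulation step is skipped (files mode).
    """
    config.validate()
    if seed is not None:
        config.sim.seed = int(seed)
    started = time.time()
    if cohort is None:
        cohort = generate_cohort(config.sim)
    logger.info("cohort: %d individuals", len(cohort))
    brightness = process_spectra(cohort)
    physiology = process_physiology(cohort, config.analysis)
    preferred = process_gradient(cohort, config.analysis)
    subsets = build_subsets(cohort, brightness, physiology, preferred, config.analysis)
    boot, curves = run_bootstrap(subsets, config.analysis, seed=config.sim.seed)
    tests = run_classical_tests(subsets, config.analysis)
    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.sim.seed,
        "n_bootstrap": config.analysis.n_bootstrap,
        "ci_level": config.analysis.ci_level,
        "n_individuals": len(cohort),
        "subset_sizes": {
            f"{s.species}/{s.sex}": s.morph_counts() for s in subsets
        },
        "started_unix": started,
        "elapsed_s": None,
        "output_files": [],
    }
    result = PipelineResult(
        config=config,
        brightness=brightness,
        physiology=physiology,
        preferred=preferred,
        bootstrap=boot,
        curves=curves,
        tests=tests,
        subsets=subsets,
        manifest=manifest,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if write_inputs:
            written = write_cohort(cohort, out_dir / "inputs")
            manifest["input_files"] = sorted(written.values())
        outputs = {
            "brightness.csv": brightness,
            "physiology.csv": physiology,
            "preferred.csv": preferred,
            "bootstrap_results.csv": boot,
            "bootstrap_curves.csv": curves,
            "tests.csv": tests,
        }
        for name, frame in outputs.items():
            path = out_dir / name
            frame.to_csv(path, index=False)
            manifest["output_files"].append(str(path))
        manifest["elapsed_s"] = round(time.time() - started, 3)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    else:
        manifest["elapsed_s"] = round(time.time() - started, 3)
    return result
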