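"""End-to-end orchestration: simulate or load -> describe -> associate ->
permutation test -> linear-model diagnostics -> count models -> threshold
conversion.

Every stage writes a delimited table into the output directory; a plain-
text run log records the configuration, per-stage seeds and timings.  A
run with an identical configuration produces identical outputs: one
global seed fans out deterministically to per-stage child seeds so each
stage can also be re-run in isolation.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import chi_square_2x2, contingency_from_pairs, fisher_exact_2x2, phi_coefficient
from .correlation import correlate_pairs
from .count_models import Family, compare_models, fit_count_model, validate_fit
from .data import DataError, Dataset, Species, complete_case_pairs, read_dataset, write_dataset
from .descriptive import classify_pairs, summarize
from .lm_diagnostics import Transform, diagnose_lm
from .permutation import permutation_test
from .simulate import default_config, generate_dataset
from .threshold import (
    DAMAGE_THRESHOLDS,
    Method,
    abundance_from_fit,
    convert_threshold,
    ratio_estimate,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

DEFAULT_FAMILIES = (
    Family.poisson,
    Family.quasipoisson,
    Family.negbin,
    Family.zip,
    Family.zinb,
    Family.hurdle_nb,
    Family.lm,
)


@dataclass
class PipelineConfig:
    output_dir: str | Path = "results"
    input_file: str | Path | None = None        # load mode when set
    species: tuple[Species, ...] = tuple(Species)
    n_perm: int = 600_000
    seed: int = 0
    families: tuple[Family, ...] = DEFAULT_FAMILIES
    thresholds: dict[Species, float] = dc_field(
        default_factory=lambda: dict(DAMAGE_THRESHOLDS)
    )
    # simulate mode
    n_fields: int = 16
    points_per_field: tuple[int, int] = (12, 48)

    def validate(self) -> None:
        for sp in self.species:
            if sp not in self.thresholds:
                raise DataError(f"no damage threshold configured for {sp.value}")
        if self.n_perm < 1:
            raise DataError("n_perm must be >= 1")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage, below 2**31.

    Uses a stable string hash (crc32) so runs are reproducible across
    processes, unlike the built-in randomized ``hash``.
    """
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, outdir: Path, name: str, log: list[str]) -> None:
    path = outdir / name
    df.to_csv(path, index=False)
    log.append(f"wrote {name} ({len(df)} rows)")


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage for every configured species; return the tables."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"wireworm {__version__}", f"seed={cfg.seed}"]
    t0 = time.time()
    tables: dict[str, pd.DataFrame] = {}

    # --- data -----------------------------------------------------------
    datasets: dict[Species, Dataset] = {}
    if cfg.input_file is not None:
        ds = read_dataset(cfg.input_file)
        for sp in cfg.species:
            datasets[sp] = Dataset(ds.subset(sp), provenance=ds.provenance)
        log.append(f"loaded {cfg.input_file}")
    else:
        for sp in cfg.species:
            gcfg = default_config(
                sp,
                n_fields=cfg.n_fields,
                points_per_field=cfg.points_per_field,
                seed=stage_seed(cfg.seed, f"simulate:{sp.value}"),
            )
            datasets[sp] = generate_dataset(gcfg, sp)
            write_dataset(datasets[sp], outdir / f"dataset_{sp.value}.csv")
        log.append("simulated datasets with calibrated species defaults")

    pairs = {sp: complete_case_pairs(datasets[sp]) for sp in cfg.species}

    # --- descriptive summaries and concordance --------------------------
    rows = []
    for sp in cfg.species:
        obs = datasets[sp].observations
        for method, attr in (("soil_cores", "soil_count"), ("traps", "trap_count")):
            vals = [getattr(o, attr) for o in obs]
            s = summarize(vals, total_n=len(vals))
            rows.append({"species": sp.value, "method": method, **s.__dict__})
    tables["summary"] = pd.DataFrame(rows)
    _write(tables["summary"], outdir, "summary_stats.csv", log)

    rows = []
    for sp in cfg.species:
        c = classify_pairs(pairs[sp])
        rows.append({"species": sp.value, "n": c.n, **c.__dict__, **{
            f"prop_{k}": v for k, v in c.proportions().items()}})
    tables["concordance"] = pd.DataFrame(rows)
    _write(tables["concordance"], outdir, "concordance.csv", log)

    # --- association tests ----------------------------------------------
    rows = []
    pooled_cells = np.zeros(4, dtype=int)
    for sp in cfg.species:
        t = contingency_from_pairs(pairs[sp])
        pooled_cells += [t.a, t.b, t.c, t.d]
        chi = chi_square_2x2(t, continuity_correction=False)
        chi_y = chi_square_2x2(t, continuity_correction=True)
        fis = fisher_exact_2x2(t)
        rows.append({
            "species": sp.value, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n,
            "chi2": chi.statistic, "chi2_p": chi.p_value,
            "chi2_yates": chi_y.statistic, "chi2_yates_p": chi_y.p_value,
            "fisher_p": fis.p_value, "phi": phi_coefficient(t),
        })
    if len(cfg.species) > 1:
        from .association import ContingencyTable2x2

        tp = ContingencyTable2x2(*pooled_cells.tolist())
        chi = chi_square_2x2(tp, continuity_correction=False)
        rows.append({
            "species": "pooled", "a": tp.a, "b": tp.b, "c": tp.c, "d": tp.d,
            "n": tp.n, "chi2": chi.statistic, "chi2_p": chi.p_value,
            "chi2_yates": chi_square_2x2(tp, True).statistic,
            "chi2_yates_p": chi_square_2x2(tp, True).p_value,
            "fisher_p": fisher_exact_2x2(tp).p_value, "phi": phi_coefficient(tp),
        })
    tables["association"] = pd.DataFrame(rows)
    _write(tables["association"], outdir, "association.csv", log)

    # --- permutation test -------------------------------------------------
    rows = []
    for sp in cfg.species:
        res = permutation_test(
            pairs[sp], n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, f"permtest:{sp.value}"),
        )
        rows.append({
            "species": sp.value, "observed_chi2_yates": res.observed_stat,
            "n_perm": res.n_perm, "p_perm": res.p_perm,
        })
    tables["permutation"] = pd.DataFrame(rows)
    _write(tables["permutation"], outdir, "permutation.csv", log)

    # --- correlations ------------------------------------------------------
    rows = []
    for sp in cfg.species:
        for name, res in correlate_pairs(pairs[sp]).items():
            rows.append({
                "species": sp.value, "method": name, "n": res.n,
                "estimate": res.estimate, "p_value": res.p_value,
            })
    tables["correlation"] = pd.DataFrame(rows)
    _write(tables["correlation"], outdir, "correlation.csv", log)

    # --- linear-model diagnostics ------------------------------------------
    rows = []
    for sp in cfg.species:
        for tr in Transform:
            rep = diagnose_lm(
                pairs[sp], tr, seed=stage_seed(cfg.seed, f"diagnose:{sp.value}:{tr.value}")
            )
            rows.append({
                "species": sp.value, "transform": tr.value,
                "shapiro_p": rep.shapiro_p, "breusch_pagan_p": rep.breusch_pagan_p,
                "durbin_watson": rep.durbin_watson_stat,
                "durbin_watson_p": rep.durbin_watson_p,
                **{f"verdict_{k}": v for k, v in rep.verdicts.items()},
            })
    tables["lm_diagnostics"] = pd.DataFrame(rows)
    _write(tables["lm_diagnostics"], outdir, "lm_diagnostics.csv", log)

    # --- count models -------------------------------------------------------
    comparison_frames = []
    validation_rows = []
    zinb_fits = {}
    for sp in cfg.species:
        fits = [fit_count_model(pairs[sp], fam) for fam in cfg.families]
        cmp = compare_models(fits)
        cmp.insert(0, "species", sp.value)
        comparison_frames.append(cmp)
        for f in fits:
            if f.family is Family.zinb:
                zinb_fits[sp] = f
                v = validate_fit(f)
                validation_rows.append({
                    "species": sp.value, "irr": v.irr, "rmse": v.rmse,
                    "mad": v.mad_mean, "corr_pred_obs": v.corr_pred_obs,
                    "zero_freq_observed": v.zero_freq_observed,
                    "zero_freq_predicted": v.zero_freq_predicted,
                })
    tables["model_comparison"] = pd.concat(comparison_frames, ignore_index=True)
    _write(tables["model_comparison"], outdir, "model_comparison.csv", log)
    tables["model_validation"] = pd.DataFrame(validation_rows)
    _write(tables["model_validation"], outdir, "model_validation.csv", log)

    # --- threshold conversion ------------------------------------------------
    rows = []
    for sp in cfg.species:
        soil_fit = fit_count_model(
            pairs[sp], Family.zinb, response="soil", intercept_only=True
        )
        core = abundance_from_fit(soil_fit, method=Method.soil_core, species=sp)
        trap = abundance_from_fit(zinb_fits[sp], method=Method.bait_trap, species=sp)
        r = ratio_estimate(trap, core)
        conv = convert_threshold(cfg.thresholds[sp], r)
        rows.append({
            "species": sp.value,
            "damage_threshold_per_trap": conv.threshold_per_trap,
            "core_mean": core.mean, "core_sd": core.sd,
            "trap_mean": trap.mean, "trap_sd": trap.sd,
            "ratio": r.ratio, "ratio_sd": r.sd,
            "threshold_per_core": conv.threshold_per_core,
            "threshold_per_core_sd": conv.threshold_per_core_sd,
            "threshold_per_m2": conv.threshold_per_m2,
            "threshold_per_m2_sd": conv.threshold_per_m2_sd,
        })
    tables["thresholds"] = pd.DataFrame(rows)
    _write(tables["thresholds"], outdir, "thresholds.csv", log)

    log.append(f"elapsed {time.time() - t0:.1f} s")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return tables
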