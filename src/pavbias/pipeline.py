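"""End-to-end orchestration: simulate -> fit -> compare -> describe ->
longitudinal, from one declarative config with deterministic seed derivation
and a run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import descriptives as desc
from . import longitudinal as lng
from .emfit import fit_em
from .models import get_model
from .simulate import PopulationSpec, simulate_cohort
from .task import Cohort, load_cohort, write_cohort


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "pavbias_run"
    seed: int = 0
    population: dict | None = None       # PopulationSpec fields
    inputs: list = field(default_factory=list)   # existing cohort CSVs
    models: list = field(default_factory=lambda: ["valenced_learning"])
    stages: list = field(default_factory=lambda: ["simulate", "fit", "describe"])
    fit: dict = field(default_factory=dict)      # fit_em kwargs
    lol: dict = field(default_factory=dict)      # LolConfig overrides
    longitudinal_measures: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes) a manifest listing every stage's status, seed,
    artifacts and checksums.  A failed stage records the error, skips
    downstream stages and raises :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "artifacts": {}}
    state = {"cohorts": [], "fits": {}}
    failed = False

    def record(stage, status, seed=None, error=None, t0=None):
        manifest["stages"].append({
            "stage": stage, "status": status, "seed": seed,
            "error": error,
            "seconds": None if t0 is None else round(time.time() - t0, 3)})

    def add_artifact(path: Path):
        manifest["artifacts"][str(path)] = _sha256(path)

    stage_fns = {
        "simulate": _stage_simulate, "load": _stage_load, "fit": _stage_fit,
        "compare": _stage_compare, "describe": _stage_describe,
        "longitudinal": _stage_longitudinal, "lol": _stage_lol,
    }
    stages = list(config.stages)
    if config.inputs and "load" not in stages and "simulate" not in stages:
        stages.insert(0, "load")
    for stage in stages:
        if failed:
            record(stage, "skipped")
            continue
        fn = stage_fns.get(stage)
        if fn is None:
            record(stage, "failed", error=f"unknown stage {stage!r}")
            failed = True
            continue
        t0 = time.time()
        seed = config.stage_seed(stage)
        try:
            fn(config, state, out, add_artifact, seed)
            record(stage, "completed", seed=seed, t0=t0)
        except Exception as exc:  # noqa: BLE001 - manifest must record it
            record(stage, "failed", seed=seed, error=str(exc), t0=t0)
            failed = True
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    if failed:
        raise PipelineError(f"pipeline failed; see {manifest_path}")
    return manifest


def _stage_simulate(config, state, out, add_artifact, seed):
    pop = dict(config.population or {})
    pop.setdefault("seed", seed)
    spec = PopulationSpec(**pop)
    cohorts, params = simulate_cohort(spec)
    state["cohorts"] = cohorts
    state["true_params"] = params
    for cohort, wave_params in zip(cohorts, params):
        path = out / f"cohort_{cohort.wave}.csv"
        write_cohort(cohort, path)
        add_artifact(path)
        ptab = pd.DataFrame(wave_params)
        ptab.insert(0, "participant_id",
                    [s.participant_id for s in cohort])
        ppath = out / f"true_params_{cohort.wave}.csv"
        ptab.to_csv(ppath, index=False)
        add_artifact(ppath)


def _stage_load(config, state, out, add_artifact, seed):
    if not config.inputs:
        raise PipelineError("load stage requires input paths")
    cohorts = []
    for i, path in enumerate(config.inputs):
        if not Path(path).exists():
            raise PipelineError(f"input file not found: {path}")
        cohorts.append(load_cohort(path, wave=f"wave{i + 1}"))
    state["cohorts"] = cohorts


def _stage_fit(config, state, out, add_artifact, seed):
    if not state["cohorts"]:
        raise PipelineError("fit stage needs cohorts (simulate or load first)")
    for cohort in state["cohorts"]:
        for name in config.models:
            model = get_model(name)
            fit = fit_em(cohort, model, seed=seed, **config.fit)
            state["fits"][(cohort.wave, model.name)] = fit
            table = fit.parameter_table()
            path = out / f"fit_{cohort.wave}_{model.name}.csv"
            table.to_csv(path, index=False)
            add_artifact(path)
            jpath = out / f"fit_{cohort.wave}_{model.name}.json"
            jpath.write_text(json.dumps({
                "model": model.name, "wave": cohort.wave,
                "ibic": fit.ibic, "il_total": fit.il_total,
                "converged": fit.converged,
                "prior_mean": fit.prior.mean.tolist(),
                "prior_var": fit.prior.var.tolist(),
                "n_iterations": len(fit.trace)}, indent=2))
            add_artifact(jpath)


def _stage_compare(config, state, out, add_artifact, seed):
    if len(config.models) < 2:
        raise PipelineError("compare stage needs >= 2 models")
    rows = []
    for cohort in state["cohorts"]:
        fits = [state["fits"][(cohort.wave, get_model(m).name)]
                for m in config.models]
        res = cmp.compare_ibic(fits[0], fits[1])
        il_matrix = np.column_stack(
            [[s.il for s in f.subjects] for f in fits])
        pxp = cmp.protected_exceedance(il_matrix, seed=seed)
        rows.append({
            "wave": cohort.wave, "model_a": get_model(config.models[0]).name,
            "model_b": get_model(config.models[1]).name,
            "delta_ibic": res["delta_ibic"], "wilcoxon_p": res["wilcoxon_p"],
            **{f"pxp_{get_model(m).name}": float(p)
               for m, p in zip(config.models, pxp["pxp"])}})
    path = out / "model_comparison.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    add_artifact(path)


def _stage_describe(config, state, out, add_artifact, seed):
    for cohort in state["cohorts"]:
        summary = desc.performance_summary(cohort)
        path = out / f"performance_{cohort.wave}.csv"
        summary.to_csv(path)
        add_artifact(path)
        tests = desc.cross_condition_tests(cohort, phase="early")
        tpath = out / f"cross_condition_early_{cohort.wave}.csv"
        tests.to_csv(tpath)
        add_artifact(tpath)


def _stage_longitudinal(config, state, out, add_artifact, seed):
    if len(state["cohorts"]) < 2:
        raise PipelineError("longitudinal stage needs two waves")
    w1, w2 = state["cohorts"][:2]
    model = get_model(config.models[0])
    f1 = state["fits"].get((w1.wave, model.name))
    f2 = state["fits"].get((w2.wave, model.name))
    if f1 is None or f2 is None:
        raise PipelineError("longitudinal stage needs fits for both waves")
    t1 = f1.parameter_table().set_index("participant_id")
    t2 = f2.parameter_table().set_index("participant_id")
    cols = list(model.params) + ["il"]
    stats_table = lng.retest_statistics(t1[cols], t2[cols],
                                        methods=config.longitudinal_measures)
    path = out / "retest_statistics.csv"
    stats_table.to_csv(path)
    add_artifact(path)
    common = t1.index.intersection(t2.index)
    x1 = lng.gaussianize(t1.loc[common, "theta_b_pav"].to_numpy())
    x2 = lng.gaussianize(t2.loc[common, "theta_b_pav"].to_numpy())
    lcs = lng.fit_lcs(x1, x2)
    (out / "lcs_b_pav.json").write_text(json.dumps({
        "beta": lcs.beta, "change_mean": lcs.change_mean,
        "change_var": lcs.change_var, "chi2_rtm": lcs.chi2_rtm,
        "p_rtm": lcs.p_rtm, "chi2_nochange": lcs.chi2_nochange,
        "p_nochange": lcs.p_nochange, "bic": lcs.bic}, indent=2))
    add_artifact(out / "lcs_b_pav.json")
    if len(common) >= 50:
        clusters = lng.cluster_fit_values(
            t1.loc[common, "il"].to_numpy(), t2.loc[common, "il"].to_numpy(),
            seed=seed)
        cpath = out / "fit_clusters.csv"
        pd.DataFrame({"participant_id": common,
                      "cluster": clusters.assignments}).to_csv(cpath,
                                                               index=False)
        add_artifact(cpath)


def _stage_lol(config, state, out, add_artifact, seed):
    if not state["cohorts"]:
        raise PipelineError("lol stage needs cohorts")
    lol_cfg = cmp.LolConfig(seed=seed, **config.lol)
    result = cmp.lol_compare(state["cohorts"][0], config.models[:2], lol_cfg)
    path = out / "lol_result.json"
    path.write_text(json.dumps({
        "models": result.models,
        "median_delta_ppt": result.median_delta_ppt,
        "ci": [result.ci_low, result.ci_high],
        "grand_mean_ppt": result.grand_mean_ppt,
        "n_excluded": len(result.excluded)}, indent=2))
    add_artifact(path)


# ---------------------------------------------------------------------------
# parameter-recovery harness

def recovery_report(spec: PopulationSpec, fit_kwargs: dict | None = None,
                    n_boot: int = 2000) -> pd.DataFrame:
    """Simulate a cohort, refit it, and tabulate per-parameter recovery.

    Correlations are Pearson r between generative and recovered transformed
    values; bias and RMSE are in transformed space.  With a zero-variance
    population the correlation is undefined and reported as NaN.
    """
    from .models import transform_params

    model = spec.model_spec
    cohorts, params = simulate_cohort(spec)
    fit = fit_em(cohorts[0], model, seed=spec.seed, **(fit_kwargs or {}))
    true_T = np.array([transform_params(p, model, "to_transformed")
                       for p in params[0]])
    rec_T = fit.theta_matrix()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for j, p in enumerate(model.params):
        t, r = true_T[:, j], rec_T[:, j]
        if np.std(t) == 0:
            corr, lo, hi = np.nan, np.nan, np.nan
        else:
            corr = float(np.corrcoef(t, r)[0, 1])
            idx = rng.integers(0, t.size, size=(n_boot, t.size))
            boots = [float(np.corrcoef(t[i], r[i])[0, 1]) for i in idx]
            lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"parameter": p, "correlation": corr,
                     "corr_ci_low": lo, "corr_ci_high": hi,
                     "bias": float(np.mean(r - t)),
                     "rmse": float(np.sqrt(np.mean((r - t) ** 2)))})
    return pd.DataFrame(rows).set_index("parameter")
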