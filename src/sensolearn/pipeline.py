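"""End-to-end pipeline: simulate/ingest -> fit -> select -> compare.

A :class:`RunConfig` describes a synthetic cohort (experiment, group
sizes, generating model and per-group — optionally per-condition —
parameters), the candidate model set, fitting and BMS settings, and the
group-statistics plan.  :func:`run_pipeline` executes the stages in
order, returns every intermediate artefact, and (optionally) writes the
delimited tables, JSON summaries and a manifest with checksums so a run
is exactly reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sensolearn.agents import AgentRecord, simulate_agent
from sensolearn.bms import BMSResult, rfx_bms
from sensolearn.designs import gen_interception_design, gen_swi_design
from sensolearn.errors import ValidationError
from sensolearn.inversion import FitResult, PriorSpec, elicit_priors, map_fit
from sensolearn.learning import BeliefTrajectory, mean_learning_rate
from sensolearn.models import MODEL_NAMES, get_model
from sensolearn import stats as gstats

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "import_trial_table", "simulate_cohort"]

REQUIRED_COLUMNS = ("subject", "group", "condition", "trial", "u", "y")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    experiment: str = "interception"          # "swi" | "interception"
    n_per_group: dict = field(default_factory=lambda: {
        "autism": 10, "neurotypical": 10})
    generating_model: str = "HGF3"
    # group -> {param: value} (plus "zeta"), or group -> {condition:
    # {param: value}} for condition-specific generative parameters
    group_params: dict = field(default_factory=dict)
    models: tuple = MODEL_NAMES
    n_restarts: int = 4
    elicit: bool = False
    alpha0: float = 1.0
    bms_samples: int = 100000
    seed: int = 1
    # parameters entering the group-statistics stage; None = all
    # extracted parameters
    stats_params: tuple | None = None
    nonparametric_params: tuple = ("alpha3",)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        if self.stats_params is not None:
            d["stats_params"] = list(self.stats_params)
        d["nonparametric_params"] = list(self.nonparametric_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        if d.get("stats_params") is not None:
            d["stats_params"] = tuple(d["stats_params"])
        if "nonparametric_params" in d:
            d["nonparametric_params"] = tuple(d["nonparametric_params"])
        known = cls.__dataclass_fields__
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.experiment not in ("swi", "interception"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        for m in (self.generating_model, *self.models):
            get_model(m)  # raises for unregistered models


@dataclass
class PipelineResult:
    config: RunConfig
    trials: pd.DataFrame
    agents: list[AgentRecord]
    fits: pd.DataFrame                 # subject x condition x model rows
    lme_matrix: pd.DataFrame           # subjects x models
    bms: BMSResult
    winning_model: str
    parameters: pd.DataFrame           # subject, group, condition, parameter, value
    stats: dict
    manifest: dict


def _resolve_params(group_params: dict, group: str, condition: str,
                    model_name: str) -> tuple[dict, float]:
    spec = get_model(model_name)
    base = spec.default_params()
    cfg = dict(group_params.get(group, {}))
    if condition in cfg or any(isinstance(v, dict) for v in cfg.values()):
        cfg = dict(cfg.get(condition, {}))
    params = {**base, **cfg}
    zeta = float(params.pop("zeta"))
    return params, zeta


def simulate_cohort(config: RunConfig) -> list[AgentRecord]:
    """Simulate the configured cohort; every agent's seed derives from
    the config seed so the cohort is exactly regenerable."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    agents: list[AgentRecord] = []
    sid = 0
    for group, n in config.n_per_group.items():
        for _ in range(n):
            sid += 1
            subject = f"S{sid:03d}"
            if config.experiment == "swi":
                order = 1 + (sid - 1) % 3
                design = gen_swi_design(order_id=order)
                conds = [("swi", design)]
            else:
                conds = [
                    (c, gen_interception_design(
                        c, seed=int(rng.integers(2**31 - 1))))
                    for c in ("stable", "volatile")
                ]
            for cond, design in conds:
                params, zeta = _resolve_params(
                    config.group_params, group, cond,
                    config.generating_model)
                agents.append(simulate_agent(
                    design, config.generating_model, params,
                    {"zeta": zeta}, seed=int(rng.integers(2**31 - 1)),
                    subject=subject, group=group))
    return agents


def _extract_parameters(fit: FitResult, agent: AgentRecord) -> dict:
    """Scalar parameters of interest from one winning-model fit:
    MAP estimates plus trajectory means of beliefs and learning rates."""
    out = {"zeta": fit.params["zeta"]}
    spec = get_model(fit.model)
    perceptual = {k: v for k, v in fit.params.items() if k != "zeta"}
    out.update(perceptual)
    traj = spec.filter(agent.u, perceptual)
    if isinstance(traj, BeliefTrajectory):
        out["mu2"] = float(np.mean(traj.mu[2]))
        out["mu3"] = float(np.mean(traj.mu[3]))
        out["alpha2"] = mean_learning_rate(traj, 2)
        out["alpha3"] = mean_learning_rate(traj, 3)
        if traj.levels >= 4:
            out["mu4"] = float(np.mean(traj.mu[4]))
            out["alpha4"] = mean_learning_rate(traj, 4)
    else:
        out["alpha2"] = float(np.mean(traj.alpha))
        out["v_final"] = float(traj.v[-1])
    return out


def _stats_stage(config: RunConfig, params: pd.DataFrame) -> dict:
    """The parameter-comparison battery of the analysis plan."""
    results: dict = {}
    names = (config.stats_params if config.stats_params is not None
             else tuple(sorted(params["parameter"].unique())))
    two_condition = params["condition"].nunique() == 2

    for name in names:
        sub = params[params["parameter"] == name]
        if sub.empty or sub["value"].std(ddof=0) == 0:
            continue
        entry: dict = {}
        if two_condition:
            nonpar = name in config.nonparametric_params
            if nonpar:
                entry["condition"] = gstats.rank_tests(
                    sub["value"], sub["condition"], "friedman",
                    subjects=sub["subject"])
                entry["group"] = gstats.rank_tests(
                    sub["value"], sub["group"], "kruskal")
                follow = {
                    cond: gstats.rank_tests(
                        c["value"], c["group"], "mannwhitney")
                    for cond, c in sub.groupby("condition")
                }
            else:
                entry.update(gstats.mixed_anova_2x2(
                    sub, dv="value", between="group", within="condition",
                    subject="subject"))
                follow = {
                    cond: gstats.two_sample_tests(
                        c["value"], c["group"], variance_rule="welch")
                    for cond, c in sub.groupby("condition")
                }
            adj = gstats.holm_bonferroni([f.p for f in follow.values()])
            for (cond, f), a in zip(follow.items(), adj):
                f.p_holm = float(a)
                entry[f"followup_{cond}"] = f
        else:
            entry["group"] = gstats.two_sample_tests(
                sub["value"], sub["group"])
        results[name] = entry
    return results


def _stats_to_jsonable(stats: dict) -> dict:
    out = {}
    for pname, entry in stats.items():
        out[pname] = {}
        for key, r in entry.items():
            out[pname][key] = {
                "test": r.test, "statistic": r.statistic, "df": r.df,
                "p": r.p, "p_holm": r.p_holm,
                "effect_size": r.effect_size, "effect_type": r.effect_type,
            }
    return out


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis on a synthetic cohort.

    Stages: simulate -> (inputs/responses already coded by the
    simulator) -> fit all candidate models per subject by MAP ->
    random-effects BMS on the summed-over-conditions LME matrix ->
    extract the winning model's parameters -> group statistics.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    agents = simulate_cohort(config)
    trials = pd.concat([a.to_frame() for a in agents], ignore_index=True)

    priors: dict[str, PriorSpec | None] = {m: None for m in config.models}
    if config.elicit:
        u_seqs = [a.u for a in agents]
        priors = {m: elicit_priors(u_seqs, m) for m in config.models}

    fit_rows = []
    fit_objs: dict[tuple, FitResult] = {}
    for a in agents:
        cond = getattr(a.design, "condition", "swi")
        for m in config.models:
            fit = map_fit(a.u, a.y, m, priors=priors[m],
                          n_restarts=config.n_restarts,
                          seed=int(rng.integers(2**31 - 1)),
                          subject=a.subject)
            fit_objs[(a.subject, cond, m)] = fit
            fit_rows.append({
                "subject": a.subject, "group": a.group, "condition": cond,
                "model": m, "lme": fit.lme, "loglik": fit.loglik,
                "converged": fit.converged,
                **{f"param_{k}": v for k, v in fit.params.items()},
            })
    fits = pd.DataFrame(fit_rows)
    if not fits["converged"].all():
        bad = fits.loc[~fits["converged"], ["subject", "model"]]
        raise RuntimeError(
            f"fit stage failed to converge for: {bad.to_dict('records')}")

    lme = fits.pivot_table(index="subject", columns="model", values="lme",
                           aggfunc="sum")[list(config.models)]
    bms = rfx_bms(lme.to_numpy(), models=list(config.models),
                  alpha0=config.alpha0, seed=config.seed,
                  n_samples=config.bms_samples)
    winning = bms.models[int(np.argmax(bms.pxp))]

    param_rows = []
    for a in agents:
        cond = getattr(a.design, "condition", "swi")
        fit = fit_objs[(a.subject, cond, winning)]
        for k, v in _extract_parameters(fit, a).items():
            param_rows.append({
                "subject": a.subject, "group": a.group, "condition": cond,
                "parameter": k, "value": v,
            })
    parameters = pd.DataFrame(param_rows)

    stats = _stats_stage(config, parameters)

    manifest = {
        "config": config.to_dict(),
        "n_subjects": int(trials["subject"].nunique()),
        "n_agents": len(agents),
        "winning_model": winning,
        "priors": {
            m: (None if p is None else
                {"means": p.means, "variances": p.variances,
                 "source": p.source})
            for m, p in priors.items()
        },
        "bms": {
            "models": bms.models,
            "frequencies": bms.frequencies.tolist(),
            "ep": bms.ep.tolist(), "bor": bms.bor,
            "pxp": bms.pxp.tolist(),
        },
        "exclusions": [],  # synthetic cohorts: every simulated subject kept
    }

    result = PipelineResult(
        config=config, trials=trials, agents=agents, fits=fits,
        lme_matrix=lme, bms=bms, winning_model=winning,
        parameters=parameters, stats=stats, manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    result.trials.to_csv(outdir / "trials.csv", index=False)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.lme_matrix.to_csv(outdir / "lme_matrix.csv")
    result.parameters.to_csv(outdir / "parameters.csv", index=False)
    result.bms.to_frame().to_csv(outdir / "bms.csv", index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(_stats_to_jsonable(result.stats), fh, indent=2)
    for name in ("trials.csv", "fits.csv", "lme_matrix.csv",
                 "parameters.csv", "bms.csv", "stats.json"):
        files[name] = _sha256(outdir / name)
    result.manifest["checksums"] = files
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def import_trial_table(path, dialect: str = "csv"
                       ) -> tuple[pd.DataFrame, dict]:
    """Load and validate a coded trial table.

    Requires the columns subject, group, condition, trial, u, y;
    unknown columns are preserved.  Subjects missing more than 15% of
    their condition's trials (relative to the modal trial count) are
    flagged excluded in the returned report — never silently dropped.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    for col in ("u", "y"):
        vals = df[col].dropna()
        if not vals.isin([0, 1]).all():
            raise ValidationError(f"column {col!r} must be binary (0/1)")

    counts = df.dropna(subset=["u", "y"]).groupby(
        ["condition", "subject"]).size()
    report = {"n_subjects": int(df["subject"].nunique()),
              "excluded": [], "warnings": []}
    for cond, grp in counts.groupby(level="condition"):
        expected = int(grp.max())
        for (c, subj), n in grp.items():
            if n < (1.0 - 0.15) * expected:
                report["excluded"].append(
                    {"subject": str(subj), "condition": str(c),
                     "rule": "missing > 15% of trials",
                     "n_valid": int(n), "expected": expected})
    return df, report
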