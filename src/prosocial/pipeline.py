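"""End-to-end orchestration: simulate → QC → fit → indices → stats → CCA.

A :class:`RunConfig` fully determines a run; every stochastic stage (choice
simulation, multi-start draws, permutations) is seeded from the config seed
through independent child seeds, so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cca as cca_mod
from . import effort as effort_mod
from . import harm as harm_mod
from . import io as io_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .traits import TRAIT_NAMES, PlantedStructure, generate_trait_cohort
from .trials import generate_effort_trialset, generate_harm_trialset

log = logging.getLogger("prosocial")


@dataclass
class RunConfig:
    seed: int = 0
    n: int = 325
    # generator
    loadings: dict = field(default_factory=dict)  # empty → package defaults
    r_target: float = 0.4
    mean_hyperaltruism: float = 0.08
    mean_prosocial_effort: float = -0.08
    sd_hyperaltruism: float = 0.20
    sd_prosocial_effort: float = 0.12
    null_cohort: bool = False
    miss_rate: float = 0.02
    check_fail_prob: float = 0.02
    n_regular_per_condition: int = 35
    n_checks_per_condition: int = 2
    # fitting
    n_starts: int = 10
    # inference
    n_perm: int = 1000
    loading_threshold: float = 0.3

    def planted(self) -> PlantedStructure:
        if self.null_cohort:
            return PlantedStructure.null()
        kwargs = dict(
            r_target=self.r_target,
            mean_hyperaltruism=self.mean_hyperaltruism,
            mean_prosocial_effort=self.mean_prosocial_effort,
            sd_hyperaltruism=self.sd_hyperaltruism,
            sd_prosocial_effort=self.sd_prosocial_effort,
        )
        if self.loadings:
            kwargs["loadings"] = dict(self.loadings)
        return PlantedStructure(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Cohort:
    harm_records: dict
    effort_records: dict
    traits: pd.DataFrame
    ground_truth: pd.DataFrame


def simulate_cohort(config: RunConfig) -> Cohort:
    """Generate a full synthetic cohort: traits, true parameters, choices."""
    if config.n <= 0:
        raise ValueError("cohort size must be positive")
    root = np.random.default_rng(config.seed)
    traits, gt = generate_trait_cohort(
        config.n, config.planted(), seed=int(root.integers(2**31))
    )
    trial_seed = int(root.integers(2**31))
    harm_trials = generate_harm_trialset(
        config.n_regular_per_condition, config.n_checks_per_condition, seed=trial_seed
    )
    effort_trials = generate_effort_trialset()
    harm_records, effort_records = {}, {}
    for row in gt.itertuples(index=False):
        pid = int(row.participant_id)
        hp = harm_mod.HarmParams(
            row.kappa_self, row.kappa_other,
            min(row.beta_self, 100.0), min(row.beta_other, 100.0),
        )
        ep = effort_mod.EffortParams(
            row.lambda_self, row.lambda_other, min(row.beta_effort, 30.0)
        )
        harm_records[pid] = sim_mod.simulate_harm_choices(
            hp, harm_trials, seed=int(root.integers(2**31)),
            check_fail_prob=config.check_fail_prob,
        )
        effort_records[pid] = sim_mod.simulate_effort_choices(
            ep, effort_trials, seed=int(root.integers(2**31)),
            miss_rate=config.miss_rate,
        )
    return Cohort(harm_records, effort_records, traits, gt)


def _manifest(config: RunConfig, tables: dict[str, pd.DataFrame]) -> dict:
    cfg = config.to_json()
    return {
        "config": json.loads(cfg),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
    }


def run_simulate(config: RunConfig, out_dir) -> Path:
    """Write a simulated cohort (trials/traits/ground-truth CSVs + manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    io_mod.write_trials_csv(out / "trials.csv", cohort.harm_records, cohort.effort_records)
    io_mod.write_traits_csv(out / "traits.csv", cohort.traits)
    io_mod.write_ground_truth_csv(out / "ground_truth.csv", cohort.ground_truth)
    manifest = _manifest(
        config,
        {
            "trials": io_mod.trials_frame(cohort.harm_records, cohort.effort_records),
            "traits": cohort.traits,
            "ground_truth": cohort.ground_truth,
        },
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("cohort of %d participants written to %s", config.n, out)
    return out


def fit_participants(cohort: Cohort, retained, n_starts: int, seed: int):
    """Fit both choice models per retained participant; returns fit dicts."""
    rng = np.random.default_rng(seed)
    harm_fits, effort_fits = {}, {}
    for pid in retained:
        harm_fits[pid] = harm_mod.fit(
            cohort.harm_records[pid], n_starts=n_starts,
            seed=int(rng.integers(2**31)),
        )
        effort_fits[pid] = effort_mod.fit(
            cohort.effort_records[pid], n_starts=n_starts,
            seed=int(rng.integers(2**31)),
        )
    return harm_fits, effort_fits


def indices_frame(harm_fits: dict, effort_fits: dict) -> pd.DataFrame:
    """Per-participant prosociality indices from fitted parameters."""
    rows = []
    for pid in harm_fits:
        rows.append(
            dict(
                participant_id=pid,
                hyperaltruism=harm_mod.hyperaltruism(harm_fits[pid].params),
                prosocial_effort=effort_mod.prosocial_effort(effort_fits[pid].params),
            )
        )
    return pd.DataFrame(rows)


def behavioral_battery(harm_params: pd.DataFrame, effort_params: pd.DataFrame,
                       effort_records: dict) -> list:
    """The univariate analyses: Wilcoxon contrasts, cross-task Spearman
    correlations, the Fisher-Z correlation comparison, and the two ANOVAs."""
    res = []
    res.append(stats_mod.wilcoxon_signed_rank(
        harm_params["kappa_other"], harm_params["kappa_self"],
        name="wilcoxon_kappa_other_vs_self"))
    res.append(stats_mod.wilcoxon_signed_rank(
        effort_params["lambda_other"], effort_params["lambda_self"],
        name="wilcoxon_lambda_other_vs_self"))
    hyper = harm_params["kappa_other"] - harm_params["kappa_self"]
    pros_eff = -(effort_params["lambda_other"] - effort_params["lambda_self"])
    r_pros = stats_mod.spearman(hyper, pros_eff, name="spearman_hyperaltruism_prosocial_effort")
    r_other = stats_mod.spearman(
        harm_params["kappa_other"], -effort_params["lambda_other"],
        name="spearman_kappa_other_rev_lambda_other")
    r_self = stats_mod.spearman(
        harm_params["kappa_self"], effort_params["lambda_self"],
        name="spearman_kappa_self_lambda_self")
    res += [r_pros, r_other, r_self]
    n = len(harm_params)
    res.append(stats_mod.fisher_z_difference(
        r_pros.statistic, n, r_self.statistic, n,
        name="fisherz_prosocial_vs_self"))
    res.append(stats_mod.fisher_z_difference(
        r_other.statistic, n, r_self.statistic, n,
        name="fisherz_other_vs_self"))
    for factor in ("effort_level", "reward"):
        cells = stats_mod.work_proportion_cells(effort_records, factor)
        for tr in stats_mod.rm_anova_2xk(cells, "p_work", (factor, "beneficiary"), "subject"):
            res.append(stats_mod.TestResult(
                f"anova_{factor}:{tr.name}", tr.statistic, tr.p_value,
                tr.df1, tr.df2, tr.effect_size))
    return res


def trait_cca(traits: pd.DataFrame, indices: pd.DataFrame, n_perm: int,
              threshold: float, seed: int):
    """CCA of the 18 traits against the two indices, with permutation p,
    function-1 role classification, and commonality partition."""
    merged = traits.merge(indices, on="participant_id")
    X = merged[list(TRAIT_NAMES)]
    Y = merged[["hyperaltruism", "prosocial_effort"]]
    result = cca_mod.fit_cca(X, Y)
    perm = cca_mod.permutation_test(X, Y, n_perm=n_perm, seed=seed)
    roles = cca_mod.classify_roles(
        result.x_loadings[:, 0], result.x_weights[:, 0], threshold=threshold)
    sel = cca_mod.select_commonality_predictors(
        result.x_loadings[:, 0], result.x_weights[:, 0], threshold=threshold)
    comm = cca_mod.commonality(X.iloc[:, sel], result.y_scores[:, 0])
    return result, perm, roles, comm


def run_full(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order and write all result tables.

    Returns the tables as a dict of DataFrames (plus the CCAResult under
    'cca_result').
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()
    cohort = simulate_cohort(config)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    retained, reports = qc_mod.apply_exclusions(cohort.harm_records, cohort.effort_records)
    qc_table = io_mod.qc_frame(reports)
    timings["qc"] = time.perf_counter() - t0
    log.info("QC: %d of %d participants retained", len(retained), config.n)
    if len(retained) <= 20:
        raise RuntimeError("qc stage: too few participants retained for the trait CCA")

    t0 = time.perf_counter()
    root = np.random.default_rng(config.seed + 1)
    harm_fits, effort_fits = fit_participants(
        cohort, retained, config.n_starts, int(root.integers(2**31)))
    harm_table = io_mod.harm_params_frame(harm_fits)
    effort_table = io_mod.effort_params_frame(effort_fits)
    indices = indices_frame(harm_fits, effort_fits)
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    effort_retained = {pid: cohort.effort_records[pid] for pid in retained}
    stats_results = behavioral_battery(harm_table, effort_table, effort_retained)
    stats_table = io_mod.stats_frame(stats_results)
    timings["stats"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result, perm, roles, comm = trait_cca(
        cohort.traits, indices, config.n_perm, config.loading_threshold,
        seed=int(root.integers(2**31)))
    functions = result.wilks.copy()
    functions.insert(1, "r", result.correlations)
    functions["perm_p"] = [perm.p_value] + [float("nan")] * (len(functions) - 1)
    coef = io_mod.cca_coefficients_frame(result)
    role_map = dict(zip(result.x_names, roles))
    coef["role"] = [
        role_map.get(v, "") if s == "traits" and k == 1 else ""
        for s, v, k in zip(coef["set"], coef["variable"], coef["function"])
    ]
    timings["cca"] = time.perf_counter() - t0

    tables = {
        "qc": qc_table, "harm_params": harm_table, "effort_params": effort_table,
        "indices": indices, "stats": stats_table, "cca_functions": functions,
        "cca_coefficients": coef, "commonality": comm,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = _manifest(config, tables)
    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["n_retained"] = len(retained)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    tables["cca_result"] = result
    tables["permutation"] = perm
    return tables


def run_recovery(n: int = 200, n_starts: int = 10, seed: int = 0,
                 kappa_range=(0.05, 0.95), beta_harm: float = 5.0,
                 lambda_range=(0.0, 0.3), beta_effort: float = 2.0) -> pd.DataFrame:
    """Parameter-recovery experiment: simulate known parameters at the tasks'
    trial counts, refit, and tabulate true vs recovered values."""
    rng = np.random.default_rng(seed)
    harm_trials = generate_harm_trialset(seed=int(rng.integers(2**31)))
    effort_trials = generate_effort_trialset()
    rows = []
    for i in range(n):
        ks, ko = rng.uniform(*kappa_range, size=2)
        ls, lo = rng.uniform(*lambda_range, size=2)
        hp = harm_mod.HarmParams(ks, ko, beta_harm, beta_harm)
        ep = effort_mod.EffortParams(ls, lo, beta_effort)
        hrec = sim_mod.simulate_harm_choices(hp, harm_trials, seed=int(rng.integers(2**31)))
        erec = sim_mod.simulate_effort_choices(ep, effort_trials, seed=int(rng.integers(2**31)))
        hfit = harm_mod.fit(hrec, n_starts=n_starts, seed=int(rng.integers(2**31)))
        efit = effort_mod.fit(erec, n_starts=n_starts, seed=int(rng.integers(2**31)))
        rows.append(dict(
            participant=i,
            kappa_self_true=ks, kappa_other_true=ko,
            kappa_self_hat=hfit.params.kappa_self, kappa_other_hat=hfit.params.kappa_other,
            lambda_self_true=ls, lambda_other_true=lo,
            lambda_self_hat=efit.params.lambda_self, lambda_other_hat=efit.params.lambda_other,
        ))
    return pd.DataFrame(rows)


def run_calibration(n_replicates: int = 500, n: int = 325, n_perm: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Type-I calibration batch: permutation p-values on null cohorts."""
    rng = np.random.default_rng(seed)
    null = PlantedStructure.null()
    rows = []
    for i in range(n_replicates):
        traits, gt = generate_trait_cohort(n, null, seed=int(rng.integers(2**31)))
        X = traits[list(TRAIT_NAMES)]
        Y = gt[["hyperaltruism", "prosocial_effort"]]
        perm = cca_mod.permutation_test(X, Y, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append(dict(replicate=i, p=perm.p_value, roy=perm.statistic))
    return pd.DataFrame(rows)
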