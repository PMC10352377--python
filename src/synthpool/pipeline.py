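"""End-to-end study orchestration.

One call runs the whole comparison: simulate both countries' ground truth,
fit the sequential synthesis model on country A, sample m synthetic
replicates, run the membership-disclosure attack (reported, not blocking),
pool each replicate with country B's real table, fit the univariable,
main-effects and country-interaction regressions per replicate, combine them
with the partial-synthesis rules, fit the exact federated oracle on the two
real tables, and evaluate SMD balance plus per-coefficient concordance.
Every artifact is a pure function of (config, master seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combining import EstimateSet, combine_model
from .federated import (
    ModelSpec, interaction_spec, main_effects_spec, pooled_ols,
    solve_federated, summarize_node, univariable_specs,
)
from .membership import AttackConfig, MembershipAttackResult, attack
from .schema import HarmonizedSurveyTable, concat_tables
from .simulate import (
    DEMOGRAPHICS, CountrySpec, austria_like, canada_like, simulate_country,
)
from .synthesis import SynthesisModel, TuningConfig, fit_sequential, generate_replicates
from .utility import ComparisonReport, SmdReport, compare_fits, smd_report

logger = logging.getLogger("synthpool")


@dataclass
class StudyConfig:
    """Full study configuration; country A is synthesized, B stays real."""

    spec_a: CountrySpec = field(default_factory=lambda: canada_like(20_000))
    spec_b: CountrySpec = field(default_factory=lambda: austria_like(5_000))
    m: int = 5
    tuning: TuningConfig = field(default_factory=lambda: TuningConfig(n_trials=0))
    order: object = None           # None = schema order, "auto" = greedy heuristic
    attack_config: AttackConfig = field(default_factory=AttackConfig)
    n_attack_targets: int = 1000   # members and non-members each
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2 for combining-rule inference")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        stock = {"canada_like": canada_like, "austria_like": austria_like}
        spec_a = stock[d.get("synthesize_country", "canada_like")](
            int(d.get("n_synthesize", 20_000)))
        spec_b = stock[d.get("real_country", "austria_like")](
            int(d.get("n_real", 5_000)))
        att = d.get("attack", {}) or {}
        h = att.get("h", "adaptive")
        h = None if h in (None, "adaptive") else float(h)
        return cls(
            spec_a=spec_a, spec_b=spec_b,
            m=int(d.get("m", 5)),
            tuning=TuningConfig(n_trials=int(d.get("tuning_trials", 0))),
            order=d.get("order"),
            attack_config=AttackConfig(h=h),
            n_attack_targets=int(att.get("n_targets", 1000)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class StudyReport:
    """Everything run_study produces, in memory."""

    config: StudyConfig
    table_a: HarmonizedSurveyTable
    table_b: HarmonizedSurveyTable
    synthesis_model: SynthesisModel
    replicates: list
    privacy: MembershipAttackResult
    smd: SmdReport
    comparisons: dict            # model name -> ComparisonReport
    combined_tables: dict        # model name -> combined coefficient DataFrame
    oracle_fits: dict            # model name -> OlsFit

    def summary(self) -> dict:
        per_model = {}
        for name, comp in self.comparisons.items():
            per_model[name] = {
                "n_coefficients": comp.n_coefficients,
                "sign_agreement_rate": comp.sign_agreement_rate,
                "significance_agreement_rate": comp.significance_agreement_rate,
                "ci_overlap_rate": comp.ci_overlap_rate,
                "r2_oracle": comp.r2_oracle,
                "r2_pooled": comp.r2_pooled,
            }
        return {
            "privacy": {
                "relative_f1": self.privacy.relative_f1,
                "f1": self.privacy.f1,
                "naive_f1": self.privacy.naive_f1,
                "precision": self.privacy.precision,
                "recall": self.privacy.recall,
            },
            "smd": {
                "max_mean_smd": float(self.smd.summary["mean_smd"].max()),
                "any_flagged": self.smd.any_flagged,
            },
            "models": per_model,
            "seed": self.config.seed,
            "m": self.config.m,
            "n_a": self.table_a.n,
            "n_b": self.table_b.n,
        }


def _fit_all_models(pooled_reps, table_a, table_b, specs):
    """Oracle (federated over the two real nodes) and combined pooled fits."""
    oracle_fits, combined_tables, comparisons = {}, {}, {}
    for spec in specs:
        oracle = solve_federated([summarize_node(table_a, spec),
                                  summarize_node(table_b, spec)])
        rep_fits = [pooled_ols(t, spec) for t in pooled_reps]
        names = list(oracle.params.index)
        sets = [EstimateSet(nm,
                            np.array([f.params[nm] for f in rep_fits]),
                            np.array([f.variances[nm] for f in rep_fits]))
                for nm in names]
        combined = combine_model(sets)
        r2_pooled = float(np.mean([f.r2 for f in rep_fits]))
        oracle_fits[spec.name] = oracle
        combined_tables[spec.name] = combined
        comparisons[spec.name] = compare_fits(oracle, combined, r2_pooled=r2_pooled)
    return oracle_fits, combined_tables, comparisons


def run_study(cfg: StudyConfig, out_dir=None) -> StudyReport:
    """Execute the full workflow; optionally write all artifacts to out_dir."""
    seeds = np.random.default_rng(cfg.seed).integers(2**31 - 1, size=6)

    logger.info("simulating country %s (n=%d) and %s (n=%d)",
                cfg.spec_a.country, cfg.spec_a.n,
                cfg.spec_b.country, cfg.spec_b.n)
    table_a = simulate_country(cfg.spec_a, int(seeds[0]))
    table_b = simulate_country(cfg.spec_b, int(seeds[1]))

    logger.info("fitting sequential synthesis model on country %s", cfg.spec_a.country)
    model = fit_sequential(table_a, order=cfg.order, config=cfg.tuning,
                           seed=int(seeds[2]))
    reps = generate_replicates(model, n=table_a.n, m=cfg.m, seed=int(seeds[3]))

    logger.info("membership-disclosure attack on %d replicates", cfg.m)
    rng = np.random.default_rng(int(seeds[4]))
    k = min(cfg.n_attack_targets, table_a.n)
    member_idx = np.sort(rng.choice(table_a.n, size=k, replace=False))
    members = table_a.subset(table_a.data.index.isin(member_idx))
    nonmember_spec = CountrySpec(
        cfg.spec_a.country, k, cfg.spec_a.marginals, cfg.spec_a.effect_logits,
        cfg.spec_a.missing_rates, cfg.spec_a.continuous_bmi)
    non_members = simulate_country(nonmember_spec, int(seeds[5]))
    privacy = attack(members, non_members, reps.tables, cfg.attack_config)
    logger.info("relative membership F1 = %.4f", privacy.relative_f1)

    pooled_oracle = concat_tables([table_a, table_b])
    pooled_reps = [concat_tables([t, table_b]) for t in reps.tables]
    smd = smd_report(pooled_oracle, pooled_reps, variables=list(DEMOGRAPHICS))

    specs = univariable_specs() + [main_effects_spec(), interaction_spec()]
    oracle_fits, combined_tables, comparisons = _fit_all_models(
        pooled_reps, table_a, table_b, specs)

    report = StudyReport(cfg, table_a, table_b, model, reps.tables, privacy,
                         smd, comparisons, combined_tables, oracle_fits)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir) -> None:
    """Write all study artifacts (CSV tables + JSON reports) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table_a.write_csv(out / "country_a.csv")
    report.table_b.write_csv(out / "country_b.csv")
    for i, t in enumerate(report.replicates):
        t.write_csv(out / f"synthetic_replicate_{i}.csv")
    report.synthesis_model.save(out / "synthesis_model.json")
    (out / "privacy.json").write_text(
        json.dumps(report.privacy.to_dict(), indent=2, sort_keys=True))
    report.smd.per_replicate.to_csv(out / "smd_per_replicate.csv", index=False)
    report.smd.summary.to_csv(out / "smd_summary.csv")
    for name, combined in report.combined_tables.items():
        combined.to_csv(out / f"combined_{name}.csv")
        report.oracle_fits[name].table().to_csv(out / f"federated_{name}.csv")
        report.comparisons[name].table.to_csv(out / f"comparison_{name}.csv")
    (out / "report.json").write_text(
        json.dumps(report.summary(), indent=2, sort_keys=True))
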