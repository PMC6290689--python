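"""End-to-end orchestration: cohort directory -> metrics table -> summaries.

The real challenge had incomplete datasets, so the per-submission loop is
failure-contained: an entry that cannot be processed is logged and skipped,
and the run continues.  All stages are deterministic given inputs, config
and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import (
    case_average,
    consensus,
    kruskal_wallis_dunn,
    percent_diff,
    rank_cases,
    summary,
)
from .errors import AneuvarError, InsufficientDataError
from .hemodynamics import (
    BloodProperties,
    KAPPA_DEFAULT,
    TAU_LOW_DEFAULT,
    compute_submission,
)
from .io_formats import MetricsTable, write_metrics_table
from .synthetic import (
    PerturbationConfig,
    default_cases,
    load_submission,
    sample_cohort,
    save_submission,
)

__all__ = ["AnalysisConfig", "generate_cohort_dir", "compute_metrics",
           "summarize_metrics", "PARENT_PARAMETERS", "SAC_PARAMETERS"]

PARENT_PARAMETERS = ["diameter", "flow_rate", "velocity", "reynolds",
                     "poiseuille_wss", "calculated_wss", "wss_ratio",
                     "flow_division"]
SAC_PARAMETERS = ["awss", "mwss", "lsa", "awss_star", "mwss_star", "lsa_star"]


@dataclass
class AnalysisConfig:
    """Pipeline settings: thresholds, estimators, cohort size, seed."""

    tau_low: float = TAU_LOW_DEFAULT       # Pa
    kappa: float = KAPPA_DEFAULT           # x parent WSS
    quantile_method: str = "exclusive"
    alpha: float = 0.05
    seed: int = 0
    n_teams: int = 28
    resolution: int = 64
    pairs: list = field(default_factory=list)   # [[team_a, team_b], ...]

    def __post_init__(self) -> None:
        if self.tau_low <= 0 or self.kappa <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "AnalysisConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def generate_cohort_dir(out_dir: str | Path, config: AnalysisConfig,
                        pert: PerturbationConfig | None = None) -> Path:
    """Write a full virtual challenge (n_teams x 5 cases) to a directory."""
    if config.n_teams < 3:
        raise ValueError("n_teams must be >= 3")
    pert = pert or PerturbationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = default_cases(resolution=config.resolution)
    manifest = {"seed": int(config.seed), "n_teams": int(config.n_teams),
                "resolution": int(config.resolution), "cases": [], "truth": []}
    for i, case in enumerate(cases):
        subs = sample_cohort(case, pert, config.n_teams,
                             seed=int(config.seed) + i)
        manifest["cases"].append(case.case_id)
        for sub in subs:
            save_submission(sub, out / case.case_id / sub.truth.team_id)
            manifest["truth"].append(sub.truth.to_dict())
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def compute_metrics(cohort_dir: str | Path, config: AnalysisConfig,
                    out_csv: str | Path | None = None,
                    log_path: str | Path | None = None) -> MetricsTable:
    """Run the per-submission analysis over a cohort directory.

    Failures are contained per (team, case): the entry is recorded in the
    skip log and the run continues.
    """
    root = Path(cohort_dir)
    rows = []
    meta = {}
    skipped = []
    for sub_yaml in sorted(root.glob("*/*/submission.yaml")):
        d = sub_yaml.parent
        team = d.name
        case = d.parent.name
        try:
            sub = load_submission(d)
            props = BloodProperties(density=sub.meta.density,
                                    viscosity=sub.meta.viscosity)
            result = compute_submission(
                sub.mesh, sub.sections, sub.regions, props, meta=sub.meta,
                tau_low=config.tau_low, kappa=config.kappa,
                team=team, case=case)
            meta[team] = sub.meta
            for param, value in result.as_records():
                rows.append({"team": team, "case": case,
                             "parameter": param, "value": value})
        except (AneuvarError, OSError, ValueError) as exc:
            skipped.append({"team": team, "case": case, "error": str(exc)})
    table = MetricsTable(pd.DataFrame(rows, columns=["team", "case",
                                                     "parameter", "value"]),
                         meta)
    if out_csv is not None:
        write_metrics_table(table, out_csv)
    if log_path is not None:
        with open(log_path, "w") as fh:
            json.dump({"skipped": skipped}, fh, indent=2)
    return table


def _stratum_values(vals: pd.Series, table: MetricsTable,
                    stratum: str) -> pd.Series:
    if stratum == "All":
        return vals
    keep = [t for t in vals.index if table.experience_of(t) == stratum.lower()]
    return vals.loc[keep]


def summarize_metrics(table: MetricsTable, config: AnalysisConfig,
                      out_dir: str | Path | None = None) -> dict:
    """Dispersion summaries, rank consensus and hypothesis tests.

    Returns {"summary": DataFrame, "ranks": DataFrame, "tests": dict,
    "pairs": DataFrame-or-None}; optionally writes summary.csv, ranks.csv,
    tests.json and pairs.csv.  Summaries cover each case individually and
    the case-average statistics, stratified by All/High/Medium/Low
    experience.  Every row carries its grouping provenance.
    """
    parameters = [p for p in PARENT_PARAMETERS + SAC_PARAMETERS
                  if p in table.parameters]
    strata = ["All", "High", "Medium", "Low"]
    sum_rows = []
    rank_rows = []
    tests: dict = {}

    for param in parameters:
        wide = table.pivot(param).reindex(columns=table.cases)
        groupings: list[tuple[str, pd.Series]] = [
            (c, wide[c].dropna()) for c in table.cases]
        groupings.append(("case_average", case_average(table, param)))
        for gname, vals in groupings:
            for stratum in strata:
                sel = _stratum_values(vals, table, stratum)
                try:
                    s = summary(sel.values, method=config.quantile_method)
                except InsufficientDataError:
                    continue
                sum_rows.append({
                    "parameter": param, "grouping": gname,
                    "experience": stratum, "n": s.n,
                    "median": s.median, "q1": s.q1, "q3": s.q3,
                    "cod_pct": round(100 * s.cod) if s.cod_defined else None,
                    "cod": s.cod, "p10": s.p10, "p90": s.p90,
                })

        # hypothesis tests: across cases, and across experience levels
        # (case-average values)
        case_groups = {c: v.values for c, v in groupings[:-1] if len(v) >= 2}
        param_tests = {}
        if len(case_groups) >= 2 and sum(len(v) for v in case_groups.values()) >= 5:
            res = kruskal_wallis_dunn(case_groups)
            param_tests["across_cases"] = {
                "H": res.h, "p": res.p,
                "significant": bool(res.p < config.alpha),
                "dunn": {f"{a}|{b}": p_adj
                         for (a, b), (_, _, p_adj) in res.pairwise.items()},
            }
        ca = groupings[-1][1]
        exp_groups = {}
        for level in ("high", "medium", "low"):
            vals = [v for t, v in ca.items() if table.experience_of(t) == level]
            if vals:
                exp_groups[level] = np.asarray(vals)
        if len(exp_groups) >= 2 and sum(len(v) for v in exp_groups.values()) >= 5:
            res = kruskal_wallis_dunn(exp_groups)
            param_tests["across_experience"] = {
                "H": res.h, "p": res.p,
                "significant": bool(res.p < config.alpha),
            }
        if param_tests:
            tests[param] = param_tests

        # rank-order consensus across cases
        ranks = rank_cases(table, param)
        if len(ranks) > 0:
            cons = consensus(ranks, meta=table.meta)
            for case_label in cons.counts.index:
                for rank in cons.counts.columns:
                    rank_rows.append({
                        "parameter": param, "case": case_label,
                        "rank": int(rank),
                        "n_teams": int(cons.counts.loc[case_label, rank]),
                        "majority_case": cons.majority[int(rank)],
                    })

    summary_df = pd.DataFrame(sum_rows)
    ranks_df = pd.DataFrame(rank_rows)

    pairs_df = None
    if config.pairs:
        pair_rows = []
        for a, b in config.pairs:
            for param in parameters:
                ca = case_average(table, param)
                if a in ca.index and b in ca.index and ca[a] + ca[b] > 0:
                    pair_rows.append({
                        "parameter": param, "team_a": a, "team_b": b,
                        "value_a": ca[a], "value_b": ca[b],
                        "pct_diff": round(percent_diff(ca[a], ca[b])),
                    })
        pairs_df = pd.DataFrame(pair_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out / "summary.csv", index=False)
        ranks_df.to_csv(out / "ranks.csv", index=False)
        with open(out / "tests.json", "w") as fh:
            json.dump(tests, fh, indent=2)
        if pairs_df is not None:
            pairs_df.to_csv(out / "pairs.csv", index=False)

    return {"summary": summary_df, "ranks": ranks_df, "tests": tests,
            "pairs": pairs_df}
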