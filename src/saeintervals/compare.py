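"""Method comparison and coverage evaluation.

Mirrors the comparison logic of the study design: a table of per-area
means and 95% intervals per method, interval widths and width ratios,
ranked county estimates (the ranking-plot data), wall-clock timing split
into the model-construction and post-stratification phases, and -- because
synthetic worlds come with exact truths -- empirical coverage of each
method's intervals against true county prevalences.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayes import McmcConfig, bayes_intervals, run_mcmc
from .bootstrap import BootstrapConfig, bootstrap_intervals
from .design import DesignSpec, build_design
from .direct import direct_estimate
from .drawset import STATE_ID, percentile_interval  # noqa: F401  (re-exported)
from .glmm import fit_glmm
from .mc import mc_intervals
from .poststrat import build_frame
from .synthetic import AreaTruth, GeneratorConfig, SyntheticWorld, generate_world


@dataclass
class ComparisonReport:
    """Per-area estimates with widths/ranks plus per-method summaries."""

    table: pd.DataFrame  # area_id, method, mean, lo95, hi95, width, rank
    method_summary: pd.DataFrame  # per method: median county width, coverage, timings

    def ranking_data(self, method: str) -> pd.DataFrame:
        """County estimates sorted by mean for one method (plot-ready)."""
        sub = self.table[(self.table.method == method) & (self.table.area_id != STATE_ID)]
        return sub.sort_values("mean").reset_index(drop=True)

    def median_width_ratio(self, method_a: str, method_b: str) -> float:
        """Median over counties of width(a) / width(b)."""
        t = self.table[self.table.area_id != STATE_ID]
        wa = t[t.method == method_a].set_index("area_id")["width"]
        wb = t[t.method == method_b].set_index("area_id")["width"]
        return float((wa / wb).median())


def compare_methods(
    estimates: list[pd.DataFrame],
    truth: AreaTruth | None = None,
    timings: dict[str, tuple[float, float]] | None = None,
) -> ComparisonReport:
    """Assemble the cross-method comparison from per-method estimate tables.

    All estimate sets must cover the same areas; a mismatch is an error
    naming the difference.  When a truth is supplied, per-method county
    coverage (fraction of county truths inside the interval) is added.
    """
    tables = [e.copy() for e in estimates]
    areas = [set(t.area_id) for t in tables]
    for t, a in zip(tables[1:], areas[1:]):
        if a != areas[0]:
            diff = sorted(a.symmetric_difference(areas[0]))
            raise ValueError(f"estimate sets cover different areas; difference: {diff}")
    big = pd.concat(tables, ignore_index=True)
    big["width"] = big["hi95"] - big["lo95"]
    county = big[big.area_id != STATE_ID]
    big["rank"] = county.groupby("method")["mean"].rank(method="first")

    rows = []
    for method, sub in big.groupby("method"):
        csub = sub[sub.area_id != STATE_ID]
        row = {
            "method": method,
            "median_county_width": float(csub["width"].median()),
            "state_mean": float(sub.loc[sub.area_id == STATE_ID, "mean"].iloc[0]),
            "state_width": float(sub.loc[sub.area_id == STATE_ID, "width"].iloc[0]),
        }
        if truth is not None:
            tr = pd.Series(truth.county_prevalence, index=[str(c) for c in truth.county_ids])
            m = csub.set_index("area_id")
            cov = ((tr >= m["lo95"]) & (tr <= m["hi95"])).mean()
            row["county_coverage"] = float(cov)
        if timings and method in timings:
            row["model_construction_s"], row["poststratification_s"] = timings[method]
        rows.append(row)
    return ComparisonReport(table=big, method_summary=pd.DataFrame(rows).set_index("method"))


def run_all_methods(
    world: SyntheticWorld,
    budgets: dict | None = None,
    seed: int = 0,
    methods: tuple[str, ...] = ("bayes", "mc", "parboot", "npboot", "direct"),
    spec: DesignSpec | None = None,
) -> tuple[list[pd.DataFrame], dict[str, tuple[float, float]]]:
    """Run the selected interval methods on one world; return estimates + timings.

    ``budgets`` overrides per-method simulation sizes, e.g.
    {"mc": {"R": 200}, "bayes": {"iterations": 20000, "burn_in": 2000}}.
    Timings are (model-construction seconds, post-stratification seconds).
    """
    budgets = budgets or {}
    spec = spec or DesignSpec()
    X, y, cidx, cids = build_design(world.survey, world.covariates, spec)
    frame = world.frame if world.frame is not None else build_frame(world.census, world.covariates, spec)

    t0 = time.perf_counter()
    fit = fit_glmm(X, y, cidx, cids, column_names=spec.column_names).require_converged()
    t_fit = time.perf_counter() - t0

    out, timings = [], {}
    for method in methods:
        if method == "mc":
            t0 = time.perf_counter()
            est = mc_intervals(fit, frame, seed=seed, **budgets.get("mc", {}))
            timings["mc"] = (t_fit, time.perf_counter() - t0)
        elif method == "bayes":
            cfg = McmcConfig(seed=seed, **budgets.get("bayes", {}))
            t0 = time.perf_counter()
            draws = run_mcmc(X, y, cidx, cfg, county_ids=cids)
            t1 = time.perf_counter()
            est = bayes_intervals(draws, frame)
            timings["bayes"] = (t1 - t0, time.perf_counter() - t1)
        elif method in ("parboot", "npboot"):
            mode = "parametric" if method == "parboot" else "nonparametric"
            cfg = BootstrapConfig(mode=mode, seed=seed, **budgets.get(method, {}))
            t0 = time.perf_counter()
            est = bootstrap_intervals(world.survey, world.covariates, world.census,
                                      cfg, base_fit=fit, spec=spec)
            timings[method] = (t_fit + (time.perf_counter() - t0), 0.0)
        elif method == "direct":
            t0 = time.perf_counter()
            est = direct_estimate(world.survey)
            timings["direct"] = (0.0, time.perf_counter() - t0)
        else:
            raise ValueError(f"unknown method {method!r}; valid: bayes, mc, parboot, npboot, direct")
        out.append(est)
    return out, timings


def coverage_experiment(
    gen_config: GeneratorConfig,
    methods: tuple[str, ...] = ("mc",),
    n_worlds: int = 100,
    budgets: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical county-interval coverage over regenerated synthetic worlds.

    For each world the truth is known exactly, so coverage is the pooled
    fraction of (world, county) pairs whose true prevalence falls inside
    the method's 95% interval.  Worlds whose base fit fails are skipped
    and counted.  Fully reproducible from one seed.
    """
    hits: dict[str, list] = {m: [] for m in methods}
    n_failed = 0
    for w in range(n_worlds):
        ws = int(np.random.SeedSequence((seed, w)).generate_state(1)[0] % (2**31))
        world = generate_world(replace(gen_config, seed=ws))
        try:
            ests, _ = run_all_methods(world, budgets=budgets, seed=ws, methods=methods)
        except RuntimeError:
            n_failed += 1
            continue
        tr = pd.Series(world.truth.county_prevalence,
                       index=[str(c) for c in world.truth.county_ids])
        for m, est in zip(methods, ests):
            sub = est[est.area_id != STATE_ID].set_index("area_id")
            hits[m].append(((tr >= sub["lo95"]) & (tr <= sub["hi95"])).to_numpy())
    rows = []
    for m in methods:
        h = np.concatenate(hits[m]) if hits[m] else np.array([])
        rows.append({
            "method": m,
            "coverage": float(h.mean()) if h.size else np.nan,
            "n_intervals": int(h.size),
            "n_worlds_used": len(hits[m]),
            "n_worlds_failed": n_failed,
        })
    return pd.DataFrame(rows).set_index("method")
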