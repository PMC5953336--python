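"""The model-building framework for latent transition models.

Steps, run in order with full provenance:

* Step 0 — fit per-occasion latent class models over a range of class counts
  and build a candidate pool of counts supported by at least one information
  criterion at at least one occasion (entropy is reported, never used for
  pool membership).
* Step 1 — test longitudinal measurement invariance of the item-response
  probabilities for each candidate count via the likelihood-ratio difference
  test between the occasion-varying and occasion-invariant models.
* Step 2 — select among surviving candidates, emit the status profile table
  (highlighting probabilities above a threshold), and order statuses by
  descending first-occasion prevalence.
* Step 3 — test transition-probability invariance (needs T >= 3) and, for
  grouped data, prevalence/transition homogeneity across groups.
* Step 4 — add covariates on the prevalences (and optionally transitions)
  and test their effects; sparseness failures are findings, not crashes.
* Step 5 — distal outcomes: placeholder, not implemented here.

Reports are deterministic functions of (data, config, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .covariates import coefficients, covariate_effect_test, odds_ratios
from .errors import ConfigurationError, EstimationError, SparsenessError
from .evaluation import fit_statistics, lrdt
from .lca import LatentClassAnalysis
from .lta import LatentTransitionAnalysis, ModelSpec
from .panel import ResponsePanel, pattern_frequencies


@dataclass
class FrameworkConfig:
    """Resolved configuration for a framework run; embedded in the report."""

    class_range: tuple = (2, 5)
    alpha: float = 0.05
    criteria: tuple = ("AIC", "BIC", "CAIC", "ABIC")
    selection_criterion: str = "AIC"
    arbiter: str = "lrdt"              # decides when LRDT and criteria clash
    highlight_threshold: float = 0.5
    lca_starts: int = 40
    lta_starts: int = 20
    tol: float = 1e-8
    max_iter: int = 5000
    seed: int = 0
    covariates: tuple = ()
    covariates_on_transitions: bool = False
    include: tuple = ()
    exclude: tuple = ()
    status_labels: tuple = None

    @classmethod
    def from_dict(cls, d: dict) -> "FrameworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        return cfg


def derive_seed(base: int, *tokens) -> int:
    """Stable sub-seed from a base seed and string tokens (below 2**31)."""
    h = zlib.crc32("/".join(map(str, tokens)).encode())
    return int((int(base) * 1_000_003 + h) % (2 ** 31 - 1))


@dataclass
class CandidatePool:
    grid: pd.DataFrame
    pool: list
    support: dict
    notes: list = field(default_factory=list)


@dataclass
class FrameworkReport:
    config: dict
    step0: dict = None
    step1: dict = None
    step2: dict = None
    step3: dict = None
    step4: dict = None
    step5: dict = field(default_factory=lambda: {
        "status": "not implemented",
        "note": "distal outcomes are outside this package's scope"})
    selected: dict = None
    warnings: list = field(default_factory=list)

    def to_json(self, indent=2) -> str:
        return json.dumps(asdict(self), indent=indent, default=_jsonable,
                          sort_keys=True)

    def to_markdown(self) -> str:
        out = ["# Latent transition model-building report", ""]
        out += ["## Configuration", "```json",
                json.dumps(self.config, indent=2, default=_jsonable,
                           sort_keys=True), "```", ""]
        for name, step in [("Step 0 — candidate pool", self.step0),
                           ("Step 1 — measurement invariance", self.step1),
                           ("Step 2 — status definition", self.step2),
                           ("Step 3 — transition invariance", self.step3),
                           ("Step 4 — covariates", self.step4),
                           ("Step 5 — distal outcomes", self.step5)]:
            out.append(f"## {name}")
            if step is None:
                out += ["(not reached)", ""]
                continue
            for key, val in step.items():
                if isinstance(val, str) and "\n" in val:
                    out += [f"### {key}", "```csv", val.rstrip(), "```"]
                else:
                    out.append(f"- **{key}**: "
                               f"{json.dumps(val, default=_jsonable)}")
            out.append("")
        if self.warnings:
            out += ["## Warnings"] + [f"- {w}" for w in self.warnings] + [""]
        return "\n".join(out)

    def save(self, outdir):
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        (outdir / "report.md").write_text(self.to_markdown())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_csv()
    return str(obj)


def _stats_row(stats) -> dict:
    d = stats.as_dict()
    return {k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in d.items()}


# ---------------------------------------------------------------------------
# steps


def step0_candidate_pool(panel: ResponsePanel, class_range, config:
                         FrameworkConfig) -> CandidatePool:
    """Per-occasion latent class grid and the candidate pool of class counts.

    A count joins the pool when it minimizes at least one configured
    criterion at at least one occasion. Entropy is reported for every cell
    but never drives membership. ``include``/``exclude`` overrides are
    honored and logged.
    """
    lo, hi = int(class_range[0]), int(class_range[1])
    if lo < 1 or hi < lo:
        raise ConfigurationError("class_range must be (lo, hi) with 1<=lo<=hi")
    rows = []
    notes = []
    for t in range(panel.n_occasions):
        table = pattern_frequencies(panel, t)
        if hi > table.n_patterns:
            notes.append(f"occasion {t + 1}: range top {hi} exceeds "
                         f"{table.n_patterns} distinct patterns")
        for k in range(lo, hi + 1):
            est = LatentClassAnalysis(
                k, n_starts=config.lca_starts, tol=config.tol,
                max_iter=config.max_iter,
                random_state=derive_seed(config.seed, "step0", t, k))
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                est.fit(table)
            spec = ModelSpec(n_statuses=k, n_occasions=1,
                             n_categories=tuple(int(c) for c in
                                                table.n_categories))
            post = est.predict_proba(table)
            stats = fit_statistics(est.loglik_, table, spec, posteriors=post,
                                   weights=table.frequencies)
            rows.append({"occasion": t + 1, "classes": k,
                         **_stats_row(stats)})
    grid = pd.DataFrame(rows)

    support = {}
    for crit in config.criteria:
        for t, sub in grid.groupby("occasion"):
            k_best = int(sub.loc[sub[crit].idxmin(), "classes"])
            support.setdefault(k_best, []).append(f"{crit}@occasion{t}")
    pool = sorted(support)
    for k in config.include:
        if k not in pool and lo <= k <= hi:
            pool.append(int(k))
            notes.append(f"count {k} force-included by configuration")
    for k in config.exclude:
        if k in pool:
            pool.remove(k)
            notes.append(f"count {k} excluded by configuration override")
    pool = sorted(pool)
    if not pool:
        raise ConfigurationError(
            "candidate pool is empty; widen class_range or relax excludes")
    return CandidatePool(grid=grid, pool=pool, support=support, notes=notes)


def _fit_lta(panel_or_table, S, config, *, measurement_invariance,
             transition_invariance=False, seed_tokens=(), init_params=None,
             covariates=None, on_transitions=False):
    import warnings as _w
    kw = dict(
        measurement_invariance=measurement_invariance,
        transition_invariance=transition_invariance,
        n_starts=config.lta_starts, tol=config.tol, max_iter=config.max_iter,
        random_state=derive_seed(config.seed, *seed_tokens))
    if covariates is not None:
        kw["covariate_effects"] = ("prevalence+transitions" if on_transitions
                                   else "prevalence")
    est = LatentTransitionAnalysis(S, **kw)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        if covariates is not None:
            est.fit(panel_or_table, covariates=list(covariates),
                    init_params=init_params)
        else:
            est.fit(panel_or_table, init_params=init_params)
    return est


def _lta_stats(est, table):
    post = est.posteriors(table)
    return fit_statistics(est.loglik_, table, est.spec_,
                          posteriors=post["marginal"][:, 0, :],
                          weights=table.frequencies,
                          N_effective=est.n_effective_)


def step1_measurement_invariance(panel: ResponsePanel, pool, config:
                                 FrameworkConfig):
    """Invariant-rho vs free-rho LTA per candidate count; a candidate
    survives when the LRDT retains invariance at the configured alpha."""
    table = pattern_frequencies(panel)
    records = {}
    survivors = []
    fits = {}
    for S in pool:
        try:
            inv = _fit_lta(table, S, config, measurement_invariance=True,
                           seed_tokens=("step1", S, "inv"))
            free = _fit_lta(table, S, config, measurement_invariance=False,
                            seed_tokens=("step1", S, "free"),
                            init_params=[inv.params_])
        except EstimationError as exc:
            records[S] = {"error": str(exc)}
            continue
        st_inv = _lta_stats(inv, table)
        st_free = _lta_stats(free, table)
        cmp_ = lrdt(st_inv, st_free, alpha=config.alpha)
        records[S] = {
            "invariant": _stats_row(st_inv), "free": _stats_row(st_free),
            "G2_delta": cmp_.G2_delta, "df_delta": cmp_.df_delta,
            "p_value": cmp_.p_value, "decision": cmp_.decision,
            "conflict": cmp_.conflict,
        }
        if cmp_.decision == "restricted_retained":
            survivors.append(S)
            fits[S] = (inv, st_inv)
    fallback = None
    if not survivors:
        fallback = ("no candidate holds longitudinal measurement invariance; "
                    "fit repeated-measures latent class models with "
                    "occasion-specific classes instead")
    return records, survivors, fits, fallback


def step2_define_statuses(fits, survivors, config: FrameworkConfig):
    """Select among surviving candidates and emit the status profile table."""
    crit = config.selection_criterion
    ranked = sorted(survivors,
                    key=lambda S: getattr(fits[S][1], crit))
    S_sel = ranked[0]
    est, stats = fits[S_sel]
    warnings_ = []
    bic_ranked = sorted(survivors, key=lambda S: fits[S][1].BIC)
    if bic_ranked[0] != S_sel:
        warnings_.append(
            f"criterion conflict: {crit} selects {S_sel} statuses but BIC "
            f"selects {bic_ranked[0]}; decision follows {crit} "
            "(override via include/exclude)")

    rho = est.rho_ if est.rho_.ndim == 3 else est.rho_.mean(axis=0)
    s, j_items, _ = rho.shape
    top_cat = rho[..., -1]  # probability of the highest category per item
    items = getattr(est, "items_", None) or [f"item{j + 1}"
                                             for j in range(j_items)]
    profile = pd.DataFrame(top_cat.T, index=items,
                           columns=[f"status{k + 1}" for k in range(s)])
    highlighted = profile >= config.highlight_threshold
    elevated = [c for c in profile.columns if bool(highlighted[c].all())]
    labels = list(config.status_labels) if config.status_labels else None
    return {
        "selected_classes": S_sel,
        "profile_top_category": profile,
        "highlight_threshold": config.highlight_threshold,
        "highlighted": highlighted,
        "globally_elevated_statuses": elevated,
        "status_labels": labels,
        "delta": est.delta_,
        "warnings": warnings_,
    }, est, stats


def step3_invariance_tests(panel: ResponsePanel, est, stats, config:
                           FrameworkConfig):
    """Transition-probability invariance (T >= 3) and, when the panel is
    grouped, prevalence/transition homogeneity across groups."""
    table = pattern_frequencies(panel)
    S = est.spec_.n_statuses
    record = {}
    selected_est, selected_stats = est, stats
    if panel.n_occasions < 3:
        record["transition_invariance"] = {
            "skipped": "transition invariance needs more than two occasions"}
    else:
        try:
            ti = _fit_lta(table, S, config, measurement_invariance=True,
                          transition_invariance=True,
                          seed_tokens=("step3", S, "ti"))
        except EstimationError as exc:
            record["transition_invariance"] = {"error": str(exc)}
            ti = None
        if ti is not None:
            st_ti = _lta_stats(ti, table)
            cmp_ = lrdt(st_ti, stats, alpha=config.alpha,
                        rule=config.arbiter)
            use_restricted = (cmp_.decision == "restricted_retained"
                              if config.arbiter == "lrdt"
                              else cmp_.delta_AIC <= 0)
            record["transition_invariance"] = {
                "invariant": _stats_row(st_ti), "free": _stats_row(stats),
                "G2_delta": cmp_.G2_delta, "df_delta": cmp_.df_delta,
                "p_value": cmp_.p_value, "decision": cmp_.decision,
                "conflict": cmp_.conflict, "notes": cmp_.notes,
                "selected": "invariant" if use_restricted else "free",
            }
            if use_restricted:
                selected_est, selected_stats = ti, st_ti

    if panel.group is not None:
        grp = {}
        try:
            hom = _fit_lta(panel, S, config, measurement_invariance=True,
                           seed_tokens=("step3", S, "hom"))
            het = LatentTransitionAnalysis(
                S, measurement_invariance=True, group_delta=True,
                group_tau=True, n_starts=config.lta_starts, tol=config.tol,
                max_iter=config.max_iter,
                random_state=derive_seed(config.seed, "step3", S, "het"))
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                het.fit(panel, group=np.asarray(panel.group))
            st_hom = _lta_stats(hom, table)
            st_het = fit_statistics(het.loglik_, table, het.spec_,
                                    N_effective=het.n_effective_)
            cmp_ = lrdt(st_hom, st_het, alpha=config.alpha)
            grp = {"G2_delta": cmp_.G2_delta, "df_delta": cmp_.df_delta,
                   "p_value": cmp_.p_value, "decision": cmp_.decision}
        except EstimationError as exc:
            grp = {"error": str(exc)}
        record["group_homogeneity"] = grp
    return record, selected_est, selected_stats


def step4_covariates(panel: ResponsePanel, est, stats, config:
                     FrameworkConfig):
    """Covariate effects on prevalences (and transitions when enabled)."""
    if not config.covariates:
        return {"skipped": "no covariates configured"}
    table = pattern_frequencies(panel)
    S = est.spec_.n_statuses
    record = {}
    for cov in config.covariates:
        entry = {}
        try:
            with_cov = _fit_lta(
                panel, S, config,
                measurement_invariance=est.spec_.measurement_invariance,
                transition_invariance=est.spec_.transition_invariance,
                seed_tokens=("step4", S, cov), covariates=[cov])
            st_with = fit_statistics(with_cov.loglik_, table, with_cov.spec_,
                                     N_effective=with_cov.n_effective_)
            cmp_ = covariate_effect_test(st_with, stats, alpha=config.alpha)
            coef = coefficients(with_cov, [cov])
            entry = {
                "G2_delta": cmp_.G2_delta, "df_delta": cmp_.df_delta,
                "p_value": cmp_.p_value,
                "significant": cmp_.p_value < config.alpha,
                "beta": coef.beta, "odds_ratios": odds_ratios(coef),
            }
        except SparsenessError as exc:
            entry = {"sparseness_failure": str(exc), "cells": exc.cells}
        except EstimationError as exc:
            entry = {"error": str(exc)}
        if config.covariates_on_transitions and "error" not in entry:
            try:
                with_tr = _fit_lta(
                    panel, S, config,
                    measurement_invariance=est.spec_.measurement_invariance,
                    transition_invariance=est.spec_.transition_invariance,
                    seed_tokens=("step4", S, cov, "tr"), covariates=[cov],
                    on_transitions=True)
                st_tr = fit_statistics(with_tr.loglik_, table, with_tr.spec_,
                                       N_effective=with_tr.n_effective_)
                entry["transitions"] = {"loglik": with_tr.loglik_,
                                        "P": st_tr.P}
            except SparsenessError as exc:
                entry["transitions"] = {"sparseness_failure": str(exc),
                                        "cells": exc.cells}
        record[cov] = entry
    return record


def run_framework(panel: ResponsePanel, config) -> FrameworkReport:
    """Execute Steps 0-4 in order; identical (data, config, seed) give an
    identical report. A hard failure in a step terminates with the partial
    report attached to the raised error."""
    if isinstance(config, dict):
        config = FrameworkConfig.from_dict(config)
    report = FrameworkReport(config=asdict(config))
    try:
        pool = step0_candidate_pool(panel, config.class_range, config)
        report.step0 = {
            "grid": pool.grid.to_csv(index=False),
            "pool": pool.pool,
            "support": {str(k): v for k, v in pool.support.items()},
            "notes": pool.notes,
        }

        records, survivors, fits, fallback = step1_measurement_invariance(
            panel, pool.pool, config)
        report.step1 = {"candidates": {str(k): v for k, v in records.items()},
                        "survivors": survivors}
        if fallback:
            report.step1["fallback"] = fallback
            report.warnings.append(fallback)
            return report

        step2, est, stats = step2_define_statuses(fits, survivors, config)
        report.step2 = {
            "selected_classes": step2["selected_classes"],
            "profile_top_category": step2["profile_top_category"].to_csv(),
            "globally_elevated_statuses": step2["globally_elevated_statuses"],
            "delta": step2["delta"],
            "status_labels": step2["status_labels"],
        }
        report.warnings.extend(step2["warnings"])

        step3, est, stats = step3_invariance_tests(panel, est, stats, config)
        report.step3 = step3

        report.step4 = step4_covariates(panel, est, stats, config)
        for cov, entry in (report.step4 or {}).items():
            if isinstance(entry, dict) and "sparseness_failure" in entry:
                report.warnings.append(
                    f"covariate {cov}: transition/prevalence cells too sparse")

        report.selected = {
            "n_statuses": est.spec_.n_statuses,
            "measurement_invariance": est.spec_.measurement_invariance,
            "transition_invariance": est.spec_.transition_invariance,
            "loglik": est.loglik_,
            "G2": stats.G2, "AIC": stats.AIC, "df": stats.df,
            "delta": est.delta_,
            "tau": est.tau_,
        }
    except (ConfigurationError, EstimationError) as exc:
        report.warnings.append(f"terminated: {exc}")
        exc.partial_report = report
        raise
    return report
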