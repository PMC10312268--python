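"""Greedy modification-index network search at four aggregation levels.

All searches share one move: fit the current model, score every admissible
fixed path with a 1-df modification index (MI), free the best significant
candidate, and repeat until either the excellent-fit stopping rule is met
or no candidate is significant. The levels differ in what counts as "best":

* aggregate — one search on the cohort concatenated into a single series;
* idiographic — an independent search per subject, no group information;
* group — a candidate is added when its MI is significant for at least a
  supermajority (default 75%) of subjects;
* subgroup — the group step repeated within detected communities with a
  majority (>50%) threshold;
* individual finalization — each subject's search seeded with the group
  (and subgroup) paths as the null model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries_io import ROITimeSeries, standardize
from .usem_core import (MI_CRITICAL_95, LaggedData, NetworkModel, PathSpec,
                        ar_paths, evaluate_fit, excellent_fit, fit_usem,
                        lag_augment, modification_indices, prune)

__all__ = [
    "SearchOptions",
    "CohortSearchResult",
    "search_aggregate",
    "search_individual",
    "group_search",
    "subgroup_search",
    "finalize_individuals",
    "detect_outlier_models",
    "concatenate_cohort",
]


class SearchError(RuntimeError):
    pass


@dataclass
class SearchOptions:
    """Tunables shared by the search procedures."""

    mi_critical: float = MI_CRITICAL_95    # chi2(1) .05 critical value
    alpha: float = 0.05                    # pruning z-test level
    gamma: float = 0.75                    # group supermajority
    subgroup_gamma: float = 0.5            # subgroup majority (strict >)
    free_ar: bool = True                   # AR paths freed in the null model
    exogenous_lag0: bool = True
    exogenous_lag1: bool = False
    excellent_min: int = 2                 # stopping rule: 2 of 4 excellent
    # once fit is excellent, keep adding only candidates whose MI survives
    # a Bonferroni-level threshold (alpha / n_candidates on chi2(1)): the
    # global indices are nearly blind to one missing strong path, while
    # the max of ~2p^2 null MIs routinely exceeds the nominal critical
    # value, so neither plain rule alone controls both error types
    strict_after_excellent: bool = True
    max_additions: int = 60
    standardize: bool = True
    fit_options: dict = field(default_factory=dict)


@dataclass
class CohortSearchResult:
    """Multi-level search output with the nesting guarantees asserted."""

    group_paths: set[PathSpec]
    individual_models: dict[str, NetworkModel]
    subgroup_membership: pd.Series | None = None
    subgroup_paths: dict[int, set[PathSpec]] = field(default_factory=dict)
    search_log: pd.DataFrame | None = None
    flagged: list[str] = field(default_factory=list)

    def assert_nesting(self):
        for sid, model in self.individual_models.items():
            if not self.group_paths <= model.free_paths:
                raise AssertionError(f"group paths missing from {sid}")
            label = (int(self.subgroup_membership[sid])
                     if self.subgroup_membership is not None else 0)
            sub = self.subgroup_paths.get(label, set())
            if not sub <= model.free_paths:
                raise AssertionError(f"subgroup paths missing from {sid}")
            if self.group_paths & sub:
                raise AssertionError("group and subgroup sets overlap")

    def levels_of(self, sid: str) -> dict[PathSpec, str]:
        return {pth: pth.level
                for pth in self.individual_models[sid].free_paths}


def _null_free_set(data: LaggedData, opts: SearchOptions) -> set[PathSpec]:
    return ar_paths(data) if opts.free_ar else set()


def _greedy_search(data: LaggedData, base: set[PathSpec], level: str,
                   opts: SearchOptions, log: list | None = None,
                   scope: str = "") -> NetworkModel:
    """Shared greedy MI loop starting from ``base`` (which stays free).

    Before the excellent-fit stopping rule triggers, any candidate MI
    significant at the nominal level may be added; afterwards only
    candidates surviving the Bonferroni-level threshold are (see
    ``SearchOptions.strict_after_excellent``).
    """
    from scipy.stats import chi2 as chi2_dist

    free = set(base)
    model = fit_usem(data, free, options=opts.fit_options)
    prev_chi2 = model.fit.chi2
    for step in range(opts.max_additions):
        is_excellent = excellent_fit(model.fit, opts.excellent_min)
        if is_excellent and not opts.strict_after_excellent:
            break
        mi = modification_indices(model, data,
                                  exogenous_lag0=opts.exogenous_lag0,
                                  exogenous_lag1=opts.exogenous_lag1)
        if mi.empty:
            break
        mi = mi.sort_values(["mi", "from_node", "to_node", "lag"],
                            ascending=[False, True, True, True])
        best = mi.iloc[0]
        threshold = opts.mi_critical
        if is_excellent:
            threshold = float(chi2_dist.ppf(1.0 - opts.alpha / len(mi), 1))
        if not (best.mi >= threshold):
            break
        new = PathSpec(best.from_node, best.to_node, int(best.lag), level)
        free.add(new)
        model = fit_usem(data, free, options=opts.fit_options)
        if model.fit.chi2 > prev_chi2 + 1e-6 * max(1.0, prev_chi2):
            warnings.warn(f"chi-square increased when freeing {new!r}; "
                          "possible convergence failure")
        prev_chi2 = model.fit.chi2
        if log is not None:
            log.append(dict(scope=scope, action="add", from_node=new.from_node,
                            to_node=new.to_node, lag=new.lag, level=level,
                            mi=float(best.mi), chi2=model.fit.chi2))
    return model


def concatenate_cohort(cohort: list[ROITimeSeries], opts: SearchOptions
                       ) -> tuple[ROITimeSeries, list[int]]:
    """Standardize each subject and stack into one series with segment
    boundaries so lag embedding never pairs across subjects."""
    if not cohort:
        raise SearchError("empty cohort")
    names = cohort[0].node_names
    for ts in cohort:
        if ts.node_names != names:
            raise SearchError("inconsistent node names across subjects")
    std = [standardize(ts) if opts.standardize else ts for ts in cohort]
    values = np.vstack([ts.values for ts in std])
    exo = np.vstack([ts.exogenous for ts in std])
    bounds, off = [], 0
    for ts in std:
        bounds.append(off)
        off += ts.n_timepoints
    combined = ROITimeSeries(
        subject_id="aggregate", values=values, node_names=list(names),
        exogenous=exo, exogenous_names=list(cohort[0].exogenous_names),
        tr_seconds=cohort[0].tr_seconds)
    return combined, bounds


def search_aggregate(cohort: list[ROITimeSeries],
                     opts: SearchOptions | None = None) -> NetworkModel:
    """Aggregate search on the concatenated cohort (aggSEM-style)."""
    opts = opts or SearchOptions()
    combined, bounds = concatenate_cohort(cohort, opts)
    data = lag_augment(combined, bounds,
                       lagged_exogenous=opts.exogenous_lag1)
    model = _greedy_search(data, _null_free_set(data, opts), "aggregate", opts)
    model = prune(model, data, alpha=opts.alpha, options=opts.fit_options)
    return model


def search_individual(series: ROITimeSeries,
                      opts: SearchOptions | None = None) -> NetworkModel:
    """Idiographic search on one subject, using no group information."""
    opts = opts or SearchOptions()
    ts = standardize(series) if opts.standardize else series
    data = lag_augment(ts, lagged_exogenous=opts.exogenous_lag1)
    model = _greedy_search(data, _null_free_set(data, opts), "individual",
                           opts)
    model = prune(model, data, alpha=opts.alpha, options=opts.fit_options)
    return model


def _fit_all(datas: dict[str, LaggedData], free: set[PathSpec],
             opts: SearchOptions,
             warm: dict[str, NetworkModel] | None = None
             ) -> dict[str, NetworkModel]:
    out = {}
    for sid, data in datas.items():
        init = None
        if warm and sid in warm and warm[sid].free_paths == free:
            init = warm[sid].theta
        out[sid] = fit_usem(data, free, options=opts.fit_options, init=init)
    return out


def _count_significant_mis(models, datas, opts) -> pd.DataFrame:
    """Per-candidate count of subjects whose MI is significant, with the
    summed MI over those subjects as the tie-breaker."""
    counts: dict[tuple, int] = {}
    sums: dict[tuple, float] = {}
    for sid, model in models.items():
        if not model.fit.converged:
            continue  # non-converged subjects count as non-significant
        mi = modification_indices(model, datas[sid],
                                  exogenous_lag0=opts.exogenous_lag0,
                                  exogenous_lag1=opts.exogenous_lag1)
        sig = mi[mi.mi >= opts.mi_critical]
        for r in sig.itertuples():
            key = (r.from_node, r.to_node, r.lag)
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + float(r.mi)
    rows = [dict(from_node=k[0], to_node=k[1], lag=k[2], count=v,
                 mi_sum=sums[k])
            for k, v in counts.items()]
    df = pd.DataFrame(rows, columns=["from_node", "to_node", "lag", "count",
                                     "mi_sum"])
    return df.sort_values(["count", "mi_sum", "from_node", "to_node", "lag"],
                          ascending=[False, False, True, True, True])


def group_search(cohort: list[ROITimeSeries],
                 opts: SearchOptions | None = None,
                 base_paths: set[PathSpec] | None = None,
                 level: str = "group",
                 gamma: float | None = None, strict: bool = False):
    """Majority-driven group search.

    Iteratively adds the candidate whose MI is significant for the largest
    number of subjects, provided that count reaches the supermajority
    ``gamma`` (>= by default, strict > for the subgroup stage); afterwards
    prunes group paths whose estimates are significant for fewer than
    ``gamma`` of subjects, least supported first.

    Returns (group path set, per-subject fitted models, per-subject lagged
    data, search log DataFrame).
    """
    opts = opts or SearchOptions()
    if len(cohort) < 2:
        raise SearchError("group search needs at least 2 subjects")
    gamma = opts.gamma if gamma is None else gamma
    datas: dict[str, LaggedData] = {}
    for ts in cohort:
        std = standardize(ts) if opts.standardize else ts
        datas[ts.subject_id] = lag_augment(
            std, lagged_exogenous=opts.exogenous_lag1)
    n = len(datas)
    any_data = next(iter(datas.values()))
    free = set(_null_free_set(any_data, opts)) | set(base_paths or ())
    group: set[PathSpec] = set()
    log: list[dict] = []
    models = _fit_all(datas, free, opts)

    def _reaches(count: int) -> bool:
        frac = count / n
        return frac > gamma if strict else frac >= gamma

    for _ in range(opts.max_additions):
        counts = _count_significant_mis(models, datas, opts)
        if counts.empty:
            break
        best = counts.iloc[0]
        if not _reaches(int(best["count"])):
            break
        new = PathSpec(best.from_node, best.to_node, int(best.lag), level)
        group.add(new)
        free = free | {new}
        models = _fit_all(datas, free, opts, warm=None)
        log.append(dict(scope=level, action="add", from_node=new.from_node,
                        to_node=new.to_node, lag=new.lag, level=level,
                        count=int(best["count"]), n=n))

    # prune group paths with sub-majority significant estimates
    while group:
        props = {}
        for pth in group:
            sig = 0
            for model in models.values():
                z = model.z.get(pth, np.nan)
                if np.isfinite(z) and abs(z) >= 1.959963984540054:
                    sig += 1
            props[pth] = sig / n
        worst = min(sorted(props, key=PathSpec.sort_key), key=props.get)
        keep = props[worst] > gamma if strict else props[worst] >= gamma
        if keep:
            break
        group.discard(worst)
        free = free - {worst}
        models = _fit_all(datas, free, opts)
        log.append(dict(scope=level, action="drop", from_node=worst.from_node,
                        to_node=worst.to_node, lag=worst.lag, level=level,
                        count=int(round(props[worst] * n)), n=n))

    log_df = pd.DataFrame(
        log, columns=["scope", "action", "from_node", "to_node", "lag",
                      "level", "count", "n"])
    return group, models, datas, log_df


def subgroup_search(cohort, membership: pd.Series, group: set[PathSpec],
                    opts: SearchOptions | None = None):
    """Run the majority search within each detected community, on top of
    the group paths; returns {label: subgroup path set} and a log."""
    opts = opts or SearchOptions()
    sub_paths: dict[int, set[PathSpec]] = {}
    logs = []
    by_id = {ts.subject_id: ts for ts in cohort}
    for label in sorted(membership.unique()):
        members = [by_id[s] for s in membership[membership == label].index]
        if len(members) < 2:
            sub_paths[int(label)] = set()
            continue
        paths, _, _, log = group_search(
            members, opts, base_paths=group, level="subgroup",
            gamma=opts.subgroup_gamma, strict=True)
        sub_paths[int(label)] = {p.relevel("subgroup") for p in paths}
        log["scope"] = f"subgroup{label}"
        logs.append(log)
    log_df = (pd.concat(logs, ignore_index=True) if logs
              else pd.DataFrame())
    return sub_paths, log_df


def finalize_individuals(cohort: list[ROITimeSeries],
                         group: set[PathSpec],
                         subgroup_paths: dict[int, set[PathSpec]] | None = None,
                         membership: pd.Series | None = None,
                         opts: SearchOptions | None = None,
                         datas: dict[str, LaggedData] | None = None
                         ) -> CohortSearchResult:
    """Per-subject search seeded with the group (and subgroup) null model.

    Individual-level paths are added greedily and pruned; group and
    subgroup paths are kept free regardless of per-subject significance,
    preserving the nesting invariant.
    """
    opts = opts or SearchOptions()
    group = {p.relevel("group") for p in group}
    if datas is None:
        datas = {}
        for ts in cohort:
            std = standardize(ts) if opts.standardize else ts
            datas[ts.subject_id] = lag_augment(
                std, lagged_exogenous=opts.exogenous_lag1)
    models: dict[str, NetworkModel] = {}
    log: list[dict] = []
    for ts in cohort:
        sid = ts.subject_id
        data = datas[sid]
        label = int(membership[sid]) if membership is not None else 0
        sub = {p.relevel("subgroup")
               for p in (subgroup_paths or {}).get(label, set())}
        base = _null_free_set(data, opts) | group | sub
        model = _greedy_search(data, base, "individual", opts, log, scope=sid)
        model = prune(model, data, alpha=opts.alpha,
                      prunable_levels={"individual"},
                      options=opts.fit_options)
        evaluate_fit(model.fit)
        models[sid] = model
    result = CohortSearchResult(
        group_paths=group, individual_models=models,
        subgroup_membership=membership,
        subgroup_paths={k: {p.relevel("subgroup") for p in v}
                        for k, v in (subgroup_paths or {}).items()},
        search_log=pd.DataFrame(log))
    result.assert_nesting()
    return result


def detect_outlier_models(result: CohortSearchResult,
                          z_abs_max: float = 20.0,
                          beta_abs_max: float = 10.0) -> list[str]:
    """Flag subjects whose fitted models look numerically pathological:
    any |estimate| or |z| beyond the thresholds, or non-convergence."""
    flagged = []
    for sid, model in result.individual_models.items():
        zs = model.z
        bad = (not model.fit.converged
               or any(abs(b) > beta_abs_max for b in model.estimates.values())
               or any(np.isfinite(z) and abs(z) > z_abs_max
                      for z in zs.values()))
        if bad:
            flagged.append(sid)
    result.flagged = flagged
    return flagged
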