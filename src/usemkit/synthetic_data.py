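"""Synthetic cohort generation from known multi-level uSEM structures.

A :class:`SimScenario` plants a ground-truth directed network at three
levels of aggregation — paths shared by the whole cohort, paths specific to
latent subgroups, and paths sprinkled per subject — and generates each
subject's multivariate series from the structural model

    x_t = (I - A_s)^{-1} (Phi_s x_{t-1} + Lambda_s u_t + zeta_t)

where the subscript s marks the subject's realized matrices (group union
subgroup union individual draws), u_t are task regressors built by
convolving simulated event boxcars with the canonical hemodynamic response,
and zeta_t is independent Gaussian innovation noise. Behavioral outcomes
can be linked linearly (or through a logit) to known network features, so
the full search -> feature -> association pipeline can be validated against
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries_io import ROITimeSeries, TaskEvents, build_task_regressors
from .usem_core import PathSpec

__all__ = [
    "SimScenario",
    "BehaviorSpec",
    "CohortLedger",
    "make_scenario",
    "simulate_task_events",
    "simulate_subject",
    "simulate_cohort",
    "simulate_behavior",
    "simulate_qc",
    "write_cohort",
]


class ScenarioError(ValueError):
    """Unsatisfiable scenario configuration."""


class GenerationError(RuntimeError):
    """Stationary structure could not be realized within the retry budget."""


# study-scale defaults: cohort size, node count, scan length
DEFAULTS = dict(
    n_subjects=103,
    n_endogenous=15,
    n_exogenous=2,
    n_timepoints=239,
    tr_seconds=2.0,
    n_group_paths=6,
    subgroup_defs=None,          # list of (fraction, n_paths)
    n_individual_pool=8,
    individual_prob=0.25,
    beta_range=(0.3, 0.7),
    positive_fraction=0.8,
    ar_range=(0.4, 0.7),
    noise_sd=1.0,
    exogenous_beta=0.5,
    burn_in=50,
    contemporaneous_fraction=0.5,  # share of planted paths at lag 0
    lagged_exogenous=False,
    seed=0,
    max_retries=200,
)


@dataclass
class SimScenario:
    """Planted multi-level ground truth for a synthetic cohort."""

    n_subjects: int
    n_endogenous: int
    n_exogenous: int
    n_timepoints: int
    tr_seconds: float
    group_paths: dict[PathSpec, float]
    subgroup_defs: list[tuple[float, dict[PathSpec, float]]]
    individual_path_pool: dict[PathSpec, float]
    individual_prob: float
    ar_coefficients: np.ndarray
    noise_sd: np.ndarray
    exogenous_paths: dict[PathSpec, float]
    seed: int
    burn_in: int = 50
    node_names: list[str] = field(default_factory=list)
    exog_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_names:
            self.node_names = [f"roi{i + 1:02d}" for i in range(self.n_endogenous)]
        if not self.exog_names:
            self.exog_names = [f"task{i + 1}" for i in range(self.n_exogenous)]
        if self.subgroup_defs:
            total = sum(f for f, _ in self.subgroup_defs)
            if abs(total - 1.0) > 1e-9:
                raise ScenarioError(
                    f"subgroup fractions sum to {total}, expected 1")
        for path in self.all_paths():
            if path.to_node not in self.node_names:
                raise ScenarioError(
                    f"path targets non-endogenous node '{path.to_node}'")

    def all_paths(self):
        yield from self.group_paths
        for _, paths in self.subgroup_defs or []:
            yield from paths
        yield from self.individual_path_pool
        yield from self.exogenous_paths

    # ------------------------------------------------------------------
    def subgroup_assignment(self) -> np.ndarray:
        """Deterministic membership: contiguous fraction blocks, shuffled
        under the scenario seed. Label 0 means 'no subgroup stage'."""
        n = self.n_subjects
        if not self.subgroup_defs:
            return np.zeros(n, dtype=int)
        sizes = [int(round(f * n)) for f, _ in self.subgroup_defs]
        sizes[-1] = n - sum(sizes[:-1])
        labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
        rng = np.random.default_rng(self.seed)
        rng.shuffle(labels)
        return labels

    def subject_structure(self, subject_index: int
                          ) -> tuple[pd.DataFrame, int]:
        """Ground-truth path table (level, from, to, lag, beta) and
        subgroup label for one subject."""
        if not (0 <= subject_index < self.n_subjects):
            raise ScenarioError(f"subject index {subject_index} out of range")
        labels = self.subgroup_assignment()
        label = int(labels[subject_index])
        rows = []
        for pth, b in sorted(self.group_paths.items(),
                             key=lambda kv: kv[0].sort_key()):
            rows.append(("group", pth, b))
        if label > 0:
            for pth, b in sorted(self.subgroup_defs[label - 1][1].items(),
                                 key=lambda kv: kv[0].sort_key()):
                rows.append(("subgroup", pth, b))
        rng = np.random.default_rng((self.seed, 7919, subject_index))
        for pth, b in sorted(self.individual_path_pool.items(),
                             key=lambda kv: kv[0].sort_key()):
            if rng.random() < self.individual_prob:
                rows.append(("individual", pth, b))
        for pth, b in sorted(self.exogenous_paths.items(),
                             key=lambda kv: kv[0].sort_key()):
            rows.append(("exogenous", pth, b))
        df = pd.DataFrame(
            [dict(level=lv, from_node=p.from_node, to_node=p.to_node,
                  lag=p.lag, beta=b) for lv, p, b in rows])
        return df, label

    def realized_matrices(self, subject_index: int):
        """(A, Phi, Lambda) for one subject, AR diagonal included in Phi."""
        p, q = self.n_endogenous, self.n_exogenous
        idx = {nm: i for i, nm in enumerate(self.node_names)}
        exidx = {nm: i for i, nm in enumerate(self.exog_names)}
        A = np.zeros((p, p))
        Phi = np.zeros((p, p))
        Lam = np.zeros((p, q))
        Phi[np.diag_indices(p)] = self.ar_coefficients
        struct, label = self.subject_structure(subject_index)
        for _, r in struct.iterrows():
            i = idx[r.to_node]
            if r.from_node in exidx:
                Lam[i, exidx[r.from_node]] = r.beta
            elif r.lag == 0:
                A[i, idx[r.from_node]] = r.beta
            else:
                Phi[i, idx[r.from_node]] = r.beta
        return A, Phi, Lam, label


@dataclass
class BehaviorSpec:
    """Linear (or logistic) link between network features and an outcome.

    ``feature_effects`` maps (PathSpec, encoding) to a coefficient, where
    encoding 'presence' uses the 0/1 indicator of the path being in the
    subject's true (or estimated) set and 'beta' uses its coefficient.
    """

    outcome_name: str
    feature_effects: dict[tuple[PathSpec, str], float]
    noise_sd: float = 1.0
    link: str = "identity"

    def __post_init__(self):
        if self.link not in ("identity", "logistic"):
            raise ScenarioError(f"unknown link '{self.link}'")


def _spectral_radius(A: np.ndarray, Phi: np.ndarray) -> float:
    Ci = np.linalg.inv(np.eye(A.shape[0]) - A)
    return float(np.max(np.abs(np.linalg.eigvals(Ci @ Phi))))


def _draw_paths(rng, node_names, n_paths, contemporaneous_fraction,
                beta_range, positive_fraction, taken: set) -> dict:
    """Draw distinct directed paths avoiding already-taken (from,to,lag)."""
    p = len(node_names)
    slots = []
    for i, to in enumerate(node_names):
        for j, frm in enumerate(node_names):
            if i != j:
                slots.append(PathSpec(frm, to, 0))
                slots.append(PathSpec(frm, to, 1))
    slots = [s for s in slots if s not in taken]
    lag0 = [s for s in slots if s.lag == 0]
    lag1 = [s for s in slots if s.lag == 1]
    n0 = int(round(n_paths * contemporaneous_fraction))
    n1 = n_paths - n0
    if n0 > len(lag0) // 2 + 1 or n1 > len(lag1):
        raise ScenarioError(
            f"requested {n_paths} paths but only {len(slots)} free slots "
            f"remain (lag0: {len(lag0)}, lag1: {len(lag1)})")
    # contemporaneous paths avoid reciprocal (2-cycle) pairs, which are not
    # identifiable with diagonal residual covariance; and no ordered pair
    # carries both its lag-0 and lag-1 path, which are near-confusable at
    # typical scan lengths
    picked = []
    order = rng.permutation(len(lag0))
    blocked: set = {(t.to_node, t.from_node) for t in taken if t.lag == 0}
    pair_taken: set = {(t.from_node, t.to_node) for t in taken}
    for i in order:
        if len(picked) == n0:
            break
        s = lag0[i]
        if (s.from_node, s.to_node) in blocked or \
                (s.from_node, s.to_node) in pair_taken:
            continue
        picked.append(s)
        blocked.add((s.to_node, s.from_node))
        pair_taken.add((s.from_node, s.to_node))
    if len(picked) < n0:
        raise ScenarioError("not enough acyclic contemporaneous slots")
    order = rng.permutation(len(lag1))
    for i in order:
        if len(picked) == n_paths:
            break
        s = lag1[i]
        if (s.from_node, s.to_node) in pair_taken:
            continue
        picked.append(s)
        pair_taken.add((s.from_node, s.to_node))
    if len(picked) < n_paths:
        raise ScenarioError("not enough distinct lag-1 slots")
    out = {}
    for s in picked:
        mag = rng.uniform(*beta_range)
        sign = 1.0 if rng.random() < positive_fraction else -1.0
        out[s] = sign * mag
    return out


def make_scenario(config: dict | None = None) -> SimScenario:
    """Build a scenario from a flat config map (missing keys defaulted).

    Path coefficients are drawn with |beta| in ``beta_range`` and a random
    sign (``positive_fraction`` controls the positive share); AR
    coefficients are uniform in ``ar_range``. Draws are rejected and
    retried (up to ``max_retries``) until every subject's realized system
    is stationary (companion spectral radius < 1 with margin).
    """
    cfg = dict(DEFAULTS)
    unknown = set(config or {}) - set(cfg)
    if unknown:
        raise ScenarioError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config or {})
    p = cfg["n_endogenous"]
    if p < 2:
        raise ScenarioError("n_endogenous must be >= 2")
    if cfg["n_timepoints"] < 50:
        raise ScenarioError("n_timepoints must be >= 50")
    if not (0.0 <= cfg["individual_prob"] <= 1.0):
        raise ScenarioError("individual_prob must lie in [0, 1]")

    node_names = [f"roi{i + 1:02d}" for i in range(p)]
    exog_names = [f"task{i + 1}" for i in range(cfg["n_exogenous"])]
    sub_defs_cfg = cfg["subgroup_defs"]
    rng = np.random.default_rng(cfg["seed"])

    for attempt in range(cfg["max_retries"]):
        taken: set = set()
        group = _draw_paths(rng, node_names, cfg["n_group_paths"],
                            cfg["contemporaneous_fraction"],
                            cfg["beta_range"], cfg["positive_fraction"], taken)
        taken |= set(group)
        sub_defs = []
        for frac, n_paths in (sub_defs_cfg or []):
            paths = _draw_paths(rng, node_names, n_paths,
                                cfg["contemporaneous_fraction"],
                                cfg["beta_range"], cfg["positive_fraction"],
                                taken)
            taken |= set(paths)
            sub_defs.append((frac, paths))
        pool = _draw_paths(rng, node_names, cfg["n_individual_pool"],
                           cfg["contemporaneous_fraction"],
                           cfg["beta_range"], cfg["positive_fraction"], taken)
        ar = rng.uniform(*cfg["ar_range"], size=p)
        exo = {PathSpec(ex, node_names[i % p], 0): cfg["exogenous_beta"]
               for i, ex in enumerate(exog_names)}
        noise = np.full(p, float(cfg["noise_sd"]))
        scen = SimScenario(
            n_subjects=cfg["n_subjects"], n_endogenous=p,
            n_exogenous=cfg["n_exogenous"],
            n_timepoints=cfg["n_timepoints"], tr_seconds=cfg["tr_seconds"],
            group_paths=group, subgroup_defs=sub_defs,
            individual_path_pool=pool, individual_prob=cfg["individual_prob"],
            ar_coefficients=ar, noise_sd=noise, exogenous_paths=exo,
            seed=cfg["seed"], burn_in=cfg["burn_in"],
            node_names=node_names, exog_names=exog_names)
        # every subject's realized system must be stationary with margin
        ok = True
        for s in range(scen.n_subjects):
            A, Phi, _, _ = scen.realized_matrices(s)
            if (abs(np.linalg.det(np.eye(p) - A)) < 1e-8
                    or _spectral_radius(A, Phi) >= 0.97):
                ok = False
                break
        if ok:
            return scen
    raise GenerationError(
        f"no stationary structure found in {cfg['max_retries']} retries")


def simulate_task_events(n_trials: int = 24, trial_seconds: float = 17.0,
                         tr_seconds: float = 2.0,
                         iti_mean: float = 3.0, iti_jitter: float = 2.0,
                         seed: int = 0) -> TaskEvents:
    """Simulate an event-related reward task's anticipation/outcome events.

    Each trial: 4 s choice window, 6 s anticipation period, 1 s outcome
    display, fixation for the remainder of ``trial_seconds``; trials are
    separated by a jittered intertrial interval uniform on
    ``iti_mean +/- iti_jitter``. The default ITI mean of 3 s lets the
    default 24-trial task fit within a 478 s scan.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for _ in range(n_trials):
        rows.append(dict(onset=t + 4.0, duration=6.0,
                         trial_type="anticipation"))
        rows.append(dict(onset=t + 10.0, duration=1.0, trial_type="outcome"))
        iti = rng.uniform(iti_mean - iti_jitter, iti_mean + iti_jitter)
        t += trial_seconds + iti
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    return TaskEvents(df)


def _exogenous_matrix(scenario: SimScenario, seed: int) -> np.ndarray:
    """Task regressors shared by the cohort (one convolved column per
    trial type, mapped onto the scenario's exogenous names)."""
    T, q = scenario.n_timepoints, scenario.n_exogenous
    if q == 0:
        return np.zeros((T, 0))
    events = simulate_task_events(tr_seconds=scenario.tr_seconds, seed=seed)
    # the scan simply ends: drop events past the end, clip partial ones
    scan_end = T * scenario.tr_seconds
    tab = events.table[events.table.onset < scan_end].copy()
    tab["duration"] = np.minimum(tab["duration"],
                                 scan_end - tab["onset"])
    from .timeseries_io import TaskEvents
    events = TaskEvents(tab)
    cols, types = build_task_regressors(events, T, scenario.tr_seconds)
    U = np.zeros((T, q))
    for j in range(q):
        U[:, j] = cols[:, j % len(types)]
    return U


def simulate_subject(scenario: SimScenario, subject_index: int,
                     seed: int | None = None,
                     exogenous: np.ndarray | None = None) -> ROITimeSeries:
    """Generate one subject's series from its realized structure.

    A burn-in of ``scenario.burn_in`` initial steps (with the task inputs
    silent) is discarded to remove initial-condition transients.
    """
    A, Phi, Lam, _ = scenario.realized_matrices(subject_index)
    p = scenario.n_endogenous
    C = np.eye(p) - A
    if abs(np.linalg.det(C)) < 1e-10:
        raise GenerationError("(I - A) is singular for subject "
                              f"{subject_index}")
    Ci = np.linalg.inv(C)
    T, burn = scenario.n_timepoints, scenario.burn_in
    if exogenous is None:
        exogenous = _exogenous_matrix(scenario, scenario.seed)
    U = np.vstack([np.zeros((burn, scenario.n_exogenous)), exogenous])
    rng = np.random.default_rng(
        (scenario.seed, 104729, subject_index) if seed is None
        else (seed, 104729, subject_index))
    Z = rng.standard_normal((T + burn, p)) * scenario.noise_sd
    X = np.zeros((T + burn, p))
    M1 = Ci @ Phi
    M2 = Ci @ Lam
    for t in range(1, T + burn):
        X[t] = M1 @ X[t - 1] + M2 @ U[t] + Ci @ Z[t]
    return ROITimeSeries(
        subject_id=f"sub{subject_index + 1:03d}",
        values=X[burn:], node_names=list(scenario.node_names),
        exogenous=exogenous.copy(), exogenous_names=list(scenario.exog_names),
        tr_seconds=scenario.tr_seconds)


@dataclass
class CohortLedger:
    """Ground truth of a simulated cohort: per-subject true paths with
    their level, coefficient, and subgroup label."""

    table: pd.DataFrame      # subject_id, level, from, to, lag, beta, subgroup
    membership: pd.Series    # subject_id -> subgroup label (0 = none)

    def true_paths(self, subject_id: str,
                   levels: tuple[str, ...] = ("group", "subgroup",
                                              "individual")) -> set[PathSpec]:
        t = self.table
        sel = t[(t.subject_id == subject_id) & t.level.isin(levels)]
        return {PathSpec(r.from_node, r.to_node, int(r.lag), r.level)
                for r in sel.itertuples()}


def simulate_cohort(scenario: SimScenario
                    ) -> tuple[list[ROITimeSeries], CohortLedger]:
    """Simulate every subject and assemble the ground-truth ledger."""
    U = _exogenous_matrix(scenario, scenario.seed)
    series = []
    rows = []
    labels = {}
    for s in range(scenario.n_subjects):
        ts = simulate_subject(scenario, s, exogenous=U)
        series.append(ts)
        struct, label = scenario.subject_structure(s)
        labels[ts.subject_id] = label
        for _, r in struct.iterrows():
            rows.append(dict(subject_id=ts.subject_id, level=r.level,
                             from_node=r.from_node, to_node=r.to_node,
                             lag=int(r.lag), beta=float(r.beta),
                             subgroup=label))
    ledger = CohortLedger(
        table=pd.DataFrame(rows),
        membership=pd.Series(labels, name="subgroup"))
    return series, ledger


def _truth_feature(ledger: CohortLedger, path: PathSpec, encoding: str
                   ) -> pd.Series:
    subjects = ledger.membership.index
    t = ledger.table
    sel = t[(t.from_node == path.from_node) & (t.to_node == path.to_node)
            & (t.lag == path.lag)]
    if sel.empty:
        raise ScenarioError(f"feature path {path!r} not in the scenario")
    if encoding == "presence":
        present = set(sel.subject_id)
        return pd.Series([1.0 if s in present else 0.0 for s in subjects],
                         index=subjects)
    vals = dict(zip(sel.subject_id, sel.beta))
    return pd.Series([vals.get(s, 0.0) for s in subjects], index=subjects)


def simulate_behavior(spec: BehaviorSpec, ledger: CohortLedger,
                      estimated_features=None, seed: int = 0,
                      standardize_features: bool = True) -> pd.Series:
    """Per-subject outcomes linked to network features.

    Features resolve against the ground-truth ledger by default, or against
    a supplied estimated feature matrix (see ``association.FeatureMatrix``).
    With ``standardize_features`` (the default) each feature column is
    z-scored before its effect applies, so coefficients are per-SD effect
    sizes — the same scale on which the association stage operates, since
    it standardizes its design matrix.
    """
    subjects = list(ledger.membership.index)
    eta = np.zeros(len(subjects))
    for (path, encoding), beta in spec.feature_effects.items():
        if estimated_features is not None:
            col = estimated_features.column(path, encoding)
        else:
            col = _truth_feature(ledger, path, encoding).to_numpy()
        col = np.asarray(col, dtype=float)
        if standardize_features:
            sd = col.std()
            if sd == 0:
                raise ScenarioError(
                    f"feature {path!r} ({encoding}) is constant; cannot "
                    "standardize")
            col = (col - col.mean()) / sd
        eta += beta * col
    rng = np.random.default_rng((seed, 15485863))
    if spec.link == "identity":
        y = eta + rng.standard_normal(len(subjects)) * spec.noise_sd
    else:
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(len(subjects)) < prob).astype(float)
    return pd.Series(y, index=subjects, name=spec.outcome_name)


def simulate_qc(scenario: SimScenario, seed: int = 0,
                n_bad_motion: int = 0, n_low_compliance: int = 0
                ) -> pd.DataFrame:
    """Plausible QC values for a simulated cohort (lognormal mean FD around
    0.2 mm, tSNR around 60), with optional planted high-motion and
    low-compliance subjects for exercising the exclusion rules."""
    rng = np.random.default_rng((seed, 32452843))
    n, T = scenario.n_subjects, scenario.n_timepoints
    ids = [f"sub{s + 1:03d}" for s in range(n)]
    mean_fd = rng.lognormal(np.log(0.2), 0.4, n)
    tsnr = rng.normal(60, 8, n)
    compliance = np.clip(rng.normal(0.95, 0.04, n), 0, 1)
    bad = rng.choice(n, size=min(n_bad_motion, n), replace=False)
    mean_fd[bad] *= 8
    lowc = rng.choice(n, size=min(n_low_compliance, n), replace=False)
    compliance[lowc] = rng.uniform(0.3, 0.7, len(lowc))
    return pd.DataFrame(dict(subject_id=ids, mean_fd_mm=mean_fd, tsnr=tsnr,
                             compliance_fraction=compliance))


def write_cohort(series: list[ROITimeSeries], ledger: CohortLedger,
                 out_dir) -> None:
    """Write one delimited file per subject plus the ground-truth ledger."""
    from pathlib import Path

    from .timeseries_io import write_timeseries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in series:
        write_timeseries(ts, out / f"{ts.subject_id}.csv")
    ledger.table.to_csv(out / "ledger.csv", index=False)
    ledger.membership.rename_axis("subject_id").to_csv(out / "membership.csv")
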