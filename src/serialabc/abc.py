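"""ABC engine: reference-table simulation, rejection, scenario choice by
multinomial logistic regression, parameter posteriors, and sensitivity runs.

The procedure mirrors classic rejection/regression ABC for microsatellite
data: simulate large numbers of datasets per scenario from the priors,
summarise each with the fixed statistic vector, retain the tolerance
fraction of simulations nearest the observed vector (Euclidean distance on
robust-SD-normalised statistics), then (a) regress the scenario label on the
retained statistics to read off posterior scenario probabilities at the
observed point, and (b) summarise the retained parameter draws of the
chosen scenario by their median and credibility intervals.

Two credibility intervals are reported side by side: the primary 2.5–97.5%
quantile interval, and a density-threshold interval that drops retained
values where a kernel density estimate falls below 5% of its maximum (the
"excluding all values below 5% frequency" reading).  A Beaumont-style
local-linear regression adjustment on log-transformed sizes is available as
a switch.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .coalescent import MutationModel, simulate_copies_raw
from .scenarios import (
    GenerationClock,
    SamplingDesign,
    ScenarioSpec,
    draw_scenario_params_batch,
)
from .sumstats import StatVector, stat_layout
from .sumstats import stat_vector_from_copies

__all__ = [
    "ReferenceTable",
    "RetainedSet",
    "PosteriorSummary",
    "simulate_reference_table",
    "retain_nearest",
    "scenario_posteriors",
    "parameter_posterior",
    "fit_scenario",
    "sensitivity_drop_stats",
    "compare_generation_clocks",
]


def _row_seed(master_seed: int, scenario_id: int, row: int) -> int:
    """Deterministic per-row simulator substream, independent of batching."""
    return int(np.random.SeedSequence([master_seed, scenario_id, row]).generate_state(1)[0])


@dataclass
class ReferenceTable:
    """Bank of (scenario id, parameter vector, statistic vector) triples."""

    scenario_ids: np.ndarray  # (n,)
    params: np.ndarray  # (n, max_p), NaN-padded
    stats: np.ndarray  # (n, n_stats)
    stat_names: list[str]
    param_names: dict[int, list[str]]  # per scenario
    n_groups: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.scenario_ids.shape[0]
        if self.params.shape[0] != n or self.stats.shape[0] != n:
            raise ValueError("misaligned reference table")
        if not np.isfinite(self.stats).all():
            raise ValueError("reference table contains non-finite statistics")

    @property
    def n_rows(self) -> int:
        return self.scenario_ids.shape[0]

    def robust_scale(self) -> np.ndarray:
        """Per-column robust SD (1.4826 x MAD); 0 marks degenerate columns."""
        med = np.median(self.stats, axis=0)
        return 1.4826 * np.median(np.abs(self.stats - med), axis=0)

    def to_csv(self, path, sidecar: bool = True) -> None:
        max_p = self.params.shape[1]
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        for j in range(max_p):
            df.insert(j, f"param_{j + 1}", self.params[:, j])
        df.insert(0, "scenario", self.scenario_ids)
        df.to_csv(path, index=False)
        if sidecar:
            meta = {
                "param_names": {str(k): v for k, v in self.param_names.items()},
                "n_groups": self.n_groups,
                "provenance": self.provenance,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        pcols = [c for c in df.columns if c.startswith("param_")]
        scols = [c for c in df.columns if c != "scenario" and c not in pcols]
        return cls(
            scenario_ids=df["scenario"].to_numpy(),
            params=df[pcols].to_numpy(),
            stats=df[scols].to_numpy(),
            stat_names=scols,
            param_names={int(k): v for k, v in meta["param_names"].items()},
            n_groups=meta["n_groups"],
            provenance=meta.get("provenance", {}),
        )


def simulate_reference_table(
    specs: list[ScenarioSpec],
    n_per_scenario: int,
    design: SamplingDesign,
    clock: GenerationClock,
    seed: int,
    mutation: MutationModel | None = None,
    labels: list[int] | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and record their
    statistic vectors.  Deterministic per seed.

    ``labels`` overrides the row labels (used by the generation-clock
    comparison, where several specs share a scenario id).
    """
    if n_per_scenario < 100:
        raise ValueError("n_per_scenario must be >= 100")
    mutation = mutation or MutationModel()
    names, _ = stat_layout(design.n_groups)
    tip_times = design.tip_times(clock)
    max_p = max(s.n_params for s in specs)
    total = n_per_scenario * len(specs)
    scen_col = np.empty(total, dtype=int)
    par = np.full((total, max_p), np.nan)
    sts = np.empty((total, len(names)))
    group_sizes = np.array(design.sample_sizes)
    failures = 0
    row = 0
    for si, spec in enumerate(specs):
        label = labels[si] if labels is not None else spec.scenario_id
        srng = np.random.default_rng(np.random.SeedSequence([seed, si, 0xA5]))
        draws = draw_scenario_params_batch(spec, n_per_scenario, srng)
        mus = np.stack([mutation.draw_locus_rates(design.n_loci, srng) for _ in range(n_per_scenario)])
        bnds_asc = spec.boundaries[::-1].copy()
        for i in range(n_per_scenario):
            sizes_asc = draws[i][spec.epoch_param_idx][::-1].copy()
            for attempt in range(3):
                copies = simulate_copies_raw(
                    tip_times, bnds_asc, sizes_asc, mus[i], mutation,
                    _row_seed(seed, label * 100 + si, i + attempt * total),
                )
                v = stat_vector_from_copies(copies, group_sizes, mutation.n_states)
                if np.isfinite(v).all():
                    break
                failures += 1
            scen_col[row] = label
            par[row, : spec.n_params] = draws[i]
            sts[row] = v
            row += 1
    return ReferenceTable(
        scenario_ids=scen_col,
        params=par,
        stats=sts,
        stat_names=names,
        param_names={
            (labels[si] if labels is not None else s.scenario_id): s.param_names
            for si, s in enumerate(specs)
        },
        n_groups=design.n_groups,
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "scenarios": [s.scenario_id for s in specs],
            "resimulated_rows": failures,
        },
    )


@dataclass
class RetainedSet:
    """Nearest-fraction rows of a reference table, distance-sorted."""

    indices: np.ndarray
    distances: np.ndarray  # non-decreasing
    scenario_ids: np.ndarray
    params: np.ndarray
    residuals: np.ndarray  # (stats - observed) / scale over retained rows
    param_names: dict[int, list[str]]
    stat_names: list[str]
    used_columns: np.ndarray  # boolean mask of columns entering the distance

    @property
    def n_retained(self) -> int:
        return self.indices.shape[0]


def retain_nearest(
    table: ReferenceTable,
    observed: StatVector | np.ndarray,
    fraction: float = 0.01,
    column_mask: np.ndarray | None = None,
) -> RetainedSet:
    """Keep the ``ceil(fraction * n)`` simulations nearest the observed
    statistics (Euclidean distance on robust-SD-normalised columns; ties
    broken by row index).  Zero-variance columns are excluded with a warning;
    ``column_mask`` restricts the distance to a column subset (sensitivity
    analyses)."""
    obs = observed.values if isinstance(observed, StatVector) else np.asarray(observed, float)
    if obs.shape != (len(table.stat_names),):
        raise ValueError("observed vector does not match the table's statistics")
    if not np.isfinite(obs).all():
        raise ValueError("observed statistics must be finite")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    scale = table.robust_scale()
    used = scale > 0
    if column_mask is not None:
        used &= np.asarray(column_mask, bool)
    if (scale == 0).any() and column_mask is None:
        warnings.warn(
            f"excluded {int((scale == 0).sum())} zero-variance column(s) from the distance"
        )
    if not used.any():
        raise ValueError("no usable statistic columns")
    z = (table.stats[:, used] - obs[used]) / scale[used]
    d = np.sqrt(np.einsum("ij,ij->i", z, z))
    m = math.ceil(fraction * table.n_rows)
    order = np.argsort(d, kind="stable")[:m]
    resid = (table.stats[order] - obs) / np.where(scale > 0, scale, 1.0)
    return RetainedSet(
        indices=order,
        distances=d[order],
        scenario_ids=table.scenario_ids[order],
        params=table.params[order],
        residuals=resid,
        param_names=table.param_names,
        stat_names=table.stat_names,
        used_columns=used,
    )


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        return np.ones_like(distances)
    return np.maximum(1.0 - (distances / dmax) ** 2, 1.0e-8)


def scenario_posteriors(retained: RetainedSet) -> dict:
    """Per-scenario posterior probabilities at the observed point.

    Multinomial logistic regression of the scenario label on the retained,
    observed-centred statistics with Epanechnikov distance weights,
    evaluated at the observed point (the centred origin); the direct-count
    estimate (retained proportions) is always reported alongside and serves
    as the fallback when the regression cannot be fitted.
    """
    labels = np.unique(retained.scenario_ids)
    counts = {
        int(s): float((retained.scenario_ids == s).mean()) for s in labels
    }
    out = {"counts": counts, "method": "logistic"}
    if labels.size < 2:
        out["logistic"] = {int(labels[0]): 1.0}
        out["method"] = "degenerate"
        return out
    X = retained.residuals[:, retained.used_columns]
    w = _epanechnikov(retained.distances)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            # moderate ridge penalty keeps the fit stable when the retained
            # set is small relative to the statistic dimension
            clf = LogisticRegression(max_iter=5000, C=1.0)
            clf.fit(X, retained.scenario_ids, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        out["logistic"] = {int(c): float(p) for c, p in zip(clf.classes_, probs)}
    except (ConvergenceWarning, ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"logistic regression failed ({exc}); falling back to counts")
        out["logistic"] = dict(counts)
        out["method"] = "counts_fallback"
    return out


@dataclass
class PosteriorSummary:
    """Scenario probabilities plus per-parameter posterior summaries."""

    scenario_probabilities: dict[int, float]
    counts_probabilities: dict[int, float]
    best_scenario: int
    parameters: dict[str, dict]
    method: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "scenario_probabilities": {str(k): v for k, v in self.scenario_probabilities.items()},
                    "counts_probabilities": {str(k): v for k, v in self.counts_probabilities.items()},
                    "best_scenario": self.best_scenario,
                    "parameters": self.parameters,
                    "method": self.method,
                },
                fh,
                indent=2,
            )


def parameter_posterior(
    values: np.ndarray,
    residuals: np.ndarray | None = None,
    distances: np.ndarray | None = None,
    regression_adjust: bool = False,
) -> dict:
    """Posterior summary of one parameter from its retained draws.

    Point estimate: median.  Primary interval: 2.5–97.5% quantiles.
    Alternative interval: the density-threshold rule — a Gaussian KDE on
    log-transformed values (all sizes are positive) and the span of retained
    values whose density exceeds 5% of the KDE maximum.  Optional
    local-linear (Beaumont) regression adjustment on the log scale.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 50:
        raise ValueError("need at least 50 retained draws")
    if regression_adjust:
        if residuals is None or distances is None:
            raise ValueError("regression adjustment needs residuals and distances")
        w = _epanechnikov(distances)
        y = np.log(values)
        X = np.column_stack([np.ones(values.size), residuals])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
        values = np.exp(beta[0] + (y - X @ beta))
    med = float(np.median(values))
    q = np.quantile(values, [0.025, 0.975])
    if np.ptp(values) == 0:
        kde_iv = [float(values[0]), float(values[0])]
    else:
        logv = np.log(values)
        kde = gaussian_kde(logv)
        dens = kde(logv)
        keep = values[dens >= 0.05 * dens.max()]
        kde_iv = [float(keep.min()), float(keep.max())]
    return {
        "median": med,
        "ci95_quantile": [float(q[0]), float(q[1])],
        "ci95_density": kde_iv,
        "n": int(values.size),
        "adjusted": bool(regression_adjust),
    }


def fit_scenario(
    table: ReferenceTable,
    observed: StatVector | np.ndarray,
    fraction: float = 0.01,
    regression_adjust: bool = False,
) -> PosteriorSummary:
    """Retention + scenario choice + parameter posteriors in one call."""
    retained = retain_nearest(table, observed, fraction)
    sp = scenario_posteriors(retained)
    probs = sp["logistic"]
    best = max(probs, key=probs.get)
    # parameter estimation uses the nearest fraction of the chosen
    # scenario's own simulations
    rows = table.scenario_ids == best
    sub = ReferenceTable(
        scenario_ids=table.scenario_ids[rows],
        params=table.params[rows],
        stats=table.stats[rows],
        stat_names=table.stat_names,
        param_names=table.param_names,
        n_groups=table.n_groups,
        provenance=dict(table.provenance),
    )
    # keep at least ~200 draws so quantiles and the KDE are usable even in
    # scaled-down tables
    frac_best = max(fraction, min(1.0, 200.0 / max(sub.n_rows, 1)))
    ret_best = retain_nearest(sub, observed, frac_best)
    pnames = retained.param_names[best]
    pars = {}
    for j, name in enumerate(pnames):
        vals = ret_best.params[:, j]
        try:
            pars[name] = parameter_posterior(
                vals,
                residuals=ret_best.residuals[:, ret_best.used_columns],
                distances=ret_best.distances,
                regression_adjust=regression_adjust,
            )
        except ValueError as exc:
            pars[name] = {"error": str(exc), "n": int(ret_best.n_retained)}
    return PosteriorSummary(
        scenario_probabilities=probs,
        counts_probabilities=sp["counts"],
        best_scenario=int(best),
        parameters=pars,
        method=sp["method"],
    )


def sensitivity_drop_stats(
    table: ReferenceTable,
    observed: StatVector | np.ndarray,
    scenario_pair: tuple[int, int],
    fraction: float = 0.01,
) -> pd.DataFrame:
    """Re-run retention + scenario choice with each statistic category
    removed in turn, restricted to one pair of scenarios.

    Returns one row per removed category plus the full-set baseline.
    """
    _, categories = stat_layout(table.n_groups)
    keep_rows = np.isin(table.scenario_ids, scenario_pair)
    sub = ReferenceTable(
        scenario_ids=table.scenario_ids[keep_rows],
        params=table.params[keep_rows],
        stats=table.stats[keep_rows],
        stat_names=table.stat_names,
        param_names=table.param_names,
        n_groups=table.n_groups,
        provenance=dict(table.provenance),
    )
    rows = []
    full_mask = np.ones(len(table.stat_names), dtype=bool)
    for label, mask in [("full", full_mask)] + [
        (f"drop:{cat}", np.where(np.isin(np.arange(full_mask.size), idx), False, full_mask))
        for cat, idx in categories.items()
    ]:
        if not mask.any():
            raise ValueError("cannot remove every statistic category")
        retained = retain_nearest(sub, observed, fraction, column_mask=mask)
        sp = scenario_posteriors(retained)
        row = {"removed": label, "method": sp["method"]}
        for s in scenario_pair:
            row[f"p{s}_logistic"] = sp["logistic"].get(s, 0.0)
            row[f"p{s}_counts"] = sp["counts"].get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_generation_clocks(
    observed: StatVector | np.ndarray,
    scenario_id: int,
    design: SamplingDesign,
    clocks: list[GenerationClock],
    n_per_clock: int,
    seed: int,
    mutation: MutationModel | None = None,
    fraction: float = 0.01,
    rainfall=None,
    build=None,
) -> dict:
    """Treat each candidate generations/year clock as a competing model.

    The same demographic scenario is simulated under each clock (epoch
    boundaries re-derived per clock) and the scenario-choice machinery
    returns a posterior probability per clock, keyed by generations/year.
    """
    from .scenarios import build_scenario

    build = build or build_scenario
    specs = [build(scenario_id, design, c, rainfall=rainfall) for c in clocks]
    if len(specs) == 1:
        return {"logistic": {clocks[0].generations_per_year: 1.0},
                "counts": {clocks[0].generations_per_year: 1.0}, "method": "degenerate"}
    # label rows 0..k-1 by clock index; simulate each spec under its own clock
    tables = []
    for ci, (spec, c) in enumerate(zip(specs, clocks)):
        tables.append(
            simulate_reference_table(
                [spec], n_per_clock, design, c, seed + 7919 * ci, mutation, labels=[ci]
            )
        )
    table = ReferenceTable(
        scenario_ids=np.concatenate([t.scenario_ids for t in tables]),
        params=np.vstack([t.params for t in tables]),
        stats=np.vstack([t.stats for t in tables]),
        stat_names=tables[0].stat_names,
        param_names={ci: t.param_names[ci] for ci, t in enumerate(tables)},
        n_groups=design.n_groups,
        provenance={"seed": seed, "clocks": [c.generations_per_year for c in clocks]},
    )
    retained = retain_nearest(table, observed, fraction)
    sp = scenario_posteriors(retained)
    gpy = [c.generations_per_year for c in clocks]
    keys = [g if gpy.count(g) == 1 else f"{g}#{i}" for i, g in enumerate(gpy)]
    return {
        "logistic": {keys[k]: v for k, v in sp["logistic"].items()},
        "counts": {keys[k]: v for k, v in sp["counts"].items()},
        "method": sp["method"],
    }
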