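"""Causal intervention effects in the five-state model.

Three approaches are implemented:

* :func:`manipulate` — artificially block or reroute transition intensities
  and product-integrate the manipulated matrix (the modularity approach);
* :func:`ipw_weights` / :func:`ipw_analysis` — inverse probability of
  initial-state or exposure weighting, followed by a weighted multi-state
  analysis;
* :func:`gcomputation` — average covariate-specific predicted probability
  paths over the cohort under a forced exposure value or initial state
  (standardization), with :func:`average_covariate_shortcut` as the cheap
  surrogate that is exact for constant additive hazards.

Uncertainty is by person-level bootstrap (:func:`bootstrap_bands`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .event_history import (
    DISABILITY,
    N_STATES,
    TRANSIENT_STATES,
    EventHistory,
    to_transition_rows,
)
from .intensities import CumulativeIntensity, HazardModel, nelson_aalen
from .probabilities import TransitionProbability, product_integral

log = logging.getLogger(__name__)

__all__ = [
    "InterventionSpec",
    "WeightSet",
    "ContrastCurve",
    "manipulate",
    "ipw_weights",
    "ipw_analysis",
    "gcomputation",
    "average_covariate_shortcut",
    "bootstrap_bands",
    "default_report_grid",
]


class SpecConflictError(ValueError):
    """An intervention spec is internally inconsistent."""


@dataclass(frozen=True)
class InterventionSpec:
    """Declarative description of a counterfactual.

    ``kind`` is one of ``manipulate_intensity`` (with ``actions`` tuples
    ``('block', h, j)`` or ``('reroute', h, j, j_new)``),
    ``set_initial_state`` (forced baseline state in 1-4) or ``set_exposure``
    (forced binary exposure value; ``None`` means the observed value, i.e.
    the null intervention).
    """

    kind: str
    actions: tuple[tuple, ...] = ()
    initial_state: int | None = None
    exposure_value: int | None = None
    exposure_col: str = "exposure"

    def __post_init__(self) -> None:
        if self.kind not in (
            "manipulate_intensity",
            "set_initial_state",
            "set_exposure",
        ):
            raise SpecConflictError(f"unknown intervention kind {self.kind!r}")
        blocked = set()
        for act in self.actions:
            if act[0] == "block":
                _, h, j = act
                blocked.add((h, j))
            elif act[0] == "reroute":
                _, h, j, jn = act
                if jn == h or not 1 <= jn <= N_STATES:
                    raise SpecConflictError(
                        f"reroute target {jn} invalid for source state {h}"
                    )
            else:
                raise SpecConflictError(f"unknown action {act[0]!r}")
            if act[1] == DISABILITY:
                raise SpecConflictError("cannot manipulate exits from state 5")
        for act in self.actions:
            if act[0] == "reroute" and (act[1], act[3]) in blocked:
                raise SpecConflictError(
                    f"reroute ({act[1]},{act[2]})->({act[1]},{act[3]}) targets "
                    "a blocked transition"
                )
        if self.kind == "set_initial_state" and self.initial_state not in (
            1,
            2,
            3,
            4,
        ):
            raise SpecConflictError("forced initial state must be in 1-4")
        if self.kind == "set_exposure" and self.exposure_value not in (0, 1, None):
            raise SpecConflictError("forced exposure must be 0, 1 or None")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "actions": [list(a) for a in self.actions],
                "initial_state": self.initial_state,
                "exposure_value": self.exposure_value,
                "exposure_col": self.exposure_col,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "InterventionSpec":
        d = json.loads(payload)
        return cls(
            kind=d["kind"],
            actions=tuple(tuple(a) for a in d.get("actions", ())),
            initial_state=d.get("initial_state"),
            exposure_value=d.get("exposure_value"),
            exposure_col=d.get("exposure_col", "exposure"),
        )


def manipulate(A: CumulativeIntensity, spec: InterventionSpec) -> CumulativeIntensity:
    """Apply block/reroute actions to a cumulative intensity matrix.

    Block ``(h, j)`` zeroes that transition's increments; reroute
    ``(h, j) -> (h, j')`` adds the original increments of ``(h, j)`` onto
    ``(h, j')`` and zeroes the source.  Only named entries (and the
    diagonals of touched rows) change; everything else is bitwise
    unchanged — the modularity contract.
    """
    if spec.kind != "manipulate_intensity":
        raise SpecConflictError("manipulate() needs a manipulate_intensity spec")
    orig = A.dA
    new = orig.copy()
    touched_rows: set[int] = set()
    # reroutes read from the original increments (declarative semantics)
    for act in spec.actions:
        if act[0] == "reroute":
            _, h, j, jn = act
            new[:, h - 1, jn - 1] = new[:, h - 1, jn - 1] + orig[:, h - 1, j - 1]
            touched_rows.add(h)
    for act in spec.actions:
        h, j = act[1], act[2]
        new[:, h - 1, j - 1] = 0.0
        touched_rows.add(h)
    for h in touched_rows:
        off = new[:, h - 1, :].copy()
        off[:, h - 1] = 0.0
        new[:, h - 1, h - 1] = -off.sum(axis=1)
    return CumulativeIntensity(
        times=A.times.copy(),
        dA=new,
        method=A.method,
        covariate_profile=None
        if A.covariate_profile is None
        else dict(A.covariate_profile),
    )


# ---------------------------------------------------------------------------
# inverse probability weighting
# ---------------------------------------------------------------------------


@dataclass
class WeightSet:
    """Per-person inverse-probability weights with diagnostics."""

    weights: pd.Series
    target: str
    coef: np.ndarray
    coef_names: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)


class PositivityError(ValueError):
    """A fitted assignment probability is exactly zero."""


def _fit_logit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as err:
        raise PositivityError(f"exposure model separated: {err}") from err
    return np.asarray(res.params, dtype=float)


def ipw_weights(
    table: pd.DataFrame,
    target: str,
    covariates: Sequence[str],
    exposure_col: str = "exposure",
    state_col: str = "initial_state",
    states: tuple[int, int] = (2, 3),
    stabilized: bool = False,
    floor: float = 0.01,
) -> WeightSet:
    """Inverse probability of exposure / initial-state weights.

    ``target='exposure'`` weights every person by ``1 / P(E = e_k | Z_k)``;
    ``target='initial_state'`` restricts the table to persons starting in
    the two contrasted ``states`` and weights by ``1 / P(S = s_k | Z_k)``.
    Probabilities come from ordinary logistic regression on ``covariates``.
    Stabilized weights multiply by the marginal probability of the realized
    value.
    """
    covariates = list(covariates)
    if target == "exposure":
        sub = table
        y = sub[exposure_col].to_numpy(dtype=float)
    elif target == "initial_state":
        sub = table[table[state_col].isin(states)]
        if sub.empty:
            raise ValueError(f"no persons start in states {states}")
        y = (sub[state_col] == states[1]).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown target {target!r}")

    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    coef = _fit_logit(y, X)
    p1 = 1.0 / (1.0 + np.exp(-(X @ coef)))
    p_realized = np.where(y == 1, p1, 1.0 - p1)
    if np.any(p_realized == 0):
        raise PositivityError("fitted assignment probability of exactly 0")
    offenders = sub.index[p_realized < floor]
    if len(offenders):
        log.warning(
            "positivity warning for target %s: %d persons with fitted "
            "probability < %.3g (min %.3g): %s",
            target,
            len(offenders),
            floor,
            p_realized.min(),
            list(offenders[:10]),
        )
    w = 1.0 / p_realized
    if stabilized:
        marg = y.mean()
        w = w * np.where(y == 1, marg, 1.0 - marg)
    weights = pd.Series(w, index=sub.index, name="weight")
    ess = float(w.sum() ** 2 / (w**2).sum())
    return WeightSet(
        weights=weights,
        target=target,
        coef=coef,
        coef_names=("_intercept",) + tuple(covariates),
        diagnostics={
            "min_weight": float(w.min()),
            "max_weight": float(w.max()),
            "effective_sample_size": ess,
            "n": int(len(w)),
            "n_below_floor": int(len(offenders)),
        },
    )


def ipw_analysis(
    histories: Sequence[EventHistory],
    weights: WeightSet,
    scenario: InterventionSpec,
    t_max: float | None = None,
) -> TransitionProbability:
    """Weighted multi-state analysis under an IPW scenario.

    Intensities are re-estimated with the weights as case weights (weighted
    Nelson-Aalen) and product-integrated from 0.  For a
    ``set_initial_state`` scenario the weighted pseudo-population carries a
    copy of each person in every contrasted initial state, so the scenario
    curve is the anchor-state row of the weighted ``P(0, .)``.  For a
    ``set_exposure`` scenario intensities come from the weighted subset with
    the scenario's observed exposure value.
    """
    by_id = {str(h.person_id): h for h in histories}
    if scenario.kind == "set_exposure":
        keep = [
            pid
            for pid in weights.weights.index.astype(str)
            if pid in by_id
            and by_id[pid].covariates is not None
            and by_id[pid].covariates.get(scenario.exposure_col)
            == scenario.exposure_value
        ]
        tag = f"ipw:{scenario.exposure_col}={scenario.exposure_value}"
    elif scenario.kind == "set_initial_state":
        keep = [pid for pid in weights.weights.index.astype(str) if pid in by_id]
        tag = f"ipw:start={scenario.initial_state}"
    else:
        raise SpecConflictError(
            "ipw_analysis supports set_exposure / set_initial_state scenarios"
        )
    sub = [by_id[pid] for pid in keep]
    if not sub:
        raise ValueError("no persons left for the requested scenario")
    rows = to_transition_rows(sub)
    wmap = weights.weights.copy()
    wmap.index = wmap.index.astype(str)
    rows["weight"] = rows["person_id"].astype(str).map(wmap).to_numpy()
    A = nelson_aalen(rows)
    for h in TRANSIENT_STATES:
        if not np.any(A.dA[:, h - 1, :] != 0):
            log.warning(
                "degenerate scenario: no weighted events out of state %d", h
            )
    return product_integral(A, 0.0, t_max, provenance=tag)


# ---------------------------------------------------------------------------
# G-computation
# ---------------------------------------------------------------------------


@dataclass
class ContrastCurve:
    """Difference between two scenario mean curves, with bootstrap bands."""

    anchor: tuple[int, int] | int
    destination: int
    times: np.ndarray
    delta: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    B: int = 0
    seed: int | None = None
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"t": self.times, "delta": self.delta})
        if self.lo is not None:
            out["lo"] = self.lo
            out["hi"] = self.hi
        return out


def default_report_grid(t_max: float) -> np.ndarray:
    """Daily for the first year, then every 30 days."""
    first = np.arange(1.0, min(365.0, t_max) + 1.0)
    if t_max <= 365:
        return first
    rest = np.arange(395.0, t_max + 1e-9, 30.0)
    return np.concatenate([first, rest])


def _model_kind(models: Mapping[tuple[int, int], HazardModel]) -> str:
    kinds = {m.kind for m in models.values()}
    if len(kinds) != 1:
        raise ValueError(f"mixed model kinds {kinds}")
    return kinds.pop()


def _check_covariates(
    models: Mapping[tuple[int, int], HazardModel], columns: Sequence[str]
) -> None:
    for m in models.values():
        needed = m.coef_names[1:] if m.kind == "additive_constant" else m.coef_names
        missing = [c for c in needed if c not in columns]
        if missing:
            raise KeyError(
                f"model for transition {m.transition} needs covariates "
                f"{missing} absent from the cohort table"
            )


def person_probability_paths(
    models: Mapping[tuple[int, int], HazardModel],
    table: pd.DataFrame,
    anchor: int,
    report_times: np.ndarray,
    step: float = 1.0,
) -> np.ndarray:
    """Covariate-specific ``P(0, t)`` rows for every person, batched.

    Returns an array of shape ``(n_persons, len(report_times), 5)`` holding
    the anchor-state row of each person's product-integral path.  Cox models
    jump at their Breslow baseline times; constant additive models use a
    regular grid of resolution ``step``.
    """
    _check_covariates(models, table.columns)
    kind = _model_kind(models)
    n = len(table)
    report_times = np.asarray(report_times, dtype=float)
    v = np.zeros((n, N_STATES))
    v[:, anchor - 1] = 1.0
    out = np.empty((n, len(report_times), N_STATES))

    if kind == "cox":
        grid = np.unique(
            np.concatenate([m.baseline_times for m in models.values()])
        )
        grid = grid[grid <= report_times.max() + 1e-12]
        # per-transition: indices into grid, base increments, person scales
        jumps_at: dict[int, list[tuple[int, int, float, np.ndarray]]] = {}
        for (h, j), m in models.items():
            zmat = table[list(m.coef_names)].to_numpy(dtype=float)
            scale = np.exp(zmat @ m.coef) if m.coef.size else np.ones(n)
            keep = m.baseline_times <= grid[-1] + 1e-12 if len(grid) else []
            idx = np.searchsorted(grid, m.baseline_times[keep])
            for l, inc in zip(idx, m.baseline_increments[keep]):
                jumps_at.setdefault(int(l), []).append((h, j, float(inc), scale))
    elif kind == "additive_constant":
        grid = np.arange(step, report_times.max() + step / 2, step)
        rates: list[tuple[int, int, np.ndarray]] = []
        for (h, j), m in models.items():
            zmat = table[list(m.coef_names[1:])].to_numpy(dtype=float)
            rate = m.coef[0] + (zmat @ m.coef[1:] if m.coef.size > 1 else 0.0)
            rates.append((h, j, np.broadcast_to(np.atleast_1d(rate), (n,))))
    else:
        raise ValueError(f"cannot predict with models of kind {kind!r}")

    r_idx = 0
    for l, t in enumerate(grid):
        # flush report times strictly before this jump
        while r_idx < len(report_times) and report_times[r_idx] < t:
            out[:, r_idx, :] = v
            r_idx += 1
        delta = np.zeros_like(v)
        if kind == "cox":
            for h, j, inc, scale in jumps_at.get(l, ()):
                amt = v[:, h - 1] * inc * scale
                delta[:, j - 1] += amt
                delta[:, h - 1] -= amt
        else:
            dt = grid[l] - (grid[l - 1] if l else 0.0)
            for h, j, rate in rates:
                amt = v[:, h - 1] * rate * dt
                delta[:, j - 1] += amt
                delta[:, h - 1] -= amt
        v = v + delta
        # flush report times at exactly this jump
        while r_idx < len(report_times) and report_times[r_idx] <= t:
            out[:, r_idx, :] = v
            r_idx += 1
    while r_idx < len(report_times):
        out[:, r_idx, :] = v
        r_idx += 1
    return out


def _apply_exposure(
    table: pd.DataFrame, spec: InterventionSpec, value: int | None
) -> pd.DataFrame:
    if value is None:  # null intervention: observed exposure
        return table
    out = table.copy()
    if spec.exposure_col not in out.columns:
        raise KeyError(f"cohort table lacks exposure column {spec.exposure_col!r}")
    out[spec.exposure_col] = value
    return out


@dataclass
class GComputationResult:
    times: np.ndarray
    scenario_curves: dict
    contrast: ContrastCurve


def gcomputation(
    models: Mapping[tuple[int, int], HazardModel],
    table: pd.DataFrame,
    spec: InterventionSpec,
    destination: int,
    anchor: int | None = None,
    anchor_pair: tuple[int, int] = (3, 2),
    report_times: np.ndarray | None = None,
    step: float = 1.0,
) -> GComputationResult:
    """Population-average intervention effect by standardization.

    For ``set_exposure`` the contrast is ``mean_k P_{i,j}(0, t | Z_k, E=1)
    minus the same with E=0`` for anchor state ``i``.  For
    ``set_initial_state`` the contrast is between the two anchor states in
    ``anchor_pair`` (first minus second) with covariates as observed.
    """
    if report_times is None:
        tmax = max(
            (float(m.baseline_times[-1]) for m in models.values()
             if len(m.baseline_times)),
            default=365.0,
        )
        report_times = default_report_grid(tmax)
    report_times = np.asarray(report_times, dtype=float)

    if spec.kind == "set_exposure":
        if anchor is None:
            raise ValueError("set_exposure G-computation needs an anchor state")
        curves = {}
        for e in (1, 0):
            tab = _apply_exposure(table, spec, e)
            paths = person_probability_paths(
                models, tab, anchor, report_times, step=step
            )
            curves[e] = paths.mean(axis=0)  # (T, 5)
        delta = curves[1][:, destination - 1] - curves[0][:, destination - 1]
        contrast = ContrastCurve(
            anchor=anchor,
            destination=destination,
            times=report_times,
            delta=delta,
            note=f"set_exposure:{spec.exposure_col}",
        )
        return GComputationResult(report_times, curves, contrast)

    if spec.kind == "set_initial_state":
        curves = {}
        for a in anchor_pair:
            paths = person_probability_paths(
                models, table, a, report_times, step=step
            )
            curves[a] = paths.mean(axis=0)
        delta = (
            curves[anchor_pair[0]][:, destination - 1]
            - curves[anchor_pair[1]][:, destination - 1]
        )
        contrast = ContrastCurve(
            anchor=anchor_pair,
            destination=destination,
            times=report_times,
            delta=delta,
            note="set_initial_state",
        )
        return GComputationResult(report_times, curves, contrast)

    raise SpecConflictError(
        "gcomputation supports set_exposure / set_initial_state specs"
    )


def average_covariate_shortcut(
    models: Mapping[tuple[int, int], HazardModel],
    table: pd.DataFrame,
    spec: InterventionSpec,
    destination: int,
    anchor: int,
    report_times: np.ndarray,
    step: float = 1.0,
) -> ContrastCurve:
    """Single prediction at cohort-average covariates instead of averaging.

    Exact for constant additive hazards (the hazard, hence the generator,
    is linear in Z); an approximation for Cox models, flagged in the note.
    """
    if spec.kind != "set_exposure":
        raise SpecConflictError(
            "average_covariate_shortcut applies to set_exposure specs"
        )
    kind = _model_kind(models)
    note = "average-covariate shortcut"
    if kind == "cox":
        note += " (approximation for cox models)"
        log.info("average-covariate shortcut used with cox models: approximation")
    curves = {}
    for e in (1, 0):
        tab = _apply_exposure(table, spec, e)
        zbar = tab.mean(axis=0).to_frame().T
        paths = person_probability_paths(models, zbar, anchor, report_times, step=step)
        curves[e] = paths[0]
    delta = curves[1][:, destination - 1] - curves[0][:, destination - 1]
    return ContrastCurve(
        anchor=anchor,
        destination=destination,
        times=np.asarray(report_times, dtype=float),
        delta=delta,
        note=note,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapBands:
    lo: np.ndarray
    hi: np.ndarray
    B: int
    seed: int | None
    replicates: np.ndarray | None = None


def bootstrap_bands(
    statistic: Callable[[list], np.ndarray],
    units: Sequence,
    B: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    keep_replicates: bool = False,
) -> BootstrapBands:
    """Percentile bootstrap bands from person-level resampling.

    ``statistic`` maps a resampled list of units (persons) to a fixed-length
    curve; the full pipeline (weights, model fits, probabilities) should be
    re-run inside it.  The seed makes the whole band reproducible.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    units = list(units)
    n = len(units)
    reps = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        reps.append(np.asarray(statistic([units[i] for i in idx]), dtype=float))
    arr = np.stack(reps)
    lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return BootstrapBands(
        lo=lo,
        hi=hi,
        B=B,
        seed=seed,
        replicates=arr if keep_replicates else None,
    )
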