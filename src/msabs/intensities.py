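"""Transition-intensity estimation for the five-state model.

Three estimators are provided per transition ``(h, j)``, each treating all
competing exits from ``h`` as censoring (cause-specific hazards):

* :func:`nelson_aalen` — marginal occurrence/exposure increments, optionally
  weighted;
* :func:`fit_cox_per_transition` — Cox proportional hazards with delayed
  entry on the time-since-baseline scale, Breslow tie handling (so the
  Breslow baseline and the product integral are mutually consistent), case
  weights and an optional cluster-robust sandwich variance;
* :func:`fit_additive_constant` — constant additive hazard
  ``alpha(Z) = b0 + b'Z`` fitted by identity-link Poisson likelihood with
  person-time exposure.

Fitted models are evaluated at a covariate value with
:func:`evaluate_intensity`, which assembles a row-zero-sum cumulative
intensity matrix ready for product integration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_history import DISABILITY, N_STATES, TRANSIENT_STATES, reachable_states

log = logging.getLogger(__name__)

__all__ = [
    "CumulativeIntensity",
    "HazardModel",
    "nelson_aalen",
    "fit_cox_per_transition",
    "fit_additive_constant",
    "evaluate_intensity",
    "models_to_json",
    "models_from_json",
]


@dataclass
class CumulativeIntensity:
    """Cumulative transition-intensity matrix as jump times plus increments.

    ``dA[l]`` is the 5x5 increment matrix at ``times[l]``; off-diagonal
    entries are intensity increments and the diagonal is minus the row sum,
    so every row of ``dA`` sums to zero.  Row 5 (disability) is identically
    zero.
    """

    times: np.ndarray
    dA: np.ndarray
    method: str = "nelson_aalen"
    covariate_profile: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.dA.shape != (len(self.times), N_STATES, N_STATES):
            raise ValueError("dA must have shape (len(times), 5, 5)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    @classmethod
    def from_increments(
        cls,
        increments: Mapping[tuple[int, int], tuple[np.ndarray, np.ndarray]],
        method: str = "nelson_aalen",
        covariate_profile: Mapping[str, float] | None = None,
    ) -> "CumulativeIntensity":
        """Assemble from per-transition ``(times, increments)`` pairs."""
        all_times = np.unique(
            np.concatenate(
                [np.asarray(t, dtype=float) for t, _ in increments.values()]
                or [np.empty(0)]
            )
        )
        dA = np.zeros((len(all_times), N_STATES, N_STATES))
        for (h, j), (t, inc) in increments.items():
            if h == DISABILITY:
                raise ValueError("no transitions out of the absorbing state")
            idx = np.searchsorted(all_times, np.asarray(t, dtype=float))
            dA[idx, h - 1, j - 1] += np.asarray(inc, dtype=float)
        for h in TRANSIENT_STATES:
            dA[:, h - 1, h - 1] = -(
                dA[:, h - 1, :].sum(axis=1) - dA[:, h - 1, h - 1]
            )
        return cls(
            times=all_times,
            dA=dA,
            method=method,
            covariate_profile=dict(covariate_profile)
            if covariate_profile is not None
            else None,
        )

    def validate(self) -> None:
        rowsums = self.dA.sum(axis=2)
        if not np.allclose(rowsums, 0.0, atol=1e-10):
            raise ValueError("rows of dA must sum to zero")
        if np.any(self.dA[:, DISABILITY - 1, :] != 0.0):
            raise ValueError("absorbing-state row must be zero")
        if self.method in ("nelson_aalen", "cox"):
            off = self.dA.copy()
            for h in range(N_STATES):
                off[:, h, h] = 0.0
            if np.any(off < 0):
                raise ValueError(
                    f"negative off-diagonal increments under {self.method}"
                )

    def cumulative(self, h: int, j: int) -> np.ndarray:
        """Cumulative A_hj over the jump times."""
        return np.cumsum(self.dA[:, h - 1, j - 1])

    def restricted(self, s: float, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Jump times and increments on the window ``(s, t]``."""
        mask = (self.times > s) & (self.times <= t)
        return self.times[mask], self.dA[mask]


@dataclass
class HazardModel:
    """A fitted cause-specific hazard model for one transition.

    For ``kind='cox'`` the baseline arrays hold the Breslow cumulative
    baseline-hazard step function; for ``kind='additive_constant'`` the
    hazard is ``coef[0] + coef[1:] . Z`` per day and the baseline arrays are
    empty.
    """

    transition: tuple[int, int]
    kind: str
    coef: np.ndarray
    coef_names: tuple[str, ...]
    cov: np.ndarray
    n_events: float
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_increments: np.ndarray = field(default_factory=lambda: np.empty(0))
    robust_cov: np.ndarray | None = None
    converged: bool = True
    notes: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)) if self.cov.size else np.empty(0)

    @property
    def robust_se(self) -> np.ndarray | None:
        if self.robust_cov is None:
            return None
        return np.sqrt(np.diag(self.robust_cov))

    def _zvec(self, z: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
        missing = [c for c in names if c not in z]
        if missing:
            raise KeyError(
                f"covariate profile lacks {missing} required by the "
                f"{self.transition} model"
            )
        vals = np.array([float(z[c]) for c in names])
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite covariate value in profile for {names}")
        return vals

    def cox_increments(self, z: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        assert self.kind == "cox"
        zv = self._zvec(z, self.coef_names)
        scale = float(np.exp(self.coef @ zv)) if self.coef.size else 1.0
        return self.baseline_times, self.baseline_increments * scale

    def additive_rate(self, z: Mapping[str, float]) -> float:
        assert self.kind == "additive_constant"
        zv = self._zvec(z, self.coef_names[1:])
        return float(self.coef[0] + self.coef[1:] @ zv)

    def to_dict(self) -> dict:
        return {
            "transition": list(self.transition),
            "kind": self.kind,
            "coef": self.coef.tolist(),
            "coef_names": list(self.coef_names),
            "cov": self.cov.tolist(),
            "robust_cov": None
            if self.robust_cov is None
            else self.robust_cov.tolist(),
            "n_events": self.n_events,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_increments": self.baseline_increments.tolist(),
            "converged": self.converged,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HazardModel":
        return cls(
            transition=tuple(d["transition"]),
            kind=d["kind"],
            coef=np.asarray(d["coef"], dtype=float),
            coef_names=tuple(d["coef_names"]),
            cov=np.asarray(d["cov"], dtype=float),
            robust_cov=None
            if d.get("robust_cov") is None
            else np.asarray(d["robust_cov"], dtype=float),
            n_events=d["n_events"],
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_increments=np.asarray(d["baseline_increments"], dtype=float),
            converged=d.get("converged", True),
            notes=tuple(d.get("notes", ())),
        )


class FitError(RuntimeError):
    """A hazard-model fit failed to converge."""


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------


def _risk_weight_at(
    times: np.ndarray, entry: np.ndarray, exit_: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Total weight at risk just before each time: sum w over entry < u <= exit."""
    order_e = np.argsort(entry, kind="stable")
    order_x = np.argsort(exit_, kind="stable")
    centry = np.concatenate([[0.0], np.cumsum(w[order_e])])
    cexit = np.concatenate([[0.0], np.cumsum(w[order_x])])
    n_entered = centry[np.searchsorted(entry[order_e], times, side="left")]
    n_exited = cexit[np.searchsorted(exit_[order_x], times, side="left")]
    return n_entered - n_exited


def nelson_aalen(
    rows: pd.DataFrame, weight_col: str = "weight"
) -> CumulativeIntensity:
    """Marginal (optionally weighted) Nelson-Aalen cumulative intensities.

    At each event time ``u`` of transition ``h -> j`` the increment is the
    weighted number of ``h -> j`` events at ``u`` divided by the weighted
    number at risk in ``h`` just before ``u``.
    """
    fs = rows["from_state"].to_numpy()
    ts = rows["to_state"].to_numpy()
    entry_all = rows["entry"].to_numpy(dtype=float)
    exit_all = rows["exit"].to_numpy(dtype=float)
    status = rows["status"].to_numpy()
    w_all = rows[weight_col].to_numpy(dtype=float)

    increments: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for h in TRANSIENT_STATES:
        mh = fs == h
        if not mh.any():
            continue
        # rows are stacked per destination; any single destination carries
        # the full episode set for the at-risk process in state h
        j0 = ts[mh][0]
        me = mh & (ts == j0)
        entry_sorted = np.sort(entry_all[me])
        exit_sorted_idx = np.argsort(exit_all[me], kind="stable")
        exit_sorted = exit_all[me][exit_sorted_idx]
        cum_entry = np.concatenate([[0.0], np.cumsum(w_all[me][np.argsort(entry_all[me], kind="stable")])])
        cum_exit = np.concatenate([[0.0], np.cumsum(w_all[me][exit_sorted_idx])])
        for j in reachable_states(h):
            ev = mh & (ts == j) & (status == 1)
            if not ev.any():
                continue
            times, inv = np.unique(exit_all[ev], return_inverse=True)
            d = np.bincount(inv, weights=w_all[ev])
            # weight at risk just before u: sum w over entry < u <= exit
            n_entered = cum_entry[np.searchsorted(entry_sorted, times, side="left")]
            n_exited = cum_exit[np.searchsorted(exit_sorted, times, side="left")]
            risk = n_entered - n_exited
            if np.any(risk <= 0):
                raise ValueError(
                    f"event for transition ({h},{j}) with zero at-risk weight"
                )
            increments[(h, j)] = (times, d / risk)
    return CumulativeIntensity.from_increments(increments, method="nelson_aalen")


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, delayed entry, case weights)
# ---------------------------------------------------------------------------


def _cox_fit(
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    w: np.ndarray,
    cluster: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> dict:
    """Newton-Raphson Breslow partial-likelihood fit with delayed entry."""
    n, p = Z.shape
    et = np.unique(exit_[event])
    if et.size == 0:
        raise FitError("no events")
    # risk and event indicator matrices over distinct event times
    R = ((entry[None, :] < et[:, None]) & (et[:, None] <= exit_[None, :])).astype(
        float
    )
    E = ((exit_[None, :] == et[:, None]) & event[None, :]).astype(float)
    dW = E @ w

    if p == 0:
        # no covariates: the Breslow baseline is the weighted Nelson-Aalen
        S0 = R @ w
        return {
            "beta": np.zeros(0),
            "cov": np.zeros((0, 0)),
            "robust_cov": None,
            "baseline_times": et,
            "baseline_increments": dW / S0,
            "loglik": float(-(dW * np.log(S0)).sum()),
        }

    sum_zw = (E @ (w[:, None] * Z)).sum(axis=0)

    beta = np.zeros(p)
    ll_prev = -np.inf
    info = np.eye(p)
    for _ in range(max_iter):
        eta = Z @ beta
        r = w * np.exp(eta)
        S0 = R @ r
        S1 = R @ (r[:, None] * Z)
        ll = float((w * event * eta).sum() - (dW * np.log(S0)).sum())
        zbar = S1 / S0[:, None]
        grad = sum_zw - (dW[:, None] * zbar).sum(axis=0)
        S2 = np.einsum("en,np,nq->epq", R, r[:, None] * Z, Z, optimize=True)
        V = S2 / S0[:, None, None] - np.einsum("ep,eq->epq", zbar, zbar)
        info = np.einsum("e,epq->pq", dW, V)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular information matrix: {err}") from err
        # step halving
        alpha = 1.0
        for _half in range(30):
            cand = beta + alpha * step
            eta_c = Z @ cand
            S0_c = R @ (w * np.exp(eta_c))
            ll_c = float((w * event * eta_c).sum() - (dW * np.log(S0_c)).sum())
            if ll_c >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if abs(ll_c - ll_prev) < tol and float(np.abs(grad).max()) < 1e-6:
            ll_prev = ll_c
            break
        ll_prev = ll_c
    else:
        if float(np.abs(grad).max()) > 1e-4:
            raise FitError(
                f"Cox fit did not converge (max |score| = {np.abs(grad).max():.2e})"
            )

    eta = Z @ beta
    r = w * np.exp(eta)
    S0 = R @ r
    S1 = R @ (r[:, None] * Z)
    zbar = S1 / S0[:, None]
    dL0 = dW / S0
    cov = np.linalg.inv(info) if p else np.zeros((0, 0))

    robust_cov = None
    if cluster is not None and p:
        # per-row score residuals, aggregated per cluster
        zbar_at_event = (E.T @ zbar)  # n x p (zbar at the row's event time)
        a = R.T @ dL0  # n
        B = R.T @ (dL0[:, None] * zbar)  # n x p
        resid = (
            w[:, None] * event[:, None] * (Z - zbar_at_event)
            - (w * np.exp(eta))[:, None] * (Z * a[:, None] - B)
        )
        df = pd.DataFrame(resid)
        df["__c"] = cluster
        U = df.groupby("__c").sum().to_numpy()
        meat = U.T @ U
        robust_cov = cov @ meat @ cov

    return {
        "beta": beta,
        "cov": cov,
        "robust_cov": robust_cov,
        "baseline_times": et,
        "baseline_increments": dL0,
        "loglik": ll_prev,
    }


def fit_cox_per_transition(
    rows: pd.DataFrame,
    covariates: Sequence[str],
    weight_col: str = "weight",
    robust: bool = False,
) -> dict[tuple[int, int], HazardModel]:
    """Cause-specific Cox fits, one per transition with at least one event.

    Transitions with zero events are omitted with a logged warning; their
    intensity is treated as zero downstream.  The Breslow cumulative
    baseline hazard is returned as a step function.
    """
    models: dict[tuple[int, int], HazardModel] = {}
    covariates = list(covariates)
    for h in TRANSIENT_STATES:
        for j in reachable_states(h):
            sub = rows[(rows["from_state"] == h) & (rows["to_state"] == j)]
            if sub.empty or int(sub["status"].sum()) == 0:
                log.warning(
                    "transition (%d,%d): zero events, model omitted "
                    "(intensity treated as 0)",
                    h,
                    j,
                )
                continue
            fit = _cox_fit(
                entry=sub["entry"].to_numpy(dtype=float),
                exit_=sub["exit"].to_numpy(dtype=float),
                event=sub["status"].to_numpy(dtype=bool),
                Z=sub[covariates].to_numpy(dtype=float),
                w=sub[weight_col].to_numpy(dtype=float),
                cluster=sub["person_id"].to_numpy() if robust else None,
            )
            models[(h, j)] = HazardModel(
                transition=(h, j),
                kind="cox",
                coef=fit["beta"],
                coef_names=tuple(covariates),
                cov=fit["cov"],
                robust_cov=fit["robust_cov"],
                n_events=float(sub["status"].sum()),
                baseline_times=fit["baseline_times"],
                baseline_increments=fit["baseline_increments"],
            )
    return models


# ---------------------------------------------------------------------------
# constant additive hazards
# ---------------------------------------------------------------------------


def _fit_additive_one(
    y: np.ndarray, T: np.ndarray, Z: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Identity-link Poisson fit of events ~ Poisson((b0 + b'Z) * T)."""
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import DomainWarning

    X = np.column_stack([np.ones(len(T)), Z])
    XT = X * T[:, None]
    notes: tuple[str, ...] = ()
    start = np.zeros(X.shape[1])
    start[0] = max(float((w * y).sum() / (w * T).sum()), 1e-10)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DomainWarning)
            model = sm.GLM(
                y,
                XT,
                family=sm.families.Poisson(link=sm.families.links.Identity()),
                var_weights=w,
            )
            res = model.fit(start_params=start, maxiter=200)
        coef = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not np.all(np.isfinite(coef)):
            raise ValueError("non-finite coefficients")
    except Exception as err:  # pragma: no cover - fallback path
        log.warning("identity-link Poisson fit failed (%s); using WLS fallback", err)
        # quasi-likelihood fallback: weighted least squares on rates
        W = w * T
        A = XT.T @ (w[:, None] * XT / np.maximum(T, 1e-12)[:, None])
        b = XT.T @ (w * y / np.maximum(T, 1e-12))
        coef = np.linalg.lstsq(A, b, rcond=None)[0]
        cov = np.linalg.pinv(A)
        notes = ("wls_fallback",)
    return coef, cov, notes


def fit_additive_constant(
    rows: pd.DataFrame,
    covariates: Sequence[str],
    weight_col: str = "weight",
) -> dict[tuple[int, int], HazardModel]:
    """Constant additive-hazard fits ``alpha_hj(Z) = b0 + b'Z`` per transition.

    Fitted by identity-link Poisson likelihood with person-time exposure.
    Without covariates the estimate reduces to the occurrence/exposure rate
    (total events / total person-time).  Transitions with zero events get an
    all-zero model.
    """
    models: dict[tuple[int, int], HazardModel] = {}
    covariates = list(covariates)
    p = len(covariates)
    for h in TRANSIENT_STATES:
        for j in reachable_states(h):
            sub = rows[(rows["from_state"] == h) & (rows["to_state"] == j)]
            if sub.empty:
                continue
            y = sub["status"].to_numpy(dtype=float)
            T = (sub["exit"] - sub["entry"]).to_numpy(dtype=float)
            w = sub[weight_col].to_numpy(dtype=float)
            names = ("_intercept",) + tuple(covariates)
            if y.sum() == 0:
                models[(h, j)] = HazardModel(
                    transition=(h, j),
                    kind="additive_constant",
                    coef=np.zeros(p + 1),
                    coef_names=names,
                    cov=np.zeros((p + 1, p + 1)),
                    n_events=0.0,
                    notes=("zero_events",),
                )
                continue
            Z = sub[covariates].to_numpy(dtype=float) if p else np.empty((len(y), 0))
            coef, cov, notes = _fit_additive_one(y, T, Z, w)
            models[(h, j)] = HazardModel(
                transition=(h, j),
                kind="additive_constant",
                coef=coef,
                coef_names=names,
                cov=cov,
                n_events=float(y.sum()),
                notes=notes,
            )
    return models


# ---------------------------------------------------------------------------
# evaluation at covariate values
# ---------------------------------------------------------------------------


def evaluate_intensity(
    models: Mapping[tuple[int, int], HazardModel],
    z: Mapping[str, float],
    grid: np.ndarray | None = None,
    t_max: float | None = None,
    step: float = 1.0,
    clamp_negative: bool = False,
) -> CumulativeIntensity:
    """Covariate-specific cumulative intensity matrix from fitted models.

    Cox models contribute ``dL0(u) * exp(b'z)`` at their baseline jump times;
    constant additive models contribute ``(b0 + b'z) * du`` on ``grid``
    (daily by default, requiring ``t_max``).  Negative additive increments
    are never clamped silently: they raise a logged warning and are clamped
    to zero only when ``clamp_negative`` is set.
    """
    if not models:
        raise ValueError("no fitted models supplied")
    kinds = {m.kind for m in models.values()}
    if len(kinds) > 1:
        raise ValueError(f"mixed model kinds {kinds} cannot be combined")
    kind = kinds.pop()

    increments: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    n_clamped = 0
    if kind == "cox":
        for (h, j), m in models.items():
            t, inc = m.cox_increments(z)
            increments[(h, j)] = (t, inc)
    elif kind == "additive_constant":
        if grid is None:
            if t_max is None:
                raise ValueError("additive evaluation needs a grid or t_max")
            grid = np.arange(step, t_max + step / 2, step)
        grid = np.asarray(grid, dtype=float)
        dt = np.diff(np.concatenate([[0.0], grid]))
        for (h, j), m in models.items():
            rate = m.additive_rate(z)
            if rate < 0:
                n_clamped += 1
                log.warning(
                    "transition (%d,%d): negative additive hazard %.3g at "
                    "requested covariates%s",
                    h,
                    j,
                    rate,
                    " (clamped to 0)" if clamp_negative else "",
                )
                if clamp_negative:
                    rate = 0.0
            increments[(h, j)] = (grid, np.full(len(grid), rate) * dt)
    else:
        raise ValueError(f"cannot evaluate models of kind {kind!r}")

    out = CumulativeIntensity.from_increments(
        increments,
        method=kind if kind != "additive_constant" else "additive",
        covariate_profile={k: float(v) for k, v in z.items()},
    )
    if n_clamped:
        out.covariate_profile["_n_negative_hazards"] = float(n_clamped)
    return out


def models_to_json(models: Mapping[tuple[int, int], HazardModel], path) -> None:
    payload = {f"{h}->{j}": m.to_dict() for (h, j), m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def models_from_json(path) -> dict[tuple[int, int], HazardModel]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for key, d in payload.items():
        h, j = key.split("->")
        out[(int(h), int(j))] = HazardModel.from_dict(d)
    return out
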