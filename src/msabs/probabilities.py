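"""Transition and state-occupation probabilities by product integration.

``P(s, t) = prod over u in (s, t] of (I + dA(u))`` turns a cumulative
intensity matrix into a transition-probability matrix; plugging in
Nelson-Aalen increments gives the Aalen-Johansen estimator.  Mixing the
rows of ``P(0, t)`` over an initial-state distribution gives state
occupation probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_history import DISABILITY, N_STATES, EventHistory
from .intensities import CumulativeIntensity

log = logging.getLogger(__name__)

__all__ = [
    "TransitionProbability",
    "InitialStateModel",
    "product_integral",
    "occupation_probabilities",
    "fit_initial_state_model",
]


@dataclass
class TransitionProbability:
    """Matrix-valued path ``P(s, .)`` on a grid of jump times.

    ``matrices[l]`` is ``P(s, times[l])``; between jump times the path is
    right-continuous and step-constant, so ``at(t)`` returns the matrix at
    the largest jump time ``<= t`` (identity before the first jump).
    """

    anchor: float
    times: np.ndarray
    matrices: np.ndarray
    provenance: str = "marginal"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape != (len(self.times), N_STATES, N_STATES):
            raise ValueError("matrices must have shape (len(times), 5, 5)")

    def at(self, t: float) -> np.ndarray:
        if t < self.anchor:
            raise ValueError(f"t={t} before anchor {self.anchor}")
        idx = int(np.searchsorted(self.times, t, side="right"))
        if idx == 0:
            return np.eye(N_STATES)
        return self.matrices[idx - 1]

    def path(self, times: Sequence[float]) -> np.ndarray:
        """P(s, t) stacked over an arbitrary report grid."""
        return np.stack([self.at(t) for t in times])

    def validate(self, atol: float = 1e-8) -> None:
        rowsums = self.matrices.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=atol):
            raise ValueError("rows of P(s,t) must sum to 1")
        if "additive" not in self.provenance:
            if np.any(self.matrices < -atol) or np.any(self.matrices > 1 + atol):
                raise ValueError("entries of P(s,t) must lie in [0, 1]")
        elif np.any(self.matrices < 0) or np.any(self.matrices > 1):
            log.warning(
                "additive-provenance probabilities outside [0, 1] "
                "(min %.3g, max %.3g)",
                self.matrices.min(),
                self.matrices.max(),
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV layout: anchor, t, from, to, estimate, provenance."""
        rows = []
        for l, t in enumerate(self.times):
            for h in range(N_STATES):
                for j in range(N_STATES):
                    rows.append(
                        {
                            "anchor": self.anchor,
                            "t": t,
                            "from": h + 1,
                            "to": j + 1,
                            "estimate": self.matrices[l, h, j],
                            "provenance": self.provenance,
                        }
                    )
        return pd.DataFrame(rows)


def product_integral(
    A: CumulativeIntensity,
    s: float = 0.0,
    t: float | None = None,
    provenance: str | None = None,
) -> TransitionProbability:
    """Left-to-right matrix product of ``(I + dA(u))`` over ``u in (s, t]``.

    Returns the whole path ``P(s, .)`` evaluated after every jump time in
    the window.  For ``nelson_aalen``/``cox`` provenance a negative diagonal
    in any factor (an increment exceeding 1) indicates corrupt data and
    raises.
    """
    if t is None:
        t = float(A.times[-1]) if len(A.times) else s
    if s > t:
        raise ValueError("need s <= t")
    times, dA = A.restricted(s, t)
    prov = provenance if provenance is not None else A.method
    if A.method in ("nelson_aalen", "cox"):
        diags = 1.0 + np.diagonal(dA, axis1=1, axis2=2)
        if np.any(diags < -1e-10):
            bad = times[np.any(diags < -1e-10, axis=1)][0]
            raise ValueError(
                f"increment at t={bad} exceeds 1 under {A.method} "
                "provenance; upstream data bug"
            )
    P = np.eye(N_STATES)
    mats = np.empty((len(times), N_STATES, N_STATES))
    factors = np.eye(N_STATES)[None, :, :] + dA
    for l in range(len(times)):
        P = P @ factors[l]
        mats[l] = P
    return TransitionProbability(anchor=s, times=times, matrices=mats, provenance=prov)


# ---------------------------------------------------------------------------
# initial-state model
# ---------------------------------------------------------------------------

_BASELINE_STATES = (1, 2, 3, 4)


@dataclass
class InitialStateModel:
    """Distribution of the baseline state over states 1-4.

    ``kind='empirical'`` stores constant observed proportions;
    ``kind='logistic'`` stores one-vs-rest binary logistic fits renormalized
    over the four baseline states (or one multinomial fit).
    """

    kind: str
    states: tuple[int, ...]
    probs: np.ndarray | None = None
    coef: dict[int, np.ndarray] | None = None
    coef_names: tuple[str, ...] = ()
    multinomial: bool = False

    def predict(self, z: Mapping[str, float] | pd.DataFrame | None = None) -> np.ndarray:
        """Probabilities over states 1..4 (single profile -> shape (4,))."""
        if self.kind == "empirical":
            out = np.zeros(4)
            for s, p in zip(self.states, self.probs):
                out[s - 1] = p
            return out
        if z is None:
            raise ValueError("logistic initial-state model needs covariates")
        if isinstance(z, pd.DataFrame):
            X = np.column_stack(
                [np.ones(len(z))] + [z[c].to_numpy(dtype=float) for c in self.coef_names]
            )
        else:
            X = np.concatenate([[1.0], [float(z[c]) for c in self.coef_names]])[None, :]
        if self.multinomial:
            # coefficients relative to the reference (first listed) state
            etas = np.zeros((X.shape[0], len(self.states)))
            for i, s in enumerate(self.states[1:], start=1):
                etas[:, i] = X @ self.coef[s]
            expe = np.exp(etas - etas.max(axis=1, keepdims=True))
            probs = expe / expe.sum(axis=1, keepdims=True)
        else:
            raw = np.column_stack(
                [1.0 / (1.0 + np.exp(-(X @ self.coef[s]))) for s in self.states]
            )
            probs = raw / raw.sum(axis=1, keepdims=True)
        out = np.zeros((X.shape[0], 4))
        for i, s in enumerate(self.states):
            out[:, s - 1] = probs[:, i]
        return out[0] if not isinstance(z, pd.DataFrame) else out


class SeparationError(RuntimeError):
    """Logistic fit separated; advice: drop or coarsen the offending covariate."""


def _logit_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as err:
        raise SeparationError(
            "perfect separation in initial-state logistic fit; drop or "
            "coarsen the offending covariate"
        ) from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        raise SeparationError(
            "initial-state logistic fit diverged (|coef| > 50); likely "
            "separation — drop or coarsen the offending covariate"
        )
    return params


def fit_initial_state_model(
    histories: Sequence[EventHistory] | None = None,
    kind: str = "empirical",
    covariates: Sequence[str] = (),
    multinomial: bool = False,
    initial_states: np.ndarray | None = None,
    covariate_table: pd.DataFrame | None = None,
) -> InitialStateModel:
    """Fit the baseline-state distribution.

    ``kind='empirical'`` uses observed proportions; ``kind='logistic'`` fits
    one binary logistic regression per represented state and renormalizes
    (the default multinomial surrogate), or a true multinomial logit when
    ``multinomial`` is set.
    """
    if histories is not None:
        initial_states = np.array([h.initial_state for h in histories])
        if kind == "logistic":
            covariate_table = pd.DataFrame(
                [h.covariates for h in histories]
            )
    if initial_states is None:
        raise ValueError("need histories or initial_states")
    initial_states = np.asarray(initial_states)
    if np.any(initial_states == DISABILITY):
        raise ValueError("state 5 cannot be a baseline state")
    states = tuple(int(s) for s in sorted(np.unique(initial_states)))

    if kind == "empirical":
        probs = np.array([(initial_states == s).mean() for s in states])
        return InitialStateModel(kind="empirical", states=states, probs=probs)

    if kind != "logistic":
        raise ValueError(f"unknown kind {kind!r}")
    if covariate_table is None:
        raise ValueError("logistic initial-state model needs a covariate table")
    covariates = list(covariates) or [
        c for c in covariate_table.columns if c != "person_id"
    ]
    X = np.column_stack(
        [np.ones(len(initial_states))]
        + [covariate_table[c].to_numpy(dtype=float) for c in covariates]
    )

    coef: dict[int, np.ndarray] = {}
    if multinomial:
        import statsmodels.api as sm

        # map states to 0..K-1 with the first as reference
        codes = np.searchsorted(states, initial_states)
        res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)  # (p+1, K-1)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise SeparationError("multinomial initial-state fit diverged")
        for i, s in enumerate(states[1:]):
            coef[s] = params[:, i]
    else:
        for s in states:
            coef[s] = _logit_fit((initial_states == s).astype(float), X)
    return InitialStateModel(
        kind="logistic",
        states=states,
        coef=coef,
        coef_names=tuple(covariates),
        multinomial=multinomial,
    )


def occupation_probabilities(
    P: TransitionProbability,
    init: InitialStateModel | np.ndarray,
    z: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Overall probability of being in each state over time.

    ``P`` must be anchored at 0.  ``init`` is an :class:`InitialStateModel`
    or a length-4 probability vector over baseline states 1-4.
    """
    if P.anchor != 0:
        raise ValueError("occupation probabilities need P anchored at s=0")
    if isinstance(init, InitialStateModel):
        pi = init.predict(z)
    else:
        pi = np.asarray(init, dtype=float)
    if pi.shape != (4,):
        raise ValueError("initial distribution must cover states 1-4 only")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("initial-state probabilities must sum to 1")
    pi5 = np.concatenate([pi, [0.0]])
    curves = np.einsum("k,lkj->lj", pi5, P.matrices)
    out = pd.DataFrame(curves, columns=[f"state_{j}" for j in range(1, 6)])
    out.insert(0, "t", P.times)
    return out
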