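"""Synthetic registry-cohort generator with known ground truth.

Generates cohorts with the structure the analysis assumes: covariates,
a confounded binary exposure, multinomial baseline-state assignment,
covariate-dependent Markov (or Weibull-sojourn semi-Markov) transition
dynamics on the five states, administrative censoring, and raw-spell
artifacts (overlapping registrations, one-day spells, no-benefit gaps
before disability).  Artifacts are injected after the trajectory is
realized, so the pre-artifact truth is retained and closed-form target
quantities (matrix-exponential curves for constant-rate scenarios) are
available as acceptance oracles.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .event_history import (
    DISABILITY,
    N_STATES,
    TRANSIENT_STATES,
    WORK,
    BenefitRecord,
    Episode,
    EventHistory,
)
from .interventions import InterventionSpec

__all__ = [
    "CovariateDef",
    "LinearPredictor",
    "TransitionHazard",
    "ArtifactConfig",
    "GeneratorSpec",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "truth_curves",
    "truth_delta",
]

_STATE_TO_BENEFIT = {
    2: "partial_sick_leave",
    3: "sick_leave",
    4: "work_assessment_allowance",
    5: "disability_pension",
}


@dataclass(frozen=True)
class CovariateDef:
    """Marginal distribution of one baseline covariate."""

    name: str
    kind: str  # 'bernoulli' | 'categorical' | 'normal'
    p: float | None = None
    levels: tuple[float, ...] | None = None
    probs: tuple[float, ...] | None = None
    mean: float = 0.0
    sd: float = 1.0

    def support(self) -> list[tuple[float, float]] | None:
        """(value, probability) pairs, or None for continuous covariates."""
        if self.kind == "bernoulli":
            return [(0.0, 1.0 - self.p), (1.0, self.p)]
        if self.kind == "categorical":
            return list(zip(self.levels, self.probs))
        return None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "bernoulli":
            return (rng.random(n) < self.p).astype(float)
        if self.kind == "categorical":
            return rng.choice(np.asarray(self.levels, float), size=n, p=self.probs)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, n)
        raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class LinearPredictor:
    """Intercept plus named linear coefficients over covariate columns."""

    intercept: float = 0.0
    coefs: Mapping[str, float] = field(default_factory=dict)

    def eta(self, z: Mapping[str, float]) -> float:
        return self.intercept + sum(b * float(z[c]) for c, b in self.coefs.items())

    def prob(self, z: Mapping[str, float]) -> float:
        return 1.0 / (1.0 + math.exp(-self.eta(z)))


@dataclass(frozen=True)
class TransitionHazard:
    """Constant per-day hazard for one transition as a function of covariates.

    ``form='multiplicative'``: rate = base * exp(sum coefs * z)
    ``form='additive'``:       rate = base + sum coefs * z
    """

    base: float
    coefs: Mapping[str, float] = field(default_factory=dict)
    form: str = "multiplicative"

    def rate(self, z: Mapping[str, float]) -> float:
        lin = sum(b * float(z[c]) for c, b in self.coefs.items())
        if self.form == "multiplicative":
            return self.base * math.exp(lin)
        if self.form == "additive":
            return self.base + lin
        raise ValueError(f"unknown hazard form {self.form!r}")


@dataclass(frozen=True)
class ArtifactConfig:
    """Per-person probabilities of injecting each raw-spell artifact."""

    one_day_rate: float = 0.0
    overlap_rate: float = 0.0
    predisability_gap_rate: float = 0.0


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort; seed mandatory.

    ``hazards`` maps transitions ``(h, j)`` to :class:`TransitionHazard`;
    transitions absent from the map have rate zero.  The exposure column is
    appended to the covariate table under ``exposure_name`` and may be
    referenced by name in initial-state and hazard coefficients.
    """

    n: int
    seed: int
    covariates: tuple[CovariateDef, ...] = ()
    exposure: LinearPredictor | None = None
    exposure_name: str = "exposure"
    initial_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    initial_logits: Mapping[int, LinearPredictor] | None = None
    hazards: Mapping[tuple[int, int], TransitionHazard] = field(default_factory=dict)
    censor: tuple[int, int] = (1095, 1825)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    sojourn_shape: Mapping[int, float] | None = None
    min_sojourn_days: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for (h, j) in self.hazards:
            if h not in TRANSIENT_STATES or j == h or not 1 <= j <= N_STATES:
                raise ValueError(f"invalid transition ({h},{j})")
        if self.censor[0] > self.censor[1] or self.censor[0] < 1:
            raise ValueError("censoring window must satisfy 1 <= C_min <= C_max")
        self.validate_rates()

    def covariate_names(self) -> list[str]:
        names = [c.name for c in self.covariates]
        if self.exposure is not None:
            names.append(self.exposure_name)
        return names

    def _support_patterns(self) -> list[tuple[dict[str, float], float]] | None:
        """Enumerate the joint covariate support (discrete covariates only)."""
        supports = []
        for c in self.covariates:
            s = c.support()
            if s is None:
                return None
            supports.append([(c.name, v, p) for v, p in s])
        patterns = []
        for combo in itertools.product(*supports) if supports else [()]:
            z = {name: v for name, v, _ in combo}
            p = float(np.prod([pr for _, _, pr in combo])) if combo else 1.0
            patterns.append((z, p))
        return patterns

    def validate_rates(self) -> None:
        """All rates must be non-negative over the covariate support."""
        patterns = self._support_patterns()
        if patterns is None:
            # continuous covariates: spot-check +-4 sd box corners
            grids = []
            for c in self.covariates:
                s = c.support()
                if s is not None:
                    grids.append([(c.name, v) for v, _ in s])
                else:
                    grids.append(
                        [(c.name, c.mean - 4 * c.sd), (c.name, c.mean + 4 * c.sd)]
                    )
            patterns = [
                ({name: v for name, v in combo}, 1.0)
                for combo in itertools.product(*grids)
            ]
        for z, _ in patterns:
            for e in (0.0, 1.0) if self.exposure is not None else (0.0,):
                ze = dict(z)
                ze[self.exposure_name] = e
                for (h, j), hz in self.hazards.items():
                    r = hz.rate(ze)
                    if r < 0:
                        raise ValueError(
                            f"negative rate {r:.3g} for transition ({h},{j}) "
                            f"at covariates {ze}"
                        )

    def initial_distribution(self, z: Mapping[str, float]) -> np.ndarray:
        """P(X(0) = k | Z) over baseline states 1-4."""
        if self.initial_logits is None:
            return np.asarray(self.initial_probs, dtype=float)
        etas = np.zeros(4)
        for k in (2, 3, 4):
            lp = self.initial_logits.get(k)
            if lp is not None:
                etas[k - 1] = lp.eta(z)
        expe = np.exp(etas - etas.max())
        return expe / expe.sum()

    def generator_matrix(
        self, z: Mapping[str, float], intervention: InterventionSpec | None = None
    ) -> np.ndarray:
        """Constant 5x5 intensity matrix Q at covariate values ``z``.

        A ``manipulate_intensity`` intervention blocks/reroutes rates, the
        truth-level analog of manipulating estimated increments.
        """
        rates: dict[tuple[int, int], float] = {
            (h, j): hz.rate(z) for (h, j), hz in self.hazards.items()
        }
        if intervention is not None and intervention.kind == "manipulate_intensity":
            for act in intervention.actions:
                if act[0] == "reroute":
                    _, h, j, jn = act
                    rates[(h, jn)] = rates.get((h, jn), 0.0) + rates.get((h, j), 0.0)
            for act in intervention.actions:
                rates[(act[1], act[2])] = 0.0
        Q = np.zeros((N_STATES, N_STATES))
        for (h, j), r in rates.items():
            Q[h - 1, j - 1] = r
        for h in TRANSIENT_STATES:
            Q[h - 1, h - 1] = -Q[h - 1].sum()
        return Q

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hazards"] = {f"{h}->{j}": asdict(hz) for (h, j), hz in self.hazards.items()}
        if self.initial_logits is not None:
            d["initial_logits"] = {
                str(k): asdict(lp) for k, lp in self.initial_logits.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        d["covariates"] = tuple(CovariateDef(**c) for c in d.get("covariates", ()))
        if d.get("exposure") is not None:
            d["exposure"] = LinearPredictor(**d["exposure"])
        if d.get("initial_logits") is not None:
            d["initial_logits"] = {
                int(k): LinearPredictor(**lp) for k, lp in d["initial_logits"].items()
            }
        d["hazards"] = {
            tuple(int(x) for x in key.split("->")): TransitionHazard(**hz)
            for key, hz in d.get("hazards", {}).items()
        }
        if "artifacts" in d and isinstance(d["artifacts"], dict):
            d["artifacts"] = ArtifactConfig(**d["artifacts"])
        if "censor" in d:
            d["censor"] = tuple(d["censor"])
        if "initial_probs" in d:
            d["initial_probs"] = tuple(d["initial_probs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=list)


@dataclass
class GroundTruth:
    """Pre-artifact trajectories plus the generating parameters."""

    episodes: dict[str, list[Episode]]
    censor_times: dict[str, int]
    covariates: pd.DataFrame
    spec: GeneratorSpec

    def histories(self) -> list[EventHistory]:
        return [
            EventHistory(
                person_id=pid,
                censor_time=self.censor_times[pid],
                episodes=list(eps),
                covariates=self.covariates.loc[pid].to_dict(),
            )
            for pid, eps in self.episodes.items()
        ]


@dataclass
class SimulatedCohort:
    records: list[BenefitRecord]
    covariates: pd.DataFrame
    truth: GroundTruth


def _simulate_trajectory(
    spec: GeneratorSpec,
    z: Mapping[str, float],
    s0: int,
    C: int,
    rng: np.random.Generator,
) -> list[Episode]:
    """Competing exponential (or Weibull-sojourn) clocks, day resolution."""
    eps: list[Episode] = []
    t = 0
    state = s0
    while t < C:
        if state == DISABILITY:
            eps.append(Episode(DISABILITY, t, C))
            break
        rates = {
            j: hz.rate(z)
            for (h, j), hz in spec.hazards.items()
            if h == state
        }
        total = sum(rates.values())
        if total <= 0:
            eps.append(Episode(state, t, C))
            break
        shape = None
        if spec.sojourn_shape is not None:
            shape = spec.sojourn_shape.get(state)
        if shape is None:
            tau = rng.exponential(1.0 / total)
        else:
            # Weibull sojourn with the same mean as the exponential clock
            scale = (1.0 / total) / math.gamma(1.0 + 1.0 / shape)
            tau = scale * rng.weibull(shape)
        days = max(int(math.floor(tau + 0.5)), spec.min_sojourn_days)
        # censor if the transition would not leave room for a >=2-day episode
        # (the one-day rule would discard it again downstream)
        if t + days > C - 2:
            eps.append(Episode(state, t, C))
            break
        eps.append(Episode(state, t, t + days))
        t += days
        dests = list(rates)
        probs = np.array([rates[j] for j in dests]) / total
        state = int(rng.choice(dests, p=probs))
    return eps


def _inject_artifacts(
    records: list[BenefitRecord],
    episodes: list[Episode],
    cfg: ArtifactConfig,
    rng: np.random.Generator,
    pid: str,
) -> list[BenefitRecord]:
    out = list(records)
    # spurious one-day spell inside a long work episode
    if rng.random() < cfg.one_day_rate:
        works = [e for e in episodes if e.state == WORK and e.exit - e.entry >= 4]
        if works:
            ep = works[rng.integers(len(works))]
            day = int(rng.integers(ep.entry + 1, ep.exit - 1))
            out.append(
                BenefitRecord(
                    person_id=pid,
                    benefit_type="sick_leave",
                    start=day,
                    stop=day + 1,
                    registration_order=1000 + int(rng.integers(1000)),
                )
            )
    # stale overlapping registration fully inside a newer spell
    if rng.random() < cfg.overlap_rate and out:
        benefits = [r for r in out if r.duration >= 6 and r.registration_order >= 0]
        if benefits:
            rec = benefits[rng.integers(len(benefits))]
            s = int(rng.integers(rec.start + 1, rec.stop - 3))
            t = int(rng.integers(s + 2, rec.stop))
            stale_type = "sick_leave" if rec.benefit_type != "sick_leave" else "work_assessment_allowance"
            out.append(
                BenefitRecord(
                    person_id=pid,
                    benefit_type=stale_type,
                    start=s,
                    stop=t,
                    registration_order=-1 - int(rng.integers(100)),
                )
            )
    # no-benefit gap immediately before disability
    if rng.random() < cfg.predisability_gap_rate:
        for i, ep in enumerate(episodes):
            if ep.state == DISABILITY and i > 0 and episodes[i - 1].state != WORK:
                prev = episodes[i - 1]
                max_gap = min(30, prev.exit - prev.entry - 2)
                if max_gap >= 1:
                    gap = int(rng.integers(1, max_gap + 1))
                    for k, rec in enumerate(out):
                        if (
                            rec.stop == prev.exit
                            and rec.start == prev.entry
                            and rec.state == prev.state
                        ):
                            out[k] = BenefitRecord(
                                person_id=pid,
                                benefit_type=rec.benefit_type,
                                grading=rec.grading,
                                start=rec.start,
                                stop=rec.stop - gap,
                                registration_order=rec.registration_order,
                                diagnosis_code=rec.diagnosis_code,
                            )
                            break
                break
    return out


def simulate_cohort(spec: GeneratorSpec) -> SimulatedCohort:
    """Simulate a cohort; byte-identical for identical spec + seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    data: dict[str, np.ndarray] = {}
    for c in spec.covariates:
        data[c.name] = c.draw(rng, n)
    table = pd.DataFrame(data, index=[f"p{i:06d}" for i in range(n)])
    table.index.name = "person_id"

    if spec.exposure is not None:
        ps = np.array(
            [spec.exposure.prob(row) for row in table.to_dict("records")]
        ) if len(spec.covariates) else np.full(n, spec.exposure.prob({}))
        table[spec.exposure_name] = (rng.random(n) < ps).astype(float)

    censor_times = rng.integers(spec.censor[0], spec.censor[1] + 1, n)

    episodes: dict[str, list[Episode]] = {}
    records: list[BenefitRecord] = []
    for i, (pid, row) in enumerate(table.iterrows()):
        z = row.to_dict()
        pi = spec.initial_distribution(z)
        s0 = int(rng.choice([1, 2, 3, 4], p=pi))
        eps = _simulate_trajectory(spec, z, s0, int(censor_times[i]), rng)
        episodes[pid] = eps

        recs: list[BenefitRecord] = []
        order = 1
        for ep in eps:
            if ep.state == WORK:
                continue
            recs.append(
                BenefitRecord(
                    person_id=pid,
                    benefit_type=_STATE_TO_BENEFIT[ep.state],
                    grading=50 if ep.state == 2 else 100,
                    start=ep.entry,
                    stop=ep.exit,
                    registration_order=order,
                )
            )
            order += 1
        recs = _inject_artifacts(recs, eps, spec.artifacts, rng, pid)
        records.extend(recs)

    truth = GroundTruth(
        episodes=episodes,
        censor_times={pid: int(c) for pid, c in zip(table.index, censor_times)},
        covariates=table,
        spec=spec,
    )
    return SimulatedCohort(records=records, covariates=table, truth=truth)


# ---------------------------------------------------------------------------
# closed-form truth
# ---------------------------------------------------------------------------


@dataclass
class TruthCurves:
    """True transition matrices P(0, t) averaged over the covariate law."""

    times: np.ndarray
    matrices: np.ndarray  # (T, 5, 5)
    occupation: np.ndarray  # (T, 5)


def _patterns_with_exposure(
    spec: GeneratorSpec,
    intervention: InterventionSpec | None,
    rng: np.random.Generator | None,
    mc_draws: int,
) -> list[tuple[dict[str, float], float]]:
    base = spec._support_patterns()
    if base is None:
        if mc_draws <= 0:
            raise ValueError(
                "continuous covariates need mc_draws > 0 for truth curves"
            )
        rng = rng or np.random.default_rng(spec.seed + 1)
        draws = {c.name: c.draw(rng, mc_draws) for c in spec.covariates}
        base = [
            ({name: float(vals[i]) for name, vals in draws.items()}, 1.0 / mc_draws)
            for i in range(mc_draws)
        ]

    forced_e = None
    if intervention is not None and intervention.kind == "set_exposure":
        forced_e = intervention.exposure_value

    out = []
    for z, p in base:
        if spec.exposure is None:
            out.append((dict(z), p))
            continue
        if forced_e is not None:
            ze = dict(z)
            ze[spec.exposure_name] = float(forced_e)
            out.append((ze, p))
        else:
            pe = spec.exposure.prob(z)
            for e, w in ((1.0, pe), (0.0, 1.0 - pe)):
                if w <= 0:
                    continue
                ze = dict(z)
                ze[spec.exposure_name] = e
                out.append((ze, p * w))
    return out


def truth_curves(
    spec: GeneratorSpec,
    times: Sequence[float],
    intervention: InterventionSpec | None = None,
    mc_draws: int = 0,
) -> TruthCurves:
    """Exact P(0, t) and occupation curves under the generating law.

    Per covariate pattern the constant generator gives ``expm(Q t)``; the
    population curve is the mixture over the covariate (and exposure) law.
    ``manipulate_intensity`` interventions act on the rates before
    exponentiation; ``set_exposure`` forces the exposure column.
    Continuous covariates require a Monte-Carlo pattern sample
    (``mc_draws``).
    """
    times = np.asarray(times, dtype=float)
    patterns = _patterns_with_exposure(spec, intervention, None, mc_draws)
    manip = (
        intervention
        if intervention is not None and intervention.kind == "manipulate_intensity"
        else None
    )
    mats = np.zeros((len(times), N_STATES, N_STATES))
    occ = np.zeros((len(times), N_STATES))
    for z, p in patterns:
        Q = spec.generator_matrix(z, manip)
        pi = spec.initial_distribution(z)
        if (
            intervention is not None
            and intervention.kind == "set_initial_state"
        ):
            pi = np.zeros(4)
            pi[intervention.initial_state - 1] = 1.0
        pi5 = np.concatenate([pi, [0.0]])
        for l, t in enumerate(times):
            P = expm(Q * t)
            mats[l] += p * P
            occ[l] += p * (pi5 @ P)
    total = sum(p for _, p in patterns)
    return TruthCurves(times=times, matrices=mats / total, occupation=occ / total)


def truth_delta(
    spec: GeneratorSpec,
    times: Sequence[float],
    anchor: int,
    destination: int,
    exposure_col: str | None = None,
    mc_draws: int = 0,
) -> np.ndarray:
    """True marginal exposure-effect curve Delta*(t) = P^{E=1} - P^{E=0}."""
    col = exposure_col or spec.exposure_name
    hi = truth_curves(
        spec,
        times,
        InterventionSpec(kind="set_exposure", exposure_value=1, exposure_col=col),
        mc_draws=mc_draws,
    )
    lo = truth_curves(
        spec,
        times,
        InterventionSpec(kind="set_exposure", exposure_value=0, exposure_col=col),
        mc_draws=mc_draws,
    )
    return (
        hi.matrices[:, anchor - 1, destination - 1]
        - lo.matrices[:, anchor - 1, destination - 1]
    )
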