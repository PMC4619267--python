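import numpy as np
import pytest

from msabs import (
    ArtifactConfig,
    BenefitRecord,
    CovariateDef,
    GeneratorSpec,
    LinearPredictor,
    TransitionHazard,
    build_history,
    simulate_cohort,
)


@pytest.fixture
def toy_histories():
    """Hand-enumerable three-person fixture.

    a: no benefits at all on [0, 400)
    b: sick leave [0, 100), nothing [100, 130), disability [130, 400)
    c: sick [0, 50), work [50, 80), sick [80, 120), work [120, 400)
    """
    C = 400
    a = build_history([], 0, C, person_id="a")
    b = build_history(
        [
            BenefitRecord("b", "sick_leave", 0, 100, 1),
            BenefitRecord("b", "disability_pension", 130, C, 2),
        ],
        0,
        C,
    )
    c = build_history(
        [
            BenefitRecord("c", "sick_leave", 0, 50, 1),
            BenefitRecord("c", "sick_leave", 80, 120, 2),
        ],
        0,
        C,
    )
    return [a, b, c]


def five_state_spec(
    n: int,
    seed: int,
    confounded: bool = True,
    exposure_effect: float = 0.4,
    artifacts: ArtifactConfig | None = None,
    sojourn_shape=None,
) -> GeneratorSpec:
    """Default five-state generator: one binary confounder ``z`` plus a
    binary exposure, constant rates, all 15 permitted transitions except
    work -> disability."""
    zcoef = {"z": 1.0} if confounded else {}
    return GeneratorSpec(
        n=n,
        seed=seed,
        covariates=(CovariateDef(name="z", kind="bernoulli", p=0.4),),
        exposure=LinearPredictor(intercept=-0.4, coefs=zcoef),
        initial_probs=(0.15, 0.1, 0.45, 0.3),
        hazards={
            (1, 2): TransitionHazard(0.0020),
            (1, 3): TransitionHazard(0.0040, {"z": 0.3}),
            (1, 4): TransitionHazard(0.0008),
            (2, 1): TransitionHazard(0.0150),
            (2, 3): TransitionHazard(0.0030),
            (2, 4): TransitionHazard(0.0015),
            (2, 5): TransitionHazard(0.0005),
            (3, 1): TransitionHazard(
                0.0200, {"z": -0.2, "exposure": exposure_effect}
            ),
            (3, 2): TransitionHazard(0.0050),
            (3, 4): TransitionHazard(0.0030),
            (3, 5): TransitionHazard(0.0006),
            (4, 1): TransitionHazard(0.0050, {"exposure": exposure_effect}),
            (4, 2): TransitionHazard(0.0010),
            (4, 3): TransitionHazard(0.0015),
            (4, 5): TransitionHazard(0.0020, {"z": 0.2}),
        },
        censor=(1095, 1825),
        artifacts=artifacts or ArtifactConfig(),
        sojourn_shape=sojourn_shape,
    )


@pytest.fixture(scope="session")
def markov_cohort():
    """n=2000 confounded Markov cohort used by several estimation tests."""
    return simulate_cohort(five_state_spec(2000, seed=20))


@pytest.fixture(scope="session")
def markov_histories(markov_cohort):
    return markov_cohort.truth.histories()
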