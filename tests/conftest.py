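"""Shared fixtures: small calibration problems built from the synthetic
generator.  Session-scoped because forward solves (and the first compiled
call) are the expensive part of the suite."""

import numpy as np
import pytest

from myoexo.adjoint import FitProblem
from myoexo.dynamics import ExoParams, MuscleJointSystem
from myoexo.muscle import MuscleParams, default_knee_muscles
from myoexo.synthgen import make_experiment


@pytest.fixture(scope="session")
def exo():
    return ExoParams()


@pytest.fixture(scope="session")
def knee_system(exo):
    return MuscleJointSystem(default_knee_muscles(), exo)


@pytest.fixture(scope="session")
def one_muscle_system(exo):
    m = MuscleParams.from_cm("extensor", 10.0, 800.0, 20.0, 0.04, channel="X")
    return MuscleJointSystem([m], exo)


def _one_muscle_activation(t):
    return np.atleast_1d(0.05 + 0.15 * np.sin(np.pi * np.asarray(t) / 2) ** 2)


@pytest.fixture(scope="session")
def one_muscle_problem(one_muscle_system):
    return FitProblem.from_system(one_muscle_system, _one_muscle_activation,
                                  (0.0, 2.0), rtol=1e-10, atol=1e-12)


@pytest.fixture(scope="session")
def knee_experiment():
    """Noise-free 45-degree flexion-extension session, 8-muscle truth."""
    return make_experiment(seed=3, with_emg=False, t_span=(0.0, 4.0),
                           rate_hz=0.25)


@pytest.fixture(scope="session")
def knee_problem(knee_experiment):
    """Self-consistent recovery problem on the 45-degree session."""
    return FitProblem.from_system(knee_experiment.system,
                                  knee_experiment.activations,
                                  (0.0, 4.0), rtol=1e-6, atol=1e-8)
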