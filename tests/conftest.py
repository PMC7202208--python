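"""Shared fixtures: small phantoms and ensembles generated at session scope
so expensive renders are reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from stakit import phantom as ph
from stakit.particles import ParticleRecord, ParticleSet

warnings.filterwarnings("ignore", message="candidate radius smaller")


def correlation(a, b) -> float:
    """Pearson correlation of two volumes (or arrays)."""
    x = np.asarray(getattr(a, "data", a), dtype=float).ravel()
    y = np.asarray(getattr(b, "data", b), dtype=float).ravel()
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


@pytest.fixture(scope="session")
def spec32() -> ph.PhantomSpec:
    return ph.PhantomSpec.scaled(32, snr=0.5)


@pytest.fixture(scope="session")
def scene32(spec32) -> "ph.DensityVolume":
    return ph.make_scene(spec32)


@pytest.fixture(scope="session")
def receptor64():
    return ph.make_receptor_phantom(ph.PhantomSpec())


@pytest.fixture(scope="session")
def ensemble32(spec32) -> ph.SimulatedEnsemble:
    """30 single-class particles at SNR 0.5, box 32."""
    espec = ph.EnsembleSpec(
        n_particles=30,
        tilt_sigma_deg=6.0,
        tilt_max_deg=12.0,
        shift_max_a=4.0,
        seed=101,
    )
    return ph.simulate_ensemble(espec, spec32)


@pytest.fixture(scope="session")
def ensemble32_highsnr() -> ph.SimulatedEnsemble:
    """12 particles at SNR 10, box 32, for pose-recovery checks."""
    pspec = ph.PhantomSpec.scaled(32, snr=10.0)
    espec = ph.EnsembleSpec(
        n_particles=12,
        tilt_sigma_deg=6.0,
        tilt_max_deg=12.0,
        shift_max_a=4.0,
        seed=103,
    )
    return ph.simulate_ensemble(espec, pspec)


def truth_particleset(ens: ph.SimulatedEnsemble, cc: float = 0.5) -> ParticleSet:
    """Working particle set initialised at the planted truth (the
    'post-alignment' state used by classification-stage tests)."""
    return ParticleSet(
        [
            ParticleRecord(id=t.id, pose=t.pose, shift=t.shift.copy(), cc=cc)
            for t in ens.truth
        ]
    )
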