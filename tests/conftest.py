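"""Shared fixtures: small synthetic species generated once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import splicescape as ss
from splicescape.lengths import FrechetComponent, LengthModel


def light_length_mixture() -> LengthModel:
    """A compact mixture (short genomes) for tests that don't probe lengths."""
    return LengthModel(short=FrechetComponent(3.0, 30.0, 35.0),
                       long=FrechetComponent(3.0, 60.0, 60.0),
                       weight=0.8)


def sharpen_pwm(pwm, concentration: float = 0.92):
    """Replace each column by a peaked distribution on its consensus base."""
    f = pwm.freqs.copy()
    cons = f.argmax(axis=0)
    out = np.full_like(f, (1 - concentration) / 3)
    out[cons, np.arange(f.shape[1])] = concentration
    return dataclasses.replace(pwm, freqs=out)


@pytest.fixture(scope="session")
def small_spec():
    return ss.default_species_spec("small", n_introns=400, seed=11,
                                   length_mixture=light_length_mixture())


@pytest.fixture(scope="session")
def small_species(small_spec):
    return ss.generate_species(small_spec)


@pytest.fixture(scope="session")
def small_profiles(small_species):
    bg = ss.genome_background(small_species.genome_sequences())
    return ss.build_species_profiles(
        small_species.introns, bg, ss.load_default_core_bp(),
        small_species.genome_sequences(), species="small")


@pytest.fixture(scope="session")
def core_bp():
    return ss.load_default_core_bp()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_pwm(width: int, rng: np.random.Generator,
               background=None) -> ss.PWMProfile:
    freqs = rng.dirichlet(np.ones(4), size=width).T
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=float))
    return ss.PWMProfile(freqs=freqs, background=bg)


def random_dna(n: int, rng: np.random.Generator, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=p if p is not None else None))
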