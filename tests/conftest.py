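from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from sitkit.simulate import make_canonical_fixtures  # noqa: E402


@pytest.fixture(scope="session")
def fixtures() -> dict[str, str]:
    return make_canonical_fixtures()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Introduce exactly n substitutions at distinct random positions."""
    chars = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)
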