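from __future__ import annotations

import numpy as np
import pytest

from smorfscape.io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


def records_from(named: dict[str, str], sample_id: str = "") -> list[ProteinRecord]:
    return [
        ProteinRecord(id=k, sequence=v, sample_id=sample_id)
        for k, v in named.items()
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
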