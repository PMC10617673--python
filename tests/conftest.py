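import numpy as np
import pytest
from hypothesis import settings

from catchscan.synthetic_data import (
    SheetSpec,
    build_capture_complex,
    build_decoy_complex,
)

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def capture_fixture():
    """Default idealized capture complex (strand length 8, spacing 4.8)."""
    return build_capture_complex(SheetSpec(seed=2))


@pytest.fixture(scope="session")
def capture_model(capture_fixture):
    return capture_fixture.as_model()


@pytest.fixture(scope="session")
def decoy_fixture():
    return build_decoy_complex(SheetSpec(seed=2))


def rigid_transform(rng):
    """A random rotation + translation for invariance checks."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.normal(scale=20.0, size=3)
    return rot, shift


def transform_chain(chain, rot, shift):
    from catchscan.structure_io import ChainModel, ResidueRecord

    return ChainModel(
        chain_id=chain.chain_id,
        residues=[
            ResidueRecord(
                author_number=r.author_number,
                aa=r.aa,
                atoms={k: rot @ v + shift for k, v in r.atoms.items()},
                plddt=r.plddt,
            )
            for r in chain.residues
        ],
    )
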