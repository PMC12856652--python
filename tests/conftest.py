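import numpy as np
import pytest

from lipidspin import NucleusSpec, RadicalSpec, SpinSystemSpec


def random_pair_spec(
    rng: np.random.Generator,
    bz_mT: float | None = None,
    kst_per_ns: float | None = None,
    initial_state: str = "triplet",
    anisotropic: bool = True,
) -> SpinSystemSpec:
    """Random 16-dimensional radical pair: one spin-1/2 proton per radical."""

    def tensor(scale):
        a = rng.normal(scale=scale, size=(3, 3))
        return 0.5 * (a + a.T)

    rads = []
    for _ in range(2):
        a_iso = rng.uniform(0.05, 0.5)
        a = a_iso * np.eye(3) + (tensor(0.1 * a_iso) if anisotropic else 0.0)
        g = 2.005 * np.eye(3) + (tensor(0.005) if anisotropic else 0.0)
        rads.append(RadicalSpec(g, (NucleusSpec("H", 0.5, a),)))
    if bz_mT is None:
        bz_mT = float(rng.choice([0.0, 10 ** rng.uniform(-2, 2)]))
    if kst_per_ns is None:
        kst_per_ns = float(10 ** rng.uniform(-4, 0))
    return SpinSystemSpec(
        radical_a=rads[0],
        radical_b=rads[1],
        k_s=0.2,
        k_st=kst_per_ns,
        field_mT=np.array([0.0, 0.0, bz_mT]),
        initial_state=initial_state,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
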