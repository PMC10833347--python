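import pytest

from phasekit.maps import map_from_phases
from phasekit.synthetic import (
    SyntheticSpec,
    build_structure,
    make_trace,
    medium_fixture,
    simulate_data,
    small_helix_fixture,
)

DOCK_SEQUENCE = "MKVLFDAGYTSERWHINPQCVLKFDMGTAYSEWRHINPQG"  # 40 aa, non-repetitive


@pytest.fixture(scope="session")
def small_fx():
    """10-residue helix, P1, 1.5 A."""
    return small_helix_fixture(seed=0)


@pytest.fixture(scope="session")
def medium_fx():
    """30-residue helix pair, P2(1), 2.0 A, 2% noise, 65 deg start."""
    return medium_fixture(seed=1)


@pytest.fixture(scope="session")
def dock_fx():
    """40-residue helix, P1, 1.5 A, with an exact-phase map."""
    spec = SyntheticSpec(sequence=DOCK_SEQUENCE, fold="helix",
                         spacegroup="P1", d_min=1.5)
    model, cell, sg, trace = build_structure(spec)
    true, obs = simulate_data(model, spec, cell, sg)
    dmap = map_from_phases(true, cell, sg, d_min=spec.d_min)
    return {"spec": spec, "model": model, "cell": cell, "sg": sg,
            "trace": trace, "true": true, "obs": obs, "map": dmap}


@pytest.fixture()
def half_trace(dock_fx):
    return make_trace(dock_fx["trace"], completeness=0.5,
                      displacement_rms=0.0, seed=3)
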