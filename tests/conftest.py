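import numpy as np
import pytest

from ebdims import (CAModel, DIMSParams, ENMTopology, HingeSpec,
                    build_ed_enm, make_hinge_models, run_transition)


def ca_model(coords, name="toy", chain="A", res_start=1):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return CAModel(name, np.full(n, chain), np.arange(res_start, res_start + n),
                   np.full(n, ""), np.full(n, "ALA"), coords)


@pytest.fixture(scope="session")
def hinge_models():
    """Open / mid / closed conformers of the default toy hinge."""
    return make_hinge_models(HingeSpec(n_intermediates=1))


@pytest.fixture(scope="session")
def hinge_topology(hinge_models):
    return build_ed_enm(hinge_models[0])


@pytest.fixture(scope="session")
def helix10():
    """Small compact 10-residue fixture (one helical turn and a half)."""
    spec = HingeSpec(n_per_domain=10)
    model = make_hinge_models(spec)[0]
    return ca_model(model.coords[:10], name="helix10")


@pytest.fixture(scope="session")
def two_bead():
    """Two beads joined by one spring of K=0.5 at d0=3.8 Å."""
    coords = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
    topo = ENMTopology(np.array([[0, 1]]), np.array([0.5]), np.array([3.8]),
                       coords)
    return ca_model(coords, name="dimer"), topo


@pytest.fixture(scope="session")
def hinge_forward_path(hinge_models):
    """One converged forward pathway on the toy hinge (seed 1)."""
    open_m, _, closed_m = hinge_models
    return run_transition(open_m, closed_m,
                          dims_params=DIMSParams(seed=1))
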