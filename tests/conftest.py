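import numpy as np
import pytest

from anmpath import (
    ANMModel,
    SearchSettings,
    Site,
    Structure,
    TransitionPathModel,
    TwoStatePotential,
    build_anm,
    make_toy_two_state,
)


def chain_sites(n, chain="A"):
    return tuple(Site(chain, i + 1, " ", "GLY") for i in range(n))


@pytest.fixture
def two_site_pot():
    """Two sites with reference distances 5 Å (well A) and 7 Å (well B), k=0.1.

    In the inter-site distance d the two wells are (k/2)(d-5)^2 and
    (k/2)(d-7)^2: the cusp is at d = 6 with energy 0.05 kcal/mol.
    """
    sites = chain_sites(2)
    a = Structure(sites, np.array([[0.0, 0, 0], [5.0, 0, 0]]), "a")
    b = Structure(sites, np.array([[0.0, 0, 0], [7.0, 0, 0]]), "b")
    return TwoStatePotential(build_anm(a), build_anm(b)), a, b


@pytest.fixture
def three_site_pair():
    """Two non-degenerate triangles, every pair in contact in both states."""
    sites = chain_sites(3)
    a = Structure(sites, np.array([[0.0, 0, 0], [5.0, 0, 0], [2.5, 4.0, 0]]), "a")
    b = Structure(sites, np.array([[0.0, 0, 0], [6.0, 0, 0], [3.0, 5.0, 0]]), "b")
    return a, b


@pytest.fixture(scope="session")
def helix_fit():
    """A fitted hinge transition on the well-conditioned helical toy."""
    a, b = make_toy_two_state(16, 150, 110, seed=1, geometry="helix")
    model = TransitionPathModel(a, b, spacing=0.1)
    return model, model.fit()


def ts_energy_distance_space(model_a: ANMModel, model_b: ANMModel) -> float:
    """Closed-form transition-state energy for all-pairs-connected networks.

    When every pair is a contact in both wells, the energy is a function of
    the pair-distance vector d alone: E_A = E0A + (k/2)|d - a|^2 with a the
    reference distances.  E_A - E_B is linear in d, so the cusp is the
    hyperplane c·d = gamma with c = b - a (element-wise, scaled by k) and
    the minimum of E_A on it is attained at the orthogonal projection of a:

        E_TS = E0A + (k/2) * (gamma - c·a)^2 / |c|^2.

    Independent of the Cartesian search; assumes equal k and contact maps.
    """
    assert model_a.n_contacts == model_b.n_contacts == model_a.n_sites * (model_a.n_sites - 1) // 2
    assert model_a.k == model_b.k
    a, b = model_a.ref_dists, model_b.ref_dists
    c = b - a
    gamma = 0.5 * (b @ b - a @ a) + (model_b.e0 - model_a.e0) / model_a.k
    t = (gamma - c @ a) / (c @ c)
    return model_a.e0 + 0.5 * model_a.k * t * t * (c @ c)
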