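"""Global reactivity descriptors: published-table oracles and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdftpep.errors import MissingDataError, UndefinedValueError
from cdftpep.global_reactivity import (ReactivityConfig,
                                       charge_transfer_powers,
                                       chemical_potential,
                                       classify_electrophile,
                                       classify_nucleophile,
                                       electronegativity, electrophilicity,
                                       global_descriptor_set, hardness,
                                       nucleophilicity, softness)

CONFIG = ReactivityConfig()

frontier_pairs = st.tuples(
    st.floats(-15.0, -0.2), st.floats(-10.0, 5.0)).filter(
        lambda hl: hl[1] - hl[0] > 1e-3)


@pytest.mark.parametrize("homo,lumo,expected", [
    (-6.697, -0.771, 3.734),   # Veraguamide G
    (-6.873, -0.717, 3.795),   # Veraguamide E
])
def test_electronegativity_matches_published(homo, lumo, expected):
    assert electronegativity(homo, lumo) == pytest.approx(expected,
                                                          abs=5e-4)


def test_electronegativity_symmetric_frontier_is_zero():
    assert electronegativity(-3.2, 3.2) == 0.0
    assert chemical_potential(-3.2, 3.2) == 0.0


@pytest.mark.parametrize("homo,lumo,expected", [
    (-6.635, -0.884, 5.751),   # Veraguamide A
    (-6.156, 0.0, 6.156),
])
def test_hardness_is_full_gap(homo, lumo, expected):
    assert hardness(homo, lumo) == pytest.approx(expected, abs=5e-4)


def test_hardness_warns_on_inverted_gap_but_returns():
    with pytest.warns(UserWarning, match="gap"):
        assert hardness(-1.0, -2.0) == pytest.approx(-1.0)


@pytest.mark.parametrize("eta,expected", [
    (6.156, 0.162), (5.751, 0.174), (1.0, 1.0),
])
def test_softness_is_reciprocal_hardness(eta, expected):
    assert softness(eta) == pytest.approx(expected, abs=5e-4)


def test_softness_undefined_at_zero_hardness():
    with pytest.raises(UndefinedValueError):
        softness(0.0)


@pytest.mark.parametrize("homo,lumo,expected", [
    (-6.812, -0.993, 1.309),   # Veraguamide C
    (-6.635, -0.884, 1.229),   # (7.519)^2 / (8 * 5.751)
])
def test_electrophilicity_chi2_over_2eta(homo, lumo, expected):
    assert electrophilicity(homo, lumo) == pytest.approx(expected, abs=5e-4)


def test_electrophilicity_audit_variant_is_double():
    w = electrophilicity(-6.0, -1.0)
    assert electrophilicity(-6.0, -1.0, four_eta=True) == pytest.approx(2 * w)


@pytest.mark.parametrize("homo,lumo,expected", [
    (-6.635, -0.884, (4.697, 0.937, 5.634)),   # Veraguamide A
    (-6.717, -1.016, (4.912, 1.045, 5.957)),   # Veraguamide F
])
def test_charge_transfer_powers_match_published(homo, lumo, expected):
    got = charge_transfer_powers(homo, lumo)
    assert got == pytest.approx(expected, abs=2.5e-3)


@pytest.mark.parametrize("homo,expected", [
    (-6.661, 2.132),   # Veraguamide D
    (-6.873, 1.920),   # Veraguamide E
    (CONFIG.tce_homo_reference, 0.0),
])
def test_nucleophilicity_is_tce_shifted_homo(homo, expected):
    assert nucleophilicity(homo, CONFIG) == pytest.approx(expected,
                                                          abs=5e-4)


@pytest.mark.parametrize("omega,band", [
    (1.229, "moderate"), (0.0, "marginal"), (1.51, "strong"),
    (0.8, "moderate"), (1.5, "moderate"),   # boundary ties → middle band
])
def test_electrophile_bands(omega, band):
    assert classify_electrophile(omega, CONFIG) == band


@pytest.mark.parametrize("nu,band", [
    (1.981, "marginal"), (2.132, "moderate"), (5.0, "strong"),
    (2.0, "marginal"), (3.0, "moderate"),    # boundary conventions
])
def test_nucleophile_bands(nu, band):
    assert classify_nucleophile(nu, CONFIG) == band


def test_descriptor_set_for_veraguamide_b(veraguamides_by_id):
    g = global_descriptor_set(veraguamides_by_id["Veraguamide B"], CONFIG)
    assert (g.chi, g.eta, g.softness, g.omega) == pytest.approx(
        (3.790, 5.695, 0.176, 1.261), abs=2.5e-3)
    assert (g.nu, g.omega_minus, g.omega_plus,
            g.net_electrophilicity) == pytest.approx(
        (2.156, 4.772, 0.983, 5.755), abs=2.5e-3)


def test_all_seven_molecules_match_reference_table(veraguamides,
                                                   descriptor_reference):
    for triad in veraguamides:
        g = global_descriptor_set(triad, CONFIG)
        ref = descriptor_reference.loc[triad.molecule_id]
        for col in descriptor_reference.columns:
            assert getattr(g, col) == pytest.approx(ref[col], abs=0.005), \
                f"{triad.molecule_id} {col}"


def test_descriptor_set_requires_neutral_orbitals(veraguamides_by_id):
    import copy
    broken = copy.deepcopy(veraguamides_by_id["Veraguamide A"])
    broken.neutral.lumo = None
    with pytest.raises(MissingDataError):
        global_descriptor_set(broken, CONFIG)


@settings(derandomize=True, max_examples=1000)
@given(hl=frontier_pairs)
def test_identity_donating_minus_accepting_equals_chi(hl):
    homo, lumo = hl
    w_minus, w_plus, net = charge_transfer_powers(homo, lumo)
    assert w_minus - w_plus == pytest.approx(
        electronegativity(homo, lumo), abs=1e-9)
    assert net == w_minus + w_plus  # exact by construction


@settings(derandomize=True, max_examples=200)
@given(hl=frontier_pairs)
def test_softness_hardness_product_is_one(hl):
    eta = hardness(*hl)
    assert softness(eta) * eta == pytest.approx(1.0, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(homo=st.floats(-15, -1), shift=st.floats(-5, 5))
def test_nucleophilicity_translation_invariance(homo, shift):
    base = nucleophilicity(homo, CONFIG)
    shifted = nucleophilicity(
        homo + shift,
        ReactivityConfig(tce_homo_reference=CONFIG.tce_homo_reference
                         + shift))
    assert shifted == pytest.approx(base, abs=1e-12)


def test_electrophilicity_monotone_in_electronegativity_at_fixed_gap():
    gap = 5.0
    omegas = []
    for chi in (0.5, 1.5, 3.0, 4.5):
        homo = -(chi + gap / 2)
        lumo = -(chi - gap / 2)
        omegas.append(electrophilicity(homo, lumo))
    assert omegas == sorted(omegas) and len(set(omegas)) == len(omegas)
    assert math.isclose(omegas[1] / omegas[0], 9.0)  # quadratic in chi
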