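"""Grid Fukui functions, dual descriptor and condensed variants."""

import numpy as np
import pytest

from cdftpep.cube import DensityGrid
from cdftpep.errors import GridMismatchError, SchemaError
from cdftpep.local_reactivity import (CondensedChargesTriad, GridTriad,
                                      check_grid_compat, condensed_fukui,
                                      dual_descriptor, electrophilic_fukui,
                                      integrate_grid, nucleophilic_fukui)
from cdftpep.synthetic import GaussianDensitySpec, gaussian_density_triad


@pytest.fixture(scope="module")
def triad():
    return gaussian_density_triad(
        GaussianDensitySpec(grid_shape=(48, 48, 48)))


@pytest.fixture(scope="module")
def two_center_triad():
    # the added electron of the N+1 species sits entirely on center 2
    return gaussian_density_triad(GaussianDensitySpec(
        centers=((-2.0, 0.0, 0.0), (2.0, 0.0, 0.0)),
        widths=(0.8, 0.8),
        electron_counts=(1.0, 2.0, 3.0),
        grid_shape=(48, 48, 48),
        grid_extent=7.0,
        weights_nminus=(0.5, 0.5),
        weights_n=(0.5, 0.5),
        weights_nplus=(1.0 / 3.0, 2.0 / 3.0),
    ))


def test_grid_compat_self_passes(triad):
    assert check_grid_compat(triad.rho_n, triad.rho_n).ok


def test_grid_compat_names_mismatched_dimension(triad):
    other = DensityGrid(origin=triad.rho_n.origin,
                        axes=triad.rho_n.axes,
                        values=triad.rho_n.values[:, :, :-1])
    report = check_grid_compat(triad.rho_n, other)
    assert not report.ok and "dimension(s) [2]" in report.problems[0]


def test_grid_compat_origin_tolerance(triad):
    shifted = DensityGrid(origin=triad.rho_n.origin + 1e-3,
                          axes=triad.rho_n.axes,
                          values=triad.rho_n.values)
    report = check_grid_compat(triad.rho_n, shifted)
    assert not report.ok and "origin deviation" in report.problems[0]


def test_fukui_functions_integrate_to_one_electron(triad):
    assert integrate_grid(nucleophilic_fukui(triad)) == pytest.approx(
        1.0, abs=0.01)
    assert integrate_grid(electrophilic_fukui(triad)) == pytest.approx(
        1.0, abs=0.01)


def test_dual_descriptor_integrates_to_zero(triad):
    nff = nucleophilic_fukui(triad)
    eff = electrophilic_fukui(triad)
    dd = dual_descriptor(nff, eff)
    assert integrate_grid(dd) == pytest.approx(0.0, abs=0.02)
    # linearity: integral(DD) = integral(NFF) - integral(EFF) exactly
    assert integrate_grid(dd) == pytest.approx(
        integrate_grid(nff) - integrate_grid(eff), rel=1e-9, abs=1e-9)


def test_identical_densities_give_zero_fukui(triad):
    same = GridTriad(triad.rho_n, triad.rho_n, triad.rho_n)
    assert np.all(nucleophilic_fukui(same).values == 0.0)
    assert np.all(electrophilic_fukui(same).values == 0.0)


def test_equal_shape_densities_cancel_in_dual_descriptor(triad):
    # identical center/width for every species: NFF and EFF share the same
    # spatial shape, so DD vanishes identically up to rounding
    nff = nucleophilic_fukui(triad)
    eff = electrophilic_fukui(triad)
    dd = dual_descriptor(nff, eff)
    assert np.max(np.abs(dd.values)) < 1e-12 * np.max(triad.rho_n.values)


def test_dual_descriptor_sign_localizes_added_electron(two_center_triad):
    nff = nucleophilic_fukui(two_center_triad)
    eff = electrophilic_fukui(two_center_triad)
    dd = dual_descriptor(nff, eff)
    assert integrate_grid(dd) == pytest.approx(0.0, abs=0.02)
    n = dd.shape[0]
    # center 1 at x=-2 (left half), center 2 at x=+2 (right half)
    left = dd.values[: n // 2].sum()
    right = dd.values[n // 2:].sum()
    assert right > 0 > left
    assert dd.values.max() > 0 > dd.values.min()  # both signs attained


def test_mismatched_grids_raise(triad):
    other = DensityGrid(origin=triad.rho_n.origin + 0.5,
                        axes=triad.rho_n.axes,
                        values=triad.rho_n.values)
    with pytest.raises(GridMismatchError):
        dual_descriptor(triad.rho_n, other)
    bad = GridTriad(triad.rho_nminus, triad.rho_n, other)
    with pytest.raises(GridMismatchError):
        nucleophilic_fukui(bad)


@pytest.mark.parametrize("values,volume,expected", [
    (0.0, 1.0, 0.0),
    (3.0, 0.125, 3.0 * 0.125 * 27),   # constant grid: c * V
])
def test_integrate_grid_closed_forms(values, volume, expected):
    step = volume ** (1 / 3)
    grid = DensityGrid(origin=[0, 0, 0], axes=np.eye(3) * step,
                       values=np.full((3, 3, 3), values))
    assert integrate_grid(grid) == pytest.approx(expected, rel=1e-9)


def test_condensed_fukui_hand_example():
    triad = CondensedChargesTriad(
        atom_labels=["X", "Y"],
        q_nminus=[0.6, 0.4], q_n=[0.1, -0.1], q_nplus=[-0.5, -0.5])
    df = condensed_fukui(triad)
    assert list(df["f_plus"]) == pytest.approx([0.6, 0.4])
    assert list(df["f_minus"]) == pytest.approx([0.5, 0.5])
    assert list(df["dual"]) == pytest.approx([0.1, -0.1])
    assert df["f_plus"].sum() == pytest.approx(1.0, abs=0.05)


def test_condensed_fukui_degenerate_cases():
    one = condensed_fukui(CondensedChargesTriad(
        ["A"], q_nminus=[1.0], q_n=[0.0], q_nplus=[-1.0]))
    assert one.loc["A", "f_plus"] == 1.0
    assert one.loc["A", "f_minus"] == 1.0
    assert one.loc["A", "dual"] == 0.0


def test_condensed_fukui_rejects_bad_schema():
    with pytest.raises(SchemaError, match="entries"):
        condensed_fukui(CondensedChargesTriad(
            ["A", "B"], q_nminus=[1.0], q_n=[0.0, 0.0],
            q_nplus=[-0.5, -0.5]))
    with pytest.raises(SchemaError, match="charge sums"):
        condensed_fukui(CondensedChargesTriad(
            ["A"], q_nminus=[0.3], q_n=[0.0], q_nplus=[-1.0]))


def test_condensed_agrees_with_grid_basin_integrals(two_center_triad):
    """Charge-difference and density-difference conventions must agree.

    Partition the grid into two half-space basins (one per center) and
    compare basin integrals of NFF against condensed f⁺ from the implied
    per-center charges.
    """
    nff = nucleophilic_fukui(two_center_triad)
    n = nff.shape[0]
    vol = nff.voxel_volume
    basin1 = nff.values[: n // 2].sum() * vol
    basin2 = nff.values[n // 2:].sum() * vol
    # implied per-center electron populations -> charges q = -population
    # N species: 1 e per center; N+1 species: 1 and 2 e
    charges = CondensedChargesTriad(
        ["c1", "c2"],
        q_nminus=[-0.5, -0.5], q_n=[-1.0, -1.0], q_nplus=[-1.0, -2.0])
    df = condensed_fukui(charges)
    assert basin1 == pytest.approx(df.loc["c1", "f_plus"], abs=0.02)
    assert basin2 == pytest.approx(df.loc["c2", "f_plus"], abs=0.02)
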