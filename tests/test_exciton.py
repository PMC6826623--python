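"""Exciton Hamiltonian, rotational strengths, spectra, and classification."""

import numpy as np
import pytest

from quadbind import (
    GeometryRecipe,
    apply_shift_scale,
    assign_transitions,
    build_hamiltonian,
    classify_g4_signature,
    diagonalize,
    dipole_coupling,
    ensemble_average,
    exciton_calculation,
    rotational_strengths,
    snapshot_ensemble,
    snapshot_spectrum,
)
from quadbind.constants import EV_TO_CM, NM_EV
from quadbind.exciton import (
    ChromophoreTransition,
    ExcitonError,
    SpectrumGrid,
    default_grid,
    load_transition_table,
    match_shift_scale,
)
from quadbind.structures import StructureModel

from conftest import random_rotation


def _t(e, mu, c, idx=-1):
    return ChromophoreTransition(e, np.asarray(mu, float), np.asarray(c, float), idx)


def random_transitions(rng, n, span=8.0):
    out = []
    while len(out) < n:
        c = rng.uniform(-span, span, 3)
        if all(np.linalg.norm(c - t.center) > 1.5 for t in out):
            out.append(_t(rng.uniform(4.0, 5.5), rng.normal(size=3), c, len(out)))
    return out


# ---------------------------------------------------------------------------
# transition assignment
# ---------------------------------------------------------------------------

def test_assign_transitions_count(g4_parallel):
    table = load_transition_table()
    trs = assign_transitions(g4_parallel, table)
    assert len(trs) == 12 * len(table["G"])


def test_assign_excludes_ligand():
    from quadbind import build_ideal_g4

    model = build_ideal_g4(
        GeometryRecipe("g4", n_tetrads=2, ligand_pose="end_stack_in")
    )
    trs = assign_transitions(model)
    assert len(trs) == 8 * len(load_transition_table()["G"])


def test_assign_zero_magnitude_entry_retained(duplex14):
    table = {
        "A": [{"energy_ev": 4.8, "mu_debye": 0.0, "angle_deg": 0.0}],
        "T": [{"energy_ev": 4.7, "mu_debye": 0.0, "angle_deg": 0.0}],
    }
    trs = assign_transitions(duplex14, table)
    assert len(trs) == 28
    assert all(np.allclose(t.dipole, 0) for t in trs)


def test_assign_missing_base_type_raises(duplex14):
    with pytest.raises(ExcitonError, match="missing"):
        assign_transitions(
            duplex14, {"A": [{"energy_ev": 4.8, "mu_debye": 1, "angle_deg": 0}]}
        )


def test_assign_rotation_rotates_dipoles(duplex14, rng):
    trs0 = assign_transitions(duplex14)
    Q = random_rotation(rng)
    rotated = StructureModel(0, [r.transformed(Q, np.zeros(3)) for r in duplex14.residues])
    trs1 = assign_transitions(rotated)
    for t0, t1 in zip(trs0, trs1):
        assert np.allclose(t1.dipole, Q @ t0.dipole, atol=1e-8)
        assert np.allclose(t1.center, Q @ t0.center, atol=1e-8)


# ---------------------------------------------------------------------------
# dipole coupling
# ---------------------------------------------------------------------------

def test_coupling_perpendicular_reference_value():
    # independent constant: (1 D)^2/(1 A)^3 over hc, in cm^-1
    c_indep = 1e-12 / (6.62607015e-27 * 2.99792458e10)
    t1 = _t(4.5, [0, 1, 0], [0, 0, 0])
    t2 = _t(4.5, [0, 1, 0], [10, 0, 0])
    v = dipole_coupling(t1, t2)
    assert np.isclose(v, c_indep / 1000.0, rtol=1e-4)
    assert np.isclose(v, 5.0341, atol=2e-4)


def test_coupling_orientation_factor_head_to_tail():
    perp = dipole_coupling(_t(4.5, [0, 1, 0], [0, 0, 0]), _t(4.5, [0, 1, 0], [10, 0, 0]))
    coll = dipole_coupling(_t(4.5, [1, 0, 0], [0, 0, 0]), _t(4.5, [1, 0, 0], [10, 0, 0]))
    assert np.isclose(coll, -2.0 * perp, rtol=1e-12)


def test_coupling_inverse_cube_distance():
    v1 = dipole_coupling(_t(4.5, [0, 1, 0], [0, 0, 0]), _t(4.5, [0, 1, 0], [5, 0, 0]))
    v2 = dipole_coupling(_t(4.5, [0, 1, 0], [0, 0, 0]), _t(4.5, [0, 1, 0], [10, 0, 0]))
    assert np.isclose(v1, 8.0 * v2, rtol=1e-12)


def test_coupling_coincident_centers_raise():
    with pytest.raises(ExcitonError, match="coincident"):
        dipole_coupling(_t(4.5, [0, 1, 0], [0, 0, 0]), _t(4.5, [1, 0, 0], [0, 0, 0.05]))


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

def test_hamiltonian_single_site():
    H = build_hamiltonian([_t(4.5, [1, 0, 0], [0, 0, 0])])
    assert H.shape == (1, 1)
    assert np.isclose(H[0, 0], 4.5 * EV_TO_CM)


def test_hamiltonian_homodimer_eigenvalues():
    t1 = _t(4.5, [0, 3, 0], [0, 0, 0])
    t2 = _t(4.5, [0, 3, 0], [0, 0, 3.4])
    H = build_hamiltonian([t1, t2])
    v = dipole_coupling(t1, t2)
    res = diagonalize(H)
    e0 = 4.5 * EV_TO_CM
    assert np.allclose(res.energies, sorted([e0 - abs(v), e0 + abs(v)]), atol=1e-8)


def test_hamiltonian_matches_bruteforce_pairwise_loop(rng):
    trs = random_transitions(rng, 6)
    H = build_hamiltonian(trs)
    n = len(trs)
    H_ref = np.zeros((n, n))
    for i in range(n):
        H_ref[i, i] = trs[i].site_energy_ev * EV_TO_CM
        for j in range(n):
            if i == j:
                continue
            mi, mj = trs[i].dipole, trs[j].dipole
            rv = trs[j].center - trs[i].center
            r = np.linalg.norm(rv)
            rh = rv / r
            H_ref[i, j] = 5034.12 * (mi @ mj - 3 * (mi @ rh) * (mj @ rh)) / r**3
    assert np.allclose(H, H_ref, atol=1e-10)
    assert np.allclose(H, H.T, atol=1e-12)


def test_hamiltonian_intra_residue_coupling_configurable():
    t1 = _t(4.5, [1, 0, 0], [0, 0, 0], idx=0)
    t2 = _t(5.0, [0, 1, 0], [0, 0, 0], idx=0)  # same residue, same center
    H = build_hamiltonian([t1, t2])
    assert H[0, 1] == 0.0
    H2 = build_hamiltonian([t1, t2], intra_base_coupling=123.0)
    assert H2[0, 1] == 123.0


# ---------------------------------------------------------------------------
# diagonalization
# ---------------------------------------------------------------------------

def test_diagonalize_diagonal_matrix():
    res = diagonalize(np.diag([3.0, 1.0, 2.0]))
    assert np.allclose(res.energies, [1, 2, 3])
    assert np.allclose(np.abs(res.coefficients), np.eye(3)[:, [1, 2, 0]])


def test_diagonalize_symmetric_dimer_closed_form():
    E, V = 36000.0, 250.0
    res = diagonalize(np.array([[E, V], [V, E]]))
    assert np.allclose(res.energies, [E - V, E + V])
    s = 1 / np.sqrt(2)
    assert np.allclose(np.abs(res.coefficients), [[s, s], [s, s]], atol=1e-12)


def test_diagonalize_reconstruction_and_orthonormality(rng):
    A = rng.normal(size=(8, 8))
    H = A + A.T
    res = diagonalize(H)
    U, lam = res.coefficients, res.energies
    assert np.linalg.norm(U @ np.diag(lam) @ U.T - H) < 1e-8
    assert np.allclose(U.T @ U, np.eye(8), atol=1e-8)


def test_diagonalize_rejects_asymmetric():
    with pytest.raises(ExcitonError, match="symmetric"):
        diagonalize(np.array([[1.0, 2.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# rotational strengths
# ---------------------------------------------------------------------------

def test_parallel_coplanar_dipoles_give_zero_R(rng):
    trs = [_t(4.6, [2, 0, 0], [x, 0, 0], i) for i, x in enumerate([0, 4, 8, 12.0])]
    res = rotational_strengths(diagonalize(build_hamiltonian(trs)), trs)
    assert np.allclose(res.rotational_strengths, 0, atol=1e-10)


def test_zero_sum_rule_random_systems(rng):
    for _ in range(100):
        trs = random_transitions(rng, int(rng.integers(2, 9)))
        res = rotational_strengths(diagonalize(build_hamiltonian(trs)), trs)
        R = res.rotational_strengths
        scale = np.abs(R).max()
        if scale > 0:
            assert abs(R.sum()) / scale < 1e-8


def closed_form_dimer(t1, t2):
    """Independent coupled-oscillator dimer: energies E0 -/+ |V| and
    R = -/+ (pi nu0 / 2) R12.(mu1 x mu2) for the upper/lower state."""
    e0 = t1.site_energy_ev * EV_TO_CM
    v = dipole_coupling(t1, t2)
    chirality = np.dot(t2.center - t1.center, np.cross(t1.dipole, t2.dipole))
    r_plus = -(np.pi * e0 / 2.0) * chirality  # state at e0 + v
    if v >= 0:
        return np.array([e0 - v, e0 + v]), np.array([-r_plus, r_plus])
    return np.array([e0 + v, e0 - v]), np.array([r_plus, -r_plus])


def test_dimer_matrix_method_matches_closed_form(rng):
    for _ in range(100):
        e = rng.uniform(4.0, 5.5)
        t1 = _t(e, rng.normal(size=3), rng.normal(size=3), 0)
        t2 = _t(e, rng.normal(size=3),
                t1.center + rng.normal(size=3) * 2 + [0, 0, 4], 1)
        res = rotational_strengths(
            diagonalize(build_hamiltonian([t1, t2])), [t1, t2],
            nu0_cm=e * EV_TO_CM,
        )
        e_cf, r_cf = closed_form_dimer(t1, t2)
        assert np.allclose(res.energies, e_cf, rtol=1e-8)
        scale = max(np.abs(r_cf).max(), 1e-300)
        assert np.allclose(res.rotational_strengths, r_cf, atol=1e-8 * scale)


def test_right_handed_twisted_dimer_long_wavelength_positive():
    """+36 deg twisted stack (right-handed): the low-energy exciton carries
    the positive rotational strength."""
    mu = 3.0
    t1 = _t(4.6, [mu, 0, 0], [0, 0, 0], 0)
    t2 = _t(4.6, [mu * np.cos(np.pi / 5), mu * np.sin(np.pi / 5), 0], [0, 0, 3.4], 1)
    res = rotational_strengths(diagonalize(build_hamiltonian([t1, t2])), [t1, t2])
    assert res.rotational_strengths[0] > 0  # lowest energy = longest wavelength
    assert res.rotational_strengths[1] < 0


def test_rigid_motion_invariance(duplex14, rng):
    res0, _ = exciton_calculation(duplex14)
    Q = random_rotation(rng)
    t = rng.normal(scale=20, size=3)
    moved = StructureModel(0, [r.transformed(Q, t) for r in duplex14.residues])
    res1, _ = exciton_calculation(moved)
    assert np.allclose(res1.energies, res0.energies, rtol=1e-8)
    scale = np.abs(res0.rotational_strengths).max()
    assert np.allclose(res1.rotational_strengths, res0.rotational_strengths,
                       atol=1e-8 * scale)


def test_mirror_antisymmetry(g4_parallel):
    res0, _ = exciton_calculation(g4_parallel)
    flip = np.diag([1.0, 1.0, -1.0])
    mirrored = StructureModel(
        0, [r.transformed(flip, np.zeros(3)) for r in g4_parallel.residues]
    )
    res1, _ = exciton_calculation(mirrored)
    assert np.allclose(res1.energies, res0.energies, rtol=1e-8)
    scale = np.abs(res0.rotational_strengths).max()
    assert np.allclose(res1.rotational_strengths, -res0.rotational_strengths,
                       atol=1e-8 * scale)
    s0 = snapshot_spectrum(res0)
    s1 = snapshot_spectrum(res1)
    assert np.allclose(s1.intensity, -s0.intensity, atol=1e-8 * np.abs(s0.intensity).max())


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _single_state_result(energy_ev, R):
    from quadbind.exciton import ExcitonResult

    return ExcitonResult(
        energies=np.array([energy_ev * EV_TO_CM]),
        coefficients=np.eye(1),
        rotational_strengths=np.array([R], dtype=float),
    )


def test_spectrum_zero_strength_is_flat():
    spec = snapshot_spectrum(_single_state_result(4.5, 0.0))
    assert np.allclose(spec.intensity, 0.0)


def test_spectrum_single_band_peaks_at_state_wavelength():
    spec = snapshot_spectrum(_single_state_result(4.5, 2.0), sigma_ev=0.1)
    lam_peak = spec.wavelengths[np.argmax(spec.intensity)]
    assert abs(lam_peak - NM_EV / 4.5) < 1.0
    assert spec.intensity.max() > 0


def test_spectrum_energy_integral_recovers_total_strength(rng):
    trs = random_transitions(rng, 5)
    res = rotational_strengths(diagonalize(build_hamiltonian(trs)), trs)
    res.rotational_strengths = np.abs(res.rotational_strengths) + 1.0
    grid = np.linspace(120.0, 600.0, 4001)
    spec = snapshot_spectrum(res, sigma_ev=0.12, grid_nm=grid)
    e = NM_EV / grid
    total = -np.trapezoid(spec.intensity, e)  # e descends along the nm grid
    assert np.isclose(total, res.rotational_strengths.sum(), rtol=1e-3)


def test_spectrum_rejects_bad_sigma():
    with pytest.raises(ExcitonError):
        snapshot_spectrum(_single_state_result(4.5, 1.0), sigma_ev=0.0)


def test_ensemble_average_identity_and_cancellation():
    s = snapshot_spectrum(_single_state_result(4.5, 2.0))
    assert np.allclose(ensemble_average([s]).intensity, s.intensity)
    neg = SpectrumGrid(s.wavelengths.copy(), -s.intensity)
    assert np.allclose(ensemble_average([s, neg]).intensity, 0.0)
    assert np.allclose(ensemble_average([s] * 5).intensity, s.intensity)


def test_ensemble_average_grid_mismatch():
    s1 = snapshot_spectrum(_single_state_result(4.5, 1.0), grid_nm=default_grid())
    s2 = snapshot_spectrum(_single_state_result(4.5, 1.0),
                           grid_nm=default_grid(201, 341))
    with pytest.raises(ExcitonError, match="grid"):
        ensemble_average([s1, s2])


def test_shift_scale_identity():
    s = snapshot_spectrum(_single_state_result(4.2, 1.5))
    out = apply_shift_scale(s, 0.0, 1.0)
    assert np.allclose(out.intensity, s.intensity, atol=1e-12)
    assert out.shift_applied == 0.0 and out.scale_applied == 1.0


def test_shift_moves_band_to_higher_energy():
    grid = np.linspace(230.0, 340.0, 2201)
    s = snapshot_spectrum(_single_state_result(4.0, 2.0), sigma_ev=0.1, grid_nm=grid)
    shifted = apply_shift_scale(s, 0.2, 1.0)
    lam_peak = shifted.wavelengths[np.argmax(shifted.intensity)]
    assert abs(lam_peak - NM_EV / 4.2) < 0.5  # ~295.2 nm
    assert shifted.shift_applied == 0.2


def test_shifts_compose_additively():
    grid = np.linspace(200.0, 400.0, 4001)
    s = snapshot_spectrum(_single_state_result(4.2, 1.0), sigma_ev=0.15, grid_nm=grid)
    once = apply_shift_scale(s, 0.3, 2.0)
    twice = apply_shift_scale(apply_shift_scale(s, 0.1, 2.0), 0.2, 1.0)
    assert np.isclose(once.shift_applied, twice.shift_applied)
    assert np.isclose(once.scale_applied, twice.scale_applied)
    m = np.abs(once.intensity).max()
    assert np.allclose(once.intensity, twice.intensity, atol=2e-3 * m)


def test_match_shift_scale_recovers_known_transform():
    grid = np.linspace(200.0, 400.0, 2001)
    s = snapshot_spectrum(_single_state_result(4.4, 1.0), sigma_ev=0.15, grid_nm=grid)
    ref = apply_shift_scale(s, 0.25, 3.0)
    shift, scale = match_shift_scale(s, ref, shift_range_ev=(-0.5, 0.5), n_shift=101)
    assert abs(shift - 0.25) < 0.02
    assert abs(scale - 3.0) < 0.15


# ---------------------------------------------------------------------------
# duplex couplet and classification
# ---------------------------------------------------------------------------

def test_bdna_ensemble_conservative_couplet():
    """A jittered right-handed B-DNA duplex ensemble yields a conservative
    CD with the positive lobe at longer wavelength than the negative one."""
    recipe = GeometryRecipe("duplex", sequence="A" * 14)
    models = snapshot_ensemble(recipe, 10, seed=17)
    spectra = []
    for m in models:
        res, _ = exciton_calculation(m)
        spectra.append(snapshot_spectrum(res))
    avg = ensemble_average(spectra)
    lam_pos = avg.wavelengths[np.argmax(avg.intensity)]
    lam_neg = avg.wavelengths[np.argmin(avg.intensity)]
    assert avg.intensity.max() > 0 and avg.intensity.min() < 0
    assert lam_pos > lam_neg


def synthetic_signature(bands, width=8.0):
    wl = default_grid()
    inten = np.zeros_like(wl)
    for center, sign in bands:
        inten += sign * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return SpectrumGrid(wl, inten)


@pytest.mark.parametrize(
    "bands,expected",
    [
        ([(240, -1), (265, +1)], "parallel"),
        ([(260, -1), (295, +1)], "antiparallel"),
        ([(240, -1), (270, +1), (290, +1)], "hybrid"),
    ],
)
def test_classifier_assigns_topologies(bands, expected):
    assert classify_g4_signature(synthetic_signature(bands)) == expected


def test_classifier_flat_spectrum_unknown():
    spec = SpectrumGrid(default_grid(), np.zeros(701))
    assert classify_g4_signature(spec) == "unknown"


def test_classifier_ambiguous_extrema_unknown():
    # one lone positive band matches no signature's full pattern
    assert classify_g4_signature(synthetic_signature([(265, +1)])) == "unknown"
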