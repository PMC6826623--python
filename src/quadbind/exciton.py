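"""Frenkel exciton model of electronic circular dichroism for stacked
nucleobase chromophores.

One electronic transition per (residue, table entry) is placed at the base
ring centroid and oriented in the base plane. Site energies occupy the
Hamiltonian diagonal; off-diagonal couplings follow the point-dipole
(ideal-dipole) approximation. Diagonalization yields excitonic states whose
rotational strengths are computed with the electric-dipole-only
coupled-oscillator matrix method,

    R_k = -(pi nu0 / 2) * c_k^T A c_k,   A_ij = R_ij . (mu_i x mu_j),

with nu0 the mean site wavenumber, dipoles in Debye and separations in
Angstrom. The sign convention makes the long-wavelength component of a
right-handed twisted dimer positive, matching the textbook exciton couplet.
Because every state shares the nu0 prefactor and tr(A) = 0, the rotational
strengths of any system without intrinsic monomer terms sum exactly to zero
(conservative spectrum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.signal import find_peaks

from .constants import DIPOLE_COUPLING_CM, EV_TO_CM, NM_EV
from .structures import StructureModel, base_frame


class ExcitonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromophoreTransition:
    """One localized electronic transition: site energy (eV), electric
    transition dipole (Debye, lab frame), and dipole center (Angstrom)."""

    site_energy_ev: float
    dipole: np.ndarray
    center: np.ndarray
    residue_index: int = -1
    label: str = ""


def load_transition_table(path=None) -> dict[str, list[dict]]:
    """Load a per-base-type transition parameter table.

    Defaults to the packaged table of representative monomer values. The
    format is ``{"G": [{"energy_ev", "mu_debye", "angle_deg"}, ...], ...}``.
    """
    if path is None:
        text = resources.files("quadbind.params").joinpath(
            "base_transitions.json"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {k: v for k, v in raw.items() if not k.startswith("_")}


def assign_transitions(model: StructureModel,
                       params: dict[str, list[dict]] | None = None
                       ) -> list[ChromophoreTransition]:
    """One transition per (nucleobase residue, table entry). Dipoles are
    oriented in each base's instantaneous plane:
    mu = mu_debye * (cos(angle) x_axis + sin(angle) y_axis).
    Ligand dummy residues are excluded."""
    if params is None:
        params = load_transition_table()
    transitions = []
    for idx, res in enumerate(model.residues):
        if res.is_ligand:
            continue
        if res.name not in params:
            raise ExcitonError(f"base type {res.name!r} missing from parameter table")
        frame = base_frame(res)
        for j, entry in enumerate(params[res.name]):
            phi = np.deg2rad(entry["angle_deg"])
            mu = entry["mu_debye"] * (
                np.cos(phi) * frame.x_axis + np.sin(phi) * frame.y_axis
            )
            transitions.append(
                ChromophoreTransition(
                    site_energy_ev=entry["energy_ev"],
                    dipole=mu,
                    center=frame.origin.copy(),
                    residue_index=idx,
                    label=f"{res.name}{res.number}.{j}",
                )
            )
    return transitions


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

def dipole_coupling(t_i: ChromophoreTransition, t_j: ChromophoreTransition
                    ) -> float:
    """Point-dipole coupling in cm^-1:
    V = C [mu_i.mu_j - 3 (mu_i.r)(mu_j.r)] / r^3,
    C = 5034.12 cm^-1 per Debye^2/A^3."""
    r_vec = t_j.center - t_i.center
    r = np.linalg.norm(r_vec)
    if r <= 0.1:
        raise ExcitonError(f"coincident transition centers (r = {r:.3g} A)")
    rhat = r_vec / r
    kappa_mu2 = np.dot(t_i.dipole, t_j.dipole) - 3.0 * np.dot(
        t_i.dipole, rhat
    ) * np.dot(t_j.dipole, rhat)
    return DIPOLE_COUPLING_CM * kappa_mu2 / r**3


def build_hamiltonian(transitions: list[ChromophoreTransition],
                      intra_base_coupling: float = 0.0) -> np.ndarray:
    """N x N real symmetric exciton Hamiltonian in cm^-1. Diagonal: site
    energies (converted from eV). Off-diagonal: point-dipole couplings;
    transitions sharing a residue (coincident centers) get the configurable
    intra-base coupling instead (default 0)."""
    n = len(transitions)
    if n < 1:
        raise ExcitonError("need at least one transition")
    H = np.zeros((n, n))
    for i, t in enumerate(transitions):
        H[i, i] = t.site_energy_ev * EV_TO_CM
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = transitions[i], transitions[j]
            if ti.residue_index == tj.residue_index and ti.residue_index >= 0:
                v = intra_base_coupling
            else:
                v = dipole_coupling(ti, tj)
            H[i, j] = H[j, i] = v
    return H


@dataclass
class ExcitonResult:
    """Diagonalized exciton problem: ascending energies (cm^-1), orthonormal
    eigenvector columns, and per-state rotational strengths (reduced units,
    D^2 A cm^-1)."""

    energies: np.ndarray
    coefficients: np.ndarray
    rotational_strengths: np.ndarray | None = None


def diagonalize(H: np.ndarray) -> ExcitonResult:
    """Eigendecomposition with a deterministic sign fix: each eigenvector's
    first nonzero coefficient is made positive."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ExcitonError("Hamiltonian must be square")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ExcitonError("Hamiltonian must be symmetric")
    energies, coeffs = np.linalg.eigh(H)
    for k in range(coeffs.shape[1]):
        col = coeffs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coeffs[:, k] = -col
    return ExcitonResult(energies=energies, coefficients=coeffs)


def rotational_strengths(result: ExcitonResult,
                         transitions: list[ChromophoreTransition],
                         nu0_cm: float | None = None,
                         per_state_nu: bool = False) -> ExcitonResult:
    """Fill in coupled-oscillator rotational strengths.

    By default all states share the mean site wavenumber nu0 as prefactor,
    which makes the zero-sum rule exact; ``per_state_nu=True`` weights each
    state by its own excitonic wavenumber instead (sum rule then only
    approximate)."""
    n = len(transitions)
    if result.coefficients.shape != (n, n):
        raise ExcitonError("result/transition dimension mismatch")
    centers = np.array([t.center for t in transitions])
    dipoles = np.array([t.dipole for t in transitions])
    # A_ij = (center_j - center_i) . (mu_i x mu_j); symmetric, zero diagonal
    cross = np.cross(dipoles[:, None, :], dipoles[None, :, :])
    sep = centers[None, :, :] - centers[:, None, :]
    A = np.einsum("ijk,ijk->ij", sep, cross)
    if nu0_cm is None:
        nu0_cm = float(np.mean([t.site_energy_ev for t in transitions])) * EV_TO_CM
    C = result.coefficients
    quad = np.einsum("ik,ij,jk->k", C, A, C)
    if per_state_nu:
        R = -(np.pi / 2.0) * result.energies * quad
    else:
        R = -(np.pi * nu0_cm / 2.0) * quad
    result.rotational_strengths = R
    return result


def exciton_calculation(model: StructureModel,
                        params: dict | None = None,
                        intra_base_coupling: float = 0.0) -> tuple[
                            ExcitonResult, list[ChromophoreTransition]]:
    """Convenience pipeline: transitions -> Hamiltonian -> states -> R_k."""
    transitions = assign_transitions(model, params)
    H = build_hamiltonian(transitions, intra_base_coupling)
    result = diagonalize(H)
    return rotational_strengths(result, transitions), transitions


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumGrid:
    """Signed CD intensity (arbitrary units) on an ascending wavelength grid
    (nm), with the cumulative energy shift and scaling recorded."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    shift_applied: float = 0.0
    scale_applied: float = 1.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise ExcitonError("wavelength grid must be strictly increasing")
        if self.wavelengths.shape != self.intensity.shape:
            raise ExcitonError("grid/intensity length mismatch")
        if not np.all(np.isfinite(self.intensity)):
            raise ExcitonError("non-finite intensity")


def default_grid(lo_nm: float = 200.0, hi_nm: float = 340.0,
                 n: int = 701) -> np.ndarray:
    return np.linspace(lo_nm, hi_nm, n)


def snapshot_spectrum(result: ExcitonResult, sigma_ev: float = 0.15,
                      grid_nm: np.ndarray | None = None) -> SpectrumGrid:
    """Gaussian-broadened CD spectrum of one snapshot: each excitonic state
    contributes R_k times a unit-area (in energy) Gaussian of width sigma."""
    if sigma_ev <= 0:
        raise ExcitonError("broadening sigma must be positive")
    if result.rotational_strengths is None:
        raise ExcitonError("rotational strengths not computed")
    if grid_nm is None:
        grid_nm = default_grid()
    grid_nm = np.asarray(grid_nm, dtype=float)
    e_grid = NM_EV / grid_nm  # eV
    e_states = result.energies / EV_TO_CM
    norm = 1.0 / (sigma_ev * np.sqrt(2.0 * np.pi))
    diff = e_grid[:, None] - e_states[None, :]
    gauss = norm * np.exp(-0.5 * (diff / sigma_ev) ** 2)
    intensity = gauss @ result.rotational_strengths
    return SpectrumGrid(wavelengths=grid_nm, intensity=intensity)


def ensemble_average(spectra: list[SpectrumGrid]) -> SpectrumGrid:
    """Unweighted pointwise mean over identically gridded spectra."""
    if not spectra:
        raise ExcitonError("empty ensemble")
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, ref.wavelengths):
            raise ExcitonError("ensemble spectra must share one grid")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return SpectrumGrid(ref.wavelengths.copy(), mean,
                        ref.shift_applied, ref.scale_applied)


def apply_shift_scale(spectrum: SpectrumGrid, shift_ev: float = 0.0,
                      scale: float = 1.0) -> SpectrumGrid:
    """Shift the spectrum by a rigid energy offset (re-evaluated on the same
    nm grid by interpolation in the energy domain) and scale its intensity
    uniformly. A band at energy E moves to E + shift."""
    if not (np.isfinite(shift_ev) and np.isfinite(scale)):
        raise ExcitonError("shift and scale must be finite")
    e_grid = NM_EV / spectrum.wavelengths
    order = np.argsort(e_grid)
    # I_new(E) = I_old(E - shift)
    new_int = np.interp(e_grid - shift_ev, e_grid[order],
                        spectrum.intensity[order], left=0.0, right=0.0)
    return SpectrumGrid(spectrum.wavelengths.copy(), scale * new_int,
                        spectrum.shift_applied + shift_ev,
                        spectrum.scale_applied * scale)


def match_shift_scale(simulated: SpectrumGrid, reference: SpectrumGrid,
                      shift_range_ev: tuple[float, float] = (-1.0, 1.0),
                      n_shift: int = 201) -> tuple[float, float]:
    """Least-squares (shift, scale) bringing a simulated spectrum onto a
    reference on the same grid: grid search over the shift, closed-form
    scale at each candidate. Returned values are logged, never silently
    applied."""
    if not np.array_equal(simulated.wavelengths, reference.wavelengths):
        raise ExcitonError("matcher requires identical grids")
    best = (0.0, 1.0, np.inf)
    for shift in np.linspace(*shift_range_ev, n_shift):
        shifted = apply_shift_scale(simulated, shift, 1.0)
        denom = np.dot(shifted.intensity, shifted.intensity)
        scale = (np.dot(shifted.intensity, reference.intensity) / denom
                 if denom > 0 else 1.0)
        sse = np.sum((scale * shifted.intensity - reference.intensity) ** 2)
        if sse < best[2]:
            best = (float(shift), float(scale), sse)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# Topology classification
# ---------------------------------------------------------------------------

#: CD band signatures of the three G4 topologies: (wavelength nm, sign)
G4_SIGNATURES = {
    "parallel": ((240.0, -1), (265.0, +1)),
    "antiparallel": ((260.0, -1), (295.0, +1)),
    "hybrid": ((240.0, -1), (270.0, +1), (290.0, +1)),
}


def spectrum_extrema(spectrum: SpectrumGrid,
                     prominence_frac: float = 0.05,
                     analysis_range_nm: tuple[float, float] = (225.0, 310.0)
                     ) -> list[tuple[float, int]]:
    """Significant extrema (wavelength, sign) within the analysis window,
    detected by prominence relative to the global absolute maximum."""
    wl, inten = spectrum.wavelengths, spectrum.intensity
    mask = (wl >= analysis_range_nm[0]) & (wl <= analysis_range_nm[1])
    if not np.any(mask) or np.max(np.abs(inten)) == 0:
        return []
    prom = prominence_frac * np.max(np.abs(inten))
    wl_w, in_w = wl[mask], inten[mask]
    out = []
    for sign, series in ((+1, in_w), (-1, -in_w)):
        peaks, _ = find_peaks(series, prominence=prom)
        for p in peaks:
            if series[p] > 0:
                out.append((float(wl_w[p]), sign))
    return sorted(out)


def classify_g4_signature(spectrum: SpectrumGrid,
                          window_nm: float = 10.0,
                          prominence_frac: float = 0.05) -> str:
    """Match the spectrum's extrema against the characteristic CD signatures
    of the three G-quadruplex topologies (parallel: -240/+265 nm;
    antiparallel: -260/+295 nm; hybrid: -240/+270/+290 nm).

    A topology matches only if its bands and the detected extrema are in
    one-to-one correspondence within +/- window_nm. Returns "unknown" when
    no or multiple topologies match."""
    extrema = spectrum_extrema(spectrum, prominence_frac)
    matches = []
    for topo, bands in G4_SIGNATURES.items():
        if len(extrema) != len(bands):
            continue
        unused = list(extrema)
        ok = True
        for wl0, sign in bands:
            cands = [e for e in unused if e[1] == sign and abs(e[0] - wl0) <= window_nm]
            if not cands:
                ok = False
                break
            unused.remove(min(cands, key=lambda e: abs(e[0] - wl0)))
        if ok and not unused:
            matches.append(topo)
    return matches[0] if len(matches) == 1 else "unknown"
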