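"""Alchemical absolute binding free-energy bookkeeping.

A double-decoupling cycle with geometric restraints decomposes the standard
binding free energy into four terms,

    dG0 = dG_rest_site + dG_alch_site + dG_rest_bulk + dG_alch_bulk,

where the alchemical legs are estimated from per-window energy-difference
samples (free energy perturbation, exponential averaging) or from lambda
gradients (thermodynamic integration), and the bulk restraint-release term
is evaluated analytically: the ligand's position relative to the receptor is
restrained by harmonic springs on spherical coordinates (r, theta, phi) and
its orientation by springs on Euler angles (Theta, Phi, Psi); releasing
those springs into the standard-state volume V0 = 1661 A^3 and the full
orientation space 8 pi^2 is a product of one-dimensional Gaussian integrals
with Jacobians r^2 sin(theta) and sin(Theta).

Each component is reported as the free energy of the corresponding arrow of
the cycle drawn toward the bound, unrestrained state; the total is their
plain sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, logsumexp

from .constants import KB_KCAL, V0_STANDARD_A3


class AlchemyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FEP
# ---------------------------------------------------------------------------

@dataclass
class AlchemicalLeg:
    """One alchemical transformation: ascending lambda schedule and, for each
    of the len(lambdas)-1 windows i -> i+1, forward energy-difference samples
    dU = U(lambda_{i+1}) - U(lambda_i) in kcal/mol."""

    lambdas: np.ndarray
    delta_u: list[np.ndarray]
    temperature: float = 300.0

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.size < 2 or np.any(np.diff(self.lambdas) <= 0):
            raise AlchemyError("need >= 2 strictly ascending lambda values")
        if np.any(self.lambdas < 0) or np.any(self.lambdas > 1):
            raise AlchemyError("lambdas must lie in [0, 1]")
        if len(self.delta_u) != self.lambdas.size - 1:
            raise AlchemyError("need one sample set per window")
        self.delta_u = [np.asarray(w, dtype=float) for w in self.delta_u]
        if any(w.size == 0 for w in self.delta_u):
            raise AlchemyError("empty window")


def _window_fep(du: np.ndarray, kt: float) -> float:
    # -kT ln < exp(-dU/kT) >, via logsumexp for numerical stability
    return -kt * (logsumexp(-du / kt) - np.log(du.size))


def fep_estimate(leg: AlchemicalLeg, n_blocks: int = 10,
                 n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Exponential-averaging (Zwanzig) estimate of the leg free energy:
    per-window -kT ln<exp(-beta dU)> summed over windows, in kcal/mol.

    The standard error comes from a block bootstrap: each window's samples
    are split into contiguous blocks that are resampled with replacement,
    and window errors combine in quadrature."""
    kt = KB_KCAL * leg.temperature
    total = sum(_window_fep(du, kt) for du in leg.delta_u)
    rng = np.random.default_rng(seed)
    var = 0.0
    for du in leg.delta_u:
        nb = min(n_blocks, du.size)
        blocks = np.array_split(du, nb)
        est = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, nb, size=nb)
            est[b] = _window_fep(np.concatenate([blocks[i] for i in pick]), kt)
        var += est.var(ddof=1)
    return float(total), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# TI
# ---------------------------------------------------------------------------

def ti_integrate(lambdas, mean_gradients) -> float:
    """Thermodynamic integration: trapezoidal quadrature of <dU/dlambda>
    over the lambda schedule, kcal/mol."""
    lambdas = np.asarray(lambdas, dtype=float)
    grads = np.asarray(mean_gradients, dtype=float)
    if lambdas.size < 2:
        raise AlchemyError("need >= 2 lambda points")
    if np.any(np.diff(lambdas) <= 0):
        raise AlchemyError("lambdas must be strictly ascending")
    if lambdas.shape != grads.shape:
        raise AlchemyError("lambda/gradient length mismatch")
    return float(np.trapezoid(grads, lambdas))


# ---------------------------------------------------------------------------
# Restraint release
# ---------------------------------------------------------------------------

@dataclass
class RestraintSet:
    """Harmonic restraints on the ligand's spherical position (r, theta,
    phi) and Euler orientation (Theta, Phi, Psi).

    Force constants are kcal/mol/A^2 (r) and kcal/mol/rad^2 (angles);
    references are Angstrom and radians. Polar references (theta0, Theta0)
    must avoid the coordinate poles, where the sin Jacobian vanishes."""

    k_r: float
    k_theta: float
    k_phi: float
    k_Theta: float
    k_Phi: float
    k_Psi: float
    r0: float
    theta0: float
    phi0: float
    Theta0: float
    Phi0: float
    Psi0: float

    def __post_init__(self):
        for name in ("k_r", "k_theta", "k_phi", "k_Theta", "k_Phi", "k_Psi"):
            if getattr(self, name) <= 0:
                raise AlchemyError(f"force constant {name} must be positive")
        if self.r0 <= 0:
            raise AlchemyError("r0 must be positive")
        for name in ("theta0", "Theta0"):
            if not 0.0 < getattr(self, name) < np.pi:
                raise AlchemyError(f"{name} must lie in (0, pi)")
        for name in ("phi0", "Phi0", "Psi0"):
            if not 0.0 <= getattr(self, name) <= 2.0 * np.pi:
                raise AlchemyError(f"{name} must lie in [0, 2 pi]")


def _gauss_r2(a: float, r0: float) -> float:
    """integral_0^inf r^2 exp(-a (r - r0)^2) dr, closed form."""
    sq = np.sqrt(a)
    e = np.exp(-a * r0**2)
    tail = 1.0 + erf(sq * r0)
    return float(
        r0 * e / (2.0 * a)
        + tail * np.sqrt(np.pi / a) * (1.0 / (4.0 * a) + r0**2 / 2.0)
    )


def _gauss_sin(a: float, x0: float) -> float:
    """integral_0^pi sin(x) exp(-a (x - x0)^2) dx via the complex error
    function (exact; stable for stiff springs, where the erf arguments have
    large positive real parts)."""
    sq = np.sqrt(a)
    pref = np.exp(-1.0 / (4.0 * a)) * np.sqrt(np.pi / a) / 2.0
    z1 = sq * (np.pi - x0) - 1j / (2.0 * sq)
    z2 = sq * x0 + 1j / (2.0 * sq)
    val = pref * np.exp(1j * x0) * (erf(z1) + erf(z2))
    return float(np.imag(val))


def _gauss_plain(a: float, x0: float, hi: float) -> float:
    """integral_0^hi exp(-a (x - x0)^2) dx."""
    sq = np.sqrt(a)
    return float(np.sqrt(np.pi / a) / 2.0 * (erf(sq * (hi - x0)) + erf(sq * x0)))


def restraint_partition_integrals(restraints: RestraintSet, T: float
                                  ) -> tuple[float, float]:
    """Configurational integrals of the restrained ligand:
    Z_trans over r^2 sin(theta) dr dtheta dphi (A^3) and Z_orient over
    sin(Theta) dTheta dPhi dPsi (the unnormalized orientation measure)."""
    beta = 1.0 / (KB_KCAL * T)
    h = beta / 2.0
    z_trans = (
        _gauss_r2(h * restraints.k_r, restraints.r0)
        * _gauss_sin(h * restraints.k_theta, restraints.theta0)
        * _gauss_plain(h * restraints.k_phi, restraints.phi0, 2.0 * np.pi)
    )
    z_orient = (
        _gauss_sin(h * restraints.k_Theta, restraints.Theta0)
        * _gauss_plain(h * restraints.k_Phi, restraints.Phi0, 2.0 * np.pi)
        * _gauss_plain(h * restraints.k_Psi, restraints.Psi0, 2.0 * np.pi)
    )
    return z_trans, z_orient


def restraint_release_bulk(restraints: RestraintSet, T: float = 300.0,
                           v0: float = V0_STANDARD_A3) -> float:
    """Analytic free energy (kcal/mol) of releasing the six harmonic
    restraints of a rigid ligand in bulk into the standard state:

        dG = -kT ln(V0 / Z_trans) - kT ln(8 pi^2 / Z_orient).

    Negative for any restraint stiff enough that the restrained volume is
    smaller than V0; diverges to -infinity as T -> 0 (the released phase
    space grows without bound relative to a frozen ligand)."""
    kt = KB_KCAL * T
    z_trans, z_orient = restraint_partition_integrals(restraints, T)
    return float(
        -kt * np.log(v0 / z_trans) - kt * np.log(8.0 * np.pi**2 / z_orient)
    )


# ---------------------------------------------------------------------------
# Cycle combination
# ---------------------------------------------------------------------------

@dataclass
class AlchemicalCycle:
    """The four-term decomposition of the standard binding free energy and
    its total (kcal/mol), with quadrature-combined uncertainty."""

    dg_rest_site: float
    dg_alch_site: float
    dg_rest_bulk: float
    dg_alch_bulk: float
    se_rest_site: float = 0.0
    se_alch_site: float = 0.0
    se_rest_bulk: float = 0.0
    se_alch_bulk: float = 0.0
    dg_total: float = field(init=False)
    se_total: float = field(init=False)

    def __post_init__(self):
        parts = (self.dg_rest_site, self.dg_alch_site,
                 self.dg_rest_bulk, self.dg_alch_bulk)
        if not all(np.isfinite(parts)):
            raise AlchemyError("all four cycle components must be finite")
        self.dg_total = float(sum(parts))
        self.se_total = float(np.sqrt(
            self.se_rest_site**2 + self.se_alch_site**2
            + self.se_rest_bulk**2 + self.se_alch_bulk**2
        ))


def combine_cycle(dg_rest_site: float, dg_alch_site: float,
                  dg_rest_bulk: float, dg_alch_bulk: float,
                  uncertainties: tuple[float, float, float, float] = (0, 0, 0, 0)
                  ) -> AlchemicalCycle:
    """Assemble the four-component cycle; the total is the exact sum and the
    uncertainty the quadrature combination."""
    u = uncertainties
    return AlchemicalCycle(dg_rest_site, dg_alch_site, dg_rest_bulk,
                           dg_alch_bulk, u[0], u[1], u[2], u[3])


# ---------------------------------------------------------------------------
# CSV / fixture interface
# ---------------------------------------------------------------------------

def read_fep_csv(path, temperature: float = 300.0) -> AlchemicalLeg:
    """Read per-window energy-difference samples from a CSV with columns
    ``lambda_index`` (0-based window) and ``delta_u_kcal_mol``. The lambda
    schedule is taken as uniform over [0, 1]."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("lambda_index", "delta_u_kcal_mol"):
        if col not in df.columns:
            raise AlchemyError(f"{path}: missing column {col!r}")
    if df["lambda_index"].isna().any() or df["delta_u_kcal_mol"].isna().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise AlchemyError(f"{path}: non-numeric entry at row {row}")
    idx = df["lambda_index"].astype(int)
    n_win = idx.max() + 1
    windows = [df.loc[idx == i, "delta_u_kcal_mol"].to_numpy(float)
               for i in range(n_win)]
    lambdas = np.linspace(0.0, 1.0, n_win + 1)
    return AlchemicalLeg(lambdas, windows, temperature)


def simulate_gaussian_leg(mu: float, sigma: float, n_samples: int,
                          n_windows: int = 1, temperature: float = 300.0,
                          seed: int = 0) -> AlchemicalLeg:
    """Synthetic leg whose per-window dU samples are i.i.d. N(mu, sigma^2);
    the exact per-window free energy is mu - beta sigma^2 / 2 (Gaussian
    cumulant identity), so the leg total is n_windows times that."""
    rng = np.random.default_rng(seed)
    windows = [rng.normal(mu, sigma, size=n_samples) for _ in range(n_windows)]
    return AlchemicalLeg(np.linspace(0, 1, n_windows + 1), windows, temperature)
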