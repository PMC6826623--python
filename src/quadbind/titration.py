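"""1:1 host-guest binding analysis of UV-Vis titrations.

The experiment: DNA (the host, expressed as per-base concentration) is added
stepwise to a ligand solution of fixed total concentration, and absorbance
is read at a wavelength where only the ligand absorbs (316 nm for
chelerythrine). The observed signal is a population-weighted mix of free and
bound ligand,

    A = eps_free (L0 - [HG]) + eps_bound [HG],

with the 1:1 complex concentration given by the exact mass-balance root

    [HG] = ( S - sqrt(S^2 - 4 H0 G0) ) / 2,   S = H0 + G0 + 1/Kb,

evaluated in a cancellation-safe form. Nonlinear least squares over
(Kb, eps_free, eps_bound) recovers the association constant, and
dG = -RT ln Kb converts it to a binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R_KCAL


class TitrationError(ValueError):
    pass


def strand_to_base(strand_conc: float, n_bases: int) -> float:
    """Convert an oligonucleotide strand concentration (M) to per-base
    concentration by multiplying by the number of bases in the sequence."""
    if np.any(np.asarray(strand_conc) < 0):
        raise TitrationError("negative strand concentration")
    if n_bases < 1:
        raise TitrationError("n_bases must be >= 1")
    return strand_conc * n_bases


def complex_concentration(Kb: float, H0, G0):
    """Equilibrium 1:1 complex concentration (M) for association constant Kb
    (M^-1) and total concentrations H0, G0 (M).

    Uses HG = 2 H0 G0 / (S + sqrt(S^2 - 4 H0 G0)) to avoid catastrophic
    cancellation when Kb*H0 >> 1. Kb = 0 returns 0 (no binding limit)."""
    H0 = np.asarray(H0, dtype=float)
    G0 = np.asarray(G0, dtype=float)
    if Kb < 0 or np.any(H0 < 0) or np.any(G0 < 0):
        raise TitrationError("Kb and concentrations must be non-negative")
    if Kb == 0:
        return np.zeros(np.broadcast(H0, G0).shape) if (H0.ndim or G0.ndim) else 0.0
    S = H0 + G0 + 1.0 / Kb
    disc = np.sqrt(np.maximum(S**2 - 4.0 * H0 * G0, 0.0))
    prod = H0 * G0
    with np.errstate(invalid="ignore", divide="ignore"):
        hg = np.where(prod > 0, 2.0 * prod / (S + disc), 0.0)
    return float(hg) if hg.ndim == 0 else hg


@dataclass
class TitrationSeries:
    """One UV-Vis titration: fixed total ligand concentration (M), added DNA
    per-base concentrations (M, nondecreasing) and observed absorbances."""

    ligand_total: float
    dna_base: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dna_base = np.asarray(self.dna_base, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.dna_base.shape != self.absorbance.shape:
            raise TitrationError("concentration/absorbance length mismatch")
        if self.dna_base.size < 5:
            raise TitrationError("a titration needs at least 5 points")
        if np.any(self.dna_base < 0) or np.any(np.diff(self.dna_base) < 0):
            raise TitrationError("DNA concentrations must be nonnegative, nondecreasing")
        if self.ligand_total < 0:
            raise TitrationError("negative ligand concentration")


def predicted_absorbance(Kb: float, eps_free: float, eps_bound: float,
                         series: TitrationSeries) -> np.ndarray:
    """Forward model: A = eps_free (L0 - HG) + eps_bound HG; the DNA itself
    does not absorb at the fit wavelength."""
    hg = complex_concentration(Kb, series.ligand_total, series.dna_base)
    return eps_free * (series.ligand_total - hg) + eps_bound * hg


@dataclass
class BindingFit:
    Kb: float
    Kb_se: float
    eps_free: float
    eps_bound: float
    delta_g: float
    delta_g_se: float
    converged: bool
    residual_rms: float
    temperature: float
    message: str = ""


def delta_g(Kb: float, T: float = 298.15) -> float:
    """Binding free energy -RT ln Kb in kcal/mol (R = 1.98720e-3
    kcal mol^-1 K^-1)."""
    if Kb <= 0:
        raise TitrationError("Kb must be positive")
    return -R_KCAL * T * np.log(Kb)


def fit_binding(series: TitrationSeries, T: float = 298.15,
                fix_eps_free: float | None = None) -> BindingFit:
    """Fit the 1:1 isotherm by nonlinear least squares over
    (ln Kb, eps_free, eps_bound), multi-starting over log-spaced Kb guesses
    spanning 1e2-1e8 M^-1 and keeping the best optimum.

    Standard errors come from the local Gauss-Newton curvature; the ln-Kb
    parameterization keeps Kb positive and the dG uncertainty is
    RT * (Kb_se / Kb). Degenerate data (constant absorbance) returns
    converged=False rather than raising."""
    A = series.absorbance
    if np.ptp(A) == 0 or series.ligand_total == 0:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          False, float(np.sqrt(np.mean((A - A.mean()) ** 2))),
                          T, "degenerate titration (constant absorbance)")

    float_eps_free = fix_eps_free is None

    def unpack(p):
        # clip ln Kb so trial steps cannot overflow the forward model
        kb = np.exp(np.clip(p[0], -46.0, 46.0))
        if float_eps_free:
            return kb, p[1], p[2]
        return kb, fix_eps_free, p[1]

    def resid(p):
        Kb, ef, eb = unpack(p)
        return predicted_absorbance(Kb, ef, eb, series) - A

    a0 = A[0] / series.ligand_total
    a_inf = A[-1] / series.ligand_total
    best = None
    for kb0 in np.logspace(2, 8, 7):
        if float_eps_free:
            p0 = [np.log(kb0), a0, a_inf]
        else:
            p0 = [np.log(kb0), a_inf]
        try:
            res = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success or not np.all(np.isfinite(best.x)):
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          False, np.nan, T, "optimization failed")

    Kb, ef, eb = unpack(best.x)
    n, p = A.size, best.x.size
    rms = float(np.sqrt(2.0 * best.cost / n))
    sigma2 = 2.0 * best.cost / max(n - p, 1)
    try:
        cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
        se_lnkb = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_lnkb = np.nan
    kb_se = Kb * se_lnkb
    dg = delta_g(Kb, T)
    dg_se = R_KCAL * T * se_lnkb
    return BindingFit(Kb=float(Kb), Kb_se=float(kb_se), eps_free=float(ef),
                      eps_bound=float(eb), delta_g=float(dg),
                      delta_g_se=float(dg_se), converged=True,
                      residual_rms=rms, temperature=T)


def default_dna_points(ligand_total: float, n_points: int = 20,
                       max_ratio: float = 30.0) -> np.ndarray:
    """Standard addition schedule for a 1:1 titration: a ligand-only point
    followed by geometrically spaced DNA-base concentrations from
    sub-stoichiometric (0.2 equivalents) to strong excess (`max_ratio`
    equivalents), the spacing practitioners use to resolve the isotherm
    curvature around the equivalence point."""
    if ligand_total <= 0:
        raise TitrationError("ligand_total must be positive")
    pts = np.geomspace(0.2 * ligand_total, max_ratio * ligand_total,
                       n_points - 1)
    return np.concatenate([[0.0], pts])


def simulate_titration(Kb: float, eps_free: float, eps_bound: float,
                       ligand_total: float, dna_base,
                       noise_sd: float = 0.0,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> TitrationSeries:
    """Synthetic titration: forward model plus i.i.d. Gaussian absorbance
    noise. All generating parameters are recorded in the metadata."""
    if noise_sd < 0:
        raise TitrationError("noise_sd must be >= 0")
    dna_base = np.asarray(dna_base, dtype=float)
    series = TitrationSeries(ligand_total, dna_base, np.zeros_like(dna_base))
    clean = predicted_absorbance(Kb, eps_free, eps_bound, series)
    if noise_sd > 0:
        if rng is None:
            if seed is None:
                raise TitrationError("noisy simulation requires a seed or rng")
            rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return TitrationSeries(
        ligand_total, dna_base, clean,
        metadata={"Kb": Kb, "eps_free": eps_free, "eps_bound": eps_bound,
                  "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_titration_csv(path, ligand_total: float,
                       n_bases: int | None = None) -> TitrationSeries:
    """Read a titration CSV with columns ``dna_base_conc_M`` (or
    ``dna_strand_conc_M`` plus ``n_bases`` for conversion) and
    ``absorbance``."""
    df = pd.read_csv(path)
    if "absorbance" not in df.columns:
        raise TitrationError(f"{path}: missing 'absorbance' column")
    absorb = pd.to_numeric(df["absorbance"], errors="coerce").to_numpy(float)
    if "dna_base_conc_M" in df.columns:
        base = pd.to_numeric(df["dna_base_conc_M"], errors="coerce").to_numpy(float)
    elif "dna_strand_conc_M" in df.columns:
        if n_bases is None:
            raise TitrationError(
                "strand concentrations given: n_bases required for conversion"
            )
        strand = pd.to_numeric(df["dna_strand_conc_M"], errors="coerce").to_numpy(float)
        base = strand_to_base(np.nan_to_num(strand, nan=0.0), n_bases)
        base[~np.isfinite(strand)] = np.nan
    else:
        raise TitrationError(
            f"{path}: need a 'dna_base_conc_M' or 'dna_strand_conc_M' column"
        )
    bad = ~np.isfinite(base) | ~np.isfinite(absorb)
    if np.any(bad):
        raise TitrationError(
            f"{path}: non-numeric entry at row {int(np.flatnonzero(bad)[0]) + 1}"
        )
    return TitrationSeries(ligand_total, base, absorb)


def write_titration_csv(path, series: TitrationSeries) -> None:
    pd.DataFrame({
        "dna_base_conc_M": series.dna_base,
        "absorbance": series.absorbance,
    }).to_csv(path, index=False)
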