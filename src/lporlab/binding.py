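"""Dissociation constant of the ternary LPOR/NADPH/Pchlide complex from a
spectral titration.

The measurement: UV-Vis absorption spectra of a fixed pigment concentration
[B] titrated with increasing apo-protein [A] (NADPH saturating, so
protein+NADPH acts as a single binding partner).  Binding red-shifts the
pigment Q_y band, so each mixed spectrum is a superposition of the free and
bound pigment spectra plus a turbidity baseline

    f(lambda) = a * lambda**-n + y0        (n fixed to 2)

that grows with protein concentration.  The analysis proceeds in three
layers:

1. ``unmix`` — bounded linear least squares of one mixed spectrum against
   the free and bound reference spectra plus the scatter baseline, yielding
   mole fractions of free and bound pigment.
2. ``bound_fraction`` — the ligand-depletion (Morrison) binding curve

       x_AB([A]) = S0 + (Smax-S0) * (Kd+B+A - sqrt((Kd+B+A)^2 - 4AB)) / (2B)

   valid when [A] and [B] are comparable, as here (B = 2 µM, A up to 200 µM,
   Kd from ~2 to ~130 µM).
3. ``fit_kd_global`` — a global Levenberg-Marquardt fit of the free and
   bound mole-fraction profiles to a common Kd, with iterative refinement of
   the bound reference spectrum: the bound reference is initially the
   highest-concentration spectrum and therefore contaminated with free
   pigment; the fitted plateau Smax measures that contamination
   (phi = (Smax-1)/Smax), which is subtracted and the unmixing repeated to a
   fixpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import lsq_linear

from .errors import IdentifiabilityError, ValidationError
from .spectra import Spectrum, TitrationSeries

__all__ = [
    "ScatterModel",
    "BindingModel",
    "UnmixResult",
    "BindingFitResult",
    "scatter",
    "bound_fraction",
    "unmix",
    "fit_kd_global",
]

#: cosine similarity above which free/bound references are flagged collinear
COLLINEARITY_THRESHOLD = 0.995


@dataclass
class ScatterModel:
    """Turbidity baseline a*lambda**-n + y0 (lambda in nm, result in AU)."""

    a: float = 0.0
    n: float = 2.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValidationError("scatter scale a must be >= 0")


def scatter(wavelengths, model: ScatterModel):
    """Evaluate the scatter baseline; wavelengths must be positive."""
    lam = np.asarray(wavelengths, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("wavelengths must be > 0")
    return model.a * lam ** (-model.n) + model.y0


@dataclass
class BindingModel:
    """One-site equilibrium A + B <=> AB with ligand depletion.

    ``kd`` = k_minus1/k1 in µM; only the ratio is identifiable from
    equilibrium data, the individual rate constants are nominal.  ``s0`` and
    ``smax`` are the lower/upper limits of the observed binding signal.
    """

    kd: float
    pigment_conc: float
    s0: float = 0.0
    smax: float = 1.0
    k1: float | None = None
    k_minus1: float | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError("Kd must be > 0")
        if self.pigment_conc <= 0:
            raise ValidationError("pigment concentration [B] must be > 0")
        if self.smax < self.s0:
            raise ValidationError("smax must be >= s0")


def _depletion_fraction(a, kd: float, b: float):
    """Fraction of pigment bound, [AB]/[B], from the mass-action quadratic.

    Uses the conjugate form 2A / (Kd+A+B + sqrt((Kd+A+B)^2 - 4AB)), which is
    numerically stable where the textbook difference form cancels
    catastrophically (Kd -> 0 with A >> B).  The discriminant is clamped at 0
    against rounding underflow.
    """
    a = np.asarray(a, dtype=float)
    s = kd + a + b
    disc = np.maximum(s * s - 4.0 * a * b, 0.0)
    return 2.0 * a / (s + np.sqrt(disc))


def bound_fraction(protein_conc, model: BindingModel):
    """Ligand-depletion binding signal on [s0, smax] at protein
    concentration(s) ``protein_conc`` (µM)."""
    a = np.asarray(protein_conc, dtype=float)
    if np.any(a < 0):
        raise ValidationError("protein concentration must be >= 0")
    frac = _depletion_fraction(a, model.kd, model.pigment_conc)
    out = model.s0 + (model.smax - model.s0) * frac
    return float(out) if np.isscalar(protein_conc) else out


@dataclass
class UnmixResult:
    """Per-spectrum decomposition into free/bound mole fractions + scatter."""

    x_free: float
    x_bound: float
    scatter: ScatterModel
    residual_rms: float
    collinear_references: bool = False


def _unmix_matrix(wavelengths: np.ndarray, free: np.ndarray, bound: np.ndarray,
                  n: float) -> np.ndarray:
    return np.column_stack(
        [free, bound, wavelengths ** (-n), np.ones_like(wavelengths)]
    )


def unmix(spectrum: Spectrum, free_ref: Spectrum, bound_ref: Spectrum,
          n: float = 2.0) -> UnmixResult:
    """Decompose one mixed spectrum into free/bound reference contributions
    plus the scatter baseline.

    Coefficients on the references are constrained nonnegative (mole
    fractions are physical); the scatter scale ``a`` is nonnegative, the
    offset ``y0`` is free.  Because the references are spectra of the full
    pigment concentration, the coefficients read directly as mole fractions.
    """
    for other in (free_ref, bound_ref):
        if not np.array_equal(spectrum.wavelengths, other.wavelengths):
            raise ValidationError("unmix requires a shared wavelength grid")
    lam = spectrum.wavelengths
    design = _unmix_matrix(lam, free_ref.values, bound_ref.values, n)
    lower = np.array([0.0, 0.0, 0.0, -np.inf])
    upper = np.full(4, np.inf)
    sol = lsq_linear(design, spectrum.values, bounds=(lower, upper),
                     method="bvls")
    coef = sol.x
    resid = spectrum.values - design @ coef
    f, b = free_ref.values, bound_ref.values
    cosine = abs(f @ b) / (np.linalg.norm(f) * np.linalg.norm(b))
    flag = cosine > COLLINEARITY_THRESHOLD
    if flag:
        warnings.warn("free and bound reference spectra are nearly collinear",
                      stacklevel=2)
    return UnmixResult(
        x_free=float(coef[0]),
        x_bound=float(coef[1]),
        scatter=ScatterModel(a=float(coef[2]), n=n, y0=float(coef[3])),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        collinear_references=bool(flag),
    )


@dataclass
class BindingFitResult:
    """Outcome of the global Kd fit with bound-spectrum refinement."""

    kd_hat: float
    kd_stderr: float | None
    s0_hat: float
    smax_hat: float
    unmix_results: list[UnmixResult]
    free_spectrum: Spectrum
    bound_spectrum: Spectrum
    contamination: float
    n_refinement_rounds: int
    converged: bool
    history: list[float] = field(default_factory=list)

    @property
    def mole_fractions(self) -> np.ndarray:
        """(n_samples, 2) array of [x_free, x_bound]."""
        return np.array([[u.x_free, u.x_bound] for u in self.unmix_results])


def _fit_tail_scatter(spec: Spectrum, tail_fraction: float = 0.15,
                      n: float = 2.0) -> ScatterModel:
    """Estimate a*lambda**-n + y0 from the long-wavelength, band-free tail."""
    lam = spec.wavelengths
    cut = lam[0] + (1.0 - tail_fraction) * (lam[-1] - lam[0])
    sel = lam >= cut
    design = np.column_stack([lam[sel] ** (-n), np.ones(sel.sum())])
    sol = lsq_linear(design, spec.values[sel],
                     bounds=([0.0, -np.inf], [np.inf, np.inf]), method="bvls")
    return ScatterModel(a=float(sol.x[0]), n=n, y0=float(sol.x[1]))


def _global_profile_fit(protein_conc: np.ndarray, x_free: np.ndarray,
                        x_bound: np.ndarray, pigment_conc: float,
                        kd_init: float):
    """Levenberg-Marquardt fit of both mole-fraction profiles to a shared
    Kd, S0, Smax.  The free profile is modelled as the complement of the
    bound one (total pigment is conserved)."""
    params = Parameters()
    params.add("kd", value=kd_init, min=1e-6)
    params.add("s0", value=float(np.min(x_bound)))
    params.add("smax", value=max(float(np.max(x_bound)), 1e-3))

    def residual(p):
        frac = _depletion_fraction(protein_conc, p["kd"].value, pigment_conc)
        model_bound = p["s0"].value + (p["smax"].value - p["s0"].value) * frac
        model_free = (1.0 - p["s0"].value) - (p["smax"].value - p["s0"].value) * frac
        return np.concatenate([x_bound - model_bound, x_free - model_free])

    return minimize(residual, params, method="leastsq")


def fit_kd_global(series: TitrationSeries, free_ref: Spectrum | None = None,
                  bound_ref: Spectrum | None = None,
                  max_rounds: int = 10, tol: float = 1e-4,
                  scatter_n: float = 2.0) -> BindingFitResult:
    """Global spectral Kd fit with iterative bound-reference refinement.

    Procedure: (1) the bound reference is initialised from the
    highest-concentration spectrum with its long-wavelength scatter removed;
    (2) every spectrum is unmixed against {free, bound, scatter}; (3) the
    mole-fraction profiles are globally fitted to the ligand-depletion curve
    with shared Kd, S0, Smax; (4) the fitted plateau Smax measures the free
    contamination of the bound reference (phi = (Smax-1)/Smax), which is
    subtracted and the reference renormalised; (2)-(4) repeat until the Kd
    moves by less than ``tol`` relative or ``max_rounds`` is reached.

    Requires >= 4 distinct protein concentrations including 0 (the
    zero-protein spectrum is the free reference when none is supplied).  An
    explicit initial ``bound_ref`` overrides the highest-concentration
    default; the refinement still applies to it.
    """
    series = series.sorted_by_concentration()
    conc = series.protein_conc
    if np.unique(conc).size < 4:
        raise ValidationError("need >= 4 distinct protein concentrations")
    if free_ref is None:
        if conc[0] != 0:
            raise ValidationError(
                "no zero-protein spectrum: supply free_ref explicitly")
        zero = series.spectra[0]
        zs = _fit_tail_scatter(zero, n=scatter_n)
        free_ref = zero.copy_with(zero.values - scatter(zero.wavelengths, zs))

    if bound_ref is None:
        top = series.spectra[-1]
        ts = _fit_tail_scatter(top, n=scatter_n)
        bound_ref = top.copy_with(top.values - scatter(top.wavelengths, ts))

    kd_prev = np.nan
    contamination = 0.0
    converged = False
    history: list[float] = []
    fit = None
    unmixed: list[UnmixResult] = []
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        unmixed = [unmix(s, free_ref, bound_ref, n=scatter_n)
                   for s in series.spectra]
        x_free = np.array([u.x_free for u in unmixed])
        x_bound = np.array([u.x_bound for u in unmixed])
        span = x_bound.max() - x_bound.min()
        if span < 0.05:
            raise IdentifiabilityError(
                "titration shows no binding curvature (all-free or all-bound); "
                "Kd is not identifiable")
        # initial Kd guess: concentration at half-maximal bound signal
        half = x_bound.min() + 0.5 * span
        kd_init = float(np.interp(half, x_bound, conc)) if rounds == 1 else kd_prev
        kd_init = max(kd_init, 1e-3)
        fit = _global_profile_fit(conc, x_free, x_bound,
                                  series.pigment_conc, kd_init)
        kd_hat = float(fit.params["kd"].value)
        smax = float(fit.params["smax"].value)
        history.append(kd_hat)

        if np.isfinite(kd_prev) and abs(kd_hat - kd_prev) / kd_hat < tol:
            converged = True
            break
        kd_prev = kd_hat

        # plateau > 1 means the bound reference still contains free pigment
        phi = (smax - 1.0) / smax
        phi = float(np.clip(phi, -0.5, 0.95))
        if abs(phi) > 1e-12:
            corrected = (bound_ref.values - phi * free_ref.values) / (1.0 - phi)
            bound_ref = bound_ref.copy_with(corrected)
            contamination = 1.0 - (1.0 - contamination) * (1.0 - phi)

    assert fit is not None
    stderr = fit.params["kd"].stderr
    return BindingFitResult(
        kd_hat=float(fit.params["kd"].value),
        kd_stderr=float(stderr) if stderr is not None else None,
        s0_hat=float(fit.params["s0"].value),
        smax_hat=float(fit.params["smax"].value),
        unmix_results=unmixed,
        free_spectrum=free_ref,
        bound_spectrum=bound_ref,
        contamination=float(contamination),
        n_refinement_rounds=rounds,
        converged=converged,
        history=history,
    )
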