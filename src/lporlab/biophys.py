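"""Small-angle scattering mass estimates and sequence-composition protein
parameters.

* Porod-volume mass rule: MW(Da) = V_porod(Å^3) / 1.7.
* Excluded-volume mass rule (averaged, filtered dummy-atom models):
  MW(Da) = V_excl(Å^3) / 2.
* Guinier radius of gyration: iterative linear fit of ln I vs q^2 on the
  largest low-q window with q*Rg <= 1.3, Rg = sqrt(3*|slope|).
* Composition-based molar extinction coefficient at 280 nm and average
  molecular mass of a protein sequence (the ProtParam conventions:
  eps = 5500 nW + 1490 nY [+ 125 per cystine]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import IdentifiabilityError, ValidationError

__all__ = [
    "SaxsProfile",
    "GuinierResult",
    "MassEstimates",
    "read_saxs_dat",
    "mw_from_porod",
    "mw_from_excluded_volume",
    "guinier_rg",
    "protein_params",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SaxsProfile:
    """1-D scattering profile: q in Å^-1 (strictly increasing, positive),
    intensity in arbitrary units, optional per-point uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.size != self.intensity.size:
            raise ValidationError("q and intensity must align")
        if np.any(self.q <= 0) or not np.all(np.diff(self.q) > 0):
            raise ValidationError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.q.size:
                raise ValidationError("sigma must align with q")


@dataclass
class GuinierResult:
    rg: float                   # Å
    i0: float
    window: tuple[int, int]     # [start, stop) indices of the final fit
    aggregation_flag: bool


@dataclass
class MassEstimates:
    mw_porod_kda: float | None = None
    mw_excluded_kda: float | None = None
    mw_theoretical_kda: float | None = None
    rg_guinier_a: float | None = None


def read_saxs_dat(path) -> SaxsProfile:
    """Read a whitespace three-column (q, I, sigma) text profile; comment
    and header lines are skipped."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError:
                continue
    if not rows:
        raise ValidationError(f"{path}: no numeric data rows")
    arr = np.array([r + [np.nan] * (3 - len(r)) for r in rows])
    sigma = arr[:, 2] if np.all(np.isfinite(arr[:, 2])) else None
    return SaxsProfile(arr[:, 0], arr[:, 1], sigma)


def mw_from_porod(v_porod: float) -> float:
    """Molecular mass in kDa from a Porod volume in Å^3 (divide by 1.7)."""
    if v_porod <= 0:
        raise ValidationError("Porod volume must be > 0")
    return v_porod / 1.7 / 1000.0


def mw_from_excluded_volume(v_excl: float) -> float:
    """Molecular mass in kDa from a dummy-atom excluded volume in Å^3
    (divide by 2)."""
    if v_excl <= 0:
        raise ValidationError("excluded volume must be > 0")
    return v_excl / 2.0 / 1000.0


def guinier_rg(profile: SaxsProfile, qrg_max: float = 1.3,
               min_points: int = 5, max_iter: int = 50,
               lin_tol: float = 1e-4) -> GuinierResult:
    """Radius of gyration from the Guinier limit
    ln I(q) = ln I0 - (q Rg)^2 / 3.

    Two-stage window selection, mimicking automated Guinier tools:
    (1) iterate fit -> recompute the admissible window (q*Rg <= ``qrg_max``)
    -> refit to a fixpoint; (2) shrink the window while the linear-fit
    residuals show systematic curvature clearly above the point-to-point
    noise (RMS residual > max(2x high-frequency noise, ``lin_tol``)), so an
    exact Guinier curve keeps the full window while a strongly curved form
    factor is fitted only where the approximation holds.  A non-negative
    slope (no decay at low q) raises; a systematic low-q upturn against the
    final fit sets the aggregation flag.
    """
    q, i_q = profile.q, profile.intensity
    pos = i_q > 0
    if pos.sum() < min_points:
        raise IdentifiabilityError("too few positive-intensity points")
    q, i_q = q[pos], i_q[pos]
    ln_i = np.log(i_q)
    q2 = q * q

    def linfit(start, stop):
        slope, intercept = np.polyfit(q2[start:stop], ln_i[start:stop], 1)
        resid = ln_i[start:stop] - (intercept + slope * q2[start:stop])
        return slope, intercept, resid

    def qrg_fixpoint(start):
        """Largest stop with q*Rg <= qrg_max at the fitted Rg."""
        stop = min(q.size, start + max(min_points, 20))
        while linfit(start, stop)[0] >= 0:
            if stop == q.size:
                raise IdentifiabilityError(
                    "no low-q intensity decay: Guinier fit impossible")
            stop = min(q.size, 2 * stop - start)
        prev = -1
        for _ in range(max_iter):
            slope = linfit(start, stop)[0]
            if slope >= 0:
                break
            rg = float(np.sqrt(-3.0 * slope))
            new_stop = int(np.searchsorted(q, qrg_max / rg, side="right"))
            new_stop = min(max(new_stop, start + min_points), q.size)
            if new_stop == stop or new_stop == prev:
                return new_stop
            prev, stop = stop, new_stop
        return stop

    start = 0
    stop = qrg_fixpoint(start)
    # aggregation: leading points rising systematically above the fit made
    # without them -> flag them and exclude them from the window
    aggregation = False
    for _ in range(3):
        head = max(3, (stop - start) // 10)
        if stop - (start + head) < min_points:
            break
        slope, intercept, resid = linfit(start + head, stop)
        head_resid = ln_i[start:start + head] - (
            intercept + slope * q2[start:start + head])
        sd = max(float(np.std(resid)), 1e-12)
        if float(np.mean(head_resid)) > 2.0 * sd:
            aggregation = True
            start += head
            stop = qrg_fixpoint(start)
        else:
            break
    # curvature: shrink while systematic misfit dominates point noise, so a
    # strongly curved form factor is fitted only where Guinier holds
    while stop - start > min_points:
        _, _, resid = linfit(start, stop)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        hf_noise = float(np.std(np.diff(resid)) / np.sqrt(2.0))
        if rms <= max(2.0 * hf_noise, lin_tol):
            break
        stop = max(start + min_points, start + int((stop - start) * 0.9))
    slope, intercept, _ = linfit(start, stop)
    if slope >= 0:
        raise IdentifiabilityError(
            "no low-q intensity decay: Guinier fit impossible")
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         window=(start, stop), aggregation_flag=aggregation)


def protein_params(sequence: str, cystine: bool = False
                   ) -> tuple[float, float, bool]:
    """(eps280 in M^-1 cm^-1, average MW in Da, aromatic_flag) from an
    amino-acid sequence.

    ``cystine=False`` (default) assumes all cysteines reduced, so only Trp
    and Tyr absorb; ``cystine=True`` adds 125 per cystine (paired Cys).
    ``aromatic_flag`` is False when the sequence carries no Trp/Tyr and the
    280 nm concentration method is therefore unusable.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValidationError("empty sequence")
    bad = sorted(set(seq) - _AA)
    if bad:
        raise ValidationError(f"unknown residue letters {bad}")
    analysis = ProteinAnalysis(seq)
    eps_reduced, eps_cystine = analysis.molar_extinction_coefficient()
    eps = float(eps_cystine if cystine else eps_reduced)
    mw = float(analysis.molecular_weight())
    counts = analysis.count_amino_acids()
    has_aromatic = (counts["W"] + counts["Y"]) > 0
    return eps, mw, has_aromatic
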