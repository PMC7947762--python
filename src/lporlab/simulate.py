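"""Synthetic data generators with known ground truth.

Every pipeline stage has a generator here that emulates the corresponding
measurement and returns the simulated input **together with its ground
truth**, so estimator recovery can be tested without any external data:

* ``gen_titration``     — spectral titration of 2 µM pigment with 0–200 µM
  apo-protein; Gaussian Q_y bands (free ~630 nm, bound red-shifted by
  +8 nm), per-sample lambda^-2 scatter baseline, Gaussian noise.  Bound
  fractions come from a brute-force mass-action root finder, deliberately
  independent of the closed-form binding curve being tested.
* ``gen_photoconversion`` — pulsed-illumination A672 time course (default
  1 s light / 11 s dark), Beer-Lambert product absorbance, broadband
  artifacts on frames overlapping a pulse, hard substrate-depletion clamp.
* ``gen_dsf``           — two-state F350/F330 unfolding sigmoid with its
  inflection exactly at the requested melting temperature.
* ``gen_marker_table``  — presence/absence patterns for AAPB-like,
  oxygenic-phototroph-like and non-phototroph genomes.
* ``gen_tree_set``      — trees containing a chosen clade at an exact
  frequency.

RNG contract: all draws come from ``numpy.random.default_rng`` (the
versioned PCG64 generator), seeded from ``SimConfig.seed``, so identical
configs give identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .markers import MARKERS, MarkerMatrix
from .spectra import Spectrum, SpectrumKind, TimeCourse, TitrationSeries
from .trees import TreeSet, is_monophyletic

__all__ = [
    "BandModel",
    "SimConfig",
    "TitrationTruth",
    "equilibrium_bound_fraction",
    "gen_titration",
    "gen_photoconversion",
    "gen_dsf",
    "gen_marker_table",
    "gen_tree_set",
]


@dataclass
class BandModel:
    """Gaussian absorption band: molar amplitude at the band center in
    AU µM^-1 over 1 cm, center and sigma in nm."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("band width must be > 0")
        if self.amplitude < 0:
            raise ValidationError("band amplitude must be >= 0")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-concentration band shape (AU per µM of pigment)."""
        lam = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((lam - self.center) /
                                               self.width) ** 2)


#: free pigment Q_y band (~630 nm); amplitude ~0.030 AU/µM matches a molar
#: absorptivity of ~3.0e4 M^-1 cm^-1
FREE_BAND = BandModel(center=630.0, width=9.0, amplitude=0.030)
#: bound pigment band, red-shifted by the default +8 nm
BOUND_BAND = BandModel(center=638.0, width=9.0, amplitude=0.032)


@dataclass
class SimConfig:
    """Reproducibility and noise settings shared by the generators."""

    seed: int = 0
    noise_sd: float = 0.002
    grid: tuple[float, float, float] = (620.0, 720.0, 1.0)

    def __post_init__(self) -> None:
        if self.grid[2] <= 0:
            raise ValidationError("grid step must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + 0.5 * step, step)


def equilibrium_bound_fraction(protein_conc: float, kd: float,
                               pigment_conc: float) -> float:
    """Brute-force mass-action equilibrium: solve
    Kd = ([A]-x)([B]-x)/x for the complex concentration x by bracketed
    root finding, return the bound pigment fraction x/[B].

    Serves as the independent oracle for the closed-form quadratic used by
    the fitting code.
    """
    a, b = float(protein_conc), float(pigment_conc)
    if a < 0 or b <= 0 or kd <= 0:
        raise ValidationError("need A >= 0, B > 0, Kd > 0")
    if a == 0:
        return 0.0
    hi = min(a, b)

    def f(x: float) -> float:
        return (a - x) * (b - x) - kd * x

    # f(0) = A*B > 0, f(min(A,B)) = -Kd*min(A,B) < 0
    x = brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15)
    return x / b


@dataclass
class TitrationTruth:
    """Ground truth accompanying a simulated titration."""

    kd: float
    bound_fractions: np.ndarray
    free_unit_spectrum: Spectrum
    bound_unit_spectrum: Spectrum
    clean_spectra: list[Spectrum] = field(default_factory=list)


def gen_titration(true_kd: float, cfg: SimConfig,
                  pigment_conc: float = 2.0,
                  protein_concs: np.ndarray | None = None,
                  free_band: BandModel = FREE_BAND,
                  bound_band: BandModel = BOUND_BAND,
                  scatter_a: np.ndarray | float | None = None,
                  y0: float = 0.005,
                  ) -> tuple[TitrationSeries, TitrationTruth]:
    """Simulate a spectral binding titration.

    Defaults mirror the study design: fixed 2 µM pigment, apo-protein from
    0 to 200 µM in 5 µM steps, scans from 620 to 720 nm at 1 nm.  The
    scatter scale defaults to 50 AU nm^2 per µM of protein (so 1e4 AU nm^2
    at the 200 µM endpoint — a few hundredths of an AU across the scan);
    pass ``scatter_a`` (scalar or per-sample vector) to override.
    """
    if true_kd <= 0:
        raise ValidationError("true_kd must be > 0")
    if protein_concs is None:
        protein_concs = np.arange(0.0, 201.0, 5.0)
    protein_concs = np.asarray(protein_concs, dtype=float)
    if np.any(protein_concs < 0):
        raise ValidationError("protein concentrations must be >= 0")
    if 0.0 not in protein_concs:
        raise ValidationError("the titration must include a zero-protein sample")
    lam = cfg.wavelengths()
    rng = cfg.rng()
    if scatter_a is None:
        scatter_a = 50.0 * protein_concs
    scatter_a = np.broadcast_to(np.asarray(scatter_a, float),
                                protein_concs.shape)

    free_unit = Spectrum(lam, free_band.profile(lam),
                         meta={"sample_id": "free_unit"})
    bound_unit = Spectrum(lam, bound_band.profile(lam),
                          meta={"sample_id": "bound_unit"})
    fractions = np.array([
        equilibrium_bound_fraction(a, true_kd, pigment_conc)
        for a in protein_concs
    ])

    spectra, clean = [], []
    for i, (a_conc, xb, sa) in enumerate(zip(protein_concs, fractions,
                                             scatter_a)):
        pigment = pigment_conc * ((1.0 - xb) * free_unit.values
                                  + xb * bound_unit.values)
        baseline = sa * lam ** -2.0 + y0
        meta = {"sample_id": f"A{a_conc:g}", "conc_uM": float(a_conc)}
        clean.append(Spectrum(lam, pigment + baseline, meta=dict(meta)))
        noisy = pigment + baseline + rng.normal(0.0, cfg.noise_sd, lam.size)
        spectra.append(Spectrum(lam, noisy, meta=meta))

    series = TitrationSeries(spectra, protein_concs, pigment_conc)
    truth = TitrationTruth(true_kd, fractions, free_unit, bound_unit, clean)
    return series, truth


def gen_photoconversion(rate_uM_per_min: float, cfg: SimConfig,
                        pulse_s: float = 1.0, dark_s: float = 11.0,
                        n_cycles: int = 30, eps672: float = 69950.0,
                        path_length: float = 1.0, frame_dt: float = 1.0,
                        frame_offset_s: float = 0.0,
                        substrate_uM: float = 3.5,
                        max_conversion: float = 0.5,
                        artifact_au: float = 0.5,
                        a672_0: float = 0.01,
                        ) -> tuple[TimeCourse, dict]:
    """Simulate a pulsed-illumination product-formation time course.

    Product accumulates at ``rate_uM_per_min`` per minute of *cumulative
    light time* and saturates once ``max_conversion`` of the substrate is
    converted.  A672 follows Beer-Lambert with ``eps672``.  Frames recorded
    while a pulse is on are flagged in the illumination mask and corrupted
    by a broadband ``artifact_au`` offset.

    ``frame_dt``/``frame_offset_s`` control the recording raster; with
    ``frame_dt`` equal to the cycle length and an offset inside the dark
    window the generator emits the instrument's one-spectrum-per-cycle
    sampling, giving an exactly linear pre-depletion trace.

    Returns the time course and a truth dict with the clean trace and the
    equivalent initial slope in AU/min (wall clock and per light minute).
    """
    if rate_uM_per_min < 0:
        raise ValidationError("rate must be >= 0")
    cycle = pulse_s + dark_s
    t_end = n_cycles * cycle
    times = np.arange(frame_offset_s, t_end, frame_dt)
    # cumulative seconds of light delivered up to each frame time
    k = np.floor(times / cycle)
    light_s = k * pulse_s + np.minimum(times - k * cycle, pulse_s)
    product = np.minimum(rate_uM_per_min * light_s / 60.0,
                         max_conversion * substrate_uM)
    clean = eps672 * product * 1e-6 * path_length + a672_0
    mask = (times % cycle) < pulse_s
    rng = cfg.rng()
    a672 = clean + rng.normal(0.0, cfg.noise_sd, times.size)
    a672 = a672 + artifact_au * mask
    slope_light = rate_uM_per_min * eps672 * 1e-6 * path_length
    truth = {
        "rate_uM_per_min": rate_uM_per_min,
        # slope per minute of light delivered vs per minute of wall-clock
        # time (the recorded trace dilutes the rate by the duty cycle)
        "slope_au_per_min": slope_light * pulse_s / cycle,
        "slope_au_per_light_min": slope_light,
        "duty_cycle": pulse_s / cycle,
        "clean_a672": clean,
        "light_s": light_s,
    }
    return TimeCourse(times, a672, mask), truth


def gen_dsf(tm: float, cfg: SimConfig, steepness: float = 1.5,
            baselines: tuple[float, float] = (0.8, 1.3),
            temps: np.ndarray | None = None,
            noise_sd: float | None = None) -> Spectrum:
    """Simulate a two-state F350/F330 unfolding curve with its inflection
    exactly at ``tm``.

    Defaults follow a 0.5 °C/min ramp from 15 to 85 °C sampled 18 times per
    minute (step ~0.028 °C).  ``steepness`` is the logistic width in °C
    (~1.5 °C corresponds to an unfolding enthalpy of ~120 kcal/mol for a
    mid-40s °C transition).  ``noise_sd`` defaults to 3e-4 ratio units, the
    precision of a modern nanoDSF optic; the :class:`SimConfig` noise field
    is for absorbance traces and deliberately not reused here.

    The temperature axis is stored in the wavelength slot of the returned
    ratio-kind :class:`Spectrum` (an abuse the kind flag makes explicit).
    """
    if temps is None:
        temps = np.arange(15.0, 85.0, 0.5 / 18.0)
    temps = np.asarray(temps, dtype=float)
    if not (temps[0] <= tm <= temps[-1]):
        raise ValidationError("tm must lie inside the temperature range")
    if steepness <= 0:
        raise ValidationError("steepness must be > 0")
    low, high = baselines
    ratio = low + (high - low) / (1.0 + np.exp(-(temps - tm) / steepness))
    sd = 3e-4 if noise_sd is None else noise_sd
    ratio = ratio + cfg.rng().normal(0.0, sd, temps.size)
    return Spectrum(temps, ratio, SpectrumKind.FLUORESCENCE_RATIO,
                    meta={"tm_true": float(tm), "noise_sd": sd})


# marker patterns used by gen_marker_table -----------------------------------

_AAPB_CORE = ("BchB", "BchL", "BchN", "PufL", "PufM")
_OXYGENIC_CORE = ("LPOR", "RuBisCO_large", "PRK", "PsaA", "PsaB",
                  "PsbA", "PsbD")


def gen_marker_table(n_genomes: int, cfg: SimConfig,
                     class_mix: dict[str, float] | None = None,
                     ) -> tuple[MarkerMatrix, list[str]]:
    """Draw genomes with AAPB, oxygenic-phototroph or non-phototroph marker
    patterns (class proportions must sum to 1); the true class labels are
    returned alongside the matrix.

    AAPB rows always satisfy the classification rule (DPOR + RC II + at
    least one cyclase, never both Calvin markers); oxygenic rows carry
    RuBisCO and PRK and so never satisfy it; non-phototroph rows carry at
    most a stray Calvin marker.
    """
    class_mix = class_mix or {"aapb": 0.4, "oxygenic": 0.3,
                              "non_phototroph": 0.3}
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValidationError("class proportions must sum to 1")
    rng = cfg.rng()
    classes = rng.choice(list(class_mix), size=n_genomes,
                         p=list(class_mix.values()))
    rows, labels = {}, []
    for i, cls in enumerate(classes):
        gid = f"G{i:04d}"
        row = {m: False for m in MARKERS}
        if cls == "aapb":
            for m in _AAPB_CORE:
                row[m] = True
            which = rng.integers(0, 3)  # AcsF, BchE, or both
            row["AcsF"] = which in (0, 2)
            row["BchE"] = which in (1, 2)
            row["LPOR"] = bool(rng.random() < 0.5)
            # at most one Calvin marker
            calvin = rng.integers(0, 3)
            row["RuBisCO_large"] = calvin == 1
            row["PRK"] = calvin == 2
        elif cls == "oxygenic":
            for m in _OXYGENIC_CORE:
                row[m] = True
            for m in ("BchB", "BchL", "BchN"):
                row[m] = bool(rng.random() < 0.5)
            row["AcsF"] = True
        elif cls == "non_phototroph":
            row["RuBisCO_large"] = bool(rng.random() < 0.2)
        else:
            raise ValidationError(f"unknown class {cls!r}")
        rows[gid] = row
        labels.append(str(cls))
    matrix = MarkerMatrix(pd.DataFrame.from_dict(rows, orient="index"))
    return matrix, labels


# random trees ---------------------------------------------------------------


def _random_topology(labels: list[str], rng: np.random.Generator) -> str:
    """Random unrooted binary topology as newick, by sequential joining."""
    nodes = [f"'{x}'" if " " in x else x for x in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    rng.shuffle(nodes)
    return "(" + ",".join(nodes) + ");"


def gen_tree_set(taxa: list[str], clade: set[str], frequency: float,
                 n_trees: int, cfg: SimConfig) -> TreeSet:
    """Generate ``n_trees`` random trees in which ``clade`` is monophyletic
    in exactly ``round(frequency * n_trees)`` of them; the remainder break
    the clade by swapping one clade leaf with an outside leaf."""
    clade = set(clade)
    taxa = list(taxa)
    if not 0 <= frequency <= 1:
        raise ValidationError("frequency must be in [0, 1]")
    if len(clade) < 2:
        raise ValidationError("clade must contain >= 2 taxa")
    if not clade.issubset(taxa):
        raise ValidationError("clade must be a subset of taxa")
    outside = [x for x in taxa if x not in clade]
    n_mono = round(frequency * n_trees)
    if n_mono < n_trees and len(outside) < 2:
        raise ValidationError(
            "breaking a clade needs >= 2 taxa outside it")
    rng = cfg.rng()
    newicks = []
    for i in range(n_trees):
        members = sorted(clade)
        rest = list(outside)
        if i >= n_mono:
            # swap one clade member with one outsider: the nominal clade now
            # straddles two parts of the tree and cannot be monophyletic
            a = int(rng.integers(len(members)))
            b = int(rng.integers(len(rest)))
            members[a], rest[b] = rest[b], members[a]
        sub_rng = np.random.default_rng(rng.integers(2 ** 31))
        clade_nwk = _random_topology(members, sub_rng).rstrip(";")
        if len(rest) >= 3:
            rest_nwk = _random_topology(rest, sub_rng).rstrip(";")
            nwk = f"({clade_nwk},{rest_nwk});"
        else:
            nwk = "(" + ",".join([clade_nwk] + rest) + ");"
        newicks.append(nwk)
    order = rng.permutation(n_trees)
    tree_set = TreeSet.from_strings([newicks[i] for i in order])
    # construction guarantee, cheap to assert
    count = sum(is_monophyletic(t, clade) for t in tree_set.trees)
    assert count == n_mono, "generator postcondition violated"
    return tree_set
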