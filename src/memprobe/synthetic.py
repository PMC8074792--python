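"""Synthetic data with known ground truth for every pipeline stage.

Every generator is a pure function of a :class:`SimulationConfig` (same seed
=> bit-identical output) and emulates the structure of the corresponding
experiment:

* F66 cytometry populations — per-cell lognormal dye loading split between the
  normal (N*) and tautomer (T*) emission bands by a logistic function of an
  abstract dipole-potential surrogate ``dp_param`` (higher dp => higher
  tautomer fraction => lower N*/T* ratio), live/apoptotic/necrotic
  subpopulations on scatter and viability-marker channels;
* di-8-ANEPPS excitation spectra — a Gaussian peak whose center blue-shifts
  linearly with ``dp_param`` (higher dp => bluer peak => larger blue/red
  excitation band ratio);
* polarized intensity quadruples — algebraic inversion of the anisotropy
  formulas, so the pipeline must recover (G, r) exactly without noise;
* time-stamped uptake event streams — a Poisson arrival process whose AF/NF
  intensities follow the two-compartment uptake/escape model with pH
  quenching of NF;
* two-channel membrane images — disk cells with bright rims whose blue/red
  split encodes a known generalized polarization.

``dp_param`` is an abstract unitless surrogate for the dipole potential, not
millivolts: the ratiometric readouts are never calibrated to a potential
scale, so only directions and orderings are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from memprobe.anisotropy import PolarizedReads
from memprobe.cytometry import Channel, EventTable
from memprobe.gp_imaging import ImagePair, SeedSet
from memprobe.kinetics import TwoCompartmentParams, simulate_two_compartment
from memprobe.spectra import SpectrumScan

__all__ = [
    "SimulationConfig",
    "DP_PANEL",
    "simulate_f66_population",
    "simulate_excitation_spectrum",
    "simulate_polarized_reads",
    "simulate_uptake_events",
    "simulate_membrane_image",
    "peptide_average_mass",
    "tautomer_fraction",
]

#: Logistic-link coefficients for the tautomer fraction: at dp_param = 0 the
#: tautomer fraction is exactly 2/3 (N*/T* ratio 1/2 without noise), and the
#: fraction rises with dp_param.
LOGISTIC_A0 = float(np.log(2.0))
LOGISTIC_A1 = 1.0

#: Direction-only panel of treatment surrogates: the omega-3 fatty acid ALA
#: lowers the dipole potential, saturated/omega-6 fatty acids and sterols
#: raise it, 6-ketocholestanol the most. Encodes ordering, not doses.
DP_PANEL = {
    "ALA": -0.6,
    "control": 0.0,
    "SA": 0.5,
    "GLA": 0.5,
    "7DHC": 0.9,
    "cholesterol": 1.3,
    "6KC": 1.8,
}


def _default_kinetics() -> TwoCompartmentParams:
    return TwoCompartmentParams(u_max=1.0, k_u=0.02, k_e=0.002, q=0.05, baseline=0.1)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; the seed is mandatory (no silent entropy)."""

    seed: int
    n_cells: int = 20_000
    dp_param: float = 0.0
    # noise model
    lognormal_sigma: float = 0.35       # spread of per-cell dye loading
    measurement_cv: float = 0.05        # multiplicative detector noise
    # population structure
    live_fraction: float = 0.85
    apoptotic_fraction: float = 0.10
    necrotic_fraction: float = 0.05
    # kinetic event streams
    kinetic_params: TwoCompartmentParams = field(default_factory=_default_kinetics)
    event_rate_hz: float = 20.0
    dapi_positive_fraction: float = 0.05
    # excitation spectra
    spectral_center0_nm: float = 470.0  # Gaussian center at dp_param = 0
    spectral_shift_per_dp_nm: float = 10.0
    spectral_sigma_nm: float = 40.0
    spectral_noise: float = 0.0         # additive noise, fraction of peak height
    # membrane images
    image_shape: tuple[int, int] = (256, 256)
    cell_radius_px: float = 16.0
    rim_width_px: float = 3.0
    gp_true: float = 0.0                # membrane-rim generalized polarization
    gp_interior: float = -0.3
    photon_scale: float = 2000.0        # expected rim photons per channel pair

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer (no silent entropy)")
        for name in ("live_fraction", "apoptotic_fraction", "necrotic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.live_fraction + self.apoptotic_fraction + self.necrotic_fraction > 1.0 + 1e-12:
            raise ValueError("population fractions must sum to <= 1")
        if self.lognormal_sigma < 0 or self.measurement_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.spectral_sigma_nm <= 0:
            raise ValueError("spectral sigma must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def tautomer_fraction(dp_param) -> np.ndarray:
    """Logistic link from the dipole surrogate to the T* fraction, in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-(LOGISTIC_A0 + LOGISTIC_A1 * np.asarray(dp_param, dtype=float))))


def _multiplicative_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# F66 cytometry population
# ---------------------------------------------------------------------------

_F66_CHANNELS = [
    Channel("FSC", role="scatter-forward"),
    Channel("SSC", role="scatter-side"),
    Channel("F66_N", role="fluorescence", excitation_nm=405, emission_band_nm=(480, 20)),
    Channel("F66_T", role="fluorescence", excitation_nm=405, emission_band_nm=(585, 42)),
    Channel("SYTOX", role="fluorescence", excitation_nm=488, emission_band_nm=(530, 30)),
    Channel("ANNEXIN", role="fluorescence", excitation_nm=640, emission_band_nm=(660, 20)),
]

#: Scatter cluster (FSC mean, SSC mean, common SD) per population.
_SCATTER_CLUSTERS = {
    "live": (50_000.0, 30_000.0, 5_000.0),
    "apoptotic": (32_000.0, 38_000.0, 6_000.0),
    "necrotic": (15_000.0, 12_000.0, 5_000.0),
    "debris": (5_000.0, 4_000.0, 2_500.0),
}

_MARKER_NEGATIVE_MEDIAN = 100.0
_MARKER_POSITIVE_MEDIAN = 8_000.0
_MARKER_SIGMA = 0.4


def simulate_f66_population(config: SimulationConfig) -> EventTable:
    """A seeded F66-stained population with live/apoptotic/necrotic structure.

    Live cells carry a lognormal dye load L split into the two emission bands
    by the tautomer fraction f_T(dp_param): I_N = L (1 - f_T) eps,
    I_T = L f_T eps with multiplicative measurement noise eps. Necrotic cells
    are Sytox-positive, apoptotic cells annexin-positive, live cells
    double-negative; the remainder is low-scatter debris.
    """
    rng = config.rng()
    n = config.n_cells
    p_live = config.live_fraction
    p_apo = config.apoptotic_fraction
    p_nec = config.necrotic_fraction
    p_debris = max(1.0 - p_live - p_apo - p_nec, 0.0)
    categories = rng.choice(4, size=n, p=[p_live, p_apo, p_nec, p_debris])
    names = np.array(["live", "apoptotic", "necrotic", "debris"])[categories]

    events = np.empty((n, len(_F66_CHANNELS)))
    # scatter clusters
    fsc = np.empty(n)
    ssc = np.empty(n)
    for label, (mu_f, mu_s, sd) in _SCATTER_CLUSTERS.items():
        sel = names == label
        k = int(sel.sum())
        fsc[sel] = rng.normal(mu_f, sd, size=k)
        ssc[sel] = rng.normal(mu_s, sd, size=k)
    events[:, 0] = np.clip(fsc, 0.0, None)
    events[:, 1] = np.clip(ssc, 0.0, None)

    # F66 emission bands: dye loading is reduced in dead/debris events
    load = rng.lognormal(mean=np.log(1_000.0), sigma=config.lognormal_sigma, size=n)
    load *= np.where(names == "live", 1.0, 0.3)
    f_t = float(tautomer_fraction(config.dp_param))
    events[:, 2] = load * (1.0 - f_t) * _multiplicative_noise(rng, config.measurement_cv, n)
    events[:, 3] = load * f_t * _multiplicative_noise(rng, config.measurement_cv, n)

    # viability markers
    sytox_pos = names == "necrotic"
    annexin_pos = names == "apoptotic"
    events[:, 4] = rng.lognormal(
        mean=np.log(np.where(sytox_pos, _MARKER_POSITIVE_MEDIAN, _MARKER_NEGATIVE_MEDIAN)),
        sigma=_MARKER_SIGMA)
    events[:, 5] = rng.lognormal(
        mean=np.log(np.where(annexin_pos, _MARKER_POSITIVE_MEDIAN, _MARKER_NEGATIVE_MEDIAN)),
        sigma=_MARKER_SIGMA)

    return EventTable(
        events=events,
        channels=list(_F66_CHANNELS),
        sample_meta={"dp_param": config.dp_param, "seed": config.seed,
                     "population": "f66"},
    )


# ---------------------------------------------------------------------------
# Excitation spectrum
# ---------------------------------------------------------------------------

SPECTRUM_GRID_NM = np.arange(380.0, 550.0 + 0.5, 1.0)
_SPECTRUM_PEAK = 1_000.0


def simulate_excitation_spectrum(config: SimulationConfig) -> SpectrumScan:
    """Gaussian excitation spectrum whose center blue-shifts with dp_param."""
    rng = config.rng()
    center = config.spectral_center0_nm - config.spectral_shift_per_dp_nm * config.dp_param
    wl = SPECTRUM_GRID_NM.copy()
    intensities = _SPECTRUM_PEAK * np.exp(-((wl - center) ** 2) / (2.0 * config.spectral_sigma_nm**2))
    if config.spectral_noise > 0:
        intensities = intensities + rng.normal(
            0.0, config.spectral_noise * _SPECTRUM_PEAK, size=wl.size)
    return SpectrumScan(wavelengths_nm=wl, intensities=intensities, emission_nm=660.0,
                        meta={"dp_param": config.dp_param, "center_nm": center,
                              "sigma_nm": config.spectral_sigma_nm, "seed": config.seed})


# ---------------------------------------------------------------------------
# Polarized reads
# ---------------------------------------------------------------------------

def simulate_polarized_reads(r_true: float, G_true: float,
                             total_intensity: float = 1_000.0) -> PolarizedReads:
    """Invert the anisotropy formulas for test construction.

    Chooses Ivv/Ivh so that r(Ivv, Ivh, G_true) = r_true exactly, scaled so
    Ivv + Ivh = total_intensity, and Ihv = G_true * Ihh, so the G-factor and
    anisotropy pipeline recovers (G_true, r_true) exactly without noise.
    """
    if not -0.5 < r_true < 1.0:
        raise ValueError(f"r_true must lie strictly inside (-0.5, 1), got {r_true}")
    if G_true <= 0:
        raise ValueError("G_true must be > 0")
    ivh = 1.0
    ivv = G_true * ivh * (1.0 + 2.0 * r_true) / (1.0 - r_true)
    scale = total_intensity / (ivv + ivh)
    ihh = total_intensity / 2.0
    return PolarizedReads(Ivv=ivv * scale, Ivh=ivh * scale,
                          Ihv=G_true * ihh, Ihh=ihh,
                          meta={"r_true": r_true, "G_true": G_true})


# ---------------------------------------------------------------------------
# Uptake event stream
# ---------------------------------------------------------------------------

_UPTAKE_CHANNELS = [
    Channel("AF532", role="fluorescence", excitation_nm=532),
    Channel("NF", role="fluorescence", excitation_nm=640),
    Channel("DAPI", role="fluorescence", excitation_nm=405),
]

_DAPI_NEGATIVE_MEDIAN = 50.0
_DAPI_POSITIVE_MEDIAN = 5_000.0


def simulate_uptake_events(config: SimulationConfig,
                           duration_s: float = 1_200.0) -> EventTable:
    """Time-stamped AF/NF event stream realizing the two-compartment model.

    Events arrive as a seeded Poisson process; each event's AF and NF
    intensities are the model curves at its arrival time, scaled by a shared
    per-cell lognormal loading factor (labeling is proportional, so the
    factor cancels in the NF/AF ratio) and independent multiplicative
    measurement noise. A configured fraction of events is DAPI-positive
    (membrane-compromised) with dimmer peptide signals.
    """
    rng = config.rng()
    n = int(rng.poisson(config.event_rate_hz * duration_s))
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    curves = simulate_two_compartment(config.kinetic_params, t)
    cell_factor = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)
    dapi_pos = rng.random(n) < config.dapi_positive_fraction
    signal_scale = cell_factor * np.where(dapi_pos, 0.25, 1.0)

    events = np.empty((n, 3))
    events[:, 0] = curves["F_AF"] * signal_scale * _multiplicative_noise(
        rng, config.measurement_cv, n)
    events[:, 1] = curves["F_NF"] * signal_scale * _multiplicative_noise(
        rng, config.measurement_cv, n)
    events[:, 2] = rng.lognormal(
        mean=np.log(np.where(dapi_pos, _DAPI_POSITIVE_MEDIAN, _DAPI_NEGATIVE_MEDIAN)),
        sigma=_MARKER_SIGMA)
    return EventTable(
        events=events, channels=list(_UPTAKE_CHANNELS), time_s=t,
        sample_meta={"seed": config.seed, "duration_s": duration_s,
                     "kinetic_params": config.kinetic_params},
    )


# ---------------------------------------------------------------------------
# Membrane images
# ---------------------------------------------------------------------------

_AMBIENT_LEVEL = 0.02      # additive ambient background, fraction of rim level
_INTERIOR_LEVEL = 0.3      # interior staining, fraction of rim level


def simulate_membrane_image(config: SimulationConfig):
    """Disk cells with bright membrane rims encoding a known GP.

    Returns ``(pair, seeds, truth_mask, gp_true)``: a two-channel image with
    10-15 non-overlapping disk cells, Poisson photon noise, auto-generated
    seeds (one rim, one interior and one background point per cell) and the
    true rim mask. The blue/red split of the structural intensity encodes
    ``gp_true`` on the rim and ``gp_interior`` inside; an ambient background
    (GP 0) is added everywhere so scalar background subtraction is exercised.
    """
    if not -1.0 < config.gp_true < 1.0:
        raise ValueError("gp_true must lie strictly inside (-1, 1)")
    if not -1.0 < config.gp_interior < 1.0:
        raise ValueError("gp_interior must lie strictly inside (-1, 1)")
    rng = config.rng()
    h, w = config.image_shape
    radius = config.cell_radius_px
    rim = config.rim_width_px
    margin = radius + rim + 6.0
    spacing = 2.0 * radius + rim + 12.0
    grid_r = np.arange(margin, h - margin + 1e-9, spacing)
    grid_c = np.arange(margin, w - margin + 1e-9, spacing)
    positions = [(r, c) for r in grid_r for c in grid_c]
    n_cells = int(rng.integers(10, 16))
    if len(positions) < n_cells:
        raise ValueError(
            f"image {config.image_shape} too small for {n_cells} cells of radius {radius}")
    chosen = rng.permutation(len(positions))[:n_cells]
    jitter = rng.uniform(-3.0, 3.0, size=(n_cells, 2))
    centers = np.array(positions)[chosen] + jitter

    rows, cols = np.mgrid[0:h, 0:w]
    structure = np.zeros((h, w))
    rim_mask = np.zeros((h, w), dtype=bool)
    interior_mask = np.zeros((h, w), dtype=bool)
    seeds = SeedSet(membrane=[], interior=[], background=[])
    for (cr, cc) in centers:
        dist = np.hypot(rows - cr, cols - cc)
        cell_rim = np.abs(dist - radius) <= rim / 2.0
        cell_interior = dist < radius - rim / 2.0
        rim_mask |= cell_rim
        interior_mask |= cell_interior
        structure[cell_rim] = 1.0
        structure[cell_interior] = _INTERIOR_LEVEL
        seeds.membrane.append((int(round(cr - radius)), int(round(cc))))
        seeds.interior.append((int(round(cr)), int(round(cc))))
        bg_offset = (radius + rim / 2.0 + 4.0) / np.sqrt(2.0)
        br = int(np.clip(round(cr + bg_offset), 0, h - 1))
        bc = int(np.clip(round(cc + bg_offset), 0, w - 1))
        seeds.background.append((br, bc))
    for corner in ((1, 1), (1, w - 2), (h - 2, 1), (h - 2, w - 2)):
        seeds.background.append(corner)

    gp_field = np.zeros((h, w))
    gp_field[interior_mask] = config.gp_interior
    gp_field[rim_mask] = config.gp_true
    blue_frac = (1.0 + gp_field) / 2.0
    expected_blue = config.photon_scale * (structure * blue_frac + _AMBIENT_LEVEL * 0.5)
    expected_red = config.photon_scale * (structure * (1.0 - blue_frac) + _AMBIENT_LEVEL * 0.5)
    pair = ImagePair(
        blue=rng.poisson(expected_blue).astype(float),
        red=rng.poisson(expected_red).astype(float),
        meta={"gp_true": config.gp_true, "gp_interior": config.gp_interior,
              "n_cells": n_cells, "seed": config.seed},
    )
    return pair, seeds, rim_mask, config.gp_true


# ---------------------------------------------------------------------------
# Peptide average mass
# ---------------------------------------------------------------------------

#: IUPAC average residue masses (g/mol) of the 20 canonical amino acids.
RESIDUE_AVERAGE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_AVERAGE_MASS = 18.0153
#: C-terminal amidation swaps the terminal OH for NH2: -OH (17.0073) + NH2 (16.0226).
AMIDE_CORRECTION = -0.9847


def peptide_average_mass(sequence: str, c_terminus: str = "free-acid") -> float:
    """Average molecular mass (g/mol) of a peptide from its one-letter sequence.

    The sum of average residue masses plus one water for the free acid; an
    amidated C-terminus replaces the terminal hydroxyl with an amine
    (net -0.98 g/mol). E.g. penetratin, RQIKIWFQNRRMKWKK with an amide
    C-terminus, evaluates to 2245.77 g/mol.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    if c_terminus not in ("free-acid", "amide"):
        raise ValueError(f"c_terminus must be 'free-acid' or 'amide', got {c_terminus!r}")
    mass = WATER_AVERAGE_MASS
    for letter in sequence:
        try:
            mass += RESIDUE_AVERAGE_MASS[letter]
        except KeyError:
            raise ValueError(f"unknown amino-acid letter {letter!r} in sequence") from None
    if c_terminus == "amide":
        mass += AMIDE_CORRECTION
    return mass
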