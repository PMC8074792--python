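"""Steady-state fluorescence anisotropy of membrane probes (L-format).

For TMA-DPH the steady-state anisotropy

    r = (Ivv - G * Ivh) / (Ivv + 2 * G * Ivh),     G = Ihv / Ihh,

is inversely related to membrane fluidity. Ivv/Ivh are the vertically and
horizontally polarized emission components under vertically polarized
excitation; the G factor corrects for the different sensitivity of the
detection system to the two polarizations and is measured with horizontally
polarized excitation (Ihv, Ihh).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PolarizedReads", "g_factor", "anisotropy", "anisotropy_from_reads"]

#: Photophysically plausible steady-state range; values outside are flagged.
PHYSICAL_RANGE = (-0.2, 0.4)


@dataclass(frozen=True)
class PolarizedReads:
    """The four polarized intensity components of an L-format measurement."""

    Ivv: float
    Ivh: float
    Ihv: float
    Ihh: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("Ivv", "Ivh", "Ihv", "Ihh"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def g_factor(Ihv: float, Ihh: float) -> float:
    """Instrument polarization-sensitivity correction G = Ihv / Ihh."""
    if Ihh <= 0:
        raise ValueError(f"Ihh must be > 0 to determine G, got {Ihh}")
    return Ihv / Ihh


def anisotropy(Ivv: float, Ivh: float, G: float) -> float:
    """Steady-state anisotropy r = (Ivv - G*Ivh) / (Ivv + 2*G*Ivh).

    For nonnegative intensities r lies in [-0.5, 1]. Values outside the
    photophysical range [-0.2, 0.4] are flagged with a warning, not rejected.
    """
    denominator = Ivv + 2.0 * G * Ivh
    if denominator <= 0:
        raise ValueError(f"anisotropy denominator must be > 0, got {denominator}")
    r = (Ivv - G * Ivh) / denominator
    lo, hi = PHYSICAL_RANGE
    if not lo <= r <= hi:
        warnings.warn(
            f"anisotropy r = {r:.4g} outside the photophysical range [{lo}, {hi}]",
            stacklevel=2,
        )
    return r


def anisotropy_from_reads(reads: PolarizedReads,
                          blank: PolarizedReads | None = None,
                          G: float | None = None) -> tuple[float, float]:
    """(G, r) from one polarized quadruple, optionally blank-subtracted.

    Blank (unlabeled-sample) intensities are subtracted per polarized
    component before the formulas are applied. ``G`` overrides the per-sample
    G factor with a session-level value.
    """
    ivv, ivh, ihv, ihh = reads.Ivv, reads.Ivh, reads.Ihv, reads.Ihh
    if blank is not None:
        ivv -= blank.Ivv
        ivh -= blank.Ivh
        ihv -= blank.Ihv
        ihh -= blank.Ihh
    if G is None:
        G = g_factor(ihv, ihh)
    return G, anisotropy(ivv, ivh, G)
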