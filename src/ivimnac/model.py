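"""Biexponential intravoxel incoherent motion (IVIM) signal model.

The IVIM model decomposes the diffusion-weighted MRI signal of a voxel into
a slow tissue-water diffusion pool and a fast capillary pseudo-diffusion
pool:

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

where ``D`` (mm^2/s) is the true diffusion coefficient of tissue water,
``D*`` (mm^2/s) is the pseudo-diffusion coefficient attributed to blood
microcirculation, ``f`` is the perfusion fraction of the b=0 signal and
``S0`` the signal at b=0.  All quantities are kept in SI-like units
(mm^2/s, fraction) internally; the conventional reporting scales
(x10^-3 mm^2/s, percent) are applied only at I/O boundaries.

The model is symmetric under swapping ``(D, 1-f) <-> (D*, f)``; the
identifiability convention ``D* >= D`` is therefore enforced at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DEFAULT_B_VALUES",
    "DEFAULT_NEX",
    "BValueScheme",
    "IVIMParams",
    "SignalDecay",
    "forward_signal",
]

#: 12-b breast protocol: diffusion weightings in s/mm^2 and per-b averaging
#: counts (NEX).  High-NEX acquisition at strong weighting compensates the
#: lower signal there.
DEFAULT_B_VALUES = (0.0, 10.0, 20.0, 30.0, 50.0, 70.0, 100.0, 150.0, 200.0, 400.0, 800.0, 1000.0)
DEFAULT_NEX = (1, 3, 3, 3, 3, 2, 2, 2, 2, 3, 5, 6)


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class BValueScheme:
    """A diffusion-weighting protocol: b values (s/mm^2) plus NEX per b.

    b values must be strictly increasing and start at 0; every NEX count
    must be a positive integer.  The default instance is the 12-b breast
    acquisition (b = 0..1000 s/mm^2).
    """

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    nex: tuple[int, ...] = DEFAULT_NEX

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValidationError("need at least two b values")
        if b[0] != 0.0:
            raise ValidationError("first b value must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValidationError("b values must be strictly increasing")
        if len(self.nex) != len(self.b_values):
            raise ValidationError("nex must have one entry per b value")
        if any((int(n) != n or n < 1) for n in self.nex):
            raise ValidationError("every NEX must be a positive integer")
        object.__setattr__(self, "b_values", tuple(float(x) for x in self.b_values))
        object.__setattr__(self, "nex", tuple(int(n) for n in self.nex))

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def to_bval(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write an FSL-style whitespace-separated bval line.

        The NEX list has no place in the bval dialect; it goes into a YAML
        sidecar (``{"nex": [...]}``) when ``sidecar`` is given.
        """
        Path(path).write_text(" ".join(f"{b:g}" for b in self.b_values) + "\n")
        if sidecar is not None:
            Path(sidecar).write_text(yaml.safe_dump({"nex": list(self.nex)}))

    @classmethod
    def from_bval(cls, path: str | Path, sidecar: str | Path | None = None) -> "BValueScheme":
        """Read a bval text line; NEX from a YAML sidecar or all-ones."""
        b_values = tuple(float(tok) for tok in Path(path).read_text().split())
        if sidecar is not None:
            nex = tuple(int(n) for n in yaml.safe_load(Path(sidecar).read_text())["nex"])
        else:
            nex = tuple(1 for _ in b_values)
        return cls(b_values=b_values, nex=nex)


@dataclass(frozen=True)
class IVIMParams:
    """One voxel's (or ROI's) IVIM parameter set.

    Attributes
    ----------
    D : float
        True diffusion coefficient, mm^2/s; must be positive.
    D_star : float
        Pseudo-diffusion coefficient, mm^2/s.  May be NaN when the
        perfusion pool is unidentifiable (f ~ 0).
    f : float
        Perfusion fraction in [0, 1].
    S0 : float
        Signal at b = 0, arbitrary units; must be positive.
    """

    D: float
    D_star: float
    f: float
    S0: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValidationError(f"f={self.f} outside [0, 1]")
        if not self.S0 > 0:
            raise ValidationError(f"S0={self.S0} must be positive")
        if not self.D > 0:
            raise ValidationError(f"D={self.D} must be positive")


@dataclass(frozen=True)
class SignalDecay:
    """A measured (or simulated) decay: one non-negative intensity per b."""

    scheme: BValueScheme
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.shape != (len(self.scheme),):
            raise ValidationError("signal length must match scheme")
        if np.any(sig < 0) or not np.all(np.isfinite(sig)):
            raise ValidationError("signal must be finite and non-negative")
        object.__setattr__(self, "signal", sig)

    @property
    def s0(self) -> float:
        """Measured signal at b = 0."""
        return float(self.signal[0])


def forward_signal(params: IVIMParams, scheme: BValueScheme | None = None) -> SignalDecay:
    """Evaluate the biexponential IVIM model on a b-value scheme.

    Returns a :class:`SignalDecay` with one intensity per b value;
    the b=0 entry equals ``S0`` exactly and the decay is non-increasing
    in b for positive D and D*.

    A NaN ``D_star`` is only accepted at f = 0, where the perfusion term
    vanishes identically.
    """
    if scheme is None:
        scheme = BValueScheme()
    b = scheme.b
    d_star = params.D_star
    if np.isnan(d_star):
        if params.f != 0.0:
            raise ValidationError("D_star is NaN but f > 0")
        d_star = params.D  # multiplied by f = 0, value irrelevant
    perf = params.f * np.exp(-b * d_star)
    tissue = (1.0 - params.f) * np.exp(-b * params.D)
    return SignalDecay(scheme=scheme, signal=params.S0 * (perf + tissue))
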