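"""Synthetic NIR-like spectra with day-batch structure and fault injection.

The generator emulates the acquisition design of a small meat-freshness NIRS
study: on each of ``n_days`` purchase days, ``samples_per_day_per_class``
pieces of meat (cycled over three meat types) are each scanned once fresh and
once after 24 h at room temperature (non-fresh), giving
``n_days * samples_per_day_per_class * 2`` spectra on a common wavelength
grid. At the defaults this is 8 days x 15 pieces x 2 states = 240 spectra
over 125 points spanning 908-1676 nm.

Each spectrum is a sum of Gaussian absorbance bands — a crude stand-in for
the O-H / C-H / N-H overtone and combination bands that dominate this
region — plus a day-level additive batch offset, a meat-type offset, smooth
correlated noise and white noise. The freshness signal is a fractional
amplitude change (``class_shift``) of two designated bands, so the two
classes look nearly identical to the eye, as real fresh/spoiled spectra do.
Five-scan averaging at acquisition is emulated by scaling the white-noise
standard deviation by 1/sqrt(5); no per-scan simulation is performed.

Ground-truth fault injection (`inject_outliers`) adds instrument-style
artifacts — a narrow spike, a baseline jump, or a gain fault — to chosen
samples and records their ids, so outlier-detection recall can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataio import LABEL_FRESH, LABEL_NONFRESH, SpectraDataset
from .errors import ConfigError

MEAT_TYPES = ("streaky", "foreleg", "tenderloin")

#: fractional positions of the six absorbance bands inside the grid span
_BAND_POSITIONS = (0.08, 0.24, 0.40, 0.55, 0.72, 0.90)
#: base amplitude of each band (absorbance units)
_BAND_AMPLITUDES = (0.30, 0.55, 0.40, 0.65, 0.45, 0.35)
#: band widths as a fraction of the grid span
_BAND_WIDTHS = (0.035, 0.05, 0.04, 0.06, 0.045, 0.04)
#: indices of the bands that carry the freshness signal (2 of 6, so that the
#: classes stay visually similar overall)
_SIGNAL_BANDS = (1, 4)
#: scans averaged per acquisition; white noise scales by 1/sqrt of this
_N_SCANS = 5


@dataclass
class SynthConfig:
    """Parameters of the synthetic study design. All noise scales are in
    absorbance units (typical spectra span ~0.3-1.5)."""

    n_days: int = 8
    samples_per_day_per_class: int = 15
    n_wavelengths: int = 125
    wavelength_min: float = 908.0
    wavelength_max: float = 1676.0
    n_bands: int = 6
    class_shift: float = 0.15
    day_effect_sd: float = 0.02
    meat_type_effect_sd: float = 0.01
    amplitude_jitter_sd: float = 0.02
    smooth_noise_sd: float = 0.01
    noise_correlation_length: float = 30.0  # nm
    white_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 3:
            raise ConfigError("n_days must be >= 3 (grouped CV needs >= 3 groups)")
        if self.samples_per_day_per_class < 1:
            raise ConfigError("samples_per_day_per_class must be >= 1")
        if self.n_wavelengths < 8:
            raise ConfigError("n_wavelengths must be >= 8")
        if not self.wavelength_max > self.wavelength_min:
            raise ConfigError("wavelength_max must exceed wavelength_min")
        if not 1 <= self.n_bands <= len(_BAND_POSITIONS):
            raise ConfigError(f"n_bands must be in 1..{len(_BAND_POSITIONS)}")
        for name in (
            "class_shift",
            "day_effect_sd",
            "meat_type_effect_sd",
            "amplitude_jitter_sd",
            "smooth_noise_sd",
            "white_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class OutlierTruth:
    """Ground truth of injected faults."""

    sample_ids: list = field(default_factory=list)
    types: dict = field(default_factory=dict)  # sample_id -> fault type
    magnitude: float = 0.0


def _band_profiles(config: SynthConfig, wavelengths: np.ndarray) -> np.ndarray:
    """(n_bands, n_wavelengths) matrix of unit-amplitude Gaussian bands."""
    span = config.wavelength_max - config.wavelength_min
    profiles = np.empty((config.n_bands, len(wavelengths)))
    for b in range(config.n_bands):
        center = config.wavelength_min + _BAND_POSITIONS[b] * span
        width = _BAND_WIDTHS[b] * span
        profiles[b] = np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return profiles


def generate(config: SynthConfig | None = None, seed: int | None = None) -> SpectraDataset:
    """Generate a full two-class, day-grouped synthetic dataset.

    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``). The random draws do not depend on ``class_shift``, so
    two configs differing only in the shift yield datasets that differ only
    in the amplitudes of the designated signal bands of non-fresh samples
    (exploited by :func:`difficulty_sweep`).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wavelengths = np.linspace(
        config.wavelength_min, config.wavelength_max, config.n_wavelengths
    )
    profiles = _band_profiles(config, wavelengths)
    base_amps = np.array(_BAND_AMPLITUDES[: config.n_bands])
    signal_mask = np.zeros(config.n_bands)
    for b in _SIGNAL_BANDS:
        if b < config.n_bands:
            signal_mask[b] = 1.0

    day_offsets = rng.normal(0.0, config.day_effect_sd, size=config.n_days)
    type_offsets = rng.normal(0.0, config.meat_type_effect_sd, size=len(MEAT_TYPES))

    n_pieces = config.n_days * config.samples_per_day_per_class
    m = n_pieces * 2
    X = np.empty((m, config.n_wavelengths))
    sample_ids, day, meat_type, label = [], [], [], []

    # per-class band multipliers: fresh is the reference state; non-fresh
    # bands carrying the signal are amplified by (1 + class_shift)
    class_mult = {
        LABEL_FRESH: np.ones(config.n_bands),
        LABEL_NONFRESH: 1.0 + config.class_shift * signal_mask,
    }

    sigma_pts = config.noise_correlation_length / (
        (config.wavelength_max - config.wavelength_min) / (config.n_wavelengths - 1)
    )
    white_sd = config.white_noise_sd / math.sqrt(_N_SCANS)

    row = 0
    for d in range(config.n_days):
        for p in range(config.samples_per_day_per_class):
            mt = MEAT_TYPES[p % len(MEAT_TYPES)]
            mt_idx = p % len(MEAT_TYPES)
            # one piece, two scans (fresh then non-fresh); the piece keeps
            # its own amplitude jitter so the pair is correlated like a real
            # repeated measurement of the same piece of meat
            jitter = rng.normal(0.0, config.amplitude_jitter_sd, size=config.n_bands)
            for lab in (LABEL_FRESH, LABEL_NONFRESH):
                amps = base_amps * (1.0 + jitter) * class_mult[lab]
                smooth = rng.normal(0.0, 1.0, size=config.n_wavelengths)
                smooth = gaussian_filter1d(smooth, sigma=max(sigma_pts, 1e-9), mode="reflect")
                sd = smooth.std()
                smooth = (
                    smooth / sd * config.smooth_noise_sd if sd > 0 else smooth * 0.0
                )
                white = rng.normal(0.0, white_sd, size=config.n_wavelengths)
                X[row] = (
                    amps @ profiles
                    + day_offsets[d]
                    + type_offsets[mt_idx]
                    + smooth
                    + white
                )
                state = "F" if lab == LABEL_FRESH else "N"
                sample_ids.append(f"D{d + 1}_P{p + 1:02d}_{state}")
                day.append(f"D{d + 1}")
                meat_type.append(mt)
                label.append(lab)
                row += 1

    return SpectraDataset(
        sample_ids=np.array(sample_ids, dtype=object),
        X=X,
        wavelengths=wavelengths,
        day=np.array(day, dtype=object),
        meat_type=np.array(meat_type, dtype=object),
        label=np.array(label, dtype=object),
    )


FAULT_TYPES = ("spike", "baseline", "scale")


def inject_outliers(
    dataset: SpectraDataset,
    k: int,
    types: Sequence[str] = FAULT_TYPES,
    magnitude: float = 1.0,
    seed: int = 0,
    balance_classes: bool = True,
) -> tuple[SpectraDataset, OutlierTruth]:
    """Perturb ``k`` spectra with instrument-style faults.

    Fault types (``magnitude`` in absorbance units, except ``scale``):

    - ``spike``: narrow Gaussian bump of height ``magnitude`` at a random
      wavelength (detector glitch);
    - ``baseline``: additive step of ``magnitude`` from a random index on
      (baseline drift / referencing fault);
    - ``scale``: multiplicative gain fault, spectrum scaled by
      ``1 + magnitude``.

    With ``balance_classes`` the ``k`` faulty samples are split as evenly as
    possible between the two classes. Unperturbed rows are bit-identical to
    the input. Returns a new dataset and the ground truth.
    """
    for t in types:
        if t not in FAULT_TYPES:
            raise ConfigError(f"unknown fault type {t!r}; valid: {FAULT_TYPES}")
    rng = np.random.default_rng(seed)
    y = dataset.label
    if balance_classes:
        chosen: list[int] = []
        per_class = {LABEL_FRESH: (k + 1) // 2, LABEL_NONFRESH: k // 2}
        for lab, kc in per_class.items():
            pool = np.flatnonzero(y == lab)
            if kc >= pool.size:
                raise ConfigError(
                    f"k for class {lab!r} ({kc}) must be < class size ({pool.size})"
                )
            chosen.extend(rng.choice(pool, size=kc, replace=False))
        chosen_idx = np.array(sorted(chosen), dtype=int)
    else:
        if k >= dataset.n_samples:
            raise ConfigError("k must be < dataset size")
        chosen_idx = np.sort(rng.choice(dataset.n_samples, size=k, replace=False))

    X = dataset.X.copy()
    n = dataset.n_wavelengths
    truth = OutlierTruth(magnitude=magnitude)
    for i in chosen_idx:
        fault = types[rng.integers(len(types))]
        if fault == "spike":
            pos = rng.integers(n)
            width = max(n // 60, 1)
            grid = np.arange(n)
            X[i] += magnitude * np.exp(-0.5 * ((grid - pos) / width) ** 2)
        elif fault == "baseline":
            pos = rng.integers(1, n)
            X[i, pos:] += magnitude
        else:  # scale
            X[i] *= 1.0 + magnitude
        sid = dataset.sample_ids[i]
        truth.sample_ids.append(sid)
        truth.types[sid] = fault

    out = SpectraDataset(
        sample_ids=dataset.sample_ids.copy(),
        X=X,
        wavelengths=dataset.wavelengths.copy(),
        day=dataset.day.copy(),
        meat_type=dataset.meat_type.copy(),
        label=dataset.label.copy(),
    )
    return out, truth


def difficulty_sweep(
    base_config: SynthConfig, shifts: Sequence[float]
) -> list[SpectraDataset]:
    """One dataset per class-shift value, sharing all seed-derived structure.

    Shifts must be positive and ascending. Because the generator's random
    stream does not depend on the shift, the returned datasets differ only
    in the designated signal-band amplitudes of non-fresh samples, so a
    sweep isolates separability from sampling noise.
    """
    shifts = list(shifts)
    if any(s <= 0 for s in shifts) or any(
        b <= a for a, b in zip(shifts, shifts[1:])
    ):
        raise ConfigError("shifts must be positive and strictly ascending")
    return [generate(replace(base_config, class_shift=s)) for s in shifts]
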