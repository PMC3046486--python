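"""Synthetic region generator with planted shifts, orientations and noise.

Templates model a nucleosome-depleted trough flanked by a phased array of
Gaussian occupancy peaks (log2 units).  Datasets are built by cropping a
padded template at a planted per-region offset (no wraparound), optionally
mirroring the row, and adding i.i.d. Gaussian noise; the planted truth is
recorded and everything is reproducible from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal import RegionMatrix

__all__ = [
    "TEMPLATE_KINDS",
    "TemplateParams",
    "SyntheticTruth",
    "make_template",
    "generate_dataset",
    "PaddedRegionSet",
    "validation_source",
]

TEMPLATE_KINDS = ("tss_like", "origin_like", "asymmetric_ctcf_like", "null")


@dataclass(frozen=True)
class TemplateParams:
    """Shape parameters of the deterministic architecture, in bins/log2 units."""

    period_bins: float = 17.0          # ~170 bp nucleosome repeat at 10 bp/bin
    amplitude: float = 1.0             # peak height of the proximal nucleosome
    decay: float = 0.85                # geometric decay of phasing with distance
    ndr_depth: float = 1.5             # depth of the depleted-region trough
    ndr_width_bins: float = 6.0        # trough s.d.
    peak_width_bins: float = 4.0       # nucleosome bump s.d.
    n_nucleosomes: int = 8             # bumps per flank
    minor_flank_scale: float = 0.35    # relative amplitude of the weak flank


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-region shifts and orientations."""

    shift_bins: np.ndarray
    reversed: np.ndarray
    master_seed: int
    max_shift_bins: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift_bins", np.asarray(self.shift_bins, dtype=int))
        object.__setattr__(self, "reversed", np.asarray(self.reversed, dtype=bool))
        if np.abs(self.shift_bins).max(initial=0) > self.max_shift_bins:
            raise ValueError("planted shift exceeds declared maximum")


def _bumps(
    x: np.ndarray,
    first: float,
    step: float,
    count: int,
    amplitude: float,
    decay: float,
    width: float,
) -> np.ndarray:
    out = np.zeros_like(x)
    for k in range(count):
        pos = first + k * step
        out += amplitude * decay**k * np.exp(-0.5 * ((x - pos) / width) ** 2)
    return out


def make_template(
    kind: str,
    length_bins: int = 200,
    params: TemplateParams | None = None,
) -> np.ndarray:
    """Deterministic architecture template of ``length_bins`` values.

    ``tss_like``: central trough, strong phased array downstream and a
    weaker one upstream (asymmetric, as at transcription starts).
    ``origin_like``: trough with symmetric flanking arrays.
    ``asymmetric_ctcf_like``: phased array on the left of the trough only.
    ``null``: all zeros (no deterministic component).
    """
    if kind not in TEMPLATE_KINDS:
        raise ValueError(f"unknown template kind {kind!r}; choose from {TEMPLATE_KINDS}")
    if length_bins < 4:
        raise ValueError("template needs at least 4 bins")
    if kind == "null":
        return np.zeros(length_bins)
    p = params or TemplateParams()
    x = np.arange(length_bins, dtype=float)
    center = (length_bins - 1) / 2.0  # mirror-symmetric on the integer grid
    gap = p.ndr_width_bins + p.period_bins / 2.0
    template = -p.ndr_depth * np.exp(-0.5 * ((x - center) / p.ndr_width_bins) ** 2)
    right = _bumps(
        x, center + gap, p.period_bins, p.n_nucleosomes, p.amplitude, p.decay,
        p.peak_width_bins,
    )
    left = _bumps(
        x, center - gap, -p.period_bins, p.n_nucleosomes, p.amplitude, p.decay,
        p.peak_width_bins,
    )
    if kind == "tss_like":
        template += right + p.minor_flank_scale * left
    elif kind == "origin_like":
        template += right + left
    else:  # asymmetric_ctcf_like
        template += left
    return template


def _padded_template(
    kind: str, length_bins: int, pad_bins: int, params: TemplateParams | None
) -> np.ndarray:
    """Template rendered over the padded support so crops never wrap."""
    padded = make_template(kind, length_bins + 2 * pad_bins, params)
    return padded


def _noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sd: float,
    smooth_bins: float,
) -> np.ndarray:
    """I.i.d. or spatially autocorrelated Gaussian noise with sd ``sd`` per bin.

    ``smooth_bins > 0`` low-pass filters white noise with a Gaussian kernel
    and rescales it back to the requested marginal s.d., mimicking the
    nucleosome-scale smoothness of real occupancy fluctuations.
    """
    if sd == 0:
        return np.zeros(shape)
    noise = rng.normal(0.0, sd, size=shape)
    if smooth_bins > 0:
        noise = gaussian_filter1d(noise, smooth_bins, axis=1)
        # variance shrinks by ~1/(2*sqrt(pi)*sigma); restore marginal sd
        noise *= sd / noise.std()
    return noise


def generate_dataset(
    kind: str,
    n: int,
    length_bins: int = 200,
    max_shift_bins: int = 15,
    reversal_prob: float = 0.0,
    noise_sd: float = 0.1,
    master_seed: int = 0,
    bin_size: int = 10,
    params: TemplateParams | None = None,
    noise_smooth_bins: float = 0.0,
) -> tuple[RegionMatrix, SyntheticTruth]:
    """Regions sharing one architecture seen through shifts, flips and noise.

    Region ``r`` is the template cropped at offset ``shift_r`` from a
    padded copy (so nothing wraps around), mirrored with probability
    ``reversal_prob``, plus additive Gaussian noise on the log2 scale.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 regions, got {n}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if max_shift_bins < 0:
        raise ValueError("max_shift_bins must be >= 0")
    rng = np.random.default_rng(master_seed)
    pad = max_shift_bins
    padded = _padded_template(kind, length_bins, pad, params)
    shifts = (
        rng.integers(-max_shift_bins, max_shift_bins + 1, size=n)
        if max_shift_bins > 0
        else np.zeros(n, dtype=int)
    )
    flips = rng.random(n) < reversal_prob
    rows = np.empty((n, length_bins))
    for r in range(n):
        lo = pad + int(shifts[r])
        row = padded[lo : lo + length_bins]
        if flips[r]:
            row = row[::-1]
        rows[r] = row
    rows = rows + _noise(rng, rows.shape, noise_sd, noise_smooth_bins)
    truth = SyntheticTruth(shifts, flips, master_seed, max_shift_bins)
    matrix = RegionMatrix.from_values(
        rows, bin_size=bin_size, ids=[f"synth_{r}" for r in range(n)]
    )
    return matrix, truth


class PaddedRegionSet:
    """Fixed noisy padded rows, re-croppable at arbitrary shifts.

    Emulates re-extracting regions from the same genomic track at shifted
    coordinates: the underlying (noisy) signal of each region is generated
    once over a padded support; each call crops every row at its shift.
    """

    def __init__(
        self,
        kind: str,
        n: int,
        length_bins: int,
        pad_bins: int,
        noise_sd: float,
        bin_size: int,
        seed: int,
        params: TemplateParams | None = None,
        noise_smooth_bins: float = 0.0,
    ) -> None:
        if n < 2:
            raise ValueError("need n >= 2 regions")
        if pad_bins < 1:
            raise ValueError("pad_bins must be >= 1")
        rng = np.random.default_rng(seed)
        base = _padded_template(kind, length_bins, pad_bins, params)
        self.rows = base[None, :] + _noise(
            rng, (n, len(base)), noise_sd, noise_smooth_bins
        )
        self.n = n
        self.length_bins = length_bins
        self.pad_bins = pad_bins
        self.bin_size = bin_size

    def __call__(self, shifts_bp: np.ndarray) -> RegionMatrix:
        shifts_bp = np.asarray(shifts_bp)
        if len(shifts_bp) != self.n:
            raise ValueError(f"expected {self.n} shifts, got {len(shifts_bp)}")
        shift_bins = np.round(shifts_bp / self.bin_size).astype(int)
        if np.abs(shift_bins).max(initial=0) > self.pad_bins:
            raise ValueError("shift exceeds padding")
        out = np.empty((self.n, self.length_bins))
        for r in range(self.n):
            lo = self.pad_bins + int(shift_bins[r])
            out[r] = self.rows[r, lo : lo + self.length_bins]
        return RegionMatrix.from_values(
            out, bin_size=self.bin_size, ids=[f"synth_{r}" for r in range(self.n)]
        )


def validation_source(
    kind: str = "tss_like",
    n: int = 100,
    length_bins: int = 200,
    max_shift_bp: int = 250,
    noise_sd: float = 0.1,
    bin_size: int = 10,
    seed: int = 0,
    params: TemplateParams | None = None,
    noise_smooth_bins: float = 0.0,
) -> PaddedRegionSet:
    """A randomization source sized so the largest grid shift still fits."""
    pad_bins = -(-max_shift_bp // bin_size)
    return PaddedRegionSet(
        kind, n, length_bins, pad_bins, noise_sd, bin_size, seed, params,
        noise_smooth_bins,
    )


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_id\tshift_bins\treversed\n")
        for r in range(len(truth.shift_bins)):
            fh.write(
                f"synth_{r}\t{int(truth.shift_bins[r])}\t"
                f"{int(truth.reversed[r])}\n"
            )


def write_params_json(path: str | Path, **params) -> None:
    def default(o):
        if isinstance(o, TemplateParams):
            return asdict(o)
        if isinstance(o, np.generic):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, default=default)
        fh.write("\n")
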