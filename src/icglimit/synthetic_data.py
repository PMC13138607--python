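"""Synthetic measurement fixtures with known ground truth.

No experimental data ship with this package, so every pipeline stage is
exercised against generated stand-ins that emulate the structure of the real
measurements:

* a multispectral *skin-like* background series (object background ``Sbg``,
  non-fluorescent PTFE-like reference ``Sbg_ref``, reflectance ratio, and the
  reference fluorescence ``Sf0``) with a known autofluorescence/scatter split;
* a *Lipofundin-like* concentration series of total signals for a dilution
  ladder of the contrast agent.

Only the measured anchor values seed the defaults (at 785 nm the
autofluorescence is 3200 counts against a 20,000-count reference
fluorescence signal; the AF/scatter ratio rises from 4x at 792 nm to 25x at
650 nm); the spectral shape between anchors is a synthetic stand-in, not a
reproduction of any measured curve.

The noise model mimics ROI averaging of a camera image: per-pixel Poisson
shot noise reduced by the pixel count of the ROI, plus an additive
instrumental floor expressed as a fraction of the minimum signal in the
series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .background_separation import SignalRecord
from .sbr_sensitivity import FilterSet, TissueScenario, nmin_curve

#: Measurement wavelengths of the skin series (nm).
DEFAULT_WAVELENGTHS = (650.0, 690.0, 760.0, 785.0, 792.0)

_ANCHOR_WAVELENGTH = 785.0
_ANCHOR_SAF = 3200.0
_ANCHOR_SF0 = 20_000.0
#: AF/scatter ratio anchors: (wavelength, ratio).
_RATIO_ANCHORS = ((650.0, 25.0), (792.0, 4.0))
#: Synthetic spectral slope: AF falls ~8x from 650 to 792 nm (log-linear).
_SAF_DECADE_SPAN = 8.0


def _loglinear(wl: float, x0: float, y0: float, x1: float, y1: float) -> float:
    t = (wl - x0) / (x1 - x0)
    return y0 * (y1 / y0) ** t


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth components behind a generated skin series."""

    wavelengths: tuple[float, ...]
    true_saf: tuple[float, ...]
    true_ssc: tuple[float, ...]
    rd_ratio: float
    s_f0: float
    concentration_series: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.true_saf) or any(v < 0 for v in self.true_ssc):
            raise ValueError("truth components must be >= 0")
        order = np.argsort(self.wavelengths)
        saf_sorted = np.asarray(self.true_saf)[order]
        if np.any(np.diff(saf_sorted) > 1e-9):
            raise ValueError(
                "true_saf must be monotone non-increasing with wavelength"
            )

    @classmethod
    def default(cls, wavelengths=DEFAULT_WAVELENGTHS, rd_ratio: float = 0.8,
                s_f0: float = _ANCHOR_SF0) -> "SyntheticTruth":
        """Preset pinned to the measured anchors.

        Saf(785) = 3200 counts; Saf/Ssc interpolates log-linearly between 25x
        at 650 nm and 4x at 792 nm; the Saf spectrum itself falls log-linearly
        by a factor ``_SAF_DECADE_SPAN`` across 650-792 nm (synthetic shape).
        """
        (w_lo, r_lo), (w_hi, r_hi) = _RATIO_ANCHORS
        saf_650 = _ANCHOR_SAF * _SAF_DECADE_SPAN ** (
            (_ANCHOR_WAVELENGTH - 650.0) / (792.0 - 650.0)
        )
        saf_792 = saf_650 / _SAF_DECADE_SPAN
        saf = [_loglinear(w, 650.0, saf_650, 792.0, saf_792) for w in wavelengths]
        ratio = [_loglinear(w, w_lo, r_lo, w_hi, r_hi) for w in wavelengths]
        ssc = [s / r for s, r in zip(saf, ratio)]
        return cls(
            wavelengths=tuple(wavelengths),
            true_saf=tuple(saf),
            true_ssc=tuple(ssc),
            rd_ratio=rd_ratio,
            s_f0=s_f0,
        )

    def to_json(self, path: str | Path) -> None:
        """Write the ground truth as a sidecar JSON file."""
        payload = {
            "wavelengths_nm": list(self.wavelengths),
            "true_saf": list(self.true_saf),
            "true_ssc": list(self.true_ssc),
            "rd_ratio": self.rd_ratio,
            "s_f0": self.s_f0,
            "concentration_series": [list(p) for p in self.concentration_series],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class NoiseModel:
    """ROI-averaged measurement noise.

    shot_noise : apply Poisson-count variance ``S / roi_pixels`` to each
        ROI-averaged signal (the per-pixel variance divided by the number of
        averaged pixels).
    floor_fraction : additive instrumental noise, expressed as a fraction of
        the minimum signal in the series (default 3.5%).
    roi_pixels : number of averaged pixels (default 20,050).
    """

    shot_noise: bool = True
    floor_fraction: float = 0.035
    roi_pixels: int = 20_050
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_fraction < 0:
            raise ValueError("floor_fraction must be >= 0")
        if self.roi_pixels < 1:
            raise ValueError("roi_pixels must be >= 1")

    def stderr(self, signal: float, floor_scale: float) -> float:
        """Standard deviation of one ROI-averaged signal."""
        var = 0.0
        if self.shot_noise:
            var += max(signal, 0.0) / self.roi_pixels
        var += (self.floor_fraction * floor_scale) ** 2
        return math.sqrt(var)


def make_skin_series(
    truth: SyntheticTruth | None = None,
    noise: NoiseModel | None = None,
) -> tuple[list[SignalRecord], SyntheticTruth]:
    """Generate the multispectral skin-like background series.

    Emits one :class:`SignalRecord` per wavelength with
    ``s_bg = Saf + Ssc`` and ``s_bg_ref = Ssc / rd_ratio``, noisy unless
    ``noise`` disables both components (``NoiseModel(shot_noise=False,
    floor_fraction=0.0)`` makes the generator exact).  Returns the records
    and the truth object for recovery tests.
    """
    truth = truth or SyntheticTruth.default()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    signals_bg = [saf + ssc for saf, ssc in zip(truth.true_saf, truth.true_ssc)]
    signals_ref = [ssc / truth.rd_ratio for ssc in truth.true_ssc]
    floor_scale = min(min(signals_bg), min(signals_ref))
    records = []
    for wl, s_bg, s_ref in zip(truth.wavelengths, signals_bg, signals_ref):
        sd_bg = noise.stderr(s_bg, floor_scale)
        sd_ref = noise.stderr(s_ref, floor_scale)
        sd_f0 = noise.stderr(truth.s_f0, floor_scale)
        records.append(
            SignalRecord(
                wavelength=wl,
                s_bg=max(s_bg + rng.normal(0.0, sd_bg) if sd_bg else s_bg, 0.0),
                s_bg_ref=max(s_ref + rng.normal(0.0, sd_ref) if sd_ref else s_ref, 0.0),
                rd_ratio=truth.rd_ratio,
                s_f0=max(truth.s_f0 + rng.normal(0.0, sd_f0) if sd_f0 else truth.s_f0, 0.0),
                s_bg_stderr=sd_bg,
                s_bg_ref_stderr=sd_ref,
                s_f0_stderr=sd_f0,
            )
        )
    return records, truth


def skin_series_frame(records: list[SignalRecord]) -> pd.DataFrame:
    """Records -> the CSV schema consumed by background separation."""
    return pd.DataFrame(
        {
            "wavelength_nm": [r.wavelength for r in records],
            "s_bg": [r.s_bg for r in records],
            "s_bg_ref": [r.s_bg_ref for r in records],
            "rd_ratio": [r.rd_ratio for r in records],
            "s_f0": [r.s_f0 for r in records],
            "s_bg_stderr": [r.s_bg_stderr for r in records],
            "s_bg_ref_stderr": [r.s_bg_ref_stderr for r in records],
            "s_f0_stderr": [r.s_f0_stderr for r in records],
        }
    )


def make_concentration_series(
    concentrations: "list[float] | np.ndarray",
    scenario: TissueScenario,
    filters: FilterSet,
    noise: NoiseModel | None = None,
    rf_rd_source: pd.DataFrame | None = None,
    s_f0: float = _ANCHOR_SF0,
    include_af: bool = True,
) -> tuple[list[SignalRecord], pd.DataFrame]:
    """Generate total signals for a contrast-agent dilution ladder.

    For each concentration ``n``: ``Sf(n) = Sf0 * n / n0`` (linearity in
    concentration), a constant scattered background
    ``Ssc = (Ssc/Sf)(n0) * Sf0`` derived from the Monte Carlo grid through the
    filter model, optionally a constant autofluorescence background
    ``Saf = (Saf/Sf)(n0) * Sf0``, and ``s_total = Sf + Ssc (+ Saf)``.  The
    noiseless series therefore reproduces the closed-form SBR model exactly.

    Returns the records plus a truth table (n, sf, ssc, saf, sbr_true).
    """
    concentrations = list(np.asarray(concentrations, dtype=float))
    if len(concentrations) == 0:
        raise ValueError("empty concentration list")
    noise = noise or NoiseModel()
    sens = nmin_curve(scenario, filters, od_values=[filters.od_ex],
                      rf_rd_source=rf_rd_source)
    n0 = scenario.fluorophore.concentration
    ssc = sens.ssc_over_sf * s_f0
    saf = sens.saf_over_sf * s_f0 if include_af else 0.0
    background = ssc + saf
    rng = np.random.default_rng(noise.seed + 1)
    rd_ratio = 0.8
    sf_values = [s_f0 * n / n0 for n in concentrations]
    floor_scale = background if background > 0 else min(sf_values)
    records = []
    rows = []
    for n, sf in zip(concentrations, sf_values):
        s_total = sf + background
        sd_tot = noise.stderr(s_total, floor_scale)
        sd_bg = noise.stderr(background, floor_scale)
        sd_ref = noise.stderr(ssc / rd_ratio, floor_scale)
        records.append(
            SignalRecord(
                wavelength=_ANCHOR_WAVELENGTH,
                s_bg=max(background + rng.normal(0.0, sd_bg), 0.0),
                s_bg_ref=max(ssc / rd_ratio + rng.normal(0.0, sd_ref), 0.0),
                rd_ratio=rd_ratio,
                s_f0=s_f0,
                s_total=max(s_total + rng.normal(0.0, sd_tot), 0.0),
                s_bg_stderr=sd_bg,
                s_bg_ref_stderr=sd_ref,
            )
        )
        sbr_true = s_total / background - 1.0 if background > 0 else math.inf
        rows.append({"n": n, "sf": sf, "ssc": ssc, "saf": saf, "sbr_true": sbr_true})
    return records, pd.DataFrame(rows)


def write_synthetic_images(
    out_dir: str | Path,
    truth: SyntheticTruth | None = None,
    noise: NoiseModel | None = None,
    shape: tuple[int, int] = (160, 140),
    roi: tuple[int, int, int, int] = (10, 150, 10, 130),
    wavelength: float = _ANCHOR_WAVELENGTH,
) -> dict[str, Path]:
    """Write a synthetic 16-bit grayscale TIFF pair for the ROI helper.

    The with/without-agent pair matches the scalar fixtures at the given
    wavelength: per-pixel Poisson counts around the true mean inside the
    whole frame.  Returns the written paths keyed by 'background' and
    'total'.
    """
    import tifffile

    truth = truth or SyntheticTruth.default()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed + 2)
    idx = truth.wavelengths.index(wavelength)
    mean_bg = truth.true_saf[idx] + truth.true_ssc[idx]
    mean_total = mean_bg + truth.s_f0
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mean in (("background", mean_bg), ("total", mean_total)):
        if noise.shot_noise:
            img = rng.poisson(mean, size=shape).astype(np.uint16)
        else:
            img = np.full(shape, round(mean), dtype=np.uint16)
        path = out_dir / f"synthetic_{name}_{int(wavelength)}nm.tif"
        tifffile.imwrite(str(path), img)
        paths[name] = path
    return paths
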