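"""Separation of a measured fluorescence-imaging background into its parts.

An image of tissue without contrast agent still shows signal: endogenous
autofluorescence (``Saf``) plus excitation light backscattered by the tissue
and leaking through the emission filter (``Ssc``).  The two are separated
with a non-fluorescent scattering reference (PTFE): the reference signal is
pure filter leak, and scaling it by the ratio of the diffuse reflectances of
object and reference (measured without emission filters) gives the object's
scattered component,

    Ssc = (Rd / Rd_ref) * Sbg_ref,      Saf = Sbg - Ssc.

The recovered autofluorescence is then normalized to the fluorescence signal
``Sf0`` of a reference fluorophore medium with known concentration, giving
the dimensionless ``Saf / Sf0`` used by the sensitivity model.

This module works on ROI-averaged scalar signals (camera counts).  A helper
is provided to produce such scalars from a raw grayscale image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SignalRecord:
    """ROI-averaged signals of one excitation wavelength.

    All signals are camera counts acquired under identical conditions
    (exposure, power, optics); ``rd_ratio`` is the object/reference diffuse
    reflectance ratio measured without emission filters.  ``s_total`` (object
    with contrast agent) and ``s_f0`` (reference fluorophore medium) are
    optional; ``*_stderr`` fields carry measurement standard errors used for
    uncertainty propagation.
    """

    wavelength: float
    s_bg: float
    s_bg_ref: float
    rd_ratio: float
    s_f0: float | None = None
    s_total: float | None = None
    s_bg_stderr: float = 0.0
    s_bg_ref_stderr: float = 0.0
    s_f0_stderr: float = 0.0
    acquisition: str = "default"

    def __post_init__(self) -> None:
        for name in ("s_bg", "s_bg_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.rd_ratio > 0:
            raise ValueError("rd_ratio must be > 0 (missing reflectance ratio?)")
        if self.s_f0 is not None and self.s_f0 < 0:
            raise ValueError("s_f0 must be >= 0")


@dataclass(frozen=True)
class SeparatedBackground:
    """Scattered / autofluorescence split of one background record."""

    wavelength: float
    s_sc: float
    s_af: float
    s_af_stderr: float = 0.0
    clipped: bool = False


def separate_background(record: SignalRecord) -> SeparatedBackground:
    """Split a background signal into scatter and autofluorescence.

    ``s_sc = rd_ratio * s_bg_ref``; ``s_af = s_bg - s_sc``.  A negative
    difference (possible only through noise: autofluorescence cannot be
    negative) is clipped to zero and flagged.  Standard errors propagate in
    quadrature: ``var(s_af) = var(s_bg) + rd_ratio**2 * var(s_bg_ref)``.
    """
    s_sc = record.rd_ratio * record.s_bg_ref
    s_af = record.s_bg - s_sc
    stderr = math.hypot(record.s_bg_stderr, record.rd_ratio * record.s_bg_ref_stderr)
    clipped = False
    if s_af < 0:
        s_af = 0.0
        clipped = True
    return SeparatedBackground(
        wavelength=record.wavelength,
        s_sc=s_sc,
        s_af=s_af,
        s_af_stderr=stderr,
        clipped=clipped,
    )


def af_reference_ratio(
    s_af: float,
    s_f0: float,
    acquisition_af: str = "default",
    acquisition_f0: str = "default",
) -> float:
    """Normalize autofluorescence to the reference fluorescence signal.

    Both signals must come from the same acquisition conditions; the optional
    metadata tags assert that.  Returns the dimensionless ``Saf / Sf0``.
    """
    if s_f0 is None or s_f0 <= 0:
        raise ValueError("s_f0 must be > 0: a reference fluorescence signal is required")
    if acquisition_af != acquisition_f0:
        raise ValueError(
            f"acquisition metadata mismatch: {acquisition_af!r} != {acquisition_f0!r}; "
            "Saf and Sf0 must be measured under identical conditions"
        )
    if s_af < 0:
        raise ValueError("s_af must be >= 0")
    return s_af / s_f0


def roi_mean(image: np.ndarray, roi: tuple[int, int, int, int]) -> tuple[float, float, int]:
    """ROI average of a grayscale image.

    ``roi`` is (row0, row1, col0, col1) with half-open bounds.  Returns
    ``(mean, stderr, n_pixels)`` where stderr is the standard error of the
    pixel mean.
    """
    r0, r1, c0, c1 = roi
    patch = np.asarray(image, dtype=float)[r0:r1, c0:c1]
    if patch.size == 0:
        raise ValueError("empty ROI")
    return float(patch.mean()), float(patch.std(ddof=1) / math.sqrt(patch.size)), patch.size


def roi_mean_from_tiff(path: str | Path, roi: tuple[int, int, int, int]) -> tuple[float, float, int]:
    """ROI average of a grayscale TIFF image on disk."""
    import tifffile

    return roi_mean(tifffile.imread(str(path)), roi)


# ---------------------------------------------------------------------------
# Tabular interface

_REQUIRED_COLUMNS = ("wavelength_nm", "s_bg", "s_bg_ref", "rd_ratio")


def records_from_frame(df: pd.DataFrame) -> list[SignalRecord]:
    """Build records from a table with the documented CSV schema.

    Required columns: wavelength_nm, s_bg, s_bg_ref, rd_ratio.  Optional:
    s_f0, s_total, s_bg_stderr, s_bg_ref_stderr, s_f0_stderr.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing required columns: {missing}")

    def _opt(row, col, default=None):
        if col in df.columns and not pd.isna(row[col]):
            return float(row[col])
        return default

    records = []
    for _, row in df.iterrows():
        records.append(
            SignalRecord(
                wavelength=float(row["wavelength_nm"]),
                s_bg=float(row["s_bg"]),
                s_bg_ref=float(row["s_bg_ref"]),
                rd_ratio=float(row["rd_ratio"]),
                s_f0=_opt(row, "s_f0"),
                s_total=_opt(row, "s_total"),
                s_bg_stderr=_opt(row, "s_bg_stderr", 0.0),
                s_bg_ref_stderr=_opt(row, "s_bg_ref_stderr", 0.0),
                s_f0_stderr=_opt(row, "s_f0_stderr", 0.0),
            )
        )
    return records


def separate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`separate_background` to every row of a signal table.

    Returns the input table with added columns s_sc, s_af, s_af_stderr,
    clipped.
    """
    records = records_from_frame(df)
    separated = [separate_background(r) for r in records]
    out = df.copy()
    out["s_sc"] = [s.s_sc for s in separated]
    out["s_af"] = [s.s_af for s in separated]
    out["s_af_stderr"] = [s.s_af_stderr for s in separated]
    out["clipped"] = [s.clipped for s in separated]
    return out


def separate_csv(path_in: str | Path, path_out: str | Path | None = None) -> pd.DataFrame:
    """Read a signal CSV, separate backgrounds, optionally write the result."""
    df = pd.read_csv(path_in, comment="#")
    out = separate_table(df)
    if path_out is not None:
        out.to_csv(path_out, index=False)
    return out
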