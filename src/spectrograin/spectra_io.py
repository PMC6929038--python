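"""Hyperspectral cube handling and flat spectra-table I/O.

Covers the acquisition-side plumbing of the pipeline: panel-based reflectance
conversion ``R = DN / DN_panel * R_panel``, region-of-interest (ROI) mean
extraction from a digital-number cube, front/back side averaging, a minimal
read-only ENVI (.hdr + raw) loader, and the CSV spectra-table dialect that the
rest of the package speaks.

CSV dialect: first column ``sample_id``, second ``label``, remaining columns
named by wavelength in nm (>= 2 decimals); UTF-8 with a mandatory header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import SpectrumSet
from .exceptions import (
    CalibrationError,
    InvalidArgumentError,
    SegmentationError,
    SpectraParseError,
)

__all__ = [
    "HypercubeImage",
    "PanelCalibration",
    "convert_reflectance",
    "extract_roi_mean",
    "average_sides",
    "read_spectra_table",
    "write_spectra_table",
    "read_envi_cube",
]


@dataclass
class HypercubeImage:
    """3-D digital-number cube (rows x cols x bands) with its wavelength grid."""

    dn: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.dn.ndim != 3:
            raise InvalidArgumentError(f"cube must be 3-D, got shape {self.dn.shape}")
        if self.dn.shape[2] != self.wavelengths.size:
            raise InvalidArgumentError(
                f"band dimension {self.dn.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if np.any(self.dn < 0):
            raise InvalidArgumentError("digital numbers must be non-negative")


@dataclass
class PanelCalibration:
    """Per-band digital number and known reflectance of the reference panel."""

    dn_panel: np.ndarray
    r_panel: np.ndarray

    def __post_init__(self) -> None:
        self.dn_panel = np.asarray(self.dn_panel, dtype=float)
        self.r_panel = np.asarray(self.r_panel, dtype=float)
        if self.dn_panel.shape != self.r_panel.shape:
            raise InvalidArgumentError(
                "panel DN and reflectance vectors must have equal length"
            )
        if np.any(self.dn_panel <= 0):
            raise CalibrationError("panel digital numbers must be > 0 in every band")
        if np.any((self.r_panel <= 0) | (self.r_panel > 1)):
            raise CalibrationError("panel reflectance must lie in (0, 1]")


def convert_reflectance(
    dn: np.ndarray,
    cal: PanelCalibration,
    dark: np.ndarray | None = None,
) -> np.ndarray:
    """Panel-referenced reflectance conversion.

    ``R = DN / DN_panel * R_panel`` per band. An optional per-band dark-current
    vector is subtracted from both the sample and panel digital numbers first
    (dark subtraction is normally already applied upstream).
    """
    dn = np.asarray(dn, dtype=float)
    if dn.shape[-1] != cal.dn_panel.size:
        raise InvalidArgumentError(
            f"DN band count {dn.shape[-1]} != calibration band count {cal.dn_panel.size}"
        )
    dn_panel = cal.dn_panel
    if dark is not None:
        dark = np.asarray(dark, dtype=float)
        if dark.shape != cal.dn_panel.shape:
            raise InvalidArgumentError("dark vector length must match band count")
        dn = dn - dark
        dn_panel = dn_panel - dark
        if np.any(dn_panel == 0):
            raise CalibrationError("dark-corrected panel DN hit zero in some band")
    r = dn / dn_panel * cal.r_panel
    if not np.all(np.isfinite(r)):
        raise CalibrationError("reflectance conversion produced non-finite values")
    return r


def extract_roi_mean(
    cube: HypercubeImage,
    threshold_band: float = 685.0,
    threshold: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment the seed and average its digital numbers per band.

    The mask is the largest 4-connected component of pixels whose DN at the
    band nearest ``threshold_band`` (nm) exceeds ``threshold``; the return is
    the per-band mean DN over that mask plus the boolean mask itself.
    """
    wl = cube.wavelengths
    if not (wl.min() <= threshold_band <= wl.max()):
        raise InvalidArgumentError(
            f"threshold_band {threshold_band} nm outside cube range "
            f"[{wl.min()}, {wl.max()}]"
        )
    band = int(np.argmin(np.abs(wl - threshold_band)))
    bright = cube.dn[:, :, band] > threshold
    # default 2-D structure of ndimage.label is 4-connectivity
    labeled, n_comp = ndimage.label(bright)
    if n_comp == 0:
        raise SegmentationError(
            f"no pixel exceeds threshold {threshold} at band {wl[band]:.1f} nm"
        )
    sizes = ndimage.sum_labels(bright, labeled, index=np.arange(1, n_comp + 1))
    mask = labeled == (int(np.argmax(sizes)) + 1)
    mean_dn = cube.dn[mask].mean(axis=0)
    return mean_dn, mask


def average_sides(front: np.ndarray, back: np.ndarray) -> np.ndarray:
    """Arithmetic mean of front- and back-side spectra of one seed."""
    front = np.asarray(front, dtype=float)
    back = np.asarray(back, dtype=float)
    if front.shape != back.shape:
        raise InvalidArgumentError(
            f"front ({front.shape}) and back ({back.shape}) lengths differ"
        )
    return (front + back) / 2.0


# ---------------------------------------------------------------------------
# CSV spectra table
# ---------------------------------------------------------------------------

def write_spectra_table(sset: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as the package's CSV dialect (lossless round trip)."""
    frame = sset.to_dataframe()
    frame.to_csv(path, index=False, float_format="%.12g")


def read_spectra_table(path: str | Path) -> SpectrumSet:
    """Read the CSV spectra-table dialect back into a SpectrumSet."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraParseError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise SpectraParseError(f"{path}: table contains no samples")
    cols = list(frame.columns)
    if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "label":
        raise SpectraParseError(
            f"{path}: first two columns must be 'sample_id' and 'label', got {cols[:2]}"
        )
    band_cols = cols[2:]
    wavelengths = []
    for c in band_cols:
        try:
            wavelengths.append(float(c))
        except ValueError as exc:
            raise SpectraParseError(
                f"{path}: band column {c!r} is not a numeric wavelength"
            ) from exc
    ids = frame["sample_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise SpectraParseError(f"{path}: duplicate sample ids {dup[:5]}")
    data = frame[band_cols]
    bad = data.isna() | ~data.map(np.isreal)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectraParseError(
            f"{path}: non-numeric or missing value at row {r + 2} "
            f"(sample {ids.iloc[r]!r}), column {band_cols[c]!r}"
        )
    try:
        reflectance = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectraParseError(f"{path}: band columns are not numeric: {exc}") from exc
    if not np.all(np.isfinite(reflectance)):
        r, c = np.argwhere(~np.isfinite(reflectance))[0]
        raise SpectraParseError(
            f"{path}: non-finite value at row {r + 2}, column {band_cols[c]!r}"
        )
    return SpectrumSet(
        reflectance=reflectance,
        wavelengths=np.asarray(wavelengths),
        labels=frame["label"].to_numpy(),
        sample_ids=ids.to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# ENVI reader (read-only)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 12: np.uint16}


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI 'key = value' header text, including { ... } list values."""
    header: dict = {}
    # join brace-delimited blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and value.endswith("}"):
            items = [v.strip() for v in value[1:-1].split(",") if v.strip()]
            header[key] = items
        else:
            header[key] = value
    return header


def read_envi_cube(header_path: str | Path, data_path: str | Path | None = None) -> HypercubeImage:
    """Read an ENVI hyperspectral cube (header + raw) into a HypercubeImage.

    Supports BSQ/BIL/BIP interleave, data types 4 (float32) and 12 (uint16),
    and a ``wavelength`` list in the header. Writing cubes is out of scope.
    """
    header_path = Path(header_path)
    text = header_path.read_text(encoding="utf-8", errors="replace")
    if not text.lstrip().upper().startswith("ENVI"):
        raise SpectraParseError(f"{header_path}: missing ENVI magic line")
    hdr = _parse_envi_header(text)
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
        interleave = str(hdr["interleave"]).lower()
    except KeyError as exc:
        raise SpectraParseError(f"{header_path}: missing header field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise SpectraParseError(
            f"{header_path}: unsupported ENVI data type {dtype_code} "
            f"(supported: {sorted(_ENVI_DTYPES)})"
        )
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = int(hdr.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    if "wavelength" not in hdr:
        raise SpectraParseError(f"{header_path}: header lists no wavelengths")
    wavelengths = np.asarray([float(w) for w in hdr["wavelength"]])
    if wavelengths.size != bands:
        raise SpectraParseError(
            f"{header_path}: {wavelengths.size} wavelengths for {bands} bands"
        )
    if data_path is None:
        stem = header_path.with_suffix("")
        for cand in (stem, stem.with_suffix(".raw"), stem.with_suffix(".img"),
                     stem.with_suffix(".dat")):
            if cand.exists() and cand != header_path:
                data_path = cand
                break
        if data_path is None:
            raise SpectraParseError(f"no raw data file found next to {header_path}")
    offset = int(hdr.get("header offset", 0))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise SpectraParseError(
            f"{data_path}: expected {expected} values, found {raw.size}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise SpectraParseError(f"{header_path}: unknown interleave {interleave!r}")
    return HypercubeImage(dn=np.ascontiguousarray(cube, dtype=float), wavelengths=wavelengths)
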