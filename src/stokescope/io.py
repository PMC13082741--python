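"""Readers and writers for cubes, masks and tables.

Cube serialization is multi-page TIFF (one page per band, in wavelength
order) with a JSON sidecar ``<stem>.json`` listing the wavelengths, plane
name and free-form metadata; an ENVI-style header + band-sequential raw
binary pair is available as an alternate format. Label and ROI masks are
single-channel PNG (0 = background, 255 = foreground) with a JSON manifest.
Spectra and p-values travel as tidy CSV via pandas.

Coordinate convention everywhere: row-major rasters, origin at the top-left,
0-based indices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .spectra import PValueSeries, ROIMask, Spectrum

__all__ = [
    "write_cube",
    "read_cube",
    "write_envi_cube",
    "read_envi_cube",
    "write_mask",
    "read_masks",
    "spectra_to_frame",
    "write_spectra_csv",
    "read_spectra_csv",
    "pvalues_to_frame",
    "write_pvalues_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(
    path: str | Path,
    data: np.ndarray,
    wavelengths: np.ndarray | None = None,
    band_labels: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a (bands, rows, cols) cube as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"cube must be (bands, rows, cols), got shape {data.shape}")
    tifffile.imwrite(path, data, photometric="minisblack")
    header = {
        "format": "stokescope-cube",
        "version": 1,
        "shape": list(data.shape),
        "wavelengths_nm": None if wavelengths is None else np.asarray(wavelengths).tolist(),
        "band_labels": None if band_labels is None else list(band_labels),
        "plane_order": "band-ascending",
        "metadata": metadata or {},
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1, default=str))
    return path


def read_cube(path: str | Path):
    """Read a cube written by :func:`write_cube`.

    Returns ``(data, wavelengths, header)`` with the band axis ordered by
    increasing wavelength regardless of on-disk page order. Rejects a
    missing sidecar or a band-count mismatch between sidecar and pages.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"cube sidecar {sidecar} not found; cubes must be written with their "
            f"JSON header (see stokescope.io.write_cube)"
        )
    header = json.loads(sidecar.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    wavelengths = header.get("wavelengths_nm")
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.size != data.shape[0]:
            raise ValueError(
                f"header lists {wavelengths.size} bands but file has "
                f"{data.shape[0]} pages"
            )
        order = np.argsort(wavelengths, kind="stable")
        data = data[order]
        wavelengths = wavelengths[order]
    return data, wavelengths, header


def write_envi_cube(
    path: str | Path,
    data: np.ndarray,
    wavelengths: np.ndarray | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write a cube as ENVI header (.hdr) + band-sequential float64 raw file."""
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    data = np.asarray(data, dtype="<f8")
    if data.ndim == 2:
        data = data[np.newaxis]
    data.tofile(path)
    lines = [
        "ENVI",
        "description = {stokescope cube}",
        f"samples = {data.shape[2]}",
        f"lines = {data.shape[1]}",
        f"bands = {data.shape[0]}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",  # 64-bit float
        "interleave = bsq",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in np.asarray(wavelengths, dtype=float))
        lines += ["wavelength units = nm", "wavelength = {" + wl + "}"]
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(lines) + "\n")
    return path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_brace = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if not in_brace:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip().lower(), value.strip()
            if value.startswith("{") and not value.endswith("}"):
                in_brace, buf = True, [value.lstrip("{")]
            else:
                fields[key] = value.strip("{}").strip()
        else:
            if line.endswith("}"):
                buf.append(line.rstrip("}"))
                fields[key] = " ".join(buf).strip()
                in_brace = False
            else:
                buf.append(line)
    return fields


def read_envi_cube(path: str | Path):
    """Read a BSQ float64 ENVI cube written by :func:`write_envi_cube`."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header {hdr_path} not found")
    fields = _parse_envi_header(hdr_path.read_text())
    if fields.get("interleave", "bsq").lower() != "bsq" or fields.get("data type") != "5":
        raise ValueError("only BSQ float64 ENVI cubes are supported")
    shape = (int(fields["bands"]), int(fields["lines"]), int(fields["samples"]))
    data = np.fromfile(path, dtype="<f8")
    if data.size != np.prod(shape):
        raise ValueError(
            f"raw file holds {data.size} values but header describes {shape}"
        )
    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.asarray(
            [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
        )
        if wavelengths.size != shape[0]:
            raise ValueError(
                f"header lists {wavelengths.size} wavelengths for {shape[0]} bands"
            )
    return data.reshape(shape), wavelengths, fields


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean mask as single-channel PNG (0 background, 255 foreground)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask).astype(bool) * np.uint8(255)))
    return path


def read_masks(directory: str | Path, manifest_name: str = "masks.json") -> list[ROIMask]:
    """Read a directory of PNG masks described by a JSON manifest.

    The manifest is a list of ``{"file", "cell_id", "class_label"}`` records.
    """
    directory = Path(directory)
    manifest = json.loads((directory / manifest_name).read_text())
    out = []
    for rec in manifest:
        img = iio.imread(directory / rec["file"])
        if img.ndim == 3:
            img = img[..., 0]
        out.append(
            ROIMask(
                mask=img > 127,
                cell_id=rec["cell_id"],
                class_label=rec.get("class_label", ""),
                source_plane=rec.get("source_plane", "S0"),
            )
        )
    return out


def spectra_to_frame(spectra: Sequence[Spectrum]) -> pd.DataFrame:
    """Tidy long-format table: one row per (cell, parameter, wavelength)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": s.cell_id,
                    "class": s.class_label,
                    "parameter": s.parameter_name,
                    "wavelength_nm": s.wavelengths,
                    "value": s.values,
                    "n_pixels": s.n_pixels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_spectra_csv(path: str | Path, spectra: Sequence[Spectrum]) -> Path:
    path = Path(path)
    spectra_to_frame(spectra).to_csv(path, index=False)
    return path


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Rebuild Spectrum objects from a tidy CSV written by write_spectra_csv."""
    df = pd.read_csv(path)
    out = []
    for (cell_id, param), grp in df.groupby(["cell_id", "parameter"], sort=False):
        grp = grp.sort_values("wavelength_nm")
        out.append(
            Spectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                n_pixels=int(grp["n_pixels"].iloc[0]),
                parameter_name=str(param),
                cell_id=cell_id,
                class_label=str(grp["class"].iloc[0]),
            )
        )
    return out


def pvalues_to_frame(series: Sequence[PValueSeries]) -> pd.DataFrame:
    frames = []
    for pv in series:
        frame = pd.DataFrame(
            {
                "parameter": pv.parameter_name,
                "wavelength_nm": pv.wavelengths,
                "p_raw": pv.p_values,
                "n_group_a": pv.group_sizes[0],
                "n_group_b": pv.group_sizes[1],
            }
        )
        frame["p_bh"] = pv.adjusted if pv.adjusted is not None else np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_pvalues_csv(path: str | Path, series: Sequence[PValueSeries]) -> Path:
    path = Path(path)
    pvalues_to_frame(series).to_csv(path, index=False)
    return path
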