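"""Readers and writers: images with physical-scale sidecars, bath configs,
uptake CSVs and result tables."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import SpiBands
from .kinetics import DyebathRecord, UptakeSeries, compute_Mt, absorbance_to_concentration
from .morphometry import FibreImage

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_bath_json",
    "write_bath_json",
    "read_uptake_csv",
    "write_uptake_csv",
]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    window_um: float = 100.0
    hill_cutoff: float = 0.5
    spi_bands: SpiBands = SpiBands()
    output_dir: str = "woolscale_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.window_um > 0:
            raise ValueError("window_um must be positive")
        if not 0 < self.hill_cutoff <= 1:
            raise ValueError("hill_cutoff must lie in (0, 1]")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_image(path, sidecar=None) -> FibreImage:
    """Load a grayscale raster plus its mandatory µm-per-pixel sidecar.

    8-bit PNG and 16-bit TIFF are accepted; multi-channel input is converted
    to luminance.  The sidecar defaults to ``<stem>.json`` next to the image
    and must provide ``um_per_px`` — physical units are mandatory.
    """
    path = Path(path)
    side = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not side.exists():
        raise ValueError(f"no physical scale: missing sidecar {side}")
    meta = json.loads(side.read_text())
    if "um_per_px" not in meta:
        raise ValueError(f"no physical scale: sidecar {side} lacks 'um_per_px'")

    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim == 3:
        weights = np.array([0.2126, 0.7152, 0.0722])[: arr.shape[2]]
        arr = arr[..., : weights.size] @ (weights / weights.sum())
    return FibreImage(
        pixels=arr, um_per_px=float(meta["um_per_px"]), id=meta.get("id", path.stem)
    )


def write_image(image: FibreImage, path, bit_depth: int | None = None) -> Path:
    """Write a raster plus its sidecar.  PNG is written as 8-bit, TIFF as
    16-bit (values rescaled from the 0–255 grey convention)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = np.asarray(image.pixels, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        depth = bit_depth or 16
        arr = np.clip(px / 255.0 * (2**depth - 1), 0, 2**depth - 1)
        tifffile.imwrite(path, arr.round().astype(np.uint16))
    else:
        from PIL import Image

        arr = np.clip(px, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr).save(path)
    _sidecar_path(path).write_text(
        json.dumps({"um_per_px": image.um_per_px, "id": image.id}, indent=2)
    )
    return path


def read_bath_json(path) -> DyebathRecord:
    meta = json.loads(Path(path).read_text())
    radius_cm = meta.get("radius_cm")
    if radius_cm is None and "radius_um" in meta:
        radius_cm = meta["radius_um"] * 1e-4
    if radius_cm is None:
        raise ValueError("bath config must provide radius_cm or radius_um")
    calibration = meta.get("calibration")
    return DyebathRecord(
        C0=meta["C0"],
        V=meta["V"],
        W=meta["W"],
        radius_cm=radius_cm,
        calibration=tuple(calibration) if calibration is not None else None,
    )


def write_bath_json(bath: DyebathRecord, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "C0": bath.C0,
        "V": bath.V,
        "W": bath.W,
        "radius_cm": bath.radius_cm,
    }
    if bath.calibration is not None:
        payload["calibration"] = list(bath.calibration)
    path.write_text(json.dumps(payload, indent=2))
    return path


_UPTAKE_COLUMNS = ("mt_mg_g", "ce_mg_ml", "absorbance")


def read_uptake_csv(path, bath: DyebathRecord) -> list[UptakeSeries]:
    """Read an uptake table into per-replicate series.

    The CSV must contain ``time_min`` and exactly one of ``mt_mg_g``,
    ``ce_mg_ml`` or ``absorbance`` (converted via the bath calibration and
    the mass-balance Mt = (C0 - Ce) V / W).  Rows are grouped by an optional
    ``replicate_id`` column; times are sorted with a warning if unordered.
    """
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError("uptake CSV must contain a 'time_min' column")
    present = [c for c in _UPTAKE_COLUMNS if c in df.columns]
    if len(present) != 1:
        raise ValueError(
            f"uptake CSV must contain exactly one of {_UPTAKE_COLUMNS}, found {present}"
        )
    value_col = present[0]
    if (df["time_min"] < 0).any():
        raise ValueError("negative times in uptake CSV")
    if "replicate_id" not in df.columns:
        df = df.assign(replicate_id="r1")

    series = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        if grp["time_min"].duplicated().any():
            raise ValueError(f"duplicate times within replicate {rid!r}")
        if not grp["time_min"].is_monotonic_increasing:
            warnings.warn(f"unsorted times in replicate {rid!r}; sorting")
            grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        if value_col == "absorbance":
            if bath.calibration is None:
                raise ValueError(
                    "absorbance column requires a calibration in the bath config"
                )
            vals = absorbance_to_concentration(vals, bath.calibration)
            value_col_eff = "ce_mg_ml"
        else:
            value_col_eff = value_col
        if value_col_eff == "ce_mg_ml":
            mt = compute_Mt(bath.C0, np.clip(vals, 0.0, bath.C0), bath.V, bath.W)
        else:
            mt = vals
        series.append(
            UptakeSeries(
                bath=bath,
                times_min=tuple(t.tolist()),
                mt_mg_g=tuple(np.asarray(mt, dtype=float).tolist()),
                replicate_id=str(rid),
            )
        )
    return series


def write_uptake_csv(series: list[UptakeSeries], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {
                "replicate_id": s.replicate_id,
                "time_min": s.times_min,
                "mt_mg_g": s.mt_mg_g,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
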