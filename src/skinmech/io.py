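"""Readers and writers for the pipeline's text and image formats.

Relaxation records travel as delimited text with ``# key: value`` header
comments (units, subject, direction, ...) and columns
``time_s,value,phase,cycle,strain``; loading curves as two-column CSV;
images as float TIFF or PNG with a YAML sidecar holding the pixel pitch;
layer ROIs as YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bilinear import LoadingCurve
from .errors import InvalidInputError
from .rheology import RelaxationRecord, TestProtocol
from .spectral import ImageGrid, LayerROI

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_loading_csv",
    "read_loading_csv",
    "write_image",
    "read_image",
    "write_rois_yaml",
    "read_rois_yaml",
]

_RECORD_COLUMNS = ["time_s", "value", "phase", "cycle", "strain"]


def _read_comment_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def write_record_csv(rec: RelaxationRecord, path, meta: dict | None = None) -> None:
    """Write a relaxation record with ``# key: value`` header comments."""
    path = Path(path)
    meta = {"units": rec.units, **(meta or {})}
    df = pd.DataFrame({
        "time_s": rec.t, "value": rec.y, "phase": rec.phase,
        "cycle": rec.cycle, "strain": rec.strain_history,
    })
    buf = _io.StringIO()
    for key, val in meta.items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def read_record_csv(path, protocol: TestProtocol | None = None
                    ) -> tuple[RelaxationRecord, dict[str, str]]:
    """Read a relaxation record; returns the record and its header metadata.

    When the ``strain`` column is missing, the imposed strain history is
    reconstructed from the protocol (constant-rate ramp to the target strain,
    then constant hold).
    """
    path = Path(path)
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "value", "phase", "cycle"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path.name}: missing columns {sorted(missing)}")
    if "strain" in df.columns:
        strain = df["strain"].to_numpy(float)
    elif protocol is not None:
        strain = _reconstruct_strain(df, protocol)
    else:
        raise InvalidInputError(
            f"{path.name}: no strain column and no protocol to reconstruct it")
    rec = RelaxationRecord(
        t=df["time_s"].to_numpy(float),
        y=df["value"].to_numpy(float),
        phase=df["phase"].to_numpy(str),
        cycle=df["cycle"].to_numpy(int),
        strain_history=strain,
        units=meta.get("units", "Pa"),
    )
    return rec, meta


def _reconstruct_strain(df: pd.DataFrame, proto: TestProtocol) -> np.ndarray:
    t = df["time_s"].to_numpy(float)
    cyc = df["cycle"].to_numpy(int)
    strain = np.empty_like(t)
    for c in np.unique(cyc):
        m = cyc == c
        tc = t[m] - t[m][0]
        strain[m] = np.minimum(proto.strain_rate * tc, proto.target_strain)
    return strain


def write_loading_csv(curve: LoadingCurve, path) -> None:
    pd.DataFrame({"strain": curve.strain, "stress_pa": curve.stress}).to_csv(
        path, index=False, float_format="%.10g")


def read_loading_csv(path) -> LoadingCurve:
    df = pd.read_csv(path, comment="#")
    if not {"strain", "stress_pa"} <= set(df.columns):
        raise InvalidInputError(f"{Path(path).name}: need strain,stress_pa columns")
    return LoadingCurve(strain=df["strain"].to_numpy(float),
                        stress=df["stress_pa"].to_numpy(float))


# ---------------------------------------------------------------------------
# images


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(img: ImageGrid, path) -> None:
    """Write a grayscale image (float32 TIFF or 16-bit PNG) plus a YAML
    sidecar with the pixel pitch."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.intensities.astype(np.float32))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = img.intensities
        lo, hi = data.min(), data.max()
        scaled = np.zeros_like(data) if hi <= lo else (data - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    else:
        raise InvalidInputError("supported image formats: .tif/.tiff, .png")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({"pitch_x_um": float(img.pitch_x),
                        "pitch_y_um": float(img.pitch_y)}, fh)


def read_image(path, pitch_x: float | None = None,
               pitch_y: float | None = None) -> ImageGrid:
    """Read a grayscale image; pitch comes from the YAML sidecar unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:  # collapse RGB(A) to luminance
            data = data[..., :3].mean(axis=-1)
    else:
        raise InvalidInputError("supported image formats: .tif/.tiff, .png")
    if pitch_x is None or pitch_y is None:
        side = _sidecar(path)
        if not side.exists():
            raise InvalidInputError(
                f"{path.name}: no pixel pitch given and no sidecar {side.name}")
        with open(side) as fh:
            sc = yaml.safe_load(fh)
        pitch_x = pitch_x if pitch_x is not None else float(sc["pitch_x_um"])
        pitch_y = pitch_y if pitch_y is not None else float(sc["pitch_y_um"])
    return ImageGrid(data, pitch_x=pitch_x, pitch_y=pitch_y)


# ---------------------------------------------------------------------------
# ROIs


def write_rois_yaml(rois: list[LayerROI], path,
                    pitch_x: float | None = None,
                    pitch_y: float | None = None) -> None:
    doc: dict = {"rois": [
        {"name": r.name, "rows": list(r.rows), "cols": list(r.cols)}
        for r in rois]}
    if pitch_x is not None:
        doc["pitch_x_um"] = float(pitch_x)
    if pitch_y is not None:
        doc["pitch_y_um"] = float(pitch_y)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_rois_yaml(path) -> tuple[list[LayerROI], float | None, float | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rois = [LayerROI(d["name"], tuple(d["rows"]), tuple(d["cols"]))
            for d in doc["rois"]]
    return rois, doc.get("pitch_x_um"), doc.get("pitch_y_um")
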