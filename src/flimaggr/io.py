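"""File I/O contracts: TIFF cubes with JSON sidecars, CSV curves, JSON reports.

Formats
-------
* FLIM cube — multi-frame TIFF, frame k = photon counts in TCSPC channel k,
  with a JSON sidecar ``{bin_width_ns, rep_period_ns, pixel_size_um, n_bins}``
  next to it (same stem, ``.json``).
* IRF — CSV with columns ``bin_index,counts``; the binning metadata travels
  in ``# key = value`` comment lines so the file is self-describing.
* Lifetime image — 32-bit float TIFF (NaN = invalid pixel) plus a photon-count
  TIFF and a JSON sidecar with ``min_photons``/``pixel_size_um``.
* Curves, tables and fit reports — CSV with a ``#``-comment provenance header
  (tool version, seed, config hash), and JSON reports with a ``provenance``
  block.  No timestamps are written anywhere, so identical inputs produce
  byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .exceptions import FormatError
from .lifetime import FLIMStack, LifetimeImage, TCSPCHistogram

__all__ = [
    "make_provenance",
    "sha256_file",
    "write_flim_stack",
    "read_flim_stack",
    "stack_to_histogram",
    "write_label_image",
    "read_label_image",
    "write_lifetime_image",
    "read_lifetime_image",
    "write_irf_csv",
    "read_irf_csv",
    "write_table_csv",
    "read_table_csv",
    "write_json_report",
    "read_json_report",
    "save_lifetime_png",
]


def make_provenance(seed: int | None = None, config_hash: str | None = None,
                    **extra) -> dict:
    prov = {"tool": f"flimaggr {__version__}"}
    if seed is not None:
        prov["seed"] = int(seed)
    if config_hash is not None:
        prov["config_sha256"] = config_hash
    prov.update(extra)
    return prov


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# FLIM cubes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_flim_stack(stack: FLIMStack, path: str | Path) -> tuple[Path, Path]:
    """Write a (rows, cols, n_bins) stack as a bins-first multi-frame TIFF."""
    path = Path(path)
    frames = np.moveaxis(stack.data, 2, 0)
    tifffile.imwrite(path, frames.astype(np.int32))
    sidecar = _sidecar_path(path)
    meta = {
        "bin_width_ns": stack.bin_width,
        "rep_period_ns": stack.rep_period,
        "pixel_size_um": stack.pixel_size,
        "n_bins": stack.n_bins,
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path, sidecar


def read_flim_stack(path: str | Path) -> FLIMStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for FLIM cube: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("bin_width_ns", "rep_period_ns", "pixel_size_um"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required key {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:            # single-frame cube
        frames = frames[None]
    if "n_bins" in meta and int(meta["n_bins"]) != frames.shape[0]:
        raise FormatError(
            f"sidecar declares {meta['n_bins']} bins but TIFF has {frames.shape[0]} frames"
        )
    return FLIMStack(
        np.moveaxis(frames, 0, 2),
        bin_width=float(meta["bin_width_ns"]),
        rep_period=float(meta["rep_period_ns"]),
        pixel_size=float(meta["pixel_size_um"]),
    )


def stack_to_histogram(stack: FLIMStack) -> TCSPCHistogram:
    """Collapse a single-pixel (1×1×N) stack to a TCSPCHistogram."""
    if stack.shape != (1, 1):
        raise FormatError("only a 1x1 stack collapses to a single histogram")
    return TCSPCHistogram(stack.data[0, 0].astype(float), stack.bin_width, stack.rep_period)


# ---------------------------------------------------------------------------
# label / lifetime images
# ---------------------------------------------------------------------------

def write_label_image(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32))
    return path


def read_label_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)


def write_lifetime_image(img: LifetimeImage, stem: str | Path) -> tuple[Path, Path, Path]:
    """Write ``<stem>_tau.tif`` (float32), ``<stem>_photons.tif`` and sidecar."""
    stem = Path(stem)
    tau_path = stem.parent / (stem.name + "_tau.tif")
    ph_path = stem.parent / (stem.name + "_photons.tif")
    meta_path = stem.parent / (stem.name + "_meta.json")
    tifffile.imwrite(tau_path, img.tau.astype(np.float32))
    tifffile.imwrite(ph_path, img.photons.astype(np.float32))
    meta_path.write_text(json.dumps(
        {
            "min_photons": img.min_photons,
            "rep_period_ns": img.rep_period,
            "pixel_size_um": img.pixel_size,
        },
        indent=1, sort_keys=True,
    ) + "\n")
    return tau_path, ph_path, meta_path


def read_lifetime_image(stem: str | Path) -> LifetimeImage:
    stem = Path(stem)
    tau_path = stem.parent / (stem.name + "_tau.tif")
    ph_path = stem.parent / (stem.name + "_photons.tif")
    meta_path = stem.parent / (stem.name + "_meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing lifetime-image sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return LifetimeImage(
        tau=np.asarray(tifffile.imread(tau_path), dtype=float),
        photons=np.asarray(tifffile.imread(ph_path), dtype=float),
        min_photons=int(meta["min_photons"]),
        rep_period=float(meta["rep_period_ns"]),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
    )


# ---------------------------------------------------------------------------
# CSV / JSON
# ---------------------------------------------------------------------------

def _write_csv_with_header(df: pd.DataFrame, path: Path, header: dict) -> Path:
    lines = [f"# {k} = {v}" for k, v in header.items()]
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def _read_csv_header(path: Path) -> dict:
    header = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].split("=", 1)
                header[k.strip()] = v.strip()
    return header


def write_irf_csv(irf: TCSPCHistogram, path: str | Path,
                  provenance: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "bin_index": np.arange(irf.n_bins),
        "counts": irf.counts,
    })
    header = dict(provenance or {})
    header["bin_width_ns"] = irf.bin_width
    header["rep_period_ns"] = irf.rep_period
    return _write_csv_with_header(df, path, header)


def read_irf_csv(path: str | Path) -> TCSPCHistogram:
    path = Path(path)
    header = _read_csv_header(path)
    for key in ("bin_width_ns", "rep_period_ns"):
        if key not in header:
            raise FormatError(f"IRF csv {path} missing header key {key!r}")
    df = pd.read_csv(path, comment="#")
    if not {"bin_index", "counts"} <= set(df.columns):
        raise FormatError(f"IRF csv {path} must have bin_index,counts columns")
    n_bins = int(df["bin_index"].max()) + 1
    counts = np.zeros(n_bins)
    counts[df["bin_index"].to_numpy(int)] = df["counts"].to_numpy(float)
    return TCSPCHistogram(counts, float(header["bin_width_ns"]), float(header["rep_period_ns"]))


def write_table_csv(df: pd.DataFrame, path: str | Path,
                    provenance: dict | None = None) -> Path:
    return _write_csv_with_header(df, Path(path), dict(provenance or {}))


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json_report(obj: dict, path: str | Path,
                      provenance: dict | None = None) -> Path:
    path = Path(path)
    payload = dict(obj)
    if provenance:
        payload["provenance"] = provenance

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserialisable type {type(o)!r}")

    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_default) + "\n")
    return path


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_lifetime_png(
    img: LifetimeImage,
    path: str | Path,
    vmin: float = 2.5,
    vmax: float = 7.6,
    cmap: str = "turbo",
) -> Path:
    """Render the lifetime map with a fixed-range colormap (invalid = black)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    shown = np.ma.masked_invalid(img.tau)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.imshow(shown, cmap=cm, vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="lifetime (ns)")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
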