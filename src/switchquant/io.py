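"""File formats: window CSVs with metadata headers, manifests, results.

The CSV dialect is fixed (comma, UTF-8, '.' decimal, header row) and
floats are written with 9 significant digits so repeated runs produce
byte-identical, checksummable files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cyto import EventTable
from .pmf import PmfProfile, UmbrellaWindow

FLOAT_FMT = "%.9g"


def write_window_csv(window: UmbrellaWindow, path) -> None:
    """One umbrella window: '# key=value' metadata then time_ns, xi_angstrom."""
    path = Path(path)
    t = (np.arange(window.series.size) + 1) * window.sampling_interval_ns
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# center={window.center:.9g}\n")
        fh.write(f"# k={window.spring_constant:.9g}\n")
        fh.write(f"# sampling_interval_ns={window.sampling_interval_ns:.9g}\n")
        fh.write("time_ns,xi_angstrom\n")
        for ti, xi in zip(t, window.series):
            fh.write(f"{ti:.9g},{xi:.9g}\n")


def read_window_csv(path) -> UmbrellaWindow:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
            pos += 1
    df = pd.read_csv(path, comment="#")
    return UmbrellaWindow(
        center=meta["center"],
        spring_constant=meta["k"],
        series=df["xi_angstrom"].to_numpy(dtype=float),
        sampling_interval_ns=meta["sampling_interval_ns"],
    )


def write_window_panel(windows: Sequence[UmbrellaWindow], outdir) -> Path:
    """Write one CSV per window plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, win in enumerate(windows):
        name = f"window_{i:02d}.csv"
        write_window_csv(win, outdir / name)
        rows.append({"file": name, "center": win.center, "spring_constant": win.spring_constant})
    manifest = outdir / "windows_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=FLOAT_FMT)
    return manifest


def read_window_panel(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [read_window_csv(manifest_path.parent / row["file"]) for _, row in df.iterrows()]


def write_pmf_csv(profile: PmfProfile, path) -> None:
    df = pd.DataFrame(
        {
            "bin_center_A": profile.bin_centers,
            "F_kcal_mol": profile.F,
            "sigma_F_kcal_mol": profile.sigma_F,
            "defined_flag": profile.defined.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_run_summary(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_events_csv(events: EventTable, path) -> None:
    cols = [events.channels["fsc"], events.channels["ssc"], events.channels["fl"]]
    events.data[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def write_image_pair(li, image_path, mask_path) -> None:
    import tifffile

    tifffile.imwrite(image_path, np.asarray(li.image, dtype=np.uint16))
    tifffile.imwrite(mask_path, np.asarray(li.mask, dtype=np.uint16))
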