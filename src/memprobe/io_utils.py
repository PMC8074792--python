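"""File helpers shared by the batch pipelines and the CLI: TIFF image pairs,
seed JSON files, spectrum CSVs."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from memprobe.gp_imaging import ImagePair, SeedSet
from memprobe.spectra import SpectrumScan


def load_seed_json(path) -> SeedSet:
    """Seed JSON: {"membrane": [[r, c], ...], "interior": [...], "background": [...]}."""
    with open(path) as fh:
        raw = json.load(fh)
    if "membrane" not in raw:
        raise ValueError(f"{path}: seed file must define membrane seeds")
    as_coords = lambda pts: [(int(r), int(c)) for r, c in pts]
    return SeedSet(membrane=as_coords(raw["membrane"]),
                   interior=as_coords(raw.get("interior", [])),
                   background=as_coords(raw.get("background", [])))


def save_seed_json(seeds: SeedSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({"membrane": [list(p) for p in seeds.membrane],
                   "interior": [list(p) for p in seeds.interior],
                   "background": [list(p) for p in seeds.background]}, fh)


def load_image_pair(blue_path, red_path=None) -> ImagePair:
    """An image pair from one 2-channel TIFF or two single-channel TIFFs."""
    if red_path is None:
        stack = tifffile.imread(blue_path)
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError(f"{blue_path}: expected a 2-channel TIFF stack")
        return ImagePair(blue=stack[0].astype(float), red=stack[1].astype(float))
    return ImagePair(blue=tifffile.imread(blue_path).astype(float),
                     red=tifffile.imread(red_path).astype(float))


def save_image_pair(pair: ImagePair, path) -> None:
    tifffile.imwrite(path, np.stack([pair.blue, pair.red]).astype(np.float32))


def load_image_entry(row) -> tuple[ImagePair, SeedSet]:
    """Manifest-row loader for gp_imaging.batch_image_gp."""
    red = row.get("red_path") if hasattr(row, "get") else row["red_path"]
    pair = load_image_pair(row["blue_path"], red if red and not pd.isna(red) else None)
    return pair, load_seed_json(row["seeds_path"])


def load_spectrum_csv(path, emission_nm: float | None = None) -> SpectrumScan:
    """Spectrum CSV with columns wavelength_nm,intensity."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: spectrum CSV missing column {col!r}")
    return SpectrumScan(wavelengths_nm=df["wavelength_nm"].to_numpy(float),
                        intensities=df["intensity"].to_numpy(float),
                        emission_nm=emission_nm)


def save_spectrum_csv(scan: SpectrumScan, path) -> None:
    pd.DataFrame({"wavelength_nm": scan.wavelengths_nm,
                  "intensity": scan.intensities}).to_csv(path, index=False)
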