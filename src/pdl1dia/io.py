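"""Reading and writing of stacks, truth tables, label maps and reports.

ChannelStack ↔ multi-page TIFF (one page per channel, channel name in the
page description) with a JSON sidecar for pixel size and channel order.
CoreTruth ↔ per-cell CSV plus a GeoJSON-style nest-polygon file and a
params JSON.  H-DAB images are plain RGB TIFFs with the stain matrix in a
sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import ChannelStack, CoreTruth, HDABImage, SimParams, TrueCell


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _p(prefix, ext: str) -> Path:
    return Path(str(prefix) + ext)


def write_channel_stack(path, stack: ChannelStack) -> None:
    path = Path(path)
    names = list(stack.channels)
    with tifffile.TiffWriter(path) as tif:
        for name in names:
            tif.write(stack.channels[name].astype(np.float32), description=name)
    _sidecar(path).write_text(json.dumps(
        {"pixel_size_um": stack.pixel_size_um, "channels": names}
    ))


def read_channel_stack(path) -> ChannelStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray().astype(float) for p in tif.pages]
    names = meta["channels"]
    if len(pages) != len(names):
        raise ValueError(f"{path}: {len(pages)} pages but {len(names)} channel names")
    return ChannelStack(dict(zip(names, pages)), meta["pixel_size_um"])


def write_truth(prefix, truth: CoreTruth) -> None:
    """Write <prefix>.cells.csv, <prefix>.nests.json and <prefix>.params.json."""
    prefix = Path(prefix)
    truth.to_dataframe().to_csv(_p(prefix, ".cells.csv"), index=False)
    nests = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"nest": i},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [np.vstack([v, v[:1]]).tolist()],
                },
            }
            for i, v in enumerate(truth.nests)
        ],
    }
    _p(prefix, ".nests.json").write_text(json.dumps(nests))
    params = dataclasses.asdict(truth.params)
    params["crosstalk"] = np.asarray(params["crosstalk"]).tolist()
    _p(prefix, ".params.json").write_text(json.dumps(params))


def read_truth(prefix) -> CoreTruth:
    prefix = Path(prefix)
    params_d = json.loads(_p(prefix, ".params.json").read_text())
    params = SimParams(**{**params_d, "crosstalk": np.asarray(params_d["crosstalk"])})
    cells_df = pd.read_csv(_p(prefix, ".cells.csv"), float_precision="round_trip")
    cells = [
        TrueCell(int(r.id), float(r.x), float(r.y), float(r.radius),
                 str(r.lineage), bool(r.pdl1), bool(r.intratumoural))
        for r in cells_df.itertuples()
    ]
    nest_d = json.loads(_p(prefix, ".nests.json").read_text())
    nests = [
        np.asarray(f["geometry"]["coordinates"][0][:-1], dtype=float)
        for f in nest_d["features"]
    ]
    return CoreTruth(cells=cells, nests=nests, params=params)


def write_hdab(path, img: HDABImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.rgb, photometric="rgb")
    _sidecar(path).write_text(json.dumps({"stain_matrix": img.stain_matrix.tolist()}))


def read_hdab(path) -> HDABImage:
    path = Path(path)
    rgb = tifffile.imread(path)
    sm = np.asarray(json.loads(_sidecar(path).read_text())["stain_matrix"])
    return HDABImage(rgb=rgb, stain_matrix=sm)


def write_label_map(path, labels) -> None:
    """Label images as a 2-page 16-bit TIFF (nucleus page, cell page)."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        tif.write(labels.nucleus_labels.astype(np.uint16), description="nucleus_labels")
        tif.write(labels.cell_labels.astype(np.uint16), description="cell_labels")


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    if "pdl1_call" in table.columns:
        table["pdl1_call"] = table["pdl1_call"].astype("boolean")
    return table


def write_cell_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
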