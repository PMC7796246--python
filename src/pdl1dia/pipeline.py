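"""End-to-end analysis of single cores for both modalities.

One function per scoring path: ``analyse_mif`` runs detection on DAPI,
expansion, measurement, the gating cascade and the tumour proportion score;
``analyse_dab`` runs detection on the deconvolved haematoxylin channel of a
pseudo-H-DAB PD-L1 section and scores cells on DAB optical density within
the tumour compartment.  These are the building blocks the experiments and
the command-line interface compose.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as draw_polygon

from . import phenotype as ph
from . import score as sc
from . import segment as seg
from . import simulate as sim


def nest_mask(truth: sim.CoreTruth) -> np.ndarray:
    """Rasterise the nest polygons into a binary tumour-region mask."""
    h = w = truth.params.core_diameter_px
    mask = np.zeros((h, w), dtype=bool)
    for verts in truth.nests:
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
        mask[rr, cc] = True
    return mask


def match_to_truth(table, truth: sim.CoreTruth, max_dist_px: float = 6.0):
    """Nearest-neighbour match of detected centroids to true cells.

    Adds ``matched_truth_id`` (−1 where unmatched), ``true_lineage`` and
    ``true_pdl1`` columns.  Greedy one-to-one matching on ascending distance.
    """
    out = table.copy()
    out["matched_truth_id"] = -1
    out["true_lineage"] = ""
    out["true_pdl1"] = False
    if len(out) == 0 or not truth.cells:
        return out
    det = out[["x", "y"]].to_numpy(float)
    tru = np.array([[c.x, c.y] for c in truth.cells])
    d = np.sqrt(((det[:, None, :] - tru[None, :, :]) ** 2).sum(-1))
    pairs = np.argwhere(d <= max_dist_px)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_det, used_tru = set(), set()
    idx = out.index.to_numpy()
    for di, ti in pairs[order]:
        if di in used_det or ti in used_tru:
            continue
        used_det.add(di)
        used_tru.add(ti)
        c = truth.cells[ti]
        out.loc[idx[di], ["matched_truth_id", "true_lineage", "true_pdl1"]] = (c.id, c.lineage, c.pdl1_positive)
    return out


def segment_and_measure(
    stack: sim.ChannelStack,
    seg_params: seg.SegmentationParams | None = None,
    dab_od: dict[str, np.ndarray] | None = None,
):
    """DAPI detection → cell expansion → per-cell measurement."""
    seg_params = seg_params or seg.SegmentationParams()
    nuclei = seg.detect_nuclei(stack.channels["DAPI"], seg_params)
    labels = seg.expand_cells(nuclei, stack.pixel_size_um, seg_params)
    return labels, seg.measure_cells(labels, stack, dab_od=dab_od)


def analyse_mif(
    truth: sim.CoreTruth,
    seg_params: seg.SegmentationParams | None = None,
    cascade: ph.CascadeConfig | None = None,
    scheme: sc.CategoryScheme | None = None,
    core_id: str = "core",
    stack: sim.ChannelStack | None = None,
):
    """Full fluorescence path on one core; returns (classified table, CoreScore)."""
    stack = stack if stack is not None else sim.render_channels(truth)
    _, table = segment_and_measure(stack, seg_params)
    table = ph.classify_cells(table, cascade or ph.CascadeConfig())
    return table, sc.tumour_proportion_score(table, core_id=core_id, scheme=scheme)


def analyse_mif_naive(
    truth: sim.CoreTruth,
    seg_params: seg.SegmentationParams | None = None,
    cascade: ph.CascadeConfig | None = None,
    scheme: sc.CategoryScheme | None = None,
    core_id: str = "core",
    stack: sim.ChannelStack | None = None,
):
    """Fluorescence path with the naive PD-L1-first ordering."""
    stack = stack if stack is not None else sim.render_channels(truth)
    _, table = segment_and_measure(stack, seg_params)
    table = ph.naive_pdl1_first(table, cascade or ph.CascadeConfig(), nests=truth.nests)
    return table, sc.naive_tumour_proportion_score(table, core_id=core_id, scheme=scheme)


def analyse_dab(
    truth: sim.CoreTruth,
    marker: str = "PDL1",
    seg_params: seg.SegmentationParams | None = None,
    scoring: sc.ScoringConfig | None = None,
    core_id: str = "core",
    serial_section: bool = True,
    tumour_region: str = "nests",
):
    """Chromogenic path: render H-DAB, detect on haematoxylin, score on DAB OD.

    By default the DAB slide is an emulated *serial* section of the same
    core (jittered, thinned), as adjacent slides are in practice.  The
    tumour compartment comes from the nest-polygon mask (``"nests"``) — the
    stand-in for a trained tumour/stroma classifier — or from cells whose
    own DAB footprint marks them when scoring a CK slide.
    """
    seg_params = seg_params or seg.SegmentationParams()
    scoring = scoring or sc.ScoringConfig()
    section = sim.emulate_serial_section(truth) if serial_section else truth
    hdab = sim.render_hdab(section, marker)
    od_h, od_d = seg.deconvolve_hdab(hdab)
    nuclei = seg.detect_nuclei(od_h, seg_params)
    labels = seg.expand_cells(nuclei, truth.params.pixel_size_um, seg_params)
    table = seg.measure_cells(labels, dab_od={"dab_od": od_d})
    if tumour_region == "nests":
        mask = nest_mask(section)
        iy = np.clip(np.round(table["y"].to_numpy()).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip(np.round(table["x"].to_numpy()).astype(int), 0, mask.shape[1] - 1)
        table["tumour_class"] = mask[iy, ix]
    elif tumour_region == "all":
        table["tumour_class"] = True
    else:
        raise ValueError(f"unknown tumour_region {tumour_region!r}")
    return table, sc.score_dab(table, scoring, core_id=core_id)


def dab_positive_count(table, threshold: float = 0.15, od_col: str = "dab_od_nucleus") -> int:
    """Number of detected cells whose DAB optical density passes the threshold."""
    return int((table[od_col] >= threshold).sum())
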