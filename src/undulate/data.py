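"""Containers and on-disk formats for per-frame detections.

A detection is one segmented cell in one frame: a boolean mask patch
plus its offset inside the full camera frame, with centroid and area
already converted to physical units.  Datasets are written as a
multi-page TIFF (one page per frame) plus a JSON-lines sidecar holding
per-detection records and, for synthetic data, the generative ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Detection:
    """One segmented cell in one frame."""

    frame_index: int
    mask: np.ndarray              # boolean patch
    offset: tuple[int, int]       # (row0, col0) of the patch in the frame
    centroid: tuple[float, float]  # (x, y) in µm, channel coordinates
    area: float                   # µm²
    truth: dict | None = None     # generative ground truth, if synthetic

    def mask_in_frame(self, frame_shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(frame_shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0:r0 + h, c0:c0 + w] = self.mask
        return out


@dataclass
class Dataset:
    """Frame-indexed detections plus synthetic ground truth."""

    detections: list[Detection]
    frame_shape: tuple[int, int]
    pixel_size: float
    fps: float
    n_frames: int
    cells: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def by_frame(self) -> dict[int, list[Detection]]:
        frames: dict[int, list[Detection]] = {}
        for det in self.detections:
            frames.setdefault(det.frame_index, []).append(det)
        return frames

    def render_frame(self, frame_index: int) -> np.ndarray:
        frame = np.zeros(self.frame_shape, dtype=np.uint8)
        for det in self.detections:
            if det.frame_index == frame_index:
                r0, c0 = det.offset
                h, w = det.mask.shape
                frame[r0:r0 + h, c0:c0 + w] |= det.mask.astype(np.uint8)
        return frame


def _round(x: float, nd: int = 6) -> float:
    """Fixed decimal rounding so serialized records are byte-stable."""
    return round(float(x), nd)


def detection_record(det: Detection) -> dict:
    rec = {
        "frame_index": int(det.frame_index),
        "offset": [int(det.offset[0]), int(det.offset[1])],
        "centroid_um": [_round(det.centroid[0]), _round(det.centroid[1])],
        "area_um2": _round(det.area),
    }
    if det.truth is not None:
        rec["truth"] = {
            k: (_round(v) if isinstance(v, float) else v)
            for k, v in det.truth.items()
        }
    return rec


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  stem: str = "dataset") -> dict[str, Path]:
    """Write masks as a multi-page TIFF and detections as JSON-lines.

    Only frames that contain at least one cell are written (empty
    frames dominate a recording and carry no information); the sidecar
    header maps TIFF pages back to camera frame indices.  Pages are
    streamed one at a time and zlib-compressed, so memory stays at one
    frame and the output is deterministic: no timestamps or
    environment-dependent metadata are embedded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{stem}_masks.tiff"
    jsonl_path = out_dir / f"{stem}_detections.jsonl"

    by_frame = dataset.by_frame()
    frame_pages = sorted(by_frame)
    with tifffile.TiffWriter(tiff_path) as writer:
        for frame_index in frame_pages:
            frame = np.zeros(dataset.frame_shape, dtype=np.uint8)
            for det in by_frame[frame_index]:
                r0, c0 = det.offset
                h, w = det.mask.shape
                frame[r0:r0 + h, c0:c0 + w] |= det.mask.astype(np.uint8)
            writer.write(frame, photometric="minisblack",
                         compression="zlib", contiguous=False)

    with open(jsonl_path, "w") as fh:
        header = {
            "frame_shape": list(dataset.frame_shape),
            "pixel_size_um": dataset.pixel_size,
            "fps": dataset.fps,
            "n_frames": int(dataset.n_frames),
            "frame_pages": [int(i) for i in frame_pages],
            "meta": dataset.meta,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for det in dataset.detections:
            fh.write(json.dumps(detection_record(det), sort_keys=True) + "\n")
    return {"masks": tiff_path, "detections": jsonl_path}


def load_detections(jsonl_path: str | Path,
                    tiff_path: str | Path | None = None
                    ) -> tuple[list[Detection], dict]:
    """Read detections back; masks are re-cut from the TIFF if given.

    Pages are decoded one at a time (detections are grouped by frame),
    so memory stays at a single frame regardless of recording length.
    Each detection's mask is the connected component at its recorded
    centroid; overlapping cells therefore merge, exactly as they would
    for a real segmenter, and are left for the filters to reject.
    """
    jsonl_path = Path(jsonl_path)
    detections: list[Detection] = []
    with open(jsonl_path) as fh:
        header = json.loads(fh.readline())
        records = [json.loads(line) for line in fh]

    page_of = {f: i for i, f in enumerate(header.get("frame_pages", []))}
    tif = tifffile.TiffFile(tiff_path) if tiff_path is not None else None
    try:
        from scipy import ndimage
        cache_frame, cache_lab = None, None
        for rec in sorted(records, key=lambda r: r["frame_index"]):
            r0, c0 = rec["offset"]
            mask = np.zeros((1, 1), dtype=bool)
            if tif is not None and rec["frame_index"] in page_of:
                if cache_frame != rec["frame_index"]:
                    page = tif.pages[page_of[rec["frame_index"]]]
                    cache_lab, _ = ndimage.label(page.asarray() > 0)
                    cache_frame = rec["frame_index"]
                cx = rec["centroid_um"][0]
                col = int(round((cx - header["meta"].get("x_origin_um", 0.0))
                                / header["pixel_size_um"]))
                row = int(round(header["frame_shape"][0] / 2
                                + rec["centroid_um"][1]
                                / header["pixel_size_um"]))
                row = min(max(row, 0), header["frame_shape"][0] - 1)
                col = min(max(col, 0), header["frame_shape"][1] - 1)
                label = cache_lab[row, col]
                if label:
                    comp = cache_lab == label
                    rows = np.any(comp, axis=1).nonzero()[0]
                    cols = np.any(comp, axis=0).nonzero()[0]
                    r0, c0 = int(rows[0]), int(cols[0])
                    mask = comp[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
            detections.append(Detection(
                frame_index=rec["frame_index"],
                mask=mask,
                offset=(r0, c0),
                centroid=tuple(rec["centroid_um"]),
                area=rec["area_um2"],
                truth=rec.get("truth"),
            ))
    finally:
        if tif is not None:
            tif.close()
    return detections, header
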