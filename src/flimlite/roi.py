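"""Region-of-interest bookkeeping and per-ROI decay aggregation.

ROIs are sets of (row, col) pixel coordinates, 0-based with row 0 at the
top, matching the raster order of label-mask TIFFs. ROIs inside one
:class:`ROISet` may overlap; each analysis treats every ROI independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DecayCurve, FLIDataset, LabelMask
from .errors import ValidationError

__all__ = [
    "ROI",
    "ROISet",
    "rois_from_labels",
    "rois_from_threshold",
    "roi_grid",
    "merge_rois",
    "explode_to_pixels",
    "roi_decay",
    "render_mask",
]


@dataclass
class ROI:
    id: int
    pixels: frozenset[tuple[int, int]]
    name: str | None = None

    def __post_init__(self) -> None:
        self.pixels = frozenset((int(r), int(c)) for r, c in self.pixels)
        if not self.pixels:
            raise ValidationError(f"ROI {self.id} has no pixels")

    @property
    def size(self) -> int:
        return len(self.pixels)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (rows, cols) index arrays, suitable for fancy indexing."""
        coords = np.array(sorted(self.pixels), dtype=int)
        return coords[:, 0], coords[:, 1]


@dataclass
class ROISet:
    rois: list[ROI]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValidationError("ROI ids must be unique")
        rows, cols = self.shape
        for r in self.rois:
            for (i, j) in r.pixels:
                if not (0 <= i < rows and 0 <= j < cols):
                    raise ValidationError(
                        f"ROI {r.id} pixel ({i}, {j}) outside image {self.shape}"
                    )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def get(self, roi_id: int) -> ROI:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(f"no ROI with id {roi_id}")

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.rois]


def rois_from_labels(mask: LabelMask) -> ROISet:
    """One ROI per distinct non-zero label, ordered by label value."""
    rois = []
    for label in mask.label_values():
        rr, cc = np.nonzero(mask.labels == label)
        rois.append(ROI(id=int(label), pixels=frozenset(zip(rr.tolist(), cc.tolist()))))
    return ROISet(rois=rois, shape=mask.shape)


def rois_from_threshold(
    ds: FLIDataset,
    min_counts: float,
    connectivity: int = 8,
    single_roi: bool = False,
) -> ROISet:
    """ROIs from pixels whose total intensity reaches ``min_counts``.

    By default each connected component (4- or 8-connectivity) becomes one
    ROI, ids 1..n in raster order of discovery; ``single_roi=True`` instead
    lumps every above-threshold pixel into one ROI.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    above = ds.intensity_image() >= min_counts
    shape = ds.frame_shape
    if single_roi:
        rr, cc = np.nonzero(above)
        if rr.size == 0:
            return ROISet(rois=[], shape=shape)
        return ROISet(
            rois=[ROI(id=1, pixels=frozenset(zip(rr.tolist(), cc.tolist())))],
            shape=shape,
        )
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labeled, n = ndimage.label(above, structure=structure)
    rois = []
    for label in range(1, n + 1):
        rr, cc = np.nonzero(labeled == label)
        rois.append(ROI(id=label, pixels=frozenset(zip(rr.tolist(), cc.tolist()))))
    return ROISet(rois=rois, shape=shape)


def roi_grid(shape: tuple[int, int], cell: tuple[int, int]) -> ROISet:
    """Tile the image with h x w cells; partial edge cells are kept."""
    h, w = cell
    if h < 1 or w < 1:
        raise ValidationError("grid cell dimensions must be >= 1")
    rows, cols = shape
    rois = []
    roi_id = 1
    for r0 in range(0, rows, h):
        for c0 in range(0, cols, w):
            pixels = frozenset(
                (i, j)
                for i in range(r0, min(r0 + h, rows))
                for j in range(c0, min(c0 + w, cols))
            )
            rois.append(ROI(id=roi_id, pixels=pixels))
            roi_id += 1
    return ROISet(rois=rois, shape=shape)


def merge_rois(rs: ROISet, ids: list[int]) -> ROISet:
    """Replace the named ROIs by their union; new id = smallest merged id."""
    if not ids:
        raise ValidationError("merge needs at least one ROI id")
    members = [rs.get(i) for i in ids]  # KeyError on unknown id
    merged = ROI(
        id=min(ids),
        pixels=frozenset().union(*(m.pixels for m in members)),
        name="+".join(str(i) for i in sorted(ids)),
    )
    kept: list[ROI] = []
    inserted = False
    for r in rs.rois:
        if r.id in ids:
            if not inserted:
                kept.append(merged)
                inserted = True
        else:
            kept.append(r)
    return ROISet(rois=kept, shape=rs.shape)


def explode_to_pixels(rs: ROISet, roi_id: int) -> ROISet:
    """Replace one ROI by a single-pixel ROI per member pixel."""
    target = rs.get(roi_id)  # KeyError on unknown id
    next_id = max(rs.ids) + 1
    singles = []
    for k, (r, c) in enumerate(sorted(target.pixels)):
        singles.append(ROI(id=next_id + k, pixels=frozenset({(r, c)}), name=f"{roi_id}:{r},{c}"))
    kept: list[ROI] = []
    for r in rs.rois:
        if r.id == roi_id:
            kept.extend(singles)
        else:
            kept.append(r)
    return ROISet(rois=kept, shape=rs.shape)


def roi_decay(ds: FLIDataset, roi: ROI) -> DecayCurve:
    """Decay of an ROI: per-bin sum of the member pixels' counts."""
    rows, cols = ds.frame_shape
    ri, ci = roi.indices()
    if ri.max(initial=0) >= rows or ci.max(initial=0) >= cols:
        raise ValidationError(f"ROI {roi.id} does not fit dataset shape {ds.frame_shape}")
    counts = ds.counts[:, ri, ci].sum(axis=1)
    return DecayCurve(time_ns=ds.time_axis.bin_centers_ns.copy(), counts=counts.astype(float))


def render_mask(rs: ROISet) -> LabelMask:
    """Paint each ROI's id into a label image (later ROIs win on overlap)."""
    labels = np.zeros(rs.shape, dtype=np.int64)
    for r in rs.rois:
        ri, ci = r.indices()
        labels[ri, ci] = r.id
    return LabelMask(labels)
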