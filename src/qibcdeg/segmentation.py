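"""Nuclear segmentation, cytoplasmic ring masks, and per-cell intensity features.

This is the CellProfiler-equivalent stage of the pipeline: a nuclear mask is
built from the DAPI channel (Otsu threshold, hole filling, distance-transform
watershed to split touching nuclei), a ring mask approximates the cytoplasm
just outside each nucleus, and per-cell mean/integrated intensities are
measured in every channel with per-field lower-quartile background
subtraction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk as disk_footprint
from skimage.feature import peak_local_max
from skimage.segmentation import watershed


def segment_nuclei(
    dapi_image: np.ndarray,
    min_area: int = 80,
    max_area: int = 5000,
    exclude_border: bool = True,
) -> np.ndarray:
    """Segment nuclei from a DAPI image into a labelled mask.

    Pipeline: global Otsu threshold -> fill holes -> split touching nuclei by
    watershed on the distance transform -> drop components outside
    ``[min_area, max_area]`` (and, by default, components touching the image
    border).  Labels are renumbered 1..K.  A constant image yields an empty
    mask rather than an error.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    min_sep = max(1, int(round(math.sqrt(min_area / math.pi))))
    peaks = peak_local_max(
        distance, min_distance=min_sep, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    # peak_local_max orders by intensity; re-order row-major so marker ids are
    # stable and ties resolve to the lowest label id
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    for i, (r, c) in enumerate(peaks[order], start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=mask)

    return _filter_and_renumber(labels, min_area, max_area, exclude_border)


def _filter_and_renumber(labels, min_area, max_area, exclude_border):
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    border = set()
    if exclude_border:
        for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
            border.update(np.unique(edge).tolist())
    for prop in regionprops(labels):
        if prop.label in border:
            continue
        if not (min_area <= prop.area <= max_area):
            continue
        out[labels == prop.label] = next_id
        next_id += 1
    return out


def ring_mask(nuclei: np.ndarray, gap: int = 1, width: int = 5) -> np.ndarray:
    """Cytoplasmic ring mask: an annulus ``gap`` px outside each nucleus.

    Ring k = dilate(nucleus k, gap + width) minus dilate(nucleus k, gap),
    excluding every nucleus pixel.  Pixels claimed by several rings are
    assigned to the nucleus with the nearer centroid.  Rings are clipped at
    the image border.  Ring labels share the nucleus ids.
    """
    if gap < 0 or width < 1:
        raise ValueError("require gap >= 0 and width >= 1")
    nuclei = np.asarray(nuclei)
    out = np.zeros_like(nuclei, dtype=np.int32)
    best_d2 = np.full(nuclei.shape, np.inf)
    any_nucleus = nuclei > 0
    outer_fp = disk_footprint(gap + width)
    inner_fp = disk_footprint(gap) if gap > 0 else None
    pad = gap + width + 1
    for prop in regionprops(nuclei.astype(np.int32)):
        r0, c0, r1, c1 = prop.bbox
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p, c1p = min(r1 + pad, nuclei.shape[0]), min(c1 + pad, nuclei.shape[1])
        sub = nuclei[r0p:r1p, c0p:c1p] == prop.label
        outer = ndi.binary_dilation(sub, structure=outer_fp)
        inner = ndi.binary_dilation(sub, structure=inner_fp) if inner_fp is not None else sub
        ring = outer & ~inner & ~any_nucleus[r0p:r1p, c0p:c1p]
        rr, cc = np.nonzero(ring)
        if rr.size == 0:
            continue
        cy, cx = prop.centroid
        d2 = (rr + r0p - cy) ** 2 + (cc + c0p - cx) ** 2
        view_out = out[r0p:r1p, c0p:c1p]
        view_d2 = best_d2[r0p:r1p, c0p:c1p]
        closer = d2 < view_d2[rr, cc]
        view_out[rr[closer], cc[closer]] = prop.label
        view_d2[rr[closer], cc[closer]] = d2[closer]
    return out


def lower_quartile_background(image: np.ndarray) -> float:
    """Per-field background estimate: the 25th percentile of all pixels."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    return float(np.percentile(image, 25))


def extract_cell_features(
    channels: dict[str, np.ndarray],
    nuclei: np.ndarray,
    rings: np.ndarray | None = None,
    field_id: str = "",
) -> pd.DataFrame:
    """Per-nucleus intensity features for every channel.

    For each nucleus and channel: nuclear MFI (mean over nucleus pixels),
    integrated intensity (sum), ring MFI (mean over the matching ring label),
    the per-field lower-quartile background, and background-corrected MFIs
    (``max(raw - background, 0)``).  One row per nucleus.
    """
    nuclei = np.asarray(nuclei)
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    nmax = int(nuclei.max()) if ids.size else 0
    flat = nuclei.ravel()
    counts = np.bincount(flat, minlength=nmax + 1)

    if rings is not None:
        rings = np.asarray(rings)
        if rings.shape != nuclei.shape:
            raise ValueError("ring mask shape differs from nucleus mask")
        extra = set(np.unique(rings[rings > 0]).tolist()) - set(ids.tolist())
        if extra:
            raise ValueError(f"ring labels with no matching nucleus: {sorted(extra)[:5]}")
        rflat = rings.ravel()
        rcounts = np.bincount(rflat, minlength=nmax + 1)

    props = {p.label: p for p in regionprops(nuclei.astype(np.int32))}
    out = pd.DataFrame(
        {
            "cell_id": ids,
            "field_id": field_id,
            "area": counts[ids],
            "centroid_x": [props[i].centroid[1] for i in ids],
            "centroid_y": [props[i].centroid[0] for i in ids],
        }
    )
    for name, img in channels.items():
        img = np.asarray(img, dtype=float)
        if img.shape != nuclei.shape:
            raise ValueError(f"channel {name!r} shape differs from nucleus mask")
        sums = np.bincount(flat, weights=img.ravel(), minlength=nmax + 1)
        bg = lower_quartile_background(img)
        mfi = sums[ids] / counts[ids]
        out[f"{name}_mfi"] = mfi
        out[f"{name}_integrated"] = sums[ids]
        out[f"{name}_bg"] = bg
        out[f"{name}_mfi_corrected"] = np.maximum(mfi - bg, 0.0)
        out[f"{name}_integrated_corrected"] = np.maximum(mfi - bg, 0.0) * counts[ids]
        if rings is not None:
            rsums = np.bincount(rflat, weights=img.ravel(), minlength=nmax + 1)
            with np.errstate(invalid="ignore"):
                ring_mfi = np.where(rcounts[ids] > 0, rsums[ids] / np.maximum(rcounts[ids], 1), np.nan)
            out[f"{name}_ring_mfi"] = ring_mfi
            out[f"{name}_ring_mfi_corrected"] = np.maximum(ring_mfi - bg, 0.0)
    return out
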