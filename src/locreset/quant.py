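"""Per-cell compartment measurements: N/C ratio, density, rings, qPCR folds.

The N/C ratio of a tagged transcription factor is measured as the ratio of
mean background-subtracted fluorescence in a 3-plane nuclear volume (centred
on the plane of maximum nuclear-stain intensity, with nucleolar pixels —
the lowest 35% of reporter intensities inside the nucleus — excluded) to the
mean in a thin cytoplasmic ring extending 0.5 um outward from the nuclear
boundary.  Local cell density is the number of centroids within a fixed
search radius (250 px at the reference magnification, ~69 um).  The qPCR
helper implements the 2^dCt fold change normalized to a reference
housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "CompartmentMasks",
    "build_masks",
    "nc_ratio",
    "estimate_background",
    "local_density",
    "ring_intensity",
    "normalize_trace",
    "qpcr_fold_change",
]


@dataclass
class CompartmentMasks:
    """Nuclear / nucleolus-excluded / cytoplasmic-ring masks for one cell.

    All masks are boolean arrays over the full (Z, Y, X) stack (Z may be 1),
    restricted to the 3 planes around ``center_plane``.  Invariants: the
    nucleolus-excluded mask is a subset of the nuclear mask; the ring is
    disjoint from every cell's nuclear mask.
    """

    nuclear: np.ndarray
    nuclear_excl: np.ndarray
    ring: np.ndarray
    center_plane: int
    ring_radius_px: int

    @property
    def ring_empty(self) -> bool:
        return not self.ring.any()


def build_masks(labels: np.ndarray, stain: np.ndarray, reporter: np.ndarray,
                pixel_size_um: float, label_id: int,
                nucleolus_pct: float = 35.0,
                ring_um: float = 0.5) -> CompartmentMasks:
    """Construct the compartment masks for one nucleus label.

    ``labels`` may be 2D or a 3D stack (possibly a 2D label map broadcast
    over planes).  The centre plane maximizes total stain intensity within
    the label; the nuclear mask is the label restricted to centre +/- 1
    planes.  Nucleolar exclusion removes the strictly lowest
    ``nucleolus_pct`` percent of reporter intensities inside the nuclear
    mask (ties at the cut are kept).  The ring extends ``ring_um``
    (rounded to the nearest whole pixel radius, minimum 1) outward from the
    nucleus boundary in-plane, excluding all nuclear labels.
    """
    stain = np.asarray(stain, dtype=float)
    reporter = np.asarray(reporter, dtype=float)
    was_2d = labels.ndim == 2
    if was_2d:
        labels = labels[None]
        stain = stain[None] if stain.ndim == 2 else stain
        reporter = reporter[None] if reporter.ndim == 2 else reporter
    if labels.shape[0] == 1 and stain.shape[0] > 1:
        lab3 = np.broadcast_to(labels, stain.shape)
    else:
        lab3 = labels

    inlab = lab3 == label_id
    if not inlab.any():
        raise ValueError(f"label {label_id} not present")
    per_plane = np.array([(stain[z] * inlab[z]).sum() for z in range(stain.shape[0])])
    zc = int(np.argmax(per_plane))
    z0, z1 = max(zc - 1, 0), min(zc + 2, stain.shape[0])

    nuclear = np.zeros_like(inlab)
    nuclear[z0:z1] = inlab[z0:z1]

    vals = reporter[nuclear]
    k = int(np.floor(nucleolus_pct / 100.0 * vals.size))
    if k > 0 and vals.size:
        thr = np.sort(vals, kind="stable")[k]
        keep = reporter >= thr  # strictly-below pixels removed, ties kept
    else:
        keep = np.ones_like(nuclear)
    nuclear_excl = nuclear & keep

    r_px = max(int(np.rint(ring_um / pixel_size_um)), 1)
    ring = np.zeros_like(nuclear)
    any_nucleus = lab3 > 0
    for z in range(z0, z1):
        if not inlab[z].any():
            continue
        dist = ndi.distance_transform_edt(~inlab[z])
        ring[z] = (dist > 0) & (dist <= r_px) & ~any_nucleus[z]

    return CompartmentMasks(nuclear=nuclear, nuclear_excl=nuclear_excl,
                            ring=ring, center_plane=zc, ring_radius_px=r_px)


def estimate_background(image: np.ndarray, labels: np.ndarray,
                        dilate_px: int = 5) -> float:
    """Histogram mode of the image outside all (dilated) nuclei.

    Approximates the camera offset plus diffuse background.  Integer-valued
    images use an exact per-value mode; float images a 256-bin histogram.
    """
    img = np.asarray(image, dtype=float)
    lab = np.asarray(labels)
    if lab.ndim < img.ndim:
        lab = np.broadcast_to(lab, img.shape)
    outside = ndi.distance_transform_edt(lab == 0) > dilate_px
    vals = img[outside] if outside.any() else img.ravel()
    if np.allclose(vals, np.round(vals)):
        v = np.round(vals).astype(np.int64)
        mn = v.min()
        return float(np.argmax(np.bincount(v - mn)) + mn)
    hist, edges = np.histogram(vals, bins=256)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2)


def nc_ratio(reporter: np.ndarray, masks: CompartmentMasks,
             background: float = 0.0) -> float:
    """Mean nuclear (nucleolus-excluded) over mean ring intensity, both
    background-subtracted.  Returns NaN when the ring is empty/missing or
    the denominator is non-positive after subtraction."""
    rep = np.asarray(reporter, dtype=float)
    if rep.ndim == 2:
        rep = rep[None]
    if masks.ring_empty or not masks.nuclear_excl.any():
        return float("nan")
    nuc = rep[masks.nuclear_excl].mean() - background
    cyt = rep[masks.ring].mean() - background
    if cyt <= 0:
        return float("nan")
    return float(nuc / cyt)


def local_density(centroids: np.ndarray, radius: float = 250.0) -> np.ndarray:
    """Per-cell neighbour count within ``radius`` (self included).

    The count includes the cell of interest itself, so an isolated cell has
    density 1; the offset makes the self-count convention explicit.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(centroids, dtype=float)
    if pts.size == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    return np.array([len(tree.query_ball_point(p, radius)) for p in pts])


def ring_intensity(channel: np.ndarray, masks: CompartmentMasks) -> float:
    """Mean of a channel over the cytoplasmic ring; NaN if the ring is empty."""
    ch = np.asarray(channel, dtype=float)
    if ch.ndim == 2:
        ch = ch[None]
    if masks.ring_empty:
        return float("nan")
    return float(ch[masks.ring].mean())


def normalize_trace(trace: np.ndarray, window: slice | tuple[int, int]) -> np.ndarray:
    """Divide a per-cell trace by its mean over a pretreatment window."""
    x = np.asarray(trace, dtype=float)
    sl = slice(*window) if isinstance(window, tuple) else window
    ref = np.nanmean(x[sl])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("pretreatment window mean must be positive")
    return x / ref


def qpcr_fold_change(ct: pd.DataFrame, reference_gene: str,
                     baseline_condition: str, condition: str) -> pd.Series:
    """2^dCt fold change between conditions, normalized to a reference gene.

    ``ct`` is long-format with columns ``gene``, ``condition``, ``ct``
    (replicate rows).  Replicates are averaged first; per gene,
    ``dCt = Ct(baseline) - Ct(condition)`` and ``fold = 2**dCt``; each
    gene's fold is then divided by the reference gene's fold.
    """
    required = {"gene", "condition", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    if not np.all(np.isfinite(ct["ct"])):
        raise ValueError("Ct values must be finite")
    mean_ct = ct.groupby(["gene", "condition"])["ct"].mean().unstack("condition")
    for cond in (baseline_condition, condition):
        if cond not in mean_ct.columns:
            raise ValueError(f"condition {cond!r} missing from table")
    if reference_gene not in mean_ct.index:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    if mean_ct.loc[reference_gene, [baseline_condition, condition]].isna().any():
        raise ValueError(f"reference gene {reference_gene!r} missing a condition")
    delta = mean_ct[baseline_condition] - mean_ct[condition]
    fold = np.power(2.0, delta)
    return fold / fold[reference_gene]
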