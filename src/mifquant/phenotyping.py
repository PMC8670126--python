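"""Cell-level analysis: segmentation, phenotype gating, densities, activation.

Nuclei are segmented from DAPI by thresholding plus distance-transform
watershed; per-cell mean intensities are measured over the nucleus dilated by
a cytoplasm ring.  Phenotypes are assigned by explicit marker gates (e.g.
Treg = CD4+ and FOXP3+), Treg burden is reported as cells per pixel of tissue
category, T-cell activation is called per section from CD3-compartment
Ki67/GzB scores dichotomised at the cohort-wide median, and stromal aSMA can
be scored with basement-membrane (CD34/COL4/VWF) pixels excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

from .masks import CompartmentSet, Mask
from .scoring import EmptyCompartmentError, qif_score
from .synthetic import FOVImage

__all__ = [
    "PhenotypeRule",
    "segment_cells",
    "default_gates",
    "classify_phenotype",
    "treg_density",
    "activation_status",
    "basement_membrane_mask",
    "bm_excluded_sma",
    "TREG_RULE",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeRule:
    """Conjunction of marker predicates defining one phenotype label.

    ``positive`` markers must be at or above their gate, ``negative`` markers
    strictly below.  A cell gets the label of the first rule whose predicates
    all hold.
    """

    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


#: regulatory T cell: CD4 and FOXP3 double-positive
TREG_RULE = PhenotypeRule("Treg", positive=("CD4", "FOXP3"))


def segment_cells(
    fov: FOVImage,
    comps: CompartmentSet | None = None,
    *,
    min_distance: int = 3,
    min_size: int = 10,
    cytoplasm_px: int = 3,
    manual_threshold: float | None = None,
) -> pd.DataFrame:
    """Segment nuclei from DAPI and measure per-cell channel means.

    Watershed on the distance transform splits touching nuclei, seeded at
    local maxima at least ``min_distance`` apart.  Mean intensities are taken
    over the nucleus footprint expanded by ``cytoplasm_px`` so membranous and
    cytoplasmic markers are captured.  When ``comps`` is given each cell is
    assigned a tissue category (tumor vs stroma) by majority pixel overlap of
    its footprint; ties go to stroma.

    Returns one row per cell: cell_id, fov_id, row, col, area_px,
    tissue_category, and ``mean_<marker>`` per channel.
    """
    dapi = np.asarray(fov.channels["DAPI"])
    if manual_threshold is not None:
        binary = dapi >= manual_threshold
    elif np.ptp(dapi) == 0:
        binary = np.zeros(dapi.shape, dtype=bool)
    else:
        # skimage's Otsu value is an exclusive lower bound for foreground
        binary = dapi > threshold_otsu(dapi)
    binary = remove_small_objects(binary, max_size=min_size - 1)
    markers_cols = [c for c in fov.channels if c != "DAPI"]
    cols = [
        "cell_id", "section_id", "fov_id", "row", "col", "area_px",
        "tissue_category", *[f"mean_{m}" for m in markers_cols],
    ]
    if not binary.any():
        return pd.DataFrame(columns=cols)

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=binary, exclude_border=False
    )
    seeds = np.zeros(dapi.shape, dtype=int)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, seeds, mask=binary)
    footprint = expand_labels(labels, distance=cytoplasm_px)

    tumor_px = comps.tumor.pixels if comps is not None else None
    stromal_px = comps.stromal.pixels if comps is not None else None

    rows = []
    for prop in regionprops(labels):
        lab = prop.label
        foot = footprint == lab
        rec = {
            "cell_id": f"{fov.fov_id}:s{lab}",
            "section_id": fov.section_id,
            "fov_id": fov.fov_id,
            "row": float(prop.centroid[0]),
            "col": float(prop.centroid[1]),
            "area_px": int(prop.area),
        }
        if tumor_px is not None:
            in_tumor = int(np.count_nonzero(foot & tumor_px))
            in_stroma = int(np.count_nonzero(foot & stromal_px))
            rec["tissue_category"] = "tumor" if in_tumor > in_stroma else "stroma"
        else:
            rec["tissue_category"] = None
        for m in markers_cols:
            rec[f"mean_{m}"] = float(fov.channels[m][foot].mean())
        rows.append(rec)
    return pd.DataFrame(rows, columns=cols)


def default_gates(cells: pd.DataFrame, markers: list[str]) -> dict[str, float]:
    """Per-marker Otsu gate on the distribution of cell mean intensities."""
    gates = {}
    for m in markers:
        vals = cells[f"mean_{m}"].to_numpy(dtype=float)
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError(
                f"cannot derive an automatic gate for {m}: degenerate intensities"
            )
        gates[m] = float(threshold_otsu(vals))
    return gates


def classify_phenotype(
    cells: pd.DataFrame,
    gates: dict[str, float],
    rules: list[PhenotypeRule],
) -> pd.DataFrame:
    """Label cells by the first rule whose marker predicates all hold.

    Positive predicate: mean intensity >= gate; negative: < gate.  Cells
    matching no rule are labelled ``None``.  A rule naming a marker without a
    gate or measured channel fails at configuration time.
    """
    for rule in rules:
        for m in (*rule.positive, *rule.negative):
            if m not in gates:
                raise KeyError(f"rule {rule.label!r}: no gate for marker {m!r}")
            if f"mean_{m}" not in cells.columns:
                raise KeyError(f"rule {rule.label!r}: no measured channel {m!r}")
    out = cells.copy()
    labels = np.full(len(out), None, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for rule in rules:
        hit = unassigned.copy()
        for m in rule.positive:
            hit &= out[f"mean_{m}"].to_numpy(dtype=float) >= gates[m]
        for m in rule.negative:
            hit &= out[f"mean_{m}"].to_numpy(dtype=float) < gates[m]
        labels[hit] = rule.label
        unassigned &= ~hit
    out["phenotype"] = labels
    return out


def treg_density(
    cells: pd.DataFrame,
    comps: CompartmentSet,
    *,
    label: str = "Treg",
) -> pd.DataFrame:
    """Treg burden per tissue category: (number of Tregs) / (pixel area).

    One row per category (tumor, stroma) with n, area_px and density in cells
    per pixel.  A zero-area category has an undefined density (NaN, flagged).
    """
    areas = {"tumor": comps.tumor.area, "stroma": comps.stromal.area}
    is_treg = cells["phenotype"] == label
    rows = []
    for cat, area in areas.items():
        n = int((is_treg & (cells["tissue_category"] == cat)).sum())
        if area == 0:
            logger.warning(
                "FOV %s: %s area is zero; density undefined", comps.fov_id, cat
            )
            dens = float("nan")
        else:
            dens = n / area
        rows.append(
            {
                "fov_id": comps.fov_id,
                "tissue_category": cat,
                "n_tregs": n,
                "area_px": area,
                "density": dens,
            }
        )
    return pd.DataFrame(rows)


def activation_status(
    section_scores: pd.DataFrame,
    *,
    ki67_col: str = "ki67",
    gzb_col: str = "gzb",
    combiner: str = "or",
) -> pd.DataFrame:
    """Call each section active or dormant from CD3-compartment Ki67/GzB.

    Cutoffs are the cohort-wide medians (both groups pooled); a score at or
    above its cutoff is "high" (ties go high, for determinism).  The default
    combiner calls a section active when either marker is high; ``"and"``
    requires both.
    """
    if len(section_scores) < 2:
        raise ValueError("need at least 2 sections to set median cutoffs")
    if combiner not in ("or", "and"):
        raise ValueError("combiner must be 'or' or 'and'")
    out = section_scores.copy()
    for col in (ki67_col, gzb_col):
        if out[col].nunique() == 1:
            logger.warning(
                "all %s scores identical: every section is high (>= median ties)",
                col,
            )
    ki67_cut = float(out[ki67_col].median())
    gzb_cut = float(out[gzb_col].median())
    out["ki67_high"] = out[ki67_col] >= ki67_cut
    out["gzb_high"] = out[gzb_col] >= gzb_cut
    if combiner == "or":
        active = out["ki67_high"] | out["gzb_high"]
    else:
        active = out["ki67_high"] & out["gzb_high"]
    out["status"] = np.where(active, "active", "dormant")
    out.attrs["ki67_cutoff"] = ki67_cut
    out.attrs["gzb_cutoff"] = gzb_cut
    return out


def basement_membrane_mask(
    fov: FOVImage,
    *,
    bm_markers: tuple[str, ...] = ("CD34", "COL4", "VWF"),
    min_size: int = 20,
    manual_thresholds: dict[str, float] | None = None,
) -> Mask:
    """Union of the binarized basement-membrane marker compartments."""
    from .masks import binarize_channel

    manual_thresholds = manual_thresholds or {}
    union = np.zeros(fov.shape, dtype=bool)
    for m in bm_markers:
        if m not in fov.channels:
            continue
        union |= binarize_channel(
            fov.channels[m],
            min_size=min_size,
            label=m,
            fov_id=fov.fov_id,
            manual_threshold=manual_thresholds.get(m),
        ).pixels
    return Mask(union, "basement_membrane", fov.fov_id)


def bm_excluded_sma(
    sma: np.ndarray,
    stromal: Mask,
    bm_mask: Mask,
) -> float:
    """Stromal aSMA score with basement-membrane pixels removed.

    Vascular and glandular smooth muscle carries aSMA that would contaminate
    the myofibroblast signal; scoring in stromal-minus-BM isolates the
    myofibroblastic component.  Raises :class:`EmptyCompartmentError` when
    the BM mask covers the whole stromal compartment.
    """
    residual = stromal - bm_mask
    residual.label = "stromal-bm"
    try:
        return qif_score(sma, residual)
    except EmptyCompartmentError:
        logger.warning(
            "FOV %s: stromal compartment fully covered by basement membrane",
            stromal.fov_id,
        )
        raise
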