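"""Molecular compartment masks and the FOV quality-control filter.

The scoring compartments follow the AQUA convention: an epithelial tumor mask
obtained by binarizing the cytokeratin channel, a nuclear mask from DAPI, a
stromal mask defined as nuclear minus tumor, and arbitrary marker-defined
compartments (e.g. a CD3 compartment in which Ki67 is scored).  FOVs with
staining artifacts or under 2% tumor are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .synthetic import FOVImage

__all__ = [
    "Mask",
    "CompartmentSet",
    "QCDecision",
    "binarize_channel",
    "nuclear_mask",
    "tumor_mask",
    "stromal_mask",
    "build_compartments",
    "qc_filter",
]

logger = logging.getLogger(__name__)

TUMOR_FRACTION_MIN = 0.02  # FOVs with less tumor are dropped


@dataclass
class Mask:
    """Binary pixel set naming a compartment within one FOV."""

    pixels: np.ndarray
    label: str = ""
    fov_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.pixels & other.pixels, f"{self.label}&{other.label}", self.fov_id)

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.pixels | other.pixels, f"{self.label}|{other.label}", self.fov_id)

    def __sub__(self, other: "Mask") -> "Mask":
        return Mask(self.pixels & ~other.pixels, f"{self.label}-{other.label}", self.fov_id)


@dataclass
class CompartmentSet:
    """The named compartments of one FOV.

    Invariants enforced at construction: stromal = nuclear minus tumor (hence
    disjoint from tumor and contained in nuclear), and tissue is the support
    union nuclear | tumor which contains both.
    """

    nuclear: Mask
    tumor: Mask
    stromal: Mask
    tissue: Mask
    marker_compartments: dict[str, Mask] = field(default_factory=dict)
    fov_id: str = ""

    def __post_init__(self) -> None:
        if (self.stromal.pixels & self.tumor.pixels).any():
            raise ValueError("stromal and tumor compartments must be disjoint")
        if (self.stromal.pixels & ~self.nuclear.pixels).any():
            raise ValueError("stromal compartment must lie within the nuclear mask")
        for m in (self.nuclear, self.tumor):
            if (m.pixels & ~self.tissue.pixels).any():
                raise ValueError("tissue support must contain nuclear and tumor")


def binarize_channel(
    raster: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
    *,
    min_size: int = 20,
    fill_holes: bool = True,
    min_foreground_ratio: float = 1.5,
    label: str = "",
    fov_id: str = "",
) -> Mask:
    """Threshold a channel into a binary compartment, with cleanup.

    Pixels at or above the threshold are foreground.  The automatic method is
    Otsu's between-class-variance maximisation; a ``manual_threshold``
    overrides it (AQUA workflows often use operator-set thresholds).  Cleanup
    fills holes and removes objects smaller than ``min_size`` pixels.

    Otsu always splits the histogram, even when the channel holds nothing but
    background noise; to guard against that the automatic path requires the
    foreground class mean to exceed ``min_foreground_ratio`` times the
    background class mean, otherwise the channel is treated as signal-free
    (empty mask).  A constant raster likewise yields an empty mask with a
    logged warning.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if manual_threshold is not None:
        # manual thresholds are inclusive: pixels at the threshold are set
        binary = raster >= float(manual_threshold)
    else:
        if method != "otsu":
            raise ValueError(f"unknown thresholding method: {method!r}")
        if np.ptp(raster) == 0:
            logger.warning(
                "constant raster for %s/%s: no foreground distinguishable",
                fov_id,
                label,
            )
            return Mask(np.zeros(raster.shape, dtype=bool), label, fov_id)
        # skimage's Otsu value is an exclusive lower bound for foreground
        binary = raster > float(threshold_otsu(raster))
        mu_fg = float(raster[binary].mean()) if binary.any() else 0.0
        mu_bg = float(raster[~binary].mean()) if (~binary).any() else 0.0
        if mu_fg < min_foreground_ratio * max(mu_bg, 1e-12):
            logger.debug(
                "channel %s/%s looks signal-free (class means %.1f vs %.1f)",
                fov_id,
                label,
                mu_fg,
                mu_bg,
            )
            return Mask(np.zeros(raster.shape, dtype=bool), label, fov_id)
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    if min_size > 1:
        # max_size removes objects <= value, hence min_size - 1
        binary = remove_small_objects(binary, max_size=min_size - 1)
    return Mask(binary, label, fov_id)


def nuclear_mask(dapi: np.ndarray, *, min_size: int = 20, **kwargs) -> Mask:
    """Nuclear compartment from the DAPI channel."""
    return binarize_channel(dapi, min_size=min_size, label="nuclear", **kwargs)


def tumor_mask(cytokeratin: np.ndarray, *, min_size: int = 20, **kwargs) -> Mask:
    """Epithelial tumor compartment by binarizing the cytokeratin signal."""
    return binarize_channel(cytokeratin, min_size=min_size, label="tumor", **kwargs)


def stromal_mask(nuclear: Mask, tumor: Mask) -> Mask:
    """Stromal compartment: tumor mask subtracted from the nuclear mask."""
    if nuclear.shape != tumor.shape:
        raise ValueError(
            f"mask shapes differ: nuclear {nuclear.shape} vs tumor {tumor.shape}"
        )
    out = Mask(nuclear.pixels & ~tumor.pixels, "stromal", nuclear.fov_id or tumor.fov_id)
    return out


def build_compartments(
    fov: FOVImage,
    *,
    marker_compartment_channels: tuple[str, ...] = (),
    min_size: int = 20,
    manual_thresholds: dict[str, float] | None = None,
) -> CompartmentSet:
    """Construct the full compartment set for one FOV.

    ``marker_compartment_channels`` names target channels to binarize into
    marker compartments (CD3 for activation scoring, CD34/COL4/VWF for the
    basement-membrane exclusion, ...).  ``manual_thresholds`` overrides the
    Otsu threshold per channel.
    """
    manual_thresholds = manual_thresholds or {}

    def _thr(ch: str) -> float | None:
        return manual_thresholds.get(ch)

    nuc = nuclear_mask(
        fov.channels["DAPI"], min_size=min_size, fov_id=fov.fov_id,
        manual_threshold=_thr("DAPI"),
    )
    if "CK" in fov.channels:
        tum = tumor_mask(
            fov.channels["CK"], min_size=min_size, fov_id=fov.fov_id,
            manual_threshold=_thr("CK"),
        )
    else:
        tum = Mask(np.zeros(fov.shape, dtype=bool), "tumor", fov.fov_id)
    stro = stromal_mask(nuc, tum)
    tissue = Mask(nuc.pixels | tum.pixels, "tissue", fov.fov_id)
    marker_comps = {}
    for ch in marker_compartment_channels:
        if ch not in fov.channels:
            continue
        marker_comps[ch] = binarize_channel(
            fov.channels[ch],
            min_size=min_size,
            label=ch,
            fov_id=fov.fov_id,
            manual_threshold=_thr(ch),
        )
    return CompartmentSet(
        nuclear=nuc,
        tumor=tum,
        stromal=stro,
        tissue=tissue,
        marker_compartments=marker_comps,
        fov_id=fov.fov_id,
    )


@dataclass(frozen=True)
class QCDecision:
    """Include/exclude decision for one FOV."""

    fov_id: str
    tumor_fraction: float
    artifact_flag: bool
    included: bool


def qc_filter(
    comps: CompartmentSet,
    artifact_flag: bool = False,
    *,
    min_tumor_fraction: float = TUMOR_FRACTION_MIN,
) -> QCDecision:
    """Exclude FOVs with staining artifacts or under 2% tumor.

    The tumor fraction denominator is the tissue support (nuclear | tumor);
    a FOV with no tissue at all is excluded with fraction reported as 0.
    """
    tissue_area = comps.tissue.area
    if tissue_area == 0:
        logger.warning("FOV %s has no tissue support; excluded", comps.fov_id)
        return QCDecision(comps.fov_id, 0.0, artifact_flag, False)
    frac = comps.tumor.area / tissue_area
    included = (not artifact_flag) and frac >= min_tumor_fraction
    return QCDecision(comps.fov_id, float(frac), bool(artifact_flag), included)
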