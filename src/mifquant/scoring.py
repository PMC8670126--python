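"""AQUA-style quantitative immunofluorescence (QIF) scoring.

A QIF score for a target in a molecular compartment is the sum of the
target's pixel intensities over the compartment divided by the compartment's
pixel area.  Raw scores are normalized multiplicatively to reference
acquisition settings (exposure time and camera bit depth) so that scores from
different imaging runs are comparable, and aggregated to section level as the
median over QC-included FOVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import CompartmentSet, Mask, QCDecision
from .synthetic import FOVImage

__all__ = [
    "EmptyCompartmentError",
    "QIFScore",
    "SectionScore",
    "qif_score",
    "normalize_score",
    "score_fov",
    "section_score",
    "section_scores",
    "REF_EXPOSURE_MS",
    "REF_BIT_DEPTH",
]

logger = logging.getLogger(__name__)

REF_EXPOSURE_MS = 100.0
REF_BIT_DEPTH = 8
_VALID_BIT_DEPTHS = (8, 12, 16)


class EmptyCompartmentError(ValueError):
    """A score was requested in a compartment with zero pixel area."""


@dataclass(frozen=True)
class QIFScore:
    fov_id: str
    marker: str
    compartment: str
    raw: float  # intensity units per pixel
    normalized: float  # dimensionless, at reference exposure/bit depth
    area_px: int


@dataclass(frozen=True)
class SectionScore:
    section_id: str
    marker: str
    compartment: str
    median_score: float
    n_fovs_included: int


def qif_score(raster: np.ndarray, compartment: Mask) -> float:
    """Sum of target pixel intensities over the compartment / its pixel area.

    Raises :class:`EmptyCompartmentError` for an empty compartment — the score
    is undefined there, never zero.
    """
    raster = np.asarray(raster)
    if raster.shape != compartment.shape:
        raise ValueError(
            f"raster shape {raster.shape} != mask shape {compartment.shape}"
        )
    area = compartment.area
    if area == 0:
        raise EmptyCompartmentError(
            f"compartment {compartment.label!r} in {compartment.fov_id!r} is empty"
        )
    return float(raster[compartment.pixels].sum(dtype=np.float64) / area)


def normalize_score(
    raw: float,
    exposure_ms: float,
    bit_depth: int,
    *,
    ref_exposure_ms: float = REF_EXPOSURE_MS,
    ref_bit_depth: int = REF_BIT_DEPTH,
) -> float:
    """Rescale a raw score to reference exposure time and bit depth.

    normalized = raw * (T_ref / T) * ((2**b_ref - 1) / (2**b - 1)).  Linear in
    the raw score, identity at the reference settings, and maps full-scale
    signal at any bit depth to full scale at the reference depth.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    if bit_depth not in _VALID_BIT_DEPTHS:
        raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
    return (
        raw
        * (ref_exposure_ms / exposure_ms)
        * ((2 ** ref_bit_depth - 1) / (2 ** bit_depth - 1))
    )


def _compartment_lookup(comps: CompartmentSet, name: str) -> Mask:
    builtin = {
        "nuclear": comps.nuclear,
        "tumor": comps.tumor,
        "stromal": comps.stromal,
        "tissue": comps.tissue,
    }
    if name in builtin:
        return builtin[name]
    if name in comps.marker_compartments:
        return comps.marker_compartments[name]
    raise KeyError(f"unknown compartment {name!r}")


def score_fov(
    fov: FOVImage,
    comps: CompartmentSet,
    targets: list[tuple[str, str]],
) -> pd.DataFrame:
    """Score each (marker, compartment) pair in one FOV.

    Returns a long-format frame with columns section_id, fov_id, marker,
    compartment, raw, normalized, area_px.  Pairs whose compartment is empty
    are reported with NaN scores (flagged missing), not zero.
    """
    rows = []
    for marker, comp_name in targets:
        if marker not in fov.channels:
            continue
        comp = _compartment_lookup(comps, comp_name)
        try:
            raw = qif_score(fov.channels[marker], comp)
            norm = normalize_score(
                raw, fov.exposure_ms.get(marker, REF_EXPOSURE_MS), fov.bit_depth
            )
        except EmptyCompartmentError:
            raw = norm = float("nan")
        rows.append(
            {
                "section_id": fov.section_id,
                "fov_id": fov.fov_id,
                "marker": marker,
                "compartment": comp_name,
                "raw": raw,
                "normalized": norm,
                "area_px": comp.area,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "section_id",
            "fov_id",
            "marker",
            "compartment",
            "raw",
            "normalized",
            "area_px",
        ],
    )


def section_score(
    section_id: str,
    marker: str,
    compartment: str,
    scores: "pd.Series | np.ndarray | list[float]",
    included: "pd.Series | np.ndarray | list[bool] | None" = None,
) -> SectionScore | None:
    """Median normalized score over QC-included FOVs of one section.

    Even counts use the midpoint of the two central order statistics.  With
    zero included FOVs the section is dropped (returns ``None``) with a
    logged reason.
    """
    vals = np.asarray(scores, dtype=float)
    if included is not None:
        vals = vals[np.asarray(included, dtype=bool)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        logger.warning(
            "section %s %s/%s: no QC-included FOVs with a score; dropped",
            section_id,
            marker,
            compartment,
        )
        return None
    return SectionScore(
        section_id=section_id,
        marker=marker,
        compartment=compartment,
        median_score=float(np.median(vals)),
        n_fovs_included=int(vals.size),
    )


def section_scores(
    fov_scores: pd.DataFrame,
    qc: list[QCDecision] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate FOV-level scores to section level.

    ``qc`` maps fov_id to inclusion; excluded FOVs do not enter the median.
    Returns columns section_id, marker, compartment, median_score,
    n_fovs_included.
    """
    df = fov_scores
    if qc is not None:
        if isinstance(qc, list):
            qc = pd.DataFrame(
                [
                    {"fov_id": d.fov_id, "included": d.included}
                    for d in qc
                ]
            )
        keep = set(qc.loc[qc["included"], "fov_id"])
        df = df[df["fov_id"].isin(keep)]
    rows = []
    for (sec, marker, comp), grp in df.groupby(
        ["section_id", "marker", "compartment"], sort=False
    ):
        rec = section_score(sec, marker, comp, grp["normalized"])
        if rec is not None:
            rows.append(
                {
                    "section_id": rec.section_id,
                    "marker": rec.marker,
                    "compartment": rec.compartment,
                    "median_score": rec.median_score,
                    "n_fovs_included": rec.n_fovs_included,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "section_id",
            "marker",
            "compartment",
            "median_score",
            "n_fovs_included",
        ],
    )
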