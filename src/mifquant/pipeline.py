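"""End-to-end case-control pipeline: simulate -> mask -> score -> phenotype
-> compare.

Driven by a small config mapping (or YAML file).  FOVs are processed in a
single streaming pass (images are not retained in memory); section-level
aggregation, activation calls and the group statistics run on the collected
tables.  Every output is written as CSV plus a provenance JSON (config hash,
seed, package versions), and a fixed config + seed reproduces the bundle
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .masks import build_compartments, qc_filter
from .phenotyping import (
    TREG_RULE,
    activation_status,
    basement_membrane_mask,
    bm_excluded_sma,
    classify_phenotype,
    default_gates,
    segment_cells,
)
from .scoring import EmptyCompartmentError, normalize_score, score_fov, section_scores
from .stats import compare_markers, summary_table
from .synthetic import (
    CohortSpec,
    PhenotypeSpec,
    default_phenotypes,
    iter_cohort_fovs,
)

__all__ = ["PipelineError", "spec_from_config", "run_case_control"]

BM_MARKERS = ("CD34", "COL4", "VWF")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending unit."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


def spec_from_config(config: dict) -> CohortSpec:
    """Build a CohortSpec from the ``cohort`` block of a config mapping."""
    c = dict(config.get("cohort", {}))
    phenos = c.pop("phenotypes", None)
    if phenos is None:
        phenotypes = default_phenotypes()
    else:
        phenotypes = tuple(
            PhenotypeSpec(
                name=p["name"],
                marker_means=dict(p["marker_means"]),
                marker_sds=dict(p["marker_sds"]),
                abundance=float(p["abundance"]),
            )
            for p in phenos
        )
    for key in ("fovs_per_section", "shape"):
        if key in c:
            c[key] = tuple(c[key])
    return CohortSpec(phenotypes=phenotypes, **c)


def _default_targets(spec: CohortSpec) -> list[tuple[str, str]]:
    """Score every target in tumor and stroma; activation antigens also in CD3."""
    targets = []
    for m in spec.markers:
        if m == "CK":
            continue
        targets.append((m, "tumor"))
        targets.append((m, "stromal"))
    for m in ("Ki67", "GzB"):
        if m in spec.markers:
            targets.append((m, "CD3"))
    return targets


def _markdown_table(df: pd.DataFrame) -> str:
    cols = [c for c in df.columns if c != "p_value"]
    lines = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_case_control(
    config: dict | str | Path,
    out_dir: str | Path,
    *,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full synthetic case-control study and write the artifact bundle.

    ``config`` is a mapping (or YAML path) with blocks ``cohort`` (CohortSpec
    fields), optional ``qc`` (``artifact_fovs``: explicit artifact flags),
    ``scoring`` (``targets``: (marker, compartment) pairs) and ``phenotyping``
    (``enabled``, default true).  ``seed`` overrides the spec seed.

    Writes scores.csv, qc.csv, sections.csv, activation.csv,
    treg_density.csv, cells.csv, results.csv and provenance.json under
    ``out_dir`` and returns the tables.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    if seed is not None:
        config.setdefault("cohort", {})
        config["cohort"] = {**config["cohort"], "seed": int(seed)}
    try:
        spec = spec_from_config(config)
    except (KeyError, TypeError, ValueError) as e:
        raise PipelineError("configure", str(e)) from e

    artifact_fovs = set(config.get("qc", {}).get("artifact_fovs", []))
    targets = [
        tuple(t) for t in config.get("scoring", {}).get("targets", [])
    ] or _default_targets(spec)
    phenotyping_on = config.get("phenotyping", {}).get("enabled", True)
    marker_comp_channels = tuple(
        {c for _, c in targets} - {"tumor", "stromal", "nuclear", "tissue"}
    ) + tuple(m for m in BM_MARKERS if m in spec.markers)

    score_frames: list[pd.DataFrame] = []
    qc_rows: list[dict] = []
    cell_frames: list[pd.DataFrame] = []
    fov_areas: list[dict] = []
    manifest_rows: list[dict] = []

    # simulate + mask + score, one FOV at a time
    fov_iter = iter_cohort_fovs(spec)
    while True:
        try:
            item = next(fov_iter, None)
        except ValueError as e:
            raise PipelineError("simulate", str(e)) from e
        if item is None:
            break
        sec_id, group, fov, _ = item
        fov_id = fov.fov_id
        if not manifest_rows or manifest_rows[-1]["section_id"] != sec_id:
            manifest_rows.append(
                {"section_id": sec_id, "group": group, "n_fovs": 0}
            )
        manifest_rows[-1]["n_fovs"] += 1
        try:
            comps = build_compartments(
                fov, marker_compartment_channels=marker_comp_channels
            )
            qc = qc_filter(comps, artifact_flag=fov_id in artifact_fovs)
        except ValueError as e:
            raise PipelineError("mask", f"{sec_id}/{fov_id}: {e}") from e
        qc_rows.append(
            {
                "section_id": sec_id,
                "fov_id": fov_id,
                "tumor_fraction": qc.tumor_fraction,
                "artifact_flag": qc.artifact_flag,
                "included": qc.included,
            }
        )
        if not qc.included:
            continue
        sf = score_fov(fov, comps, targets)
        if "aSMA" in fov.channels and any(m in fov.channels for m in BM_MARKERS):
            bm = basement_membrane_mask(fov)
            try:
                raw = bm_excluded_sma(fov.channels["aSMA"], comps.stromal, bm)
                norm = normalize_score(
                    raw, fov.exposure_ms.get("aSMA", 100.0), fov.bit_depth
                )
            except EmptyCompartmentError:
                raw = norm = float("nan")
            extra = pd.DataFrame(
                [
                    {
                        "section_id": sec_id,
                        "fov_id": fov_id,
                        "marker": "aSMA",
                        "compartment": "stromal-bm",
                        "raw": raw,
                        "normalized": norm,
                        "area_px": (comps.stromal - bm).area,
                    }
                ]
            )
            sf = pd.concat([sf, extra], ignore_index=True)
        score_frames.append(sf)
        if phenotyping_on:
            cells = segment_cells(fov, comps)
            cell_frames.append(cells)
            fov_areas.append(
                {
                    "section_id": sec_id,
                    "fov_id": fov_id,
                    "tumor": comps.tumor.area,
                    "stroma": comps.stromal.area,
                }
            )

    qc_df = pd.DataFrame(qc_rows)
    manifest = pd.DataFrame(manifest_rows)
    labels = config.get("group_labels")
    if labels:
        manifest["group"] = manifest["group"].map(
            {"a": str(labels[0]), "b": str(labels[1])}
        )
    if not score_frames:
        raise PipelineError(
            "score",
            f"no FOV passed QC ({len(qc_df)} FOVs, "
            f"{int(qc_df['artifact_flag'].sum()) if len(qc_df) else 0} artifact-flagged)",
        )
    scores = pd.concat(score_frames, ignore_index=True)
    sections = section_scores(scores)  # QC already applied in the stream
    sections = sections.merge(manifest[["section_id", "group"]], on="section_id")

    # activation calls from CD3-compartment Ki67/GzB
    activation = None
    cd3 = sections[sections["compartment"] == "CD3"]
    if {"Ki67", "GzB"} <= set(cd3["marker"]):
        wide = cd3.pivot_table(
            index="section_id", columns="marker", values="median_score"
        ).reset_index()
        wide = wide.rename(columns={"Ki67": "ki67", "GzB": "gzb"}).dropna(
            subset=["ki67", "gzb"]
        )
        if len(wide) >= 2:
            activation = activation_status(wide).merge(
                manifest[["section_id", "group"]], on="section_id"
            )

    # Treg densities from segmented cells with pooled-cohort gates
    treg = None
    cells_df = None
    if cell_frames:
        cells_df = pd.concat(cell_frames, ignore_index=True)
        gate_markers = [
            m for m in ("CD4", "FOXP3") if f"mean_{m}" in cells_df.columns
        ]
        if len(gate_markers) == 2 and len(cells_df):
            try:
                gates = default_gates(cells_df, gate_markers)
            except ValueError:
                gates = None
            if gates:
                cells_df = classify_phenotype(cells_df, gates, [TREG_RULE])
                areas = pd.DataFrame(fov_areas)
                counts = (
                    cells_df[cells_df["phenotype"] == "Treg"]
                    .groupby(["fov_id", "tissue_category"])
                    .size()
                    .rename("n_tregs")
                    .reset_index()
                )
                long_areas = areas.melt(
                    id_vars=["section_id", "fov_id"],
                    value_vars=["tumor", "stroma"],
                    var_name="tissue_category",
                    value_name="area_px",
                )
                treg = long_areas.merge(
                    counts, on=["fov_id", "tissue_category"], how="left"
                )
                treg["n_tregs"] = treg["n_tregs"].fillna(0).astype(int)
                treg["density"] = np.where(
                    treg["area_px"] > 0, treg["n_tregs"] / treg["area_px"], np.nan
                )

    results = compare_markers(sections, activation=activation)

    # Treg density section medians enter the comparison as pseudo-markers
    if treg is not None and len(treg):
        dens_sections = (
            treg.groupby(["section_id", "tissue_category"])["density"]
            .median()
            .reset_index()
            .rename(columns={"density": "median_score"})
        )
        dens_sections["marker"] = "Treg density"
        dens_sections["compartment"] = dens_sections["tissue_category"]
        dens_sections = dens_sections.merge(
            manifest[["section_id", "group"]], on="section_id"
        )
        dens_res = compare_markers(
            dens_sections[
                ["section_id", "group", "marker", "compartment", "median_score"]
            ]
        )
        results = pd.concat([results, dens_res], ignore_index=True)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {
        "manifest": manifest,
        "qc": qc_df,
        "scores": scores,
        "sections": sections,
        "results": results,
    }
    if activation is not None:
        bundle["activation"] = activation
    if treg is not None:
        bundle["treg_density"] = treg
    if cells_df is not None:
        bundle["cells"] = cells_df
    for name, df in bundle.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)

    covs = config.get("summary_covariates")
    if covs:
        summary = summary_table(manifest, covs)
        summary.to_csv(out_dir / "summary_table.csv", index=False)
        (out_dir / "summary_table.md").write_text(_markdown_table(summary))
        bundle["summary_table"] = summary

    import scipy
    import skimage

    provenance = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": spec.seed,
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
            if k != "phenotypes"
        },
        "versions": {
            "mifquant": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=str)
    )
    return bundle
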