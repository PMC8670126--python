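"""Seeded simulation experiments: type-I error and power of the pipeline's
group comparison.

Both experiments generate synthetic cohorts with :func:`generate_cohort`
(ground truth only — the sampled per-cell marker intensities, section
heterogeneity and planted effects are identical whether or not pixels are
rendered), summarise them exactly as the analysis does (per-FOV marker mean,
per-section median over FOVs) and run the per-marker Mann-Whitney comparison.
Replicate counts and cohort sizes are arguments so the experiments scale from
quick checks to the full calibration runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import ALPHA, mann_whitney
from .synthetic import (
    CohortSpec,
    default_phenotypes,
    effect_for_sd_shift,
    generate_cohort,
    section_marker_medians,
)

__all__ = [
    "simulation_spec",
    "cohort_rejections",
    "type_one_error",
    "power_estimate",
]


def simulation_spec(
    *,
    n_per_group: int = 20,
    fovs: int = 6,
    effect_log2: dict[str, float] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Compact cohort for repeated-simulation experiments.

    Sections carry the default phenotype panel and heterogeneity model but
    only ``fovs`` FOVs each, and no pixels are rendered, so hundreds of
    replicates run in minutes on one CPU.
    """
    return CohortSpec(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        fovs_per_section=(fovs, fovs),
        phenotypes=default_phenotypes(),
        effect_log2=effect_log2 or {},
        seed=seed,
    )


def cohort_rejections(spec: CohortSpec, markers: list[str], alpha: float = ALPHA) -> dict[str, bool]:
    """One replicate: generate, summarise to section medians, test per marker."""
    res = generate_cohort(spec, render=False)
    med = section_marker_medians(res.ground_truth.cells, markers)
    med = med.merge(res.manifest[["section_id", "group"]], on="section_id")
    out = {}
    for m in markers:
        x = med.loc[med["group"] == "a", m].dropna()
        y = med.loc[med["group"] == "b", m].dropna()
        out[m] = mann_whitney(x, y).p_value < alpha
    return out


def type_one_error(
    *,
    n_replicates: int = 400,
    n_per_group: int = 20,
    fovs: int = 6,
    markers: tuple[str, ...] = ("CD45", "CD3", "CD8"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-marker rejection rate on null cohorts (no planted effect).

    With no group effect the rejection rate of each marker's Mann-Whitney
    comparison should sit at the nominal alpha.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) >> 1  # keep below 2**31
    counts = {m: 0 for m in markers}
    for rs in rep_seeds:
        spec = simulation_spec(n_per_group=n_per_group, fovs=fovs, seed=int(rs))
        for m, rej in cohort_rejections(spec, list(markers)).items():
            counts[m] += rej
    return pd.DataFrame(
        {
            "marker": list(markers),
            "rejection_rate": [counts[m] / n_replicates for m in markers],
            "n_replicates": n_replicates,
        }
    )


def power_estimate(
    *,
    n_replicates: int = 200,
    n_per_group: int = 50,
    fovs: int = 6,
    marker: str = "CD45",
    effect_sd: float = 0.8,
    seed: int = 0,
) -> float:
    """Rejection rate with a planted shift of ``effect_sd`` section-score SDs.

    The planted log2 effect is calibrated through the generator's
    heterogeneity model (see :func:`effect_for_sd_shift`); at d = 0.8 with 50
    sections per group the normal-approximation power of the Mann-Whitney
    test is ~0.97.
    """
    base = simulation_spec(seed=0)
    eff = effect_for_sd_shift(base, effect_sd)
    ss = np.random.SeedSequence(seed + 1)
    rep_seeds = ss.generate_state(n_replicates) >> 1
    hits = 0
    for rs in rep_seeds:
        spec = simulation_spec(
            n_per_group=n_per_group,
            fovs=fovs,
            effect_log2={marker: eff},
            seed=int(rs),
        )
        hits += cohort_rejections(spec, [marker])[marker]
    return hits / n_replicates
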