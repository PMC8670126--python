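"""Synthetic multiplex-immunofluorescence cohort generator with known ground truth.

Emulates the acquisition geometry of an AQUA-style quantitative
immunofluorescence study: a case-control cohort of tissue sections, each
imaged as a series of multichannel fields of view (FOVs) with a DAPI nuclear
counterstain, a cytokeratin (CK) epithelial channel, and up to three target
markers per staining round.  Cells are rendered as nuclear disks with a
cytoplasmic annulus; per-cell marker intensities are drawn from per-phenotype
truncated normals, so every downstream stage (masking, scoring, phenotyping,
statistics) can be validated against exact ground truth.

Group effects are planted as log2 shifts of group-b marker means or phenotype
abundances.  Between-section biological heterogeneity is modelled as a
per-section, per-marker lognormal multiplier; this is what gives section-level
scores a realistic spread and makes planted effects expressible in
standard-deviation units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

__all__ = [
    "PhenotypeSpec",
    "CohortSpec",
    "FOVImage",
    "GroundTruth",
    "CohortResult",
    "generate_fov",
    "generate_cohort",
    "iter_cohort_fovs",
    "cohort_manifest",
    "default_phenotypes",
    "default_cohort_spec",
    "fov_marker_means",
    "section_marker_medians",
    "effect_for_sd_shift",
]

#: markers painted on the nucleus disk only (transcription factors,
#: proliferation antigens); everything else covers the whole cell footprint
#: except CK which is cytoplasmic/membranous (annulus only).
NUCLEAR_MARKERS = frozenset({"FOXP3", "Ki67"})
CYTOPLASM_MARKERS = frozenset({"CK"})

_VALID_BIT_DEPTHS = (8, 12, 16)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One cell population: expected abundance and per-marker intensity model.

    ``marker_means``/``marker_sds`` give the mean and SD of the fluorescence
    signal (above background, raw camera units) for each marker the phenotype
    expresses; unlisted markers contribute background only.  A phenotype that
    expresses CK is an epithelial (tumor) cell and is rendered with a CK
    cytoplasmic annulus.
    """

    name: str
    marker_means: dict[str, float]
    marker_sds: dict[str, float]
    abundance: float  # expected cells per FOV

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"{self.name}: abundance must be >= 0")
        for m, v in self.marker_means.items():
            if v < 0:
                raise ValueError(f"{self.name}: mean for {m} must be >= 0")
        for m, v in self.marker_sds.items():
            if v < 0:
                raise ValueError(f"{self.name}: sd for {m} must be >= 0")

    @property
    def is_tumor(self) -> bool:
        return "CK" in self.marker_means


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic case-control imaging cohort.

    Defaults mirror the study design this package models: two groups of 49
    and 51 sections, 40-200 FOVs captured per section at a x20-like scale
    (256 x 256 px rasters), and at most three target channels per staining
    round besides DAPI and CK.
    """

    n_group_a: int = 49
    n_group_b: int = 51
    fovs_per_section: tuple[int, int] = (40, 200)
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    #: marker -> log2 shift planted on group-b mean intensities
    effect_log2: dict[str, float] = field(default_factory=dict)
    #: phenotype name -> log2 shift planted on group-b abundance
    abundance_log2: dict[str, float] = field(default_factory=dict)
    noise_mean: float = 100.0
    noise_sd: float = 10.0
    dapi_mean: float = 2000.0
    dapi_sd: float = 200.0
    exposure_ms: dict[str, float] = field(default_factory=dict)  # default 100 ms
    bit_depth: int = 12
    shape: tuple[int, int] = (256, 256)
    nucleus_radius: int = 4
    cytoplasm_px: int = 3
    #: SD (log2 units) of the per-section, per-marker lognormal multiplier
    #: modelling between-tumor biological heterogeneity
    section_sigma_log2: float = 0.5
    #: fraction of FOVs rendered without tumor cells (QC-filter fodder)
    tumor_free_fraction: float = 0.0
    allow_overlap: bool = False
    fixed_counts: bool = False  # exactly round(abundance) cells instead of Poisson
    max_place_tries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one section")
        lo, hi = self.fovs_per_section
        if not (1 <= lo <= hi):
            raise ValueError("fovs_per_section must be a valid range [low, high]")
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
        if min(self.shape) < 64:
            raise ValueError("raster shape must be at least 64x64")
        if not (0.0 <= self.tumor_free_fraction <= 1.0):
            raise ValueError("tumor_free_fraction must lie in [0, 1]")

    @property
    def markers(self) -> tuple[str, ...]:
        """Target channels (CK included), stable order of first appearance."""
        seen: dict[str, None] = {}
        for ph in self.phenotypes:
            for m in ph.marker_means:
                seen.setdefault(m, None)
        return tuple(seen)

    @property
    def channels(self) -> tuple[str, ...]:
        return ("DAPI",) + self.markers

    @property
    def rounds(self) -> tuple[tuple[str, ...], ...]:
        """Targets chunked into staining rounds of at most 3 (CK/DAPI shared)."""
        targets = [m for m in self.markers if m != "CK"]
        return tuple(
            tuple(targets[i : i + 3]) for i in range(0, len(targets), 3)
        )

    def exposure_for(self, marker: str) -> float:
        return float(self.exposure_ms.get(marker, 100.0))

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class FOVImage:
    """One acquired field of view: channel rasters plus acquisition metadata."""

    section_id: str
    fov_id: str
    channels: dict[str, np.ndarray]
    exposure_ms: dict[str, float]
    bit_depth: int
    rounds: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channel rasters must share one shape")
        top = 2 ** self.bit_depth - 1
        for name, raster in self.channels.items():
            if raster.min() < 0 or raster.max() > top:
                raise ValueError(f"channel {name} exceeds [0, {top}]")
        for rnd in self.rounds:
            targets = [m for m in rnd if m not in ("DAPI", "CK")]
            if len(targets) > 3:
                raise ValueError(
                    "at most 3 targets besides DAPI and CK per staining round"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class GroundTruth:
    """Planted truth for a cohort (or one FOV slice of it).

    ``cells`` has one row per cell: section_id, fov_id, cell_id, row, col,
    radius, phenotype, and one column per marker holding the drawn signal
    intensity (0 for markers the phenotype does not express).
    """

    cells: pd.DataFrame
    planted_effects: dict[str, float] = field(default_factory=dict)
    tumor_free_fovs: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class CohortResult:
    images: dict[str, list[FOVImage]] | None
    manifest: pd.DataFrame  # section_id, group, n_fovs
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# defaults: a compact representative immune/stromal panel


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """Representative TNBC microenvironment populations.

    Intensities are on a 12-bit raw scale (background ~100).  The panel covers
    the marker hierarchy the scoring pipeline consumes: pan-leukocyte CD45
    with a CD14 myeloid split, CD3/CD4/CD8/CD20 lymphoid subsets,
    CD4+FOXP3+ Tregs, Ki67/GzB activation antigens in T cells, aSMA
    myofibroblasts, and a CD34/COL4/VWF endothelial population that also
    carries basement-membrane-associated aSMA.
    """
    return (
        PhenotypeSpec(
            "tumor",
            {"CK": 1800, "Ki67": 600},
            {"CK": 350, "Ki67": 220},
            abundance=14,
        ),
        PhenotypeSpec(
            "t_helper",
            {"CD45": 1200, "CD3": 1300, "CD4": 1200, "Ki67": 320},
            {"CD45": 250, "CD3": 260, "CD4": 250, "Ki67": 150},
            abundance=6,
        ),
        PhenotypeSpec(
            "t_cytotoxic",
            {"CD45": 1200, "CD3": 1300, "CD8": 1200, "GzB": 520, "Ki67": 320},
            {"CD45": 250, "CD3": 260, "CD8": 250, "GzB": 210, "Ki67": 150},
            abundance=4,
        ),
        PhenotypeSpec(
            "treg",
            {"CD45": 1100, "CD3": 1250, "CD4": 1150, "FOXP3": 900},
            {"CD45": 230, "CD3": 250, "CD4": 240, "FOXP3": 200},
            abundance=1.5,
        ),
        PhenotypeSpec(
            "b_cell",
            {"CD45": 1200, "CD20": 1300},
            {"CD45": 250, "CD20": 260},
            abundance=2,
        ),
        PhenotypeSpec(
            "macrophage",
            {"CD45": 1000, "CD14": 1200},
            {"CD45": 220, "CD14": 250},
            abundance=3,
        ),
        PhenotypeSpec(
            "fibroblast",
            {"aSMA": 1400},
            {"aSMA": 280},
            abundance=5,
        ),
        PhenotypeSpec(
            "endothelium",
            {"CD34": 1300, "COL4": 1200, "VWF": 1100, "aSMA": 800},
            {"CD34": 260, "COL4": 240, "VWF": 220, "aSMA": 200},
            abundance=2,
        ),
    )


def default_cohort_spec(**overrides) -> CohortSpec:
    """Study-scale cohort: 49 + 51 sections, 40-200 FOVs each."""
    kw = dict(phenotypes=default_phenotypes())
    kw.update(overrides)
    return CohortSpec(**kw)


def effect_for_sd_shift(spec: CohortSpec, d: float) -> float:
    """log2 effect that shifts a marker's section-level score by ``d`` SDs.

    Section-level log2 scores are dominated by the per-section lognormal
    heterogeneity term (SD ``section_sigma_log2``); within-section sampling
    noise adds <1% of variance once a section has a handful of FOVs with
    >= ~10 expressing cells, so ``d * section_sigma_log2`` is the planted
    log2 shift that realises a ``d``-SD separation of the two groups.
    """
    if spec.section_sigma_log2 <= 0:
        raise ValueError("requires section_sigma_log2 > 0")
    return d * spec.section_sigma_log2


# ---------------------------------------------------------------------------
# FOV-level generation


def _fov_seed_seq(spec: CohortSpec, section_id: str, fov_id: str) -> np.random.SeedSequence:
    # counter-based splitting keyed on the id strings: generation order and
    # FOV order never change the stream any FOV sees
    key = (zlib.crc32(section_id.encode()), zlib.crc32(fov_id.encode()))
    return np.random.SeedSequence(entropy=spec.seed, spawn_key=key)


def _place_cells(
    n: int,
    shape: tuple[int, int],
    margin: int,
    min_dist: float,
    rng: np.random.Generator,
    allow_overlap: bool,
    max_tries: int,
) -> np.ndarray:
    """Rejection-sample ``n`` centroids at least ``min_dist`` apart."""
    lo_r, hi_r = margin, shape[0] - margin - 1
    lo_c, hi_c = margin, shape[1] - margin - 1
    if hi_r < lo_r or hi_c < lo_c:
        raise ValueError("raster too small to place cells inside the margin")
    if n == 0:
        return np.empty((0, 2))
    if allow_overlap:
        rows = rng.uniform(lo_r, hi_r, size=n)
        cols = rng.uniform(lo_c, hi_c, size=n)
        return np.column_stack([rows, cols])
    placed_r: list[float] = []
    placed_c: list[float] = []
    d2 = min_dist * min_dist
    for _ in range(n):
        for _try in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            ok = True
            for pr, pc in zip(placed_r, placed_c):
                if (pr - r) ** 2 + (pc - c) ** 2 < d2:
                    ok = False
                    break
            if ok:
                placed_r.append(r)
                placed_c.append(c)
                break
        else:
            raise ValueError(
                f"raster too small: could not place cell "
                f"{len(placed_r) + 1} of {n} without overlap after "
                f"{max_tries} tries"
            )
    return np.column_stack([placed_r, placed_c])


def _sample_cells(
    spec: CohortSpec,
    section_id: str,
    fov_id: str,
    rng: np.random.Generator,
    mean_scale: dict[str, float],
    abundance_scale: dict[str, float],
    tumor_free: bool,
) -> dict[str, np.ndarray]:
    """Draw phenotype counts, positions and per-cell marker intensities.

    Returns a column dict (cheap to concatenate across FOVs); callers wrap it
    in a DataFrame where the public API requires one.
    """
    markers = spec.markers
    counts = []
    for ph in spec.phenotypes:
        lam = ph.abundance * abundance_scale.get(ph.name, 1.0)
        if tumor_free and ph.is_tumor:
            lam = 0.0
        n = int(round(lam)) if spec.fixed_counts else int(rng.poisson(lam))
        counts.append(n)
    total = sum(counts)
    margin = spec.nucleus_radius + spec.cytoplasm_px + 1
    centers = _place_cells(
        total,
        spec.shape,
        margin,
        # +3 keeps rasterised nuclei separated, not merely non-overlapping
        min_dist=2 * spec.nucleus_radius + 3,
        rng=rng,
        allow_overlap=spec.allow_overlap,
        max_tries=spec.max_place_tries,
    )
    # vectorised intensity draws: one truncated-normal sample block per
    # phenotype x marker
    intens = np.zeros((total, len(markers)))
    labels = np.empty(total, dtype=object)
    k = 0
    for ph, n in zip(spec.phenotypes, counts):
        if n == 0:
            continue
        labels[k : k + n] = ph.name
        for j, m in enumerate(markers):
            mu = ph.marker_means.get(m, 0.0) * mean_scale.get(m, 1.0)
            if mu > 0:
                sd = ph.marker_sds.get(m, 0.0)
                intens[k : k + n, j] = np.maximum(0.0, rng.normal(mu, sd, n))
        k += n
    data = {
        "section_id": np.repeat(section_id, total),
        "fov_id": np.repeat(fov_id, total),
        "cell_id": [f"{fov_id}:c{i}" for i in range(total)],
        "row": centers[:, 0],
        "col": centers[:, 1],
        "radius": np.full(total, spec.nucleus_radius),
        "phenotype": labels,
    }
    for j, m in enumerate(markers):
        data[m] = intens[:, j]
    return data


def _render(
    spec: CohortSpec,
    cells: dict[str, np.ndarray],
    noise_rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Paint cells onto noisy background rasters and quantise to bit depth."""
    shape = spec.shape
    out: dict[str, np.ndarray] = {}
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    top = float(spec.max_value)

    n_cells = len(cells["row"])

    # precompute per-cell footprints once
    nuc_px, cell_px, annulus_px = [], [], []
    for row, col, radius in zip(cells["row"], cells["col"], cells["radius"]):
        nuc = _draw_disk((row, col), radius + 0.5, shape=shape)
        whole = _draw_disk((row, col), radius + spec.cytoplasm_px + 0.5, shape=shape)
        nuc_set = set(zip(*nuc))
        ann = tuple(
            np.array(v)
            for v in zip(*[p for p in zip(*whole) if p not in nuc_set])
        ) or (np.array([], dtype=int), np.array([], dtype=int))
        nuc_px.append(nuc)
        cell_px.append(whole)
        annulus_px.append(ann)

    for ch in spec.channels:
        img = np.full(shape, spec.noise_mean, dtype=float)
        if spec.noise_sd > 0:
            img += noise_rng.normal(0.0, spec.noise_sd, size=shape)
        if ch == "DAPI":
            for i in range(n_cells):
                val = max(0.0, noise_rng.normal(spec.dapi_mean, spec.dapi_sd))
                img[nuc_px[i]] += val
        else:
            values = cells.get(ch, np.zeros(n_cells))
            if ch in NUCLEAR_MARKERS:
                footprints = nuc_px
            elif ch in CYTOPLASM_MARKERS:
                footprints = annulus_px
            else:
                footprints = cell_px
            for i, val in enumerate(values):
                if val > 0:
                    img[footprints[i]] += val
        out[ch] = np.clip(np.rint(img), 0, top).astype(dtype)
    return out


def generate_fov(
    spec: CohortSpec,
    section_id: str,
    fov_id: str,
    rng_state: int | np.random.SeedSequence | None = None,
    *,
    mean_scale: dict[str, float] | None = None,
    abundance_scale: dict[str, float] | None = None,
    tumor_free: bool = False,
    render: bool = True,
) -> tuple[FOVImage | None, GroundTruth]:
    """Generate one FOV and its ground-truth slice.

    ``rng_state`` defaults to a stream derived from ``spec.seed`` and the two
    id strings, so regeneration of any single FOV is bit-identical regardless
    of generation order.  ``mean_scale``/``abundance_scale`` carry section- and
    group-level multipliers when called from :func:`generate_cohort`.  With
    ``render=False`` only the ground truth is produced (the sampled cells are
    identical either way).
    """
    fov, data = _generate_fov_raw(
        spec,
        section_id,
        fov_id,
        rng_state,
        mean_scale=mean_scale or {},
        abundance_scale=abundance_scale or {},
        tumor_free=tumor_free,
        render=render,
    )
    gt = GroundTruth(
        cells=pd.DataFrame(data),
        planted_effects=dict(spec.effect_log2),
        tumor_free_fovs={(section_id, fov_id)} if tumor_free else set(),
    )
    return fov, gt


def _generate_fov_raw(
    spec: CohortSpec,
    section_id: str,
    fov_id: str,
    rng_state: int | np.random.SeedSequence | None,
    *,
    mean_scale: dict[str, float],
    abundance_scale: dict[str, float],
    tumor_free: bool,
    render: bool,
) -> tuple[FOVImage | None, dict[str, np.ndarray]]:
    if rng_state is None:
        ss = _fov_seed_seq(spec, section_id, fov_id)
    elif isinstance(rng_state, np.random.SeedSequence):
        ss = rng_state
    else:
        ss = np.random.SeedSequence(int(rng_state))
    cells_ss, noise_ss = ss.spawn(2)
    data = _sample_cells(
        spec,
        section_id,
        fov_id,
        np.random.default_rng(cells_ss),
        mean_scale,
        abundance_scale,
        tumor_free,
    )
    if not render:
        return None, data
    channels = _render(spec, data, np.random.default_rng(noise_ss))
    fov = FOVImage(
        section_id=section_id,
        fov_id=fov_id,
        channels=channels,
        exposure_ms={ch: spec.exposure_for(ch) for ch in spec.channels},
        bit_depth=spec.bit_depth,
        rounds=spec.rounds,
    )
    return fov, data


# ---------------------------------------------------------------------------
# cohort-level generation


def _section_ids(spec: CohortSpec) -> list[tuple[str, str]]:
    ids = [(f"A{i + 1:03d}", "a") for i in range(spec.n_group_a)]
    ids += [(f"B{i + 1:03d}", "b") for i in range(spec.n_group_b)]
    return ids


def _iter_cohort_raw(spec: CohortSpec, *, render: bool):
    """Internal stream yielding (sec_id, group, fov|None, column dict, tf)."""
    markers = spec.markers
    for si, (sec_id, group) in enumerate(_section_ids(spec)):
        sec_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, si))
        sec_rng = np.random.default_rng(sec_ss)
        lo, hi = spec.fovs_per_section
        n_fovs = int(sec_rng.integers(lo, hi + 1))
        mean_scale = {
            m: float(2.0 ** sec_rng.normal(0.0, spec.section_sigma_log2))
            for m in markers
        }
        abundance_scale: dict[str, float] = {}
        if group == "b":
            for m, eff in spec.effect_log2.items():
                mean_scale[m] = mean_scale.get(m, 1.0) * 2.0 ** eff
            abundance_scale = {
                name: 2.0 ** eff for name, eff in spec.abundance_log2.items()
            }
        for fi in range(n_fovs):
            fov_id = f"{sec_id}-f{fi + 1:03d}"
            is_tf = (
                spec.tumor_free_fraction > 0
                and sec_rng.uniform() < spec.tumor_free_fraction
            )
            fov, data = _generate_fov_raw(
                spec,
                sec_id,
                fov_id,
                None,
                mean_scale=mean_scale,
                abundance_scale=abundance_scale,
                tumor_free=is_tf,
                render=render,
            )
            yield sec_id, group, fov_id, fov, data, is_tf


def iter_cohort_fovs(spec: CohortSpec, *, render: bool = True):
    """Stream the cohort one FOV at a time.

    Yields ``(section_id, group, fov_image_or_None, ground_truth_slice)``.
    Section-level draws (FOV count, lognormal heterogeneity multipliers,
    tumor-free flags) come from a per-section stream keyed ``(1, si)``, which
    cannot collide with the crc32 pairs keying the per-FOV streams, so the
    whole cohort is reproducible FOV by FOV.
    """
    for sec_id, group, fov_id, fov, data, is_tf in _iter_cohort_raw(
        spec, render=render
    ):
        gt = GroundTruth(
            cells=pd.DataFrame(data),
            planted_effects=dict(spec.effect_log2),
            tumor_free_fovs={(sec_id, fov_id)} if is_tf else set(),
        )
        yield sec_id, group, fov, gt


def cohort_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Section -> group manifest with the drawn per-section FOV counts."""
    rows = []
    for si, (sec_id, group) in enumerate(_section_ids(spec)):
        sec_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, si))
        )
        lo, hi = spec.fovs_per_section
        rows.append(
            {
                "section_id": sec_id,
                "group": group,
                "n_fovs": int(sec_rng.integers(lo, hi + 1)),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, *, render: bool = True) -> CohortResult:
    """Generate the full two-group cohort.

    Returns the rendered images grouped by section (``None`` when
    ``render=False``), a manifest mapping section to group, and the pooled
    ground truth.  Group-b sections get ``2**effect_log2[marker]`` applied to
    marker means and ``2**abundance_log2[name]`` to phenotype abundances, on
    top of each section's own lognormal heterogeneity multiplier.
    """
    images: dict[str, list[FOVImage]] | None = {} if render else None
    chunks: list[dict[str, np.ndarray]] = []
    tumor_free: set[tuple[str, str]] = set()
    manifest_rows: list[dict] = []
    for sec_id, group, fov_id, fov, data, is_tf in _iter_cohort_raw(
        spec, render=render
    ):
        if not manifest_rows or manifest_rows[-1]["section_id"] != sec_id:
            manifest_rows.append(
                {"section_id": sec_id, "group": group, "n_fovs": 0}
            )
            if render:
                images[sec_id] = []
        manifest_rows[-1]["n_fovs"] += 1
        chunks.append(data)
        if is_tf:
            tumor_free.add((sec_id, fov_id))
        if render:
            images[sec_id].append(fov)
    if chunks:
        cells = pd.DataFrame(
            {
                col: np.concatenate([c[col] for c in chunks])
                for col in chunks[0]
            }
        )
    else:
        cells = pd.DataFrame()
    return CohortResult(
        images=images,
        manifest=pd.DataFrame(manifest_rows),
        ground_truth=GroundTruth(
            cells=cells,
            planted_effects=dict(spec.effect_log2),
            tumor_free_fovs=tumor_free,
        ),
    )


# ---------------------------------------------------------------------------
# ground-truth summaries (used by the simulation experiments and tests)


def fov_marker_means(cells: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Mean ground-truth signal per marker over all cells in each FOV."""
    if cells.empty:
        return pd.DataFrame(columns=["section_id", "fov_id", *markers])
    return (
        cells.groupby(["section_id", "fov_id"], sort=False)[list(markers)]
        .mean()
        .reset_index()
    )


def section_marker_medians(cells: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Median over FOVs of the per-FOV marker means, per section."""
    per_fov = fov_marker_means(cells, markers)
    if per_fov.empty:
        return pd.DataFrame(columns=["section_id", *markers])
    return (
        per_fov.groupby("section_id", sort=False)[list(markers)]
        .median()
        .reset_index()
    )
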