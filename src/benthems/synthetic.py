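"""Synthetic incidence data with known ground truth.

Two generators back the test bed:

* :func:`gen_structure` emits an incidence matrix built to one of the
  idealized metacommunity geometries (nested, Clementsian, Gleasonian,
  evenly spaced, checkerboard, random), optionally perturbed by symmetric
  bit-flip noise — the round-trip target for the EMS classifier.

* :func:`gen_survey` emits a two-period depth-gradient survey: species
  with contiguous depth-niche ranges, Bernoulli occupancy within range,
  and a chosen fraction of species whose maximal depth contracts in the
  recent period, with trait-dependent selection of the shifted set — the
  round-trip target for the depth-change stage.

Both are deterministic given their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .incidence import (
    POSITION_CLASSES,
    SIZE_CLASSES,
    TAXON_GROUPS,
    IncidenceMatrix,
    SiteRecord,
    SpeciesRecord,
)

__all__ = [
    "StructureSpec",
    "SurveySpec",
    "SyntheticTruth",
    "SurveyData",
    "gen_structure",
    "gen_survey",
]

Structure = Literal[
    "nested", "clementsian", "gleasonian", "evenly_spaced", "checkerboard", "random"
]


@dataclass
class StructureSpec:
    structure: Structure
    n_sites: int = 30
    n_species: int = 60
    noise: float = 0.0
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise < 0.5):
            raise ValueError("noise must lie in [0, 0.5)")
        if self.n_sites < 4 or self.n_species < 4:
            raise ValueError("need at least 4 sites and 4 species")


@dataclass
class SurveySpec:
    """Two-period depth-gradient survey design.

    Defaults mirror a soft-bottom benthic survey over a 19-80 m gradient:
    per-species contiguous depth ranges, high within-range detection
    (sites pool several grab replicates), and in the recent period a third
    of the species contracting maximal depth by on average 20 m, with
    large-bodied and (semi)emergent species carrying higher odds of being
    in the shifted set.
    """

    depth_min_m: float = 19.0
    depth_max_m: float = 80.0
    n_sites: int = 40
    n_species: int = 120
    occupancy_prob: float = 0.95
    width_min_m: float = 20.0
    width_max_m: float = 61.0
    shift_fraction: float = 0.33
    shift_mean_m: float = 20.0
    shift_sd_m: float = 5.0
    trait_effect: float = 4.0
    shared_sites: bool = True
    deep_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.shift_fraction <= 1):
            raise ValueError("shift_fraction must lie in [0, 1]")
        if self.shift_mean_m < 0:
            raise ValueError("shift_mean_m must be >= 0")
        if not self.depth_min_m < self.depth_max_m:
            raise ValueError("depth_min_m must be < depth_max_m")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``structure`` for idealized matrices; for surveys, the set of truly
    shifted species (restricted to species present in the emitted
    matrices) and their realized contractions in meters.
    """

    structure: str | None = None
    shifted_species: set[str] = field(default_factory=set)
    contractions_m: dict[str, float] = field(default_factory=dict)


@dataclass
class SurveyData:
    old: IncidenceMatrix
    recent: IncidenceMatrix
    site_records: list[SiteRecord]
    species_records: list[SpeciesRecord]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Idealized structures
# ---------------------------------------------------------------------------

def _contiguous(n_sites: int, start: int, width: int) -> np.ndarray:
    col = np.zeros(n_sites, dtype=np.int8)
    col[start : start + width] = 1
    return col


def _build_structure(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    n, s = spec.n_sites, spec.n_species
    cols = []
    if spec.structure == "nested":
        # species j occupies the first w_j sites; widths shrink with j,
        # giving a perfect subset chain (sites ordered rich -> poor)
        for j in range(s):
            w = max(1, round((s - j) * n / s))
            cols.append(_contiguous(n, 0, w))
    elif spec.structure == "clementsian":
        n_comp = int(spec.params.get("n_compartments", 4))
        if not 2 <= n_comp <= min(n, s):
            raise ValueError(f"infeasible compartment count {n_comp}")
        site_edges = np.linspace(0, n, n_comp + 1).round().astype(int)
        for j in range(s):
            c = j % n_comp
            cols.append(_contiguous(n, site_edges[c], site_edges[c + 1] - site_edges[c]))
    elif spec.structure == "gleasonian":
        wmin = int(spec.params.get("width_min", max(2, n // 6)))
        wmax = int(spec.params.get("width_max", max(wmin + 1, n // 2)))
        for _ in range(s):
            w = int(rng.integers(wmin, wmax + 1))
            start = int(rng.integers(0, n - w + 1))
            cols.append(_contiguous(n, start, w))
    elif spec.structure == "evenly_spaced":
        w = int(spec.params.get("width", max(2, n // 3)))
        for j in range(s):
            start = round(j * (n - w) / max(1, s - 1))
            cols.append(_contiguous(n, start, w))
    elif spec.structure == "checkerboard":
        # complementary random site sets within each species pair
        for _ in range(0, s, 2):
            mask = rng.integers(0, 2, size=n).astype(np.int8)
            if mask.sum() in (0, n):  # both members must occupy >= 1 site
                mask[0] ^= 1
            cols.append(mask)
            cols.append(1 - mask)
        cols = cols[:s]
    elif spec.structure == "random":
        fill = float(spec.params.get("fill", 0.3))
        return (rng.random((n, s)) < fill).astype(np.int8)
    else:
        raise ValueError(f"unknown structure {spec.structure!r}")
    return np.column_stack(cols)


def gen_structure(spec: StructureSpec) -> tuple[IncidenceMatrix, SyntheticTruth]:
    """Generate one idealized matrix plus its ground-truth label.

    With ``noise == 0`` the output satisfies the defining algebraic
    property of its structure exactly (nested: subset chain; checkerboard:
    zero within-pair co-occurrence; clementsian/gleasonian/evenly spaced:
    contiguous ranges over the built-in site order).
    """
    rng = np.random.default_rng(spec.seed)
    values = _build_structure(spec, rng)
    if spec.noise > 0:
        flips = rng.random(values.shape) < spec.noise
        values = values ^ flips.astype(np.int8)
    sites = [f"s{i:03d}" for i in range(spec.n_sites)]
    species = [f"sp{j:03d}" for j in range(spec.n_species)]
    return (
        IncidenceMatrix(sites, species, values),
        SyntheticTruth(structure=spec.structure),
    )


# ---------------------------------------------------------------------------
# Two-period depth-gradient survey
# ---------------------------------------------------------------------------

def _assign_traits(s: int, rng: np.random.Generator) -> list[SpeciesRecord]:
    taxa = rng.choice(len(TAXON_GROUPS), size=s, p=[0.30, 0.20, 0.15, 0.10, 0.05, 0.10, 0.10])
    sizes = rng.choice(len(SIZE_CLASSES), size=s, p=[0.35, 0.40, 0.25])
    positions = rng.choice(len(POSITION_CLASSES), size=s, p=[0.40, 0.60])
    return [
        SpeciesRecord(
            species_id=f"sp{j:03d}",
            taxon_group=TAXON_GROUPS[taxa[j]],
            size_class=SIZE_CLASSES[sizes[j]],
            position_class=POSITION_CLASSES[positions[j]],
        )
        for j in range(s)
    ]


def _site_depths(spec: SurveySpec, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(spec.n_sites)
    if spec.deep_bias:
        u = np.sqrt(u)  # skew toward the deep end, as in a dense old survey
    d = spec.depth_min_m + u * (spec.depth_max_m - spec.depth_min_m)
    return np.sort(d)


def _occupancy(
    depths: np.ndarray, lo: np.ndarray, hi: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    in_range = (depths[:, None] >= lo[None, :]) & (depths[:, None] <= hi[None, :])
    return (in_range & (rng.random(in_range.shape) < p)).astype(np.int8)


def gen_survey(spec: SurveySpec) -> SurveyData:
    """Generate an old/recent incidence-matrix pair over a depth gradient.

    Species ranges are contiguous in depth (uniform midpoint, uniform
    width, clipped to the gradient). A weighted draw without replacement
    picks ``round(shift_fraction * n_species)`` species to contract, with
    odds multiplied by ``trait_effect`` for large or (semi)emergent
    species; each contracts its range's deep limit by a truncated-normal
    draw around ``shift_mean_m``. Occupancy is Bernoulli within range,
    redrawn independently per period.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.n_species

    depths_old = _site_depths(spec, rng)
    if spec.shared_sites:
        depths_rec = depths_old
        old_site_ids = rec_site_ids = [f"s{i:03d}" for i in range(spec.n_sites)]
    else:
        depths_rec = _site_depths(spec, rng)
        old_site_ids = [f"o{i:03d}" for i in range(spec.n_sites)]
        rec_site_ids = [f"r{i:03d}" for i in range(spec.n_sites)]

    species_records = _assign_traits(s, rng)

    mid = rng.uniform(spec.depth_min_m, spec.depth_max_m, size=s)
    width = rng.uniform(spec.width_min_m, spec.width_max_m, size=s)
    lo = np.clip(mid - width / 2, spec.depth_min_m, None)
    hi = np.clip(mid + width / 2, None, spec.depth_max_m)

    # trait-weighted draw of the shifted set (exact count)
    n_shift = round(spec.shift_fraction * s)
    sensitive = np.array(
        [r.size_class == "L" or r.position_class == "emergent_semiemergent" for r in species_records]
    )
    weights = np.where(sensitive, spec.trait_effect, 1.0)
    shifted_idx = rng.choice(s, size=n_shift, replace=False, p=weights / weights.sum())
    shifted = np.zeros(s, dtype=bool)
    shifted[shifted_idx] = True

    contraction = np.maximum(rng.normal(spec.shift_mean_m, spec.shift_sd_m, size=s), 1.0)
    hi_rec = hi.copy()
    hi_rec[shifted] = np.maximum(lo[shifted] + 1.0, hi[shifted] - contraction[shifted])

    old_vals = _occupancy(depths_old, lo, hi, spec.occupancy_prob, rng)
    rec_vals = _occupancy(depths_rec, lo, hi_rec, spec.occupancy_prob, rng)

    species_ids = [r.species_id for r in species_records]
    old = IncidenceMatrix(list(old_site_ids), list(species_ids), old_vals)
    recent = IncidenceMatrix(list(rec_site_ids), list(species_ids), rec_vals)

    site_records = [
        SiteRecord(site_id=sid, depth_m=float(d), period="old")
        for sid, d in zip(old_site_ids, depths_old)
    ]
    if not spec.shared_sites:
        site_records += [
            SiteRecord(site_id=sid, depth_m=float(d), period="recent")
            for sid, d in zip(rec_site_ids, depths_rec)
        ]

    emitted = old.present_species() | recent.present_species()
    truth = SyntheticTruth(
        shifted_species={species_ids[j] for j in np.flatnonzero(shifted)} & emitted,
        contractions_m={
            species_ids[j]: float(hi[j] - hi_rec[j])
            for j in np.flatnonzero(shifted)
            if species_ids[j] in emitted
        },
    )
    return SurveyData(old, recent, site_records, species_records, truth)
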