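"""Per-species maximal-depth-of-occurrence change between survey periods.

For every species recorded in both an old and a recent survey, the deepest
occupied site defines its maximal depth of occurrence (the lower limit of
its depth range). Comparing the two periods yields a change category
(decrease / increase / unchanged), a paired t-test of the depth records
within a category, and — with a fishing-pressure depth threshold — a
transition class between the shallow low-fishing-pressure (LFP) and deep
high-fishing-pressure (HFP) zones. Trait and taxon cross-tabulations
summarize which kinds of species moved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import IncidenceMatrix, SiteRecord, SpeciesRecord

__all__ = [
    "ZoneConfig",
    "DepthChangeRecord",
    "max_depth",
    "compare_periods",
    "depth_shift_test",
    "transition_summary",
    "shallow_fraction",
    "composition_tables",
]

HFP_TO_LFP = "HFP->LFP"
STAY_HFP = "stay-HFP"
LFP_TO_HFP = "LFP->HFP"
STAY_LFP = "stay-LFP"
TRANSITIONS = (HFP_TO_LFP, STAY_HFP, LFP_TO_HFP, STAY_LFP)


@dataclass(frozen=True)
class ZoneConfig:
    """Fishing-pressure zoning of the depth gradient.

    ``threshold_m`` splits the gradient into the shallow LFP and deep HFP
    zones; a species exactly at the threshold is HFP by default (the zones
    are labelled 19-30 m and 30-80 m, sharing the boundary; set
    ``threshold_open`` to put the boundary itself in LFP).
    ``depth_floor_m`` caps *reported* maximal depths; zone logic always
    uses the uncapped value.
    """

    threshold_m: float = 30.0
    depth_floor_m: float | None = 79.0
    threshold_open: bool = False

    def zone(self, depth: float) -> str:
        if self.threshold_open:
            return "HFP" if depth > self.threshold_m else "LFP"
        return "HFP" if depth >= self.threshold_m else "LFP"


@dataclass(frozen=True)
class DepthChangeRecord:
    """One shared species: old vs recent maximal depth and derived classes."""

    species_id: str
    max_old: float
    max_recent: float
    delta: float          # max_recent - max_old (m); negative = shallower
    category: str         # decrease | increase | unchanged
    zone_old: str
    zone_recent: str
    transition: str


def max_depth(
    matrix: IncidenceMatrix,
    site_records: Sequence[SiteRecord],
    floor_m: float | None = None,
) -> dict[str, float]:
    """Maximal depth of occurrence per species with >= 1 presence.

    Optionally capped at ``floor_m`` (a reporting convention for plots and
    tables; pass None for the raw values used in zone logic).
    """
    depths = {r.site_id: r.depth_m for r in site_records}
    missing = [s for s in matrix.site_ids if s not in depths]
    if missing:
        raise ValueError(f"depths missing for sites: {missing}")
    d = np.array([depths[s] for s in matrix.site_ids])
    out: dict[str, float] = {}
    for j, sp in enumerate(matrix.species_ids):
        occ = matrix.values[:, j] > 0
        if not occ.any():
            continue
        m = float(d[occ].max())
        out[sp] = min(m, floor_m) if floor_m is not None else m
    return out


def _categorize(delta: float) -> str:
    if delta < 0:
        return "decrease"
    if delta > 0:
        return "increase"
    return "unchanged"


def _transition(zone_old: str, zone_recent: str) -> str:
    return {
        ("HFP", "LFP"): HFP_TO_LFP,
        ("HFP", "HFP"): STAY_HFP,
        ("LFP", "HFP"): LFP_TO_HFP,
        ("LFP", "LFP"): STAY_LFP,
    }[(zone_old, zone_recent)]


def compare_periods(
    old_matrix: IncidenceMatrix,
    recent_matrix: IncidenceMatrix,
    site_records: Sequence[SiteRecord],
    zones: ZoneConfig | None = None,
) -> list[DepthChangeRecord]:
    """Depth-change records for every species present in both matrices.

    Matrices must already be harmonized; ``site_records`` must cover the
    sites of both. Categories partition the shared species by the sign of
    delta; zones and transitions come from the uncapped maximal depths.
    """
    zones = zones or ZoneConfig()
    old_max = max_depth(old_matrix, site_records)
    rec_max = max_depth(recent_matrix, site_records)
    shared = [s for s in old_matrix.species_ids if s in old_max and s in rec_max]
    records = []
    for sp in shared:
        mo, mr = old_max[sp], rec_max[sp]
        zo, zr = zones.zone(mo), zones.zone(mr)
        records.append(
            DepthChangeRecord(
                species_id=sp,
                max_old=mo,
                max_recent=mr,
                delta=mr - mo,
                category=_categorize(mr - mo),
                zone_old=zo,
                zone_recent=zr,
                transition=_transition(zo, zr),
            )
        )
    return records


def depth_shift_test(
    records: Iterable[DepthChangeRecord],
    category: str,
    paired: bool = True,
) -> dict[str, float]:
    """Student's t test of old vs recent maximal depths within one change
    category.

    Default is the paired test on the per-species differences (df = n - 1);
    t is computed on (old - recent), so a decreasing category yields a
    positive t. ``paired=False`` gives the two-sample (Welch) variant.
    Zero variance of the differences is flagged (t infinite).
    """
    sel = [r for r in records if r.category == category]
    if len(sel) < 2:
        raise ValueError(f"need >= 2 records in category {category!r}, got {len(sel)}")
    old = np.array([r.max_old for r in sel])
    rec = np.array([r.max_recent for r in sel])
    n = len(sel)
    if paired:
        diffs = old - rec
        if np.ptp(diffs) == 0:
            return {
                "t": float("inf") if diffs[0] > 0 else -float("inf"),
                "df": n - 1,
                "p": 0.0,
                "mean_old": float(old.mean()),
                "mean_recent": float(rec.mean()),
                "n": n,
                "degenerate": True,
            }
        t, p = stats.ttest_rel(old, rec)
        df = n - 1
    else:
        t, p = stats.ttest_ind(old, rec, equal_var=False)
        df = 2 * n - 2
    return {
        "t": float(t),
        "df": int(df),
        "p": float(p),
        "mean_old": float(old.mean()),
        "mean_recent": float(rec.mean()),
        "n": n,
        "degenerate": False,
    }


def transition_summary(records: Sequence[DepthChangeRecord]) -> dict[str, float]:
    """Percentage of shared species per fishing-zone transition class.

    The four classes partition the records, so percentages sum to 100.
    """
    n = len(records)
    if n == 0:
        return {t: 0.0 for t in TRANSITIONS}
    counts = {t: sum(1 for r in records if r.transition == t) for t in TRANSITIONS}
    return {t: 100.0 * c / n for t, c in counts.items()}


def shallow_fraction(
    matrix: IncidenceMatrix,
    site_records: Sequence[SiteRecord],
    threshold_m: float = 30.0,
) -> float:
    """Percentage of species whose maximal depth is shallower than the
    threshold."""
    md = max_depth(matrix, site_records)
    if not md:
        return 0.0
    return 100.0 * sum(1 for v in md.values() if v < threshold_m) / len(md)


def composition_tables(
    records: Sequence[DepthChangeRecord],
    species_meta: Mapping[str, SpeciesRecord] | Sequence[SpeciesRecord],
) -> dict[str, pd.DataFrame]:
    """Taxon-by-category and (size x position)-by-transition contingency
    tables (counts). Species without metadata fall into the Other /
    unknown buckets."""
    if not isinstance(species_meta, Mapping):
        species_meta = {r.species_id: r for r in species_meta}
    rows = []
    for r in records:
        meta = species_meta.get(r.species_id)
        rows.append(
            {
                "species_id": r.species_id,
                "category": r.category,
                "transition": r.transition,
                "taxon_group": meta.taxon_group if meta else "Other",
                "size_class": meta.size_class if meta else "unknown",
                "position_class": meta.position_class if meta else "unknown",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return {"taxon_by_category": pd.DataFrame(), "trait_by_transition": pd.DataFrame()}
    return {
        "taxon_by_category": pd.crosstab(df["taxon_group"], df["category"]),
        "trait_by_transition": pd.crosstab(
            [df["size_class"], df["position_class"]], df["transition"]
        ),
    }


def records_to_frame(records: Sequence[DepthChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
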