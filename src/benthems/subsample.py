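"""Site-subsampling robustness study and site-based rarefaction.

A dense old survey and a sparse recent one cannot be compared directly:
more sites mean more species and potentially a different apparent
structure. The remedy implemented here draws many random subsets of k
sites from the dense matrix, reruns the full EMS classification and the
axis-depth correlation on each, and tallies how often the recent pattern
(a Clementsian label, a strong depth correlation) appears — together with
rarefied species richness at the same k-site effort, overall and per
species group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom

from .ems import NullConfig, base_label, run_ems
from .incidence import DegenerateMatrixError, IncidenceMatrix
from .ordination import (
    NoNontrivialAxisError,
    axis_depth_correlation,
    reciprocal_averaging,
)

__all__ = [
    "SubsampleConfig",
    "SubsampleSummary",
    "subsample_sites",
    "permutation_study",
    "rarefied_richness",
    "expected_richness",
    "group_ratio_report",
]

DEGENERATE = "degenerate"


@dataclass
class SubsampleConfig:
    """Settings of the subsampling study.

    ``k`` sites per draw, ``n_perm`` draws; a correlation counts as strong
    when |r| > ``r_strong`` and as significant when its two-sided p <
    ``p_sig``; ``null_config`` parameterizes the inner EMS runs.
    """

    k: int = 19
    n_perm: int = 600
    seed: int = 0
    r_strong: float = 0.80
    p_sig: float = 0.001
    alpha: float = 0.05
    null_config: NullConfig = field(default_factory=NullConfig)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.k <= 2:
            raise ValueError("k must exceed 2")


@dataclass
class SubsampleSummary:
    """Tallies over the n_perm subsamples."""

    n_perm: int
    k: int
    label_counts: dict[str, int]
    n_sig_corr: int
    n_strong_corr: int
    n_clementsian_and_sig: int
    richness_mean: float
    richness_sd: float
    group_richness: dict[str, tuple[float, float]]
    records: list[dict] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "k": self.k,
            "label_counts": self.label_counts,
            "n_sig_corr": self.n_sig_corr,
            "n_strong_corr": self.n_strong_corr,
            "n_clementsian_and_sig": self.n_clementsian_and_sig,
            "p_clementsian_and_sig": self.n_clementsian_and_sig / self.n_perm,
            "p_strong_corr": self.n_strong_corr / self.n_perm,
            "richness_mean": self.richness_mean,
            "richness_sd": self.richness_sd,
            "group_richness": {g: {"mean": m, "sd": s} for g, (m, s) in self.group_richness.items()},
        }


def subsample_sites(
    matrix: IncidenceMatrix, k: int, rng: np.random.Generator
) -> IncidenceMatrix:
    """Uniform draw of k distinct sites; empty species columns dropped.

    Site order within the subsample follows the parent matrix (the draw
    selects, it does not reorder), so downstream tie-breaking stays
    deterministic.
    """
    if k > matrix.n_sites:
        raise ValueError(f"k={k} exceeds {matrix.n_sites} sites")
    rows = np.sort(rng.choice(matrix.n_sites, size=k, replace=False))
    sub = IncidenceMatrix(
        [matrix.site_ids[i] for i in rows], list(matrix.species_ids), matrix.values[rows]
    )
    keep = sub.values.sum(axis=0) > 0
    return IncidenceMatrix(
        list(sub.site_ids),
        [s for s, kcol in zip(sub.species_ids, keep) if kcol],
        sub.values[:, keep],
    )


def permutation_study(
    matrix: IncidenceMatrix,
    depths: Mapping[str, float],
    config: SubsampleConfig,
    group_map: Mapping[str, str] | None = None,
    keep_records: bool = False,
) -> SubsampleSummary:
    """Run the EMS classification and axis-depth correlation on ``n_perm``
    random k-site subsamples and tally the outcomes.

    Degenerate subsamples (no non-trivial axis left) are recorded under
    the "degenerate" label rather than redrawn, so the reported
    frequencies are over exactly n_perm draws. Reproducible bit-for-bit
    from ``config.seed``.
    """
    missing = [s for s in matrix.site_ids if s not in depths]
    if missing:
        raise ValueError(f"depths missing for sites: {missing}")
    rng = np.random.default_rng(config.seed)
    label_counts: dict[str, int] = {}
    n_sig = n_strong = n_both = 0
    richness: list[int] = []
    group_richness: dict[str, list[int]] = {g: [] for g in set((group_map or {}).values())}
    records: list[dict] = []

    for i in range(config.n_perm):
        sub = subsample_sites(matrix, config.k, rng)
        inner = NullConfig(
            method=config.null_config.method,
            n_sim=config.null_config.n_sim,
            allow_empty_rows=config.null_config.allow_empty_rows,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        richness.append(sub.n_species)
        if group_map is not None:
            for g in group_richness:
                group_richness[g].append(
                    sum(1 for s in sub.species_ids if group_map.get(s) == g)
                )
        try:
            outcome = run_ems(sub, inner, alpha=config.alpha)
            ordn = reciprocal_averaging(sub)
            r, p, _ = axis_depth_correlation(
                ordn, np.array([depths[s] for s in sub.site_ids])
            )
            label = base_label(outcome.label)
        except (NoNontrivialAxisError, DegenerateMatrixError, ValueError):
            label, r, p = DEGENERATE, float("nan"), float("nan")
        label_counts[label] = label_counts.get(label, 0) + 1
        sig = label != DEGENERATE and p < config.p_sig
        strong = label != DEGENERATE and r > config.r_strong
        n_sig += sig
        n_strong += strong
        n_both += sig and label == "Clementsian"
        if keep_records:
            records.append(
                {"subsample": i, "label": label, "r": r, "p": p, "richness": sub.n_species}
            )

    rich = np.array(richness, dtype=float)
    return SubsampleSummary(
        n_perm=config.n_perm,
        k=config.k,
        label_counts=label_counts,
        n_sig_corr=n_sig,
        n_strong_corr=n_strong,
        n_clementsian_and_sig=n_both,
        richness_mean=float(rich.mean()),
        richness_sd=float(rich.std(ddof=1)) if len(rich) > 1 else 0.0,
        group_richness={
            g: (
                float(np.mean(v)),
                float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            )
            for g, v in group_richness.items()
        },
        records=records,
    )


def rarefied_richness(
    matrix: IncidenceMatrix,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    group_map: Mapping[str, str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Mean +/- SD distinct-species richness over n_perm k-site subsamples,
    overall ("all") and per group of ``group_map`` (species -> group)."""
    groups = sorted(set((group_map or {}).values()))
    tallies: dict[str, list[int]] = {"all": []} | {g: [] for g in groups}
    for _ in range(n_perm):
        sub = subsample_sites(matrix, k, rng)
        tallies["all"].append(sub.n_species)
        for g in groups:
            tallies[g].append(sum(1 for s in sub.species_ids if group_map.get(s) == g))
    return {
        g: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for g, v in tallies.items()
    }


def expected_richness(matrix: IncidenceMatrix, k: int) -> float:
    """Closed-form site-based rarefaction: E[S_k] = sum_j P(species j hits
    >= 1 of k sites drawn without replacement) via the hypergeometric
    distribution. The analytic check on :func:`rarefied_richness`."""
    n = matrix.n_sites
    nj = matrix.species_prevalence()
    return float(np.sum(1.0 - hypergeom.pmf(0, n, nj, k)))


def group_ratio_report(
    estimates: Mapping[str, float], measured: Mapping[str, float]
) -> dict[str, float | None]:
    """Per-group ratio of measured (recent) richness to estimated (old,
    effort-matched) richness. A zero estimate yields None (flagged)."""
    out: dict[str, float | None] = {}
    for g in estimates:
        if g not in measured:
            continue
        est = estimates[g]
        out[g] = None if est == 0 else measured[g] / est
    return out
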