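"""Elements of metacommunity structure: coherence, turnover, boundary clumping.

The stepwise procedure: (1) order the incidence matrix by the first
reciprocal-averaging axis; (2) count embedded absences (gaps inside
species and site ranges) for coherence; (3) fill species ranges and count
pairwise replacements for turnover; (4) test range-boundary clumping with
Morisita's index; (5) compare coherence and turnover against a
fixed-proportional ("r1") null model — row sums fixed, columns filled with
probability proportional to observed species prevalence, empty rows
allowed — with every null matrix independently re-ordinated; (6) map the
three results onto the idealized structure vocabulary (checkerboard,
nested, evenly spaced, Gleasonian, Clementsian, their quasi- variants, and
random).

Significance uses the normal (z) approximation from the null mean and SD,
two-tailed, which permits p-values below 1/n_sim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from scipy import stats

from .incidence import IncidenceMatrix, drop_empty
from .ordination import (
    NoNontrivialAxisError,
    order_matrix,
    reciprocal_averaging,
)

__all__ = [
    "MetricResult",
    "ClumpingResult",
    "NullConfig",
    "EMSOutcome",
    "embedded_absences",
    "fill_ranges",
    "replacements",
    "boundary_clumping",
    "null_matrices",
    "metric_significance",
    "classify",
    "run_ems",
]


@dataclass
class MetricResult:
    """Observed value of a count statistic against its null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    degenerate: bool = False

    @classmethod
    def from_null(cls, observed: float, nulls: np.ndarray) -> "MetricResult":
        mean = float(np.mean(nulls))
        sd = float(np.std(nulls, ddof=1))
        if sd == 0:
            return cls(observed, mean, 0.0, 0.0, 1.0 if observed == mean else 0.0, True)
        z = (observed - mean) / sd
        p = 2.0 * stats.norm.sf(abs(z))
        return cls(float(observed), mean, sd, float(z), float(p))


@dataclass
class ClumpingResult:
    """Morisita dispersion test of species range boundaries over sites."""

    morisita: float
    chi2: float
    df: int
    p: float


@dataclass
class NullConfig:
    """Null-model settings. ``method`` is pluggable but only "r1" ships."""

    method: str = "r1"
    n_sim: int = 1000
    allow_empty_rows: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 2:
            raise ValueError("n_sim must be >= 2")
        if self.method != "r1":
            raise ValueError(f"unknown null model {self.method!r}")


@dataclass
class EMSOutcome:
    """Full EMS result for one matrix: three metrics plus the structure label."""

    coherence: MetricResult
    turnover: MetricResult
    clumping: ClumpingResult
    label: str
    alpha: float = 0.05
    ordered: IncidenceMatrix | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "coherence": {
                "absences": self.coherence.observed,
                "p": self.coherence.p,
                "mean": self.coherence.null_mean,
                "sd": self.coherence.null_sd,
                "z": self.coherence.z,
            },
            "turnover": {
                "replacements": self.turnover.observed,
                "p": self.turnover.p,
                "mean": self.turnover.null_mean,
                "sd": self.turnover.null_sd,
                "z": self.turnover.z,
            },
            "boundary_clumping": {
                "morisita": self.clumping.morisita,
                "p": self.clumping.p,
                "df": self.clumping.df,
            },
            "label": self.label,
            "alpha": self.alpha,
        }


# ---------------------------------------------------------------------------
# Metrics on the ordered matrix
# ---------------------------------------------------------------------------

def _range_bounds(values: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(first, last, any) index of presence along ``axis`` for each line."""
    v = values if axis == 0 else values.T
    any_ = v.any(axis=0)
    first = np.argmax(v, axis=0)
    last = v.shape[0] - 1 - np.argmax(v[::-1], axis=0)
    return first, last, any_


def embedded_absences(ordered: IncidenceMatrix, rows: bool = True) -> int:
    """Embedded absences: zeros strictly inside each species' range (between
    its first and last presence down the ordered sites), plus — by default —
    the same count inside each site's range across the ordered species.
    Set ``rows=False`` for the column-only variant.
    """
    v = ordered.values
    total = 0
    for axis in (0, 1) if rows else (0,):
        first, last, any_ = _range_bounds(v, axis)
        counts = (v if axis == 0 else v.T).sum(axis=0)
        span = np.where(any_, last - first + 1, 0)
        total += int((span - np.where(any_, counts, 0)).sum())
    return total


def fill_ranges(ordered: IncidenceMatrix) -> IncidenceMatrix:
    """Set every cell inside each species' site range to presence."""
    v = ordered.values
    top = np.maximum.accumulate(v, axis=0)
    bottom = np.maximum.accumulate(v[::-1], axis=0)[::-1]
    return IncidenceMatrix(
        list(ordered.site_ids), list(ordered.species_ids), (top & bottom).astype(np.int8)
    )


def replacements(ordered: IncidenceMatrix) -> int:
    """Species turnover: on the range-filled matrix, sum over unordered
    species pairs of (#sites exclusive to one) x (#sites exclusive to the
    other)."""
    filled = fill_ranges(ordered).values.astype(np.int64)
    n = filled.sum(axis=0)                      # range sizes
    co = filled.T @ filled                      # shared sites per pair
    prod = np.outer(n, n) - co * (n[:, None] + n[None, :]) + co * co
    return int(np.triu(prod, k=1).sum())


def boundary_clumping(ordered: IncidenceMatrix, df_offset: int = 3) -> ClumpingResult:
    """Morisita's index of dispersion of species range boundaries over sites.

    Each species with a non-empty range contributes its first- and
    last-presence sites as two boundaries (a single-site range counts its
    one site twice). I > 1 means boundaries clump at shared sites
    (Clementsian-like), I < 1 means hyperdispersion. The chi-square
    statistic is I*(F-1) + Q - F on ``Q - df_offset`` degrees of freedom
    (default offset 3), with the right tail tested when I > 1 and the left
    tail when I <= 1.
    """
    v = ordered.values
    first, last, any_ = _range_bounds(v, axis=0)
    q = ordered.n_sites
    f = np.zeros(q, dtype=np.int64)
    np.add.at(f, first[any_], 1)
    np.add.at(f, last[any_], 1)
    F = int(f.sum())
    if F < 2:
        raise ValueError("fewer than 2 range boundaries: Morisita's index undefined")
    morisita = q * (f * (f - 1)).sum() / (F * (F - 1))
    chi2 = morisita * (F - 1) + q - F
    df = q - df_offset
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (Q={q}, offset={df_offset})")
    if morisita > 1:
        p = stats.chi2.sf(chi2, df)
    else:
        p = stats.chi2.cdf(chi2, df)
    return ClumpingResult(float(morisita), float(chi2), int(df), float(p))


# ---------------------------------------------------------------------------
# r1 null model
# ---------------------------------------------------------------------------

def null_matrices(matrix: IncidenceMatrix, config: NullConfig) -> Iterator[np.ndarray]:
    """Stream of r1 null matrices (as 0/1 arrays) reproducible from the seed.

    Each null keeps every site's observed richness exactly; within a row the
    occupied columns are a weighted sample without replacement with
    inclusion probability proportional to observed species prevalence
    (Efraimidis–Spirakis exponential-key sampling). Zero rows are allowed
    and simply stay empty.
    """
    v = matrix.values
    n_sites, n_species = v.shape
    row_sums = v.sum(axis=1)
    if (row_sums > n_species).any():
        raise ValueError("row sum exceeds species count")
    w = v.sum(axis=0).astype(float)
    if (w == 0).any():
        raise ValueError("all-zero species columns present; apply drop_empty first")
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_sim):
        # smallest-key weighted sampling without replacement, all rows at once
        keys = rng.exponential(size=(n_sites, n_species)) / w
        order = np.argsort(keys, axis=1)
        null = np.zeros((n_sites, n_species), dtype=np.int8)
        for i in range(n_sites):
            null[i, order[i, : row_sums[i]]] = 1
        yield null


def _ordered_null(null_values: np.ndarray, matrix: IncidenceMatrix) -> IncidenceMatrix:
    """Re-ordinate one null matrix by RA; empty columns are dropped first
    (they carry no range), and a degenerate null falls back to its raw
    order."""
    m = IncidenceMatrix(list(matrix.site_ids), list(matrix.species_ids), null_values)
    m = drop_empty(m, "species")
    try:
        return order_matrix(m, reciprocal_averaging(m))
    except NoNontrivialAxisError:
        return m


def metric_significance(
    matrix: IncidenceMatrix,
    metric: Literal["coherence", "turnover"],
    config: NullConfig,
    ordered: IncidenceMatrix | None = None,
) -> MetricResult:
    """Observed metric vs its r1 null distribution (nulls re-ordinated)."""
    if metric not in ("coherence", "turnover"):
        raise ValueError(f"unknown metric {metric!r}")
    if ordered is None:
        ordered = order_matrix(matrix, reciprocal_averaging(matrix))
    fn = embedded_absences if metric == "coherence" else replacements
    observed = fn(ordered)
    nulls = np.array([fn(_ordered_null(nv, matrix)) for nv in null_matrices(matrix, config)])
    return MetricResult.from_null(observed, nulls)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _clump_subtype(clumping: ClumpingResult, alpha: float) -> str:
    if clumping.p < alpha and clumping.morisita > 1:
        return "clumped"
    if clumping.p < alpha and clumping.morisita < 1:
        return "hyperdispersed"
    return "random"


def classify(
    coherence: MetricResult,
    turnover: MetricResult,
    clumping: ClumpingResult,
    alpha: float = 0.05,
) -> str:
    """Map the three metric results onto the idealized-structure vocabulary.

    Decision tree: significantly more embedded absences than the null ->
    Checkerboard; non-significant coherence -> Random; significantly fewer
    absences -> positively coherent, branch on turnover. Significant
    turnover: fewer replacements -> Nested, more -> Clementsian /
    Gleasonian / EvenlySpaced by boundary clumping (clumped / random /
    hyperdispersed). Non-significant turnover gives the corresponding
    Quasi- variants by the sign of the replacement deviation. Nested and
    Quasi-nested labels carry the clumping subtype in parentheses.
    """
    if coherence.p >= alpha:
        return "Random"
    if coherence.observed > coherence.null_mean:
        return "Checkerboard"
    # positive coherence
    sub = _clump_subtype(clumping, alpha)
    nested_name = f"Nested ({sub} boundaries)"
    by_clump = {"clumped": "Clementsian", "random": "Gleasonian", "hyperdispersed": "EvenlySpaced"}
    if turnover.p < alpha:
        if turnover.observed < turnover.null_mean:
            return nested_name
        return by_clump[sub]
    if turnover.observed <= turnover.null_mean:
        return f"Quasi-{nested_name}"
    return f"Quasi-{by_clump[sub]}"


def base_label(label: str) -> str:
    """Collapse a classification to its structure family (drops the
    boundary-clumping subtype of nested labels): "Quasi-Nested (clumped
    boundaries)" -> "Quasi-Nested"."""
    return label.split(" (")[0]


def run_ems(
    matrix: IncidenceMatrix,
    config: NullConfig | None = None,
    alpha: float = 0.05,
    df_offset: int = 3,
    keep_ordered: bool = False,
) -> EMSOutcome:
    """The full stepwise EMS analysis of one incidence matrix.

    Coherence and turnover share one null stream (the same ordered null
    matrices feed both counts), matching the one-randomization design and
    halving the cost. Deterministic given ``config.seed``.
    """
    config = config or NullConfig()
    matrix = drop_empty(matrix, "species")
    ordered = order_matrix(matrix, reciprocal_averaging(matrix))

    obs_abs = embedded_absences(ordered)
    obs_rep = replacements(ordered)
    null_abs = np.empty(config.n_sim)
    null_rep = np.empty(config.n_sim)
    for k, nv in enumerate(null_matrices(matrix, config)):
        on = _ordered_null(nv, matrix)
        null_abs[k] = embedded_absences(on)
        null_rep[k] = replacements(on)

    coherence = MetricResult.from_null(obs_abs, null_abs)
    turnover = MetricResult.from_null(obs_rep, null_rep)
    clumping = boundary_clumping(ordered, df_offset=df_offset)
    label = classify(coherence, turnover, clumping, alpha)
    return EMSOutcome(
        coherence, turnover, clumping, label, alpha, ordered if keep_ordered else None
    )
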