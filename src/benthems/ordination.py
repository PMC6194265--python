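"""Reciprocal averaging (first-axis correspondence analysis) of incidence data.

The first non-trivial CA axis orders sites and species along the dominant
latent gradient; all downstream metacommunity metrics are computed on the
matrix reordered by these scores. The axis is extracted by SVD of the
chi-square standardized residual matrix; the classical iterative reciprocal
averaging scheme is kept as an independent cross-check (the two must agree
up to sign and scale).

Empty rows are tolerated because the r1 null model can produce all-zero
sites: they get score 0 (the weighted mean of the centered axis) and sort
stably among ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .incidence import IncidenceMatrix

__all__ = [
    "OrdinationResult",
    "NoNontrivialAxisError",
    "reciprocal_averaging",
    "ra_scores_iterative",
    "order_matrix",
    "axis_depth_correlation",
]


class NoNontrivialAxisError(ValueError):
    """Matrix has no non-trivial CA axis (rank < 2, e.g. all cells equal)."""


@dataclass
class OrdinationResult:
    """First-axis CA scores plus the induced row/column orders."""

    site_scores: np.ndarray
    species_scores: np.ndarray
    eigenvalue: float
    row_order: np.ndarray
    col_order: np.ndarray

    def to_dict(
        self, site_ids: list[str], species_ids: list[str]
    ) -> dict:
        """JSON-ready representation with scores keyed by label."""
        return {
            "eigenvalue": self.eigenvalue,
            "site_scores": {s: float(v) for s, v in zip(site_ids, self.site_scores)},
            "species_scores": {
                s: float(v) for s, v in zip(species_ids, self.species_scores)
            },
        }

    def oriented(self, flip: bool) -> "OrdinationResult":
        if not flip:
            return self
        return OrdinationResult(
            site_scores=-self.site_scores,
            species_scores=-self.species_scores,
            eigenvalue=self.eigenvalue,
            row_order=_stable_order(-self.site_scores),
            col_order=_stable_order(-self.species_scores),
        )


def _stable_order(scores: np.ndarray) -> np.ndarray:
    """Ascending order with input-order tie-breaking."""
    return np.argsort(scores, kind="stable")


def _first_axis(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First non-trivial CA axis of a non-negative matrix with no empty
    rows/columns. Returns (row standard coords, col standard coords,
    eigenvalue = squared singular value)."""
    total = values.sum()
    p = values / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    # chi-square standardized residuals
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    if len(sv) < 1 or sv[0] < 1e-10:
        raise NoNontrivialAxisError("matrix has no non-trivial correspondence axis")
    row = u[:, 0] / np.sqrt(r)
    col = vt[0] / np.sqrt(c)
    return row, col, float(sv[0] ** 2)


def reciprocal_averaging(matrix: IncidenceMatrix) -> OrdinationResult:
    """First-axis RA/CA scores for sites and species.

    Empty rows score 0; empty columns are not allowed (drop them first).
    Sign convention: the first non-empty site's score is <= the last
    non-empty site's (callers with depth data re-orient via
    :func:`axis_depth_correlation`). Raises
    :class:`NoNontrivialAxisError` on rank-deficient input.
    """
    values = matrix.values.astype(float)
    col_tot = values.sum(axis=0)
    if (col_tot == 0).any():
        raise ValueError("all-zero species columns present; apply drop_empty first")
    row_tot = values.sum(axis=1)
    nonempty = row_tot > 0
    if nonempty.sum() < 2 or matrix.n_species < 2:
        raise NoNontrivialAxisError("need >= 2 non-empty sites and >= 2 species")

    row_sub, col_scores, eig = _first_axis(values[nonempty])
    site_scores = np.zeros(matrix.n_sites)
    site_scores[nonempty] = row_sub

    # deterministic orientation: first non-empty site <= last non-empty site
    ne_idx = np.flatnonzero(nonempty)
    if site_scores[ne_idx[0]] > site_scores[ne_idx[-1]]:
        site_scores = -site_scores
        col_scores = -col_scores

    return OrdinationResult(
        site_scores=site_scores,
        species_scores=col_scores,
        eigenvalue=eig,
        row_order=_stable_order(site_scores),
        col_order=_stable_order(col_scores),
    )


def ra_scores_iterative(
    matrix: IncidenceMatrix, tol: float = 1e-13, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical iterative reciprocal averaging, the cross-check route.

    Alternately sets species scores to the mean score of their sites and
    site scores to the mean score of their species, deflating the trivial
    axis by weighted centering and renormalizing each sweep. Returns
    (site scores, species scores, eigenvalue); scores match the SVD route
    up to sign and positive scale.
    """
    values = matrix.values.astype(float)
    row_tot = values.sum(axis=1)
    col_tot = values.sum(axis=0)
    if (col_tot == 0).any():
        raise ValueError("all-zero species columns present")
    nonempty = row_tot > 0
    v = values[nonempty]
    rt = v.sum(axis=1)
    total = v.sum()

    rng = np.random.default_rng(0)  # fixed start; result is start-independent
    x = rng.standard_normal(v.shape[0])
    eig = 0.0
    for _ in range(max_iter):
        y = (v.T @ x) / col_tot           # species = weighted mean of site scores
        x_new = (v @ y) / rt              # sites = weighted mean of species scores
        x_new = x_new - (rt @ x_new) / total  # deflate trivial (constant) axis
        norm = np.sqrt((rt * x_new**2).sum() / total)
        if norm < 1e-14:
            raise NoNontrivialAxisError("iteration collapsed: no non-trivial axis")
        x_new /= norm
        delta = min(np.abs(x_new - x).max(), np.abs(x_new + x).max())
        eig = norm
        x = x_new
        if delta < tol:
            break
    y = (v.T @ x) / col_tot
    site = np.zeros(matrix.n_sites)
    site[nonempty] = x
    return site, y, float(eig)


def order_matrix(matrix: IncidenceMatrix, ordination: OrdinationResult) -> IncidenceMatrix:
    """Permute rows and columns by ascending first-axis score (stable)."""
    ro, co = ordination.row_order, ordination.col_order
    return IncidenceMatrix(
        site_ids=[matrix.site_ids[i] for i in ro],
        species_ids=[matrix.species_ids[j] for j in co],
        values=matrix.values[np.ix_(ro, co)],
    )


def axis_depth_correlation(
    ordination: OrdinationResult, depths: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of first-axis site scores with water depth.

    CA axis orientation is arbitrary, so the axis is first oriented to make
    the correlation non-negative; the reported r is therefore |r| with its
    two-sided p. Returns (r, p, n).
    """
    depths = np.asarray(depths, dtype=float)
    scores = ordination.site_scores
    if len(depths) != len(scores):
        raise ValueError("one depth per scored site required")
    n = len(scores)
    if n < 3:
        raise ValueError("correlation undefined for fewer than 3 sites")
    r, p = stats.pearsonr(scores, depths)
    return abs(float(r)), float(p), n
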