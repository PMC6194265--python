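"""EMS metrics against brute-force oracles; classifier totality."""

import itertools

import numpy as np
import pytest

from benthems.ems import (
    ClumpingResult,
    MetricResult,
    NullConfig,
    base_label,
    boundary_clumping,
    classify,
    embedded_absences,
    fill_ranges,
    replacements,
    run_ems,
)
from benthems.incidence import IncidenceMatrix

from conftest import random_matrix


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementations)
# ---------------------------------------------------------------------------

def brute_embedded_absences(v: np.ndarray, rows: bool = True) -> int:
    total = 0
    axes = [v.T, v] if rows else [v.T]
    for mat in axes:  # mat rows = lines scanned (species cols first)
        for line in mat:
            idx = np.flatnonzero(line)
            if len(idx) == 0:
                continue
            total += sum(1 for k in range(idx[0], idx[-1] + 1) if line[k] == 0)
    return total


def brute_fill(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    for j in range(v.shape[1]):
        idx = np.flatnonzero(v[:, j])
        if len(idx):
            out[idx[0] : idx[-1] + 1, j] = 1
    return out


def brute_replacements(v: np.ndarray) -> int:
    f = brute_fill(v)
    s = f.shape[1]
    total = 0
    for i in range(s):
        for j in range(i + 1, s):
            a = int(((f[:, i] == 1) & (f[:, j] == 0)).sum())
            b = int(((f[:, j] == 1) & (f[:, i] == 0)).sum())
            total += a * b
    return total


def brute_morisita(v: np.ndarray) -> float:
    q = v.shape[0]
    tally = np.zeros(q, dtype=int)
    for j in range(v.shape[1]):
        idx = np.flatnonzero(v[:, j])
        if len(idx) == 0:
            continue
        tally[idx[0]] += 1
        tally[idx[-1]] += 1
    F = tally.sum()
    return q * sum(f * (f - 1) for f in tally) / (F * (F - 1))


def _mat(v: np.ndarray) -> IncidenceMatrix:
    return IncidenceMatrix(
        [f"s{i}" for i in range(v.shape[0])],
        [f"p{j}" for j in range(v.shape[1])],
        v,
    )


class TestEmbeddedAbsences:
    def test_contiguous_ranges_count_zero(self):
        v = np.array([[1, 0], [1, 1], [0, 1]])
        assert embedded_absences(_mat(v)) == 0

    def test_single_gappy_column(self):
        v = np.array([[1], [0], [1]])
        assert embedded_absences(_mat(v)) == 1

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            v = (rng.random((6, 8)) < 0.4).astype(np.int8)
            m = _mat(v)
            assert embedded_absences(m) == brute_embedded_absences(v)
            assert embedded_absences(m, rows=False) == brute_embedded_absences(v, rows=False)


class TestFillRanges:
    def test_fills_single_column(self):
        v = np.array([[1], [0], [1]])
        assert (fill_ranges(_mat(v)).values[:, 0] == [1, 1, 1]).all()

    def test_no_column_gaps_after_filling(self, rng):
        for _ in range(20):
            m = _mat((rng.random((7, 7)) < 0.35).astype(np.int8))
            assert embedded_absences(fill_ranges(m), rows=False) == 0

    def test_presence_conservation_identity(self, rng):
        """Presences after filling = before + column-embedded absences."""
        for _ in range(50):
            m = _mat((rng.random((6, 9)) < 0.3).astype(np.int8))
            gained = fill_ranges(m).total_presences() - m.total_presences()
            assert gained == embedded_absences(m, rows=False)


class TestReplacements:
    def test_perfectly_nested_is_zero(self):
        v = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [1, 0, 0]])
        assert replacements(_mat(v)) == 0

    def test_two_disjoint_blocks(self):
        v = np.zeros((5, 2), dtype=np.int8)
        v[:2, 0] = 1  # block of 2 sites
        v[2:, 1] = 1  # block of 3 sites
        assert replacements(_mat(v)) == 2 * 3

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            v = (rng.random((7, 7)) < 0.4).astype(np.int8)
            assert replacements(_mat(v)) == brute_replacements(v)


class TestBoundaryClumping:
    def test_one_boundary_per_site_gives_zero_index(self):
        # 3 species, 6 sites, each boundary at a distinct site
        v = np.zeros((6, 3), dtype=np.int8)
        v[0:2, 0] = 1
        v[2:4, 1] = 1
        v[4:6, 2] = 1
        res = boundary_clumping(_mat(v))
        assert res.morisita == 0.0

    def test_all_boundaries_at_one_site_gives_q(self):
        v = np.zeros((5, 4), dtype=np.int8)
        v[2, :] = 1  # every range is the single site 2
        res = boundary_clumping(_mat(v))
        assert res.morisita == pytest.approx(5.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            v = (rng.random((8, 8)) < 0.4).astype(np.int8)
            if v.any(axis=0).sum() < 2:
                continue
            assert boundary_clumping(_mat(v)).morisita == pytest.approx(brute_morisita(v))

    def test_df_follows_site_count_minus_offset(self, rng):
        m = random_matrix(rng, 9, 6)
        assert boundary_clumping(m).df == 6
        assert boundary_clumping(m, df_offset=1).df == 8

    def test_degenerate_boundaries_signal(self):
        v = np.zeros((4, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="boundaries"):
            boundary_clumping(_mat(v))


class TestClassify:
    @staticmethod
    def _metric(p: float, obs: float, mean: float) -> MetricResult:
        return MetricResult(obs, mean, 1.0, obs - mean, p)

    @staticmethod
    def _clump(p: float, morisita: float) -> ClumpingResult:
        return ClumpingResult(morisita, 0.0, 5, p)

    def test_non_significant_coherence_is_random(self):
        label = classify(
            self._metric(0.5, 10, 12), self._metric(0.001, 5, 1), self._clump(0.001, 2.0)
        )
        assert label == "Random"

    def test_checkerboard_from_excess_absences(self):
        label = classify(
            self._metric(0.001, 20, 12), self._metric(0.5, 5, 5), self._clump(0.5, 1.0)
        )
        assert label == "Checkerboard"

    def test_clementsian_cell(self):
        label = classify(
            self._metric(1e-4, 5, 12), self._metric(1e-4, 30, 20), self._clump(1e-4, 2.0)
        )
        assert label == "Clementsian"

    def test_totality_and_determinism_over_metric_space(self):
        """Every combination of significance/direction for the three metrics
        maps to exactly one label from the closed vocabulary."""
        vocabulary = {
            "Random", "Checkerboard", "Clementsian", "Gleasonian", "EvenlySpaced",
            "Nested", "Quasi-Nested", "Quasi-Clementsian", "Quasi-Gleasonian",
            "Quasi-EvenlySpaced",
        }
        subtypes = {"clumped boundaries", "random boundaries", "hyperdispersed boundaries"}
        seen = set()
        for coh_p, coh_side in itertools.product([0.001, 0.5], [-1, 1]):
            for tur_p, tur_side in itertools.product([0.001, 0.5], [-1, 1]):
                for cl_p, cl_i in itertools.product([0.001, 0.5], [0.4, 1.0, 2.5]):
                    label = classify(
                        self._metric(coh_p, 10 + coh_side, 10),
                        self._metric(tur_p, 10 + tur_side, 10),
                        self._clump(cl_p, cl_i),
                    )
                    assert isinstance(label, str) and label
                    assert base_label(label) in vocabulary
                    if "(" in label:
                        assert label.split("(")[1].rstrip(")") in subtypes
                    seen.add(base_label(label))
        # the tree actually reaches all structure families
        assert vocabulary <= seen


class TestMetricResult:
    def test_observed_at_null_mean_gives_z_zero_p_one(self):
        res = MetricResult.from_null(5.0, np.array([4.0, 5.0, 6.0]))
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_three_sd_deviation_p(self):
        nulls = np.array([9.0, 10.0, 11.0, 10.0, 9.0, 11.0, 10.0, 10.0])
        sd = nulls.std(ddof=1)
        res = MetricResult.from_null(10.0 - 3 * sd, nulls)
        assert res.p == pytest.approx(0.0026998, abs=1e-4)

    def test_zero_variance_nulls_flagged_degenerate(self):
        res = MetricResult.from_null(3.0, np.array([3.0, 3.0, 3.0]))
        assert res.degenerate and res.p == 1.0
        res2 = MetricResult.from_null(4.0, np.array([3.0, 3.0, 3.0]))
        assert res2.degenerate and res2.p == 0.0


class TestMetricSignificance:
    def test_observed_value_matches_direct_metric(self, rng):
        from benthems.ems import metric_significance
        from benthems.ordination import order_matrix, reciprocal_averaging

        m = random_matrix(rng, 9, 12)
        ordered = order_matrix(m, reciprocal_averaging(m))
        res = metric_significance(m, "coherence", NullConfig(n_sim=30, seed=5))
        assert res.observed == embedded_absences(ordered)
        assert 0 <= res.p <= 1
        res_t = metric_significance(m, "turnover", NullConfig(n_sim=30, seed=5))
        assert res_t.observed == replacements(ordered)

    def test_unknown_metric_rejected(self, rng):
        from benthems.ems import metric_significance

        with pytest.raises(ValueError, match="unknown metric"):
            metric_significance(random_matrix(rng, 5, 6), "nestedness", NullConfig(n_sim=5))


class TestRunEms:
    def test_deterministic_given_seed(self, rng):
        m = random_matrix(rng, 10, 14)
        a = run_ems(m, NullConfig(n_sim=50, seed=42))
        b = run_ems(m, NullConfig(n_sim=50, seed=42))
        assert a.label == b.label
        assert a.coherence.null_mean == b.coherence.null_mean
        assert a.turnover.null_sd == b.turnover.null_sd
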