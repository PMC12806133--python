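"""Unit and property tests for the nearest-centroid bias classifier."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadbias import (
    CATEGORIES,
    DEFAULT_CENTROIDS,
    NOT_EXPRESSED,
    SimplexPoint,
    assign_all,
    category_proportions,
    classify_triad,
    normalize_triad,
    summarize_group,
    ternary_coordinates,
)
from triadbias.bias import CATEGORIES, proportions_table

# independent oracle: plain loop over the seven centroid distances,
# accumulating components in the same order as the implementation
def brute_force_classify(a, b, d):
    best_name, best_dist = None, None
    for name in CATEGORIES:
        c = DEFAULT_CENTROIDS[name]
        dist = math.sqrt(
            (a - c.frac_A) ** 2 + (b - c.frac_B) ** 2 + (d - c.frac_D) ** 2
        )
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    return best_name, best_dist


def simplex_grid(n):
    """All (i/n, j/n, k/n) with i+j+k = n."""
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return pts


simplex_points = st.tuples(
    st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
).filter(lambda t: sum(t) > 1e-6).map(
    lambda t: SimplexPoint(*(x / sum(t) for x in t))
)


class TestNormalizeTriad:
    @pytest.mark.parametrize(
        "abd,expected",
        [
            ((10, 20, 70), (0.1, 0.2, 0.7)),
            ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            ((5, 0, 0), (1.0, 0.0, 0.0)),
        ],
    )
    def test_unit_sum_fractions(self, abd, expected):
        p = normalize_triad(*abd, min_total=0.5)
        assert p is not None
        assert np.allclose(p.as_array(), expected)
        assert abs(sum(p.as_array()) - 1.0) <= 1e-9

    def test_below_floor_is_not_expressed(self):
        assert normalize_triad(0, 0, 0, min_total=0.5) is None
        assert normalize_triad(0.1, 0.1, 0.1, min_total=0.5) is None

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (float("nan"), 1, 1), (float("inf"), 0, 0)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_triad(*bad)

    @given(
        st.tuples(st.floats(0.01, 1e6), st.floats(0.0, 1e6), st.floats(0.0, 1e6)),
        st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, abd, k):
        """Multiplying all three TPM values by k>0 leaves the category fixed."""
        a, b, d = abd
        p1 = normalize_triad(a, b, d, min_total=0.0)
        p2 = normalize_triad(k * a, k * b, k * d, min_total=0.0)
        assert classify_triad(p1)[0] == classify_triad(p2)[0]


class TestClassifyTriad:
    @pytest.mark.parametrize(
        "point,category,distance",
        [
            ((1 / 3, 1 / 3, 1 / 3), "balanced", 0.0),
            ((0.6, 0.2, 0.2), "balanced", 0.3265986323710904),
            ((0.8, 0.1, 0.1), "A.dominant", 0.24494897427831777),
        ],
    )
    def test_worked_examples(self, point, category, distance):
        cat, dist = classify_triad(SimplexPoint(*point))
        assert cat == category
        assert dist == pytest.approx(distance, abs=1e-12)

    def test_centroid_fixed_points(self):
        for name, c in DEFAULT_CENTROIDS.items():
            cat, dist = classify_triad(c)
            assert cat == name
            assert dist == 0.0

    def test_oracle_equivalence_on_grid(self):
        """Implementation agrees with the brute-force loop over ≥10,000 points."""
        pts = simplex_grid(140)
        assert len(pts) >= 10_000
        for a, b, d in pts:
            cat, dist = classify_triad(SimplexPoint(a, b, d))
            ocat, odist = brute_force_classify(a, b, d)
            assert cat == ocat, (a, b, d)
            assert dist == pytest.approx(odist, abs=1e-12)

    @given(simplex_points)
    @settings(derandomize=True, max_examples=200)
    def test_permutation_equivariance(self, p):
        """Permuting subgenome inputs permutes the assigned label accordingly."""
        def permute_label(cat, perm):
            if cat == "balanced":
                return cat
            sub, kind = cat.split(".")
            mapping = dict(zip("ABD", perm))
            return f"{mapping[sub]}.{kind}"

        base, _ = classify_triad(p)
        comps = {"A": p.frac_A, "B": p.frac_B, "D": p.frac_D}
        for perm in itertools.permutations("ABD"):
            # the gene that was subgenome X now plays the role perm[X]
            new = {dst: comps[src] for src, dst in zip("ABD", perm)}
            q = SimplexPoint(new["A"], new["B"], new["D"])
            got, _ = classify_triad(q)
            expected = permute_label(base, perm)
            # skip exact-tie boundary points, where the winner is order-dependent
            dists = sorted(
                math.dist(q.as_array(), c.as_array()) for c in DEFAULT_CENTROIDS.values()
            )
            if dists[1] - dists[0] < 1e-9:
                continue
            assert got == expected

    def test_invalid_point_rejected(self):
        with pytest.raises(ValueError):
            SimplexPoint(0.9, 0.9, 0.9)


class TestAssignAll:
    def test_groups_and_categories(self, small_matrix, small_triads):
        asg = assign_all(small_matrix, small_triads)
        by = {(a.triad_id, a.group): a for a in asg}
        assert len(by) == 6
        assert by[("t1", "G1")].category == "balanced"
        assert by[("t2", "G1")].category == "A.dominant"
        assert by[("t2", "G2")].category == "A.suppressed"
        assert by[("t3", "G2")].category == NOT_EXPRESSED
        assert math.isnan(by[("t3", "G2")].distance)

    def test_missing_gene_treated_as_zero(self, small_matrix, small_triads, caplog):
        matrix = small_matrix
        matrix.values = matrix.values.drop(index="t2_A")
        with caplog.at_level("WARNING"):
            asg = assign_all(matrix, small_triads)
        assert "t2_A" in caplog.text
        by = {(a.triad_id, a.group): a for a in asg}
        # (0, 10, 10) → A.suppressed in G1
        assert by[("t2", "G1")].category == "A.suppressed"

    def test_empty_triads_rejected(self, small_matrix):
        from triadbias import TriadSet

        with pytest.raises(ValueError):
            assign_all(small_matrix, TriadSet([]))


class TestSummaries:
    def test_replicate_mean(self, small_matrix):
        means = summarize_group(small_matrix, "G1")
        assert means["t1_A"] == 10
        with pytest.raises(KeyError):
            summarize_group(small_matrix, "nope")

    def test_category_proportions(self, small_matrix, small_triads):
        asg = assign_all(small_matrix, small_triads)
        props = category_proportions(asg, "G2")
        # G2: t1 balanced, t2 A.suppressed, t3 not expressed
        assert props["balanced"] == pytest.approx(0.5)
        assert props["A.suppressed"] == pytest.approx(0.5)
        assert abs(sum(props.values()) - 1.0) <= 1e-9
        table = proportions_table(asg)
        assert table.at["G2", "n_not_expressed"] == 1
        assert table.at["G2", "n_expressed"] == 2

    def test_proportions_need_expressed_triads(self, small_matrix, small_triads):
        asg = assign_all(small_matrix, small_triads)
        with pytest.raises(ValueError):
            category_proportions(asg, "absent_group")


class TestTernaryCoordinates:
    @pytest.mark.parametrize(
        "point,xy",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, math.sqrt(3) / 2)),
            ((1 / 3, 1 / 3, 1 / 3), (0.5, math.sqrt(3) / 6)),
        ],
    )
    def test_vertices_and_center(self, point, xy):
        assert ternary_coordinates(SimplexPoint(*point)) == pytest.approx(xy)
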