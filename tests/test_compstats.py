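"""Derived ceramide variables, clr transform, additive ANOVA, Newman-Keuls
letters, ternary coordinates and confidence ellipses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from gangliomics import compstats
from gangliomics.compstats import (DERIVED_VARIABLES, anova_additive,
                                   clr_transform, clr_response,
                                   confidence_ellipse, derive_variables,
                                   mean_in_ellipse, newman_keuls,
                                   ternary_coordinates, ternary_parts)
from gangliomics.core import DEFAULT_CERAMIDE_PANEL, StructureError

PANEL = [c.label for c in DEFAULT_CERAMIDE_PANEL]


class TestDeriveVariables:
    def test_simple_sums(self):
        v = derive_variables({"36:1": 0.6, "38:1": 0.3, "34:1": 0.1})
        assert v["36:1+38:1"] == pytest.approx(0.9)
        assert v["34:1"] == pytest.approx(0.1)
        assert v["40:1+42:2+42:1"] == 0.0
        assert v["<=34C"] == pytest.approx(0.1)
        assert v[">=42C"] == 0.0
        assert v["1-unsaturation"] == pytest.approx(1.0)

    def test_point_mass_on_42_2(self):
        v = derive_variables({"42:2": 1.0})
        assert v["40:1+42:2+42:1"] == 1.0
        assert v["2-unsaturations"] == 1.0
        assert v[">=42C"] == 1.0
        assert v["36:1+38:1"] == 0.0

    def test_exactly_seven_variables(self):
        comp = {s: 1.0 / len(PANEL) for s in PANEL}
        assert len(derive_variables(comp)) == 7
        assert tuple(derive_variables(comp)) == DERIVED_VARIABLES

    def test_unparseable_label_rejected(self):
        with pytest.raises(StructureError, match="others"):
            derive_variables({"36:1": 0.9, "others": 0.1})

    @given(st.lists(st.floats(0.0, 1.0), min_size=19, max_size=19))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_filter_sums(self, raw):
        """The seven sums equal an independent filter-and-sum oracle on
        random closed compositions over the 19-species panel."""
        total = sum(raw) or 1.0
        comp = {s: x / total for s, x in zip(PANEL, raw)}
        v = derive_variables(comp)

        def carbons(s):
            return int(s.split(":")[0])

        def dbs(s):
            return int(s.split(":")[1])

        assert v["36:1+38:1"] == pytest.approx(comp["36:1"] + comp["38:1"])
        assert v["34:1"] == pytest.approx(comp["34:1"])
        assert v["40:1+42:2+42:1"] == pytest.approx(
            comp["40:1"] + comp["42:2"] + comp["42:1"])
        assert v["1-unsaturation"] == pytest.approx(
            sum(p for s, p in comp.items() if dbs(s) == 1))
        assert v["2-unsaturations"] == pytest.approx(
            sum(p for s, p in comp.items() if dbs(s) == 2))
        assert v["<=34C"] == pytest.approx(
            sum(p for s, p in comp.items() if carbons(s) <= 34))
        assert v[">=42C"] == pytest.approx(
            sum(p for s, p in comp.items() if carbons(s) >= 42))


class TestClr:
    def test_midpoint_maps_to_zero(self):
        assert clr_transform(0.5).coords == pytest.approx((0.0, 0.0))

    def test_zero_sum_over_grid(self):
        for v in np.linspace(0.001, 0.999, 97):
            c = clr_transform(float(v)).coords
            assert c[0] + c[1] == pytest.approx(0.0, abs=1e-9)

    def test_first_coordinate_is_half_logit(self):
        for v in np.linspace(0.01, 0.99, 23):
            c = clr_transform(float(v))
            assert c.response == pytest.approx(0.5 * math.log(v / (1 - v)),
                                               abs=1e-9)

    def test_boundary_needs_delta_and_flags(self):
        with pytest.raises(ValueError):
            clr_transform(0.0)
        c = clr_transform(0.0, delta=0.01)
        assert c.zero_replaced
        assert c.parts[0] == pytest.approx(0.01)
        c1 = clr_transform(1.0, delta=0.01)
        assert c1.parts == pytest.approx((0.99, 0.01))

    def test_default_delta_is_half_min_nonzero(self):
        values = [0.0, 0.2, 0.5, 0.004]
        resp = clr_response(values)
        # delta = 0.5 * 0.004 = 0.002
        assert resp[0] == pytest.approx(0.5 * math.log(0.002 / 0.998))

    def test_default_delta_capped_for_degenerate_variables(self):
        # all-or-nothing variable: delta must stay a small perturbation
        assert compstats.default_delta([0.0, 1.0, 1.0]) == pytest.approx(0.01)


def _make_anova_frame(rng, n_by_tissue, shift_by_tissue, subject_sd=0.5,
                      noise_sd=0.5):
    rows = []
    n_subjects = max(n_by_tissue.values())
    subject_effects = rng.normal(0, subject_sd, size=n_subjects)
    for tissue, n in n_by_tissue.items():
        for i in range(n):
            rows.append({
                "response": shift_by_tissue[tissue] + subject_effects[i]
                + rng.normal(0, noise_sd),
                "tissue": tissue,
                "subject": f"D{i + 1}",
            })
    return pd.DataFrame(rows)


class TestAnovaAdditive:
    def test_degenerate_constant_response(self):
        df = pd.DataFrame({"response": [1.0] * 6,
                           "tissue": ["a", "a", "a", "b", "b", "b"],
                           "subject": ["s1", "s2", "s3"] * 2})
        res = anova_additive(df)
        assert res.degenerate
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_anova_lm_type2(self):
        """Dual route: the model-comparison Type II table equals
        statsmodels' anova_lm(typ=2) on an unbalanced design."""
        rng = np.random.default_rng(5)
        df = _make_anova_frame(rng, {"retina": 7, "brain": 7, "plasma": 4},
                               {"retina": 1.0, "brain": 0.0, "plasma": -0.5})
        res = anova_additive(df)
        fitted = smf.ols("response ~ C(tissue) + C(subject)", data=df).fit()
        ref = sm.stats.anova_lm(fitted, typ=2)
        assert res.table.loc["tissue", "sum_sq"] == pytest.approx(
            ref.loc["C(tissue)", "sum_sq"])
        assert res.table.loc["subject", "sum_sq"] == pytest.approx(
            ref.loc["C(subject)", "sum_sq"])
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(
            ref.loc["Residual", "sum_sq"])
        assert res.table.loc["tissue", "PR(>F)"] == pytest.approx(
            ref.loc["C(tissue)", "PR(>F)"])

    def test_balanced_type2_equals_sequential(self):
        rng = np.random.default_rng(8)
        df = _make_anova_frame(rng, {"a": 5, "b": 5, "c": 5},
                               {"a": 0.0, "b": 0.3, "c": 0.9})
        res = anova_additive(df)
        fitted = smf.ols("response ~ C(tissue) + C(subject)", data=df).fit()
        seq = sm.stats.anova_lm(fitted, typ=1)
        assert res.table.loc["tissue", "sum_sq"] == pytest.approx(
            seq.loc["C(tissue)", "sum_sq"])
        assert res.table.loc["subject", "sum_sq"] == pytest.approx(
            seq.loc["C(subject)", "sum_sq"])

    def test_power_with_two_sigma_shift(self):
        """A 2-sigma tissue shift at the study's group sizes is detected at
        alpha = 0.05 in well over 90% of seeded replicates."""
        sizes = {"retina": 7, "brain": 7, "rpe": 7, "nerve": 6,
                 "ciliary": 4, "plasma": 4}
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            shifts = {t: 0.0 for t in sizes}
            shifts["retina"] = 2.0  # 2 x residual sd (sd = 1 below)
            df = _make_anova_frame(rng, sizes, shifts, subject_sd=0.5,
                                   noise_sd=1.0)
            res = anova_additive(df)
            if res.table.loc["tissue", "PR(>F)"] < 0.05:
                hits += 1
        assert hits / n_rep > 0.90

    def test_single_observation_tissue_warns(self, caplog):
        df = pd.DataFrame({"response": [1.0, 2.0, 3.0, 2.5, 0.5],
                           "tissue": ["a", "a", "a", "a", "b"],
                           "subject": ["s1", "s2", "s3", "s4", "s1"]})
        with caplog.at_level("WARNING"):
            anova_additive(df)
        assert "single observation" in caplog.text


from functools import lru_cache


@lru_cache(maxsize=None)
def _oracle_qcrit(alpha, r, df):
    # cache only the expensive scipy quantile; the oracle logic stays below
    return stats.studentized_range.ppf(1 - alpha, r, df)


def snk_oracle(means, ms, df, sizes, alpha=0.05):
    """Independent Newman-Keuls implementation: recursive range testing,
    then letters from the non-significant pair relation."""
    names = sorted(means, key=lambda t: -means[t])
    k = len(names)
    sig = {}

    def test_range(i, j):
        # returns True if (i, j) significant under stepwise protection
        r = j - i + 1
        nh = 2.0 / (1.0 / sizes[names[i]] + 1.0 / sizes[names[j]])
        q = (means[names[i]] - means[names[j]]) / math.sqrt(ms / nh)
        return q > _oracle_qcrit(alpha, r, df)

    # mark non-significant stretches top-down
    ns = set()
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            if any(a <= i and j <= b for a, b in ns):
                continue
            if not test_range(i, j):
                ns.add((i, j))
    maximal = [iv for iv in ns
               if not any(a <= iv[0] and iv[1] <= b and iv != (a, b)
                          for a, b in ns)]
    covered = {x for a, b in maximal for x in range(a, b + 1)}
    maximal += [(i, i) for i in range(k) if i not in covered]
    maximal.sort()
    out = {t: "" for t in names}
    for idx, (a, b) in enumerate(maximal):
        for i in range(a, b + 1):
            out[names[i]] += chr(ord("a") + idx)
    return out


class TestNewmanKeuls:
    def test_two_far_groups(self):
        letters = newman_keuls({"a_t": 10.0, "b_t": 0.0}, residual_ms=1.0,
                               residual_df=10, group_sizes={"a_t": 5, "b_t": 5})
        assert letters == {"a_t": "a", "b_t": "b"}

    def test_identical_means_share_a(self):
        letters = newman_keuls({"x": 1.0, "y": 1.0, "z": 1.0}, residual_ms=1.0,
                               residual_df=12, group_sizes={"x": 4, "y": 4, "z": 4})
        assert set(letters.values()) == {"a"}

    def test_a_attached_to_highest_mean(self):
        letters = newman_keuls({"low": 0.0, "high": 50.0}, residual_ms=1.0,
                               residual_df=8, group_sizes={"low": 4, "high": 4})
        assert letters["high"] == "a"

    def test_three_clusters_against_oracle(self):
        means = {"t1": 10.0, "t2": 9.8, "t3": 5.0, "t4": 4.9, "t5": 0.1, "t6": 0.0}
        sizes = {t: 6 for t in means}
        letters = newman_keuls(means, residual_ms=0.5, residual_df=25,
                               group_sizes=sizes)
        assert letters == {"t1": "a", "t2": "a", "t3": "b", "t4": "b",
                           "t5": "c", "t6": "c"}
        assert letters == snk_oracle(means, 0.5, 25, sizes)

    def test_matches_oracle_on_random_configurations(self):
        """Letter displays equal an independent SNK implementation on many
        random mean/MS/n configurations, and are transitively consistent."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            k = rng.integers(2, 7)
            means = {f"t{i}": float(rng.normal(0, 2)) for i in range(k)}
            ms = float(rng.uniform(0.1, 3.0))
            sizes = {t: int(rng.integers(3, 9)) for t in means}
            df = float(rng.integers(5, 40))
            got = newman_keuls(means, ms, df, sizes)
            assert got == snk_oracle(means, ms, df, sizes)
            # transitive consistency: sharing a letter implies both sit in a
            # common non-significant stretch, so each tissue has >= 1 letter
            assert all(got.values())

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            newman_keuls({"a_t": 1.0, "b_t": 0.0}, 1.0, 0, {"a_t": 3, "b_t": 3})


class TestTernary:
    def test_vertices(self):
        assert ternary_coordinates([1, 0, 0]).xy == pytest.approx((0.0, 0.0))
        assert ternary_coordinates([0, 1, 0]).xy == pytest.approx((1.0, 0.0))
        assert ternary_coordinates([0, 0, 1]).xy == pytest.approx(
            (0.5, math.sqrt(3) / 2))

    def test_centroid(self):
        assert ternary_coordinates([1 / 3] * 3).xy == pytest.approx(
            (0.5, math.sqrt(3) / 6))

    def test_closure_invariance(self):
        assert ternary_coordinates([2, 2, 2]).xy == pytest.approx(
            ternary_coordinates([1 / 3] * 3).xy)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ternary_coordinates([0, 0, 0])

    def test_scheme_parts_close_to_one(self):
        comp = {s: 1.0 / len(PANEL) for s in PANEL}
        for scheme in ("chain_groups", "unsaturation", "chain_length"):
            parts = ternary_parts(comp, scheme)
            assert sum(parts) == pytest.approx(1.0, abs=1e-9)


def _logistic_normal_cluster(rng, mean_ilr, cov, n):
    z = rng.multivariate_normal(mean_ilr, cov, size=n)
    return compstats._ilr_inverse(z)


class TestConfidenceEllipse:
    def test_identical_points_collapse(self):
        pts = [[0.5, 0.3, 0.2]] * 5
        ell = confidence_ellipse(pts)
        assert ell.degenerate
        assert np.allclose(ell.polyline, ell.polyline[0])

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        pts = _logistic_normal_cluster(rng, [0.3, -0.2],
                                       np.diag([0.05, 0.08]), 40)
        e1 = confidence_ellipse(pts)
        perm = rng.permutation(len(pts))
        e2 = confidence_ellipse(pts[perm])
        assert np.allclose(e1.polyline, e2.polyline)

    def test_polyline_inside_triangle(self):
        rng = np.random.default_rng(4)
        pts = _logistic_normal_cluster(rng, [0.0, 0.0], np.eye(2) * 0.2, 30)
        ell = confidence_ellipse(pts)
        x, y = ell.polyline[:, 0], ell.polyline[:, 1]
        assert (y >= -1e-9).all()
        assert (y <= math.sqrt(3) * np.minimum(x, 1 - x) + 1e-9).all()

    def test_coverage_on_logistic_normal_clusters(self):
        """95% mean-confidence ellipses cover the generating mean in 90-99%
        of 200 seeded replicates (500 draws each)."""
        mean_ilr = np.array([0.4, -0.3])
        cov = np.array([[0.06, 0.01], [0.01, 0.04]])
        target = compstats._ilr_inverse(mean_ilr[None, :])[0]
        covered = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            pts = _logistic_normal_cluster(rng, mean_ilr, cov, 500)
            if mean_in_ellipse(pts, target, level=0.95):
                covered += 1
        assert 0.90 <= covered / n_rep <= 0.99
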