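"""Core EAF estimator: WADs, molecular-weight chain, filter, bootstrap."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qsipgrowth import qsip

# Frozen constants from an independent Decimal-arithmetic evaluation of the
# published estimator chain at w_light = 1.70, w_lab = 1.706.
GC_AT_170 = 0.6459775345484157
M_LIGHT_AT_170 = 308.0114048571360
M_LAB_AT_170 = 309.0985039331024
EAF_170_1706 = 0.08983043728934339
EAF_HALF_SPAN = 0.4989997855  # m_lab - m_light = 6.038735 (half the 18O span)


class TestTaxonCopies:
    @pytest.mark.parametrize("reads,total,copies,expected", [
        (50, 100, 2e6, 1e6),
        (0, 100, 2e6, 0.0),
        (10, 40, 8e5, 2e5),  # hand-computed proportion oracle
    ])
    def test_proportionality(self, reads, total, copies, expected):
        assert qsip.taxon_copies_per_fraction(reads, total, copies) == pytest.approx(expected)

    def test_nonzero_reads_with_zero_total_is_invariant_error(self):
        with pytest.raises(ValueError):
            qsip.taxon_copies_per_fraction(5, 0, 1e6)


class TestWeightedAverageDensity:
    def test_equal_copies_give_midpoint(self):
        assert qsip.weighted_average_density(
            [1.70, 1.71, 1.72], [3, 3, 3]) == pytest.approx(1.71)

    def test_single_occupied_fraction(self):
        assert qsip.weighted_average_density(
            [1.68, 1.72, 1.74], [0, 5, 0]) == pytest.approx(1.72)

    def test_hand_computed_weighted_mean(self):
        assert qsip.weighted_average_density(
            [1.68, 1.70, 1.73], [2, 5, 3]) == pytest.approx(1.7050, abs=1e-12)

    def test_absent_taxon_is_nan(self):
        assert np.isnan(qsip.weighted_average_density([1.7, 1.71], [0, 0]))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.floats(1.6, 1.8),
                              st.floats(0, 1e9, allow_subnormal=False)),
                    min_size=1, max_size=30))
    def test_matches_brute_force_oracle(self, pairs):
        d = [p[0] for p in pairs]
        w = [p[1] for p in pairs]
        total = sum(w)
        got = qsip.weighted_average_density(d, w)
        if total <= 0:
            assert np.isnan(got)
        else:
            expected = sum(x * y for x, y in pairs) / total
            assert got == pytest.approx(expected, rel=1e-12)
            assert min(d) - 1e-12 <= got <= max(d) + 1e-12


class TestMolecularWeightChain:
    def test_no_shift_means_no_weight_change(self):
        mw = qsip.molecular_weights_from_wad(1.70, 1.70)
        assert mw.m_lab == pytest.approx(mw.m_light, rel=1e-15)

    def test_calibration_intercept(self):
        mw = qsip.molecular_weights_from_wad(1.646057, 1.646057)
        assert mw.gc == pytest.approx(0.0, abs=1e-12)
        assert mw.m_light == pytest.approx(307.691, abs=1e-9)

    def test_frozen_formula_oracle(self):
        mw = qsip.molecular_weights_from_wad(1.70, 1.706)
        assert mw.gc == pytest.approx(GC_AT_170, rel=1e-12)
        assert mw.m_light == pytest.approx(M_LIGHT_AT_170, rel=1e-12)
        assert mw.m_lab == pytest.approx(M_LAB_AT_170, rel=1e-12)
        assert mw.m_heavy_max == pytest.approx(M_LIGHT_AT_170 + 12.07747, rel=1e-12)

    def test_gc_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="qsipgrowth"):
            mw = qsip.molecular_weights_from_wad(1.60, 1.61)
        assert mw.gc == 0.0
        assert any("clamping" in r.message for r in caplog.records)


class TestExcessAtomFraction:
    def test_zero_shift_is_exactly_zero(self):
        mw = qsip.MolecularWeights(gc=0.5, m_light=308.0, m_lab=308.0,
                                   m_heavy_max=320.07747)
        assert qsip.excess_atom_fraction(mw) == 0.0

    def test_full_labeling_bound(self):
        mw = qsip.MolecularWeights(gc=0.5, m_light=308.0,
                                   m_lab=308.0 + 12.07747,
                                   m_heavy_max=308.0 + 12.07747)
        assert qsip.excess_atom_fraction(mw) == pytest.approx(
            1 - 0.002000429, rel=1e-12)

    def test_half_span_oracle(self):
        mw = qsip.MolecularWeights(gc=0.5, m_light=308.0,
                                   m_lab=308.0 + 6.038735,
                                   m_heavy_max=308.0 + 12.07747)
        assert qsip.excess_atom_fraction(mw) == pytest.approx(
            EAF_HALF_SPAN, rel=1e-9)

    def test_vectorized_chain_matches_scalar(self):
        got = qsip.eaf_from_wads(1.70, 1.706)
        assert got == pytest.approx(EAF_170_1706, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1.68, 1.74), st.floats(1.68, 1.74), st.floats(1e-5, 0.02))
    def test_monotone_in_labeled_wad(self, w_light, w_lab, dw):
        lo = qsip.eaf_from_wads(w_light, w_lab)
        hi = qsip.eaf_from_wads(w_light, w_lab + dw)
        assert hi > lo


def _brute_force_filter(features, tubes, criteria):
    """Exhaustive evaluation of the presence criteria (independent oracle)."""
    passed = {}
    for (site, treat), gtubes in tubes.groupby(["site", "temperature_treatment"]):
        ids = set(gtubes["tube_id"])
        taxa = set(features.loc[features["tube_id"].isin(ids) &
                                (features["read_count"] > 0), "taxon_id"])
        ok = set()
        for taxon in taxa:
            good = True
            for iso in ("light", "heavy"):
                iso_tubes = gtubes.loc[gtubes["isotope_treatment"] == iso,
                                       "tube_id"]
                n_rep = 0
                for t in iso_tubes:
                    sub = features[(features["taxon_id"] == taxon)
                                   & (features["tube_id"] == t)
                                   & (features["read_count"] > 0)]
                    if sub["fraction_index"].nunique() >= criteria.min_fractions:
                        n_rep += 1
                if n_rep < criteria.min_replicates:
                    good = False
            if good:
                ok.add(taxon)
        passed[(site, treat)] = ok
    return passed


def _toy_tubes():
    rows = []
    for iso in ("light", "heavy"):
        for rep in (1, 2, 3):
            rows.append({"tube_id": f"{iso}{rep}", "site": "early",
                         "temperature_treatment": "control",
                         "isotope_treatment": iso,
                         "replicate_plot": f"p{rep}"})
    return pd.DataFrame(rows)


class TestFilterTaxa:
    def _features(self, spec):
        rows = [{"taxon_id": tax, "tube_id": tube, "fraction_index": f,
                 "read_count": 1} for tax, tube, fracs in spec for f in fracs]
        return pd.DataFrame(rows)

    def test_four_fractions_two_reps_both_isotopes_passes(self):
        feats = self._features([
            ("a", "light1", range(1, 5)), ("a", "light2", range(1, 5)),
            ("a", "heavy1", range(1, 5)), ("a", "heavy2", range(1, 5))])
        got = qsip.filter_taxa(feats, _toy_tubes())
        assert got[("early", "control")] == {"a"}

    def test_three_fractions_in_one_required_tube_fails(self):
        feats = self._features([
            ("a", "light1", range(1, 5)), ("a", "light2", range(1, 4)),
            ("a", "heavy1", range(1, 5)), ("a", "heavy2", range(1, 5))])
        got = qsip.filter_taxa(feats, _toy_tubes())
        assert got[("early", "control")] == set()

    def test_missing_isotope_arm_is_config_error(self):
        tubes = _toy_tubes()
        tubes = tubes[tubes["isotope_treatment"] == "light"]
        feats = self._features([("a", "light1", range(1, 5))])
        with pytest.raises(ValueError, match="heavy"):
            qsip.filter_taxa(feats, tubes)

    def test_randomized_tables_match_brute_force(self):
        rng = np.random.default_rng(123)
        tubes = _toy_tubes()
        crit = qsip.FilterCriteria(min_fractions=3, min_replicates=2)
        for _ in range(50):
            n = rng.integers(1, 60)
            feats = pd.DataFrame({
                "taxon_id": rng.choice(list("abcdefgh"), n),
                "tube_id": rng.choice(tubes["tube_id"], n),
                "fraction_index": rng.integers(1, 8, n),
                "read_count": rng.integers(0, 3, n),
            }).drop_duplicates(["taxon_id", "tube_id", "fraction_index"])
            assert (qsip.filter_taxa(feats, tubes, crit)
                    == _brute_force_filter(feats, tubes, crit))


class TestBootstrapEAF:
    def test_degenerate_resampling_gives_point_ci(self):
        # zero between-tube variance: CI collapses onto the point estimate
        light = np.full(5, 1.70)
        target = 0.1
        m_light = qsip.MW_GC_SLOPE * ((1.70 - qsip.GC_DENSITY_INTERCEPT)
                                      / qsip.GC_DENSITY_SLOPE) + qsip.MW_INTERCEPT
        # invert the estimator chain to place the heavy WAD at EAF = 0.1
        heavy = np.full(5, 1.70 * (m_light + target
                        / (1 - qsip.NATURAL_18O_ABUNDANCE) * 12.07747) / m_light)
        est = qsip.bootstrap_eaf("a", "early", "control", light, heavy,
                                 n_boot=200, seed=0)
        assert est.ci_low == pytest.approx(target, rel=1e-12)
        assert est.ci_high == pytest.approx(target, rel=1e-12)
        assert est.eaf_median == pytest.approx(target, rel=1e-12)
        assert est.significant

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        light = 1.70 + rng.normal(0, 0.002, 5)
        heavy = 1.71 + rng.normal(0, 0.002, 5)
        a = qsip.bootstrap_eaf("a", "early", "control", light, heavy,
                               n_boot=500, seed=99)
        b = qsip.bootstrap_eaf("a", "early", "control", light, heavy,
                               n_boot=500, seed=99)
        assert np.array_equal(a.draws, b.draws)
        assert (a.eaf_median, a.ci_low, a.ci_high) == (b.eaf_median, b.ci_low,
                                                       b.ci_high)

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(2)
        light = 1.70 + rng.normal(0, 0.003, 5)
        heavy = 1.705 + rng.normal(0, 0.003, 5)
        est = qsip.bootstrap_eaf("a", "early", "control", light, heavy,
                                 n_boot=1000, seed=3)
        assert est.ci_low <= est.eaf_median <= est.ci_high

    def test_empty_arm_raises(self):
        with pytest.raises(ValueError, match="isotope"):
            qsip.bootstrap_eaf("a", "early", "control", [np.nan], [1.71])

    def test_significance_requires_ci_above_zero(self):
        light = np.full(4, 1.70)
        heavy = np.full(4, 1.70)
        est = qsip.bootstrap_eaf("a", "early", "control", light, heavy,
                                 n_boot=100, seed=0)
        assert est.eaf_median == 0.0 and not est.significant


class TestPerReplicateEAF:
    def test_zero_when_heavy_equals_light_mean(self):
        got = qsip.per_replicate_eaf([1.70], [1.69, 1.71])
        assert got[0] == pytest.approx(0.0, abs=1e-15)

    def test_mean_equals_pooled_shift_eaf(self):
        # EAF is linear in the labeled WAD at fixed light WAD, so the mean of
        # per-replicate EAFs equals the EAF of the mean heavy WAD.
        light = np.array([1.699, 1.701])
        heavy = np.array([1.705, 1.709])
        per_rep = qsip.per_replicate_eaf(heavy, light)
        pooled = qsip.eaf_from_wads(light.mean(), heavy.mean())
        assert len(set(np.round(per_rep, 12))) == 2
        assert per_rep.mean() == pytest.approx(pooled, rel=1e-10)


class TestRecovery:
    def test_simulated_eaf_recovery(self, one_group_dataset):
        """Median absolute EAF error < 0.02 on 40 simulated taxa."""
        from qsipgrowth.pipeline import qsip_analysis
        d = one_group_dataset
        res = qsip_analysis(d["fractions"], d["features"], d["tubes"],
                            d["water"], d["taxonomy"], n_boot=1000, seed=1)
        merged = res["eaf"].merge(d["truth"],
                                  on=["taxon_id", "site", "temperature_treatment"])
        assert len(merged) == 40
        assert (merged["eaf_median"] - merged["true_eaf"]).abs().median() < 0.02
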