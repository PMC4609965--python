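"""Gamma2 computation, significance filtering, contact maps, regions, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from prekit.pre import (
    PREEntry,
    PREProfile,
    RegionMap,
    align_sequences,
    alpha_synuclein_regions,
    beta_synuclein_regions,
    build_contact_map,
    compute_pre,
    region_summary,
    significance_mask,
)
from prekit.relaxation import R2Fit, RelaxationProfile, SampleInfo


def profile_from_rates(rates, errors=None, arm="para", site=11, ratio=1.0):
    errors = errors if errors is not None else {i: 0.5 for i in rates}
    return RelaxationProfile(
        residues={i: R2Fit(r2=r, r2_error=errors[i], amplitude=100.0, fit_quality=1.0)
                  for i, r in rates.items()},
        noise=0.02,
        sample=SampleInfo("alpha", "alpha", site, arm, ratio),
    )


def pre_profile(gammas, site=11):
    return PREProfile(
        residues={i: PREEntry(g, 0.5) for i, g in gammas.items()},
        sample=SampleInfo("alpha", "alpha", site, None, 1.0),
    )


class TestComputePre:
    def test_subtraction_and_quadrature(self):
        para = profile_from_rates({1: 25.0, 2: 20.0, 3: 18.0, 4: 16.0},
                                  errors={i: 1.0 for i in range(1, 5)})
        dia = profile_from_rates({1: 15.0, 2: 15.0, 3: 15.0, 4: 15.0},
                                 errors={i: 1.0 for i in range(1, 5)}, arm="dia")
        pre = compute_pre(para, dia)
        assert pre.residues[1].gamma2 == pytest.approx(10.0)
        assert pre.residues[1].gamma2_error == pytest.approx(np.sqrt(2.0))

    def test_identical_profiles_give_zero_and_nothing_significant(self):
        rates = {i: 15.0 + i for i in range(1, 11)}
        para = profile_from_rates(rates)
        dia = profile_from_rates(rates, arm="dia")
        pre = compute_pre(para, dia)
        assert all(e.gamma2 == 0.0 for e in pre.residues.values())
        assert pre.significant_set() == set()

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(1)
        para = profile_from_rates({i: float(r) for i, r in
                                   enumerate(rng.uniform(15, 40, 20), start=1)})
        dia = profile_from_rates({i: float(r) for i, r in
                                  enumerate(rng.uniform(10, 25, 20), start=1)}, arm="dia")
        fwd = compute_pre(para, dia)
        rev = compute_pre(dia, para)
        for i in fwd.residues:
            assert rev.residues[i].gamma2 == pytest.approx(-fwd.residues[i].gamma2)

    def test_residues_missing_in_either_arm_are_absent(self):
        para = profile_from_rates({1: 25.0, 2: 20.0, 3: 18.0, 4: 16.0, 5: 30.0})
        dia = profile_from_rates({1: 15.0, 2: 15.0, 3: 15.0, 4: 15.0, 6: 15.0}, arm="dia")
        pre = compute_pre(para, dia)
        assert set(pre.residues) == {1, 2, 3, 4}

    def test_metadata_mismatch_raises(self):
        para = profile_from_rates({1: 25.0, 2: 20.0, 3: 18.0, 4: 16.0}, site=11)
        dia = profile_from_rates({1: 15.0, 2: 15.0, 3: 15.0, 4: 15.0}, site=44, arm="dia")
        with pytest.raises(ValueError, match="mismatch"):
            compute_pre(para, dia)

    def test_empty_intersection_raises(self):
        para = profile_from_rates({1: 25.0, 2: 22.0, 3: 21.0})
        dia = profile_from_rates({4: 15.0, 5: 15.0, 6: 15.0}, arm="dia")
        with pytest.raises(ValueError, match="no residue"):
            compute_pre(para, dia)


def brute_force_filter(values, floor=8.0):
    """Independent clause-by-clause evaluation of the contact filter."""
    values = list(values)
    mean = sum(values) / len(values)
    q3 = float(np.percentile(values, 75))
    return [v >= 2 * mean and v > q3 and v >= floor for v in values]


class TestSignificanceFilter:
    def test_all_zero_vector_passes_nothing(self):
        assert not significance_mask(np.zeros(10)).any()

    def test_floor_blocks_even_dominant_values(self):
        # 7.9 s^-1 dominates its strip but sits below the 8 Hz floor
        v = np.array([7.9, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        assert not significance_mask(v).any()

    def test_single_spike_vector(self):
        v = np.array([1.0] * 9 + [20.0])
        mask = significance_mask(v)
        assert mask.tolist() == brute_force_filter(v)
        assert np.flatnonzero(mask).tolist() == [9]

    def test_requires_four_residues(self):
        with pytest.raises(ValueError):
            significance_mask(np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        arrays(
            float, st.integers(min_value=4, max_value=60),
            elements=st.floats(min_value=-5.0, max_value=40.0),
        )
    )
    def test_matches_brute_force_oracle(self, values):
        assert significance_mask(values).tolist() == brute_force_filter(values)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        arrays(float, 20, elements=st.floats(min_value=0.0, max_value=30.0)),
        st.floats(min_value=0.01, max_value=50.0),
    )
    def test_raising_a_passing_residue_keeps_it_passing(self, values, delta):
        mask = significance_mask(values)
        passing = np.flatnonzero(mask)
        if passing.size == 0:
            return
        idx = int(passing[0])
        raised = values.copy()
        raised[idx] += delta
        assert significance_mask(raised)[idx]


class TestRegionMap:
    def test_alpha_defaults_tile_sequence(self):
        rm = alpha_synuclein_regions()
        assert len(rm.sequence) == 140
        assert rm.regions == {"N": (1, 60), "NAC": (61, 95), "C": (96, 140)}
        assert rm.hot_spot == (38, 45)

    def test_beta_defaults(self):
        rm = beta_synuclein_regions()
        assert len(rm.sequence) == 134
        assert rm.regions["C"] == (85, 134)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            RegionMap("A" * 50, {"N": (1, 30), "NAC": (25, 40), "C": (41, 50)})

    def test_hot_spot_outside_n_rejected(self):
        with pytest.raises(ValueError, match="hot spot"):
            RegionMap("A" * 50, {"N": (1, 20), "NAC": (21, 35), "C": (36, 50)},
                      hot_spot=(30, 34))

    def test_interval_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            RegionMap("A" * 10, {"N": (1, 20)})


class TestContactMap:
    def make_map(self, sites=(132, 11, 44)):
        rng = np.random.default_rng(0)
        regions = alpha_synuclein_regions()
        strips = [
            pre_profile({i: float(g) for i, g in
                         enumerate(rng.uniform(0, 5, 140), start=1)}, site=s)
            for s in sites
        ]
        return build_contact_map(strips, regions)

    def test_strips_ordered_by_site(self):
        cmap = self.make_map()
        assert cmap.sites == [11, 44, 132]

    def test_four_strips(self):
        cmap = self.make_map(sites=(11, 44, 90, 132))
        assert cmap.sites == [11, 44, 90, 132]

    def test_inconsistent_visible_species_rejected(self):
        a = pre_profile({i: 0.0 for i in range(1, 141)}, site=11)
        b = PREProfile(
            residues={i: PREEntry(0.0, 0.5) for i in range(1, 135)},
            sample=SampleInfo("beta", "alpha", 44, None, 1.0),
        )
        with pytest.raises(ValueError, match="species"):
            build_contact_map([a, b], alpha_synuclein_regions())

    def test_binning_clamps_and_saturates(self):
        strip = pre_profile(
            {1: -3.0, 2: 0.0, 3: 5.0, 4: 11.9, 5: 12.0, 6: 12.1, 7: 50.0}, site=11
        )
        cmap = build_contact_map([strip], alpha_synuclein_regions())
        binned = cmap.binned()
        assert binned[0, 0] == 0  # negative clamps to zero
        assert binned[0, 4] == 5  # exactly 12 stays below the top bin
        assert binned[0, 5] == 6  # > 12 saturates
        assert binned[0, 6] == 6
        assert np.isnan(binned[0, 7])  # absent residue

    def test_rendering_is_idempotent_and_pure(self):
        cmap = self.make_map()
        raw_before = cmap.matrix().copy()
        b1, b2 = cmap.binned(), cmap.binned()
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(cmap.matrix(), raw_before)

    def test_no_significant_means_no_top_bins_flagged(self):
        cmap = self.make_map()
        assert all(not s for s in cmap.significant_sets().values())


class TestAlignment:
    def test_identical_sequences_identity_map(self):
        m = align_sequences("MDVFMKGLS", "MDVFMKGLS")
        assert m == {i: i for i in range(1, 10)}

    def test_small_gap_case(self):
        m = align_sequences("ACDE", "ACE")
        assert m == {1: 1, 2: 2, 4: 3}

    def test_synuclein_pair_has_single_11_residue_nac_gap(self):
        a = alpha_synuclein_regions().sequence
        b = beta_synuclein_regions().sequence
        m = align_sequences(a, b)
        unmapped = sorted(set(range(1, 141)) - set(m))
        runs, run = [], [unmapped[0]]
        for i in unmapped[1:]:
            if i == run[-1] + 1:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        nac_runs = [r for r in runs if 61 <= r[0] and r[-1] <= 95]
        assert len(nac_runs) == 1 and len(nac_runs[0]) == 11

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACDE")


class TestRegionSummary:
    def test_no_significant_residues_topology_none(self):
        strip = pre_profile({i: 0.0 for i in range(1, 141)}, site=11)
        cmap = build_contact_map([strip], alpha_synuclein_regions())
        summary, topologies = region_summary(cmap)
        assert topologies == set()
        assert (summary["n_significant"] == 0).all()

    def test_head_to_head_and_head_to_tail_detection(self):
        gam = {i: 0.0 for i in range(1, 141)}
        for i in range(38, 43):
            gam[i] = 20.0
        for i in range(126, 132):
            gam[i] = 15.0
        strip = PREProfile(
            residues={i: PREEntry(g, 0.5, significant=g >= 8.0) for i, g in gam.items()},
            sample=SampleInfo("alpha", "alpha", 11, None, 1.0),
        )
        cmap = build_contact_map([strip], alpha_synuclein_regions())
        _, topologies = region_summary(cmap)
        assert topologies == {"head-to-head", "head-to-tail"}

    def test_short_runs_do_not_count_as_interacting(self):
        gam = {i: 0.0 for i in range(1, 141)}
        gam[38] = 20.0  # isolated single significant residue
        strip = PREProfile(
            residues={i: PREEntry(g, 0.5, significant=g >= 8.0) for i, g in gam.items()},
            sample=SampleInfo("alpha", "alpha", 11, None, 1.0),
        )
        cmap = build_contact_map([strip], alpha_synuclein_regions())
        summary, topologies = region_summary(cmap)
        assert topologies == set()
        n_row = summary[(summary.spin_label_site == 11) & (summary.region == "N")]
        assert int(n_row["n_significant"].iloc[0]) == 1
        assert not bool(n_row["interacting"].iloc[0])
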