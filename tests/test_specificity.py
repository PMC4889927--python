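"""Sample pairing, the specificity index and replicate thresholds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dnaends import (
    Band,
    ExperimentDesign,
    PairedAbundance,
    Phase,
    QuantifiedObservation,
    SampleKey,
    apply_specificity_filter,
    compute_specificity,
    pair_samples,
    replicate_presence,
    specificity_index,
)
from dnaends.specificity import SpecificityResult, pool_pairs


def obs(experiment, phase, band, accession, empai, n_observed=3, n_observable=10):
    return QuantifiedObservation(
        SampleKey(experiment, phase, band), accession, n_observed, n_observable, empai
    )


def pairs_from(m_values, b_values, accession="P1"):
    return [
        PairedAbundance(i + 1, Band.B720, accession, m, b)
        for i, (m, b) in enumerate(zip(m_values, b_values))
        if m + b > 0
    ]


class TestPairSamples:
    def test_absence_conventions(self):
        quantified = [
            obs(1, "ends", "720", "P1", 2.0),
            obs(1, "control", "720", "P2", 1.0),
        ]
        pairs = {p.accession: p for p in pair_samples(quantified)}
        assert (pairs["P1"].M, pairs["P1"].B) == (2.0, 0.0)
        assert (pairs["P2"].M, pairs["P2"].B) == (0.0, 1.0)

    def test_unpaired_sixth_experiment_flagged(self):
        quantified = [obs(6, "ends", "720", "P1", 2.0)]
        (pair,) = pair_samples(quantified)
        assert pair.B == 0.0 and not pair.paired
        assert pair_samples(quantified, paired_only=True) == []

    def test_control_without_ends_counterpart_is_an_error(self):
        design = ExperimentDesign(
            n_ends_experiments=3,
            n_control_experiments=2,
            min_experiments_venn=3,
        )
        quantified = [obs(3, "control", "720", "P1", 1.0)]
        with pytest.raises(ValueError, match="control"):
            pair_samples(quantified, design)

    def test_pooling_sums_across_bands(self):
        quantified = [
            obs(1, "ends", "720", "P1", 2.0),
            obs(1, "ends", "480", "P1", 1.0),
            obs(1, "control", "240", "P1", 0.5),
        ]
        (pooled,) = pool_pairs(pair_samples(quantified))
        assert (pooled.M, pooled.B) == (3.0, 0.5)
        assert pooled.band is None


class TestSpecificityIndex:
    def test_all_control_zero_gives_one(self):
        result = specificity_index(pairs_from((4.0, 1.0, 0.5), (0, 0, 0)))
        assert result.index == pytest.approx(1.0)
        assert result.retained and result.exclusive_to_ends

    def test_hand_computed_mixture(self):
        # (0.5 + 0.75 + 0.25) / 3 evaluated by hand
        result = specificity_index(pairs_from((2, 6, 2), (2, 2, 6)))
        assert result.index == pytest.approx(0.5)
        assert not result.retained

    def test_below_minimum_replicates_is_undefined(self):
        result = specificity_index(pairs_from((2, 3), (0, 0)))
        assert result.n_experiments == 2
        assert result.index is None and not result.retained
        assert result.exclusive_to_ends

    def test_empty_pair_list_is_an_error(self):
        with pytest.raises(ValueError):
            specificity_index([])

    def test_mixed_accessions_rejected(self):
        pairs = pairs_from((1, 1, 1), (0, 0, 0)) + pairs_from((1,), (1,), "P2")
        with pytest.raises(ValueError):
            specificity_index(pairs)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=100),
                st.one_of(
                    st.just(0.0), st.floats(min_value=1e-6, max_value=100)
                ),
            ),
            min_size=3,
            max_size=6,
        )
    )
    def test_bounds_and_permutation_invariance(self, mb):
        m_values, b_values = zip(*mb)
        base = specificity_index(pairs_from(m_values, b_values))
        assert 0.0 <= base.index <= 1.0
        rng = np.random.default_rng(0)
        order = rng.permutation(len(mb))
        permuted = specificity_index(
            pairs_from([m_values[i] for i in order], [b_values[i] for i in order])
        )
        assert permuted.index == pytest.approx(base.index, abs=1e-12)
        # I = 1 iff every control-side value is zero (exact: each term is
        # exactly 1.0 only when B_i is exactly 0)
        assert (base.index == 1.0) == all(b == 0 for b in b_values)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=50),
                st.floats(min_value=0.01, max_value=50),
            ),
            min_size=3,
            max_size=6,
        ),
        st.integers(min_value=0, max_value=5),
    )
    def test_monotone_in_single_components(self, mb, which):
        which %= len(mb)
        m_values, b_values = map(list, zip(*mb))
        base = specificity_index(pairs_from(m_values, b_values)).index
        m_up = list(m_values)
        m_up[which] *= 2
        assert specificity_index(pairs_from(m_up, b_values)).index >= base - 1e-12
        b_up = list(b_values)
        b_up[which] *= 2
        assert specificity_index(pairs_from(m_values, b_up)).index <= base + 1e-12

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=50),
                st.floats(min_value=0.01, max_value=50),
            ),
            min_size=3,
            max_size=6,
        ),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_per_experiment_scaling_invariance(self, mb, factor):
        m_values, b_values = map(list, zip(*mb))
        base = specificity_index(pairs_from(m_values, b_values)).index
        m_values[0] *= factor
        b_values[0] *= factor
        scaled = specificity_index(pairs_from(m_values, b_values)).index
        assert scaled == pytest.approx(base, rel=1e-9)


class TestFilter:
    def make(self, accession, index):
        return SpecificityResult(
            accession, "pooled", 3, index, index is not None and index >= 0.9, False
        )

    def test_boundary_and_partition(self):
        results = [
            self.make("EXACT", 0.9),
            self.make("BELOW", 0.8999999),
            self.make("UNDEF", None),
            self.make("HIGH", 0.95),
        ]
        retained, removed = apply_specificity_filter(results, 0.9)
        assert {r.accession for r in retained} == {"EXACT", "HIGH"}
        assert {r.accession for r in removed} == {"BELOW", "UNDEF"}
        assert len(retained) + len(removed) == len(results)


class TestReplicatePresence:
    def test_distinct_experiment_counting(self):
        quantified = [
            obs(1, "ends", "720", "P1", 1.0),
            obs(1, "ends", "480", "P1", 1.0),  # same experiment, other band
            obs(2, "ends", "720", "P1", 1.0),
            obs(1, "ends", "720", "P2", 1.0),
        ]
        assert replicate_presence(quantified, Phase.ENDS, 2) == {"P1"}
        assert replicate_presence(quantified, Phase.ENDS, 1) == {"P1", "P2"}
        assert replicate_presence(quantified, Phase.ENDS, 3) == set()

    @pytest.mark.parametrize("experiments,threshold,expected", [
        ({1, 2, 3, 4}, 4, True),
        ({1, 2, 3}, 4, False),
    ])
    def test_threshold_boundary(self, experiments, threshold, expected):
        quantified = [obs(e, "ends", "720", "P1", 1.0) for e in experiments]
        present = "P1" in replicate_presence(quantified, Phase.ENDS, threshold)
        assert present is expected


class TestComputeSpecificity:
    def test_band_and_pooled_scopes(self):
        quantified = [
            obs(e, "ends", "720", "P1", 2.0) for e in (1, 2, 3)
        ] + [obs(e, "control", "720", "P1", 2.0) for e in (1, 2, 3)]
        results = compute_specificity(quantified, scope="both")
        scopes = {r.scope: r for r in results}
        assert scopes["pooled"].index == pytest.approx(0.5)
        assert scopes["720"].index == pytest.approx(0.5)

    def test_ends_only_convention_drops_control_only_experiments(self):
        quantified = [
            obs(e, "ends", "720", "P1", 2.0) for e in (1, 2, 3)
        ] + [obs(4, "control", "720", "P1", 2.0)]
        either = compute_specificity(quantified, scope="pooled")[0]
        ends_only = compute_specificity(
            quantified, scope="pooled", identified_on="ends"
        )[0]
        assert either.n_experiments == 4
        assert either.index == pytest.approx(0.75)
        assert ends_only.n_experiments == 3
        assert ends_only.index == pytest.approx(1.0)
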