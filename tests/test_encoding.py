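import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import daccspot as ds
from daccspot.encoding import parse_feature_name, sequence_to_dinucleotide_indices
from daccspot.errors import InvalidSequenceError, SequenceLengthError

from conftest import brute_force_dacc, random_sequence, subtable

dna = st.text(alphabet="ACGT", min_size=8, max_size=60)


def test_profile_examples(table):
    profile, mean = ds.dinucleotide_profile("ACGT", "F-roll", table)
    assert np.allclose(profile, [0.06, 0.04, 0.06])
    assert mean == pytest.approx(0.16 / 3)
    profile, _ = ds.dinucleotide_profile("ACGT", "F-tilt", table)
    assert np.allclose(profile, [0.07, 0.06, 0.07])
    profile, _ = ds.dinucleotide_profile("AAAA", "twist", table)
    assert np.ptp(profile) == 0.0


def test_profile_rejects_bad_character_with_position(table):
    with pytest.raises(InvalidSequenceError, match="position 3"):
        ds.dinucleotide_profile("ACNT", "F-roll", table)
    with pytest.raises(InvalidSequenceError):
        sequence_to_dinucleotide_indices("ACGU")  # RNA is rejected


def test_hand_computed_toy_covariances(table):
    # three-term hand computation from the printed F-roll/F-tilt values
    assert ds.dac("ACGT", "F-roll", 1, table) == pytest.approx(-8.888888888888889e-5)
    assert ds.dcc("ACGT", "F-roll", "F-tilt", 1, table) == pytest.approx(
        -4.444444444444444e-5
    )


@pytest.mark.parametrize("lag", range(1, 7))
def test_homopolymer_dac_is_zero(table, lag):
    for base in "ACGT":
        assert ds.dac(base * 20, "F-slide", lag, table) == pytest.approx(0.0, abs=1e-15)


def test_single_summand_equals_deviation_product(table):
    seq = "ACGTA"  # L=5, lag=3 leaves exactly one summand
    profile, mean = ds.dinucleotide_profile(seq, "F-slide", table)
    expected = (profile[0] - mean) * (profile[3] - mean)
    assert ds.dac(seq, "F-slide", 3, table) == pytest.approx(expected)


def test_dcc_requires_distinct_properties(table):
    with pytest.raises(ValueError, match="dac"):
        ds.dcc("ACGTACGT", "F-roll", "F-roll", 1, table)


def test_length_errors_state_minimum(table):
    with pytest.raises(SequenceLengthError, match="L >= 8"):
        ds.dac("ACGTACG", "F-roll", 6, table)
    with pytest.raises(SequenceLengthError):
        ds.encode_dacc("ACGTA", ds.EncodingConfig(lag=6))


def test_dcc_is_order_sensitive(table):
    rng = np.random.default_rng(5)
    seq = random_sequence(rng, 80)
    fwd = ds.dcc(seq, "F-slide", "entropy", 2, table)
    rev = ds.dcc(seq, "entropy", "F-slide", 2, table)
    assert fwd != pytest.approx(rev, abs=1e-12)


@pytest.mark.parametrize("n_props,lag", [(2, 1), (2, 3), (3, 2), (5, 4), (15, 6)])
def test_dimension_law(table, n_props, lag):
    config = ds.EncodingConfig(
        lag=lag, table=subtable(table, table.property_names[:n_props])
    )
    names = ds.feature_names(config)
    assert len(names) == n_props * n_props * lag
    dac_block = [n for n in names if n.startswith("DAC")]
    dcc_block = [n for n in names if n.startswith("DCC")]
    assert len(dac_block) == n_props * lag
    assert len(dcc_block) == n_props * (n_props - 1) * lag
    # DAC block first, canonical property-major / lag-minor order
    assert names[: len(dac_block)] == tuple(dac_block)
    vec = ds.encode_dacc(random_sequence(np.random.default_rng(0), 40), config)
    assert vec.values.shape == (len(names),)


def test_default_dimensions():
    config = ds.EncodingConfig()
    assert config.n_features == 1350
    names = ds.feature_names(config)
    assert names[0] == "DAC(F-roll,1)"
    assert names[90] == "DCC(F-roll,F-tilt,1)"
    assert parse_feature_name("DCC(F-tilt,tilt,3)") == ("F-tilt", "tilt", 3)
    assert parse_feature_name("DAC(F-tilt,3)") == ("F-tilt", None, 3)


def test_vectorized_encoder_matches_brute_force(table):
    config = ds.EncodingConfig(lag=4, table=subtable(table, table.property_names[:4]))
    rng = np.random.default_rng(17)
    for length in (10, 23, 57, 180):
        seq = random_sequence(rng, length)
        expected = brute_force_dacc(seq, config)
        got = ds.encode_dacc(seq, config).values
        np.testing.assert_allclose(got, expected, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seq=dna)
def test_case_insensitive_and_deterministic(seq):
    config = ds.EncodingConfig(lag=2)
    upper = ds.encode_dacc(seq, config).values
    lower = ds.encode_dacc(seq.lower(), config).values
    np.testing.assert_array_equal(upper, lower)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(base=st.sampled_from("ACGT"), length=st.integers(10, 80))
def test_zero_law_for_constant_class_sequences(base, length):
    """A sequence with a single dinucleotide class encodes to the zero vector."""
    vec = ds.encode_dacc(base * length, ds.EncodingConfig(lag=3))
    np.testing.assert_allclose(vec.values, 0.0, atol=1e-12)


def test_iid_sequence_dac_shrinks_with_length(table):
    # for i.i.d. uniform bases the population DAC at lags >= 2 is 0 (the
    # dinucleotides are disjoint, hence independent); the estimate at
    # L=10000 must be within a few standard errors of 0.  Lag 1 is excluded:
    # adjacent dinucleotide steps share a base, which leaves a genuine
    # nonvanishing correlation even in i.i.d. sequences.
    rng = np.random.default_rng(23)
    seq = random_sequence(rng, 10_000)
    profile, mean = ds.dinucleotide_profile(seq, "F-rise", table)
    var = np.var(profile)
    for lag in (2, 3, 6):
        se = var / np.sqrt(len(profile) - lag)
        assert abs(ds.dac(seq, "F-rise", lag, table)) < 5 * se


def test_encode_batch_contract(table):
    config = ds.EncodingConfig(lag=2)
    rng = np.random.default_rng(2)
    records = [(f"s{i}", random_sequence(rng, 30)) for i in range(3)]
    matrix, skipped = ds.encode_batch(records, config, labels=[1, -1, 1])
    assert matrix.values.shape == (3, config.n_features)
    assert matrix.ids == ("s0", "s1", "s2")
    assert not skipped
    np.testing.assert_array_equal(matrix.labels, [1, -1, 1])

    # a record with an ambiguity code fails the batch unless skipping is on
    bad = records + [("s3", "ACGTNACGT")]
    with pytest.raises(InvalidSequenceError, match="s3"):
        ds.encode_batch(bad, config, labels=[1, -1, 1, -1])
    matrix, skipped = ds.encode_batch(
        bad, config, labels=[1, -1, 1, -1], skip_invalid=True
    )
    assert matrix.n_samples == 3
    assert skipped[0][0] == "s3"

    with pytest.raises(ValueError, match="no encodable"):
        ds.encode_batch([], config)
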