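"""Dinucleotide auto-cross covariance (DACC) sequence encoding.

A DNA sequence of length ``L`` is first turned into one numeric profile per
property: position ``i`` (1-based, ``i = 1..L-1``) carries the property value
of the dinucleotide starting there.  The auto covariance (DAC) of property
``mu`` at offset ``lag`` is

    DAC(mu, lag) = sum_{i=1}^{L-1-lag} (P_mu(i) - Pbar_mu) (P_mu(i+lag) - Pbar_mu)
                   / (L - 1 - lag)

with ``Pbar_mu`` the mean of the profile over all ``L-1`` positions.  The
cross covariance (DCC) replaces the second factor by a different property's
profile; both orderings of a pair are emitted.  Concatenating all DAC terms
(``N * LAG`` of them) and all DCC terms (``N * (N-1) * LAG``) gives the DACC
vector of fixed length ``N * N * LAG`` regardless of sequence length, which
is how variable-length sequences become comparable feature vectors.

Feature order is canonical: the DAC block iterates properties in table order
(outer) then lag ``1..LAG`` (inner); the DCC block iterates ordered property
pairs (first property outer, second middle, skipping equal pairs) then lag.
Names are ``DAC(mu,lag)`` and ``DCC(mu1,mu2,lag)`` with property names as
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    InvalidSequenceError,
    SequenceLengthError,
    ShapeError,
)
from .properties import ALL_DINUCLEOTIDES, PropertyTable, default_table

_DINUC_INDEX = {d: i for i, d in enumerate(ALL_DINUCLEOTIDES)}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class EncodingConfig:
    """Configuration of the DACC encoder.

    Parameters
    ----------
    lag
        Maximum dinucleotide offset ``LAG`` (every lag ``1..LAG`` is encoded).
    table
        Property table; defaults to the packaged fifteen-property table.
    standardize_properties
        If True, z-score each property row across the ten classes before
        computing covariances.  Default keeps the raw printed values.
    """

    lag: int = 6
    table: PropertyTable = field(default_factory=default_table)
    standardize_properties: bool = False

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.table.n_properties < 2:
            raise ValueError("at least two properties are required for DCC")
        if self.standardize_properties and not self.table.standardized:
            object.__setattr__(self, "table", self.table.standardize())

    @property
    def n_properties(self) -> int:
        return self.table.n_properties

    @property
    def n_features(self) -> int:
        # N*LAG DAC features plus N*(N-1)*LAG DCC features = N*N*LAG
        n = self.n_properties
        return n * n * self.lag

    @property
    def min_length(self) -> int:
        """Shortest sequence for which every lag has at least one summand."""
        return self.lag + 2


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[0]:
            raise ShapeError("names and values lengths differ")


@dataclass(frozen=True)
class FeatureMatrix:
    """Row-per-sequence feature matrix with optional +/-1 labels."""

    names: tuple[str, ...]
    values: np.ndarray
    ids: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ShapeError(
                f"matrix is {self.values.shape}, expected n x {len(self.names)}"
            )
        if self.values.shape[0] != len(self.ids):
            raise ShapeError("one id per row is required")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ShapeError("one label per row is required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def sequence_to_dinucleotide_indices(sequence: str) -> np.ndarray:
    """Indices into :data:`ALL_DINUCLEOTIDES` for each of the L-1 steps.

    Case-insensitive; any character outside A/C/G/T (including U and IUPAC
    ambiguity codes) raises :class:`InvalidSequenceError` naming the 1-based
    offending position.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise SequenceLengthError(
            f"sequence of length {len(seq)} has no dinucleotides (need L >= 2)"
        )
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    base = np.full(codes.shape, -1, dtype=np.int64)
    for ch, idx in _BASE_INDEX.items():
        base[codes == ord(ch)] = idx
    bad = np.flatnonzero(base < 0)
    if bad.size:
        pos = int(bad[0]) + 1
        raise InvalidSequenceError(
            f"invalid character {seq[bad[0]]!r} at position {pos} (1-based); "
            "only A/C/G/T are accepted"
        )
    return base[:-1] * 4 + base[1:]


def feature_names(config: EncodingConfig) -> tuple[str, ...]:
    """Canonical DAC-then-DCC feature names for a configuration."""
    props = config.table.property_names
    names = [
        f"DAC({mu},{lag})" for mu in props for lag in range(1, config.lag + 1)
    ]
    names += [
        f"DCC({mu1},{mu2},{lag})"
        for mu1 in props
        for mu2 in props
        if mu2 != mu1
        for lag in range(1, config.lag + 1)
    ]
    return tuple(names)


def parse_feature_name(name: str) -> tuple[str, str | None, int]:
    """Split ``DAC(mu,lag)`` / ``DCC(mu1,mu2,lag)`` into its parts."""
    kind, _, rest = name.partition("(")
    parts = rest.rstrip(")").split(",")
    if kind == "DAC":
        return parts[0], None, int(parts[1])
    return parts[0], parts[1], int(parts[2])


def dinucleotide_profile(
    sequence: str, property_name: str, table: PropertyTable | None = None
) -> tuple[np.ndarray, float]:
    """Per-position property profile and its mean.

    Returns the length ``L-1`` series whose element ``i`` (1-based) is the
    property value of the dinucleotide at positions ``i..i+1``, together with
    the mean over all positions.
    """
    table = table if table is not None else default_table()
    row = table.property_index(property_name)
    idx = sequence_to_dinucleotide_indices(sequence)
    profile = table.dinucleotide_matrix()[row][idx]
    return profile, float(profile.mean())


def _check_length(L: int, lag: int) -> None:
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if L < lag + 2:
        raise SequenceLengthError(
            f"sequence length {L} too short for lag {lag}; need L >= {lag + 2}"
        )


def dac(
    sequence: str,
    property_name: str,
    lag: int,
    table: PropertyTable | None = None,
) -> float:
    """Auto covariance of one property's profile at a single offset."""
    _check_length(len(sequence), lag)
    profile, mean = dinucleotide_profile(sequence, property_name, table)
    dev = profile - mean
    n = dev.shape[0] - lag
    return float(dev[:n] @ dev[lag:] / n)


def dcc(
    sequence: str,
    property1: str,
    property2: str,
    lag: int,
    table: PropertyTable | None = None,
) -> float:
    """Cross covariance between two different properties' profiles."""
    if property1 == property2:
        raise ValueError(
            f"dcc requires two different properties (got {property1!r} twice); "
            "use dac for the auto term"
        )
    _check_length(len(sequence), lag)
    p1, m1 = dinucleotide_profile(sequence, property1, table)
    p2, m2 = dinucleotide_profile(sequence, property2, table)
    d1, d2 = p1 - m1, p2 - m2
    n = d1.shape[0] - lag
    return float(d1[:n] @ d2[lag:] / n)


def _covariance_blocks(profiles: np.ndarray, max_lag: int) -> np.ndarray:
    """(max_lag, N, N) array of lagged covariances of centered profiles.

    ``profiles`` is the (N, L-1) matrix of property profiles; entry
    ``[lag-1, a, b]`` is the covariance of property ``a`` at position ``i``
    with property ``b`` at position ``i+lag``.
    """
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    n_pos = centered.shape[1]
    out = np.empty((max_lag, centered.shape[0], centered.shape[0]))
    for lag in range(1, max_lag + 1):
        n = n_pos - lag
        out[lag - 1] = centered[:, :n] @ centered[:, lag:].T / n
    return out


def _blocks_to_vector(blocks: np.ndarray, n_props: int, max_lag: int) -> np.ndarray:
    # DAC block: property-major, lag-minor
    diag = blocks[:, np.arange(n_props), np.arange(n_props)]  # (lag, N)
    dac_block = diag.T.reshape(-1)
    # DCC block: mu1-major, mu2-middle (mu2 != mu1), lag-minor
    cross = blocks.transpose(1, 2, 0)  # (mu1, mu2, lag)
    off = ~np.eye(n_props, dtype=bool)
    dcc_block = cross[off].reshape(-1)
    return np.concatenate([dac_block, dcc_block])


def encode_dacc(sequence: str, config: EncodingConfig | None = None) -> FeatureVector:
    """Full DACC feature vector for one sequence (DAC block then DCC block)."""
    config = config or EncodingConfig()
    _check_length(len(sequence), config.lag)
    idx = sequence_to_dinucleotide_indices(sequence)
    profiles = config.table.dinucleotide_matrix()[:, idx]
    blocks = _covariance_blocks(profiles, config.lag)
    values = _blocks_to_vector(blocks, config.n_properties, config.lag)
    return FeatureVector(feature_names(config), values)


def encode_batch(
    records: Iterable[tuple[str, str]],
    config: EncodingConfig | None = None,
    labels: Sequence[int] | None = None,
    skip_invalid: bool = False,
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Encode ``(id, sequence)`` records into a feature matrix.

    Row order follows input order.  ``labels`` (one +/-1 per record, aligned
    with the input) is carried through, dropping entries for skipped records.
    With ``skip_invalid`` the failing records are collected as ``(id, reason)``
    pairs instead of aborting the batch.
    """
    config = config or EncodingConfig()
    records = list(records)
    if labels is not None and len(labels) != len(records):
        raise ShapeError(f"{len(labels)} labels for {len(records)} records")

    rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    kept_labels: list[int] = []
    skipped: list[tuple[str, str]] = []
    for i, (rec_id, seq) in enumerate(records):
        try:
            rows.append(encode_dacc(seq, config).values)
        except (InvalidSequenceError, SequenceLengthError) as exc:
            if not skip_invalid:
                raise type(exc)(f"record {rec_id!r}: {exc}") from exc
            skipped.append((rec_id, str(exc)))
            continue
        kept_ids.append(rec_id)
        if labels is not None:
            kept_labels.append(int(labels[i]))
    if not rows:
        raise ValueError("no encodable sequences in batch")
    matrix = FeatureMatrix(
        names=feature_names(config),
        values=np.vstack(rows),
        ids=tuple(kept_ids),
        labels=np.asarray(kept_labels) if labels is not None else None,
    )
    return matrix, skipped
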