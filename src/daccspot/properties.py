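"""Dinucleotide physicochemical property table.

Fifteen properties (six flexibility parameters ``F-roll`` ... ``F-rise``,
six structural parameters ``roll`` ... ``rise``, and three thermodynamic
parameters ``energy``, ``enthalpy``, ``entropy``) are tabulated over the ten
strand-symmetric dinucleotide classes.  A dinucleotide and its reverse
complement describe the same base-pair step read from opposite strands, so
the sixteen dinucleotides collapse onto ten classes::

    AA/TT  AC/GT  AG/CT  AT  CA/TG  CC/GG  CG  GA/TC  GC  TA

The default table ships with the package as a CSV; a user-supplied CSV of
the same shape (15 rows x 10 class columns) can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegeneratePropertyError, InvalidSequenceError, UnknownPropertyError

CLASS_LABELS: tuple[str, ...] = (
    "AA/TT",
    "AC/GT",
    "AG/CT",
    "AT",
    "CA/TG",
    "CC/GG",
    "CG",
    "GA/TC",
    "GC",
    "TA",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

NUCLEOTIDES = "ACGT"

ALL_DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (upper-case A/C/G/T only)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise InvalidSequenceError(f"non-ACGT character {exc.args[0]!r}") from exc


def dinucleotide_class(dinucleotide: str) -> str:
    """Map a dinucleotide to its strand-symmetric class label.

    The class label is the dinucleotide itself if it appears in a label,
    otherwise the label containing its reverse complement; self-complementary
    steps (AT, CG, GC, TA) form singleton classes.
    """
    d = dinucleotide.upper()
    if len(d) != 2 or any(c not in _COMPLEMENT for c in d):
        raise InvalidSequenceError(f"not a dinucleotide over ACGT: {dinucleotide!r}")
    for label in CLASS_LABELS:
        if d in label.split("/"):
            return label
    rc = reverse_complement(d)
    for label in CLASS_LABELS:
        if rc in label.split("/"):
            return label
    raise AssertionError("unreachable: every ACGT dinucleotide has a class")


#: dinucleotide -> class label, for all sixteen dinucleotides
CLASS_OF: dict[str, str] = {d: dinucleotide_class(d) for d in ALL_DINUCLEOTIDES}


@dataclass(frozen=True)
class PropertyTable:
    """A named set of dinucleotide properties over the ten symmetric classes.

    Parameters
    ----------
    table
        DataFrame indexed by property name with one column per class label
        (in :data:`CLASS_LABELS` order).
    standardized
        Whether each property row has been z-scored across the ten classes.
    """

    table: pd.DataFrame
    standardized: bool = False
    # 15 x 16 lookup: column j holds the values for ALL_DINUCLEOTIDES[j]
    _dinuc_matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.table.columns) != CLASS_LABELS:
            raise ValueError(
                f"property table columns must be {CLASS_LABELS}, got {tuple(self.table.columns)}"
            )
        col_idx = [CLASS_LABELS.index(CLASS_OF[d]) for d in ALL_DINUCLEOTIDES]
        mat = self.table.to_numpy(dtype=float)[:, col_idx]
        object.__setattr__(self, "_dinuc_matrix", mat)

    @property
    def property_names(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_properties(self) -> int:
        return len(self.table.index)

    def property_index(self, name: str) -> int:
        try:
            return self.property_names.index(name)
        except ValueError:
            raise UnknownPropertyError(
                f"unknown property {name!r}; known: {', '.join(self.property_names)}"
            ) from None

    def value(self, property_name: str, dinucleotide: str) -> float:
        """Value of ``property_name`` for a dinucleotide's symmetric class."""
        row = self.property_index(property_name)
        d = dinucleotide.upper()
        if d not in CLASS_OF:
            raise InvalidSequenceError(f"not a dinucleotide over ACGT: {dinucleotide!r}")
        return float(self._dinuc_matrix[row, ALL_DINUCLEOTIDES.index(d)])

    def dinucleotide_matrix(self) -> np.ndarray:
        """(n_properties, 16) array over :data:`ALL_DINUCLEOTIDES`."""
        return self._dinuc_matrix.copy()

    def standardize(self) -> "PropertyTable":
        """Z-score each property row across the ten classes (population sd)."""
        values = self.table.to_numpy(dtype=float)
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0.0)
        if zero.size:
            names = [self.property_names[i] for i in zero]
            raise DegeneratePropertyError(
                f"zero variance across classes for: {', '.join(names)}"
            )
        z = (values - mean) / sd
        return PropertyTable(
            pd.DataFrame(z, index=self.table.index, columns=self.table.columns),
            standardized=True,
        )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="property")


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load the packaged default table, or a user CSV of the same shape."""
    if path is None:
        with resources.files("daccspot.data").joinpath(
            "dinucleotide_properties.csv"
        ).open() as fh:
            frame = pd.read_csv(fh, index_col=0)
    else:
        frame = pd.read_csv(path, index_col=0)
    frame.index.name = "property"
    frame.columns = [c.strip() for c in frame.columns]
    return PropertyTable(frame)


def default_table(standardized: bool = False) -> PropertyTable:
    table = load_property_table()
    return table.standardize() if standardized else table
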