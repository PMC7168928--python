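"""The four clinically motivated biomarker ratios.

Mineral and carbonate content are normalized to amide I, calcium and
phenylalanine to amide III (the two amide bands differ in polarization
sensitivity, so each numerator is paired with the denominator measured under
comparable conditions):

* mineral-to-matrix   = area(nu1 PO4, 960) / area(amide I, 1660)
* carbonate-to-matrix = area(nu1 CO3, 1074) / area(amide I, 1660)
* calcium             = area(nu2 PO4, 430) / area(amide III, 1275)
* phenylalanine       = [area(phe 1005) + area(phe 1609)] / area(amide III)

Both measured phenylalanine bands contribute to the numerator by default
(``phenylalanine_bands="both"``); pass ``"1005"`` to use the 1005 cm^-1 band
alone. Ratios are scale-invariant: multiplying a spectrum by any positive
constant leaves all four unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerVector",
    "InvalidRecordError",
    "compute_biomarkers",
    "biomarker_table",
    "BIOMARKER_NAMES",
    "REQUIRED_BANDS",
    "DEFAULT_EPSILON",
]

BIOMARKER_NAMES = ("mineral_to_matrix", "carbonate_to_matrix", "calcium",
                   "phenylalanine")
REQUIRED_BANDS = ("nu2PO4", "nu1PO4", "phe1005", "nu1CO3", "amideIII",
                  "phe1609", "amideI")

#: Smallest admissible denominator, in normalized-area units.
DEFAULT_EPSILON = 1e-12


class InvalidRecordError(ValueError):
    """A spectrum whose band areas cannot form valid ratios (near-zero
    denominator). Such records are excluded downstream, not propagated as
    infinities."""


@dataclass(frozen=True)
class BiomarkerVector:
    """The four ratios for one spectrum; all finite and (with area clamping
    enabled upstream) non-negative."""

    mineral_to_matrix: float
    carbonate_to_matrix: float
    calcium: float
    phenylalanine: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mineral_to_matrix, self.carbonate_to_matrix,
                         self.calcium, self.phenylalanine])


def compute_biomarkers(
    areas: Mapping[str, float],
    epsilon: float = DEFAULT_EPSILON,
    phenylalanine_bands: str = "both",
) -> BiomarkerVector:
    """Band areas -> the four ratios.

    Raises ``KeyError`` if any of the seven required bands is missing and
    ``InvalidRecordError`` if an amide denominator falls below ``epsilon``.
    """
    missing = [b for b in REQUIRED_BANDS if b not in areas]
    if missing:
        raise KeyError(f"missing band areas: {missing}")
    amide_i = areas["amideI"]
    amide_iii = areas["amideIII"]
    if amide_i < epsilon or amide_iii < epsilon:
        raise InvalidRecordError(
            f"amide denominator below epsilon={epsilon:g} "
            f"(amideI={amide_i:g}, amideIII={amide_iii:g})"
        )
    if phenylalanine_bands == "both":
        phe = areas["phe1005"] + areas["phe1609"]
    elif phenylalanine_bands == "1005":
        phe = areas["phe1005"]
    else:
        raise ValueError(f"phenylalanine_bands must be 'both' or '1005', "
                         f"got {phenylalanine_bands!r}")
    return BiomarkerVector(
        mineral_to_matrix=areas["nu1PO4"] / amide_i,
        carbonate_to_matrix=areas["nu1CO3"] / amide_i,
        calcium=areas["nu2PO4"] / amide_iii,
        phenylalanine=phe / amide_iii,
    )


def biomarker_table(
    areas: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    phenylalanine_bands: str = "both",
) -> tuple[pd.DataFrame, int]:
    """Vectorized ratios for a per-spectrum band-area table.

    ``areas`` carries one row per spectrum with the seven band columns plus
    any id columns (``spectrum_id``, ``sample_id``, ``class``), which are
    passed through. Rows with an amide denominator below ``epsilon`` are
    flagged invalid and excluded; the count of exclusions is returned
    alongside the table of valid records.
    """
    missing = [b for b in REQUIRED_BANDS if b not in areas.columns]
    if missing:
        raise KeyError(f"missing band-area columns: {missing}")
    valid = (areas["amideI"] >= epsilon) & (areas["amideIII"] >= epsilon)
    n_invalid = int((~valid).sum())
    ok = areas.loc[valid]
    phe = ok["phe1005"] + (ok["phe1609"] if phenylalanine_bands == "both" else 0.0)
    out = pd.DataFrame(index=ok.index)
    for col in ("spectrum_id", "sample_id", "class"):
        if col in ok.columns:
            out[col] = ok[col]
    out["mineral_to_matrix"] = ok["nu1PO4"] / ok["amideI"]
    out["carbonate_to_matrix"] = ok["nu1CO3"] / ok["amideI"]
    out["calcium"] = ok["nu2PO4"] / ok["amideIII"]
    out["phenylalanine"] = phe / ok["amideIII"]
    return out.reset_index(drop=True), n_invalid
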