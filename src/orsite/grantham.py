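"""Grantham amino-acid distance: first-principles formula and the canonical table.

The Grantham distance combines three physicochemical properties of an amino
acid — atomic composition (c), polarity (p) and molecular volume (v) — into a
single dissimilarity

    D(a, b) = rho * sqrt(alpha*(c_a - c_b)**2 + beta*(p_a - p_b)**2
                         + gamma*(v_a - v_b)**2)

with the global scale rho chosen so that the mean over the 190 distinct
residue pairs is 100.

Two routes to a distance are provided and deliberately kept separate:

* :func:`grantham_distance` / :func:`build_matrix` evaluate the formula at
  full floating precision, for any parameterization.
* :func:`canonical_matrix` returns the published 1974 integer table, shipped
  as versioned package data.  The published table was computed by hand and is
  *not* exactly the rounded formula: 45 of 190 pairs differ by one unit and
  the D–W entry by ~10 (an arithmetic erratum in the original).  Because the
  integer table is what the field — clinical variant annotation included —
  operationally means by "Grantham distance", it is the default used by the
  conservation screen.
"""

from __future__ import annotations

import functools
import itertools
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "GranthamParams",
    "amino_acid_properties",
    "grantham_distance",
    "build_matrix",
    "canonical_matrix",
]

#: The 20 standard residues, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Composition, polarity, volume per residue (Grantham 1974, Table 1; values
# identical to AAindex entries GRAR740101/2/3).
_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.00, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.00, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0),
    "M": (0.00, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
}


@dataclass(frozen=True)
class GranthamParams:
    """Weights and scale of the Grantham formula.

    Defaults are the published constants: ``alpha`` weights the squared
    composition difference, ``beta`` polarity, ``gamma`` volume, and ``rho``
    rescales so that the 190-pair mean is ~100.
    """

    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float = 50.723

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "rho"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"GranthamParams.{name} must be strictly positive, got {v!r}")


def amino_acid_properties() -> pd.DataFrame:
    """Return the residue property table (composition, polarity, volume)."""
    df = pd.DataFrame.from_dict(
        _PROPERTIES, orient="index", columns=["composition", "polarity", "volume"]
    )
    df.index.name = "residue"
    return df.loc[list(AMINO_ACIDS)]


def _validate_residue(code: str, props: pd.DataFrame) -> str:
    if not isinstance(code, str) or len(code) != 1:
        raise ValueError(f"residue code must be a single letter, got {code!r}")
    up = code.upper()
    if up not in props.index:
        raise ValueError(f"unknown residue code {code!r}: not one of the 20 standard residues")
    return up


def grantham_distance(
    a: str,
    b: str,
    params: GranthamParams | None = None,
    props: pd.DataFrame | None = None,
) -> float:
    """Grantham distance between residues ``a`` and ``b`` from the formula.

    Symmetric, non-negative, zero iff ``a == b``. Gap characters, ambiguity
    codes and non-standard residues (B, Z, X, U, O) are rejected; callers
    that tolerate them must filter first.
    """
    params = params or GranthamParams()
    props = amino_acid_properties() if props is None else props
    a = _validate_residue(a, props)
    b = _validate_residue(b, props)
    ca, pa, va = props.loc[a]
    cb, pb, vb = props.loc[b]
    return float(
        params.rho
        * np.sqrt(
            params.alpha * (ca - cb) ** 2
            + params.beta * (pa - pb) ** 2
            + params.gamma * (va - vb) ** 2
        )
    )


def build_matrix(
    params: GranthamParams | None = None,
    props: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full 20x20 formula-computed distance matrix (full floating precision).

    Raises ``ValueError`` listing any residues missing from ``props``.
    """
    params = params or GranthamParams()
    props = amino_acid_properties() if props is None else props
    missing = sorted(set(AMINO_ACIDS) - set(props.index))
    if missing:
        raise ValueError(f"property table incomplete, missing residues: {', '.join(missing)}")
    aas = list(AMINO_ACIDS)
    mat = pd.DataFrame(0.0, index=aas, columns=aas)
    for x, y in itertools.combinations(aas, 2):
        d = grantham_distance(x, y, params, props)
        mat.loc[x, y] = d
        mat.loc[y, x] = d
    return mat


@functools.lru_cache(maxsize=1)
def _canonical_cached() -> pd.DataFrame:
    ref = resources.files("orsite.data").joinpath("grantham1974.json")
    data = json.loads(ref.read_text())
    aas = list(AMINO_ACIDS)
    mat = pd.DataFrame(0.0, index=aas, columns=aas)
    for key, val in data["pairs"].items():
        x, y = key[0], key[1]
        mat.loc[x, y] = float(val)
        mat.loc[y, x] = float(val)
    return mat


def canonical_matrix() -> pd.DataFrame:
    """The published 1974 integer distance table as a 20x20 DataFrame.

    This is the operational Grantham matrix used throughout the field and is
    the default for the conservation screen.
    """
    return _canonical_cached().copy()
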