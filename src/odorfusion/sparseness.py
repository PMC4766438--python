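"""Tuning-breadth statistics: lifetime/population kurtosis and sparseness.

Lifetime kurtosis (LTK) of a response profile r_1..r_M is the excess
kurtosis

    LTK = (1/M) * sum(((r_i - mean) / sd)^4) - 3

with the *population* standard deviation (divide by M).  0 corresponds to a
Gaussian response distribution; large positive values indicate a narrowly
tuned unit, negative values broad tuning.  The same formula applied across
responding units for one odorant is the population kurtosis (PK).

Lifetime sparseness (LTS) uses the Rolls-Tovee form from the sparseness
literature,

    LTS = (1 - (sum r / M)^2 / (sum r^2 / M)) / (1 - 1/M),

which lies in [0, 1] and requires non-negative responses (negatives are
rectified to 0, with a logged count).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import SCALE_SFR_RESET, ResponseMatrix
from .identifiers import SFR_KEY


class DegenerateProfileError(ValueError):
    """Kurtosis is undefined for a constant profile (sd = 0)."""


def _clean(values, min_n: int) -> np.ndarray:
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < min_n:
        raise ValueError(f"need at least {min_n} responses, got {arr.size}")
    return arr


def lifetime_kurtosis(values, sample_sd: bool = False) -> float:
    """Excess kurtosis of a response profile (missing entries dropped).

    ``sample_sd`` switches to the n-1 standard deviation for sensitivity
    checks; the default is the population convention matching the
    (1/M) sum(.)^4 - 3 form.
    """
    arr = _clean(values, 4)
    sd = arr.std(ddof=1 if sample_sd else 0)
    if sd == 0:
        raise DegenerateProfileError("degenerate profile: zero variance")
    return float(np.mean(((arr - arr.mean()) / sd) ** 4) - 3.0)


def lifetime_sparseness(values) -> tuple[float, int]:
    """Rolls-Tovee lifetime sparseness; returns (LTS, n_rectified).

    Negative responses are rectified to 0 (LTS requires non-negativity);
    the number of rectified entries is returned alongside.
    """
    arr = _clean(values, 2)
    n_rect = int(np.sum(arr < 0))
    arr = np.clip(arr, 0.0, None)
    if np.all(arr == 0):
        raise ValueError("all-zero profile: sparseness undefined")
    m = arr.size
    lts = (1.0 - (arr.sum() / m) ** 2 / (np.sum(arr**2) / m)) / (1.0 - 1.0 / m)
    return float(lts), n_rect


def population_kurtosis(
    matrix: ResponseMatrix,
    odorant: str,
    min_units: int = 39,
    sample_sd: bool = False,
) -> float | None:
    """Kurtosis of one odorant's responses across units.

    Returns None (excluded, with the count available from the matrix row)
    when the odorant was measured in fewer than ``min_units`` units --
    mirroring the convention of requiring at least half the catalogued
    units before interpreting PK.
    """
    row = matrix.values.loc[odorant].dropna()
    if row.size < min_units:
        return None
    return lifetime_kurtosis(row, sample_sd=sample_sd)


def rank_profiles_by_ltk(
    matrix: ResponseMatrix, min_n: int = 50, sample_sd: bool = False
) -> pd.DataFrame:
    """LTK ranking of all units with at least ``min_n`` odorant responses.

    Expects an SFR-reset matrix; the SFR pseudo-odorant (exactly 0 by
    construction) is excluded from both the count and the statistic.
    Sorted by LTK descending, ties broken by unit id.
    """
    if matrix.scale_state != SCALE_SFR_RESET:
        raise ValueError("rank_profiles_by_ltk expects an sfr-reset matrix")
    df = matrix.values.drop(index=SFR_KEY, errors="ignore")
    rows = []
    for unit in df.columns:
        col = df[unit].dropna()
        if col.size < min_n:
            continue
        rows.append({"unit_id": unit, "ltk": lifetime_kurtosis(col, sample_sd), "n": col.size})
    out = pd.DataFrame(rows, columns=["unit_id", "ltk", "n"])
    return out.sort_values(
        ["ltk", "unit_id"], ascending=[False, True], ignore_index=True
    )


def tuning_curve(profile: pd.Series) -> pd.DataFrame:
    """Bell arrangement of a profile: strongest odorant central.

    Odorants are sorted by descending response (ties: odorant id) and
    placed alternately right then left of the centre, producing the
    standard tuning-curve layout.  Returns columns (position, odorant,
    value), position 1..M left to right.
    """
    prof = profile.dropna()
    if prof.empty:
        raise ValueError("empty profile")
    ordered = sorted(prof.items(), key=lambda kv: (-kv[1], kv[0]))
    centre, rest = ordered[0], ordered[1:]
    left: list = []
    right: list = []
    for i, item in enumerate(rest):
        (right if i % 2 == 0 else left).append(item)
    arrangement = list(reversed(left)) + [centre] + right
    return pd.DataFrame(
        {
            "position": np.arange(1, len(arrangement) + 1),
            "odorant": [k for k, _ in arrangement],
            "value": [v for _, v in arrangement],
        }
    )
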