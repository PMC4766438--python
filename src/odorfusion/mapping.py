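"""Query tools over a consensus matrix.

* :func:`map_receptor` -- match an unknown response profile against every
  unit by Pearson correlation over shared odorants (two-sided p from the
  t-transform), flagging hits that are both significant (p < 0.05) and
  relevant (r > 0.75).
* :func:`identify_sensillum` -- given one profile per recorded neuron of a
  sensillum, rank candidate sensilla by optimally assigning recordings to
  that sensillum's units.
* :func:`private_odorant` -- find the odorant that activates a given unit
  with the largest margin over every other unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ResponseMatrix, rescale_unit_interval
from .identifiers import SFR_KEY


@dataclass
class MappingResult:
    unit_id: str
    r: float
    p: float
    n: int
    passes: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p via t = r*sqrt((n-2)/(1-r^2))."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def map_receptor(
    profile: pd.Series,
    matrix: ResponseMatrix,
    min_overlap: int = 10,
    alpha: float = 0.05,
    r_min: float = 0.75,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate a profile (keyed by InChIKey) with every unit column.

    Units sharing fewer than ``min_overlap`` measured odorants with the
    profile are omitted (reported in the ``omitted`` attribute of the
    result).  Returns a table sorted by r descending with the double
    pass criterion (p < alpha and r > r_min).
    """
    prof = profile.dropna().astype(float)
    rows: list[MappingResult] = []
    omitted: list[tuple[str, str]] = []
    for unit in matrix.units:
        col = matrix.column(unit).dropna()
        shared = prof.index.intersection(col.index)
        if len(shared) < min_overlap:
            omitted.append((unit, f"overlap {len(shared)} < {min_overlap}"))
            continue
        x = prof[shared].to_numpy()
        y = col[shared].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            omitted.append((unit, "zero variance on shared odorants"))
            continue
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
            r, p = float(r), float(p)
        else:
            r, p = _pearson(x, y)
        rows.append(
            MappingResult(
                unit_id=unit, r=r, p=p, n=len(shared), passes=(p < alpha and r > r_min)
            )
        )
    if not rows:
        raise ValueError(
            "no unit reaches the overlap minimum: "
            + "; ".join(f"{u} ({why})" for u, why in omitted)
        )
    out = pd.DataFrame([vars(m) for m in rows]).sort_values(
        ["r", "unit_id"], ascending=[False, True], ignore_index=True
    )
    out.attrs["omitted"] = omitted
    return out


def _pair_score(
    rec: pd.Series, col: pd.Series, metric: str, min_overlap: int
) -> float | None:
    shared = rec.dropna().index.intersection(col.dropna().index)
    if len(shared) < min_overlap:
        return None
    x = rec[shared].to_numpy(dtype=float)
    y = col[shared].to_numpy(dtype=float)
    if metric == "correlation":
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        return float(np.corrcoef(x, y)[0, 1])
    # euclidean on [0, 1]-rescaled profiles, RMS per odorant so that
    # scores are comparable across overlap sizes
    try:
        xs = rescale_unit_interval(x)
        ys = rescale_unit_interval(y)
    except ValueError:
        return None
    return float(np.sqrt(np.mean((xs - ys) ** 2)))


def identify_sensillum(
    recordings: dict[str, pd.Series],
    matrix: ResponseMatrix,
    unit_info: pd.DataFrame,
    metric: str = "correlation",
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Rank sensilla by how well the recorded profiles fit their units.

    For each sensillum the recordings are assigned one-to-one to the
    sensillum's responding units (exhaustively -- sensilla house at most
    four neurons) so that the mean correlation is maximal (or the mean
    rescaled Euclidean distance minimal).  Sensilla where no valid
    assignment exists are skipped with a reason.
    """
    if metric not in ("correlation", "euclidean"):
        raise ValueError(f"unknown metric: {metric}")
    maximize = metric == "correlation"
    sens_units: dict[str, list[str]] = {}
    for _, row in unit_info.iterrows():
        if row["unit_id"] in matrix.units:
            sens_units.setdefault(row["sensillum"], [])
            if row["unit_id"] not in sens_units[row["sensillum"]]:
                sens_units[row["sensillum"]].append(row["unit_id"])
    rec_ids = sorted(recordings)
    rows = []
    skipped: list[tuple[str, str]] = []
    for sensillum in sorted(sens_units):
        units = sorted(sens_units[sensillum])
        scores = {
            (rid, u): _pair_score(
                recordings[rid], matrix.column(u), metric, min_overlap
            )
            for rid in rec_ids
            for u in units
        }
        k = min(len(rec_ids), len(units))
        best_assign, best_val = None, None
        for unit_subset in itertools.permutations(units, k):
            assign = list(zip(rec_ids[:k], unit_subset))
            vals = [scores[pair] for pair in assign]
            if any(v is None for v in vals):
                continue
            mean = float(np.mean(vals))
            better = (
                best_val is None
                or (maximize and mean > best_val + 1e-15)
                or (not maximize and mean < best_val - 1e-15)
            )
            if better:
                best_assign, best_val = assign, mean
        if best_assign is None:
            skipped.append((sensillum, "no unit reaches the overlap minimum"))
            continue
        rows.append(
            {
                "sensillum": sensillum,
                "score": best_val,
                "assignment": "; ".join(f"{r}->{u}" for r, u in best_assign),
                "n_units": len(units),
            }
        )
    out = pd.DataFrame(rows, columns=["sensillum", "score", "assignment", "n_units"])
    out = out.sort_values(
        ["score", "sensillum"], ascending=[not maximize, True], ignore_index=True
    )
    out.attrs["skipped"] = skipped
    return out


def glomerulus_table(
    values: pd.Series, unit_info: pd.DataFrame
) -> pd.DataFrame:
    """Map per-unit values onto antennal-lobe glomeruli.

    ``values`` is keyed by unit id (e.g. one odorant's row of the
    consensus matrix); the result is a (glomerulus, unit_id, value) table
    suitable for external rendering.  Units without a glomerulus
    annotation are dropped.
    """
    glom = (
        unit_info[["unit_id", "glomerulus"]]
        .drop_duplicates()
        .set_index("unit_id")["glomerulus"]
    )
    rows = []
    for unit, value in values.dropna().items():
        g = glom.get(unit, "")
        if g:
            rows.append({"glomerulus": g, "unit_id": unit, "value": float(value)})
    return pd.DataFrame(rows, columns=["glomerulus", "unit_id", "value"]).sort_values(
        ["glomerulus", "unit_id"], ignore_index=True
    )


def private_odorant(
    unit_id: str,
    matrix: ResponseMatrix,
    exclude_sfr: bool = True,
) -> tuple[str, float, pd.DataFrame]:
    """Find the odorant most private to ``unit_id``.

    The specificity score of odorant o is the unit's response minus the
    maximum response of any other unit to o (computed over units with a
    measured value); the score is invariant under adding a constant to the
    whole matrix.  Returns (best odorant, score, full ranked table).
    """
    if unit_id not in matrix.units:
        raise KeyError(f"unknown unit: {unit_id}")
    df = matrix.values
    if exclude_sfr:
        df = df.drop(index=SFR_KEY, errors="ignore")
    target = df[unit_id].dropna()
    if target.empty:
        raise ValueError(f"unit {unit_id} has no non-missing responses")
    others = df.drop(columns=[unit_id])
    rows = []
    for odorant, value in target.items():
        other = others.loc[odorant].dropna()
        if other.empty:
            continue
        rows.append(
            {
                "odorant": odorant,
                "score": float(value - other.max()),
                "response": float(value),
                "max_other": float(other.max()),
            }
        )
    if not rows:
        raise ValueError("no odorant measured in any other unit")
    table = pd.DataFrame(rows).sort_values(
        ["score", "odorant"], ascending=[False, True], ignore_index=True
    )
    return table.loc[0, "odorant"], float(table.loc[0, "score"]), table
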