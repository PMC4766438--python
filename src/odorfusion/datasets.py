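"""Data model and file I/O for odorant-response datasets.

A *study dataset* holds one study's responses for one responding unit
(receptor, OSN, sensillum or glomerulus), in whatever measurement units the
study used.  Spontaneous activity (SFR) is carried as the pseudo-odorant
``"SFR"`` so the merge machinery can treat it like any other stimulus; its
value is 0 for studies that did not report it.  A *response matrix* is the
wide odorant x unit table produced by merging, with an explicit scale state.

File formats (all plain delimited text):

* dataset file: columns ``InChIKey, Name, CAS, CID, SMILES, Response``
  (identity columns other than InChIKey optional); TSV by default, CSV
  accepted.
* matrix file: wide TSV, first column ``InChIKey``, one column per unit,
  ``NA`` for missing.
* dataset.info: TSV with per-dataset metadata and duplicate-merge notes.

Numbers are written with 6 significant digits so that load -> write -> load
round-trips byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .identifiers import SFR_KEY, validate_inchikey

# canonical scale states of a ResponseMatrix
SCALE_RAW = "raw"
SCALE_UNIT = "unit-scaled"
SCALE_GLOBAL = "globally-normalized"
SCALE_SFR_RESET = "sfr-reset"


class DegenerateRangeError(ValueError):
    """Raised when a value range collapses (max == min) during rescaling."""


def format_number(x: float) -> str:
    """Canonical on-disk number format: 6 significant digits, '.' separator."""
    if pd.isna(x):
        return "NA"
    return f"{x:.6g}"


def rescale_unit_interval(values, allow_flat: bool = False):
    """Affinely map finite values onto [0, 1]: (x - min) / (max - min).

    Missing entries (NaN) are preserved.  A constant vector carries no rank
    information, so by default it is an error; ``allow_flat`` downgrades it
    to an all-zeros result.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to rescale")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        if not allow_flat:
            raise DegenerateRangeError("degenerate range: all values identical")
        out = np.where(np.isfinite(arr), 0.0, np.nan)
    else:
        out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class StudyDataset:
    """One study's raw responses for one responding unit."""

    study_id: str
    unit_id: str
    responses: pd.Series  # index: InChIKey (plus "SFR"), values: float
    sfr_reported: bool = False
    technique: str = ""
    load_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.responses.index.has_duplicates:
            raise ValueError("duplicate odorant keys in StudyDataset")
        if not np.all(np.isfinite(self.responses.to_numpy(dtype=float))):
            raise ValueError("non-finite response values")
        if SFR_KEY not in self.responses.index:
            self.responses = pd.concat(
                [self.responses, pd.Series({SFR_KEY: 0.0})]
            )
            self.sfr_reported = False
        if not self.sfr_reported and self.responses[SFR_KEY] != 0.0:
            raise ValueError("SFR must be 0 when sfr_reported is false")

    @property
    def odorants(self) -> pd.Index:
        """Chemical odorant keys (the SFR sentinel excluded)."""
        return self.responses.index[self.responses.index != SFR_KEY]

    def scaled(self, allow_flat: bool = False) -> pd.Series:
        """Responses (including SFR) rescaled to the unit interval."""
        return rescale_unit_interval(self.responses, allow_flat=allow_flat)


@dataclass
class RespondingUnitInfo:
    """Metadata of one responding unit (after the shipped unit table)."""

    unit_id: str
    receptors: list[str]
    osn: str = ""
    sensillum: str = ""
    glomerulus: str = ""


def load_unit_info(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load the responding-unit metadata table.

    Defaults to the fixture shipped with the package: one row per
    (sensillum, unit) pair with receptor, co-receptor, OSN and glomerulus
    annotations.  A unit housed in several sensilla appears once per
    sensillum.
    """
    if path is None:
        with resources.files("odorfusion.data").joinpath(
            "responding_units.tsv"
        ).open() as fh:
            return pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def unit_info_records(table: pd.DataFrame | None = None) -> dict[str, RespondingUnitInfo]:
    """Collapse the unit table to one :class:`RespondingUnitInfo` per unit."""
    if table is None:
        table = load_unit_info()
    records: dict[str, RespondingUnitInfo] = {}
    for _, row in table.iterrows():
        uid = row["unit_id"]
        if uid in records:
            if row["sensillum"] not in records[uid].sensillum.split("|"):
                records[uid].sensillum += "|" + row["sensillum"]
            continue
        records[uid] = RespondingUnitInfo(
            unit_id=uid,
            receptors=[r for r in row["receptors"].split(",") if r],
            osn=row["osn"],
            sensillum=row["sensillum"],
            glomerulus=row["glomerulus"],
        )
    return records


class MalformedIdentifierError(ValueError):
    """A dataset row carries a key that is neither an InChIKey nor 'SFR'."""


def _read_table(path_or_buf, sep: str | None) -> pd.DataFrame:
    if sep is None:
        name = getattr(path_or_buf, "name", str(path_or_buf))
        sep = "," if str(name).endswith(".csv") else "\t"
    return pd.read_csv(path_or_buf, sep=sep)


def load_dataset(
    path,
    study_id: str | None = None,
    unit_id: str | None = None,
    technique: str = "",
    sep: str | None = None,
) -> StudyDataset:
    """Load one (study, responding unit) dataset file.

    Rows sharing an InChIKey (duplicate entries of one compound, e.g. two
    CAS spellings that hash to the same structure) are collapsed to their
    arithmetic mean; every collapse is recorded in the load log.  A missing
    SFR row is inserted as 0 with ``sfr_reported=False``.
    """
    table = _read_table(path, sep)
    if "InChIKey" not in table.columns or "Response" not in table.columns:
        raise ValueError("dataset file needs 'InChIKey' and 'Response' columns")
    keys = table["InChIKey"].astype(str)
    bad = sorted(
        k for k in keys.unique() if k != SFR_KEY and not validate_inchikey(k)
    )
    if bad:
        raise MalformedIdentifierError(
            "unparseable odorant identifiers: " + ", ".join(bad)
        )
    values = pd.to_numeric(table["Response"], errors="raise").astype(float)
    if len(values) == 0:
        raise ValueError("empty dataset")
    log: list[str] = []
    grouped = values.groupby(keys, sort=False).mean()
    counts = keys.value_counts()
    for key in counts.index[counts > 1]:
        log.append(
            f"collapsed {counts[key]} rows for {key} to mean {format_number(grouped[key])}"
        )
    sfr_reported = SFR_KEY in grouped.index
    name = getattr(path, "name", str(path))
    if study_id is None or unit_id is None:
        stem = os.path.splitext(os.path.basename(str(name)))[0]
        parts = stem.split("_", 1)
        study_id = study_id or parts[0]
        unit_id = unit_id or (parts[1] if len(parts) > 1 else stem)
    # keep SFR first, chemical odorants in file order
    order = [SFR_KEY] if sfr_reported else []
    order += [k for k in keys.unique() if k != SFR_KEY]
    return StudyDataset(
        study_id=study_id,
        unit_id=unit_id,
        responses=grouped.reindex(order),
        sfr_reported=sfr_reported,
        technique=technique,
        load_log=log,
    )


def write_dataset(ds: StudyDataset, path) -> None:
    """Write a dataset in the canonical format (SFR row first, 6 sig. digits)."""
    order = [SFR_KEY] + list(ds.odorants)
    out = pd.DataFrame(
        {
            "InChIKey": order,
            "Response": [format_number(ds.responses[k]) for k in order],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_dataset_info(datasets: Iterable[StudyDataset], path) -> None:
    """Write the dataset.info companion table."""
    rows = []
    for ds in datasets:
        rows.append(
            {
                "study_id": ds.study_id,
                "unit_id": ds.unit_id,
                "technique": ds.technique,
                "sfr_reported": ds.sfr_reported,
                "n_odorants": len(ds.odorants),
                "notes": "; ".join(ds.load_log),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ResponseMatrix:
    """Odorant x responding-unit response grid with an explicit scale state."""

    values: pd.DataFrame  # index: InChIKey (+ SFR), columns: unit ids
    scale_state: str = SCALE_RAW
    normalization_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate odorants or units in ResponseMatrix")

    @property
    def odorants(self) -> list[str]:
        return list(self.values.index)

    @property
    def units(self) -> list[str]:
        return list(self.values.columns)

    def column(self, unit_id: str) -> pd.Series:
        return self.values[unit_id]


def reset_sfr(matrix: ResponseMatrix) -> ResponseMatrix:
    """Subtract each unit's SFR value from all its responses.

    Restores negative values for inhibitory odorants; the SFR row becomes
    exactly 0.  Idempotent.
    """
    if matrix.scale_state not in (SCALE_UNIT, SCALE_GLOBAL, SCALE_SFR_RESET):
        raise ValueError("reset_sfr expects a scaled matrix")
    df = matrix.values.copy()
    if SFR_KEY not in df.index:
        df.loc[SFR_KEY] = 0.0
    sfr = df.loc[SFR_KEY].fillna(0.0)
    df = df.sub(sfr, axis=1)
    df.loc[SFR_KEY] = 0.0
    return ResponseMatrix(
        values=df,
        scale_state=SCALE_SFR_RESET,
        normalization_flags=dict(matrix.normalization_flags),
    )


def write_matrix(matrix: ResponseMatrix, path) -> None:
    out = matrix.values.map(format_number)
    out.index.name = "InChIKey"
    out.to_csv(path, sep="\t")


def load_matrix(path, scale_state: str = SCALE_UNIT) -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col="InChIKey", na_values=["NA"])
    return ResponseMatrix(values=df.astype(float), scale_state=scale_state)
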