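"""Odorant identity: InChIKey validation and local identifier translation.

InChIKeys (the 27-character hashed form of the IUPAC InChI) are the primary
odorant keys throughout the package.  Other identifier schemes (trivial
names, CAS registry numbers, PubChem CIDs, SMILES) are ambiguous -- e.g. a
single compound may carry several CAS numbers -- so they are carried only as
annotations and resolved through a small lookup table shipped with the
package.  No network service is consulted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Reserved pseudo-odorant key for spontaneous (baseline) activity.
SFR_KEY = "SFR"

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def validate_inchikey(s: str) -> bool:
    """Return True iff ``s`` is syntactically a standard InChIKey.

    The reserved sentinel ``"SFR"`` is *not* a chemical identifier and
    returns False; dataset loaders accept it separately.
    """
    return bool(_INCHIKEY_RE.match(s)) if isinstance(s, str) else False


@dataclass(frozen=True)
class OdorantID:
    """One odorant's identity record.  ``inchikey`` is the primary key."""

    inchikey: str
    name: str = ""
    cas: str | None = None
    cid: int | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not validate_inchikey(self.inchikey):
            raise ValueError(f"invalid InChIKey: {self.inchikey!r}")


def _load_lookup() -> pd.DataFrame:
    with resources.files("odorfusion.data").joinpath("odorants.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    return table


_LOOKUP_CACHE: pd.DataFrame | None = None


def identifier_table() -> pd.DataFrame:
    """The shipped InChIKey <-> name/CAS/CID/SMILES lookup table."""
    global _LOOKUP_CACHE
    if _LOOKUP_CACHE is None:
        _LOOKUP_CACHE = _load_lookup()
    return _LOOKUP_CACHE.copy()


def translate_id(value: str, source: str = "inchikey", target: str = "name") -> list[str]:
    """Translate an identifier via the local lookup table.

    ``source`` / ``target`` are column names of :func:`identifier_table`
    (``inchikey``, ``name``, ``cas``, ``cid``, ``smiles``).  A CAS cell may
    hold several registry numbers separated by ``|`` (CAS numbers are
    non-unique); each is matched individually.  Returns every match --
    conflicting mappings are surfaced rather than silently collapsed.
    """
    table = identifier_table()
    if source not in table.columns or target not in table.columns:
        raise KeyError(f"unknown identifier column: {source!r} or {target!r}")
    if source == "cas":
        mask = table["cas"].map(lambda c: value in c.split("|") if c else False)
    else:
        mask = table[source] == value
    hits = [v for v in table.loc[mask, target] if v]
    out: list[str] = []
    for h in hits:  # preserve order, drop duplicates
        if h not in out:
            out.append(h)
    return out
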