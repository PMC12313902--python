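"""Packaged reference dataset: 17 bladder-cancer drugs.

Two CSV fixtures ship with the package: ``properties.csv`` with seven
physicochemical properties per drug (boiling point BP, enthalpy of
vaporization EV, flash point FP, molar refractivity MR, polar surface area
SA, molar volume MV, polarizability P; units as tabulated by the source,
treated as consistent arbitrary units) and ``descriptors.csv`` with the ten
degree-based topological indices per drug.

One descriptor cell (Axitinib's forgotten index F) is not printed in the
source table and is reconstructed through the exact identity
HZ = F + 2*M2; it is flagged in the ``reconstructed`` column.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .graph import EdgePartition
from .indices import INDEX_NAMES, DescriptorVector

__all__ = ["PROPERTY_NAMES", "DrugRecord", "load_drug_table",
           "load_properties", "load_descriptors", "lenalidomide_partition",
           "validate_descriptor_table"]

PROPERTY_NAMES: tuple[str, ...] = ("BP", "EV", "FP", "MR", "SA", "MV", "P")

N_DRUGS = 17


@dataclass(frozen=True)
class DrugRecord:
    name: str
    properties: dict[str, float]
    descriptors: DescriptorVector
    reconstructed: tuple[str, ...] = ()


def _read_csv(fname: str) -> pd.DataFrame:
    with resources.files("topoqspr.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def load_properties() -> pd.DataFrame:
    """Property table indexed by drug name (17 rows x 7 columns)."""
    df = _read_csv("properties.csv").set_index("name")
    _check_shape(df, list(PROPERTY_NAMES))
    return df


def load_descriptors() -> pd.DataFrame:
    """Descriptor table indexed by drug name (17 rows x 10 index columns)."""
    df = _read_csv("descriptors.csv").set_index("name")
    out = df[list(INDEX_NAMES)].astype(float)
    _check_shape(out, list(INDEX_NAMES))
    return out


def _check_shape(df: pd.DataFrame, cols: list[str]) -> None:
    if len(df) != N_DRUGS:
        raise ValueError(f"fixture corruption: expected {N_DRUGS} drugs, "
                         f"found {len(df)}")
    if df[cols].isna().any().any():
        raise ValueError("fixture corruption: missing values")


def load_drug_table() -> list[DrugRecord]:
    """All 17 drugs, in the reference row order (Lenalidomide first)."""
    props = load_properties()
    raw = _read_csv("descriptors.csv").set_index("name")
    records = []
    for name in props.index:
        desc = DescriptorVector(**{n: float(raw.loc[name, n])
                                   for n in INDEX_NAMES})
        flagged = raw.loc[name, "reconstructed"]
        flagged = () if pd.isna(flagged) else tuple(str(flagged).split(";"))
        records.append(DrugRecord(
            name=name,
            properties={p: float(props.loc[name, p]) for p in PROPERTY_NAMES},
            descriptors=desc,
            reconstructed=flagged,
        ))
    return records


def lenalidomide_partition() -> EdgePartition:
    """Edge partition of the Lenalidomide heavy-atom graph (21 edges)."""
    return EdgePartition({(1, 3): 4, (2, 2): 3, (2, 3): 8, (3, 3): 6})


def validate_descriptor_table(tolerance: float = 1.0) -> pd.DataFrame:
    """Per-drug integrity report for the packaged descriptor table.

    Checks the exact identity HZ = F + 2*M2 within ``tolerance`` (the table
    is printed at 4 decimals, so |HZ - F - 2*M2| <= 1 allows rounding), and
    strict positivity of every descriptor.  Returns a report frame; never
    raises on a violation.
    """
    rows = []
    for rec in load_drug_table():
        d = rec.descriptors
        gap = d.HZ - d.F - 2.0 * d.M2
        rows.append({
            "name": rec.name,
            "identity_gap": gap,
            "identity_ok": abs(gap) <= tolerance,
            "all_positive": all(v > 0 for v in d.as_tuple()),
            "reconstructed": ";".join(rec.reconstructed),
        })
    return pd.DataFrame(rows).set_index("name")
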