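"""Specimen records and the derived mandibular-motion predictors.

Each museum specimen carries its tooth-row OPCR values plus four
measurements of mandibular motion taken from reconstructed occlusion:
lateral translation t (mm), ventral rotational distance d (mm), sagittal
occlusal angle a (degrees from vertical) and glenoid fossae width w (mm,
a body-size proxy).  The statistics operate on size-corrected, natural
log transformed quantities:

    rt = ln(t / w)      relative lateral translation
    rd = ln(d / w)      relative ventral rotational distance
    ln_a = ln(a)
    ln_upper, ln_lower = ln(tooth-row OPCR)

The sagittal angle is kept strictly as a measured input; it is never
recomputed from t and d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "SchemaError",
    "SpecimenRecord",
    "DerivedMeasures",
    "derive_measures",
    "load_specimen_table",
    "records_to_frame",
    "derived_frame",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "order_name", "family", "genus", "species", "collection", "number",
    "n_upper_teeth", "n_lower_teeth", "upper_opcr", "lower_opcr",
    "t", "d", "a", "w",
)


class SchemaError(ValueError):
    """Specimen table does not match the expected schema."""


@dataclass
class SpecimenRecord:
    order_name: str
    family: str
    genus: str
    species: str
    collection: str
    number: str
    n_upper_teeth: int
    n_lower_teeth: int
    upper_opcr: float
    lower_opcr: float
    t: float  # lateral translation, mm
    d: float  # ventral rotational distance, mm
    a: float  # sagittal occlusal angle, degrees
    w: float  # glenoid fossae width, mm

    def __post_init__(self) -> None:
        for name in ("t", "d", "w", "upper_opcr", "lower_opcr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"specimen field '{name}' must be positive")
        if not 0 < self.a < 90:
            raise ValueError("specimen field 'a' must lie in (0, 90) degrees")
        for name in ("n_upper_teeth", "n_lower_teeth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"specimen field '{name}' must be >= 1")


@dataclass
class DerivedMeasures:
    ln_upper: float
    ln_lower: float
    rt: float
    rd: float
    ln_a: float
    avg_upper: float
    avg_lower: float


def derive_measures(rec: SpecimenRecord) -> DerivedMeasures:
    """Log-transformed, size-corrected measures of one specimen."""
    return DerivedMeasures(
        ln_upper=math.log(rec.upper_opcr),
        ln_lower=math.log(rec.lower_opcr),
        rt=math.log(rec.t / rec.w),
        rd=math.log(rec.d / rec.w),
        ln_a=math.log(rec.a),
        avg_upper=rec.upper_opcr / rec.n_upper_teeth,
        avg_lower=rec.lower_opcr / rec.n_lower_teeth,
    )


def load_specimen_table(path_or_name="table1") -> list[SpecimenRecord]:
    """Load a specimen CSV; the name ``"table1"`` loads the packaged
    34-specimen fixture (20 Carnivora, 14 Dasyuromorphia)."""
    if str(path_or_name) == "table1":
        src = resources.files("dentaltopo").joinpath("data/table1.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path_or_name)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"specimen table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SpecimenRecord(
                order_name=str(row["order_name"]), family=str(row["family"]),
                genus=str(row["genus"]), species=str(row["species"]),
                collection=str(row["collection"]), number=str(row["number"]),
                n_upper_teeth=int(row["n_upper_teeth"]),
                n_lower_teeth=int(row["n_lower_teeth"]),
                upper_opcr=float(row["upper_opcr"]), lower_opcr=float(row["lower_opcr"]),
                t=float(row["t"]), d=float(row["d"]), a=float(row["a"]), w=float(row["w"]),
            ))
        except (TypeError, ValueError) as e:
            raise SchemaError(f"specimen row {i}: {e}") from e
    return records


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def derived_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    """One row per specimen: raw columns plus all derived measures."""
    raw = records_to_frame(records)
    der = pd.DataFrame([vars(derive_measures(r)) for r in records])
    return pd.concat([raw, der], axis=1)
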