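"""Biophysical input measurements for rate inference.

The model is parameterized by three FRAP/abundance quantities per protein:
absolute nuclear copy number, chromatin-bound fraction and mean chromatin
residence time, measured in unperturbed (wild-type) HeLa cells.  The builtin
``hela_wt`` table ships these literature-curated values; users may override
them from a CSV/TSV table with columns ``species, copies, bound_fraction,
residence_s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SPECIES = ("RAD21", "NIPBL", "WAPL", "PDS5")


@dataclass(frozen=True)
class ProteinMeasurement:
    """Copy number, bound fraction and residence time of one protein."""

    species: str
    copy_number: float
    bound_fraction: float
    residence_time: float  # seconds

    def __post_init__(self):
        if self.copy_number <= 0:
            raise ValueError(f"{self.species}: copy number must be > 0")
        if not 0.0 < self.bound_fraction < 1.0:
            raise ValueError(f"{self.species}: bound fraction must lie in (0, 1)")
        if self.residence_time <= 0:
            raise ValueError(f"{self.species}: residence time must be > 0")

    @property
    def bound_copies(self) -> float:
        return self.copy_number * self.bound_fraction


class MeasurementSet(dict):
    """Mapping species name -> :class:`ProteinMeasurement` (one per species)."""

    def __init__(self, measurements):
        entries = {m.species: m for m in measurements}
        if len(entries) != len(list(measurements)):
            raise ValueError("duplicate species in measurement set")
        missing = set(SPECIES) - set(entries)
        if missing:
            raise ValueError(f"missing measurements for {sorted(missing)}")
        super().__init__(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": m.species,
                    "copies": m.copy_number,
                    "bound_fraction": m.bound_fraction,
                    "residence_s": m.residence_time,
                }
                for m in self.values()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeasurementSet":
        return cls(
            [
                ProteinMeasurement(
                    str(row["species"]),
                    float(row["copies"]),
                    float(row["bound_fraction"]),
                    float(row["residence_s"]),
                )
                for _, row in df.iterrows()
            ]
        )

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))


#: Literature-curated wild-type HeLa values (copies/nucleus, bound fraction,
#: mean residence time in seconds), averaging mass-spectrometry and FCS
#: abundance estimates and FRAP binding kinetics; PDS5A and PDS5B amalgamated.
HELA_WT = MeasurementSet(
    [
        ProteinMeasurement("RAD21", 264_000, 0.65, 822.0),
        ProteinMeasurement("NIPBL", 111_000, 0.40, 72.0),
        ProteinMeasurement("WAPL", 65_000, 0.35, 45.0),
        ProteinMeasurement("PDS5", 164_000, 0.45, 70.0),
    ]
)


def load_measurements(source="hela_wt") -> MeasurementSet:
    """Resolve a measurement source: builtin name, path, or MeasurementSet."""
    if isinstance(source, MeasurementSet):
        return source
    if source == "hela_wt":
        return HELA_WT
    if isinstance(source, (str, Path)) and Path(source).exists():
        return MeasurementSet.from_csv(source)
    raise ValueError(f"unknown measurement source {source!r}")
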