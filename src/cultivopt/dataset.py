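"""Treatment-level growth dataset: container, packaged fixture, CSV I/O.

The packaged fixture is the 66-treatment light × sucrose micropropagation
experiment: 22 distinct LED spectra (blue/red/white/far-red channels, each
0–100 μmol/m²/s) crossed with sucrose at 1, 3 and 6 % (w/v), with five
growth traits recorded as mean ± SE over 4 replicate plantlets per treatment
(264 plantlets in total).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed input-column order used by every design matrix in the package.
INPUT_NAMES: tuple[str, ...] = ("blue", "red", "white", "far_red", "sucrose")

#: Fixed trait order: shoot length (mm), root length (mm), node number,
#: shoot number, canopy surface area (mm²).
TRAITS: tuple[str, ...] = (
    "shoot_length",
    "root_length",
    "node_number",
    "shoot_number",
    "canopy_area",
)

#: Input-box bounds: irradiance channels in [0, 100] μmol/m²/s, sucrose in
#: [1, 6] % (w/v).
INPUT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 100.0),
    (0.0, 100.0),
    (0.0, 100.0),
    (0.0, 100.0),
    (1.0, 6.0),
)

_FIXTURE_NAME = "table1.csv"


class DatasetError(ValueError):
    """Raised for schema violations, out-of-range values or a bad fixture."""


@dataclass(frozen=True)
class Treatment:
    """One combination of light-channel irradiances and sucrose level."""

    blue: float
    red: float
    white: float
    far_red: float
    sucrose: float

    def __post_init__(self) -> None:
        for name in ("blue", "red", "white", "far_red"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DatasetError(
                    f"{name} irradiance {v} outside [0, 100] μmol/m²/s"
                )
        if not 1.0 <= self.sucrose <= 6.0:
            raise DatasetError(f"sucrose {self.sucrose} outside [1, 6] % (w/v)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.blue, self.red, self.white, self.far_red, self.sucrose]
        )

    @property
    def spectrum(self) -> tuple[float, float, float, float]:
        """Light-channel part of the treatment (sucrose excluded)."""
        return (self.blue, self.red, self.white, self.far_red)


@dataclass(frozen=True)
class TreatmentRecord:
    """Per-treatment trait means and standard errors over replicates."""

    treatment: Treatment
    trait_means: Mapping[str, float]
    trait_ses: Mapping[str, float]
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise DatasetError("n_replicates must be positive")
        missing = set(self.trait_means) ^ set(self.trait_ses)
        if missing:
            raise DatasetError(f"mean/SE trait sets differ: {sorted(missing)}")
        for t, m in self.trait_means.items():
            if m < 0:
                raise DatasetError(f"negative mean for {t}: {m}")
            if self.trait_ses[t] < 0:
                raise DatasetError(f"negative SE for {t}")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(t for t in TRAITS if t in self.trait_means) or tuple(
            self.trait_means
        )


@dataclass(frozen=True)
class GrowthDataset:
    """Ordered collection of treatment records sharing one trait set."""

    records: tuple[TreatmentRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetError("dataset must contain at least one record")
        keys = [r.treatment for r in self.records]
        if len(set(keys)) != len(keys):
            raise DatasetError("duplicate treatment keys in dataset")
        trait_sets = {r.traits for r in self.records}
        if len(trait_sets) != 1:
            raise DatasetError("records carry inconsistent trait sets")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def traits(self) -> tuple[str, ...]:
        return self.records[0].traits

    @property
    def n_spectra(self) -> int:
        return len({r.treatment.spectrum for r in self.records})

    @property
    def n_plantlets(self) -> int:
        return sum(r.n_replicates for r in self.records)

    def get(self, treatment: Treatment) -> TreatmentRecord:
        for r in self.records:
            if r.treatment == treatment:
                return r
        raise KeyError(treatment)

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-treatment view (mean_<trait>/se_<trait>)."""
        rows = []
        for r in self.records:
            row: dict[str, float] = dict(
                zip(INPUT_NAMES, r.treatment.as_array())
            )
            row["n"] = r.n_replicates
            for t in r.traits:
                row[f"mean_{t}"] = r.trait_means[t]
                row[f"se_{t}"] = r.trait_ses[t]
            rows.append(row)
        return pd.DataFrame(rows)


def _dataset_from_wide(df: pd.DataFrame, source: str) -> GrowthDataset:
    for col in INPUT_NAMES:
        if col not in df.columns:
            raise DatasetError(f"{source}: missing required column '{col}'")
    traits = [
        c[len("mean_"):] for c in df.columns if c.startswith("mean_")
    ]
    if not traits:
        raise DatasetError(f"{source}: no mean_<trait> columns found")
    records = []
    for i, row in df.iterrows():
        try:
            tr = Treatment(*(float(row[c]) for c in INPUT_NAMES))
            rec = TreatmentRecord(
                treatment=tr,
                trait_means={t: float(row[f"mean_{t}"]) for t in traits},
                trait_ses={t: float(row[f"se_{t}"]) for t in traits},
                n_replicates=int(row["n"]) if "n" in df.columns else 4,
            )
        except DatasetError as exc:
            raise DatasetError(f"{source}: row {i}: {exc}") from exc
        records.append(rec)
    return GrowthDataset(tuple(records))


def load_table1() -> GrowthDataset:
    """Load the packaged 66-treatment fixture.

    Raises
    ------
    DatasetError
        If the packaged file is missing or fails validation.
    """
    ref = resources.files("cultivopt.data").joinpath(_FIXTURE_NAME)
    try:
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise DatasetError(f"packaged fixture {_FIXTURE_NAME} not found") from exc
    ds = _dataset_from_wide(df, _FIXTURE_NAME)
    if len(ds) != 66:
        raise DatasetError(
            f"corrupt fixture {_FIXTURE_NAME}: expected 66 records, got {len(ds)}"
        )
    return ds


def trait_matrix(
    dataset: GrowthDataset, trait: str
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and target vector for one trait.

    Columns follow :data:`INPUT_NAMES`; row order follows the dataset.
    """
    if trait not in dataset.traits:
        raise DatasetError(
            f"unknown trait '{trait}'; valid traits: {list(dataset.traits)}"
        )
    X = np.stack([r.treatment.as_array() for r in dataset.records])
    y = np.array([r.trait_means[trait] for r in dataset.records])
    return X, y


def trait_extremes(dataset: GrowthDataset) -> pd.DataFrame:
    """Per-trait argmax/argmin over observed treatment means.

    Ties are broken by the first record in dataset order; exact zeros count
    toward the minimum.
    """
    rows = []
    for t in dataset.traits:
        means = np.array([r.trait_means[t] for r in dataset.records])
        imax = int(np.argmax(means))
        imin = int(np.argmin(means))
        rows.append(
            {
                "trait": t,
                "argmax": dataset.records[imax].treatment,
                "max": float(means[imax]),
                "argmin": dataset.records[imin].treatment,
                "min": float(means[imin]),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


LONG_COLUMNS = ("blue", "red", "white", "far_red", "sucrose", "trait", "mean", "se", "n")


def write_csv(
    path: str | Path, dataset: GrowthDataset, layout: str = "long"
) -> None:
    """Write a dataset as CSV.

    ``layout='long'`` emits one row per (treatment, trait) with columns
    ``blue,red,white,far_red,sucrose,trait,mean,se,n``; ``layout='wide'``
    emits one row per treatment with ``mean_<trait>``/``se_<trait>`` columns.
    Values round-trip at full float precision.
    """
    path = Path(path)
    if layout == "wide":
        df = dataset.to_frame()
    elif layout == "long":
        rows = []
        for r in dataset.records:
            base = dict(zip(INPUT_NAMES, r.treatment.as_array()))
            for t in r.traits:
                rows.append(
                    {
                        **base,
                        "trait": t,
                        "mean": r.trait_means[t],
                        "se": r.trait_ses[t],
                        "n": r.n_replicates,
                    }
                )
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    else:
        raise DatasetError(f"unknown layout '{layout}' (use 'long' or 'wide')")
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str | Path) -> GrowthDataset:
    """Read a dataset written by :func:`write_csv` (either layout)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "trait" in df.columns:  # long layout
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"{path.name}: missing columns {missing}")
        records = []
        grouped = df.groupby(list(INPUT_NAMES), sort=False)
        for key, g in grouped:
            try:
                tr = Treatment(*(float(v) for v in key))
                rec = TreatmentRecord(
                    treatment=tr,
                    trait_means=dict(zip(g["trait"], g["mean"].astype(float))),
                    trait_ses=dict(zip(g["trait"], g["se"].astype(float))),
                    n_replicates=int(g["n"].iloc[0]),
                )
            except DatasetError as exc:
                idx = int(g.index[0])
                raise DatasetError(f"{path.name}: row {idx}: {exc}") from exc
            records.append(rec)
        return GrowthDataset(tuple(records))
    return _dataset_from_wide(df, path.name)
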