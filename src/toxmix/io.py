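"""CSV schemas and validated readers/writers for the pipeline.

Three input schemas are supported, all concentrations in mg L^-1:

* ``singles.csv``   — compound,conc_mg_L,n_exposed,n_dead,replicate
* ``mixtures.csv``  — compound_a,compound_b,tu_a,tu_b,obs_mean_pct,obs_sd_pct,n_reps
* ``biomarkers.csv``— endpoint,treatment,bio_replicate,tech_replicate,value,unit

Readers validate headers and numeric cells with row-addressed errors;
writers serialize at full precision so a write -> read round trip is
value-exact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dose_response import MortalityRecord
from .exceptions import SchemaError
from .toxic_units import MixtureTrial

__all__ = [
    "read_singles",
    "read_mixtures",
    "read_biomarkers",
    "write_table",
    "SINGLES_COLUMNS",
    "MIXTURES_COLUMNS",
    "BIOMARKERS_COLUMNS",
]

SINGLES_COLUMNS = ("compound", "conc_mg_L", "n_exposed", "n_dead", "replicate")
MIXTURES_COLUMNS = (
    "compound_a",
    "compound_b",
    "tu_a",
    "tu_b",
    "obs_mean_pct",
    "obs_sd_pct",
    "n_reps",
)
BIOMARKERS_COLUMNS = (
    "endpoint",
    "treatment",
    "bio_replicate",
    "tech_replicate",
    "value",
    "unit",
)


def _load(path, required, numeric) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no records")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: malformed numeric cell in column {col!r}, row(s) {list(bad + 2)}"
            )
        if coerced.isna().any():
            raise SchemaError(f"{path}: empty cell in numeric column {col!r}")
        df[col] = coerced
    return df


def read_singles(path) -> list[MortalityRecord]:
    """Read single-compound acute records; all compounds in one file."""
    df = _load(path, SINGLES_COLUMNS, ("conc_mg_L", "n_exposed", "n_dead"))
    return [
        MortalityRecord(
            compound=str(r.compound),
            concentration=float(r.conc_mg_L),
            n_exposed=int(r.n_exposed),
            n_dead=int(r.n_dead),
            replicate_id=str(r.replicate),
        )
        for r in df.itertuples()
    ]


def read_mixtures(path) -> tuple[tuple[str, str], list[MixtureTrial]]:
    """Read mixture-trial summaries; one component pair per file."""
    df = _load(
        path, MIXTURES_COLUMNS, ("tu_a", "tu_b", "obs_mean_pct", "obs_sd_pct", "n_reps")
    )
    pairs = df[["compound_a", "compound_b"]].drop_duplicates()
    if len(pairs) != 1:
        raise SchemaError(f"{path}: expected one component pair, found {len(pairs)}")
    trials = [
        MixtureTrial(
            tu_a=float(r.tu_a),
            tu_b=float(r.tu_b),
            observed_mean=float(r.obs_mean_pct),
            observed_sd=float(r.obs_sd_pct),
            n_replicates=int(r.n_reps),
        )
        for r in df.itertuples()
    ]
    first = pairs.iloc[0]
    return (str(first.compound_a), str(first.compound_b)), trials


def read_biomarkers(path) -> pd.DataFrame:
    """Read the long-format biomarker file (validated, otherwise as-is)."""
    return _load(path, BIOMARKERS_COLUMNS, ("value",))


def write_table(df: pd.DataFrame, path) -> None:
    """Write a report table at full float precision (round-trip exact)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
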