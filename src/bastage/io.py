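"""File formats and run configuration for the staging pipeline.

Two plain-text inputs drive every run:

* **expression TSV** — tab-delimited, first column probe IDs, header row
  sample IDs, remaining cells log2 intensities (decimal point);
* **sample CSV** — comma-delimited per-sample metadata with histology
  scores (0-3), age at surgery in days, categorical covariates, and the
  two-year outcome (follow-up months + transplant/death event flag).

Validation is strict: duplicate IDs, non-numeric expression cells,
out-of-range scores and unknown category levels are rejected with
messages naming the offending value.  Missing metadata values stay as
explicit empty cells; nothing is imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "inflammation_grade",
    "fibrosis_stage",
    "age_days",
    "sex",
    "clinical_type",
    "cholangitis",
    "ascites",
    "followup_months",
    "event",
)

VOCABULARIES = {
    "sex": {"female", "male"},
    "clinical_type": {"perinatal", "BASM"},
    "cholangitis": {0, 1},
    "ascites": {0, 1},
    "event": {0, 1},
}


class FormatError(ValueError):
    """Malformed input file."""


def read_expression_tsv(path: "str | Path") -> pd.DataFrame:
    """Read a probes x samples log2 expression matrix.

    Returns a float DataFrame with probe IDs as index and sample IDs as
    columns.  Duplicated IDs and non-numeric cells are rejected with
    coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dup_samples = sorted({h for h in header if h in seen or seen.add(h)})
    if dup_samples:
        raise FormatError(f"{path}: duplicated sample IDs: {dup_samples}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    dup_probes = df.index[df.index.duplicated()].unique().tolist()
    if dup_probes:
        raise FormatError(f"{path}: duplicated probe IDs: {dup_probes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    numeric.index.name = "probe_id"
    return numeric.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: "str | Path") -> None:
    matrix.to_csv(Path(path), sep="\t")


def read_sample_table(path: "str | Path") -> pd.DataFrame:
    """Read and validate the per-sample metadata CSV.

    Extra columns (e.g. the simulator's truth columns) pass through
    untouched; required columns are typed and range-checked.  Missing
    values in non-key columns are kept as NaN.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicated sample IDs: {dup}")
    for col in ("inflammation_grade", "fibrosis_stage"):
        values = df[col].dropna()
        bad = values[~values.isin([0, 1, 2, 3])]
        if not bad.empty:
            raise FormatError(
                f"{path}: {col} must be in 0..3, got {bad.iloc[0]!r} "
                f"for sample {df.loc[bad.index[0], 'sample_id']!r}"
            )
    for col, vocab in VOCABULARIES.items():
        values = df[col].dropna()
        bad = values[~values.isin(list(vocab))]
        if not bad.empty:
            raise FormatError(
                f"{path}: {col} value {bad.iloc[0]!r} not in {sorted(map(str, vocab))} "
                f"for sample {df.loc[bad.index[0], 'sample_id']!r}"
            )
    for col in ("age_days", "followup_months"):
        values = pd.to_numeric(df[col], errors="coerce")
        neg = df.loc[values < 0, "sample_id"]
        if not neg.empty:
            raise FormatError(f"{path}: negative {col} for sample {neg.iloc[0]!r}")
        df[col] = values
    return df


def write_sample_table(samples: pd.DataFrame, path: "str | Path") -> None:
    samples.to_csv(Path(path), index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (flat YAML key-value file on disk)."""

    expression_tsv: str
    sample_csv: str
    output_dir: str
    histology_threshold: int = 2
    fc_threshold: float = 2.0
    alpha: float = 0.05
    fdr: float = 0.05
    priors: str = "empirical"
    m_variant: str = "plus"
    delta_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    repetitions: int = 10
    folds: int = 10
    vote_threshold: int = 6
    external_vote_mode: str = "fold_majority"
    rng_seed: int = 0
    censor_months: float = 24.0

    def validate(self) -> None:
        if self.histology_threshold not in (1, 2, 3):
            raise FormatError("histology_threshold must be in {1, 2, 3}")
        if self.fc_threshold <= 0:
            raise FormatError("fc_threshold must be positive")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise FormatError(f"{name} must be in (0, 1), got {v}")
        if not 1 <= self.vote_threshold <= self.repetitions:
            raise FormatError("vote_threshold must be in 1..repetitions")
        if 0.0 not in self.delta_grid:
            raise FormatError("delta_grid must include 0")
        if self.censor_months <= 0:
            raise FormatError("censor_months must be positive")


def load_pipeline_config(path: "str | Path") -> PipelineConfig:
    """Parse a flat YAML key-value file into a PipelineConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "delta_grid" in raw:
        raw["delta_grid"] = tuple(float(x) for x in raw["delta_grid"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_pipeline_config(config: PipelineConfig, path: "str | Path") -> None:
    payload = dataclasses.asdict(config)
    payload["delta_grid"] = list(config.delta_grid)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
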