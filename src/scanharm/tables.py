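"""Typed subject tables and model-bundle persistence.

A cohort table is a pandas DataFrame with canonical metadata columns
(``subject_id``, ``scanner``, ``age``, ``sex``, ``tiv``), raw ROI volume
columns in mm^3, optional relative-volume columns (prefixed
``relvol.``), IQM columns, and optional quality-probability columns.
All access is by column name; a :class:`TableSchema` maps user headers
to the canonical roles.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: prefix for relative-volume columns inside the flat DataFrame
REL_PREFIX = "relvol."

CANONICAL_COLS = ("subject_id", "scanner", "age", "sex", "tiv")
QC_PROB_COLS = ("qc_prob_image", "qc_prob_seg")

BUNDLE_FORMAT_VERSION = "1.0"


class SchemaError(ValueError):
    """A required column is missing or a value cannot be interpreted."""


@dataclass(frozen=True)
class TableSchema:
    """Maps the columns of a user file onto canonical roles.

    ``roi_columns=None`` means: every numeric column that is not a
    metadata, IQM, or quality column is treated as a raw ROI volume.
    """

    subject_id: str = "subject_id"
    scanner: str = "scanner"
    age: str = "age"
    sex: str = "sex"
    tiv: str = "tiv"
    qc_prob_image: str | None = None
    qc_prob_seg: str | None = None
    sex_levels: Mapping[Any, int] = field(
        default_factory=lambda: {"F": 0, "M": 1, "0": 0, "1": 1, 0: 0, 1: 1}
    )
    roi_columns: Sequence[str] | None = None
    iqm_columns: Sequence[str] = ()


@dataclass
class CohortTable:
    """One row per subject; columns addressed by name, never position."""

    data: pd.DataFrame
    roi_cols: tuple[str, ...]
    iqm_cols: tuple[str, ...] = ()
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roi_cols = tuple(self.roi_cols)
        self.iqm_cols = tuple(self.iqm_cols)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def scanners(self) -> list[str]:
        return sorted(self.data["scanner"].unique().tolist())

    def scanner_sizes(self) -> dict[str, int]:
        return self.data["scanner"].value_counts().to_dict()

    @staticmethod
    def rel_col(roi: str) -> str:
        return REL_PREFIX + roi

    @property
    def rel_cols(self) -> tuple[str, ...]:
        return tuple(self.rel_col(r) for r in self.roi_cols)

    @property
    def has_relative(self) -> bool:
        return all(c in self.data.columns for c in self.rel_cols)

    def relative_volumes(self) -> pd.DataFrame:
        """Relative volumes as a subject-indexed frame with plain ROI names."""
        if not self.has_relative:
            raise ValueError("relative volumes not computed; run qc.compute_relative_volumes")
        out = self.data.set_index("subject_id")[list(self.rel_cols)].copy()
        out.columns = list(self.roi_cols)
        return out

    def with_relative_volumes(self, rel: pd.DataFrame) -> "CohortTable":
        """Return a copy whose relative-volume columns are replaced by ``rel``
        (subject-indexed frame with plain ROI names). Raw ROI volumes are
        rescaled to ``rel * tiv`` so the table invariant keeps holding."""
        new = self.copy()
        aligned = rel.loc[new.data["subject_id"].to_numpy()]
        tiv = new.data["tiv"].to_numpy(float)
        for roi in self.roi_cols:
            vals = aligned[roi].to_numpy(float)
            new.data[self.rel_col(roi)] = vals
            if roi in new.data.columns:
                new.data[roi] = vals * tiv
        return new

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.roi_cols, self.iqm_cols, dict(self.meta))

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            self.roi_cols,
            self.iqm_cols,
            dict(self.meta),
        )

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        d = self.data
        if d["subject_id"].duplicated().any():
            dup = d.loc[d["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if d["scanner"].isna().any() or (d["scanner"].astype(str).str.len() == 0).any():
            raise ValueError("every row must carry a non-empty scanner label")
        if self.has_relative and all(r in d.columns for r in self.roi_cols):
            raw = d[list(self.roi_cols)].to_numpy(float)
            tiv = d["tiv"].to_numpy(float)[:, None]
            rel = d[list(self.rel_cols)].to_numpy(float)
            expected = raw / tiv
            scale = np.maximum(np.abs(expected), 1.0)
            if not np.all(np.abs(rel - expected) <= 1e-12 * scale):
                raise ValueError("relative_volumes inconsistent with roi_volumes / tiv")


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    if path.suffix.lower() in (".tsv", ".txt"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_cohort_table(
    path: str | Path,
    schema: TableSchema | None = None,
    sep: str | None = None,
) -> CohortTable:
    """Read a cohort table from CSV/TSV, coercing mandatory columns.

    Rows whose mandatory fields cannot be parsed are dropped; the drop
    count is logged and stored in ``table.meta['n_dropped_parse']``.
    """
    schema = schema or TableSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path, sep), dtype=str)
    if raw.empty:
        raise SchemaError(f"{path}: table is empty")

    rename = {
        schema.subject_id: "subject_id",
        schema.scanner: "scanner",
        schema.age: "age",
        schema.sex: "sex",
        schema.tiv: "tiv",
    }
    if schema.qc_prob_image:
        rename[schema.qc_prob_image] = "qc_prob_image"
    if schema.qc_prob_seg:
        rename[schema.qc_prob_seg] = "qc_prob_seg"
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}")
    df = raw.rename(columns=rename)

    # numeric coercion of mandatory fields; unparseable rows are dropped
    bad = df["scanner"].isna() | (df["scanner"].astype(str).str.strip() == "")
    for col in ("age", "tiv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna()
        df[col] = vals
    sex_map = dict(schema.sex_levels)
    sex = df["sex"].map(lambda v: sex_map.get(v, sex_map.get(str(v).strip())))
    unknown = sex.isna() & df["sex"].notna() & ~bad
    if unknown.any():
        lvl = df.loc[unknown, "sex"].iloc[0]
        raise SchemaError(f"unknown sex level {lvl!r}; configure TableSchema.sex_levels")
    bad |= sex.isna()
    df["sex"] = sex
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with unparseable mandatory fields", path, n_dropped)
    df = df.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise SchemaError(f"{path}: no parseable rows")
    df["sex"] = df["sex"].astype(int)

    reserved = set(CANONICAL_COLS) | set(QC_PROB_COLS)
    iqm_cols = tuple(schema.iqm_columns)
    for c in iqm_cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: IQM column {c!r} not found")
    value_cols = [c for c in df.columns if c not in reserved and c not in iqm_cols]
    for c in value_cols + list(iqm_cols):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in QC_PROB_COLS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    if schema.roi_columns is not None:
        roi_cols = tuple(schema.roi_columns)
        for c in roi_cols:
            if c not in df.columns:
                raise SchemaError(f"{path}: ROI column {c!r} not found")
    else:
        roi_cols = tuple(c for c in value_cols if not c.startswith(REL_PREFIX))

    table = CohortTable(df, roi_cols, iqm_cols, meta={"n_dropped_parse": n_dropped, "source": str(path)})
    table.validate()
    return table


def write_cohort_table(table: CohortTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sniff_sep(path, sep), index=False, float_format="%.17g")


def parse_freesurfer_aseg(path: str | Path) -> tuple[dict[str, float], float]:
    """Parse a FreeSurfer ``aseg.stats``-dialect file.

    Returns ``(roi_volumes, tiv)``; structure names are preserved
    verbatim.  Header comments start with ``#``; the TIV comes from the
    ``# Measure EstimatedTotalIntraCranialVol`` line; body rows are
    whitespace-delimited with StructName in column 5 and Volume_mm3 in
    column 4 (1-based), as written by ``asegstats``.
    """
    path = Path(path)
    tiv: float | None = None
    volumes: dict[str, float] = {}
    col_struct, col_vol = 4, 3  # defaults of the aseg.stats body layout
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "Measure EstimatedTotalIntraCranialVol" in line:
                    try:
                        tiv = float(line.split(",")[-2].strip())
                    except (IndexError, ValueError) as exc:
                        raise ValueError(f"{path}:{lineno}: malformed TIV measure line") from exc
                elif line.startswith("# ColHeaders"):
                    headers = line.split()[2:]
                    if "StructName" in headers and "Volume_mm3" in headers:
                        col_struct = headers.index("StructName")
                        col_vol = headers.index("Volume_mm3")
                continue
            parts = line.split()
            if len(parts) <= max(col_struct, col_vol):
                raise ValueError(f"{path}:{lineno}: malformed body row")
            name = parts[col_struct]
            try:
                vol = float(parts[col_vol])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric volume for {name!r}") from exc
            if name in volumes:
                raise ValueError(f"{path}:{lineno}: duplicate StructName {name!r}")
            volumes[name] = vol
    if tiv is None:
        raise ValueError(f"{path}: no EstimatedTotalIntraCranialVol measure line")
    return volumes, tiv


# ---------------------------------------------------------------------------
# model bundles

@dataclass
class ModelBundle:
    kind: str
    version: str
    created: str
    feature_names: list[str]
    training_ranges: dict[str, tuple[float, float]]
    config_snapshot: dict[str, Any]
    model: Any


def save_bundle(model: Any, path: str | Path, config_snapshot: dict | None = None) -> None:
    """Persist a fitted model as a directory: human-readable manifest + payload."""
    from .combat import CombatModel
    from .learner import HarmonyModel

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, CombatModel):
        kind = "combat"
        feature_names = list(model.feature_names)
        training_ranges: dict[str, tuple[float, float]] = {}
    elif isinstance(model, HarmonyModel):
        kind = "harmony"
        feature_names = list(model.feature_names)
        training_ranges = {k: (float(v[0]), float(v[1])) for k, v in model.training_ranges.items()}
    else:
        raise TypeError(f"cannot bundle object of type {type(model).__name__}")
    manifest = {
        "kind": kind,
        "version": BUNDLE_FORMAT_VERSION,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "feature_names": feature_names,
        "training_ranges": {k: list(v) for k, v in training_ranges.items()},
        "config_snapshot": config_snapshot or {},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    joblib.dump(model, path / "payload.joblib")


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{path}: not a model bundle (no manifest.json)")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"{path}: bundle format version {manifest.get('version')!r} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION!r})"
        )
    payload = path / "payload.joblib"
    if not payload.exists():
        raise FileNotFoundError(f"{path}: payload.joblib missing")
    try:
        model = joblib.load(payload)
    except Exception as exc:  # noqa: BLE001 - surface as corruption
        raise ValueError(f"{path}: corrupted payload ({exc})") from exc
    return ModelBundle(
        kind=manifest["kind"],
        version=manifest["version"],
        created=manifest["created"],
        feature_names=manifest["feature_names"],
        training_ranges={k: tuple(v) for k, v in manifest["training_ranges"].items()},
        config_snapshot=manifest["config_snapshot"],
        model=model,
    )
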