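"""Reading and writing of spectra matrices, sample metadata and model reports.

Spectra travel as a :class:`SpectraMatrix`: a shared, strictly monotone ppm
axis (descending by NMR plotting convention) plus one intensity row per
sample.  On disk a spectra matrix is a plain CSV whose header row carries the
ppm axis and whose first column carries sample identifiers.  Sample metadata
is a CSV with one row per sample; model/validation summaries are versioned
JSON.  Missing metadata cells stay missing — nothing is imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "SampleTable",
    "SpectraParseError",
    "CLASS_LABELS",
    "BATCH_LABELS",
    "read_spectra",
    "write_spectra",
    "read_sample_table",
    "write_sample_table",
    "build_report",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

#: Closed vocabulary of sample class labels.  ``case``/``control`` and the
#: household/village split cover the human cohorts; ``pre_dose``/``post_dose``
#: and ``al_only``/``al_ddt`` cover the acute and co-dosing mouse designs.
CLASS_LABELS = frozenset(
    {
        "case",
        "control",
        "household_control",
        "village_control",
        "pre_dose",
        "post_dose",
        "al_only",
        "al_ddt",
    }
)

#: Collection batches: the two human field collections and the two mouse studies.
BATCH_LABELS = frozenset({"2008", "2009", "mouse_acute", "mouse_codose"})

REPORT_SCHEMA_VERSION = 1


class SpectraParseError(ValueError):
    """Raised when a spectra or metadata file cannot be parsed/validated."""


@dataclass
class SpectraMatrix:
    """Samples x chemical-shift intensity matrix with a shared ppm axis.

    Parameters
    ----------
    ppm
        Strictly monotone chemical-shift axis in ppm.  Stored descending by
        convention; an ascending axis is accepted but every reader reverses
        it with a warning.
    intensities
        Array of shape ``(n_samples, n_points)``.
    sample_ids
        Unique sample identifiers, one per row.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float).ravel()
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.ppm.size < 1:
            raise ValueError("SpectraMatrix needs at least one ppm point")
        if self.intensities.shape[0] < 1:
            raise ValueError("SpectraMatrix needs at least one sample")
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError(
                f"shape mismatch: intensities {self.intensities.shape}, "
                f"{len(self.sample_ids)} sample ids, {self.ppm.size} ppm points"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dup = next(s for s in self.sample_ids if s in seen or seen.add(s))
            raise ValueError(f"duplicate sample id: {dup!r}")
        d = np.diff(self.ppm)
        if self.ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.ppm)):
            raise ValueError("non-finite ppm value")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValueError(
                f"non-finite intensity at sample {self.sample_ids[bad[0]]!r}, "
                f"ppm {self.ppm[bad[1]]:g}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def nearest_index(self, ppm_value: float) -> int:
        """Index of the grid point closest to ``ppm_value``."""
        return int(np.argmin(np.abs(self.ppm - float(ppm_value))))

    def row(self, sample_id: str) -> np.ndarray:
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        return self.intensities[i]

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(self.ppm.copy(), self.intensities.copy(), list(self.sample_ids))


# ---------------------------------------------------------------------------
# sample metadata

_REQUIRED_META = ("id", "class_label")
_OPTIONAL_META = (
    "batch",
    "gender",
    "age",
    "al_level",
    "alt",
    "histopathology_score",
    "duration_months",
    "subject",
)
_NUMERIC_META = ("age", "al_level", "alt", "histopathology_score", "duration_months")


@dataclass
class SampleTable:
    """Typed per-sample metadata (class label, batch, gender, AL level, ...).

    Wraps a :class:`pandas.DataFrame` with one row per sample.  Class labels
    come from the closed vocabulary :data:`CLASS_LABELS`; the histopathology
    severity score, when present, is an integer 1-5 (1 = normal ... 5 = zone 2
    and 3 necrosis).  Missing values stay ``NaN``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _REQUIRED_META:
            if col not in df.columns:
                raise SpectraParseError(f"missing required column {col!r}")
        for col in _OPTIONAL_META:
            if col not in df.columns:
                df[col] = np.nan
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise SpectraParseError(f"duplicate sample id: {dup!r}")
        labels = df["class_label"].astype(str).str.strip().str.lower()
        unknown = sorted(set(labels) - CLASS_LABELS)
        if unknown:
            raise SpectraParseError(
                f"unknown class label(s) {unknown}; allowed: {sorted(CLASS_LABELS)}"
            )
        df["class_label"] = labels
        batch = df["batch"].astype(object)
        known = batch.dropna().astype(str)
        bad = sorted(set(known) - BATCH_LABELS)
        if bad:
            raise SpectraParseError(
                f"unknown batch label(s) {bad}; allowed: {sorted(BATCH_LABELS)}"
            )
        for col in _NUMERIC_META:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SpectraParseError(f"column {col!r} is not numeric: {exc}") from exc
        score = df["histopathology_score"].dropna()
        if len(score) and not score.isin([1, 2, 3, 4, 5]).all():
            raise SpectraParseError("histopathology_score must be an integer 1-5")
        neg = df["al_level"].dropna()
        if len(neg) and (neg < 0).any():
            raise SpectraParseError("al_level must be >= 0")
        self.df = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def class_counts(self) -> dict[str, int]:
        return self.df["class_label"].value_counts().to_dict()

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        """Class labels in the order of ``sample_ids``."""
        lookup = dict(zip(self.df["id"], self.df["class_label"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"sample ids absent from metadata: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids])

    def column_for(self, sample_ids: list[str], column: str) -> np.ndarray:
        lookup = dict(zip(self.df["id"], self.df[column]))
        return np.array([lookup[s] for s in sample_ids])


# ---------------------------------------------------------------------------
# readers / writers

_FLOAT_FMT = "%.12g"


def write_spectra(matrix: SpectraMatrix, path: str | Path) -> Path:
    """Write a spectra matrix as CSV (header row = ppm axis, first col = id)."""
    path = Path(path)
    header = "sample_id," + ",".join(_FLOAT_FMT % v for v in matrix.ppm)
    lines = [header]
    for sid, row in zip(matrix.sample_ids, matrix.intensities):
        lines.append(sid + "," + ",".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read a spectra CSV written by :func:`write_spectra`.

    An ascending ppm header is reversed (with a warning) so the in-memory
    axis is always descending.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) < 2:
            raise SpectraParseError(f"{path}: header row has no ppm values")
        try:
            ppm = np.array([float(v) for v in header[1:]])
        except ValueError as exc:
            raise SpectraParseError(f"{path}: non-numeric ppm in header: {exc}") from exc
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != ppm.size + 1:
                raise SpectraParseError(
                    f"{path}:{lineno}: expected {ppm.size + 1} cells, got {len(cells)}"
                )
            sid = cells[0]
            if sid in ids:
                raise SpectraParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            try:
                vals = np.array([float(v) for v in cells[1:]])
            except ValueError as exc:
                raise SpectraParseError(
                    f"{path}:{lineno}: non-numeric intensity for sample {sid!r}: {exc}"
                ) from exc
            ids.append(sid)
            rows.append(vals)
    if not rows:
        raise SpectraParseError(f"{path}: no sample rows")
    inten = np.vstack(rows)
    if ppm.size > 1 and ppm[0] < ppm[-1]:
        warnings.warn(f"{path}: ascending ppm axis reversed to descending", stacklevel=2)
        ppm = ppm[::-1].copy()
        inten = inten[:, ::-1].copy()
    try:
        return SpectraMatrix(ppm, inten, ids)
    except ValueError as exc:
        raise SpectraParseError(f"{path}: {exc}") from exc


def write_sample_table(table: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    """Read and validate a sample-metadata CSV (see :class:`SampleTable`)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"batch": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectraParseError(f"{path}: {exc}") from exc
    try:
        return SampleTable(df)
    except SpectraParseError as exc:
        raise SpectraParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# model/validation report

_MODEL_KEYS = ("Q2Y", "R2Y", "R2X", "perm_p")


def build_report(
    model_summaries: list[dict],
    validation_results: list[dict] | None = None,
) -> dict:
    """Assemble the versioned report payload, one block per fitted model.

    ``model_summaries`` carries per-model descriptive fields (name, class
    comparison, n per class, orthogonal components, R2X/R2Y, significant
    variables); ``validation_results`` (parallel list, optional) carries Q2Y
    and permutation p which are merged into the matching block.  Every block
    is guaranteed to contain the keys Q2Y, R2Y, R2X, perm_p and a
    ``significant_variables`` list (possibly empty).
    """
    blocks = []
    validation_results = validation_results or [{}] * len(model_summaries)
    if len(validation_results) != len(model_summaries):
        raise ValueError("model_summaries and validation_results differ in length")
    for summ, val in zip(model_summaries, validation_results):
        block = dict(summ)
        block.update(val)
        for key in _MODEL_KEYS:
            block.setdefault(key, None)
        block.setdefault("significant_variables", [])
        blocks.append(block)
    return {"schema_version": REPORT_SCHEMA_VERSION, "models": blocks}


def write_report(
    model_summaries: list[dict],
    validation_results: list[dict] | None,
    path: str | Path,
) -> Path:
    """Write the :func:`build_report` payload as deterministic JSON."""
    path = Path(path)
    payload = build_report(model_summaries, validation_results)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {payload.get('schema_version')!r}"
        )
    return payload
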