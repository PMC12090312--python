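"""Reading, validation and writing of connectomes, cohort tables and the region table.

All index and file conventions of the package are fixed here:

* Nodes are the 84 regions of the Desikan-Killiany parcellation
  (68 cortical + 16 subcortical), in the canonical order of the packaged
  fixture ``data/desikan_killiany_84.tsv`` — left cortical (34), left
  subcortical (8), right cortical (34), right subcortical (8). Node indices
  are 0-based internally; every emitted table uses region *names*.
* One delimited text file per subject per weight kind,
  ``<subject_id>_<weight_kind>.csv`` (delimiter auto-detected), 84 numeric
  columns x 84 rows, optional header row of region names.
* The cohort is a single delimited table with a documented header; missing
  clinical values are empty fields on disk and ``NaN`` in memory (never 0 —
  0 is a valid S-FMDRS score).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_REGIONS = 84
N_CORTICAL = 68
N_SUBCORTICAL = 16

WEIGHT_KINDS = ("fa", "nstreamlines", "mean_length_mm")

#: tolerated float noise above 1.0 for FA entries; values in (1, 1+FA_TOL] are clamped to 1
FA_TOL = 1e-9
#: maximum |matrix - matrix.T| that is silently symmetrized by averaging
SYMMETRY_TOL = 1e-9

GROUPS = ("FND", "HC")
SEXES = ("female", "male")

#: cohort table header, in canonical column order
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "medication_any_psychotropic",
    "bdi",
    "stai_state",
    "stai_trait",
    "sf36_physical_health",
    "sf36_mental_health",
    "sf36_general_health",
    "sf36_physical_functioning",
    "sfmdrs",
    "cgi",
    "illness_duration_months",
]

#: clinical fields defined for FND patients only; must be missing for every HC
FND_ONLY_COLUMNS = ["sfmdrs", "cgi", "illness_duration_months"]


class ValidationError(ValueError):
    """An input violated a structural invariant; the message names it."""


# ---------------------------------------------------------------------------
# region table
# ---------------------------------------------------------------------------

def load_region_table() -> pd.DataFrame:
    """Load the canonical 84-region Desikan-Killiany table.

    Returns a DataFrame with columns ``index`` (0..83, the canonical node
    index used by every other module), ``name``, ``hemisphere``
    (left/right) and ``tissue_class`` (cortical/subcortical).
    """
    with resources.files("fndconn.data").joinpath("desikan_killiany_84.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    _validate_region_table(table)
    return table


def _validate_region_table(table: pd.DataFrame) -> None:
    if list(table.columns) != ["index", "name", "hemisphere", "tissue_class"]:
        raise ValidationError(f"region table columns malformed: {list(table.columns)}")
    if len(table) != N_REGIONS:
        raise ValidationError(f"region table must have {N_REGIONS} rows, found {len(table)}")
    if list(table["index"]) != list(range(N_REGIONS)):
        raise ValidationError("region indices must be contiguous from 0")
    if table["name"].duplicated().any():
        raise ValidationError("region names must be unique")
    n_cort = int((table["tissue_class"] == "cortical").sum())
    n_sub = int((table["tissue_class"] == "subcortical").sum())
    if (n_cort, n_sub) != (N_CORTICAL, N_SUBCORTICAL):
        raise ValidationError(
            f"expected {N_CORTICAL} cortical / {N_SUBCORTICAL} subcortical regions, "
            f"found {n_cort}/{n_sub}"
        )
    if not set(table["hemisphere"]) <= {"left", "right"}:
        raise ValidationError("hemisphere must be 'left' or 'right'")


def region_names() -> list[str]:
    """Canonical region names in node-index order."""
    return list(load_region_table()["name"])


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

@dataclass
class SubjectConnectome:
    """One subject's symmetric 84x84 connectome of a single weight kind.

    Invariants (enforced on construction): symmetric, zero diagonal,
    nonnegative; FA entries <= 1; streamline counts are integers.
    """

    subject_id: str
    weight_kind: str
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        validate_connectome_matrix(self.matrix, self.weight_kind)


def validate_connectome_matrix(matrix: np.ndarray, weight_kind: str) -> None:
    """Enforce every SubjectConnectome invariant, in place where tolerances allow."""
    if weight_kind not in WEIGHT_KINDS:
        raise ValidationError(f"unknown weight kind {weight_kind!r}; expected one of {WEIGHT_KINDS}")
    if matrix.shape != (N_REGIONS, N_REGIONS):
        raise ValidationError(f"connectome must be {N_REGIONS}x{N_REGIONS}, got {matrix.shape}")
    asym = np.abs(matrix - matrix.T).max()
    if asym > SYMMETRY_TOL:
        raise ValidationError(f"matrix asymmetric beyond tolerance (max |A-A'| = {asym:g})")
    if asym > 0:
        matrix[:] = 0.5 * (matrix + matrix.T)
    diag = np.abs(np.diag(matrix)).max()
    if diag > SYMMETRY_TOL:
        raise ValidationError(f"diagonal must be zero (max |diag| = {diag:g})")
    np.fill_diagonal(matrix, 0.0)
    if matrix.min() < 0:
        raise ValidationError(f"negative entries not allowed (min = {matrix.min():g})")
    if weight_kind == "fa":
        if matrix.max() > 1.0 + FA_TOL:
            raise ValidationError(f"FA entries must be <= 1 (max = {matrix.max():g})")
        np.clip(matrix, 0.0, 1.0, out=matrix)
    if weight_kind == "nstreamlines":
        rounded = np.rint(matrix)
        if np.abs(matrix - rounded).max() > 1e-6:
            raise ValidationError("streamline counts must be nonnegative integers")
        matrix[:] = rounded


def read_connectome(path: str | Path, weight_kind: str, subject_id: str | None = None) -> SubjectConnectome:
    """Read one subject's connectome from a delimited text file.

    The delimiter (comma or tab) is auto-detected and an optional header row
    of region names is skipped. ``subject_id`` defaults to the filename stem
    stripped of the ``_<weight_kind>`` suffix.
    """
    path = Path(path)
    text = path.read_text()
    first_line = text.splitlines()[0] if text else ""
    sep = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    has_header = any(not _is_number(tok) for tok in first_line.split(sep) if tok.strip())
    frame = pd.read_csv(io.StringIO(text), sep=sep, header=0 if has_header else None,
                        float_precision="round_trip")
    matrix = frame.to_numpy(dtype=float)
    if subject_id is None:
        subject_id = path.stem
        suffix = f"_{weight_kind}"
        if subject_id.endswith(suffix):
            subject_id = subject_id[: -len(suffix)]
    return SubjectConnectome(subject_id=subject_id, weight_kind=weight_kind, matrix=matrix)


def write_connectome(conn: SubjectConnectome, directory: str | Path, header: bool = True) -> Path:
    """Write a connectome as ``<subject_id>_<weight_kind>.csv``; returns the path.

    Values are written at full float precision so write->read round-trips
    are exact to well below 1e-12.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{conn.subject_id}_{conn.weight_kind}.csv"
    names = region_names()
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(names) + "\n")
        for row in conn.matrix:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")
    return path


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cohort table; returns the normalized frame.

    Enumerations are normalized case-insensitively; HC rows must have every
    FND-only clinical field missing; group/age/sex must be complete.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort table missing columns: {missing_cols}")
    cohort = cohort[COHORT_COLUMNS].copy()

    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")

    for col in ("group", "age", "sex"):
        if cohort[col].isna().any():
            raise ValidationError(f"missing values in required column {col!r}")

    group = cohort["group"].astype(str).str.strip().str.upper()
    if not set(group) <= set(GROUPS):
        bad = sorted(set(group) - set(GROUPS))
        raise ValidationError(f"unknown group label(s) {bad}; expected {GROUPS}")
    cohort["group"] = group

    sex = cohort["sex"].astype(str).str.strip().str.lower()
    if not set(sex) <= set(SEXES):
        bad = sorted(set(sex) - set(SEXES))
        raise ValidationError(f"unknown sex label(s) {bad}; expected {SEXES}")
    cohort["sex"] = sex

    med = cohort["medication_any_psychotropic"]
    if med.dtype != bool:
        med = med.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False, "1.0": True, "0.0": False}
        )
        if med.isna().any():
            raise ValidationError("medication_any_psychotropic must be boolean")
    cohort["medication_any_psychotropic"] = med.astype(bool)

    numeric = [c for c in COHORT_COLUMNS if c not in
               ("subject_id", "group", "sex", "medication_any_psychotropic")]
    for col in numeric:
        cohort[col] = pd.to_numeric(cohort[col], errors="raise")

    hc = cohort["group"] == "HC"
    for col in FND_ONLY_COLUMNS:
        if cohort.loc[hc, col].notna().any():
            bad_id = cohort.loc[hc & cohort[col].notna(), "subject_id"].iloc[0]
            raise ValidationError(
                f"HC subject {bad_id!r} has a value for FND-only field {col!r}"
            )
    if (cohort["age"] <= 0).any():
        raise ValidationError("age must be positive")
    for col, lo, hi in (("bdi", 0, 63), ("cgi", 0, 7)):
        vals = cohort[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"{col} outside instrument range [{lo}, {hi}]")
    if (cohort["sfmdrs"].dropna() < 0).any():
        raise ValidationError("sfmdrs must be >= 0")
    if (cohort["illness_duration_months"].dropna() < 0).any():
        raise ValidationError("illness_duration_months must be >= 0")
    return cohort.reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table (CSV or TSV, delimiter auto-detected)."""
    path = Path(path)
    first_line = path.read_text().splitlines()[0]
    sep = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_cohort(frame)


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    """Write a validated cohort table; missing values become empty fields."""
    cohort = validate_cohort(cohort)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = cohort.copy()
    float_cols = [c for c in COHORT_COLUMNS if c not in
                  ("subject_id", "group", "sex", "medication_any_psychotropic")]
    for col in float_cols:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else format(float(v), ".17g"))
    out["medication_any_psychotropic"] = out["medication_any_psychotropic"].map(
        {True: "true", False: "false"})
    out.to_csv(path, sep=sep, index=False)
    return path
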