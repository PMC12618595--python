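"""Data model, validation, normalization and file I/O for connectomes.

Connectivity matrices are square, symmetric, zero-diagonal arrays over a fixed
parcellation (a Desikan-Killiany-style cortical + subcortical atlas by
default, 84 regions).  Three kinds are distinguished:

* ``SC`` -- structural connectivity, one of five edge weightings: streamline
  count (``NS``), volume-normalized streamline count (``NSv``), fractional
  anisotropy (``FA``), inverse radial diffusivity (``iRD``) and total
  restricted signal fraction (``FRt``).
* ``FC`` -- functional connectivity from MEG amplitude-amplitude correlations
  in one of four frequency bands: ``delta`` (1-4 Hz), ``theta`` (4-8 Hz),
  ``alpha`` (8-13 Hz), ``beta`` (13-30 Hz).
* ``ED`` -- Euclidean distances between region centroids, in mm.

All edge-level computation in the package runs on the canonical upper-triangle
edge vector: row-major over pairs (i, j) with i < j, 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SC_VARIANTS = ("NS", "NSv", "FA", "iRD", "FRt")
FC_BANDS = ("delta", "theta", "alpha", "beta")
KINDS = ("SC", "FC", "ED")

SYMMETRY_ATOL = 1e-8

MANIFEST_COLUMNS = (
    "id",
    "age",
    "group",
    "panss_total",
    "panss_positive",
    "panss_negative",
    "panss_general",
)


class ConnectomeError(ValueError):
    """Base class for all validation errors raised by this package."""


class DimensionError(ConnectomeError):
    """Matrix shape does not match the parcellation."""


class AsymmetryError(ConnectomeError):
    """Matrix is not symmetric within tolerance."""


class NegativeWeightError(ConnectomeError):
    """SC or ED matrix contains negative entries."""


class NonNumericError(ConnectomeError):
    """A matrix cell could not be parsed as a number."""


class LabelOrderError(ConnectomeError):
    """File header labels do not match the parcellation order."""


class DiagonalError(ConnectomeError):
    """Matrix diagonal is not exactly zero."""


class NonFiniteError(ConnectomeError):
    """Matrix contains NaN or infinite entries."""


class AllZeroMatrixError(ConnectomeError):
    """Matrix has no nonzero off-diagonal entry (cannot be normalized)."""


class ManifestError(ConnectomeError):
    """Subject manifest is malformed."""


class VariantError(ConnectomeError):
    """Unknown kind/variant combination."""


@dataclass(frozen=True)
class Parcellation:
    """Ordered region labels, optionally with centroid coordinates in mm."""

    labels: tuple[str, ...]
    centroids: Optional[np.ndarray] = None

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ConnectomeError("parcellation labels must be unique")
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (len(labels), 3):
                raise DimensionError(
                    f"centroids shape {c.shape} != ({len(labels)}, 3)"
                )
            if not np.all(np.isfinite(c)):
                raise NonFiniteError("centroids must be finite")
            object.__setattr__(self, "centroids", c)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    @classmethod
    def generic(cls, n: int) -> "Parcellation":
        """A label-only parcellation with ``n`` generically named regions."""
        return cls(labels=tuple(f"region_{i:03d}" for i in range(n)))


def _check_variant(kind: str, variant: Optional[str]) -> None:
    if kind not in KINDS:
        raise VariantError(f"unknown matrix kind {kind!r}; expected one of {KINDS}")
    if kind == "SC" and variant not in SC_VARIANTS:
        raise VariantError(f"SC variant must be one of {SC_VARIANTS}, got {variant!r}")
    if kind == "FC" and variant not in FC_BANDS:
        raise VariantError(f"FC band must be one of {FC_BANDS}, got {variant!r}")
    if kind == "ED" and variant is not None:
        raise VariantError("ED matrices take no variant")


@dataclass
class ConnectivityMatrix:
    """A validated square symmetric connectivity matrix.

    Invariants enforced at construction: symmetry within ``SYMMETRY_ATOL``,
    exactly-zero diagonal, finite entries, and nonnegativity for SC and ED
    (FC amplitude-amplitude correlations may be negative).
    """

    values: np.ndarray
    kind: str
    variant: Optional[str]
    parcellation: Parcellation
    normalized: bool = False

    def __post_init__(self):
        _check_variant(self.kind, self.variant)
        v = np.asarray(self.values, dtype=float)
        n = self.parcellation.n
        if v.shape != (n, n):
            raise DimensionError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise NonFiniteError(f"{self.kind} matrix contains non-finite entries")
        asym = np.max(np.abs(v - v.T)) if n else 0.0
        if asym > SYMMETRY_ATOL:
            raise AsymmetryError(
                f"matrix asymmetric: max |A - A.T| = {asym:.3g} > {SYMMETRY_ATOL}"
            )
        v = (v + v.T) / 2.0  # remove sub-tolerance asymmetry
        if np.any(np.diag(v) != 0.0):
            raise DiagonalError("matrix diagonal must be exactly zero")
        if self.kind in ("SC", "ED") and np.min(v) < 0:
            raise NegativeWeightError(f"{self.kind} entries must be nonnegative")
        if self.normalized:
            off = _offdiag_abs_max(v)
            if not np.isclose(off, 1.0, rtol=0, atol=1e-9):
                raise ConnectomeError(
                    "normalized flag set but max off-diagonal |value| "
                    f"is {off:.6g}, not 1"
                )
        self.values = v

    @property
    def n(self) -> int:
        return self.parcellation.n

    def edges(self) -> np.ndarray:
        """Canonical upper-triangle edge vector (see :func:`upper_triangle`)."""
        return upper_triangle(self.values)


def _offdiag_abs_max(v: np.ndarray) -> float:
    mask = ~np.eye(v.shape[0], dtype=bool)
    return float(np.max(np.abs(v[mask])))


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle edge vector of a square matrix.

    The ordering is (0,1), (0,2), ..., (0,n-1), (1,2), ..., (n-2,n-1): the
    single canonical edge ordering used throughout the package.
    """
    v = np.asarray(values)
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju]


def matrix_from_edges(edges: np.ndarray, n: int) -> np.ndarray:
    """Reconstruct the symmetric zero-diagonal matrix from an edge vector.

    Inverse of :func:`upper_triangle`: ``matrix_from_edges(upper_triangle(m),
    n)`` equals ``m`` exactly for valid matrices.
    """
    edges = np.asarray(edges, dtype=float)
    expected = n * (n - 1) // 2
    if edges.shape != (expected,):
        raise DimensionError(f"edge vector length {edges.shape} != ({expected},)")
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = edges
    out[ju, iu] = edges
    return out


def normalize_matrix(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every entry by the maximum off-diagonal absolute value.

    Maps nonnegative matrices into [0, 1]; idempotent; monotone in entries.
    """
    scale = _offdiag_abs_max(m.values)
    if scale == 0.0:
        raise AllZeroMatrixError("cannot normalize an all-zero matrix")
    return ConnectivityMatrix(
        values=m.values / scale,
        kind=m.kind,
        variant=m.variant,
        parcellation=m.parcellation,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# matrix file I/O: delimited text, one header row of region labels
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_matrix(
    path,
    parcellation: Parcellation,
    kind: str,
    variant: Optional[str] = None,
    symmetrize: bool = False,
) -> ConnectivityMatrix:
    """Read a delimited-text connectivity matrix (comma or tab).

    An optional single header row of labels must match the parcellation order
    exactly.  The file does not encode kind/variant; the caller supplies them.
    With ``symmetrize=True`` an asymmetric matrix is replaced by (A + A.T)/2
    instead of being rejected.
    """
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    delim = _sniff_delimiter(first)
    tokens = [t.strip() for t in first.split(delim)]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = bool(tokens) and not all(_is_number(t) for t in tokens if t)
    if has_header:
        labels = tuple(t for t in tokens if t)
        if labels != parcellation.labels:
            raise LabelOrderError(
                "header labels do not match parcellation order "
                f"(first mismatch near {_first_mismatch(labels, parcellation.labels)})"
            )
    try:
        arr = np.loadtxt(
            io.StringIO(text),
            delimiter=delim,
            skiprows=1 if has_header else 0,
            ndmin=2,
        )
    except ValueError as exc:
        raise NonNumericError(f"non-numeric cell in {path}: {exc}") from exc
    n = parcellation.n
    if arr.shape != (n, n):
        raise DimensionError(f"{path}: matrix shape {arr.shape} != ({n}, {n})")
    if symmetrize:
        arr = (arr + arr.T) / 2.0
    return ConnectivityMatrix(
        values=arr, kind=kind, variant=variant, parcellation=parcellation
    )


def _first_mismatch(a, b) -> str:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"position {i}: {x!r} vs {y!r}"
    return f"length {len(a)} vs {len(b)}"


def write_matrix(m: ConnectivityMatrix, path) -> None:
    """Write a matrix as delimited text with a header row of labels.

    Values are printed with 17 significant digits so a read/write round trip
    preserves every entry to better than 1e-12 relative tolerance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(m.parcellation.labels) + "\n")
        for row in m.values:
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

GROUPS = ("healthy", "psychosis")


@dataclass(frozen=True)
class PanssScores:
    """Positive and Negative Syndrome Scale scores of a psychosis subject."""

    total: int
    positive: int
    negative: int
    general: int

    def __post_init__(self):
        for name in ("total", "positive", "negative", "general"):
            val = getattr(self, name)
            if int(val) != val or val < 0:
                raise ManifestError(f"PANSS {name} must be a nonnegative integer")
            object.__setattr__(self, name, int(val))


@dataclass(frozen=True)
class Subject:
    id: str
    age: float
    group: str
    panss: Optional[PanssScores] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ManifestError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.age <= 0:
            raise ManifestError("age must be positive")
        if (self.group == "psychosis") != (self.panss is not None):
            raise ManifestError(
                "PANSS scores must be present iff group == 'psychosis' "
                f"(subject {self.id!r})"
            )


@dataclass
class Cohort:
    """Subjects plus their keyed connectivity matrices.

    ``matrices`` maps (subject_id, kind, variant) to a ConnectivityMatrix.
    All matrices share one parcellation.  The ED matrix is shared across the
    cohort but keyed per subject for uniform access.
    """

    subjects: list[Subject]
    matrices: dict[tuple[str, str, Optional[str]], ConnectivityMatrix]
    parcellation: Parcellation
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = {s.id for s in self.subjects}
        for (sid, _, _), m in self.matrices.items():
            if sid not in ids:
                raise ConnectomeError(f"matrix references unknown subject {sid!r}")
            if m.parcellation.labels != self.parcellation.labels:
                raise ConnectomeError("all matrices must share one parcellation")

    def get(self, subject_id: str, kind: str, variant: Optional[str] = None):
        return self.matrices[(subject_id, kind, variant)]

    @property
    def healthy(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "healthy"]

    @property
    def patients(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "psychosis"]

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)


def read_manifest(path) -> list[Subject]:
    """Read the subject manifest CSV.

    Required columns: id, age, group, panss_total, panss_positive,
    panss_negative, panss_general.  PANSS columns are empty for healthy
    subjects and must all be integers for psychosis subjects.  Group strings
    are case-insensitive.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    subjects = []
    for _, row in df.iterrows():
        group = str(row["group"]).strip().lower()
        panss = None
        if group == "psychosis":
            vals = {}
            for comp in ("total", "positive", "negative", "general"):
                raw = row[f"panss_{comp}"]
                if pd.isna(raw):
                    raise ManifestError(
                        f"psychosis subject {row['id']!r} missing panss_{comp}"
                    )
                fval = float(raw)
                if fval != int(fval):
                    raise ManifestError(
                        f"panss_{comp} for subject {row['id']!r} is not an integer"
                    )
                vals[comp] = int(fval)
            panss = PanssScores(**vals)
        subjects.append(
            Subject(id=str(row["id"]), age=float(row["age"]), group=group, panss=panss)
        )
    return subjects


def write_manifest(subjects: list[Subject], path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "age": s.age,
                "group": s.group,
                "panss_total": s.panss.total if s.panss else "",
                "panss_positive": s.panss.positive if s.panss else "",
                "panss_negative": s.panss.negative if s.panss else "",
                "panss_general": s.panss.general if s.panss else "",
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------


def _matrix_filename(subject_id: str, kind: str, variant: Optional[str]) -> str:
    tag = variant if variant is not None else "ED"
    return f"{subject_id}_{kind}_{tag}.csv"


def write_cohort(cohort: Cohort, directory) -> None:
    """Write manifest.csv plus one matrix file per (subject, kind, variant)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.subjects, directory / "manifest.csv")
    for (sid, kind, variant), m in cohort.matrices.items():
        write_matrix(m, directory / _matrix_filename(sid, kind, variant))


def read_cohort(directory, n_nodes: Optional[int] = None) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    The parcellation is recovered from the header of the first matrix file.
    """
    directory = Path(directory)
    subjects = read_manifest(directory / "manifest.csv")
    files = sorted(directory.glob("*_*_*.csv"))
    if not files:
        raise ConnectomeError(f"no matrix files found in {directory}")
    header = files[0].read_text().splitlines()[0]
    labels = tuple(t for t in header.split(_sniff_delimiter(header)) if t)
    parc = Parcellation(labels=labels)
    matrices = {}
    for f in files:
        stem_parts = f.stem.rsplit("_", 2)
        if len(stem_parts) != 3:
            continue
        sid, kind, tag = stem_parts
        if kind not in KINDS:
            continue
        variant = None if kind == "ED" else tag
        matrices[(sid, kind, variant)] = read_matrix(f, parc, kind, variant)
    return Cohort(subjects=subjects, matrices=matrices, parcellation=parc)
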