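"""Core data types, file readers/writers and validation shared by all stages.

Expression data are log2 intensities on a probe-set × sample grid (the
Affymetrix HG-U133 Plus 2.0 layout: 54,675 probe sets, but any complete
log2 matrix is accepted).  All identifiers are carried with an explicit
namespace tag (``"probe"`` or ``"gene"``): downstream set operations refuse
to mix the two, because probe sets and gene symbols are many-to-many.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ROLES = frozenset(
    {"day0_control", "diff_control", "treated", "vehicle_control"}
)

PROBE = "probe"
GENE = "gene"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix, probe sets × samples.

    ``values[i, j]`` is the log2 intensity of probe ``probe_ids[i]`` in
    sample ``sample_ids[j]``.  Identifiers are unique and every value is
    finite (the source platform is complete; missing values are rejected
    at read time).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if len(self.probe_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("matrix must have >= 1 probe and >= 1 sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValidationError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- conversions --------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            probe_ids=[str(p) for p in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        cols = [pos[s] for s in wanted]
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=wanted,
            values=self.values[:, cols],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.probe_ids), list(self.sample_ids), self.values.copy()
        )


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a tab-delimited log2 expression matrix.

    First column holds probe ids, the header row sample ids, the body is
    numeric.  Duplicate probe ids, non-numeric cells and empty files are
    hard errors naming the offending location.
    """
    if dialect != "tsv":
        raise ValidationError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty expression file: {path}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValidationError(f"expression file has no data body: {path}")
    index = [str(p) for p in frame.index]
    dup = _first_duplicate(index)
    if dup is not None:
        raise ValidationError(f"duplicate probe id in {path}: {dup!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        raw = frame[col].to_numpy(dtype=object)
        try:
            # numpy's parser is correctly rounded (exact round trip)
            converted = raw.astype(float)
        except (ValueError, TypeError):
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValidationError(
                        f"non-numeric cell in {path} at probe "
                        f"{frame.index[i]!r}, sample {col!r}"
                    ) from None
            raise
        if not np.isfinite(converted).all():
            i = int(np.argmax(~np.isfinite(converted)))
            raise ValidationError(
                f"non-numeric cell in {path} at probe {frame.index[i]!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted
    return ExpressionMatrix(
        probe_ids=index,
        sample_ids=[str(c) for c in frame.columns],
        values=values,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full-precision floats (round-trip exact)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, probe in enumerate(matrix.probe_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{probe}\t{row}\n")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


@dataclass
class SampleDesign:
    """Per-sample metadata: role, compound, concentration, batch, replicate."""

    table: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "role",
        "compound",
        "compound_class",
        "concentration",
        "conc_unit",
        "system",
        "batch",
        "replicate",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = _first_duplicate([str(s) for s in self.table["sample_id"]])
        if dup is not None:
            raise ValidationError(f"duplicate sample id in design: {dup!r}")
        bad_roles = set(self.table["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(f"unknown roles in design: {sorted(bad_roles)}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]

    def samples_with_role(self, role: str) -> list[str]:
        sel = self.table["role"] == role
        return [str(s) for s in self.table.loc[sel, "sample_id"]]

    def samples_for_compound(
        self, compound: str, concentration: float | str | None = None
    ) -> list[str]:
        sel = (self.table["role"] == "treated") & (
            self.table["compound"] == compound
        )
        if concentration is not None:
            sel &= self.table["concentration"].astype(float) == float(concentration)
        return [str(s) for s in self.table.loc[sel, "sample_id"]]

    def batches(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.table.iterrows():
            out.setdefault(str(row["batch"]), []).append(str(row["sample_id"]))
        return out

    def group_labels(self) -> pd.Series:
        """Biological group of each sample: role/compound/concentration."""
        tab = self.table
        labels = (
            tab["role"].astype(str)
            + "|"
            + tab["compound"].fillna("").astype(str)
            + "|"
            + tab["concentration"].fillna("").astype(str)
        )
        labels.index = tab["sample_id"].astype(str)
        return labels

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        have = set(matrix.sample_ids)
        missing = [s for s in self.sample_ids if s not in have]
        if missing:
            raise ValidationError(
                f"design references samples absent from matrix: {missing}"
            )


def read_sample_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t")
    return SampleDesign(frame)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Map probe_id -> set of gene symbols (possibly empty)."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for probe, symbols in self.mapping.items():
            syms = frozenset(s for s in symbols if s)
            clean[str(probe)] = syms
        self.mapping = clean

    def genes_for(self, probe_id: str) -> frozenset[str]:
        return self.mapping.get(probe_id, frozenset())

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for syms in self.mapping.values():
            out |= syms
        return frozenset(out)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a 2-column TSV probe_id<TAB>symbol; repeat rows for multi-mapping."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"annotation line {lineno} has fewer than 2 fields"
                )
            probe, symbol = parts[0], parts[1]
            if lineno == 1 and probe.lower() in {"probe_id", "probe"}:
                continue
            mapping.setdefault(probe, set()).add(symbol)
    return ProbeAnnotation({p: frozenset(s) for p, s in mapping.items()})


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\tsymbol\n")
        for probe in sorted(annotation.mapping):
            for sym in sorted(annotation.mapping[probe]):
                fh.write(f"{probe}\t{sym}\n")


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets (GO categories, TF lists) in one identifier namespace."""

    sets: dict[str, tuple[str, frozenset[str]]]
    namespace: str = GENE

    def __post_init__(self) -> None:
        if self.namespace not in (PROBE, GENE):
            raise ValidationError(f"unknown namespace {self.namespace!r}")
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, namespace: str = GENE) -> GeneSetCollection:
    """Parse a GMT file: name<TAB>description<TAB>member...<TAB>member.

    Duplicate members within a line are collapsed; a line with fewer than
    three fields is an error naming the line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(parts)} fields (need >= 3)"
                )
            name, description = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValidationError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = (description, members)
    return GeneSetCollection(sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def _jsonify(obj):
    """Convert stage outputs to plain JSON-serializable structures."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(str(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "to_record"):
        return _jsonify(obj.to_record())
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    return obj


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Serialize a stage output deterministically (sorted keys, >= 6 sig digits)."""
    path = Path(path)
    if format == "json":
        with path.open("w") as fh:
            json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(results, pd.DataFrame):
            frame = results
        else:
            frame = pd.DataFrame(_jsonify(results))
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValidationError(f"unsupported report format {format!r}")
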