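"""Readers/writers for the tabular formats the pipeline touches.

Formats
-------
* GMT (MSigDB dialect) for gene-set collections: one set per line,
  tab-separated ``name<TAB>description<TAB>member1<TAB>member2...``.
* TSV for expression matrices (rows = genes, first column = gene ID,
  remaining columns = samples), survival tables (columns ``sample_id``,
  ``time``, ``event``) and risk-score output (columns ``sample_id``,
  ``risk``).

The three domain containers (:class:`ExpressionMatrix`,
:class:`SurvivalData`, :class:`GeneSetCollection`) validate their
invariants on construction so downstream code can assume clean inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "build_super_collection",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "write_risk_scores",
    "read_risk_scores",
    "align",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous expression indices.

    Values are assumed already log-scale / normalized upstream; units are
    platform-arbitrary.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise ValidationError("need at least 1 gene and 2 samples")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes-in-rows DataFrame (index = gene IDs)."""
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalData:
    """Right-censored outcomes: per-sample follow-up time and event flag.

    ``event == 1`` means the event (death, non-recovery, relapse...) was
    observed at ``time``; ``event == 0`` means the sample was censored at
    ``time`` (the true event time is only known to exceed it).
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length does not match sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.argmin((self.time > 0) & np.isfinite(self.time)))
            raise ValidationError(
                f"non-positive or non-finite time for sample {self.sample_ids[bad]!r}"
            )
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            bad = int(np.argmax(~np.isin(self.event, [0, 1])))
            raise ValidationError(
                f"event must be 0 or 1; sample {self.sample_ids[bad]!r} has "
                f"event={self.event[bad]!r}"
            )
        self.event = self.event.astype(int)
        if self.event.sum() < 1:
            raise ValidationError("no events observed (all samples censored)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: list[str]) -> "SurvivalData":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return SurvivalData(list(sample_ids), self.time[rows], self.event[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways, regulons, chromosomal bands)."""

    name: str
    sets: dict[str, frozenset[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for set_name, members in self.sets.items():
            fs = frozenset(str(m) for m in members)
            if not fs:
                raise ValidationError(f"gene set {set_name!r} is empty")
            clean[str(set_name)] = fs
        self.sets = clean

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


def read_gmt(path: str, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields
    (set name, description, one or more member genes). Duplicate members
    within a line are deduplicated; the description is kept as provenance.
    """
    sets: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}: line {lineno}: set {set_name!r} has no members")
            if set_name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {set_name!r}")
            sets[set_name] = members
            provenance[set_name] = desc
    if not sets:
        raise ValidationError(f"{path}: no gene sets")
    return GeneSetCollection(name or str(path), sets, provenance)


def write_gmt(path: str, collection: GeneSetCollection) -> None:
    """Write a collection in GMT format (members in sorted order)."""
    with open(path, "w", encoding="utf-8") as handle:
        for set_name, members in collection.sets.items():
            desc = collection.provenance.get(set_name, "na") or "na"
            handle.write("\t".join([set_name, desc, *sorted(members)]) + "\n")


def build_super_collection(
    collections: list[GeneSetCollection], name: str = "IS"
) -> GeneSetCollection:
    """Union several collections into one integrated super collection.

    Exact duplicates (same set name *and* identical membership) are merged.
    A name that recurs with *different* membership is disambiguated by
    prefixing each conflicting set with its source collection's name.
    Identical membership under different names is kept separately.
    """
    if not collections:
        raise ValidationError("need at least one collection")
    # First pass: find names that occur with more than one distinct membership.
    memberships: dict[str, set[frozenset[str]]] = {}
    for coll in collections:
        for set_name, members in coll.sets.items():
            memberships.setdefault(set_name, set()).add(members)
    conflicted = {n for n, ms in memberships.items() if len(ms) > 1}

    sets: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    for coll in collections:
        for set_name, members in coll.sets.items():
            out_name = f"{coll.name}.{set_name}" if set_name in conflicted else set_name
            if out_name in sets:
                continue  # exact duplicate (same name, same members) -> merge
            sets[out_name] = members
            provenance[out_name] = coll.name
    return GeneSetCollection(name, sets, provenance)


def read_expression(path: str) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise ValidationError(
            f"{path}: non-numeric or missing value at gene {row!r}, sample {col!r}"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(path: str, expr: ExpressionMatrix) -> None:
    df = expr.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_survival(path: str) -> SurvivalData:
    """Read a survival TSV with columns ``sample_id``, ``time``, ``event``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    for col, series in (("time", time), ("event", event)):
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise ValidationError(f"{path}: non-numeric {col} on row {row + 2}")
    try:
        return SurvivalData(list(df["sample_id"].astype(str)), time.to_numpy(), event.to_numpy())
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_survival(path: str, surv: SurvivalData) -> None:
    surv.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_risk_scores(path: str, sample_ids: list[str], risks: np.ndarray) -> None:
    pd.DataFrame({"sample_id": sample_ids, "risk": np.asarray(risks, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_risk_scores(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "risk"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return list(df["sample_id"].astype(str)), df["risk"].to_numpy(dtype=float)


def align(expr: ExpressionMatrix, surv: SurvivalData) -> tuple[ExpressionMatrix, SurvivalData]:
    """Align survival rows to the expression sample order.

    A sample-ID mismatch in either direction is an error (silent joins can
    corrupt Cox scores undetectably), with the differing IDs listed.
    """
    expr_ids, surv_ids = set(expr.sample_ids), set(surv.sample_ids)
    if expr_ids != surv_ids:
        only_expr = sorted(expr_ids - surv_ids)
        only_surv = sorted(surv_ids - expr_ids)
        raise ValidationError(
            "expression/survival sample IDs differ; "
            f"only in expression: {only_expr}; only in survival: {only_surv}"
        )
    return expr, surv.subset(expr.sample_ids)
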