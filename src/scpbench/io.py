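"""Readers, writers and containers for proteome FASTA files and DIA-style quant reports.

The quant report is the long-format table a DIA search engine exports: one row
per run x protein group (x precursor) with a quantity. Reports are pivoted into
a :class:`QuantMatrix` (proteins x samples) with explicit missingness, the
container every downstream benchmarking and postanalysis step consumes.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Origin",
    "ProteinRecord",
    "ProteomeDB",
    "read_fasta",
    "write_fasta",
    "Dialect",
    "SPECTRONAUT_LIKE",
    "QuantReport",
    "read_quant_report",
    "write_quant_report",
    "QuantMatrix",
    "pivot_matrix",
    "melt_matrix",
    "species_from_accession",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class ReportFormatError(ValueError):
    """Raised when a quant report violates the expected schema."""


class Origin(str, enum.Enum):
    """Source database a protein entry belongs to.

    ``target`` entries come from the organism under study, ``shuffled`` from a
    residue-permuted copy of the target database, and ``entrapment`` from a
    foreign-species database known to be absent from the sample.
    """

    TARGET = "target"
    SHUFFLED = "shuffled"
    ENTRAPMENT = "entrapment"


#: accession prefixes that mark non-target origins on round-trip
ORIGIN_PREFIXES: dict[str, Origin] = {
    "SHUF_": Origin.SHUFFLED,
    "ENTRAP_": Origin.ENTRAPMENT,
}

#: accession suffixes resolving the species of a protein (two-proteome mixes)
SPECIES_SUFFIXES: dict[str, str] = {
    "_HUMAN": "human",
    "_YEAST": "yeast",
    "_CAEEL": "c_elegans",
}


def origin_from_accession(accession: str) -> Origin:
    for prefix, origin in ORIGIN_PREFIXES.items():
        if accession.startswith(prefix):
            return origin
    return Origin.TARGET


def species_from_accession(accession: str) -> str | None:
    """Resolve species from an accession suffix convention (e.g. ``_YEAST``).

    For semicolon-joined protein groups the first member decides. Returns
    ``None`` when no known suffix matches.
    """
    first = accession.split(";")[0]
    for suffix, species in SPECIES_SUFFIXES.items():
        if first.endswith(suffix):
            return species
    return None


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its database origin."""

    accession: str
    sequence: str
    description: str = ""
    origin: Origin = Origin.TARGET

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        if not self.accession:
            raise ValueError("empty accession")


class ProteomeDB:
    """An ordered collection of :class:`ProteinRecord` with unique accessions."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        self._index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self._index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self._index[rec.accession] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records)


def read_fasta(path: str | Path, origin: Origin | None = None) -> ProteomeDB:
    """Read a FASTA file into a :class:`ProteomeDB`.

    Sequences are uppercased and trailing ``*`` stop codons stripped. The
    origin of each record is taken from its accession prefix (``SHUF_``,
    ``ENTRAP_``) unless ``origin`` overrides it for the whole file.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, AttributeError) as exc:  # malformed input
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    for i, rec in enumerate(parsed, start=1):
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        acc = rec.id
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=seq,
                description=rec.description[len(rec.id):].strip(),
                origin=origin if origin is not None else origin_from_accession(acc),
            )
        )
    return ProteomeDB(records)


def write_fasta(db: ProteomeDB, path: str | Path, width: int = 60) -> None:
    """Write a :class:`ProteomeDB` as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.description)
        for rec in db
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Quant reports
# ---------------------------------------------------------------------------

#: canonical column names used internally
CANONICAL_COLUMNS = [
    "run_id",
    "condition",
    "replicate",
    "protein_group",
    "precursor_id",
    "quantity",
    "n_peptides",
    "datapoints_per_peak",
    "peak_fwhm_sec",
]

MANDATORY_COLUMNS = ["run_id", "protein_group", "quantity"]


@dataclass(frozen=True)
class Dialect:
    """Maps vendor column names onto the canonical report schema."""

    name: str
    columns: Mapping[str, str]  # canonical -> vendor

    def rename_map(self) -> dict[str, str]:
        return {vendor: canon for canon, vendor in self.columns.items()}


SPECTRONAUT_LIKE = Dialect(
    name="spectronaut-like",
    columns={
        "run_id": "Run",
        "condition": "Condition",
        "replicate": "Replicate",
        "protein_group": "ProteinGroups",
        "precursor_id": "Precursor",
        "quantity": "Quantity",
        "n_peptides": "NrOfPeptides",
        "datapoints_per_peak": "DatapointsPerPeak",
        "peak_fwhm_sec": "FWHM",
    },
)

DIALECTS: dict[str, Dialect] = {"spectronaut-like": SPECTRONAUT_LIKE}


@dataclass
class QuantReport:
    """Long-format identification/quantification records, one row per
    run x protein group (x precursor)."""

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ReportFormatError(f"report missing mandatory columns: {missing}")
        key_cols = ["run_id", "protein_group"]
        if "precursor_id" in self.data.columns and self.data["precursor_id"].notna().any():
            key_cols.append("precursor_id")
        dup = self.data.duplicated(subset=key_cols, keep=False)
        if dup.any():
            offenders = (
                self.data.loc[dup, key_cols].drop_duplicates().head(10).to_dict("records")
            )
            raise ReportFormatError(f"duplicate {tuple(key_cols)} rows: {offenders}")
        if (self.data["quantity"] < 0).any():
            raise ReportFormatError("negative quantities present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def runs(self) -> list[str]:
        return list(pd.unique(self.data["run_id"]))


def read_quant_report(
    path: str | Path, dialect: Dialect | str = SPECTRONAUT_LIKE
) -> QuantReport:
    """Read a delimited quant report, mapping vendor columns via ``dialect``.

    Rows whose quantity cannot be parsed to a finite number are dropped and
    counted in ``QuantReport.n_dropped``.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ReportFormatError(f"unknown dialect {dialect!r}") from None
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    rename = {v: c for v, c in dialect.rename_map().items() if v in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        vendor = [dialect.columns[c] for c in missing]
        raise ReportFormatError(
            f"{path}: missing mandatory column(s) {vendor} for dialect {dialect.name!r}"
        )
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()
    df["quantity"] = pd.to_numeric(df["quantity"], errors="coerce")
    bad = ~np.isfinite(df["quantity"])
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-parseable quantity", path, n_dropped)
        df = df[~bad]
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return QuantReport(df.reset_index(drop=True), n_dropped=n_dropped)


def write_quant_report(
    report: QuantReport, path: str | Path, dialect: Dialect | str = SPECTRONAUT_LIKE
) -> None:
    """Write a report back to TSV/CSV in the given dialect's column names."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    out = report.data.rename(columns=dict(dialect.columns))
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# QuantMatrix
# ---------------------------------------------------------------------------

AGGREGATIONS = {"sum", "mean", "median", "max"}


@dataclass
class QuantMatrix:
    """Proteins x samples abundance matrix with explicit missingness.

    ``values`` holds the current working values (NaN = missing before
    imputation); ``observed`` is the immutable boolean mask of truly measured
    cells, preserved through imputation and transformation for audit.
    ``stage`` tracks the pipeline state (``raw`` -> ``filtered`` ->
    ``imputed`` -> ``log2``) so downstream steps can enforce ordering.
    ``linear`` retains the post-imputation linear-scale values once ``values``
    has been log-transformed.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    protein_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    observed: pd.DataFrame | None = None
    stage: str = "raw"
    linear: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.observed is None:
            self.observed = self.values.notna()
        if self.observed.shape != self.values.shape:
            raise ValueError("observed mask shape mismatch")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        if self.protein_meta.empty:
            self.protein_meta = pd.DataFrame(index=self.values.index)
        if not self.sample_meta.index.equals(self.values.columns):
            raise ValueError("sample_meta index does not match matrix columns")
        if not self.protein_meta.index.equals(self.values.index):
            raise ValueError("protein_meta index does not match matrix rows")
        with np.errstate(invalid="ignore"):
            if self.stage != "log2" and (self.values.to_numpy() < 0).any():
                raise ValueError("negative quantities in matrix")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_for(self, condition: str) -> list[str]:
        if "condition" not in self.sample_meta.columns:
            raise KeyError("sample_meta has no 'condition' column")
        mask = self.sample_meta["condition"] == condition
        if not mask.any():
            raise KeyError(f"unknown condition {condition!r}")
        return list(self.sample_meta.index[mask])

    def subset_proteins(self, keep: pd.Index | list[str], stage: str | None = None) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values.loc[keep],
            sample_meta=self.sample_meta,
            protein_meta=self.protein_meta.loc[keep],
            observed=self.observed.loc[keep],
            stage=stage or self.stage,
            linear=None if self.linear is None else self.linear.loc[keep],
        )

    def evolve(self, **kwargs) -> "QuantMatrix":
        return replace(self, **kwargs)


def pivot_matrix(
    report: QuantReport,
    level: str = "protein",
    aggregation: str = "sum",
) -> QuantMatrix:
    """Pivot a long report into a proteins x runs matrix.

    At ``level='protein'`` precursor rows belonging to one protein group are
    aggregated with ``aggregation`` (default ``sum``); at ``level='precursor'``
    rows are kept per precursor, indexed ``protein_group::precursor_id``.
    Cells with no record stay NaN (missing), never zero.
    """
    if len(report.data) == 0:
        raise ValueError("cannot pivot an empty report")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; choose from {sorted(AGGREGATIONS)}")
    df = report.data
    if level == "protein":
        index = "protein_group"
    elif level == "precursor":
        if "precursor_id" not in df.columns or df["precursor_id"].isna().all():
            raise ValueError("report has no precursor_id column; cannot pivot at precursor level")
        df = df.assign(
            _feature=df["protein_group"].astype(str) + "::" + df["precursor_id"].astype(str)
        )
        index = "_feature"
    else:
        raise ValueError(f"unknown level {level!r}")

    values = df.pivot_table(
        index=index, columns="run_id", values="quantity", aggfunc=aggregation, dropna=True
    )
    values.index.name = "protein_id"
    values.columns.name = "sample_id"
    # keep run order as first-seen in the report
    run_order = list(pd.unique(df["run_id"]))
    values = values[run_order]

    meta_cols = [c for c in ("condition", "replicate") if c in df.columns]
    if meta_cols:
        sample_meta = (
            df.groupby("run_id", sort=False)[meta_cols].first().reindex(run_order)
        )
    else:
        sample_meta = pd.DataFrame(index=pd.Index(run_order, name="sample_id"))
    sample_meta.index.name = "sample_id"

    if level == "protein":
        group_key = df["protein_group"]
    else:
        group_key = df["_feature"]
    prot_meta = pd.DataFrame(index=values.index)
    prot_meta["species"] = [species_from_accession(p.split("::")[0]) for p in values.index]
    if "n_peptides" in df.columns:
        npep = df.groupby(group_key)["n_peptides"].max()
        prot_meta["n_peptides"] = npep.reindex(values.index)
    return QuantMatrix(values=values, sample_meta=sample_meta, protein_meta=prot_meta)


def melt_matrix(matrix: QuantMatrix) -> pd.DataFrame:
    """Melt a matrix back to long (run_id, protein_group, quantity) triples of
    observed cells — the inverse of :func:`pivot_matrix` for unaggregated data."""
    long = (
        matrix.values.stack()
        .rename("quantity")
        .reset_index()
        .rename(columns={"protein_id": "protein_group", "sample_id": "run_id"})
    )
    return long[["run_id", "protein_group", "quantity"]]


def load_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a cells.tsv-style annotation (sample_id, cell_type, cell_diameter_um, is_blank)."""
    ann = pd.read_csv(path, sep="\t")
    if "sample_id" not in ann.columns:
        raise ReportFormatError(f"{path}: annotation needs a sample_id column")
    ann = ann.set_index("sample_id")
    if "is_blank" in ann.columns:
        ann["is_blank"] = ann["is_blank"].astype(bool)
    return ann


def write_manifest(path: str | Path, command: str, params: Mapping, seed: int | None) -> None:
    """Record CLI parameters and seed for reproducibility."""
    manifest = {"command": command, "params": dict(params), "seed": seed}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
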