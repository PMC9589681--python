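"""Domain types and file I/O for replication estimation from SCCG coverage.

The pipeline's shared vocabulary lives here: the gene-order map of
single-copy core genes (SCCGs) on a circular reference genome, per-sample
tables of reads assigned to those genes, per-replicate coverage profiles,
and the final replication estimates.

Conventions
-----------
* Coordinates are 0-based, half-open internally.  GFF3 input (1-based,
  inclusive) is converted at the boundary.
* All tables are UTF-8, tab-delimited; missing values are written as "NA".
* Reads are stored per gene only (gene id + read length); coverage is
  length-normalized per gene.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("replicore")

#: Reads shorter than this many bp are discarded on input.
DEFAULT_MIN_READ_LENGTH = 35

#: QC flag: sample had fewer reads than the rarefaction depth.
QC_BELOW_MIN_COVERAGE = "below_min_coverage"
#: QC flag: mean standardized slope was negative; estimate reported as NA.
QC_NEGATIVE_SLOPE = "negative_slope_removed"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneOrderMap:
    """Ordered SCCG coordinates on a (usually circular) reference genome.

    Parameters
    ----------
    reference_id : str
        Identifier of the reference genome.
    genome_length : int
        Total genome length L in bp; used to standardize slopes (R = b*L/2)
        and for circular arithmetic.
    genes : pandas.DataFrame
        Columns ``gene_id`` (unique), ``start``, ``end`` (0-based half-open).
        Sorted by ``start`` on construction; ``order_index`` and ``midpoint``
        columns are (re)assigned.
    circular : bool
        Whether the genome is circular (the default and the case the
        terminus-anchored model assumes).
    """

    reference_id: str
    genome_length: int
    genes: pd.DataFrame
    circular: bool = True

    def __post_init__(self) -> None:
        g = self.genes
        required = {"gene_id", "start", "end"}
        missing = required - set(g.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if len(g) == 0:
            raise ValueError("no genes")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        g = g.copy()
        g["gene_id"] = g["gene_id"].astype(str)
        g["start"] = g["start"].astype(np.int64)
        g["end"] = g["end"].astype(np.int64)
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        bad = g[(g["start"] < 0) | (g["start"] >= g["end"])]
        if len(bad):
            raise ValueError(
                f"gene {bad['gene_id'].iloc[0]!r} has invalid coordinates "
                f"({bad['start'].iloc[0]}, {bad['end'].iloc[0]})"
            )
        over = g[g["end"] > self.genome_length]
        if len(over):
            raise ValueError(
                f"gene {over['gene_id'].iloc[0]!r} ends at "
                f"{over['end'].iloc[0]} > genome_length {self.genome_length}"
            )
        g = g.sort_values(["start", "gene_id"], kind="mergesort").reset_index(drop=True)
        g["order_index"] = np.arange(len(g), dtype=np.int64)
        g["midpoint"] = (g["start"] + g["end"]) // 2
        self.genes = g

    # -- derived views ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        """Gene midpoints (bp), ordered by ``order_index``."""
        return self.genes["midpoint"].to_numpy()

    @property
    def gene_lengths(self) -> np.ndarray:
        return (self.genes["end"] - self.genes["start"]).to_numpy()

    @property
    def total_gene_length(self) -> int:
        return int(self.gene_lengths.sum())

    def order_index_of(self) -> pd.Series:
        """Mapping gene_id -> order_index."""
        return pd.Series(
            self.genes["order_index"].to_numpy(), index=self.genes["gene_id"]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrderMap):
            return NotImplemented
        return (
            self.reference_id == other.reference_id
            and self.genome_length == other.genome_length
            and self.circular == other.circular
            and self.genes[["gene_id", "start", "end"]].equals(
                other.genes[["gene_id", "start", "end"]]
            )
        )


@dataclass
class MappedReadTable:
    """One sample's reads assigned to SCCGs.

    ``records`` is a two-column frame (``gene_id``, ``read_length``) holding
    one row per read; a multiset, order carries no meaning.
    """

    sample_id: str
    records: pd.DataFrame
    ecotype_id: str = ""
    collection_time: float | None = None
    collection_date: datetime.date | None = None

    def __post_init__(self) -> None:
        r = self.records
        if not {"gene_id", "read_length"} <= set(r.columns):
            raise ValueError("records need gene_id and read_length columns")
        if self.collection_time is not None and not (0 <= self.collection_time < 24):
            raise ValueError("collection_time must be in [0, 24)")
        self.records = r[["gene_id", "read_length"]].reset_index(drop=True)

    @property
    def n_reads(self) -> int:
        return len(self.records)

    def validate_against(self, gene_order: GeneOrderMap) -> None:
        """Raise if any read maps to a gene absent from the gene-order map."""
        known = set(gene_order.gene_ids)
        seen = set(self.records["gene_id"].unique())
        unknown = seen - known
        if unknown:
            raise ValueError(
                f"sample {self.sample_id!r}: gene_id {sorted(unknown)[0]!r} "
                "not present in gene-order map"
            )

    def replace_records(self, records: pd.DataFrame) -> "MappedReadTable":
        return dataclasses.replace(self, records=records)


@dataclass
class CoverageProfile:
    """Per-gene coverage for one rarefaction replicate, in genome order.

    ``coverage[i]`` is the coverage (summed read bp / gene length, unit ×)
    of the gene with ``order_index`` i.
    """

    sample_id: str
    replicate_index: int
    coverage: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage, dtype=float)
        if cov.ndim != 1:
            raise ValueError("coverage must be 1-D")
        if (cov < 0).any():
            raise ValueError("coverage must be non-negative")
        self.coverage = cov

    @property
    def n_genes(self) -> int:
        return len(self.coverage)

    @property
    def mean(self) -> float:
        return float(self.coverage.mean())


@dataclass
class ReplicationEstimate:
    """Final per-sample replication estimate R_obs with QC metadata."""

    sample_id: str
    ecotype_id: str
    terminus_bp: int
    slope_per_bp: float
    R_obs: float
    se_R_obs: float
    n_replicates: int
    mean_coverage: float
    qc: frozenset[str] = field(default_factory=frozenset)

    @property
    def passed_qc(self) -> bool:
        return not self.qc


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gene_order(
    path: str | Path,
    format: str | None = None,
    genome_length: int | None = None,
    reference_id: str | None = None,
) -> GeneOrderMap:
    """Read a gene-order map from GFF3 or TSV.

    TSV dialect: header ``gene_id<TAB>start<TAB>end`` with 0-based half-open
    coordinates; genome length is taken from a ``#genome_length=<int>``
    comment line or from the ``genome_length`` argument.  GFF3 dialect:
    1-based inclusive ``start``/``end`` converted on read, gene id from the
    ``ID=`` attribute, genome length from the ``##sequence-region`` pragma.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        return _read_gene_order_gff3(path, genome_length, reference_id)
    if format == "tsv":
        return _read_gene_order_tsv(path, genome_length, reference_id)
    raise ValueError(f"unknown gene-order format {format!r}")


def _read_gene_order_tsv(
    path: Path, genome_length: int | None, reference_id: str | None
) -> GeneOrderMap:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = val.strip()
    if genome_length is None and "genome_length" in meta:
        genome_length = int(meta["genome_length"])
    if genome_length is None:
        raise ValueError(
            "genome_length not given and no '#genome_length=' header in TSV"
        )
    if reference_id is None:
        reference_id = meta.get("reference_id", path.stem)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if len(df) == 0:
        raise ValueError("no genes")
    return GeneOrderMap(
        reference_id=reference_id, genome_length=genome_length, genes=df
    )


def _read_gene_order_gff3(
    path: Path, genome_length: int | None, reference_id: str | None
) -> GeneOrderMap:
    rows = []
    seqid_seen = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seqid_seen = seqid_seen or parts[1]
                    if genome_length is None:
                        genome_length = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            seqid, _, _, start, end, _, _, _, attrs = fields[:9]
            seqid_seen = seqid_seen or seqid
            gene_id = None
            for item in attrs.split(";"):
                key, _, val = item.partition("=")
                if key.strip() == "ID":
                    gene_id = val.strip()
                    break
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID attribute: {line!r}")
            # GFF3 is 1-based inclusive -> 0-based half-open
            rows.append((gene_id, int(start) - 1, int(end)))
    if not rows:
        raise ValueError("no genes")
    if genome_length is None:
        raise ValueError("GFF3 lacks ##sequence-region; pass genome_length")
    df = pd.DataFrame(rows, columns=["gene_id", "start", "end"])
    return GeneOrderMap(
        reference_id=reference_id or seqid_seen or path.stem,
        genome_length=genome_length,
        genes=df,
    )


def write_gene_order(gene_order: GeneOrderMap, path: str | Path) -> None:
    """Write a gene-order map in the TSV dialect `read_gene_order` accepts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#reference_id={gene_order.reference_id}\n")
        fh.write(f"#genome_length={gene_order.genome_length}\n")
        gene_order.genes[["gene_id", "start", "end"]].to_csv(
            fh, sep="\t", index=False
        )


def read_mapped_reads(
    path: str | Path,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    ecotype_id: str = "",
) -> list[MappedReadTable]:
    """Read mapped-read tables from a TSV, one table per sample.

    Expected header: ``sample_id  gene_id  read_length`` with optional
    ``time_h`` and ``date`` columns.  Reads shorter than ``min_read_length``
    are discarded (the count is logged); length exactly at the minimum is
    retained.
    """
    df = pd.read_csv(
        Path(path),
        sep="\t",
        dtype={"sample_id": str, "gene_id": str},
    )
    required = {"sample_id", "gene_id", "read_length"}
    if not required <= set(df.columns):
        raise ValueError(f"reads TSV needs columns {sorted(required)}")
    n_before = len(df)
    df = df[df["read_length"] >= min_read_length]
    n_discarded = n_before - len(df)
    if n_discarded:
        logger.info(
            "discarded %d/%d reads shorter than %d bp",
            n_discarded, n_before, min_read_length,
        )
    tables = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        time_h = None
        date = None
        if "time_h" in grp.columns:
            vals = grp["time_h"].dropna().unique()
            if len(vals):
                time_h = float(vals[0])
        if "date" in grp.columns:
            vals = grp["date"].dropna().unique()
            if len(vals):
                date = datetime.date.fromisoformat(str(vals[0]))
        tables.append(
            MappedReadTable(
                sample_id=str(sample_id),
                records=grp[["gene_id", "read_length"]],
                ecotype_id=ecotype_id,
                collection_time=time_h,
                collection_date=date,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Estimate table round-trip
# ---------------------------------------------------------------------------

_EST_COLUMNS = [
    "sample_id", "ecotype_id", "terminus_bp", "R_obs", "se_R_obs",
    "n_replicates", "mean_coverage", "qc",
]


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.9g}"


def write_estimates(
    estimates: Sequence[ReplicationEstimate], path: str | Path
) -> None:
    """Write estimates as TSV; values round-trip at 9 significant digits.

    Samples flagged ``negative_slope_removed`` are written with R_obs = NA,
    the convention downstream consumers filter on.
    """
    rows = []
    for est in estimates:
        r_obs: float | None = est.R_obs
        if QC_NEGATIVE_SLOPE in est.qc or QC_BELOW_MIN_COVERAGE in est.qc:
            r_obs = float("nan")
        rows.append({
            "sample_id": est.sample_id,
            "ecotype_id": est.ecotype_id or "NA",
            "terminus_bp": est.terminus_bp,
            "R_obs": _fmt(r_obs),
            "se_R_obs": _fmt(est.se_R_obs),
            "n_replicates": est.n_replicates,
            "mean_coverage": _fmt(est.mean_coverage),
            "qc": ",".join(sorted(est.qc)) if est.qc else "NA",
        })
    pd.DataFrame(rows, columns=_EST_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def read_estimates(path: str | Path) -> list[ReplicationEstimate]:
    """Read back an estimates TSV written by `write_estimates`."""
    df = pd.read_csv(
        Path(path), sep="\t", dtype={"sample_id": str, "ecotype_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    out = []
    for _, row in df.iterrows():
        qc_raw = row["qc"]
        qc = frozenset() if pd.isna(qc_raw) else frozenset(str(qc_raw).split(","))
        out.append(
            ReplicationEstimate(
                sample_id=row["sample_id"],
                ecotype_id="" if pd.isna(row["ecotype_id"]) else row["ecotype_id"],
                terminus_bp=int(row["terminus_bp"]),
                slope_per_bp=float("nan"),
                R_obs=float(row["R_obs"]) if not pd.isna(row["R_obs"]) else float("nan"),
                se_R_obs=float(row["se_R_obs"]) if not pd.isna(row["se_R_obs"]) else float("nan"),
                n_replicates=int(row["n_replicates"]),
                mean_coverage=float(row["mean_coverage"]),
                qc=qc,
            )
        )
    return out
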