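"""Reading, writing and validation of the pipeline's tabular and sequence formats.

All tables are tab-delimited UTF-8 with a header row and no field quoting
(the dialect used by GEO supplementary tables).  Count tables are genes x
samples with the gene identifier in the first column.  GFF3 coordinates are
1-based inclusive on disk; loci are converted to 0-based half-open intervals
at this module boundary and stay that way internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

FRACTIONS = ("global", "RISC")


class FormatError(ValueError):
    """A file violates its declared format (wrong dtype, bad header, ...)."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (counts vs sample sheet, GFF3 vs FASTA) do not."""


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integers; index = gene ids, columns = sample ids,
        both unique, order as loaded.
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``fraction`` (``global`` or
        ``RISC``), ``condition`` and ``timepoint`` (may be empty string).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            _raise_non_integer(c)
        if (c.to_numpy() < 0).any():
            g, s = np.argwhere(c.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ConsistencyError(
                f"samples missing from sample sheet: {sorted(missing)}"
            )
        meta = self.sample_meta.loc[c.columns]
        bad = meta[~meta["fraction"].isin(FRACTIONS)]
        if len(bad):
            raise ConsistencyError(
                f"unknown fraction for samples {bad.index.tolist()}; "
                f"expected one of {FRACTIONS}"
            )
        if (meta["condition"].astype(str) == "").any():
            raise ConsistencyError("every sample needs a condition label")
        self.sample_meta = meta

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.sample_meta)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.sample_meta.loc[list(sample_ids)]
        )

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.sample_meta["condition"]:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class GeneLengths:
    """Exonic length (bp) per gene, used for FPKM."""

    lengths: pd.Series  # index gene id, positive integers (bp)

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise FormatError(f"non-positive gene lengths: {bad}")


@dataclass
class MiRNAAnnotation:
    """One mature miRNA: sequence, locus, and derived grouping labels.

    ``start``/``end`` are 0-based half-open (converted from GFF3).  ``seed``,
    ``family_id`` and ``cluster_id`` are filled in by
    :mod:`isletmir.organization`.
    """

    mirna_id: str
    mature_sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    seed: Optional[str] = None
    family_id: Optional[str] = None
    cluster_id: Optional[str] = None


def _raise_non_integer(df: pd.DataFrame) -> None:
    for s in df.columns:
        col = df[s]
        if np.issubdtype(col.dtype, np.integer):
            continue
        as_float = pd.to_numeric(col, errors="coerce")
        bad = as_float.isna() | (as_float != np.floor(as_float))
        g = col.index[bad][0] if bad.any() else col.index[0]
        raise FormatError(
            f"non-integer count {col.loc[g]!r} for gene {g!r}, sample {s!r}"
        )


def load_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    """Load the TSV sample sheet (sample_id, fraction, condition[, timepoint])."""
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "fraction", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if "timepoint" not in sheet.columns:
        sheet["timepoint"] = ""
    if sheet["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    return sheet.set_index("sample_id")


def load_count_table(
    path: Union[str, Path], sample_sheet_path: Union[str, Path]
) -> CountMatrix:
    """Load a genes x samples TSV count table validated against a sample sheet.

    Row and column order are preserved from the file.  Non-integer or
    negative entries and samples absent from the sheet are errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if any(not np.issubdtype(dt, np.integer) for dt in raw.dtypes):
        _raise_non_integer(raw)
    counts = raw.astype(np.int64)
    counts.index = counts.index.astype(str)
    meta = load_sample_sheet(sample_sheet_path)
    return CountMatrix(counts, meta)


def write_count_table(cm: CountMatrix, path: Union[str, Path]) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(meta: pd.DataFrame, path: Union[str, Path]) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def load_gene_lengths(path: Union[str, Path]) -> GeneLengths:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    col = tab.columns[0]
    return GeneLengths(tab[col].astype(np.int64))


def write_gene_lengths(gl: GeneLengths, path: Union[str, Path]) -> None:
    gl.lengths.rename("exonic_length_bp").to_csv(path, sep="\t", index_label="gene_id")


def load_mirna_annotation(
    gff3_path: Union[str, Path], fasta_path: Union[str, Path]
) -> list[MiRNAAnnotation]:
    """Join GFF3 miRNA loci with mature FASTA sequences by identifier.

    Matching is by the GFF3 ``ID`` attribute against FASTA record ids,
    independent of record order.  Records present in only one file raise a
    :class:`ConsistencyError` listing the offending identifiers.  GFF3
    1-based inclusive coordinates become 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci: dict[str, tuple[str, int, int, str]] = {}
    order: list[str] = []
    for feat in db.all_features():
        ident = feat.attributes.get("ID", [feat.id])[0]
        loci[ident] = (feat.seqid, feat.start - 1, feat.end, feat.strand)
        order.append(ident)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    only_gff = sorted(set(loci) - set(seqs))
    only_fasta = sorted(set(seqs) - set(loci))
    if only_gff or only_fasta:
        raise ConsistencyError(
            f"GFF3/FASTA cross-reference failure; ids only in GFF3: {only_gff}; "
            f"ids only in FASTA: {only_fasta}"
        )
    return [
        MiRNAAnnotation(
            mirna_id=i,
            mature_sequence=seqs[i].upper().replace("T", "U"),
            chrom=loci[i][0],
            start=loci[i][1],
            end=loci[i][2],
            strand=loci[i][3],
        )
        for i in order
    ]


def write_mirna_gff3(annotations: Sequence[MiRNAAnnotation], path: Union[str, Path]) -> None:
    """Write loci as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.chrom}\tisletmir\tmiRNA\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t.\tID={a.mirna_id}\n"
            )


def write_mirna_fasta(annotations: Sequence[MiRNAAnnotation], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f">{a.mirna_id}\n{a.mature_sequence}\n")


# ---------------------------------------------------------------------------
# Result-record schemas (shared by diffexpr / risc / quantify outputs)

DE_RESULT_COLUMNS = [
    "gene_id", "mean_A", "mean_B", "log2fc", "pvalue", "qvalue", "status",
]
DIRECT_TARGET_COLUMNS = [
    "gene_id", "mode", "risc_log2fc", "risc_q", "global_log2fc", "global_q",
]
CONCORDANCE_COLUMNS = [
    "gene_id", "perturbation_direction", "developmental_direction",
    "developmental_q", "class",
]
_SCHEMAS = {
    "DEResult": DE_RESULT_COLUMNS,
    "DirectTargetCall": DIRECT_TARGET_COLUMNS,
    "ConcordanceRecord": CONCORDANCE_COLUMNS,
}


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    schema_names = set()
    for r in records:
        if dataclasses.is_dataclass(r):
            schema_names.add(type(r).__name__)
            rows.append(dataclasses.asdict(r))
        else:
            raise TypeError(f"unsupported record type {type(r)!r}")
    if len(schema_names) > 1:
        raise ValueError(f"mixed record schemas: {sorted(schema_names)}")
    name = schema_names.pop() if schema_names else None
    cols = _SCHEMAS.get(name) if name else None
    return pd.DataFrame(rows, columns=cols if cols else None)


def write_results_table(records, path: Union[str, Path], schema: Optional[str] = None) -> None:
    """Write DE / direct-target / concordance records as TSV.

    ``records`` may be a DataFrame or a homogeneous list of the record
    dataclasses; mixing schemas is a usage error.  Columns follow the fixed
    schema order; floats carry enough digits that a read-back agrees to
    better than 1e-6 relative.  An empty record list with an explicit
    ``schema`` yields a header-only file.
    """
    frame = _records_to_frame(records)
    if frame.empty and schema is not None:
        frame = pd.DataFrame(columns=_SCHEMAS[schema])
    matched = None
    for name, cols in _SCHEMAS.items():
        if set(cols) <= set(frame.columns):
            matched = cols
            break
    if matched is not None:
        frame = frame[matched + [c for c in frame.columns if c not in matched]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
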