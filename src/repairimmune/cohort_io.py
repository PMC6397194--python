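"""Readers, writers and core containers for tumor-cohort data.

This module defines the in-memory data model shared by the rest of the
package — somatic variants, the expression matrix with its per-gene
cohort z-score view, gene-set collections (GMT), peptide–allele binding
affinity tables, and clinical records — together with readers for the
plain-text formats they are exchanged in (MAF, TSV, GMT, FASTA) and the
matching writers used for round-tripping.

Conventions applied on ingest:

* gene symbols are uppercased; no HGNC aliasing is attempted,
* unknown variant classifications map to ``"other"``,
* missing SIFT/CADD scores are left absent, never imputed,
* per-gene z-scores use the sample (n−1) standard deviation; genes with
  zero variance get z = 0 and are flagged rather than set to NaN.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SomaticVariant",
    "VARIANT_CLASSES",
    "MafDialect",
    "ExpressionMatrix",
    "GeneSetCollection",
    "AffinityTable",
    "ClinicalRecord",
    "read_maf",
    "write_maf",
    "read_expression",
    "write_expression",
    "compute_zscores",
    "read_gmt",
    "write_gmt",
    "read_affinity",
    "write_affinity",
    "read_clinical",
    "write_clinical",
    "read_protein_fasta",
    "write_protein_fasta",
]


class FormatError(ValueError):
    """An input file violates the expected format."""


#: Canonical variant classes used throughout the package.
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift-indel",
    "inframe-indel",
    "splice",
    "silent",
    "other",
)


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant call (one MAF row).

    Parameters
    ----------
    sample_id : str
        Tumor sample barcode.
    gene : str
        HGNC symbol (uppercased).
    classification : str
        One of :data:`VARIANT_CLASSES`.
    protein_pos : int, optional
        1-based residue index of the protein change.
    ref_aa, alt_aa : str, optional
        Single-letter amino acids; present only for missense changes.
    sift : float, optional
        SIFT score in [0, 1]; smaller is more damaging.
    cadd : float, optional
        CADD phred-scaled score; larger is more damaging.
    intron_offset : int, optional
        Signed distance in bp from the nearest exon boundary
        (negative = intronic side).
    """

    sample_id: str
    gene: str
    classification: str
    protein_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    sift: float | None = None
    cadd: float | None = None
    intron_offset: int | None = None

    def __post_init__(self) -> None:
        if self.classification not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant classification {self.classification!r}")
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError("protein_pos must be >= 1")
        if self.sift is not None and not (0.0 <= self.sift <= 1.0):
            raise ValueError(f"SIFT score {self.sift} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"CADD score {self.cadd} must be >= 0")
        if (
            self.classification == "missense"
            and self.ref_aa is not None
            and self.alt_aa is not None
            and self.ref_aa == self.alt_aa
        ):
            raise ValueError("missense variant must change the residue")


# TCGA/cBioPortal MAF headers vary; the dialect maps logical fields to
# the column names of a particular export.
@dataclass(frozen=True)
class MafDialect:
    sample: str = "Tumor_Sample_Barcode"
    gene: str = "Hugo_Symbol"
    classification: str = "Variant_Classification"
    protein_change: tuple[str, ...] = ("Protein_Change", "HGVSp_Short")
    sift: str = "SIFT"
    cadd: str = "CADD"
    intron_offset: str = "Intron_Offset"
    classification_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "Missense_Mutation": "missense",
            "Nonsense_Mutation": "nonsense",
            "Frame_Shift_Del": "frameshift-indel",
            "Frame_Shift_Ins": "frameshift-indel",
            "In_Frame_Del": "inframe-indel",
            "In_Frame_Ins": "inframe-indel",
            "Splice_Site": "splice",
            "Splice_Region": "splice",
            "Silent": "silent",
        }
    )


_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


def _parse_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.upper() in {"NA", "NAN", ".", ""}:
        return None
    try:
        return float(text)
    except ValueError:
        # cBioPortal-style annotation e.g. "deleterious(0.03)"
        match = re.search(r"\(([\d.eE+-]+)\)", text)
        if match:
            return float(match.group(1))
        return None


def read_maf(path: str | Path, dialect: MafDialect | None = None) -> list[SomaticVariant]:
    """Read a tab-delimited MAF into :class:`SomaticVariant` records.

    Unknown variant classifications map to ``"other"``; absent SIFT/CADD
    columns or cells are left as ``None``.

    Raises
    ------
    FormatError
        If a required column is missing or a row lacks a gene symbol.
    """
    dialect = dialect or MafDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.empty and frame.columns.empty:
        logger.warning("MAF %s is empty", path)
        return []
    for col, label in ((dialect.sample, "sample"), (dialect.gene, "gene"), (dialect.classification, "classification")):
        if col not in frame.columns:
            raise FormatError(f"MAF {path} missing required {label} column {col!r}")
    if frame.empty:
        logger.warning("MAF %s has a header but no rows", path)
        return []

    protein_col = next((c for c in dialect.protein_change if c in frame.columns), None)
    variants: list[SomaticVariant] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        gene = record[dialect.gene]
        if gene is None or (isinstance(gene, float) and np.isnan(gene)) or not str(gene).strip():
            raise FormatError(f"MAF {path}: row {row_number} lacks a gene symbol")
        raw_class = str(record[dialect.classification]).strip()
        classification = dialect.classification_map.get(raw_class, "other")

        protein_pos = ref_aa = alt_aa = None
        if protein_col is not None:
            change = record.get(protein_col)
            if change is not None and isinstance(change, str):
                match = _PROTEIN_CHANGE_RE.match(change.strip())
                if match:
                    ref_aa, pos, alt = match.groups()
                    protein_pos = int(pos)
                    alt_aa = alt
        if classification != "missense":
            ref_aa = alt_aa = None

        offset = None
        if dialect.intron_offset in frame.columns:
            raw = _parse_float(record.get(dialect.intron_offset))
            offset = int(raw) if raw is not None else None

        variants.append(
            SomaticVariant(
                sample_id=str(record[dialect.sample]).strip(),
                gene=str(gene).strip().upper(),
                classification=classification,
                protein_pos=protein_pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                sift=_parse_float(record.get(dialect.sift)) if dialect.sift in frame.columns else None,
                cadd=_parse_float(record.get(dialect.cadd)) if dialect.cadd in frame.columns else None,
                intron_offset=offset,
            )
        )
    return variants


_CLASS_TO_MAF = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "frameshift-indel": "Frame_Shift_Del",
    "inframe-indel": "In_Frame_Del",
    "splice": "Splice_Site",
    "silent": "Silent",
    "other": "Other",
}


def write_maf(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    """Write variants as a TCGA-dialect MAF (inverse of :func:`read_maf`)."""
    rows = []
    for v in variants:
        change = ""
        if v.classification == "missense" and v.protein_pos is not None:
            change = f"p.{v.ref_aa}{v.protein_pos}{v.alt_aa}"
        rows.append(
            {
                "Tumor_Sample_Barcode": v.sample_id,
                "Hugo_Symbol": v.gene,
                "Variant_Classification": _CLASS_TO_MAF[v.classification],
                "Protein_Change": change,
                "SIFT": "" if v.sift is None else repr(v.sift),
                "CADD": "" if v.cadd is None else repr(v.cadd),
                "Intron_Offset": "" if v.intron_offset is None else str(v.intron_offset),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with an optional z-score view.

    ``values`` holds non-negative normalized expression; ``zscores`` is
    filled by :func:`compute_zscores` and standardizes each gene across
    the cohort.
    """

    values: pd.DataFrame
    zscores: pd.DataFrame | None = None
    zero_variance_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample identifiers in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_expression(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited genes × samples matrix.

    The first column holds gene symbols, the header row sample IDs.
    Duplicate gene rows are collapsed by their mean (logged); any
    non-numeric cell raises :class:`FormatError` with its coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str).str.upper()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise FormatError(f"non-numeric expression value at gene {gene!r}, sample {sample!r} in {path}")
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values=numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def compute_zscores(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardize each gene across samples: z = (x − mean) / sd.

    Uses the sample (n−1) standard deviation. Genes with zero variance
    get z = 0 and are listed in ``zero_variance_genes`` so downstream
    median comparisons stay defined.

    Raises
    ------
    ValueError
        With fewer than 2 samples (z-score undefined).
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=ddof)
    flat = sds == 0
    safe_sds = sds.mask(flat, 1.0)
    z = values.sub(means, axis=0).div(safe_sds, axis=0)
    z[flat] = 0.0
    return replace(matrix, zscores=z, zero_variance_genes=tuple(values.index[flat]))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (immune cell-type metagenes, gene panels)."""

    sets: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line a set name, a description, then genes."""
    sets: dict[str, tuple[str, ...]] = {}
    path = Path(path)
    with path.open() as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT {path} line {line_number}: expected name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise FormatError(f"GMT {path}: duplicate set name {name!r}")
            genes = tuple(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"GMT {path} line {line_number}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for name, genes in collection.sets.items():
            handle.write("\t".join([name, name, *genes]) + "\n")


class AffinityTable:
    """Peptide–allele MHC binding affinities in nM IC50."""

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        for (peptide, allele), ic50 in entries.items():
            if ic50 <= 0:
                raise FormatError(f"IC50 must be positive: {peptide}/{allele} = {ic50}")
            if peptide != peptide.upper():
                raise FormatError(f"peptide {peptide!r} must be uppercase")
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def lookup(self, peptide: str, allele: str) -> float:
        try:
            return self.entries[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no affinity entry for peptide {peptide!r} on allele {allele!r}") from None


def read_affinity(path: str | Path) -> AffinityTable:
    """Read a TSV with columns ``peptide``, ``allele``, ``ic50_nM``."""
    frame = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "ic50_nM"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"affinity table {path} missing columns {sorted(missing)}")
    entries = {
        (str(row.peptide).upper(), str(row.allele)): float(row.ic50_nM)
        for row in frame.itertuples(index=False)
    }
    return AffinityTable(entries)


def write_affinity(table: AffinityTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(p, a, ic50) for (p, a), ic50 in table.entries.items()],
        columns=["peptide", "allele", "ic50_nM"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical descriptors used by the survival analyses."""

    sample_id: str
    os_time: float
    os_event: bool
    dfs_time: float
    dfs_event: bool
    subtype: str | None = None
    smoking: str | None = None

    def __post_init__(self) -> None:
        if self.os_time < 0 or self.dfs_time < 0:
            raise ValueError("survival times must be >= 0")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV into a sample-indexed frame.

    Columns: ``sample_id``, ``os_time``, ``os_event``, ``dfs_time``,
    ``dfs_event`` and optionally ``subtype``/``smoking``.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "os_time", "os_event", "dfs_time", "dfs_event"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"clinical table {path} missing columns {sorted(missing)}")
    if (frame["os_time"] < 0).any() or (frame["dfs_time"] < 0).any():
        raise FormatError(f"clinical table {path} contains negative survival times")
    frame = frame.set_index("sample_id")
    frame["os_event"] = frame["os_event"].astype(bool)
    frame["dfs_event"] = frame["dfs_event"].astype(bool)
    return frame


def write_clinical(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out["os_event"] = out["os_event"].astype(int)
    out["dfs_event"] = out["dfs_event"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by gene symbol (record id)."""
    return {record.id.upper(): str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")
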