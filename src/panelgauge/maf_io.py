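"""Readers and writers for somatic-mutation tables and gene models.

Three external formats are handled here:

* **MAF** (Mutation Annotation Format) — tab-delimited somatic mutation
  calls, one row per mutation, TCGA column conventions
  (``Hugo_Symbol``, ``Tumor_Sample_Barcode``, ``Variant_Classification``,
  ``Variant_Type``).  Lines starting with ``#`` are comments.
* **CCDS-style gene models** — tab-delimited, one row per consensus
  coding-sequence entry, with a ``gene`` column and a ``cds_locations``
  column holding a bracketed, comma-separated list of ``start-end``
  genomic intervals.
* **Panel gene lists** — plain text, one Hugo symbol per line, ``#``
  comments allowed.

Coordinate convention: ``cds_locations`` intervals are treated as
*inclusive on both ends* (length = end − start + 1), the CCDS text
dialect.  Intervals belonging to the same gene — including intervals from
distinct rows/transcripts — are unioned before the coding length is
computed, so overlapping transcripts are never double counted.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# The 16 variant classifications annotated in a TCGA-style MAF.
MAF_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Silent",
        "Nonsense_Mutation",
        "Intron",
        "3'UTR",
        "5'UTR",
        "Splice_Site",
        "RNA",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
        "In_Frame_Del",
        "3'Flank",
        "5'Flank",
        "Translation_Start_Site",
    }
)

#: Variant types distinguished by the counting modes; anything else is "other".
KNOWN_VARIANT_TYPES: frozenset[str] = frozenset({"SNP", "INS", "DEL"})

#: TCGA sample barcodes identify the patient in their first 12 characters.
DEFAULT_BARCODE_LENGTH = 12

_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

_CCDS_COLUMNS = (
    "#chromosome",
    "nc_accession",
    "gene",
    "gene_id",
    "ccds_id",
    "ccds_status",
    "cds_strand",
    "cds_from",
    "cds_to",
    "cds_locations",
    "match_type",
)


class MafFormatError(ValueError):
    """A MAF file violates the expected column/row contract."""


class GeneModelFormatError(ValueError):
    """A CCDS-style gene-model file cannot be parsed."""


class PanelDefinitionError(ValueError):
    """A panel gene list is unusable (e.g. no symbol matches the universe)."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation: which patient, which gene, which class.

    ``variant_type`` distinguishes point mutations (SNP) from indels;
    values outside {SNP, INS, DEL} are normalised to ``"other"``.
    """

    patient_id: str
    gene: str
    variant_classification: str
    variant_type: str = "SNP"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.variant_classification not in MAF_CLASSES:
            raise ValueError(
                f"unknown Variant_Classification {self.variant_classification!r}"
            )
        if self.variant_type not in KNOWN_VARIANT_TYPES:
            object.__setattr__(self, "variant_type", "other")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its merged CDS intervals and total coding length.

    ``cds_intervals`` is stored normalised — sorted, non-overlapping,
    inclusive on both ends — and ``cds_length_bp`` always equals the
    total length of that union.
    """

    gene: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_length_bp: int = field(default=0)

    def __post_init__(self) -> None:
        merged = merge_intervals(self.cds_intervals)
        object.__setattr__(self, "cds_intervals", merged)
        object.__setattr__(
            self, "cds_length_bp", sum(end - start + 1 for start, end in merged)
        )


@dataclass(frozen=True)
class Panel:
    """A named gene set with its target-region size in megabases.

    ``size_mb`` defaults to the summed CDS length of the member genes;
    it may be overridden (e.g. with a vendor-documented footprint).
    """

    name: str
    genes: frozenset[str]
    size_mb: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelDefinitionError(f"panel {self.name!r} has no genes")
        if not self.size_mb > 0:
            raise PanelDefinitionError(
                f"panel {self.name!r} size_mb must be positive, got {self.size_mb}"
            )


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Union inclusive intervals: sort, then merge overlapping or adjacent.

    Adjacent intervals ([100-199], [200-299]) are merged; this never
    changes the total length since the inputs are integer-inclusive.
    """
    ordered = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ordered:
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def truncate_barcode(barcode: str, length: int | None = DEFAULT_BARCODE_LENGTH) -> str:
    """Map a sample barcode to a patient identifier by prefix truncation."""
    barcode = barcode.strip()
    if length is None:
        return barcode
    return barcode[:length]


def read_maf(
    path: str | Path,
    strict: bool = True,
    barcode_length: int | None = DEFAULT_BARCODE_LENGTH,
) -> list[MutationRecord]:
    """Read a MAF file into a list of :class:`MutationRecord`.

    Parameters
    ----------
    path:
        Tab-delimited MAF file; ``#`` comment lines are skipped.
    strict:
        If True, a row with an unknown ``Variant_Classification`` raises
        :class:`MafFormatError`; if False it is logged and skipped.
    barcode_length:
        Sample barcodes are truncated to this many characters to obtain
        the patient identifier (TCGA convention: 12).  ``None`` disables
        truncation.

    Duplicate rows are kept: TMB counts MAF rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    for column in _REQUIRED_MAF_COLUMNS:
        if column not in table.columns:
            raise MafFormatError(f"{path}: missing required MAF column {column!r}")
    if "Variant_Type" not in table.columns:
        logger.warning("%s: no Variant_Type column; assuming SNP for all rows", path)
        table["Variant_Type"] = "SNP"

    records: list[MutationRecord] = []
    skipped = 0
    class_counts: Counter[str] = Counter()
    for row in table.itertuples(index=False):
        classification = getattr(row, "Variant_Classification").strip()
        if classification not in MAF_CLASSES:
            if strict:
                raise MafFormatError(
                    f"{path}: unknown Variant_Classification {classification!r}"
                )
            skipped += 1
            continue
        records.append(
            MutationRecord(
                patient_id=truncate_barcode(
                    getattr(row, "Tumor_Sample_Barcode"), barcode_length
                ),
                gene=getattr(row, "Hugo_Symbol").strip(),
                variant_classification=classification,
                variant_type=getattr(row, "Variant_Type").strip(),
            )
        )
        class_counts[classification] += 1

    if not records:
        logger.warning("%s: no mutation records parsed", path)
    logger.info(
        "%s: %d records parsed (%d skipped); per-class counts: %s",
        path,
        len(records),
        skipped,
        dict(sorted(class_counts.items())),
    )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a MAF file round-trippable through :func:`read_maf`."""
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Tabulate records with standard MAF column names."""
    return pd.DataFrame(
        [
            (r.patient_id, r.gene, r.variant_classification, r.variant_type)
            for r in records
        ],
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Variant_Classification",
            "Variant_Type",
        ],
    )[["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "Variant_Type"]]


_INTERVAL_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


def _parse_cds_locations(text: str, path: Path, line_no: int) -> list[tuple[int, int]]:
    inner = text.strip()
    if inner.startswith("[") and inner.endswith("]"):
        inner = inner[1:-1]
    intervals: list[tuple[int, int]] = []
    for chunk in inner.split(","):
        if not chunk.strip():
            continue
        match = _INTERVAL_RE.match(chunk)
        if match is None:
            raise GeneModelFormatError(
                f"{path}:{line_no}: malformed interval {chunk.strip()!r} in cds_locations"
            )
        start, end = int(match.group(1)), int(match.group(2))
        if end < start:
            raise GeneModelFormatError(
                f"{path}:{line_no}: interval end {end} < start {start}"
            )
        intervals.append((start, end))
    return intervals


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read a CCDS-style file into a mapping gene → :class:`GeneModel`.

    Rows whose ``cds_locations`` field is ``-`` (withdrawn entries) are
    skipped.  Intervals from multiple rows of the same gene are unioned
    before the coding length is computed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table.columns = [c.lstrip("#").strip() for c in table.columns]
    for column in ("gene", "cds_locations"):
        if column not in table.columns:
            raise GeneModelFormatError(
                f"{path}: missing required column {column!r}"
            )

    per_gene: dict[str, list[tuple[int, int]]] = {}
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        locations = getattr(row, "cds_locations").strip()
        if locations in ("", "-"):
            continue
        gene = getattr(row, "gene").strip()
        per_gene.setdefault(gene, []).extend(
            _parse_cds_locations(locations, path, line_no)
        )

    models = {
        gene: GeneModel(gene=gene, cds_intervals=tuple(intervals))
        for gene, intervals in per_gene.items()
    }
    total_bp = sum(m.cds_length_bp for m in models.values())
    logger.info(
        "%s: %d gene models, total coding length %.4f Mb",
        path,
        len(models),
        total_bp / 1e6,
    )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a CCDS-dialect file readable by :func:`read_gene_models`.

    Bookkeeping columns the models do not carry (accessions, status) are
    filled with placeholders; coordinates and gene symbols round-trip.
    """
    rows = []
    for i, model in enumerate(models):
        locations = "[" + ", ".join(f"{s}-{e}" for s, e in model.cds_intervals) + "]"
        rows.append(
            (
                "1",
                "NC_000001.0",
                model.gene,
                str(i + 1),
                f"CCDS{i + 1}.1",
                "Public",
                "+",
                str(model.cds_intervals[0][0]),
                str(model.cds_intervals[-1][1]),
                locations,
                "Identical",
            )
        )
    pd.DataFrame(rows, columns=_CCDS_COLUMNS).to_csv(path, sep="\t", index=False)


def load_panel(
    genes_path: str | Path,
    gene_models: Mapping[str, GeneModel],
    name: str | None = None,
    size_override_mb: float | None = None,
) -> tuple[Panel, list[str]]:
    """Load a panel gene list and derive its size from the gene universe.

    Returns the :class:`Panel` together with the list of symbols that did
    not match the universe (reported, never silently dropped).  Symbols
    are matched case-sensitively after whitespace stripping.
    """
    genes_path = Path(genes_path)
    if not genes_path.exists():
        raise FileNotFoundError(genes_path)
    if size_override_mb is not None and size_override_mb <= 0:
        raise PanelDefinitionError(
            f"size_override_mb must be positive, got {size_override_mb}"
        )

    symbols: list[str] = []
    for line in genes_path.read_text().splitlines():
        symbol = line.split("#", 1)[0].strip()
        if symbol:
            symbols.append(symbol)

    matched = [s for s in symbols if s in gene_models]
    unmatched = [s for s in symbols if s not in gene_models]
    if unmatched:
        logger.warning(
            "%s: %d symbols not in gene universe: %s",
            genes_path,
            len(unmatched),
            ", ".join(unmatched[:10]) + ("..." if len(unmatched) > 10 else ""),
        )
    if not matched:
        raise PanelDefinitionError(
            f"{genes_path}: no panel gene matches the loaded gene universe"
        )

    if size_override_mb is not None:
        size_mb = float(size_override_mb)
    else:
        size_mb = sum(gene_models[g].cds_length_bp for g in set(matched)) / 1e6
    panel = Panel(
        name=name or genes_path.stem, genes=frozenset(matched), size_mb=size_mb
    )
    return panel, unmatched
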