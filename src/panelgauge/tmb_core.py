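"""TMB computation: mutation-class filtering, per-patient burden, hypermutation.

Tumor mutational burden (TMB) is the number of qualifying somatic
mutations in a target region divided by the size of that region in
megabases.  Which mutations qualify depends on the counting mode:

* ``total_point`` — all coding point mutations, synonymous included
  (the FoundationOne CDx convention);
* ``nonsynonymous`` — coding point mutations excluding Silent
  (the MSK-IMPACT convention).

Four classes annotated outside the coding region (Intron, RNA, 3'Flank,
5'Flank) are never counted; UTR classes and indels are likewise outside
both default modes (indels are not point mutations), though the class
sets are user-overridable because conventions differ between assays.

Hypermutated patients are defined by whole-exome total-point TMB above a
cutoff (default 50 mutations/Mb) regardless of the evaluation mode, so
the hypermutated/non-hypermutated split is identical across modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .maf_io import MAF_CLASSES, MutationRecord, Panel

logger = logging.getLogger(__name__)

#: Classes annotated outside the coding region — never counted in TMB.
REGION_EXCLUDED_CLASSES: frozenset[str] = frozenset(
    {"Intron", "RNA", "3'Flank", "5'Flank"}
)

#: Coding point-mutation classes (total-point counting, F1CDx-style).
TOTAL_POINT_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Silent",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Splice_Site",
    }
)

#: Nonsynonymous counting (MSK-IMPACT-style): total-point minus Silent.
NONSYNONYMOUS_CLASSES: frozenset[str] = TOTAL_POINT_CLASSES - {"Silent"}

#: WES-level total-point TMB above this value flags a hypermutated patient.
DEFAULT_HYPERMUTATION_CUTOFF = 50.0


class _AllGenes:
    """Sentinel: compute TMB over the whole exome, not a gene subset."""

    def __contains__(self, gene: object) -> bool:
        return True

    def __repr__(self) -> str:  # pragma: no cover
        return "ALL_GENES"


ALL_GENES = _AllGenes()


@dataclass(frozen=True)
class MutationMode:
    """A named mutation-counting convention.

    ``snp_only`` restricts counting to records with variant_type SNP,
    the default for both point-mutation modes.
    """

    name: str
    included_classes: frozenset[str]
    snp_only: bool = True

    def __post_init__(self) -> None:
        unknown = self.included_classes - MAF_CLASSES
        if unknown:
            raise ValueError(f"unknown classes in mode {self.name!r}: {sorted(unknown)}")
        overlap = self.included_classes & REGION_EXCLUDED_CLASSES
        if overlap:
            raise ValueError(
                f"mode {self.name!r} includes non-coding classes: {sorted(overlap)}"
            )


TOTAL_POINT = MutationMode("total_point", TOTAL_POINT_CLASSES)
NONSYNONYMOUS = MutationMode("nonsynonymous", NONSYNONYMOUS_CLASSES)

MODES: dict[str, MutationMode] = {m.name: m for m in (TOTAL_POINT, NONSYNONYMOUS)}


def get_mode(name: str) -> MutationMode:
    """Look up a built-in counting mode by name."""
    try:
        return MODES[name]
    except KeyError:
        raise ValueError(
            f"unknown mutation mode {name!r}; choose from {sorted(MODES)}"
        ) from None


@dataclass(frozen=True)
class PairedTMB:
    """Per-patient (panel-based x, WES-based y) TMB pair.

    ``hypermutated`` reflects the WES-level total-point TMB against the
    hypermutation cutoff, not the evaluation mode.
    """

    patient_id: str
    panel_tmb: float
    wes_tmb: float
    cancer_type: str | None = None
    hypermutated: bool = False

    def __post_init__(self) -> None:
        for label, value in (("panel_tmb", self.panel_tmb), ("wes_tmb", self.wes_tmb)):
            if not value >= 0:
                raise ValueError(f"{label} must be finite and non-negative, got {value}")


def classify_mutation(classification: str, mode: MutationMode) -> bool:
    """Return True iff a mutation of this class is counted under ``mode``."""
    if classification not in MAF_CLASSES:
        raise ValueError(f"unknown Variant_Classification {classification!r}")
    return classification in mode.included_classes


def record_counts(record: MutationRecord, mode: MutationMode) -> bool:
    """Class filter plus the mode's variant-type restriction."""
    if not classify_mutation(record.variant_classification, mode):
        return False
    return not mode.snp_only or record.variant_type == "SNP"


def compute_tmb(
    records: Iterable[MutationRecord],
    target_genes,
    region_size_mb: float,
    mode: MutationMode = TOTAL_POINT,
) -> dict[str, float]:
    """Per-patient TMB over a target gene set.

    Every patient appearing in ``records`` gets an entry; patients whose
    mutations are all filtered out get TMB 0.0, not absence.  Pass
    :data:`ALL_GENES` as ``target_genes`` for whole-exome TMB.
    """
    if not region_size_mb > 0:
        raise ValueError(f"region_size_mb must be positive, got {region_size_mb}")
    counts: dict[str, int] = {}
    for record in records:
        counts.setdefault(record.patient_id, 0)
        if record.gene in target_genes and record_counts(record, mode):
            counts[record.patient_id] += 1
    return {patient: n / region_size_mb for patient, n in counts.items()}


def label_hypermutated(
    wes_tmb: float, cutoff: float = DEFAULT_HYPERMUTATION_CUTOFF
) -> bool:
    """True iff WES-based total-point TMB strictly exceeds the cutoff."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return wes_tmb > cutoff


def pair_tmb(
    records: Iterable[MutationRecord],
    panel: Panel,
    wes_region_mb: float,
    mode: MutationMode = TOTAL_POINT,
    hyper_cutoff: float = DEFAULT_HYPERMUTATION_CUTOFF,
    cancer_types: Mapping[str, str] | None = None,
) -> list[PairedTMB]:
    """Panel-based vs WES-based TMB for every patient in the cohort.

    panel_tmb counts mutations in ``panel.genes`` over ``panel.size_mb``;
    wes_tmb counts mutations in all genes over ``wes_region_mb``.  Both
    use ``mode``.  The hypermutation flag always comes from WES-level
    *total-point* TMB versus ``hyper_cutoff``.
    """
    if not wes_region_mb > 0:
        raise ValueError(f"wes_region_mb must be positive, got {wes_region_mb}")
    records = list(records)
    panel_tmb = compute_tmb(records, panel.genes, panel.size_mb, mode)
    wes_tmb = compute_tmb(records, ALL_GENES, wes_region_mb, mode)
    hyper_basis = (
        wes_tmb
        if mode is TOTAL_POINT
        else compute_tmb(records, ALL_GENES, wes_region_mb, TOTAL_POINT)
    )
    pairs = [
        PairedTMB(
            patient_id=patient,
            panel_tmb=panel_tmb[patient],
            wes_tmb=wes_tmb[patient],
            cancer_type=None if cancer_types is None else cancer_types.get(patient),
            hypermutated=label_hypermutated(hyper_basis[patient], hyper_cutoff),
        )
        for patient in sorted(wes_tmb)
    ]
    n_hyper = sum(p.hypermutated for p in pairs)
    logger.info(
        "pair_tmb: panel %s (%d genes, %.4f Mb), %d patients, %d hypermutated",
        panel.name,
        len(panel.genes),
        panel.size_mb,
        len(pairs),
        n_hyper,
    )
    return pairs
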