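"""Synthetic cohorts and gene universes for end-to-end testing.

Real pan-cancer cohorts show a strongly right-skewed ("long-tailed")
TMB distribution: most patients carry fewer than 10 mutations/Mb, the
median sits far below the mean, and a small hypermutated tail exceeds
50 mutations/Mb (UV- and tobacco-associated tumors can pass 400).  The
generator emulates exactly that structure:

* each patient draws a true coding point-mutation rate λ (mutations/Mb)
  from a lognormal for the bulk of the cohort or, with probability
  ``hyper_fraction``, from a cutoff-shifted lognormal
  (λ = 50 + LogNormal(μ_h, σ_h)), guaranteeing every generated
  hypermutated patient has expected TMB above the cutoff;
* the patient's mutation count is Poisson with mean proportional to the
  interrogated region size, and each mutation lands on a gene with
  probability proportional to the gene's CDS length;
* mutation classes are drawn per record: Silent with probability
  ``silent_fraction``, a non-counted class (Intron, UTRs, RNA, flanks)
  with probability ``noncoding_fraction``, otherwise a nonsynonymous
  coding class.  Non-coding records are emitted, not dropped, so the
  downstream class filters are exercised end-to-end.

λ is defined as the rate of *coding point mutations* — the quantity
whole-exome total-point TMB estimates — so the total emitted record
count is Poisson(λ·A/(1−noncoding_fraction)) with A the region size in
Mb.  This keeps WES-based total-point TMB an unbiased estimator of λ,
which the parameter-recovery tests rely on.

The defaults are calibrated qualitatively against a pan-cancer WES
cohort (overall mean TMB ≈ 9.6, median ≈ 2.6, hypermutated fraction
≈ 3% with mean ≈ 150 mutations/Mb), not fitted to any dataset.
Mutations are placed independently — no hotspots, signatures, or
per-cancer-type structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .maf_io import GeneModel, MutationRecord, write_gene_models
from .tmb_core import DEFAULT_HYPERMUTATION_CUTOFF

logger = logging.getLogger(__name__)

#: Non-counted classes emitted by the generator, with relative weights.
_NONCODING_CLASSES = ("Intron", "3'UTR", "5'UTR", "RNA", "3'Flank", "5'Flank")
_NONCODING_WEIGHTS = (0.50, 0.15, 0.10, 0.10, 0.08, 0.07)

#: Nonsynonymous coding classes, with relative weights (missense-dominated).
_NONSYN_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Splice_Site",
    "Nonstop_Mutation",
    "Translation_Start_Site",
)
_NONSYN_WEIGHTS = (0.85, 0.08, 0.05, 0.01, 0.01)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    ``base_tmb_lognormal`` and ``hyper_tmb_lognormal`` are (μ, σ) of the
    underlying normal; the hypermutated rate is cutoff + LogNormal(μ_h, σ_h).
    Defaults give a cohort with mean TMB ≈ 9.6 and median ≈ 2.6
    mutations/Mb and ≈ 3% hypermutated patients averaging ≈ 150.
    """

    n_patients: int = 1000
    hyper_fraction: float = 0.03
    base_tmb_lognormal: tuple[float, float] = (math.log(2.6), 1.2)
    hyper_tmb_lognormal: tuple[float, float] = (math.log(80.0), 0.6)
    silent_fraction: float = 0.30
    noncoding_fraction: float = 0.10
    hyper_cutoff: float = DEFAULT_HYPERMUTATION_CUTOFF
    wes_region_mb: float | None = None  # None -> universe total CDS length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.hyper_fraction < 1.0:
            raise ValueError("hyper_fraction must be in [0, 1)")
        if self.silent_fraction < 0 or self.noncoding_fraction < 0:
            raise ValueError("class fractions must be non-negative")
        if self.silent_fraction + self.noncoding_fraction > 1.0:
            raise ValueError("silent_fraction + noncoding_fraction must be <= 1")
        for mu, sigma in (self.base_tmb_lognormal, self.hyper_tmb_lognormal):
            if sigma <= 0:
                raise ValueError("lognormal sigma must be positive")


@dataclass(frozen=True)
class SyntheticUniverse:
    """A synthetic gene universe standing in for a coding-region catalog."""

    genes: tuple[GeneModel, ...]
    total_mb: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "total_mb",
            sum(g.cds_length_bp for g in self.genes) / 1e6,
        )

    def as_mapping(self) -> dict[str, GeneModel]:
        return {g.gene: g for g in self.genes}


def generate_universe(
    n_genes: int,
    length_range_bp: tuple[int, int] = (300, 10_000),
    seed: int = 0,
    path: str | Path | None = None,
) -> SyntheticUniverse:
    """Generate a synthetic gene universe with log-uniform CDS lengths.

    Each gene's coding length is drawn log-uniformly from
    ``length_range_bp`` and split into 1–3 exons laid out along a
    synthetic chromosome.  When ``path`` is given, a CCDS-dialect file
    round-trippable through :func:`panelgauge.maf_io.read_gene_models`
    is written there.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range_bp
    if not (0 < lo <= hi):
        raise ValueError(f"invalid length range {length_range_bp}")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_genes))
    lengths = np.maximum(lengths.astype(int), 1)
    width = len(str(n_genes))

    genes: list[GeneModel] = []
    cursor = 1000
    for i, total in enumerate(lengths):
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False)) if (
            n_exons > 1 and total > n_exons
        ) else np.array([], dtype=int)
        pieces = np.diff(np.concatenate(([0], cuts, [total])))
        intervals = []
        for piece in pieces:
            intervals.append((cursor, cursor + int(piece) - 1))
            cursor += int(piece) + int(rng.integers(50, 500))  # intron gap
        genes.append(
            GeneModel(gene=f"G{i:0{width}d}", cds_intervals=tuple(intervals))
        )
    universe = SyntheticUniverse(genes=tuple(genes))
    if path is not None:
        write_gene_models(universe.genes, path)
    logger.info(
        "synthetic universe: %d genes, %.4f Mb total", n_genes, universe.total_mb
    )
    return universe


def generate_cohort(
    spec: CohortSpec, universe: SyntheticUniverse
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Generate MAF-style mutation records plus a per-patient truth table.

    Returns ``(records, truth)`` where ``truth`` has columns
    ``patient_id``, ``lambda`` (true coding point-mutation rate,
    mutations/Mb), ``n_mutations`` (all emitted records), and
    ``hypermutated`` (realised WES total-point TMB > cutoff).  Patients
    with zero emitted mutations cannot appear in the MAF and are listed
    in the truth table only.
    """
    if not universe.genes:
        raise ValueError("gene universe is empty")
    area_mb = spec.wes_region_mb if spec.wes_region_mb is not None else universe.total_mb
    if not area_mb > 0:
        raise ValueError("wes_region_mb must be positive")
    rng = np.random.default_rng(spec.seed)

    n = spec.n_patients
    mu, sigma = spec.base_tmb_lognormal
    mu_h, sigma_h = spec.hyper_tmb_lognormal
    is_hyper_draw = rng.random(n) < spec.hyper_fraction
    lam = np.where(
        is_hyper_draw,
        spec.hyper_cutoff + rng.lognormal(mu_h, sigma_h, size=n),
        rng.lognormal(mu, sigma, size=n),
    )

    coding_fraction = 1.0 - spec.noncoding_fraction
    n_mut = rng.poisson(lam * area_mb / coding_fraction)
    total = int(n_mut.sum())

    lengths = np.array([g.cds_length_bp for g in universe.genes], dtype=float)
    gene_probs = lengths / lengths.sum()
    gene_idx = rng.choice(len(universe.genes), size=total, p=gene_probs)

    p_nonsyn = 1.0 - spec.silent_fraction - spec.noncoding_fraction
    class_pool = ("Silent",) + _NONCODING_CLASSES + _NONSYN_CLASSES
    class_probs = np.concatenate(
        (
            [spec.silent_fraction],
            spec.noncoding_fraction * np.asarray(_NONCODING_WEIGHTS),
            p_nonsyn * np.asarray(_NONSYN_WEIGHTS),
        )
    )
    class_idx = rng.choice(len(class_pool), size=total, p=class_probs)

    width = len(str(n))
    patient_ids = [f"P{i:0{width}d}" for i in range(n)]
    patient_per_mut = np.repeat(np.arange(n), n_mut)
    gene_names = [g.gene for g in universe.genes]
    records = [
        MutationRecord(
            patient_id=patient_ids[p],
            gene=gene_names[g],
            variant_classification=class_pool[c],
            variant_type="SNP",
        )
        for p, g, c in zip(patient_per_mut, gene_idx, class_idx)
    ]

    # realised WES total-point TMB per patient (coding point = not noncoding:
    # all generated records are SNPs, so coding == Silent + nonsynonymous)
    is_coding = class_idx >= 1 + len(_NONCODING_CLASSES)
    is_coding |= class_idx == 0  # Silent
    coding_counts = np.bincount(patient_per_mut[is_coding], minlength=n)
    realized_tmb = coding_counts / area_mb

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "lambda": lam,
            "n_mutations": n_mut,
            "hypermutated": realized_tmb > spec.hyper_cutoff,
        }
    )
    logger.info(
        "synthetic cohort: %d patients, %d mutations, %d hypermutated "
        "(mean TMB %.2f, median %.2f)",
        n,
        total,
        int(truth["hypermutated"].sum()),
        float(realized_tmb.mean()),
        float(np.median(realized_tmb)),
    )
    return records, truth


def expected_panel_theta(
    lambda_: float,
    panel_fraction: float,
    panel_size_mb: float,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo oracle for the expected angular distance of one patient.

    Models the generative process directly, independent of the pipeline:
    the whole-exome count is Poisson(λ·W) with W = panel_size_mb /
    panel_fraction, and the panel catches a binomially thinned subset
    (each mutation retained with probability ``panel_fraction``).  The
    return value is the mean angular distance between the panel-based
    and WES-based TMB over ``n_draws`` replicates.  With
    ``panel_fraction`` = 1 there is no thinning and the result is 0.
    """
    if lambda_ <= 0 or panel_size_mb <= 0 or n_draws < 1:
        raise ValueError("lambda_, panel_size_mb and n_draws must be positive")
    if not 0.0 < panel_fraction <= 1.0:
        raise ValueError("panel_fraction must be in (0, 1]")
    from .panel_metrics import angular_distances

    rng = np.random.default_rng(seed)
    wes_mb = panel_size_mb / panel_fraction
    n_wes = rng.poisson(lambda_ * wes_mb, size=n_draws)
    n_panel = rng.binomial(n_wes, panel_fraction)
    x = n_panel / panel_size_mb
    y = n_wes / wes_mb
    return float(angular_distances(x, y).mean())


def write_cohort(
    records: Sequence[MutationRecord],
    truth: pd.DataFrame,
    universe: SyntheticUniverse,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three cohort artifacts (MAF, CCDS-dialect universe,
    truth CSV) to ``out_dir`` and return their paths."""
    from .maf_io import write_maf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": out_dir / "cohort.maf",
        "universe": out_dir / "universe.ccds.txt",
        "truth": out_dir / "truth.csv",
    }
    write_maf(records, paths["maf"])
    write_gene_models(universe.genes, paths["universe"])
    truth.to_csv(paths["truth"], index=False)
    return paths
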