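"""Randomized in-silico panel simulation.

Recreates the in-silico experiment behind the size–performance curves:
draw a panel size N uniformly from {1, …, max_genes}, sample N distinct
genes uniformly from the universe, take the panel's footprint as the
summed CDS length of those genes, and evaluate the panel on the cohort
with both measurements (R² and mean angular distance) on the
hypermutation-included and non-hypermutation datasets.  The documented
full-replication setting is 10,000 panels with max_genes = 3,000 on a
~19,600-gene universe; desk-scale runs use a few hundred panels on a
synthetic universe.

Reproducibility contract: panels are generated from per-panel child
seeds spawned deterministically from the master seed
(``SeedSequence(seed).spawn(n_panels)``), so results are bit-identical
across runs and independent of evaluation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .maf_io import GeneModel, MutationRecord, Panel
from .tmb_core import (
    DEFAULT_HYPERMUTATION_CUTOFF,
    MutationMode,
    NONSYNONYMOUS,
    TOTAL_POINT,
    record_counts,
)
from .panel_metrics import (
    DegenerateFitError,
    UndefinedMetricError,
    angular_distances,
    r_squared,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulatedPanelResult:
    """Metrics for one randomly generated panel on one cohort."""

    panel_index: int
    n_genes: int
    size_mb: float
    r2_included: float
    r2_nonhyper: float
    theta_included: float
    theta_nonhyper: float
    accuracy_band: float = math.nan


_RESULT_COLUMNS = [f.name for f in fields(SimulatedPanelResult)]


def results_to_frame(results: Iterable[SimulatedPanelResult]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in results], columns=_RESULT_COLUMNS)
    return frame


def generate_random_panel(
    universe: Mapping[str, GeneModel],
    max_genes: int,
    rng: np.random.Generator | int,
) -> Panel:
    """Draw one random panel: N ~ Uniform{1..max_genes}, then N distinct
    genes sampled uniformly without replacement."""
    if not universe:
        raise ValueError("gene universe is empty")
    if max_genes > len(universe):
        raise ValueError(
            f"max_genes {max_genes} exceeds universe size {len(universe)}"
        )
    if max_genes < 1:
        raise ValueError("max_genes must be >= 1")
    rng = np.random.default_rng(rng)
    names = sorted(universe)
    n = int(rng.integers(1, max_genes + 1))
    chosen = rng.choice(len(names), size=n, replace=False)
    genes = frozenset(names[i] for i in chosen)
    size_mb = sum(universe[g].cds_length_bp for g in genes) / 1e6
    return Panel(name=f"random_{n}genes", genes=genes, size_mb=size_mb)


def _cohort_matrix(
    records: Iterable[MutationRecord],
    gene_index: Mapping[str, int],
    mode: MutationMode,
) -> tuple[list[str], np.ndarray]:
    """Patient × gene matrix of mode-qualifying mutation counts.

    Every patient present in the records gets a row, including patients
    whose mutations are all filtered out.  Mutations on genes outside
    ``gene_index`` are dropped (they cannot land in any panel and, with
    the universe defining the exome, do not occur in synthetic cohorts).
    """
    patients: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    for record in records:
        p = patients.setdefault(record.patient_id, len(patients))
        if record.gene in gene_index and record_counts(record, mode):
            rows.append(p)
            cols.append(gene_index[record.gene])
    matrix = np.zeros((len(patients), len(gene_index)), dtype=np.int64)
    if rows:
        np.add.at(matrix, (np.array(rows), np.array(cols)), 1)
    ordered = sorted(patients, key=patients.get)
    return ordered, matrix


def _safe_r2(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return r_squared(x, y)
    except (DegenerateFitError, UndefinedMetricError):
        return math.nan


def _band_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    threshold: float | None,
    band: tuple[float, float] | None,
) -> float:
    if threshold is None:
        return math.nan
    keep = np.ones_like(y, dtype=bool)
    if band is not None:
        lo, hi = band
        if lo > hi:
            raise ValueError(f"band lower bound {lo} exceeds upper bound {hi}")
        keep = (y >= lo) & (y <= hi)
    if not keep.any():
        return math.nan
    return float(np.mean((x[keep] >= threshold) == (y[keep] >= threshold)))


def _sample_panels(
    n_genes_universe: int,
    lengths_bp: np.ndarray,
    n_panels: int,
    max_genes: int,
    seed: int,
) -> list[tuple[np.ndarray, float]]:
    """Sample all panel gene-index sets from per-panel child seeds."""
    if max_genes > n_genes_universe:
        raise ValueError(
            f"max_genes {max_genes} exceeds universe size {n_genes_universe}"
        )
    children = np.random.SeedSequence(seed).spawn(n_panels)
    panels = []
    for child in children:
        rng = np.random.default_rng(child)
        n = int(rng.integers(1, max_genes + 1))
        idx = rng.choice(n_genes_universe, size=n, replace=False)
        panels.append((idx, float(lengths_bp[idx].sum() / 1e6)))
    return panels


def run_simulation(
    records: Iterable[MutationRecord],
    universe: Mapping[str, GeneModel],
    n_panels: int,
    max_genes: int,
    mode: MutationMode = TOTAL_POINT,
    wes_region_mb: float | None = None,
    hyper_cutoff: float = DEFAULT_HYPERMUTATION_CUTOFF,
    seed: int = 0,
    threshold: float | None = None,
    band: tuple[float, float] | None = None,
    out_path: str | Path | None = None,
) -> list[SimulatedPanelResult]:
    """Generate ``n_panels`` random panels and evaluate each on the cohort.

    ``wes_region_mb`` defaults to the universe's total CDS length.  When
    ``out_path`` is given the result table is streamed to CSV row by row
    as panels complete.  A degenerate panel catching no mutations yields
    defined output (x = 0 for all patients, regression NaN).
    """
    if n_panels < 1:
        raise ValueError("n_panels must be >= 1")
    records = list(records)
    names = sorted(universe)
    gene_index = {g: i for i, g in enumerate(names)}
    lengths_bp = np.array([universe[g].cds_length_bp for g in names], dtype=float)
    if wes_region_mb is None:
        wes_region_mb = float(lengths_bp.sum() / 1e6)

    patients, counts = _cohort_matrix(records, gene_index, mode)
    y = counts.sum(axis=1) / wes_region_mb
    if mode is TOTAL_POINT:
        hyper = y > hyper_cutoff
    else:
        _, counts_tp = _cohort_matrix(records, gene_index, TOTAL_POINT)
        hyper = counts_tp.sum(axis=1) / wes_region_mb > hyper_cutoff
    non_hyper = ~hyper
    logger.info(
        "simulation: %d patients (%d hypermutated), %d genes, %d panels, mode=%s",
        len(patients),
        int(hyper.sum()),
        len(names),
        n_panels,
        mode.name,
    )

    writer = None
    if out_path is not None:
        writer = open(out_path, "w")
        writer.write(",".join(_RESULT_COLUMNS) + "\n")

    results: list[SimulatedPanelResult] = []
    try:
        for i, (idx, size_mb) in enumerate(
            _sample_panels(len(names), lengths_bp, n_panels, max_genes, seed)
        ):
            x = counts[:, idx].sum(axis=1) / size_mb
            theta = angular_distances(x, y)
            result = SimulatedPanelResult(
                panel_index=i,
                n_genes=len(idx),
                size_mb=size_mb,
                r2_included=_safe_r2(x, y),
                r2_nonhyper=(
                    _safe_r2(x[non_hyper], y[non_hyper]) if non_hyper.any() else math.nan
                ),
                theta_included=float(theta.mean()),
                theta_nonhyper=(
                    float(theta[non_hyper].mean()) if non_hyper.any() else math.nan
                ),
                accuracy_band=_band_accuracy(x, y, threshold, band),
            )
            results.append(result)
            if writer is not None:
                writer.write(
                    ",".join(str(getattr(result, c)) for c in _RESULT_COLUMNS) + "\n"
                )
    finally:
        if writer is not None:
            writer.close()
    return results


def summarize_size_curve(
    results: Iterable[SimulatedPanelResult] | pd.DataFrame,
    size_bins: Sequence[float],
) -> pd.DataFrame:
    """Bin panels by size (Mb) and summarise both metrics per bin.

    ``size_bins`` are ascending bin edges; each bin is (left, right].
    Bins with no panels are reported with n_panels = 0 and NaN
    statistics, not dropped.  The sd of a single-panel bin is NaN.
    """
    frame = (
        results.copy()
        if isinstance(results, pd.DataFrame)
        else results_to_frame(results)
    )
    if frame.empty:
        raise ValueError("no simulation results to summarise")
    edges = list(size_bins)
    if len(edges) < 2:
        raise ValueError("size_bins needs at least two edges")
    if any(lo >= hi for lo, hi in zip(edges[:-1], edges[1:])):
        raise ValueError("size_bins must be strictly increasing")

    frame["bin"] = pd.cut(frame["size_mb"], bins=edges)
    metrics = ["r2_included", "r2_nonhyper", "theta_included", "theta_nonhyper"]
    grouped = frame.groupby("bin", observed=False)
    summary = pd.DataFrame(
        {
            "bin_left": [iv.left for iv in grouped.size().index],
            "bin_right": [iv.right for iv in grouped.size().index],
            "n_panels": grouped.size().to_numpy(),
        }
    )
    for metric in metrics:
        summary[f"mean_{metric}"] = grouped[metric].mean().to_numpy()
        summary[f"sd_{metric}"] = grouped[metric].std(ddof=1).to_numpy()
    return summary


def compare_mutation_modes(
    records: Iterable[MutationRecord],
    universe: Mapping[str, GeneModel],
    n_panels: int,
    max_genes: int,
    wes_region_mb: float | None = None,
    hyper_cutoff: float = DEFAULT_HYPERMUTATION_CUTOFF,
    seed: int = 0,
    threshold: float | None = None,
    band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Evaluate the *same* random panels under total-point and
    nonsynonymous counting and join the results per panel.

    The same master seed is used for both runs, so the per-panel gene
    sets (hence ``n_genes`` and ``size_mb``) are identical across modes.
    """
    records = list(records)
    common = dict(
        n_panels=n_panels,
        max_genes=max_genes,
        wes_region_mb=wes_region_mb,
        hyper_cutoff=hyper_cutoff,
        seed=seed,
        threshold=threshold,
        band=band,
    )
    total = results_to_frame(
        run_simulation(records, universe, mode=TOTAL_POINT, **common)
    )
    nonsyn = results_to_frame(
        run_simulation(records, universe, mode=NONSYNONYMOUS, **common)
    )
    joined = total.merge(
        nonsyn,
        on=["panel_index", "n_genes", "size_mb"],
        suffixes=("_total_point", "_nonsynonymous"),
        validate="one_to_one",
    )
    return joined
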