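"""Differential methylation, CpG context annotation and genome binning.

Probe-level beta fractions are tested on the M-value (logit) scale with the
same moderated-t engine used for expression; ``delta_m`` is the M-scale
group difference. Each probe is annotated with its CpG context relative to
the supplied islands (inside = island; within ``shore_bp`` = shore; within
``shelf_bp`` = shelf; farther = open sea, both boundaries inclusive) and
linked to the gene with the closest transcription start site on the same
chromosome. Gene-level methylation change averages island probes near the
TSS, and genome-wide tracks are averaged in fixed half-open bins.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .diffexpr import EBayesPrior, moderated_t_test

log = logging.getLogger("tnbc_targets")

CONTEXTS = ("island", "shore", "shelf", "open_sea")

#: Default TSS window (bp) for assigning island probes to promoters.
DEFAULT_MAX_TSS_DISTANCE = 2000


def diff_methylation(
    m_values: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Per-probe differential methylation on M-values (group A minus B)."""
    result = moderated_t_test(m_values, groups, group_a, group_b, prior=prior)
    result = result.rename(columns={"log2fc": "delta_m"})
    result.index.name = "probe_id"
    return result


def _island_distance(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest island on one chromosome.

    0 when the position falls inside an island (intervals may overlap);
    otherwise the distance to the nearest interval edge, measured to the
    last contained base ``end - 1`` on the right side.
    """
    order = np.argsort(starts, kind="mergesort")
    starts = starts[order]
    ends = ends[order]
    cummax_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, pos, side="right")
    inside = (idx > 0) & (np.where(idx > 0, cummax_end[np.maximum(idx - 1, 0)], 0) > pos)
    # nearest boundary point over all islands: every start and every end-1
    bounds = np.sort(np.concatenate([starts, ends - 1]))
    j = np.searchsorted(bounds, pos)
    left = np.where(j > 0, np.abs(pos - bounds[np.maximum(j - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(j < bounds.size, np.abs(bounds[np.minimum(j, bounds.size - 1)] - pos), np.iinfo(np.int64).max)
    dist = np.minimum(left, right)
    dist[inside] = 0
    return dist


def annotate_context(
    probes: pd.DataFrame,
    islands: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> pd.Series:
    """CpG context per probe: island, shore, shelf or open_sea.

    ``probes`` needs ``chrom`` and ``pos`` columns; ``islands`` is a BED-like
    frame of 0-based half-open intervals. A chromosome with no island is all
    open sea.
    """
    cfg = cfg or PipelineConfig()
    context = pd.Series("open_sea", index=probes.index, name="context")
    for chrom, group in probes.groupby("chrom"):
        chrom_islands = islands[islands["chrom"] == chrom]
        if chrom_islands.empty:
            continue
        dist = _island_distance(
            group["pos"].to_numpy(np.int64),
            chrom_islands["start"].to_numpy(np.int64),
            chrom_islands["end"].to_numpy(np.int64),
        )
        labels = np.select(
            [dist == 0, dist <= cfg.shore_bp, dist <= cfg.shelf_bp],
            ["island", "shore", "shelf"],
            default="open_sea",
        )
        context.loc[group.index] = labels
    return context


def map_probes_to_genes(probes: pd.DataFrame, gene_annotation: pd.DataFrame) -> pd.DataFrame:
    """Link each probe to the gene with the nearest TSS on its chromosome.

    Absolute-distance ties (including several genes sharing one TSS) go to
    the lexicographically smallest gene id. Probes on chromosomes without
    any annotated gene get a missing ``nearest_gene``.
    """
    nearest = pd.Series(pd.NA, index=probes.index, dtype="object", name="nearest_gene")
    distance = pd.Series(np.nan, index=probes.index, name="tss_distance")
    for chrom, group in probes.groupby("chrom"):
        genes = gene_annotation[gene_annotation["chrom"] == chrom]
        if genes.empty:
            continue
        # one candidate per distinct TSS: its lexicographically smallest gene
        per_tss = genes.groupby("tss")["gene_id"].min().sort_index()
        tss = per_tss.index.to_numpy(np.int64)
        ids = per_tss.to_numpy(dtype=object)
        pos = group["pos"].to_numpy(np.int64)
        j = np.searchsorted(tss, pos)
        left = np.maximum(j - 1, 0)
        right = np.minimum(j, tss.size - 1)
        dist_left = np.where(j > 0, np.abs(pos - tss[left]), np.iinfo(np.int64).max)
        dist_right = np.where(j < tss.size, np.abs(tss[right] - pos), np.iinfo(np.int64).max)
        best = np.minimum(dist_left, dist_right)
        pick_left = dist_left < dist_right
        tie = dist_left == dist_right
        chosen = np.where(pick_left, ids[left], ids[right])
        if tie.any():
            lo = np.minimum(ids[left][tie], ids[right][tie])
            chosen[tie] = lo
        nearest.loc[group.index] = chosen
        distance.loc[group.index] = best
    out = probes.copy()
    out["nearest_gene"] = nearest
    out["tss_distance"] = distance
    return out


def summarize_gene_methylation(
    probes: pd.DataFrame,
    restrict_context: Sequence[str] | set[str] = ("island",),
    max_tss_distance: int = DEFAULT_MAX_TSS_DISTANCE,
) -> pd.DataFrame:
    """Gene-level methylation change: mean delta_m over qualifying probes.

    ``probes`` must carry ``delta_m``, ``context``, ``nearest_gene`` and
    ``tss_distance`` columns. Only probes whose context is in
    ``restrict_context`` and whose TSS distance is within
    ``max_tss_distance`` contribute; genes with no qualifying probe are
    absent from the output.
    """
    restrict = set(restrict_context)
    keep = (
        probes["context"].isin(restrict)
        & probes["nearest_gene"].notna()
        & (probes["tss_distance"] <= max_tss_distance)
    )
    selected = probes[keep]
    summary = (
        selected.groupby("nearest_gene")["delta_m"]
        .agg(mean_delta_m="mean", n_probes="size")
        .rename_axis("gene_id")
    )
    summary["n_probes"] = summary["n_probes"].astype(np.int64)
    return summary


def correlate_meth_expression(
    summaries: pd.DataFrame, de_results: pd.DataFrame
) -> tuple[float, int]:
    """Pearson correlation between gene methylation change and expression FC.

    Computed over genes present in both tables; fewer than 3 shared genes is
    an error because the correlation is undefined there.
    """
    shared = summaries.index.intersection(de_results.index)
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 shared genes for a correlation, got {n}")
    r, _ = stats.pearsonr(
        summaries.loc[shared, "mean_delta_m"].to_numpy(),
        de_results.loc[shared, "log2fc"].to_numpy(),
    )
    return float(r), n


def bin_genome(
    positions: pd.DataFrame,
    value_columns: Sequence[str],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Average values in fixed half-open genome bins [k*bin_bp, (k+1)*bin_bp).

    ``positions`` needs ``chrom`` and ``pos`` plus the value columns. Bins
    tile each chromosome from zero to past its last datum; empty bins are
    emitted with NaN so the track is gap-free.
    """
    cfg = cfg or PipelineConfig()
    width = cfg.bin_bp
    rows = []
    for chrom, group in positions.groupby("chrom", sort=True):
        bins = group["pos"].to_numpy(np.int64) // width
        n_bins = int(bins.max()) + 1
        for column in value_columns:
            sums = np.bincount(bins, weights=group[column].to_numpy(float), minlength=n_bins)
            counts = np.bincount(bins, minlength=n_bins)
            with np.errstate(invalid="ignore"):
                means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            if column == value_columns[0]:
                chrom_rows = pd.DataFrame(
                    {
                        "chrom": chrom,
                        "bin_start": np.arange(n_bins, dtype=np.int64) * width,
                        "bin_end": (np.arange(n_bins, dtype=np.int64) + 1) * width,
                    }
                )
            chrom_rows[f"mean_{column}"] = means
        rows.append(chrom_rows)
    return pd.concat(rows, ignore_index=True)
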