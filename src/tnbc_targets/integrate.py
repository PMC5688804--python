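"""Cross-comparison intersection, multi-omics concordance and target triage.

The three differential-expression comparisons (TNBC vs non-TNBC tissue,
TNBC vs normal tissue, TNBC vs non-TNBC cell lines) are intersected on gene
ids to give the common up- and downregulated sets. Fold-change concordance
across omics layers is summarized by Pearson correlations. Candidate
targets from the common-up set then pass through four sequential
druggability gates — literature novelty, structure availability,
structure-based druggability and ligand-based druggability percentile — and
survivors are ranked by descending percentile. The knockdown-effect metrics
quantify proliferation or cell loss from paired cell counts at two
timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .diffexpr import EBayesPrior, moderated_t_test
from .io import ExpressionMatrix

log = logging.getLogger("tnbc_targets")


@dataclass
class IntersectionReport:
    """Per-comparison DE sets, their three-way intersections and pairwise
    fold-change correlations."""

    up_sets: dict[str, set[str]]
    down_sets: dict[str, set[str]]
    common_up: set[str]
    common_down: set[str]
    pairwise_fc_corr: pd.DataFrame  # columns: a, b, r, n


def intersect_de(de_results: Mapping[str, pd.DataFrame]) -> IntersectionReport:
    """Intersect classified DE results from the three comparisons.

    Each value of ``de_results`` must carry ``log2fc`` and ``status``
    columns indexed by gene. Genes missing from any comparison are excluded
    from the common sets by construction of the intersection.
    """
    if len(de_results) < 2:
        raise ValueError("need at least two comparisons to intersect")
    up_sets = {name: set(df.index[df["status"] == "up"]) for name, df in de_results.items()}
    down_sets = {name: set(df.index[df["status"] == "down"]) for name, df in de_results.items()}
    common_up = set.intersection(*up_sets.values())
    common_down = set.intersection(*down_sets.values())
    rows = []
    names = list(de_results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r, n = correlate_fc(de_results[a], de_results[b])
            rows.append({"a": a, "b": b, "r": r, "n": n})
    log.info(
        "DE intersection: %d common up, %d common down across %s",
        len(common_up),
        len(common_down),
        names,
    )
    return IntersectionReport(
        up_sets=up_sets,
        down_sets=down_sets,
        common_up=common_up,
        common_down=common_down,
        pairwise_fc_corr=pd.DataFrame(rows),
    )


def correlate_fc(
    a: pd.DataFrame, b: pd.DataFrame, genes: Sequence[str] | None = None
) -> tuple[float, int]:
    """Pearson correlation of ``log2fc`` between two result tables.

    Computed over genes shared by both tables (optionally restricted to
    ``genes``); fewer than 3 shared genes is an error.
    """
    shared = a.index.intersection(b.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 shared genes for a correlation, got {n}")
    r, _ = stats.pearsonr(
        a.loc[shared, "log2fc"].to_numpy(), b.loc[shared, "log2fc"].to_numpy()
    )
    return float(r), n


def proteomics_concordance(
    protein: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    de_results: pd.DataFrame,
    prior: EBayesPrior | None = None,
) -> tuple[pd.DataFrame, float, int]:
    """Protein-level fold-changes and their correlation with mRNA fold-changes.

    Protein differential abundance is computed with the same moderated-t
    engine on the log-abundance matrix; the returned correlation is over
    genes shared between the protein panel and ``de_results``.
    """
    protein_de = moderated_t_test(protein.data, groups, group_a, group_b, prior=prior)
    r, n = correlate_fc(protein_de, de_results)
    return protein_de, r, n


#: Ordered triage gate names, applied sequentially.
TRIAGE_STAGES = ("common_up", "novelty", "structure", "druggable", "percentile")


def triage(
    common_up: Sequence[str] | set[str],
    annotations: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the druggability cascade to the common-up genes.

    Gates, in order: fewer than ``novelty_max_pubs`` publications; an
    available protein structure; structure-based druggability; ligand-based
    druggability percentile at or above ``ligand_percentile_min`` (a missing
    percentile fails this gate rather than erroring, mirroring "cannot be
    scored"). Genes with no annotation row are treated as failing every
    gate, with a logged warning. Survivors are ranked 1..k by descending
    percentile, ties broken by gene id.
    """
    cfg = cfg or PipelineConfig()
    genes = sorted(common_up)
    ann = annotations.set_index("gene_id")
    missing = [g for g in genes if g not in ann.index]
    if missing:
        log.warning("%d common-up genes lack annotations and fail triage: %s", len(missing), missing[:5])
    records = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    records["in_common_up"] = True
    records["pub_count"] = ann["pub_count"].reindex(genes)
    records["has_structure"] = (
        ann["has_structure"].reindex(genes).astype("boolean").fillna(False).astype(bool)
    )
    records["structure_druggable"] = (
        ann["structure_druggable"].reindex(genes).astype("boolean").fillna(False).astype(bool)
    )
    records["ligand_percentile"] = ann["ligand_percentile"].reindex(genes)

    novel = records["pub_count"].notna() & (records["pub_count"] < cfg.novelty_max_pubs)
    structure = novel & records["has_structure"]
    druggable = structure & records["structure_druggable"]
    percentile = druggable & (records["ligand_percentile"] >= cfg.ligand_percentile_min)
    records["passes_all"] = percentile

    stage_counts = {
        "common_up": len(genes),
        "novelty": int(novel.sum()),
        "structure": int(structure.sum()),
        "druggable": int(druggable.sum()),
        "percentile": int(percentile.sum()),
    }
    passing = records[records["passes_all"]].sort_values(
        ["ligand_percentile", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    records["rank"] = pd.Series(
        np.arange(1, len(passing) + 1, dtype=float), index=passing.index
    ).reindex(records.index)
    log.info("triage cascade counts: %s", stage_counts)
    return records.reset_index(), stage_counts


@dataclass
class KnockdownEffect:
    """Outcome of a knockdown proliferation assay between two timepoints."""

    metric: str  # "proliferation_pct" or "cell_loss_pct"
    value: float
    treated_ratio: float
    control_ratio: float


def knockdown_effect(
    treated_t96: float,
    treated_t192: float,
    control_t96: float,
    control_t192: float,
) -> KnockdownEffect:
    """Proliferation or cell-loss percentage from paired cell counts.

    With growth ratios R = treated(t192)/treated(t96) and
    C = control(t192)/control(t96): when the treated cells still grew
    (R >= 1) the effect is reported as percentage of proliferation,
    100 * R / C; when they shrank (R < 1) it is reported as percentage of
    cell loss, 100 * (1 - R).
    """
    for name, value in (
        ("treated_t96", treated_t96),
        ("treated_t192", treated_t192),
        ("control_t96", control_t96),
        ("control_t192", control_t192),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be a positive cell count, got {value}")
    treated_ratio = treated_t192 / treated_t96
    control_ratio = control_t192 / control_t96
    if treated_ratio >= 1.0:
        return KnockdownEffect(
            metric="proliferation_pct",
            value=100.0 * treated_ratio / control_ratio,
            treated_ratio=treated_ratio,
            control_ratio=control_ratio,
        )
    return KnockdownEffect(
        metric="cell_loss_pct",
        value=100.0 * (1.0 - treated_ratio),
        treated_ratio=treated_ratio,
        control_ratio=control_ratio,
    )
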