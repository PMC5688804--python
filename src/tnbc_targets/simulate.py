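"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* three marker genes (ER/PR/HER2 surrogates) whose log2 expression is
  bimodal, drawn from per-marker two-component Gaussian mixtures, with IHC
  labels equal to the latent component up to configurable error and
  missingness;
* negative-binomial RNA-seq counts (variance mu + alpha * mu^2) with
  up/down genes planted at a fixed log2 fold-change in each of the three
  comparisons (TNBC vs non-TNBC tissue, TNBC vs normal tissue, TNBC vs
  non-TNBC cell lines), including sets planted in all three so the triple
  intersection is non-trivial;
* promoter-island methylation probes whose M-values shift against the
  planted expression change (hypomethylated promoters for upregulated
  genes), producing a negative methylation-expression correlation;
* protein log-abundances built from the mRNA log-signal plus noise
  calibrated to a target fold-change correlation;
* a druggability annotation table in which exactly one planted common-up
  gene survives all four triage gates.

Everything is deterministic under a fixed seed; the truth table records the
latent marker labels, the planted per-comparison DE status, the methylation
genes and the planted target, which is sufficient to score every downstream
stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .io import ExpressionMatrix
from .normalize import log2p1, m_to_beta, upper_quartile_normalize

MARKERS = ("ESR1", "PGR", "ERBB2")
_IHC_COLUMN = {"ESR1": "ihc_er", "PGR": "ihc_pr", "ERBB2": "ihc_her2"}

#: Clipping bounds for generated beta values.
BETA_CLIP = (0.001, 0.999)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic scenario; defaults are the study conditions.

    Marker components sit six pooled standard deviations apart by default
    (three SD on either side of the decision boundary), which keeps the
    bimodality unambiguous while leaving a populated boundary region once
    separation is reduced. Negative-binomial dispersion 0.1 is typical bulk
    RNA-seq overdispersion; the planted effect size of two log2 units
    matches the pipeline's own two-fold calling gate.
    """

    # cohort sizes
    n_tnbc: int = 60
    n_nontnbc: int = 120
    n_normal: int = 40
    n_cell_tnbc: int = 8
    n_cell_nontnbc: int = 6
    # genes and markers
    n_genes: int = 2000
    marker_mu_neg: float = 5.0
    marker_mu_pos: float = 11.0
    marker_sd_neg: float = 1.0
    marker_sd_pos: float = 1.0
    marker_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    marker_pos_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"ESR1": 0.7, "PGR": 0.6, "ERBB2": 0.2}
    )
    ihc_missing_rate: float = 0.1
    ihc_error_rate: float = 0.02
    # planted differential expression
    n_up: int = 150
    n_down: int = 150
    n_common_up: int = 40
    n_common_down: int = 30
    planted_lfc: float = 2.0
    nb_dispersion: float = 0.1
    base_mean_log2_mean: float = 7.0
    base_mean_log2_sd: float = 1.5
    libsize_log2_sd: float = 0.25
    # methylome
    n_probes: int = 3000
    n_islands: int = 150
    island_width: int = 500
    meth_effect: float = 2.0
    meth_gene_fraction: float = 0.5
    meth_noise_sd: float = 0.5
    n_chroms: int = 10
    chrom_bp: int = 200_000_000
    # proteome and annotations
    n_protein_genes: int = 800
    protein_corr: float = 0.5
    protein_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_tnbc",
            "n_nontnbc",
            "n_normal",
            "n_cell_tnbc",
            "n_cell_nontnbc",
            "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("ihc_missing_rate", "ihc_error_rate", "meth_gene_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if not self.marker_mu_pos > self.marker_mu_neg:
            raise ValueError("marker_mu_pos must exceed marker_mu_neg")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be positive")
        if self.n_common_up > self.n_up or self.n_common_down > self.n_down:
            raise ValueError("common planted sets cannot exceed per-comparison sets")
        needed = 3 + self.planted_gene_budget()
        if needed > self.n_genes:
            raise ValueError(
                f"planted genes plus markers ({needed}) exceed n_genes ({self.n_genes})"
            )
        if not (-1.0 <= self.protein_corr <= 1.0):
            raise ValueError("protein_corr must be in [-1, 1]")

    def planted_gene_budget(self) -> int:
        exclusive = 3 * (self.n_up - self.n_common_up) + 3 * (self.n_down - self.n_common_down)
        return self.n_common_up + self.n_common_down + exclusive

    def marker_params(self, marker: str) -> dict[str, float]:
        params = {
            "mu_neg": self.marker_mu_neg,
            "mu_pos": self.marker_mu_pos,
            "sd_neg": self.marker_sd_neg,
            "sd_pos": self.marker_sd_pos,
        }
        params.update(self.marker_overrides.get(marker, {}))
        return params


@dataclass
class TruthTable:
    """Latent ground truth sufficient to score every downstream stage."""

    marker_truth: pd.DataFrame  # index sample_id; bool column per marker + 'tnbc'
    de_truth: pd.DataFrame  # index gene_id; status per comparison column
    common_up: list[str]
    common_down: list[str]
    target_gene: str | None = None
    meth_genes: pd.DataFrame | None = None  # gene_id -> planted delta_m


COMPARISONS = ("tissue", "normal", "cell")


def _simulate_marker_block(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_tnbc: int,
    n_other: int,
    sample_ids: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent marker labels and log2-scale marker values for one cohort.

    The first ``n_tnbc`` samples are triple-negative (all markers latent
    negative); the rest draw each marker positive with its configured
    fraction, conditioned on at least one positive marker.
    """
    n = n_tnbc + n_other
    latent = np.zeros((n, len(MARKERS)), dtype=bool)
    fractions = np.array([cfg.marker_pos_fraction[m] for m in MARKERS])
    for i in range(n_tnbc, n):
        while True:
            draw = rng.random(len(MARKERS)) < fractions
            if draw.any():
                latent[i] = draw
                break
    values = np.empty((n, len(MARKERS)))
    for j, marker in enumerate(MARKERS):
        p = cfg.marker_params(marker)
        pos = latent[:, j]
        values[:, j] = np.where(
            pos,
            rng.normal(p["mu_pos"], p["sd_pos"], size=n),
            rng.normal(p["mu_neg"], p["sd_neg"], size=n),
        )
    truth = pd.DataFrame(latent, index=pd.Index(sample_ids, name="sample_id"), columns=MARKERS)
    truth["tnbc"] = ~latent.any(axis=1)
    return truth, pd.DataFrame(values, index=truth.index, columns=MARKERS)


def simulate_marker_panel(
    cfg: SimulationConfig,
    n_tnbc: int | None = None,
    n_other: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Marker values, latent truth and noisy IHC labels for a tumor panel.

    Returns ``(values, truth, ihc)``: log2-scale marker expression, latent
    positive/negative labels plus TNBC truth, and IHC labels equal to the
    latent truth except flipped with ``ihc_error_rate`` and hidden with
    ``ihc_missing_rate``.
    """
    n_tnbc = cfg.n_tnbc if n_tnbc is None else n_tnbc
    n_other = cfg.n_nontnbc if n_other is None else n_other
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = [f"TUMOR{i:05d}" for i in range(n_tnbc + n_other)]
    truth, values = _simulate_marker_block(cfg, rng, n_tnbc, n_other, ids)
    ihc = _ihc_from_truth(cfg, rng, truth)
    return values, truth, ihc


def _ihc_from_truth(
    cfg: SimulationConfig, rng: np.random.Generator, truth: pd.DataFrame
) -> pd.DataFrame:
    ihc = pd.DataFrame(index=truth.index)
    for marker in MARKERS:
        observed = truth[marker].to_numpy().copy()
        flip = rng.random(len(truth)) < cfg.ihc_error_rate
        observed ^= flip
        labels = np.where(observed, "pos", "neg").astype(object)
        labels[rng.random(len(truth)) < cfg.ihc_missing_rate] = "missing"
        ihc[_IHC_COLUMN[marker]] = labels
    return ihc


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion alpha
    (variance mu + alpha * mu^2); alpha = 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _allocate_de_truth(cfg: SimulationConfig, gene_ids: Sequence[str], rng: np.random.Generator) -> TruthTable:
    """Assign planted up/down status per comparison over non-marker genes."""
    pool = [g for g in gene_ids if g not in MARKERS]
    chosen = rng.permutation(np.array(pool, dtype=object))
    cursor = 0

    def take(count: int) -> list[str]:
        nonlocal cursor
        out = list(chosen[cursor : cursor + count])
        cursor += count
        return out

    common_up = take(cfg.n_common_up)
    common_down = take(cfg.n_common_down)
    status = pd.DataFrame("ns", index=pd.Index(gene_ids, name="gene_id"), columns=list(COMPARISONS))
    for comparison in COMPARISONS:
        up = common_up + take(cfg.n_up - cfg.n_common_up)
        down = common_down + take(cfg.n_down - cfg.n_common_down)
        status.loc[up, comparison] = "up"
        status.loc[down, comparison] = "down"
    return TruthTable(
        marker_truth=pd.DataFrame(),
        de_truth=status,
        common_up=sorted(common_up),
        common_down=sorted(common_down),
    )


def simulate_cohort(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Generate the full expression scenario: counts, sample sheet, truth.

    The matrix holds tissue tumors (TNBC then non-TNBC), tissue normals and
    cell lines as columns. Marker genes are drawn on the log2(x+1) scale
    from the configured mixtures and inverse-transformed to counts; all
    other genes are negative-binomial with group means encoding the planted
    fold-changes. Cell-line receptor labels are recorded as complete,
    error-free IHC columns (their status is treated as known, as for
    authenticated laboratory lines); tissue IHC carries the configured error
    and missingness.
    """
    rng = np.random.default_rng(cfg.seed)
    tissue_ids = (
        [f"TNBC{i:04d}" for i in range(cfg.n_tnbc)]
        + [f"NONT{i:04d}" for i in range(cfg.n_nontnbc)]
    )
    normal_ids = [f"NORM{i:04d}" for i in range(cfg.n_normal)]
    cell_ids = (
        [f"CLTN{i:03d}" for i in range(cfg.n_cell_tnbc)]
        + [f"CLNT{i:03d}" for i in range(cfg.n_cell_nontnbc)]
    )
    gene_ids = list(MARKERS) + [f"GENE{i:05d}" for i in range(cfg.n_genes - len(MARKERS))]

    tumor_truth, tumor_marker_values = _simulate_marker_block(
        cfg, rng, cfg.n_tnbc, cfg.n_nontnbc, tissue_ids
    )
    cell_truth, cell_marker_values = _simulate_marker_block(
        cfg, rng, cfg.n_cell_tnbc, cfg.n_cell_nontnbc, cell_ids
    )
    truth = _allocate_de_truth(cfg, gene_ids, rng)
    marker_truth = pd.concat([tumor_truth, cell_truth])
    truth.marker_truth = marker_truth

    # group means per gene: non-TNBC tissue is the baseline
    lfc_map = {"up": cfg.planted_lfc, "down": -cfg.planted_lfc, "ns": 0.0}
    lfc = truth.de_truth.apply(lambda column: column.map(lfc_map)).astype(float)
    base = np.exp2(rng.normal(cfg.base_mean_log2_mean, cfg.base_mean_log2_sd, size=len(gene_ids)))
    base = pd.Series(base, index=gene_ids)
    means = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    means["nontnbc"] = base
    means["tnbc"] = base * np.exp2(lfc["tissue"])
    # normals share the non-TNBC baseline except where a TNBC-vs-normal
    # effect is planted, which is measured against the TNBC group mean
    means["normal"] = means["tnbc"] / np.exp2(lfc["normal"])
    means["cell_nontnbc"] = base
    means["cell_tnbc"] = base * np.exp2(lfc["cell"])

    sample_ids = tissue_ids + normal_ids + cell_ids
    group_of = (
        ["tnbc"] * cfg.n_tnbc
        + ["nontnbc"] * cfg.n_nontnbc
        + ["normal"] * cfg.n_normal
        + ["cell_tnbc"] * cfg.n_cell_tnbc
        + ["cell_nontnbc"] * cfg.n_cell_nontnbc
    )
    libfactor = np.exp2(rng.normal(0.0, cfg.libsize_log2_sd, size=len(sample_ids)))
    mean_matrix = means[group_of].to_numpy() * libfactor[None, :]
    counts = _nb_counts(rng, mean_matrix, cfg.nb_dispersion).astype(np.int64)

    # marker rows: exact mixture structure on the log2 scale, then inverted
    marker_values = pd.concat([tumor_marker_values, cell_marker_values])
    for j, marker in enumerate(MARKERS):
        row = np.zeros(len(sample_ids))
        v = marker_values[marker]
        for idx, sample in enumerate(sample_ids):
            if sample in v.index:
                row[idx] = np.exp2(v.loc[sample]) - 1.0
            else:  # normals: marker expression near the negative component
                p = cfg.marker_params(marker)
                row[idx] = np.exp2(rng.normal(p["mu_neg"], p["sd_neg"])) - 1.0
        counts[j, :] = np.maximum(np.round(row * libfactor), 0).astype(np.int64)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        unit="counts",
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue_class": ["tumor"] * len(tissue_ids)
            + ["normal"] * len(normal_ids)
            + ["tumor"] * len(cell_ids),
            "cohort": ["tissue"] * (len(tissue_ids) + len(normal_ids))
            + ["cell_line"] * len(cell_ids),
        }
    )
    ihc = _ihc_from_truth(cfg, rng, tumor_truth)
    for marker in MARKERS:
        col = _IHC_COLUMN[marker]
        labels = pd.Series("missing", index=sheet["sample_id"], dtype=object)
        labels.loc[ihc.index] = ihc[col]
        # cell-line receptor status is recorded exactly
        labels.loc[cell_truth.index] = np.where(cell_truth[marker], "pos", "neg")
        sheet[col] = labels.to_numpy()
    sheet = sheet[["sample_id", "tissue_class", *(_IHC_COLUMN[m] for m in MARKERS), "cohort"]]
    return matrix, sheet, truth


def simulate_gene_annotation(
    cfg: SimulationConfig, gene_ids: Sequence[str], seed: int | None = None
) -> pd.DataFrame:
    """Place every gene's TSS uniformly on a small synthetic genome."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 101)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    margin = 10 * cfg.island_width
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "chrom": rng.choice(chroms, size=len(gene_ids)),
            "tss": rng.integers(margin, cfg.chrom_bp - margin, size=len(gene_ids)),
            "strand": rng.choice(["+", "-"], size=len(gene_ids)),
        }
    )


def simulate_methylome(
    cfg: SimulationConfig,
    truth: TruthTable,
    gene_annotation: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe-level beta values plus CpG islands with planted promoter shifts.

    A configured fraction of the genes planted up/down in the tissue
    comparison receive a 500-bp promoter island containing the TSS and three
    probes whose TNBC M-values shift by ``-meth_effect`` for upregulated
    genes (promoter hypomethylation) and ``+meth_effect`` for downregulated
    ones, anti-correlating methylation change with expression change.
    Remaining probes and islands are placed at random. Beta values for the
    tissue tumor samples are returned clipped inside (0.001, 0.999).

    Returns ``(meta, beta, islands)``.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 202)
    ann = gene_annotation.set_index("gene_id")
    tissue_tumors = [
        s for s in truth.marker_truth.index if s.startswith("TNBC") or s.startswith("NONT")
    ]
    is_tnbc = np.array([s.startswith("TNBC") for s in tissue_tumors])

    up = [g for g in truth.de_truth.index[truth.de_truth["tissue"] == "up"]]
    down = [g for g in truth.de_truth.index[truth.de_truth["tissue"] == "down"]]
    n_up_pick = int(round(cfg.meth_gene_fraction * len(up)))
    n_down_pick = int(round(cfg.meth_gene_fraction * len(down)))
    planted_up = sorted(rng.choice(np.array(up, dtype=object), size=n_up_pick, replace=False))
    planted_down = sorted(rng.choice(np.array(down, dtype=object), size=n_down_pick, replace=False))

    meta_rows = []
    islands = []
    shifts = []
    probe_counter = 0
    for genes, sign in ((planted_up, -1.0), (planted_down, +1.0)):
        for gene in genes:
            if gene not in ann.index:
                raise ValueError(f"gene {gene!r} lacks a TSS annotation")
            chrom, tss = ann.loc[gene, "chrom"], int(ann.loc[gene, "tss"])
            start = tss - cfg.island_width // 2 + 50  # TSS inside the island
            islands.append((chrom, start, start + cfg.island_width))
            for offset in (100, cfg.island_width // 2, cfg.island_width - 100):
                meta_rows.append((f"cg{probe_counter:07d}", chrom, start + offset))
                shifts.append(sign * cfg.meth_effect)
                probe_counter += 1

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_extra_islands = max(cfg.n_islands - len(islands), 0)
    for _ in range(n_extra_islands):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, cfg.chrom_bp - cfg.island_width))
        islands.append((chrom, start, start + cfg.island_width))
    n_background = max(cfg.n_probes - len(meta_rows), 0)
    for _ in range(n_background):
        chrom = chroms[rng.integers(0, len(chroms))]
        meta_rows.append((f"cg{probe_counter:07d}", chrom, int(rng.integers(0, cfg.chrom_bp))))
        shifts.append(0.0)
        probe_counter += 1

    meta = pd.DataFrame(meta_rows, columns=["probe_id", "chrom", "pos"]).set_index("probe_id")
    island_frame = pd.DataFrame(islands, columns=["chrom", "start", "end"])
    shifts_arr = np.asarray(shifts)

    # baseline probe methylation is bimodal on the M scale, as on real arrays
    methylated = rng.random(len(meta)) < 0.5
    base_m = np.where(methylated, rng.normal(3.0, 1.0, len(meta)), rng.normal(-3.0, 1.0, len(meta)))
    m = (
        base_m[:, None]
        + rng.normal(0.0, cfg.meth_noise_sd, size=(len(meta), len(tissue_tumors)))
        + shifts_arr[:, None] * is_tnbc[None, :]
    )
    beta = pd.DataFrame(
        np.clip(m_to_beta(m), BETA_CLIP[0], BETA_CLIP[1]),
        index=meta.index,
        columns=tissue_tumors,
    )
    truth.meth_genes = pd.DataFrame(
        {
            "gene_id": list(planted_up) + list(planted_down),
            "planted_delta_m": [-cfg.meth_effect] * len(planted_up)
            + [cfg.meth_effect] * len(planted_down),
        }
    ).set_index("gene_id")
    return meta, beta, island_frame


def simulate_proteome(
    cfg: SimulationConfig,
    expression: ExpressionMatrix,
    truth: TruthTable,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Protein log-abundances concordant with mRNA fold-changes.

    Each protein value is ``protein_scale`` times the sample's log2 mRNA
    signal plus Gaussian noise whose variance is calibrated, from the
    observed spread of mRNA fold-changes, so that the expected Pearson
    correlation between protein and mRNA group fold-changes equals
    ``protein_corr``. The panel covers every common-up gene plus a random
    filler up to ``n_protein_genes``; samples are the tissue tumors.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 303)
    tumors = [s for s in expression.samples if s.startswith("TNBC") or s.startswith("NONT")]
    is_tnbc = np.array([s.startswith("TNBC") for s in tumors])
    logex = log2p1(upper_quartile_normalize(ExpressionMatrix(expression.data[tumors], unit=expression.unit)))
    pool = [g for g in expression.genes if g not in truth.common_up]
    n_fill = max(min(cfg.n_protein_genes, len(expression.genes)) - len(truth.common_up), 0)
    fill = list(rng.choice(np.array(pool, dtype=object), size=n_fill, replace=False))
    panel = sorted(set(truth.common_up) | set(fill))
    x = logex.data.loc[panel].to_numpy()

    rho = cfg.protein_corr
    na, nb = int(is_tnbc.sum()), int((~is_tnbc).sum())
    fc = x[:, is_tnbc].mean(axis=1) - x[:, ~is_tnbc].mean(axis=1)
    fc_var = float(np.var(fc, ddof=1))
    if rho == 0.0:
        protein = rng.normal(0.0, 1.0, size=x.shape)
    else:
        noise_fc_var = cfg.protein_scale**2 * fc_var * (1.0 / rho**2 - 1.0)
        sigma = float(np.sqrt(noise_fc_var / (1.0 / na + 1.0 / nb)))
        protein = cfg.protein_scale * x + rng.normal(0.0, sigma, size=x.shape)
    return ExpressionMatrix(
        pd.DataFrame(protein, index=pd.Index(panel, name="gene_id"), columns=tumors),
        unit="log_abundance",
    )


_FAILURE_MODES = ("pubs", "structure", "druggable", "percentile", "percentile_missing")


def simulate_target_annotations(
    cfg: SimulationConfig, truth: TruthTable, seed: int | None = None
) -> pd.DataFrame:
    """Druggability annotations with exactly one fully passing planted gene.

    The planted target is a common-up gene with zero publications, an
    available druggable structure and a ligand percentile of at least 95;
    every other common-up gene is given at least one failing gate. Genes
    outside the common-up set receive unconstrained random annotations.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 404)
    genes = list(truth.de_truth.index)
    common = list(truth.common_up)
    target = str(rng.choice(np.array(common, dtype=object)))
    rows = {}
    for gene in genes:
        rows[gene] = {
            "pub_count": int(rng.integers(0, 30)),
            "has_structure": bool(rng.random() < 0.5),
            "structure_druggable": bool(rng.random() < 0.5),
            "ligand_percentile": float(np.round(rng.uniform(0, 100), 2)),
        }
    for gene in common:
        if gene == target:
            rows[gene] = {
                "pub_count": 0,
                "has_structure": True,
                "structure_druggable": True,
                "ligand_percentile": float(np.round(rng.uniform(95, 99.5), 2)),
            }
            continue
        mode = _FAILURE_MODES[rng.integers(0, len(_FAILURE_MODES))]
        row = {
            "pub_count": int(rng.integers(0, 2)),
            "has_structure": True,
            "structure_druggable": True,
            "ligand_percentile": float(np.round(rng.uniform(75, 100), 2)),
        }
        if mode == "pubs":
            row["pub_count"] = int(rng.integers(2, 60))
        elif mode == "structure":
            row["has_structure"] = False
        elif mode == "druggable":
            row["structure_druggable"] = False
        elif mode == "percentile":
            row["ligand_percentile"] = float(np.round(rng.uniform(0, 74.9), 2))
        else:
            row["ligand_percentile"] = np.nan
        rows[gene] = row
    truth.target_gene = target
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id").reset_index()
    return table[["gene_id", "pub_count", "has_structure", "structure_druggable", "ligand_percentile"]]


def simulate_correlated_pairs(
    n: int, rho: float, seed: int = 0, scale_x: float = 1.0, scale_y: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal pairs with population correlation ``rho``."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = scale_x * z1
    y = scale_y * (rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2)
    return x, y


def simulate_two_group_counts(
    n_genes: int,
    n_a: int,
    n_b: int,
    n_up: int,
    n_down: int,
    lfc: float,
    dispersion: float,
    seed: int = 0,
    base_mean_log2_mean: float = 7.0,
    base_mean_log2_sd: float = 1.5,
    libsize_log2_sd: float = 0.25,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Plain two-group negative-binomial matrix with planted effects.

    A lean generator for differential-expression calibration studies:
    returns ``(counts, groups, truth_status)`` where groups maps sample to
    "A"/"B" and the planted status is up/down/ns with group A carrying the
    positive fold-changes.
    """
    if n_up + n_down > n_genes:
        raise ValueError("cannot plant more DE genes than n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    status = pd.Series("ns", index=pd.Index(gene_ids, name="gene_id"))
    picked = rng.permutation(n_genes)[: n_up + n_down]
    status.iloc[picked[:n_up]] = "up"
    status.iloc[picked[n_up:]] = "down"
    lfc_vec = status.map({"up": lfc, "down": -lfc, "ns": 0.0}).to_numpy()
    base = np.exp2(rng.normal(base_mean_log2_mean, base_mean_log2_sd, size=n_genes))
    sample_ids = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    in_a = np.array([True] * n_a + [False] * n_b)
    mean = base[:, None] * np.where(in_a[None, :], np.exp2(lfc_vec)[:, None], 1.0)
    mean = mean * np.exp2(rng.normal(0.0, libsize_log2_sd, size=len(sample_ids)))[None, :]
    counts = _nb_counts(rng, mean, dispersion).astype(np.int64)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=status.index, columns=sample_ids), unit="counts"
    )
    groups = pd.Series(np.where(in_a, "A", "B"), index=sample_ids)
    return matrix, groups, status


@dataclass
class Scenario:
    """Everything one synthetic run produces, in memory."""

    cfg: SimulationConfig
    expression: ExpressionMatrix
    sample_sheet: pd.DataFrame
    gene_annotation: pd.DataFrame
    probe_meta: pd.DataFrame
    probe_beta: pd.DataFrame
    islands: pd.DataFrame
    protein: ExpressionMatrix
    target_annotations: pd.DataFrame
    truth: TruthTable


def simulate_scenario(cfg: SimulationConfig) -> Scenario:
    """Run every generator with sub-seeds derived from ``cfg.seed``."""
    expression, sheet, truth = simulate_cohort(cfg)
    gene_annotation = simulate_gene_annotation(cfg, list(expression.genes))
    probe_meta, probe_beta, islands = simulate_methylome(cfg, truth, gene_annotation)
    protein = simulate_proteome(cfg, expression, truth)
    annotations = simulate_target_annotations(cfg, truth)
    return Scenario(
        cfg=cfg,
        expression=expression,
        sample_sheet=sheet,
        gene_annotation=gene_annotation,
        probe_meta=probe_meta,
        probe_beta=probe_beta,
        islands=islands,
        protein=protein,
        target_annotations=annotations,
        truth=truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write a complete input directory plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_matrix(scenario.expression, outdir / "expression_counts.tsv")
    tio.write_sample_sheet(scenario.sample_sheet, outdir / "samples.tsv")
    tio.write_gene_annotation(scenario.gene_annotation, outdir / "gene_annotation.tsv")
    tio.write_probe_table(scenario.probe_meta, scenario.probe_beta, outdir / "methylation_probes.tsv")
    tio.write_islands(scenario.islands, outdir / "cpg_islands.bed")
    tio.write_matrix(scenario.protein, outdir / "protein_abundance.tsv")
    tio.write_target_annotations(scenario.target_annotations, outdir / "target_annotations.tsv")
    truth = scenario.truth
    truth.marker_truth.to_csv(outdir / "truth_markers.tsv", sep="\t")
    truth.de_truth.to_csv(outdir / "truth_de.tsv", sep="\t")
    if truth.meth_genes is not None:
        truth.meth_genes.to_csv(outdir / "truth_methylation.tsv", sep="\t")
    meta = {
        "target_gene": truth.target_gene,
        "common_up": truth.common_up,
        "common_down": truth.common_down,
        "config": {
            k: (v if not isinstance(v, Mapping) else dict(v))
            for k, v in dataclasses.asdict(scenario.cfg).items()
        },
    }
    with open(outdir / "truth_meta.yaml", "w") as handle:
        yaml.safe_dump(meta, handle, sort_keys=False)
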