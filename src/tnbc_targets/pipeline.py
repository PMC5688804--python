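"""End-to-end orchestration: simulate -> normalize -> classify -> DE ->
methylation -> integration -> triage, with a run manifest."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .diffexpr import classify_de, moderated_t_test
from .integrate import IntersectionReport, intersect_de, proteomics_concordance, triage
from .markers import (
    DEFAULT_MARKERS,
    assign_markers,
    assign_tnbc,
    fit_marker_models,
    select_model_combination,
)
from .methylation import (
    annotate_context,
    bin_genome,
    correlate_meth_expression,
    diff_methylation,
    map_probes_to_genes,
    summarize_gene_methylation,
)
from .normalize import beta_to_m, log2p1, quantile_normalize, upper_quartile_normalize
from .simulate import Scenario, SimulationConfig, simulate_scenario, write_scenario

log = logging.getLogger("tnbc_targets")


@dataclass
class RunResult:
    """Everything one full pipeline run computes."""

    scenario: Scenario
    marker_modes: dict[str, str]
    assignments: pd.DataFrame  # tissue tumors: posteriors, calls, tnbc_status
    tnbc_accuracy: float  # vs latent truth (available because inputs are synthetic)
    de: dict[str, pd.DataFrame]
    intersection: IntersectionReport
    meth_probes: pd.DataFrame
    meth_gene_summary: pd.DataFrame
    meth_expr_corr: tuple[float, int]
    binned_track: pd.DataFrame
    protein_de: pd.DataFrame
    protein_corr: tuple[float, int]
    triage_records: pd.DataFrame
    stage_counts: dict[str, int]
    manifest: dict


def run_all(
    sim_cfg: SimulationConfig | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Execute the whole discovery pipeline on one synthetic scenario.

    Tissue tumors are classified by the mixture model (selecting equal- vs
    variable-variance per marker against the noisy IHC labels); cell-line
    status is taken from their complete receptor annotations. Differential
    expression runs TNBC-vs-non-TNBC tissue, TNBC-vs-normal tissue and
    TNBC-vs-non-TNBC cell line comparisons on log2(x+1) upper-quartile
    normalized counts, methylation is tested on quantile-normalized
    M-values, and the common upregulated genes go through the druggability
    cascade.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    cfg = cfg or PipelineConfig(rng_seed=sim_cfg.seed)
    scenario = simulate_scenario(sim_cfg)
    sheet = scenario.sample_sheet.set_index("sample_id")

    logex = log2p1(upper_quartile_normalize(scenario.expression))

    # --- marker classification on tissue tumors ---
    tissue_tumor = sheet[(sheet["cohort"] == "tissue") & (sheet["tissue_class"] == "tumor")]
    marker_values = logex.data.loc[list(DEFAULT_MARKERS), tissue_tumor.index].T
    fits = fit_marker_models(marker_values, DEFAULT_MARKERS, seed=cfg.rng_seed)
    modes, _ = select_model_combination(
        fits, marker_values, tissue_tumor, posterior_cutoff=cfg.posterior_cutoff
    )
    chosen = {marker: fits[marker][mode] for marker, mode in modes.items()}
    assignments = assign_markers(chosen, marker_values, posterior_cutoff=cfg.posterior_cutoff)
    assignments["tnbc_status"] = assign_tnbc(assignments)

    truth_tnbc = scenario.truth.marker_truth.loc[assignments.index, "tnbc"]
    called_tnbc = assignments["tnbc_status"] == "TNBC"
    tnbc_accuracy = float((called_tnbc == truth_tnbc).mean())

    # --- group labels for the three comparisons ---
    labels = pd.Series("other", index=sheet.index, dtype=object)
    labels[tissue_tumor.index] = assignments["tnbc_status"].map(
        {"TNBC": "tnbc", "non-TNBC": "nontnbc"}
    )
    labels[sheet.index[(sheet["cohort"] == "tissue") & (sheet["tissue_class"] == "normal")]] = "normal"
    cells = sheet[sheet["cohort"] == "cell_line"]
    cell_tnbc = (
        (cells["ihc_er"] == "neg") & (cells["ihc_pr"] == "neg") & (cells["ihc_her2"] == "neg")
    )
    labels[cells.index] = cell_tnbc.map({True: "cell_tnbc", False: "cell_nontnbc"})

    de = {
        "tissue": classify_de(moderated_t_test(logex.data, labels, "tnbc", "nontnbc"), cfg),
        "normal": classify_de(moderated_t_test(logex.data, labels, "tnbc", "normal"), cfg),
        "cell": classify_de(moderated_t_test(logex.data, labels, "cell_tnbc", "cell_nontnbc"), cfg),
    }
    intersection = intersect_de(de)

    # --- methylation: quantile normalize beta, logit to M, test, annotate ---
    m_values = beta_to_m(quantile_normalize(scenario.probe_beta))
    meth_de = diff_methylation(m_values, labels, "tnbc", "nontnbc")
    probes = scenario.probe_meta.copy()
    probes["context"] = annotate_context(probes, scenario.islands, cfg)
    probes = map_probes_to_genes(probes, scenario.gene_annotation)
    probes = probes.join(meth_de)
    gene_summary = summarize_gene_methylation(probes)
    meth_corr = correlate_meth_expression(gene_summary, de["tissue"])
    track_points = pd.concat(
        [
            probes[["chrom", "pos", "delta_m"]].rename(columns={"delta_m": "value"}).assign(layer="methylation"),
            scenario.gene_annotation.set_index("gene_id")
            .join(de["tissue"]["log2fc"])
            .rename(columns={"tss": "pos", "log2fc": "value"})[["chrom", "pos", "value"]]
            .assign(layer="expression"),
        ]
    )
    binned = pd.concat(
        [
            bin_genome(group, ["value"], cfg).assign(layer=layer)
            for layer, group in track_points.groupby("layer")
        ],
        ignore_index=True,
    )

    # --- proteomics concordance ---
    protein_de, protein_r, protein_n = proteomics_concordance(
        scenario.protein, labels, "tnbc", "nontnbc", de["tissue"]
    )

    # --- druggability triage ---
    records, stage_counts = triage(intersection.common_up, scenario.target_annotations, cfg)

    manifest = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "simulation": dataclasses.asdict(sim_cfg),
        "config": dataclasses.asdict(cfg),
        "marker_modes": modes,
        "tnbc_call_accuracy": tnbc_accuracy,
        "de_counts": {
            name: {
                "up": int((d["status"] == "up").sum()),
                "down": int((d["status"] == "down").sum()),
            }
            for name, d in de.items()
        },
        "common_up": len(intersection.common_up),
        "common_down": len(intersection.common_down),
        "meth_expr_corr": {"r": meth_corr[0], "n": meth_corr[1]},
        "protein_fc_corr": {"r": protein_r, "n": protein_n},
        "stage_counts": stage_counts,
    }

    result = RunResult(
        scenario=scenario,
        marker_modes=modes,
        assignments=assignments,
        tnbc_accuracy=tnbc_accuracy,
        de=de,
        intersection=intersection,
        meth_probes=probes,
        meth_gene_summary=gene_summary,
        meth_expr_corr=meth_corr,
        binned_track=binned,
        protein_de=protein_de,
        protein_corr=(protein_r, protein_n),
        triage_records=records,
        stage_counts=stage_counts,
        manifest=manifest,
    )
    if outdir is not None:
        _write_run(result, Path(outdir))
    return result


def _write_run(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_scenario(result.scenario, outdir / "inputs")
    result.assignments.to_csv(outdir / "marker_status.tsv", sep="\t", index_label="sample_id")
    for name, frame in result.de.items():
        frame.to_csv(outdir / f"de_{name}.tsv", sep="\t")
    result.meth_probes.to_csv(outdir / "methylation_probes_annotated.tsv", sep="\t")
    result.meth_gene_summary.to_csv(outdir / "methylation_gene_summary.tsv", sep="\t")
    result.binned_track.to_csv(outdir / "binned_track.tsv", sep="\t", index=False)
    result.protein_de.to_csv(outdir / "protein_de.tsv", sep="\t")
    result.triage_records.to_csv(outdir / "triage.tsv", sep="\t", index=False)
    with open(outdir / "manifest.yaml", "w") as handle:
        yaml.safe_dump(result.manifest, handle, sort_keys=False)
    log.info("run written to %s", outdir)
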