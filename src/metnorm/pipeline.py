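"""End-to-end orchestration of the staged analysis.

Stages run in the flow's fixed order: count normalization (background
threshold -> housekeeping selection -> global-mean scaling -> count
filter), healthy-table filtering, platform intersection, ratio
computation, classification, over-representation of the downregulated
genes, and the IHC/survival statistics.  A run manifest records the
configuration, input digests and the gene counts surviving each stage
(the filtering funnel), which together determine a reproducible rerun.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from . import background as bg
from . import ihc as ihc_mod
from . import io_formats as iof
from . import ora as ora_mod
from .errors import ValidationError
from .nanostring import NormalizationParams, NormalizationResult, normalize_counts

__all__ = ["PipelineResult", "run_cohort", "run_from_files"]


@dataclass
class PipelineResult:
    """Outputs of every stage plus the run manifest."""

    normalization: NormalizationResult
    healthy_filtered: pd.DataFrame
    ratios: bg.RatioTable
    classification: pd.DataFrame
    ora: pd.DataFrame | None
    ihc_comparisons: dict[str, ihc_mod.GroupComparison] = field(default_factory=dict)
    survival: tuple[float, float, int] | None = None
    manifest: dict = field(default_factory=dict)

    def genes_with_label(self, label: str) -> list[str]:
        cls = self.classification
        return list(cls.index[cls["label"] == label])


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_cohort(
    samples,
    healthy: pd.DataFrame,
    gene_sets=None,
    ihc: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    norm_params: NormalizationParams = NormalizationParams(),
    class_params: bg.ClassificationParams = bg.ClassificationParams(),
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``samples`` must already carry patient/tissue annotation.
    """
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": {
            "normalization": vars(norm_params).copy(),
            "classification": vars(class_params).copy(),
        },
    }
    norm = normalize_counts(samples, norm_params)
    n_panel = len(norm.matrix.values.index) + len(norm.excluded_genes)
    manifest["n_samples"] = int(norm.matrix.values.shape[1])
    manifest["n_genes_panel"] = n_panel
    manifest["n_genes_after_count_filter"] = int(norm.matrix.values.shape[0])
    manifest["housekeeping_selected"] = list(norm.housekeeping)

    healthy_kept, healthy_excluded = bg.filter_healthy(healthy, class_params)
    universe, dropped_cancer, _ = bg.intersect_platforms(
        list(norm.matrix.values.index), list(healthy.index)
    )
    manifest["n_genes_on_both_platforms"] = len(universe)
    analysed, _, _ = bg.intersect_platforms(universe, list(healthy_kept.index))
    manifest["n_genes_analysed"] = len(analysed)

    matrix = norm.matrix
    restricted = type(matrix)(
        values=matrix.values.loc[analysed],
        code_class=matrix.code_class.loc[analysed],
        samples=matrix.samples,
        stage=matrix.stage,
    )
    pairs = bg.pairs_from_samples(matrix.samples)
    ratios = bg.compute_ratios(restricted, pairs, healthy_kept, norm_params.log_floor)
    classification = bg.classify_genes(ratios, class_params)
    for label_col in ("enriched", "depleted", "upregulated", "downregulated"):
        manifest[f"n_{label_col}"] = int(classification[label_col].sum())

    ora_result = None
    if gene_sets:
        down = list(classification.index[classification["downregulated"]])
        if down:
            ora_result = ora_mod.hypergeometric_overrep(down, gene_sets, analysed)
        else:
            ora_result = pd.DataFrame()

    comparisons: dict[str, ihc_mod.GroupComparison] = {}
    survival = None
    if ihc is not None:
        statuses = ihc_mod.specimen_statuses(ihc)
        for compartment in ihc_mod.COMPARTMENTS:
            try:
                comparisons[compartment] = ihc_mod.compare_groups(statuses, compartment)
            except ValidationError:
                continue
        if clinical is not None:
            try:
                survival = ihc_mod.three_year_os(clinical, statuses)
            except ValidationError:
                survival = None
        manifest["ihc_p_values"] = {k: v.p_value for k, v in comparisons.items()}
        if survival is not None:
            manifest["three_year_os"] = {
                "chi2": survival[0],
                "p": survival[1],
                "n": survival[2],
            }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    return PipelineResult(
        normalization=norm,
        healthy_filtered=healthy_kept,
        ratios=ratios,
        classification=classification,
        ora=ora_result,
        ihc_comparisons=comparisons,
        survival=survival,
        manifest=manifest,
    )


def run_from_files(
    rcc_dir: str,
    sample_sheet: str,
    healthy: str,
    gmt: str | None = None,
    ihc: str | None = None,
    clinical: str | None = None,
    norm_params: NormalizationParams = NormalizationParams(),
    class_params: bg.ClassificationParams = bg.ClassificationParams(),
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the full analysis from files on disk, optionally writing outputs."""
    rcc_paths = sorted(glob.glob(os.path.join(rcc_dir, "*.rcc")))
    if not rcc_paths:
        raise ValidationError(f"no .rcc files found in {rcc_dir!r}")
    sheet = iof.read_sample_sheet(sample_sheet)
    samples = [iof.read_rcc(p) for p in rcc_paths]
    found = {s.sample_id for s in samples}
    missing = set(sheet["sample_id"]) - found
    if missing:
        raise ValidationError(
            f"sample sheet entries without an RCC file: {sorted(missing)}"
        )
    samples = iof.annotate_samples(samples, sheet)
    healthy_df = iof.read_expression_table(healthy)
    gene_sets = iof.read_gmt(gmt) if gmt else None
    ihc_df = iof.read_ihc_table(ihc) if ihc else None
    clinical_df = iof.read_clinical_table(clinical) if clinical else None
    result = run_cohort(
        samples,
        healthy_df,
        gene_sets,
        ihc_df,
        clinical_df,
        norm_params,
        class_params,
    )
    inputs = {os.path.basename(p): _digest(p) for p in rcc_paths}
    inputs[os.path.basename(sample_sheet)] = _digest(sample_sheet)
    inputs[os.path.basename(healthy)] = _digest(healthy)
    for p in (gmt, ihc, clinical):
        if p:
            inputs[os.path.basename(p)] = _digest(p)
    result.manifest["inputs"] = inputs
    if out_dir:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write the stage outputs and the manifest to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    norm = result.normalization
    norm.matrix.values.rename_axis("gene").to_csv(
        os.path.join(out_dir, "normalized_matrix.tsv"), sep="\t"
    )
    pd.DataFrame(
        {"background_threshold": norm.thresholds, "scale_factor": norm.scale_factors}
    ).rename_axis("sample_id").to_csv(
        os.path.join(out_dir, "sample_factors.tsv"), sep="\t"
    )
    with open(os.path.join(out_dir, "excluded_genes.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(norm.excluded_genes) + ("\n" if norm.excluded_genes else ""))
    result.classification.rename_axis("gene").to_csv(
        os.path.join(out_dir, "classification.tsv"), sep="\t"
    )
    if result.ora is not None and not result.ora.empty:
        result.ora.to_csv(os.path.join(out_dir, "ora.tsv"), sep="\t", index=False)
    if result.ihc_comparisons:
        rows = []
        for compartment, comp in result.ihc_comparisons.items():
            for grp in comp.table.index:
                rows.append(
                    {
                        "compartment": compartment,
                        "group": grp,
                        "positive": comp.table.loc[grp, "positive"],
                        "negative": comp.table.loc[grp, "negative"],
                        "p_value": comp.p_value,
                    }
                )
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, "ihc_comparisons.tsv"), sep="\t", index=False
        )
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
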