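"""Healthy-tissue-background ratio normalization and gene classification.

The central idea: a nodal metastasis sits in lymphoid tissue while the
primary tumour sits in breast tissue, so a naive LNM/PT expression ratio
confounds tumour biology with the physiological difference between the
two host tissues.  The correction subtracts, per gene, the log2 ratio of
healthy lymph node to healthy breast expression (the HEALTHY ratio, from
a two-tissue FPKM table) from each patient's matched log2 LNM/PT count
ratio (the CANCER ratio):

    normalized_ratio[g, p] = cancer_ratio[g, p] - healthy_ratio[g]

The per-gene median of the normalized ratios across patients drives a
four-way classification:

* enriched   : median normalized ratio > +1 (vs healthy lymph node)
* depleted   : median normalized ratio < -1
* upregulated: enriched AND healthy ratio < 0 (gene lower in lymph node
  than breast) AND median matched raw ratio > 0 (LNM above PT)
* downregulated: depleted AND healthy ratio > 0 AND median raw ratio < 0

All inequalities are strict; a gene at a cutoff stays unclassified.
The up/down calls thus require the cancer shift to oppose the healthy
tissue direction, which guards against calling a gene "upregulated"
merely because metastases contain less lymphoid stroma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nanostring import CountMatrix

__all__ = [
    "ClassificationParams",
    "RatioTable",
    "pairs_from_samples",
    "filter_healthy",
    "intersect_platforms",
    "compute_ratios",
    "classify_genes",
    "LABELS",
]

LABELS = (
    "LNM-upregulated",
    "LNM-enriched-only",
    "LNM-downregulated",
    "LNM-depleted-only",
    "unclassified",
)


@dataclass(frozen=True)
class ClassificationParams:
    """Cutoffs for the healthy filter and the four-way classification.

    enrichment_cutoff / depletion_cutoff
        log2 cutoffs on the median normalized LNM/PT ratio (+1/-1 by
        default, i.e. 2-fold beyond the healthy background).
    min_log2_fpkm
        Healthy-tissue expression floor (default 5, ~32 FPKM).
    healthy_filter_mode
        "both": a gene is dropped only when below the floor in both
        tissues (default); "any": dropped when below in either.
    tendency
        Which matched-ratio median the up/down "expression tendency"
        condition uses: "raw" (default, the unnormalized matched LNM/PT
        median) or "normalized".
    """

    enrichment_cutoff: float = 1.0
    depletion_cutoff: float = -1.0
    min_log2_fpkm: float = 5.0
    healthy_filter_mode: str = "both"
    tendency: str = "raw"

    def __post_init__(self) -> None:
        if not self.enrichment_cutoff > self.depletion_cutoff:
            raise ValidationError("enrichment_cutoff must exceed depletion_cutoff")
        if self.healthy_filter_mode not in ("both", "any"):
            raise ValidationError("healthy_filter_mode must be both|any")
        if self.tendency not in ("raw", "normalized"):
            raise ValidationError("tendency must be raw|normalized")


def pairs_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the patient -> (PT sample, LNM sample) map from sample annotation.

    ``samples`` is the CountMatrix annotation (index sample_id, columns
    patient_id, tissue).  Every patient must contribute exactly one PT
    and one LNM sample.
    """
    pairs = {}
    for patient, group in samples.groupby("patient_id", sort=False):
        tissues = group["tissue"].tolist()
        if sorted(tissues) != ["LNM", "PT"]:
            raise ValidationError(
                f"patient {patient!r}: expected one PT and one LNM sample, "
                f"got tissues {tissues}"
            )
        pt = group.index[group["tissue"] == "PT"][0]
        lnm = group.index[group["tissue"] == "LNM"][0]
        pairs[patient] = (pt, lnm)
    out = pd.DataFrame.from_dict(pairs, orient="index", columns=["PT", "LNM"])
    out.index.name = "patient_id"
    return out


def filter_healthy(
    table: pd.DataFrame, params: ClassificationParams = ClassificationParams()
) -> tuple[pd.DataFrame, list[str]]:
    """Drop low-expression genes from the healthy FPKM table.

    In "both" mode a gene goes iff log2 FPKM is strictly below the floor
    in *both* tissues; in "any" mode iff in at least one.  Genes with a
    zero FPKM in either tissue are additionally dropped (their healthy
    log-ratio is undefined) with a warning.

    Returns the filtered table and the excluded genes in table order.
    """
    nonpositive = (table <= 0).any(axis=1)
    if nonpositive.any():
        warnings.warn(
            f"dropping {int(nonpositive.sum())} genes with non-positive FPKM "
            "(healthy ratio undefined)"
        )
    with np.errstate(divide="ignore"):
        log2 = np.log2(table.where(table > 0))
    below = log2 < params.min_log2_fpkm
    if params.healthy_filter_mode == "both":
        low = below.all(axis=1)
    else:
        low = below.any(axis=1)
    drop = low | nonpositive
    return table.loc[~drop], list(table.index[drop])


def intersect_platforms(
    cancer_genes: list[str], healthy_genes: list[str]
) -> tuple[list[str], int, int]:
    """Intersect the count-panel and healthy-table gene lists.

    Returns the intersection in cancer-matrix order plus the number of
    genes dropped on each side.  An empty intersection is an error.
    """
    healthy = set(healthy_genes)
    universe = [g for g in cancer_genes if g in healthy]
    if not universe:
        raise ValidationError("no genes shared between count panel and healthy table")
    return universe, len(cancer_genes) - len(universe), len(healthy) - len(universe)


@dataclass
class RatioTable:
    """Per-gene ratio decomposition across matched pairs.

    healthy_ratio
        Series, per gene: log2(LYMPH_NODE FPKM) - log2(BREAST FPKM).
    cancer_ratio
        DataFrame, gene x patient: log2(LNM count) - log2(PT count).
    normalized_ratio
        cancer_ratio - healthy_ratio, element-wise.
    median_raw / median_normalized
        Per-gene medians of cancer_ratio / normalized_ratio across
        patients (even n: mean of the two middle values).
    """

    healthy_ratio: pd.Series
    cancer_ratio: pd.DataFrame
    normalized_ratio: pd.DataFrame
    median_raw: pd.Series
    median_normalized: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.healthy_ratio.index)


def compute_ratios(
    matrix: CountMatrix,
    pairs: pd.DataFrame,
    healthy: pd.DataFrame,
    log_floor: float = 1.0,
) -> RatioTable:
    """Compute HEALTHY, matched CANCER and background-normalized ratios.

    ``matrix`` must already be restricted to the analysis universe
    (genes present and expressed on both platforms).  Counts are floored
    at ``log_floor`` before log2; the healthy table must contain every
    matrix gene with positive FPKM in both tissues.
    """
    genes = list(matrix.values.index)
    missing_h = [g for g in genes if g not in healthy.index]
    if missing_h:
        raise ValidationError(f"genes missing from healthy table: {missing_h[:5]}...")
    for patient, row in pairs.iterrows():
        for col in ("PT", "LNM"):
            if row[col] not in matrix.values.columns:
                raise ValidationError(
                    f"patient {patient!r}: sample {row[col]!r} missing from matrix"
                )
    h = healthy.loc[genes]
    if (h.to_numpy() <= 0).any():
        raise ValidationError("healthy FPKM must be positive (filter upstream)")
    healthy_ratio = np.log2(h["LYMPH_NODE"]) - np.log2(h["BREAST"])
    healthy_ratio.name = "healthy_ratio"

    logged = np.log2(matrix.values.clip(lower=log_floor))
    lnm = logged[pairs["LNM"].tolist()]
    pt = logged[pairs["PT"].tolist()]
    cancer = pd.DataFrame(
        lnm.to_numpy() - pt.to_numpy(), index=genes, columns=pairs.index
    )
    normalized = cancer.sub(healthy_ratio, axis=0)
    return RatioTable(
        healthy_ratio=healthy_ratio,
        cancer_ratio=cancer,
        normalized_ratio=normalized,
        median_raw=cancer.median(axis=1).rename("median_raw"),
        median_normalized=normalized.median(axis=1).rename("median_normalized"),
    )


def classify_genes(
    ratios: RatioTable, params: ClassificationParams = ClassificationParams()
) -> pd.DataFrame:
    """Apply the four-way classification to a :class:`RatioTable`.

    Returns a DataFrame indexed by gene with columns healthy_ratio,
    median_raw, median_normalized, the four boolean flags and a summary
    ``label``.
    """
    med_n = ratios.median_normalized
    enriched = med_n > params.enrichment_cutoff
    depleted = med_n < params.depletion_cutoff
    tendency = ratios.median_raw if params.tendency == "raw" else med_n
    upregulated = enriched & (ratios.healthy_ratio < 0) & (tendency > 0)
    downregulated = depleted & (ratios.healthy_ratio > 0) & (tendency < 0)
    label = pd.Series("unclassified", index=med_n.index, name="label")
    label[enriched] = "LNM-enriched-only"
    label[depleted] = "LNM-depleted-only"
    label[upregulated] = "LNM-upregulated"
    label[downregulated] = "LNM-downregulated"
    return pd.DataFrame(
        {
            "healthy_ratio": ratios.healthy_ratio,
            "median_raw": ratios.median_raw,
            "median_normalized": med_n,
            "enriched": enriched,
            "depleted": depleted,
            "upregulated": upregulated,
            "downregulated": downregulated,
            "label": label,
        }
    )
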