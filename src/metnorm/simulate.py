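"""Seeded synthetic cohort generator with planted ground truth.

Emulates every input the pipeline consumes so all stages are testable
without any download: matched primary-tumour / nodal-metastasis
nCounter-style count files with controls and lane effects, a two-tissue
healthy FPKM table, a gene-set collection with one pathway planted over
the downregulated genes, core-level IHC intensity tables and a
clinical/survival table.

Count model
-----------
Endogenous probe counts are negative binomial with

    mean = lane_factor * 2^base_log2 * 2^(cancer_effect for LNM lanes)

and variance mean + dispersion * mean^2; negative controls are Poisson
with a small rate, positive controls follow a fixed four-fold geometric
ladder scaled by the lane factor, and housekeeping probes have
gene-specific constant means scaled by the lane factor.  Lane factors
are log-normal (``lane_factor_sd_log2`` on the log2 scale).

Planted gene classes (fractions configurable; defaults reproduce the
cohort sizes and filtering funnel of the emulated study design,
730 -> 593 -> 578 -> 360 genes across the two filters and the platform
intersection):

``null``            no cancer effect, healthy ratio 0.
``upregulated``     cancer effect +e, healthy ratio -e/2 (opposite
                    direction), hence normalized ratio +3e/2.
``downregulated``   cancer effect -e, healthy ratio +e/2.
``enriched_only``   cancer effect +e but healthy ratio +e/2 — a decoy
                    that is enriched yet must not be called upregulated.
``depleted_only``   cancer effect -e, healthy ratio -e/2 (decoy).
``low_expression``  base mean planted below the count filter.
``healthy_low``     healthy FPKM planted below the FPKM filter.

plus ``n_absent_healthy`` genes simply missing from the healthy table
(lost at the platform intersection).

The IHC arm plants per-patient Bernoulli positivity (different rates in
PT and LNM) realised through core-level intensities with dropout, and
exponential survival whose hazard is multiplied by
``hazard_ratio_c3_loss`` for patients whose metastasis has lost tumoral
staining.

A fixed seed yields byte-identical output files; every output draws
from its own PRNG stream spawned from the master seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import io_formats as iof
from .io_formats import GeneSet, ProbeRecord, SampleCounts

__all__ = [
    "SimulationConfig",
    "Cohort",
    "default_class_fractions",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort",
]

GENE_CLASSES = (
    "null",
    "enriched_only",
    "depleted_only",
    "upregulated",
    "downregulated",
    "low_expression",
    "healthy_low",
)

# Default class counts emulate the study funnel on a 730-gene panel:
# 137 genes fail the count filter (-> 593), 15 are absent from the
# healthy table (-> 578), 218 fail the FPKM filter (-> 360), and the
# analysed 360 split into 3 up / 8 enriched-only / 33 down /
# 37 depleted-only / 279 null.
_DEFAULT_CLASS_COUNTS = {
    "null": 279,
    "enriched_only": 8,
    "depleted_only": 37,
    "upregulated": 3,
    "downregulated": 33,
    "low_expression": 137,
    "healthy_low": 218,
}
_DEFAULT_N_ENDOGENOUS = 730
_DEFAULT_N_ABSENT = 15


def default_class_fractions() -> dict[str, float]:
    n = _DEFAULT_N_ENDOGENOUS - _DEFAULT_N_ABSENT
    return {k: v / n for k, v in _DEFAULT_CLASS_COUNTS.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_pairs: int = 11
    n_endogenous: int = _DEFAULT_N_ENDOGENOUS
    n_negative: int = 8
    n_positive: int = 6
    n_housekeeping: int = 40
    n_absent_healthy: int = _DEFAULT_N_ABSENT
    class_fractions: dict = field(default_factory=default_class_fractions)
    effect_log2: float = 3.0
    nb_dispersion: float = 0.1
    lane_factor_sd_log2: float = 0.2
    neg_control_lambda: float = 5.0
    healthy_fpkm_log2_mean: float = 8.0
    healthy_fpkm_log2_sd: float = 1.5
    # IHC arm
    n_patients: int = 79
    n_node_positive: int = 43
    p_pos_pt: float = 0.7
    p_pos_lnm: float = 0.35
    core_dropout: float = 0.1
    # survival arm
    baseline_hazard: float = 0.01  # per month
    hazard_ratio_c3_loss: float = 4.0
    censor_rate: float = 0.01  # per month
    max_followup_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes {sorted(unknown)}")
        total = sum(fr.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(f"class fractions must sum to 1, got {total}")
        if min(fr.values(), default=0) < 0:
            raise ValidationError("class fractions must be non-negative")
        for name in (
            "nb_dispersion",
            "lane_factor_sd_log2",
            "neg_control_lambda",
            "core_dropout",
            "baseline_hazard",
            "censor_rate",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_absent_healthy >= self.n_endogenous:
            raise ValidationError("n_absent_healthy must be below n_endogenous")
        if self.n_node_positive > self.n_patients:
            raise ValidationError("n_node_positive cannot exceed n_patients")
        if self.n_pairs > self.n_node_positive:
            raise ValidationError("count pairs must come from node-positive patients")


@dataclass
class Cohort:
    """In-memory synthetic cohort: pipeline inputs plus planted truth."""

    samples: list[SampleCounts]
    sample_sheet: pd.DataFrame
    healthy: pd.DataFrame
    gene_sets: dict[str, GeneSet]
    ihc: pd.DataFrame
    clinical: pd.DataFrame
    gene_truth: pd.DataFrame
    patient_truth: pd.DataFrame
    config: SimulationConfig


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of classes over the non-absent genes."""
    n = config.n_endogenous - config.n_absent_healthy
    raw = {k: config.class_fractions.get(k, 0.0) * n for k in GENE_CLASSES}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial in (mean, dispersion) form; Poisson limit at 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _plant_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign classes, base means and planted effects to every panel gene."""
    counts = _class_counts(config)
    classes = []
    for cls in GENE_CLASSES:
        classes.extend([cls] * counts[cls])
    classes.extend(["absent_healthy"] * config.n_absent_healthy)
    classes = np.array(classes)
    rng.shuffle(classes)
    n = config.n_endogenous
    genes = [f"G{i + 1:04d}" for i in range(n)]
    e = config.effect_log2

    # floor at 8 keeps even a -effect_log2 metastasis lane clear of the
    # mean-log2-count filter at 6
    base_log2 = np.clip(rng.normal(9.0, 1.0, size=n), 8.0, 14.0)
    low = classes == "low_expression"
    # planted safely below the count filter (mean log2 count < 6)
    base_log2[low] = np.clip(rng.normal(3.5, 0.5, size=low.sum()), 1.5, 4.8)

    cancer_effect = np.zeros(n)
    healthy_ratio = np.zeros(n)
    cancer_effect[classes == "upregulated"] = e
    healthy_ratio[classes == "upregulated"] = -e / 2
    cancer_effect[classes == "downregulated"] = -e
    healthy_ratio[classes == "downregulated"] = e / 2
    cancer_effect[classes == "enriched_only"] = e
    healthy_ratio[classes == "enriched_only"] = e / 2
    cancer_effect[classes == "depleted_only"] = -e
    healthy_ratio[classes == "depleted_only"] = -e / 2
    hl = (classes == "healthy_low") | (classes == "absent_healthy")
    healthy_ratio[hl] = rng.normal(0.0, 0.5, size=hl.sum())

    return pd.DataFrame(
        {
            "gene": genes,
            "planted_class": classes,
            "base_log2_mean": base_log2,
            "cancer_log2_effect": cancer_effect,
            "healthy_log2_ratio": healthy_ratio,
        }
    ).set_index("gene")


def _simulate_counts(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[list[SampleCounts], pd.DataFrame]:
    n_samples = 2 * config.n_pairs
    patients = [f"P{i + 1:03d}" for i in range(config.n_pairs)]
    sample_ids, patient_ids, tissues = [], [], []
    for p in patients:
        for tissue in ("PT", "LNM"):
            sample_ids.append(f"{p}_{tissue}")
            patient_ids.append(p)
            tissues.append(tissue)
    lane = 2.0 ** rng.normal(0.0, config.lane_factor_sd_log2, size=n_samples)

    base = 2.0 ** truth["base_log2_mean"].to_numpy()
    effect = truth["cancer_log2_effect"].to_numpy()
    is_lnm = np.array([t == "LNM" for t in tissues])
    mean = base[:, None] * lane[None, :] * np.where(is_lnm[None, :], 2.0 ** effect[:, None], 1.0)
    endo = _nb_draw(rng, mean, config.nb_dispersion)

    neg = rng.poisson(config.neg_control_lambda, size=(config.n_negative, n_samples))
    pos_ladder = 32.0 * 4.0 ** np.arange(config.n_positive)[::-1]  # 4-fold ladder
    pos = rng.poisson(pos_ladder[:, None] * lane[None, :])
    hk_base = 2.0 ** np.clip(rng.normal(8.5, 0.8, size=config.n_housekeeping), 7.0, 11.0)
    hk = _nb_draw(rng, hk_base[:, None] * lane[None, :], config.nb_dispersion)

    samples = []
    genes = list(truth.index)
    for j, sid in enumerate(sample_ids):
        probes = [
            ProbeRecord(g, "Endogenous", f"NM_{i + 1:06d}", int(endo[i, j]))
            for i, g in enumerate(genes)
        ]
        probes += [
            ProbeRecord(f"NEG_{chr(65 + i)}", "Negative", "", int(neg[i, j]))
            for i in range(config.n_negative)
        ]
        probes += [
            ProbeRecord(f"POS_{chr(65 + i)}", "Positive", "", int(pos[i, j]))
            for i in range(config.n_positive)
        ]
        probes += [
            ProbeRecord(f"HK{i + 1:02d}", "Housekeeping", "", int(hk[i, j]))
            for i in range(config.n_housekeeping)
        ]
        samples.append(
            SampleCounts(
                sample_id=sid,
                probes=probes,
                patient_id=patient_ids[j],
                tissue=tissues[j],
            )
        )
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "patient_id": patient_ids, "tissue": tissues}
    )
    return samples, sheet


def _simulate_healthy(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    present = truth[truth["planted_class"] != "absent_healthy"]
    r = present["healthy_log2_ratio"].to_numpy()
    cls = present["planted_class"].to_numpy()
    n = len(present)
    floor = 5.0  # keep planted genes clear of the log2-FPKM filter at 5
    base = rng.normal(config.healthy_fpkm_log2_mean, config.healthy_fpkm_log2_sd, size=n)
    base = np.maximum(base, floor + np.abs(r) / 2 + 0.3)
    low = cls == "healthy_low"
    low_base = rng.normal(3.0, 1.0, size=int(low.sum()))
    base[low] = np.clip(low_base, 0.5, floor - np.abs(r[low]) / 2 - 0.3)
    breast = 2.0 ** (base - r / 2)
    lymph = 2.0 ** (base + r / 2)
    return pd.DataFrame(
        {"BREAST": breast, "LYMPH_NODE": lymph}, index=present.index.copy()
    )


def _simulate_gene_sets(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> dict[str, GeneSet]:
    sets: dict[str, GeneSet] = {}
    down = list(truth.index[truth["planted_class"] == "downregulated"])
    if down:
        sets["PLANTED_DOWN_PATHWAY"] = GeneSet(
            "PLANTED_DOWN_PATHWAY",
            "pathway planted over the downregulated genes",
            frozenset(down),
        )
    analysed = truth[
        ~truth["planted_class"].isin(["low_expression", "healthy_low", "absent_healthy"])
    ]
    pool = np.array(analysed.index)
    for i in range(20):
        size = int(rng.integers(8, 26))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        sets[f"DECOY_SET_{i + 1:02d}"] = GeneSet(
            f"DECOY_SET_{i + 1:02d}", "random decoy set", frozenset(members.tolist())
        )
    return sets


def _simulate_ihc_and_clinical(
    config: SimulationConfig, rng_ihc: np.random.Generator, rng_surv: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    nodal = np.array(["N+"] * config.n_node_positive + ["N-"] * (n - config.n_node_positive))

    def core_intensity(latent_pos: bool) -> str:
        if rng_ihc.random() < config.core_dropout:
            return "noninformative"
        if latent_pos:
            return rng_ihc.choice(
                ["none", "weak", "moderate", "strong"], p=[0.15, 0.15, 0.4, 0.3]
            )
        return rng_ihc.choice(["none", "weak"], p=[0.5, 0.5])

    ihc_rows = []
    truth_rows = []
    for i, patient in enumerate(patients):
        tissues = ["PT"] + (["LNM"] if nodal[i] == "N+" else [])
        statuses = {}
        for tissue in tissues:
            p_pos = config.p_pos_pt if tissue == "PT" else config.p_pos_lnm
            latent = {
                "tumoral": rng_ihc.random() < p_pos,
                "stromal": rng_ihc.random() < p_pos,
            }
            statuses[tissue] = latent
            for core in range(1, 6):
                ihc_rows.append(
                    {
                        "patient_id": patient,
                        "tissue": tissue,
                        "core_index": core,
                        "tumoral_intensity": core_intensity(latent["tumoral"]),
                        "stromal_intensity": core_intensity(latent["stromal"]),
                    }
                )
        truth_rows.append(
            {
                "patient_id": patient,
                "nodal_status": nodal[i],
                "latent_pt_tumoral": statuses["PT"]["tumoral"],
                "latent_lnm_tumoral": statuses.get("LNM", {}).get("tumoral", np.nan),
            }
        )
    patient_truth = pd.DataFrame(truth_rows).set_index("patient_id")

    # survival: hazard multiplied for patients whose LNM lost tumoral staining
    loss = (patient_truth["latent_lnm_tumoral"] == False).to_numpy()  # noqa: E712
    hazard = config.baseline_hazard * np.where(loss, config.hazard_ratio_c3_loss, 1.0)
    hazard = np.clip(hazard, 1e-12, None)
    t_event = rng_surv.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_censor = rng_surv.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    t_censor = np.minimum(t_censor, config.max_followup_months)
    os_months = np.minimum(t_event, t_censor)
    os_event = np.where(t_event <= t_censor, "death", "censored")
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "nodal_status": nodal,
            "os_months": np.round(os_months, 2),
            "os_event": os_event,
        }
    )
    patient_truth["planted_c3_loss"] = loss
    return pd.DataFrame(ihc_rows), clinical, patient_truth


def generate_cohort(config: SimulationConfig = SimulationConfig()) -> Cohort:
    """Generate the full synthetic cohort for a configuration.

    Deterministic: the same config (including seed) yields identical
    output, file-for-file and byte-for-byte once written.
    """
    rngs = _streams(config.seed, ["genes", "counts", "healthy", "gene_sets", "ihc", "survival"])
    truth = _plant_genes(config, rngs["genes"])
    samples, sheet = _simulate_counts(config, truth, rngs["counts"])
    healthy = _simulate_healthy(config, truth, rngs["healthy"])
    gene_sets = _simulate_gene_sets(config, truth, rngs["gene_sets"])
    ihc, clinical, patient_truth = _simulate_ihc_and_clinical(
        config, rngs["ihc"], rngs["survival"]
    )
    return Cohort(
        samples=samples,
        sample_sheet=sheet,
        healthy=healthy,
        gene_sets=gene_sets,
        ihc=ihc,
        clinical=clinical,
        gene_truth=truth,
        patient_truth=patient_truth,
        config=config,
    )


def generate_null_cohort(config: SimulationConfig = SimulationConfig()) -> Cohort:
    """Generate a cohort with every planted effect switched off.

    All genes become effect-free (classes other than the two filter
    classes keep their base means but lose cancer effects and healthy
    ratios) and the IHC positivity rates and survival hazards are
    equalized between PT and LNM.
    """
    null_fractions = dict(config.class_fractions)
    moved = 0.0
    for cls in ("enriched_only", "depleted_only", "upregulated", "downregulated"):
        moved += null_fractions.pop(cls, 0.0)
    null_fractions["null"] = null_fractions.get("null", 0.0) + moved
    null_config = replace(
        config,
        class_fractions=null_fractions,
        effect_log2=0.0,
        p_pos_lnm=config.p_pos_pt,
        hazard_ratio_c3_loss=1.0,
    )
    return generate_cohort(null_config)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every cohort input to ``out_dir`` in its external format.

    Returns a manifest of logical name -> path.  The planted truth
    tables are written too (as TSV) for downstream evaluation.
    """
    out = os.fspath(out_dir)
    rcc_dir = os.path.join(out, "rcc")
    os.makedirs(rcc_dir, exist_ok=True)
    paths = {}
    for s in cohort.samples:
        p = os.path.join(rcc_dir, f"{s.sample_id}.rcc")
        iof.write_rcc(s, p)
    paths["rcc_dir"] = rcc_dir
    paths["sample_sheet"] = os.path.join(out, "samples.tsv")
    iof.write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"])
    paths["healthy"] = os.path.join(out, "healthy_fpkm.tsv")
    iof.write_expression_table(cohort.healthy, paths["healthy"])
    paths["gmt"] = os.path.join(out, "gene_sets.gmt")
    iof.write_gmt(cohort.gene_sets, paths["gmt"])
    paths["ihc"] = os.path.join(out, "ihc.tsv")
    iof.write_ihc_table(cohort.ihc, paths["ihc"])
    paths["clinical"] = os.path.join(out, "clinical.tsv")
    iof.write_clinical_table(cohort.clinical, paths["clinical"])
    paths["gene_truth"] = os.path.join(out, "gene_truth.tsv")
    cohort.gene_truth.reset_index().to_csv(paths["gene_truth"], sep="\t", index=False)
    paths["patient_truth"] = os.path.join(out, "patient_truth.tsv")
    cohort.patient_truth.reset_index().to_csv(paths["patient_truth"], sep="\t", index=False)
    return paths
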