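"""Immunohistochemistry scoring and its inference.

Tissue-microarray cores (up to five 1-mm cores per specimen) are scored
for staining intensity in two compartments (tumour cells and stroma).
Intensity is dichotomized — none/weak => negative, moderate/strong =>
positive — and a specimen's compartment status is the maximum over its
informative cores (any positive core makes the specimen positive).  The
overall status combines compartments: positive if either is positive,
noninformative only if both are.

Group comparisons of positivity use a two-sided Fisher exact test on
the 2x2 specimen-count table (an optional exact McNemar mode handles
matched pairs); survival differences use the Mantel-Haenszel log-rank
test, with a fixed-horizon variant that administratively censors at 36
months for 3-year overall survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .errors import ValidationError

__all__ = [
    "dichotomize",
    "aggregate_cores",
    "combine_compartments",
    "specimen_statuses",
    "fisher_exact_2x2",
    "compare_groups",
    "mcnemar_paired",
    "logrank",
    "three_year_os",
    "GroupComparison",
]

_NEGATIVE = {"none", "weak"}
_POSITIVE = {"moderate", "strong"}
COMPARTMENTS = ("tumoral", "stromal", "overall")


def dichotomize(intensity: str) -> str:
    """Map a staining intensity to negative/positive/noninformative."""
    if intensity in _NEGATIVE:
        return "negative"
    if intensity in _POSITIVE:
        return "positive"
    if intensity == "noninformative":
        return "noninformative"
    raise ValidationError(f"unknown staining intensity {intensity!r}")


def aggregate_cores(intensities) -> str:
    """Specimen status for one compartment: the maximum over informative cores.

    Positive iff any informative core is positive; negative iff at least
    one core is informative and none is positive; noninformative iff no
    core is informative.
    """
    statuses = [dichotomize(i) for i in intensities]
    informative = [s for s in statuses if s != "noninformative"]
    if not informative:
        return "noninformative"
    return "positive" if "positive" in informative else "negative"


def combine_compartments(tumoral: str, stromal: str) -> str:
    """Overall status: positive if either compartment positive,
    noninformative only if both are, else negative."""
    if "positive" in (tumoral, stromal):
        return "positive"
    if tumoral == "noninformative" and stromal == "noninformative":
        return "noninformative"
    return "negative"


def specimen_statuses(ihc: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a core-level IHC table to specimen-level statuses.

    Returns one row per (patient_id, tissue) with tumoral, stromal and
    overall status columns.
    """
    rows = []
    for (patient, tissue), group in ihc.groupby(["patient_id", "tissue"], sort=False):
        tumoral = aggregate_cores(group["tumoral_intensity"])
        stromal = aggregate_cores(group["stromal_intensity"])
        rows.append(
            {
                "patient_id": patient,
                "tissue": tissue,
                "tumoral": tumoral,
                "stromal": stromal,
                "overall": combine_compartments(tumoral, stromal),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact tests


def fisher_exact_2x2(table, tie_rtol: float = 1e-7) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Probability-ordering rule: the p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability
    does not exceed the observed one (within relative tolerance
    ``tie_rtol`` to absorb float ties).  A table with an empty margin
    has p = 1 by convention (warned).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValidationError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    observed = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= observed * (1 + tie_rtol)].sum()))


@dataclass
class GroupComparison:
    """A 2x2 positivity comparison between two specimen groups."""

    table: pd.DataFrame  # rows = groups, columns = [positive, negative]
    p_value: float
    n_informative: int
    n_excluded: int


def compare_groups(
    statuses: pd.DataFrame,
    compartment: str,
    group_a: str = "PT",
    group_b: str = "LNM",
) -> GroupComparison:
    """Fisher-exact comparison of positivity between two tissue groups.

    Noninformative specimens are excluded; each patient contributes at
    most one specimen per group (enforced upstream by specimen-level
    aggregation).
    """
    if compartment not in COMPARTMENTS:
        raise ValidationError(f"unknown compartment {compartment!r}")
    counts = {}
    informative = excluded = 0
    for grp in (group_a, group_b):
        sub = statuses[statuses["tissue"] == grp]
        pos = int((sub[compartment] == "positive").sum())
        neg = int((sub[compartment] == "negative").sum())
        excluded += int((sub[compartment] == "noninformative").sum())
        informative += pos + neg
        if pos + neg == 0:
            raise ValidationError(f"group {grp!r} empty after filtering")
        counts[grp] = [pos, neg]
    table = pd.DataFrame(counts, index=["positive", "negative"]).T
    p = fisher_exact_2x2(table.to_numpy())
    return GroupComparison(table=table, p_value=p, n_informative=informative, n_excluded=excluded)


def mcnemar_paired(
    statuses: pd.DataFrame,
    compartment: str,
    group_a: str = "PT",
    group_b: str = "LNM",
) -> tuple[pd.DataFrame, float]:
    """Exact McNemar test on matched pairs (both specimens informative).

    Returns the 2x2 paired table (group_a status x group_b status) and
    the exact binomial McNemar p-value.  Provided as the paired
    alternative to the default unpaired Fisher comparison.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    wide = statuses.pivot(index="patient_id", columns="tissue", values=compartment)
    if group_a not in wide.columns or group_b not in wide.columns:
        raise ValidationError("both groups must be present for a paired test")
    wide = wide[(wide[group_a] != "noninformative") & (wide[group_b] != "noninformative")]
    wide = wide.dropna()
    if wide.empty:
        raise ValidationError("no informative matched pairs")
    levels = ["positive", "negative"]
    table = pd.DataFrame(0, index=levels, columns=levels)
    for _, row in wide.iterrows():
        table.loc[row[group_a], row[group_b]] += 1
    res = mcnemar(table.to_numpy(), exact=True)
    return table, float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival


def logrank(times, events, groups) -> tuple[float, float]:
    """Mantel-Haenszel log-rank test between two groups.

    ``events`` are 1/True for deaths, 0/False for censoring; ``groups``
    is a binary label.  Returns (chi-square statistic with 1 df, p).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValidationError("times, events and groups must have equal length")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two non-empty groups, got {len(labels)}")
    if not events.any():
        raise ValidationError("no events observed")
    mask = groups == labels[0]
    res = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def three_year_os(
    clinical: pd.DataFrame,
    statuses: pd.DataFrame,
    compartment: str = "tumoral",
    tissue: str = "LNM",
    horizon_months: float = 36.0,
) -> tuple[float, float, int]:
    """Fixed-horizon (3-year) overall-survival log-rank by C3 status.

    Patients are grouped by their ``tissue`` specimen's ``compartment``
    status (positive vs negative; noninformative patients are dropped).
    Follow-up beyond ``horizon_months`` is administratively censored at
    the horizon, so later deaths do not count as events.

    Returns (chi-square statistic, p, number of patients analysed).
    """
    spec = statuses[statuses["tissue"] == tissue][["patient_id", compartment]]
    spec = spec[spec[compartment].isin(["positive", "negative"])]
    merged = clinical.merge(spec, on="patient_id", how="inner")
    if merged.empty:
        raise ValidationError("no patients with both clinical data and informative status")
    times = merged["os_months"].to_numpy(dtype=float)
    events = (merged["os_event"] == "death").to_numpy()
    over = times > horizon_months
    times = np.where(over, horizon_months, times)
    events = events & ~over
    if not events.any():
        return 0.0, 1.0, len(merged)
    chi2, p = logrank(times, events, merged[compartment].to_numpy())
    return chi2, p, len(merged)
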