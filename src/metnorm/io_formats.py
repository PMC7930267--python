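"""Readers and writers for the external formats the pipeline touches.

Formats
-------
RCC
    The nCounter raw reporter-count format: a sectioned text file with
    ``<Section>`` ... ``</Section>`` blocks.  Only the ``Code_Summary``
    probe table (columns ``CodeClass,Name,Accession,Count``) and a sample
    identifier (``ID`` key in ``Sample_Attributes`` or ``Header``) are
    required; unknown sections are preserved on read and ignored
    otherwise.  Real RCC exports carry no patient pairing information, so
    patient id and tissue live in a separate sample sheet.
Sample sheet
    TSV with columns ``sample_id``, ``patient_id``, ``tissue``
    (tissue in {PT, LNM}).
Healthy expression table
    TSV with columns ``gene``, ``BREAST``, ``LYMPH_NODE`` holding
    non-negative FPKM values, one row per gene.
GMT
    Standard gene-set format: one tab-separated line per set with
    ``set_name``, ``description``, then member gene symbols.
IHC table
    TSV with columns ``patient_id``, ``tissue``, ``core_index``,
    ``tumoral_intensity``, ``stromal_intensity``; one row per TMA core.
Clinical table
    TSV with columns ``patient_id``, ``nodal_status`` (N+/N-),
    ``os_months``, ``os_event`` (death/censored).

All tables are UTF-8, tab-separated, with ``.`` as decimal separator, so
write followed by read is the identity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

CODE_CLASSES = ("Endogenous", "Negative", "Positive", "Housekeeping")
TISSUES = ("PT", "LNM")
HEALTHY_TISSUES = ("BREAST", "LYMPH_NODE")
INTENSITY_LEVELS = ("none", "weak", "moderate", "strong", "noninformative")


@dataclass(frozen=True)
class ProbeRecord:
    """One probe row of an nCounter code summary."""

    name: str
    code_class: str
    accession: str
    count: int

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValidationError(
                f"probe {self.name!r}: unknown code class {self.code_class!r}"
            )
        if self.count < 0:
            raise ValidationError(f"probe {self.name!r}: negative count {self.count}")


@dataclass
class SampleCounts:
    """Raw probe counts for one nCounter lane.

    ``patient_id`` and ``tissue`` are filled in from the sample sheet,
    not from the RCC file itself.
    """

    sample_id: str
    probes: list[ProbeRecord]
    patient_id: str | None = None
    tissue: str | None = None
    sections: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        dup = _first_duplicate(names)
        if dup is not None:
            raise ValidationError(
                f"sample {self.sample_id!r}: duplicate probe name {dup!r}"
            )
        if self.tissue is not None and self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: tissue must be PT or LNM, got {self.tissue!r}"
            )

    def counts_by_class(self, code_class: str) -> dict[str, int]:
        return {p.name: p.count for p in self.probes if p.code_class == code_class}


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# RCC


def read_rcc(path: str | os.PathLike) -> SampleCounts:
    """Parse one RCC file into a :class:`SampleCounts`.

    Raises :class:`FormatError` if the ``Code_Summary`` section or the
    sample identifier is missing or a count is not an integer, and
    :class:`ValidationError` on duplicate probe names.
    """
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("</") and stripped.endswith(">"):
                current = None
            elif stripped.startswith("<") and stripped.endswith(">"):
                current = stripped[1:-1]
                sections.setdefault(current, [])
            elif current is not None:
                sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")

    sample_id = None
    for section in ("Sample_Attributes", "Header"):
        for line in sections.get(section, []):
            fields = line.split(",")
            if fields and fields[0] == "ID" and len(fields) > 1 and fields[1]:
                sample_id = fields[1]
                break
        if sample_id is not None:
            break
    if sample_id is None:
        raise FormatError(f"{path}: no ID entry in Sample_Attributes or Header")

    rows = sections["Code_Summary"]
    if not rows:
        raise FormatError(f"{path}: empty Code_Summary section")
    header = rows[0].split(",")
    required = ["CodeClass", "Name", "Accession", "Count"]
    if [h.strip() for h in header[: len(required)]] != required:
        raise FormatError(
            f"{path}: Code_Summary header must start with {','.join(required)}, "
            f"got {rows[0]!r}"
        )
    probes: list[ProbeRecord] = []
    for i, line in enumerate(rows[1:], start=2):
        fields = line.split(",")
        if len(fields) < 4:
            raise FormatError(f"{path}: Code_Summary row {i}: expected 4 fields, got {line!r}")
        code_class, name, accession, count_str = (f.strip() for f in fields[:4])
        try:
            count = int(count_str)
        except ValueError:
            raise FormatError(
                f"{path}: Code_Summary row {i} (probe {name!r}): "
                f"count {count_str!r} is not an integer"
            ) from None
        try:
            probes.append(ProbeRecord(name, code_class, accession, count))
        except ValidationError as exc:
            raise ValidationError(f"{path}: Code_Summary row {i}: {exc}") from None
    try:
        return SampleCounts(sample_id=sample_id, probes=probes, sections=sections)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_rcc(sample: SampleCounts, path: str | os.PathLike) -> None:
    """Write a :class:`SampleCounts` as a minimal RCC file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("<Header>\n")
        fh.write("FileVersion,1.7\nSoftwareVersion,metnorm\n")
        fh.write("</Header>\n")
        fh.write("<Sample_Attributes>\n")
        fh.write(f"ID,{sample.sample_id}\n")
        fh.write("</Sample_Attributes>\n")
        fh.write("<Code_Summary>\n")
        fh.write("CodeClass,Name,Accession,Count\n")
        for p in sample.probes:
            fh.write(f"{p.code_class},{p.name},{p.accession},{p.count}\n")
        fh.write("</Code_Summary>\n")


# ---------------------------------------------------------------------------
# Sample sheet


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample sheet mapping sample_id -> (patient_id, tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ValidationError(f"{path}: unknown tissue values {sorted(bad)}")
    return df.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def annotate_samples(
    samples: list[SampleCounts], sheet: pd.DataFrame
) -> list[SampleCounts]:
    """Attach patient_id/tissue from the sample sheet; every sample must appear."""
    lookup = sheet.set_index("sample_id")
    out = []
    for s in samples:
        if s.sample_id not in lookup.index:
            raise ValidationError(f"sample {s.sample_id!r} not in sample sheet")
        row = lookup.loc[s.sample_id]
        out.append(
            SampleCounts(
                sample_id=s.sample_id,
                probes=s.probes,
                patient_id=str(row["patient_id"]),
                tissue=str(row["tissue"]),
                sections=s.sections,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Healthy expression table


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the two-tissue FPKM table; returns a gene-indexed DataFrame.

    Columns are ``BREAST`` and ``LYMPH_NODE``; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene", *HEALTHY_TISSUES]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: expression table missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    values = df[list(HEALTHY_TISSUES)]
    if values.isna().any().any():
        raise ValidationError(f"{path}: missing FPKM values")
    if (values < 0).any().any():
        gene = df.loc[(values < 0).any(axis=1), "gene"].iloc[0]
        raise ValidationError(f"{path}: negative FPKM for gene {gene!r}")
    out = df.set_index("gene")[list(HEALTHY_TISSUES)].astype(float)
    return out


def write_expression_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


def read_gmt(path: str | os.PathLike) -> dict[str, GeneSet]:
    """Parse a GMT file into an ordered mapping set_name -> GeneSet.

    Duplicate members within a line are collapsed; a line with fewer than
    three fields is a :class:`FormatError` naming the line.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated fields"
                )
            name, description = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValidationError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, members)
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets.values():
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# IHC and clinical tables


def read_ihc_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the core-level IHC intensity table."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {
        "patient_id",
        "tissue",
        "core_index",
        "tumoral_intensity",
        "stromal_intensity",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: IHC table missing columns {sorted(missing)}")
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ValidationError(f"{path}: unknown tissue values {sorted(bad)}")
    for col in ("tumoral_intensity", "stromal_intensity"):
        bad = set(df[col]) - set(INTENSITY_LEVELS)
        if bad:
            raise ValidationError(f"{path}: unknown {col} levels {sorted(bad)}")
    n_cores = df.groupby(["patient_id", "tissue"])["core_index"].count()
    if (n_cores > 5).any():
        who = n_cores[n_cores > 5].index[0]
        raise ValidationError(f"{path}: specimen {who} has more than 5 cores")
    dup = df.duplicated(["patient_id", "tissue", "core_index"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate core {row['core_index']} for "
            f"{row['patient_id']}/{row['tissue']}"
        )
    return df.reset_index(drop=True)


def write_ihc_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the clinical/survival table."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "nodal_status", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate patient {dup!r}")
    bad = set(df["nodal_status"]) - {"N+", "N-"}
    if bad:
        raise ValidationError(f"{path}: unknown nodal status {sorted(bad)}")
    bad = set(df["os_event"]) - {"death", "censored"}
    if bad:
        raise ValidationError(f"{path}: unknown os_event values {sorted(bad)}")
    if (df["os_months"].astype(float) < 0).any():
        raise ValidationError(f"{path}: negative os_months")
    df["os_months"] = df["os_months"].astype(float)
    return df.reset_index(drop=True)


def write_clinical_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
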