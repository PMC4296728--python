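"""Sample-exclusion filters and case-definition subsetting.

The study design excludes, in order: children under 4, samples missing sex
or race, non-fecal specimens, antibiotic use within the past month, diabetes,
inflammatory bowel disease, and finally duplicate samples from the same
participant.  Filters are applied sequentially and each removed sample is
attributed to the first rule it violates, so the per-filter counts in the
attrition report sum to the total number removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .table import TaxonTable

__all__ = [
    "DEFAULT_COLUMNS",
    "MISSING_CODES",
    "AttritionReport",
    "read_metadata",
    "apply_exclusions",
    "case_subset",
    "CASE_FIELDS",
]

#: canonical field -> default metadata column name (American Gut style)
DEFAULT_COLUMNS = {
    "age": "AGE",
    "sex": "SEX",
    "race": "RACE",
    "bmi": "BMI",
    "body_site": "BODY_SITE",
    "antibiotic": "ANTIBIOTIC_SELECT",
    "diabetes": "DIABETES",
    "ibd": "IBD",
    "cesarean": "CSECTION",
    "appendectomy": "APPENDIX_REMOVED",
    "participant": "HOST_SUBJECT_ID",
    "region": "REGION",
    "diet": "DIET_TYPE",
    "alcohol": "ALCOHOL_FREQUENCY",
    "smoking": "SMOKING_FREQUENCY",
    "weight_change": "WEIGHT_CHANGE",
    "gluten": "GLUTEN",
    "lactose": "LACTOSE",
    "asthma": "ASTHMA",
}

#: strings treated as missing/uncertain in categorical columns
MISSING_CODES = {"", "NA", "na", "nan", "no_data", "None", "none", "unknown", "Unknown", "I don't know"}

FECAL_VALUES = {"feces", "UBERON:feces", "UBERON_feces", "stool"}
ANTIBIOTIC_PAST_MONTH = {"In the past month", "in the past month", "Week", "Month"}
YES_VALUES = {"yes", "Yes", "true", "True", "1"}
NO_VALUES = {"no", "No", "false", "False", "0"}

CASE_FIELDS = ("cesarean", "appendectomy")


@dataclass
class AttritionReport:
    """Ordered (filter name, n removed, n remaining) triples."""

    steps: list[tuple[str, int, int]]

    @property
    def total_removed(self) -> int:
        return sum(n for _, n, _ in self.steps)

    @property
    def n_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_removed", "n_remaining"])


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV whose first column is the sample ID."""
    md = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    md = md.set_index(md.columns[0])
    if md.index.has_duplicates:
        dup = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dup}")
    return md


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).str.strip().isin(MISSING_CODES)


def _numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def apply_exclusions(
    metadata: pd.DataFrame,
    table: TaxonTable,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, TaxonTable, AttritionReport]:
    """Apply the study exclusion filters and report per-filter attrition.

    Returns the filtered metadata, the table restricted to the surviving
    samples (same order as the metadata), and an :class:`AttritionReport`.
    ``columns`` overrides entries of :data:`DEFAULT_COLUMNS` to bind the
    dataset's column names to the canonical fields.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    orphans = [s for s in table.sample_ids if s not in metadata.index]
    if orphans:
        raise ValueError(f"table samples missing from metadata: {orphans[:10]}")

    md = metadata.loc[table.sample_ids].copy()

    def col(field: str) -> pd.Series:
        name = cols[field]
        if name not in md.columns:
            raise ValueError(f"metadata lacks column {name!r} (field {field!r})")
        return md[name]

    filters = [
        ("age < 4 years", _numeric(col("age")) < 4),
        ("sex missing", _is_missing(col("sex"))),
        ("race missing", _is_missing(col("race"))),
        ("specimen not feces", ~col("body_site").isin(FECAL_VALUES)),
        ("antibiotic in past month", col("antibiotic").isin(ANTIBIOTIC_PAST_MONTH)),
        ("diabetes", col("diabetes").isin(YES_VALUES)),
        ("inflammatory bowel disease", col("ibd").isin(YES_VALUES)),
    ]

    steps: list[tuple[str, int, int]] = []
    keep = pd.Series(True, index=md.index)
    for name, violates in filters:
        removed = keep & violates.fillna(False)
        keep &= ~removed
        steps.append((name, int(removed.sum()), int(keep.sum())))

    # duplicates per participant among survivors: keep first by sample-ID sort
    survivors = md.index[keep]
    participants = col("participant").loc[survivors]
    first_ids = participants.groupby(participants).apply(
        lambda s: sorted(s.index)[0]
    )
    dup_mask = pd.Series(False, index=md.index)
    dup_mask.loc[survivors] = ~participants.index.isin(set(first_ids))
    keep &= ~dup_mask
    steps.append(("duplicate participant", int(dup_mask.sum()), int(keep.sum())))

    kept_ids = [s for s in md.index if keep[s]]
    return md.loc[kept_ids], table.subset_samples(kept_ids), AttritionReport(steps)


def case_subset(
    metadata: pd.DataFrame,
    case_field: str,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict to samples with a definite yes/no case status.

    ``case_field`` is ``cesarean`` or ``appendectomy``.  Returns the
    restricted metadata and a boolean case indicator aligned with it;
    samples with missing or uncertain status are dropped.
    """
    if case_field not in CASE_FIELDS:
        raise ValueError(f"case_field must be one of {CASE_FIELDS}, got {case_field!r}")
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    name = cols[case_field]
    if name not in metadata.columns:
        raise ValueError(f"metadata lacks case column {name!r}")
    status = metadata[name].astype(str).str.strip()
    definite = status.isin(YES_VALUES | NO_VALUES)
    md = metadata.loc[definite].copy()
    case = status.loc[definite].isin(YES_VALUES).rename("case")
    return md, case
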