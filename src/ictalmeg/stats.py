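"""Responder classification, contingency tables, exact tests and clinical summaries.

The responder rule encodes the clinical definition used in drug-response
absence-epilepsy cohorts: a patient is a *nonresponder* if seizures persist
on an adequate first drug, or if seizure freedom required adding a second
antiepileptic drug (AED); substituting the first AED purely for adverse
effects does not count against response.  Group contrasts of categorical
localization outcomes use a two-sided Fisher exact test (implemented by
hypergeometric enumeration), Bonferroni-corrected across the six frequency
bands (alpha 0.05 / 6 ≈ 0.0083); continuous clinical covariates use the
equal-variance two-sample t-test and are reported as mean ± SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "PatientRecord",
    "ContingencyTable",
    "classify_response",
    "load_table1",
    "patients_from_table",
    "load_table2",
    "contingency_from_table2",
    "build_contingency",
    "fisher_exact",
    "bonferroni_gate",
    "clinical_summary",
    "BONFERRONI_N_BANDS",
]

BONFERRONI_N_BANDS = 6

#: Group sizes of the reference cohort (nonresponders, responders).
TABLE2_GROUP_SIZES = {"N": 11, "R": 13}


@dataclass
class PatientRecord:
    """One clinical row; ``group`` is derived, never hand-set in pipelines."""

    id: str
    gender: str
    age_years: float
    onset_age_years: float
    seizure_duration_s: float
    follow_up_months: float
    initial_aed: str
    aeds_added: str | None
    seizure_free: bool
    aed_substituted: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        if self.onset_age_years > self.age_years:
            raise ValidationError(
                f"patient {self.id}: onset age exceeds current age"
            )


def classify_response(record: PatientRecord) -> str:
    """Derive the responder / nonresponder label from treatment outcome.

    Nonresponder iff seizures persisted, or seizure freedom required an
    added (second) AED.  A substitution of the initial AED for adverse
    effects (``aed_substituted``) with eventual seizure freedom still counts
    as a responder.
    """
    if record.seizure_free is None or record.initial_aed is None:
        raise ValidationError(f"patient {record.id}: outcome fields missing")
    added = record.aeds_added
    has_added = added is not None and str(added).strip().upper() not in ("", "N", "NONE")
    if not record.seizure_free:
        return "nonresponder"
    if has_added and not record.aed_substituted:
        return "nonresponder"
    return "responder"


def _fixture(name: str) -> str:
    return resources.files("ictalmeg.data").joinpath(name).read_text()


def load_table1() -> pd.DataFrame:
    """The bundled 24-patient clinical reference table (with outcome labels)."""
    from io import StringIO

    return pd.read_csv(StringIO(_fixture("table1_patients.tsv")), sep="\t")


def patients_from_table(df: pd.DataFrame) -> list[PatientRecord]:
    """Clinical rows -> records with ``group`` derived by the responder rule."""
    records = []
    for _, row in df.iterrows():
        rec = PatientRecord(
            id=str(row["patient"]),
            gender=str(row["gender"]),
            age_years=float(row["age_years"]),
            onset_age_years=float(row["onset_age_years"]),
            seizure_duration_s=float(row["seizure_duration_s"]),
            follow_up_months=float(row["follow_up_months"]),
            initial_aed=str(row["initial_aed"]),
            aeds_added=None if str(row["aeds_added"]).strip().upper() in ("N", "NONE", "NAN")
            else str(row["aeds_added"]),
            seizure_free=str(row["seizure_free"]).strip().upper() in ("Y", "YES", "TRUE", "1"),
        )
        rec.group = classify_response(rec)
        records.append(rec)
    return records


def load_table2() -> pd.DataFrame:
    """Per-region localization counts by band and group (N / R columns)."""
    from io import StringIO

    return pd.read_csv(StringIO(_fixture("table2_localization.tsv")), sep="\t")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = (nonresponders, responders), cols = (in region, elsewhere)."""

    a: int  # nonresponders localized in the region
    b: int  # nonresponders elsewhere
    c: int  # responders localized in the region
    d: int  # responders elsewhere
    band: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def contingency_from_table2(band: str, region: str) -> ContingencyTable:
    """Contingency table for one (band, region) cell of the count fixture.

    One-label-per-patient reading: "elsewhere" is the group size minus the
    in-region count (the fixture's column sums can exceed group sizes in
    some bands because nested labels are printed separately).
    """
    df = load_table2().set_index("region")
    if region not in df.index:
        raise ConfigurationError(f"unknown region {region!r}")
    a = int(df.loc[region, f"{band}_N"])
    c = int(df.loc[region, f"{band}_R"])
    return ContingencyTable(
        a, TABLE2_GROUP_SIZES["N"] - a, c, TABLE2_GROUP_SIZES["R"] - c,
        band=band, region=region,
    )


def build_contingency(
    assignments: list[tuple[PatientRecord, str | set]],
    band: str,
    region: str,
) -> ContingencyTable:
    """Count predominant-region outcomes per group.

    ``assignments`` pairs each classified patient with the predominant
    region label for the band (or a set of labels in multi-label mode).
    """
    a = b = c = d = 0
    for rec, label in assignments:
        if rec.group is None:
            raise ValidationError(f"patient {rec.id} has no derived group")
        hit = region in label if isinstance(label, (set, frozenset, list, tuple)) else label == region
        if rec.group == "nonresponder":
            a, b = (a + 1, b) if hit else (a, b + 1)
        else:
            c, d = (c + 1, d) if hit else (c, d + 1)
    if a + b == 0 or c + d == 0:
        raise ValidationError("both groups must be present")
    return ContingencyTable(a, b, c, d, band=band, region=region)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    With margins fixed, the two-sided p-value is the total probability of
    all admissible tables whose point probability does not exceed that of
    the observed table (with a 1 + 1e-7 relative slack for floating-point
    ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    if n_total == 0:
        raise ValidationError("all-zero table: Fisher test undefined")
    row1, col1 = a + b, a + c
    if row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0  # degenerate margin: only one admissible table
    kmin = max(0, row1 + col1 - n_total)
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(ks, n_total, col1, row1)
    p_obs = pmf[a - kmin]
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-7)]))
    return min(p, 1.0)


def bonferroni_gate(
    p_values: dict,
    n_tests: int = BONFERRONI_N_BANDS,
    alpha: float = 0.05,
) -> tuple[dict, float]:
    """Flag p-values significant at the Bonferroni-corrected threshold."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    threshold = alpha / n_tests
    flags = {k: bool(p < threshold) for k, p in p_values.items()}
    return flags, threshold


#: Clinical covariates summarized by default: (record attribute, printed name).
CLINICAL_COVARIATES = (
    ("age_years", "age (years)"),
    ("onset_age_years", "onset age (years)"),
    ("seizure_duration_s", "seizure duration (s)"),
    ("follow_up_months", "follow-up (months)"),
)


def clinical_summary(records: list[PatientRecord]) -> pd.DataFrame:
    """Mean ± SD per covariate, overall and per group, with two-tailed t-tests.

    SD is the sample (n-1) standard deviation; the t-test is the
    equal-variance Student two-sample test.  Groups with fewer than two
    patients skip the test with a warning.
    """
    rows = []
    groups = {g: [r for r in records if r.group == g]
              for g in ("responder", "nonresponder")}
    for attr, name in CLINICAL_COVARIATES:
        all_v = np.array([getattr(r, attr) for r in records], dtype=float)
        row = {
            "covariate": name,
            "mean": float(np.mean(all_v)),
            "sd": float(np.std(all_v, ddof=1)),
        }
        for g, recs in groups.items():
            v = np.array([getattr(r, attr) for r in recs], dtype=float)
            row[f"mean_{g}"] = float(np.mean(v)) if v.size else np.nan
            row[f"sd_{g}"] = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
        vr = np.array([getattr(r, attr) for r in groups["responder"]], dtype=float)
        vn = np.array([getattr(r, attr) for r in groups["nonresponder"]], dtype=float)
        if vr.size >= 2 and vn.size >= 2:
            if np.array_equal(np.sort(vr), np.sort(vn)) and np.all(vr == vr[0]):
                t, p = 0.0, 1.0  # degenerate: identical constant groups
            else:
                t, p = sps.ttest_ind(vn, vr, equal_var=True)
            row["t"], row["p"] = float(t), float(p)
        else:
            warnings.warn(f"{name}: a group has n < 2; t-test skipped")
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)
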