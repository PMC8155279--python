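"""Level-I cognitive subtyping of Parkinson's disease patients.

Neuropsychological raw scores are converted to z-scores against normative
means and SDs (sign-flipped for time/error scores so that negative z is
always worse).  A test is failed at or below the 5th centile of the norm,
z <= -1.645.  A cognitive domain is impaired when at least two of its
tests are failed, or when its single available test is failed.  Verbal
episodic memory is the exception: the HVLT-R delayed-recall /
recognition-discrimination pattern separates an encoding/storage deficit
(both failed: the material was never stored) from a retrieval deficit
(recall failed, recognition preserved), and only the encoding/storage
pattern counts as memory impairment.

Patients are then placed in one of four mutually exclusive subtypes under
the dual-syndrome scheme:

=========  ==============================  ==============================
label      frontal axis (attention/WM,     posterior axis (visuospatial,
           executive)                      memory, language)
=========  ==============================  ==============================
PD-NC      intact                          intact
PD-FS      impaired                        intact
PD-PC      intact                          impaired
PD-MS      impaired                        impaired
=========  ==============================  ==============================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "DOMAINS",
    "FRONTAL_DOMAINS",
    "POSTERIOR_DOMAINS",
    "SUBTYPES",
    "SUBTYPE_CODES",
    "Z_CUTOFF",
    "HVLT_PARAMETERS",
    "NormativeTest",
    "DomainStatus",
    "z_transform",
    "test_failed",
    "domain_impaired",
    "memory_deficit_type",
    "classify_subtype",
    "domain_z_summary",
    "classify_table",
]

DOMAINS = ("attention_wm", "executive", "memory", "visuospatial", "language")
FRONTAL_DOMAINS = frozenset({"attention_wm", "executive"})
POSTERIOR_DOMAINS = frozenset({"memory", "visuospatial", "language"})
SUBTYPES = ("PD-NC", "PD-FS", "PD-PC", "PD-MS")
#: Ordinal severity coding used for feature selection and correlations.
SUBTYPE_CODES = {"PD-NC": 0, "PD-FS": 1, "PD-PC": 2, "PD-MS": 3}

#: Impairment boundary: the standard-normal 5th-centile quantile.  The
#: boundary itself counts as failed ("at 1.645 SD below the mean").
Z_CUTOFF = -1.645

#: HVLT-R parameters; delayed recall and recognition discrimination drive
#: the encoding/storage vs retrieval distinction.
HVLT_PARAMETERS = (
    "hvlt_total_recall",
    "hvlt_delayed_recall",
    "hvlt_retention",
    "hvlt_recognition",
)


@dataclass(frozen=True)
class NormativeTest:
    test_id: str
    domain: str
    norm_mean: float
    norm_sd: float
    higher_is_better: bool = True

    def __post_init__(self):
        if self.norm_sd <= 0:
            raise ValidationError(f"{self.test_id}: norm_sd must be > 0")
        if self.domain not in DOMAINS:
            raise ValidationError(f"{self.test_id}: unknown domain {self.domain}")


@dataclass(frozen=True)
class DomainStatus:
    """Per-domain impairment flags plus the memory deficit character."""

    attention_wm: bool
    executive: bool
    memory: bool
    visuospatial: bool
    language: bool
    memory_deficit_type: str = "none"

    def __post_init__(self):
        if self.memory != (self.memory_deficit_type == "encoding_storage"):
            raise ValidationError(
                "memory impaired iff deficit type is encoding_storage"
            )


def z_transform(raw: float, test: NormativeTest) -> float:
    """Normative z-score; negative always means worse performance."""
    if not math.isfinite(raw):
        raise ValidationError(f"{test.test_id}: non-finite raw score")
    z = (raw - test.norm_mean) / test.norm_sd
    return z if test.higher_is_better else -z


def test_failed(z: float, cutoff: float = Z_CUTOFF) -> bool:
    """Failure at or below the 5th-centile boundary (z <= -1.645)."""
    if not math.isfinite(z):
        raise ValidationError("non-finite z-score")
    return z <= cutoff


def domain_impaired(test_flags) -> bool:
    """>= 2 failed tests, or the single test failed in a one-test domain."""
    flags = list(test_flags)
    if not flags:
        raise ValidationError("domain has no tests")
    if len(flags) == 1:
        return bool(flags[0])
    return sum(bool(f) for f in flags) >= 2


def memory_deficit_type(z_delayed: float, z_recognition: float,
                        cutoff: float = Z_CUTOFF) -> str:
    """Classify the HVLT-R memory pattern.

    encoding_storage: delayed recall and recognition discrimination both
    failed; retrieval: delayed recall failed but recognition preserved;
    none otherwise.
    """
    for z in (z_delayed, z_recognition):
        if z is None or not math.isfinite(z):
            raise ValidationError("missing HVLT parameter")
    recall_failed = test_failed(z_delayed, cutoff)
    recog_failed = test_failed(z_recognition, cutoff)
    if recall_failed and recog_failed:
        return "encoding_storage"
    if recall_failed:
        return "retrieval"
    return "none"


def classify_subtype(status: DomainStatus) -> str:
    """Map a DomainStatus to one of the four subtype labels."""
    frontal = status.attention_wm or status.executive
    posterior = status.visuospatial or status.memory or status.language
    if frontal and posterior:
        return "PD-MS"
    if frontal:
        return "PD-FS"
    if posterior:
        return "PD-PC"
    return "PD-NC"


def _norm_lookup(norms: pd.DataFrame) -> dict[str, NormativeTest]:
    out = {}
    for row in norms.itertuples(index=False):
        out[row.test_id] = NormativeTest(
            test_id=row.test_id, domain=row.domain,
            norm_mean=float(row.norm_mean), norm_sd=float(row.norm_sd),
            higher_is_better=bool(row.higher_is_better),
        )
    return out


def _z_table(scores: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Per-subject z-scores for every test found in the norms table."""
    tests = _norm_lookup(norms)
    missing = [t for t in tests if t not in scores.columns]
    if missing:
        raise ValidationError(f"score table missing tests: {missing}")
    z = pd.DataFrame({"subject_id": scores["subject_id"]})
    for test_id, t in tests.items():
        raw = scores[test_id].to_numpy(dtype=float)
        sign = 1.0 if t.higher_is_better else -1.0
        z[test_id] = sign * (raw - t.norm_mean) / t.norm_sd
    return z


def domain_z_summary(scores: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Mean z-score per cognitive domain for each subject.

    This is the cognition side of the brain–cognition partial correlations.
    """
    tests = _norm_lookup(norms)
    z = _z_table(scores, norms)
    out = pd.DataFrame({"subject_id": scores["subject_id"]})
    for domain in DOMAINS:
        cols = [tid for tid, t in tests.items() if t.domain == domain]
        if not cols:
            raise ValidationError(f"no tests for domain {domain}")
        out[domain] = z[cols].mean(axis=1)
    return out


def classify_table(scores: pd.DataFrame, norms: pd.DataFrame,
                   cutoff: float = Z_CUTOFF) -> pd.DataFrame:
    """Classify every subject in a score table.

    Returns a DataFrame with per-domain impairment flags, the memory
    deficit type, and the subtype label.  Subjects with any missing test
    score are excluded with a warning rather than imputed.
    """
    tests = _norm_lookup(norms)
    for p in ("hvlt_delayed_recall", "hvlt_recognition"):
        if p not in tests:
            raise ValidationError(f"norms must include HVLT parameter {p}")
    complete = scores[list(tests)].notna().all(axis=1)
    if not complete.all():
        dropped = scores.loc[~complete, "subject_id"].tolist()
        warnings.warn(f"excluding subjects with missing scores: {dropped}")
    scores = scores.loc[complete].reset_index(drop=True)
    z = _z_table(scores, norms)

    records = []
    for i in range(len(scores)):
        flags = {}
        for domain in DOMAINS:
            if domain == "memory":
                continue
            cols = [tid for tid, t in tests.items() if t.domain == domain]
            if not cols:
                raise ValidationError(f"no tests for domain {domain}")
            flags[domain] = domain_impaired(
                [test_failed(float(z.at[i, c]), cutoff) for c in cols]
            )
        mem_type = memory_deficit_type(
            float(z.at[i, "hvlt_delayed_recall"]),
            float(z.at[i, "hvlt_recognition"]), cutoff,
        )
        flags["memory"] = mem_type == "encoding_storage"
        status = DomainStatus(memory_deficit_type=mem_type, **flags)
        records.append({
            "subject_id": scores.at[i, "subject_id"],
            **{d: flags[d] for d in DOMAINS},
            "memory_deficit_type": mem_type,
            "subtype": classify_subtype(status),
        })
    return pd.DataFrame.from_records(records)
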