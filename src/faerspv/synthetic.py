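"""Synthetic FAERS-schema databases with controlled disproportionality.

The generator emits the six quarterly tables in the exact "$"-delimited
dialect the reader consumes, with the structural features that matter to the
pipeline: follow-up duplicates under a shared CASEID, partial and missing
dates, FAERS outcome codes, demographic fields, and drug–event co-occurrence
with injectable reporting-rate ratios.

Generative model: reports are i.i.d.  A report involves the target drug as
primary suspect with probability ``drug_share``; each vocabulary PT then
enters the report's reaction set independently with its baseline probability
(background arm) or the baseline scaled by the injected rate ratio (target
arm).  Because each PT appears at most once per report, the expected
contingency cells are exact closed forms, and the expected-cell ROR of a
single injected PT equals its rate ratio exactly.

Default sizes, missingness and outcome/time-to-onset profiles emulate a
large oncology-drug cohort in a spontaneous-report database: ~0.5% of
reports on the target drug, ~70% of reports without a computable
time-to-onset, ~75% serious, and an early-onset-plus-ultra-delayed TTO
mixture.  The synthetic vocabulary covers ~27 PTs mapped by the bundled
synthetic SOC fixture.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from faerspv.faers_io import DELIMITER, WRITE_COLUMNS

STUDY_START = datetime.date(2009, 1, 1)
STUDY_END = datetime.date(2024, 9, 30)

#: uniform day ranges for the four TTO bins (the last is open-ended in
#: principle; 361–1080 keeps dates inside the study window)
TTO_BIN_RANGES = ((0, 90), (91, 180), (181, 360), (361, 1080))


class VocabTerm(BaseModel):
    pt: str
    p: float = Field(gt=0.0, le=1.0)  # baseline per-report occurrence probability
    soc: str = ""


class Injection(BaseModel):
    pt: str
    rr: float = Field(gt=0.0)  # reporting-rate ratio applied in the target arm


DEFAULT_VOCABULARY: Tuple[VocabTerm, ...] = tuple(
    VocabTerm(pt=pt, p=p)
    for pt, p in [
        ("Osteonecrosis of jaw", 0.010),
        ("Death", 0.080),
        ("Hypocalcemia", 0.015),
        ("Fatigue", 0.120),
        ("Nausea", 0.110),
        ("Pain", 0.100),
        ("Headache", 0.090),
        ("Dizziness", 0.070),
        ("Rash", 0.060),
        ("Vomiting", 0.060),
        ("Diarrhea", 0.080),
        ("Arthralgia", 0.050),
        ("Back pain", 0.040),
        ("Pain in extremity", 0.030),
        ("Dyspnea", 0.050),
        ("Pyrexia", 0.050),
        ("Anemia", 0.040),
        ("Neutropenia", 0.030),
        ("Pneumonia", 0.040),
        ("Fall", 0.030),
        ("Malaise", 0.040),
        ("Asthenia", 0.050),
        ("Insomnia", 0.030),
        ("Hypertension", 0.040),
        ("Decreased appetite", 0.030),
        ("Bone pain", 0.020),
        ("Tooth extraction", 0.005),
    ]
)

DEFAULT_INJECTIONS: Tuple[Injection, ...] = (Injection(pt="Osteonecrosis of jaw", rr=10.0),)

DEFAULT_OUTCOME_PROFILE = {
    "DE": 0.12,
    "LT": 0.02,
    "HO": 0.25,
    "DS": 0.04,
    "CA": 0.003,
    "RI": 0.001,
    "OT": 0.60,
}

TARGET_DRUGNAMES = ("XGEVA", "DENOSUMAB (XGEVA)", "Xgeva")
BACKGROUND_DRUGNAMES = ("COMPARATORIX", "OSTEOFIX", "TUMORSTAT", "GENERICOL", "PLACEBIN")
TARGET_INDICATIONS = ("Bone metastases", "Giant cell tumour of bone", "Multiple myeloma")
BACKGROUND_INDICATIONS = ("Osteoporosis", "Rheumatoid arthritis", "Hypertension", "Diabetes mellitus")
COUNTRIES = ("US", "JP", "", "DE", "FR", "CA", "NL", "GB", "IT", "AU")
COUNTRY_PROBS = (0.3133, 0.1749, 0.0764, 0.0644, 0.0487, 0.0457, 0.0348, 0.09, 0.08, 0.0718)


class SimConfig(BaseModel):
    """Full parameterization of one synthetic spontaneous-report database."""

    n_reports: int = Field(default=200_000, ge=0)
    drug_share: float = Field(default=0.005, ge=0.0, le=1.0)
    vocabulary: Tuple[VocabTerm, ...] = DEFAULT_VOCABULARY
    injections: Tuple[Injection, ...] = DEFAULT_INJECTIONS
    dup_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    missing_date_rate: float = Field(default=0.70, ge=0.0, le=1.0)
    outcome_profile: Dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROFILE))
    tto_bin_weights: Tuple[float, float, float, float] = (0.37, 0.10, 0.15, 0.38)
    sex_probs: Tuple[float, float, float] = (0.42, 0.48, 0.10)  # M, F, unknown
    age_missing_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("outcome_profile")
    @classmethod
    def _probabilities(cls, v: Dict[str, float]) -> Dict[str, float]:
        for code, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcome probability for {code} out of [0,1]: {p}")
        return v

    @model_validator(mode="after")
    def _feasible(self) -> "SimConfig":
        vocab = {t.pt for t in self.vocabulary}
        if len(vocab) != len(self.vocabulary):
            raise ValueError("duplicate PT in vocabulary")
        base = {t.pt: t.p for t in self.vocabulary}
        for inj in self.injections:
            if inj.pt not in base:
                raise ValueError(f"injection PT {inj.pt!r} not in vocabulary")
            if inj.rr * base[inj.pt] > 1.0:
                raise ValueError(
                    f"injection {inj.pt!r}: rr*p = {inj.rr * base[inj.pt]:.3f} > 1 "
                    "is not a probability"
                )
        if abs(sum(self.tto_bin_weights) - 1.0) > 1e-9:
            raise ValueError("tto_bin_weights must sum to 1")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ValueError("sex_probs must sum to 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def target_probs(self) -> np.ndarray:
        """Per-PT inclusion probabilities in the target arm (rr-scaled)."""
        rr = {inj.pt: inj.rr for inj in self.injections}
        return np.array([t.p * rr.get(t.pt, 1.0) for t in self.vocabulary])

    def background_probs(self) -> np.ndarray:
        return np.array([t.p for t in self.vocabulary])


def expected_tables(config: SimConfig) -> pd.DataFrame:
    """Analytic expectations of per-PT contingency cells under the model.

    Returns a frame indexed by PT with columns a, b, c, d (expected counts
    post-dedup, i.e. per distinct case) and expected_ror = (a·d)/(b·c) of the
    expected cells.  With a single injected PT the expected-cell ROR equals
    the injected rate ratio exactly.
    """
    n, s = float(config.n_reports), config.drug_share
    q = config.target_probs()
    p = config.background_probs()
    a = n * s * q
    c = n * (1.0 - s) * p
    cohort_units = n * s * q.sum()
    background_units = n * (1.0 - s) * p.sum()
    b = cohort_units - a
    d = background_units - c
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
    return pd.DataFrame(
        {"a": a, "b": b, "c": c, "d": d, "expected_ror": ror},
        index=[t.pt for t in config.vocabulary],
    )


def _dates_yyyymmdd(base: datetime.date, offsets: np.ndarray) -> np.ndarray:
    idx = pd.Timestamp(base) + pd.to_timedelta(offsets, unit="D")
    return pd.DatetimeIndex(idx).strftime("%Y%m%d").to_numpy()


def simulate(
    config: SimConfig, outdir: str | Path, suffix: str = "SIM"
) -> Dict[str, Path]:
    """Generate one database and write DEMO/DRUG/REAC/OUTC/THER/INDI files.

    Fully deterministic in ``config.seed`` (byte-for-byte identical output).
    Follow-up duplicates re-emit a case — demographic row and all child rows —
    under a larger PRIMARYID with a later FDA_DT, so deduplication must
    collapse them.  Event/start dates are consistent with the drawn TTO bin
    unless the report is flagged date-missing (blank or month-precision
    event date, or blank therapy start).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    J = len(config.vocabulary)
    pts = [t.pt for t in config.vocabulary]

    caseid = np.arange(1, n + 1)
    primaryid = caseid * 100 + 1
    is_target = rng.random(n) < config.drug_share

    probs = np.where(
        is_target[:, None], config.target_probs()[None, :], config.background_probs()[None, :]
    )
    include = rng.random((n, J)) < probs

    window_days = (STUDY_END - STUDY_START).days
    fda_off = rng.integers(0, window_days + 1, size=n)
    start_off = rng.integers(0, window_days - 1200 + 1, size=n)
    bin_idx = rng.choice(4, size=n, p=np.asarray(config.tto_bin_weights))
    lows = np.array([r[0] for r in TTO_BIN_RANGES])
    highs = np.array([r[1] for r in TTO_BIN_RANGES])
    tto_days = rng.integers(lows[bin_idx], highs[bin_idx] + 1)

    # date-missingness pattern: blank event, month-precision event, blank start
    miss_u = rng.random(n)
    miss_kind = np.full(n, "none", dtype=object)
    miss_kind[miss_u < config.missing_date_rate * 0.60] = "event_blank"
    miss_kind[
        (miss_u >= config.missing_date_rate * 0.60)
        & (miss_u < config.missing_date_rate * 0.85)
    ] = "event_month"
    miss_kind[
        (miss_u >= config.missing_date_rate * 0.85) & (miss_u < config.missing_date_rate)
    ] = "start_blank"

    fda_dt = _dates_yyyymmdd(STUDY_START, fda_off)
    start_full = _dates_yyyymmdd(STUDY_START, start_off)
    event_full = _dates_yyyymmdd(STUDY_START, start_off + tto_days)
    event_dt = event_full.copy()
    event_dt[miss_kind == "event_blank"] = ""
    month_mask = miss_kind == "event_month"
    event_dt[month_mask] = [s[:6] for s in event_full[month_mask]]
    start_dt = start_full.copy()
    start_dt[miss_kind == "start_blank"] = ""

    sex = rng.choice(np.array(["M", "F", ""], dtype=object), size=n, p=config.sex_probs)
    age_missing = rng.random(n) < config.age_missing_rate
    band = rng.choice(3, size=n, p=np.array([0.01, 0.395, 0.595]))
    age_years = np.select(
        [band == 0, band == 1, band == 2],
        [rng.integers(1, 18, n), rng.integers(18, 65, n), rng.integers(65, 96, n)],
    )
    use_dec = rng.random(n) < 0.03
    age = np.where(use_dec, (age_years // 10).astype(str), age_years.astype(str)).astype(object)
    age_cod = np.where(use_dec, "DEC", "YR").astype(object)
    age[age_missing] = ""
    age_cod[age_missing] = ""
    country = rng.choice(np.array(COUNTRIES, dtype=object), size=n, p=COUNTRY_PROBS)

    drugname = np.where(
        is_target,
        rng.choice(np.array(TARGET_DRUGNAMES, dtype=object), size=n),
        rng.choice(np.array(BACKGROUND_DRUGNAMES, dtype=object), size=n),
    )
    prod_ai = np.where(is_target, "DENOSUMAB", "")
    indication = np.where(
        is_target,
        rng.choice(np.array(TARGET_INDICATIONS, dtype=object), size=n),
        rng.choice(np.array(BACKGROUND_INDICATIONS, dtype=object), size=n),
    )

    codes = list(config.outcome_profile)
    outc_include = rng.random((n, len(codes))) < np.array(
        [config.outcome_profile[c] for c in codes]
    )

    dup_mask = rng.random(n) < config.dup_rate
    dup_fda = _dates_yyyymmdd(STUDY_START, fda_off + rng.integers(30, 400, size=n))

    demo_rows: List[str] = []
    drug_rows: List[str] = []
    reac_rows: List[str] = []
    outc_rows: List[str] = []
    ther_rows: List[str] = []
    indi_rows: List[str] = []

    def emit(i: int, pid: str, fda: str) -> None:
        demo_rows.append(
            DELIMITER.join(
                [pid, str(caseid[i]), fda, event_dt[i], age[i], age_cod[i], sex[i], country[i]]
            )
        )
        drug_rows.append(DELIMITER.join([pid, "1", "PS", drugname[i], prod_ai[i]]))
        for j in np.nonzero(include[i])[0]:
            reac_rows.append(DELIMITER.join([pid, pts[j]]))
        for k in np.nonzero(outc_include[i])[0]:
            outc_rows.append(DELIMITER.join([pid, codes[k]]))
        ther_rows.append(DELIMITER.join([pid, "1", start_dt[i]]))
        indi_rows.append(DELIMITER.join([pid, "1", indication[i]]))

    for i in range(n):
        emit(i, str(primaryid[i]), fda_dt[i])
        if dup_mask[i]:
            emit(i, str(primaryid[i] + 1), dup_fda[i])

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for kind, rows in (
        ("DEMO", demo_rows),
        ("DRUG", drug_rows),
        ("REAC", reac_rows),
        ("OUTC", outc_rows),
        ("THER", ther_rows),
        ("INDI", indi_rows),
    ):
        path = outdir / f"{kind}{suffix}.txt"
        with path.open("w", encoding="latin-1", newline="\n") as fh:
            fh.write(DELIMITER.join(WRITE_COLUMNS[kind]) + "\n")
            for row in rows:
                fh.write(row + "\n")
        paths[kind] = path
    return paths
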