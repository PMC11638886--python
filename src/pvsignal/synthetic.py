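"""Seeded generator of FAERS-like spontaneous-report datasets.

Emulates the multi-table quarterly structure of the FDA Adverse Event
Reporting System — DEMO/DRUG/REAC/THER (plus schema-valid OUTC and INDI
placeholders) keyed by PRIMARYID/CASEID — with the artifacts a real ingest
must survive: duplicate case versions, PS/SS/C/I role codes, partial dates,
demographic missingness, and brand-name drug spellings.

Each case carries exactly one primary-suspect (PS) drug.  Reaction preferred
terms (PTs) are sampled per case from weights ``baseline(pt) * RR(drug, pt)``
renormalized, so under the null (all RR = 1) there is no drug–event
association, while an injected pair's realized 2x2 cross-product ratio
approaches the configured relative risk in the rare-event limit.  Onset days
for configured (drug, PT) pairs follow a Weibull law, rounded up to whole
days with a 1-day minimum, matching the day resolution of FAERS dates.

Every draw flows from one ``numpy`` Generator seeded from the config, so an
identical (config, seed) reproduces byte-identical tables, and the returned
:class:`GroundTruthLedger` records exactly which signals, onset models and
duplicate versions were injected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FaersDataset

__all__ = [
    "GeneratorConfig",
    "GroundTruthLedger",
    "generate_dataset",
    "write_ascii_quarter",
    "default_config",
    "default_synonym_map",
    "default_pt_soc_map",
    "DEFAULT_IME_TERMS",
]


class ConfigurationError(ValueError):
    """An invalid generator configuration; the message names the field."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic reporting database.

    Parameters
    ----------
    n_cases:
        Number of distinct safety reports (before duplicate versions).
    drugs:
        ``(name, marginal probability)`` per drug; probabilities are
        normalized into the categorical law of the case's PS drug.
    events:
        ``(PT, SOC, baseline probability)`` per reaction term; baselines are
        the untilted sampling weights.
    signals:
        ``(drug, PT, relative risk)`` triples; the pair's sampling weight is
        multiplied by RR for cases whose PS drug matches.
    tto_models:
        ``(drug, PT, weibull scale days, weibull shape)`` onset-time laws for
        injected pairs; other cases draw onset from ``background_onset``.
    duplicate_rate:
        Probability that a case is also emitted as an older version with the
        same CASEID (smaller FDA_DT, or equal FDA_DT with smaller PRIMARYID).
    missingness:
        Per-field blanking fractions; recognized keys: ``sex``, ``age``,
        ``weight``, ``reporter_country``, ``occp_cod``, ``event_dt``,
        ``start_dt``.
    date_window:
        ``(start, end)`` calendar dates ("YYYY-MM-DD") bounding therapy
        start dates.
    partial_date_rate:
        Fraction of EVENT_DT/START_DT values truncated to YYYYMM or YYYY.
    """

    n_cases: int
    drugs: list[tuple[str, float]]
    events: list[tuple[str, str, float]]
    signals: list[tuple[str, str, float]] = field(default_factory=list)
    tto_models: list[tuple[str, str, float, float]] = field(default_factory=list)
    duplicate_rate: float = 0.0
    missingness: dict[str, float] = field(default_factory=dict)
    date_window: tuple[str, str] = ("2004-01-01", "2023-12-31")
    partial_date_rate: float = 0.0
    extra_reactions_mean: float = 1.0
    nonps_mention_rate: float = 0.3
    background_onset: tuple[float, float] = (90.0, 1.0)  # Weibull (scale, shape)
    brands: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        if not self.drugs:
            raise ConfigurationError("drugs must be nonempty")
        names = [d for d, _ in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigurationError("drugs contains duplicate names")
        for name, p in self.drugs:
            if not 0 < p < 1:
                raise ConfigurationError(f"drugs: probability for {name!r} not in (0,1)")
        if not self.events:
            raise ConfigurationError("events must be nonempty")
        for pt, _soc, p in self.events:
            if not 0 < p < 1:
                raise ConfigurationError(f"events: baseline for {pt!r} not in (0,1)")
        drug_set, pt_set = set(names), {pt for pt, _, _ in self.events}
        for d, e, rr in self.signals:
            if d not in drug_set or e not in pt_set:
                raise ConfigurationError(f"signals: unknown pair ({d!r}, {e!r})")
            if not np.isfinite(rr) or rr < 0:
                raise ConfigurationError(f"signals: RR for ({d!r}, {e!r}) not finite/nonnegative")
        for d, e, scale, shape in self.tto_models:
            if d not in drug_set or e not in pt_set:
                raise ConfigurationError(f"tto_models: unknown pair ({d!r}, {e!r})")
            if scale <= 0 or shape <= 0:
                raise ConfigurationError(f"tto_models: nonpositive parameter for ({d!r}, {e!r})")
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigurationError("duplicate_rate must be in [0,1)")
        if not 0 <= self.partial_date_rate < 1:
            raise ConfigurationError("partial_date_rate must be in [0,1)")
        for k, v in self.missingness.items():
            if not 0 <= v < 1:
                raise ConfigurationError(f"missingness[{k!r}] must be in [0,1)")
        start, end = (np.datetime64(d) for d in self.date_window)
        if not start < end:
            raise ConfigurationError("date_window is empty")


@dataclass
class GroundTruthLedger:
    """What the generator actually injected, for exact downstream checks."""

    injected_pairs: list[tuple[str, str, float]]
    true_tto_params: list[tuple[str, str, float, float]]
    duplicate_map: dict[int, int]  # superseded primaryid -> surviving primaryid
    surviving_primaryids: list[int]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.duplicate_map) & set(self.duplicate_map.values())
        if overlap:
            raise ValueError(f"duplicate_map keys overlap values: {sorted(overlap)[:5]}")

    def save(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "injected_pairs": [list(t) for t in self.injected_pairs],
            "true_tto_params": [list(t) for t in self.true_tto_params],
            "duplicate_map": {str(k): v for k, v in self.duplicate_map.items()},
            "surviving_primaryids": self.surviving_primaryids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthLedger":
        d = json.loads(Path(path).read_text())
        return cls(
            injected_pairs=[tuple(t) for t in d["injected_pairs"]],
            true_tto_params=[tuple(t) for t in d["true_tto_params"]],
            duplicate_map={int(k): int(v) for k, v in d["duplicate_map"].items()},
            surviving_primaryids=[int(x) for x in d["surviving_primaryids"]],
            seed=int(d["seed"]),
        )


_COUNTRIES = np.array(["US", "GB", "JP", "CA", "FR", "DE", "CN", "BR"])
_COUNTRY_P = np.array([0.60, 0.08, 0.07, 0.06, 0.06, 0.05, 0.04, 0.04])
_OCCP = np.array(["CN", "MD", "PH", "OT", "HP", "RN", "LW"])
_OCCP_P = np.array([0.38, 0.22, 0.12, 0.14, 0.06, 0.06, 0.02])
_OUTC = np.array(["HO", "OT", "DS", "LT", "DE", "CA", "RI"])
_OUTC_P = np.array([0.35, 0.30, 0.12, 0.08, 0.08, 0.04, 0.03])


def _dates_to_str(days: np.ndarray) -> np.ndarray:
    """datetime64[D] -> 'YYYYMMDD' strings."""
    s = np.datetime_as_string(days, unit="D")
    return np.char.replace(s, "-", "")


def generate_dataset(config: GeneratorConfig) -> tuple[FaersDataset, GroundTruthLedger]:
    """Generate one multi-table FAERS-like dataset plus its ground truth.

    Deterministic in ``(config, config.seed)``.  Surviving case versions get
    ``primaryid = caseid*10 + 2``; an injected older duplicate of the same
    case gets ``caseid*10 + 1`` with a strictly smaller FDA_DT (or, for a
    random subset, an equal FDA_DT so the PRIMARYID tie-break is exercised).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    drug_names = np.array([d for d, _ in config.drugs])
    drug_p = np.array([p for _, p in config.drugs], dtype=float)
    drug_p = drug_p / drug_p.sum()
    pts = np.array([pt for pt, _, _ in config.events])
    base_w = np.array([p for _, _, p in config.events], dtype=float)
    n_drugs, n_pts = len(drug_names), len(pts)

    drug_index = {d: i for i, d in enumerate(drug_names)}
    pt_index = {p: i for i, p in enumerate(pts)}

    # RR-tilted log-weights per drug
    log_w = np.tile(np.log(base_w), (n_drugs, 1))
    for d, e, rr in config.signals:
        log_w[drug_index[d], pt_index[e]] += np.log(rr) if rr > 0 else -np.inf

    # onset-model lookup: model index per (drug, pt), -1 = background
    tto_lookup = -np.ones((n_drugs, n_pts), dtype=np.int64)
    for m, (d, e, _sc, _sh) in enumerate(config.tto_models):
        tto_lookup[drug_index[d], pt_index[e]] = m

    # --- per-case structure -------------------------------------------------
    caseids = np.arange(1, n + 1, dtype=np.int64)
    primaryids = caseids * 10 + 2
    ps_drug = rng.choice(n_drugs, size=n, p=drug_p)
    k_react = 1 + rng.poisson(config.extra_reactions_mean, size=n)
    k_react = np.minimum(k_react, n_pts)

    # Gumbel top-k gives a weighted sample of k distinct PTs per case
    gumbel = rng.gumbel(size=(n, n_pts))
    scores = log_w[ps_drug] + gumbel
    order = np.argsort(-scores, axis=1, kind="stable")
    sel_mask = np.arange(n_pts)[None, :] < k_react[:, None]
    case_rows = np.repeat(np.arange(n), k_react)
    pt_rows = order[sel_mask]  # flattened: PT index per (case, reaction)

    # --- onset and dates ----------------------------------------------------
    window_start = np.datetime64(config.date_window[0])
    window_end = np.datetime64(config.date_window[1])
    span = int((window_end - window_start) / np.timedelta64(1, "D"))

    # a case's onset model: first configured model among its sampled PTs
    model_flat = tto_lookup[np.repeat(ps_drug, k_react), pt_rows]
    case_model = -np.ones(n, dtype=np.int64)
    np.maximum.at(case_model, case_rows, model_flat)

    bg_scale, bg_shape = config.background_onset
    onset = bg_scale * rng.weibull(bg_shape, size=n)
    for m, (_d, _e, scale, shape) in enumerate(config.tto_models):
        hit = case_model == m
        onset[hit] = scale * rng.weibull(shape, size=int(hit.sum()))
    onset_days = np.maximum(np.ceil(onset), 1).astype(np.int64)

    start_dt = window_start + rng.integers(0, max(span - 400, 1), size=n).astype("timedelta64[D]")
    event_dt = start_dt + onset_days.astype("timedelta64[D]")
    fda_dt = event_dt + rng.integers(1, 181, size=n).astype("timedelta64[D]")

    # --- demographics -------------------------------------------------------
    sex = rng.choice(np.array(["F", "M"]), size=n, p=[0.62, 0.38])
    age_years = np.clip(rng.normal(52, 17, size=n), 2, 95)
    age_unit = rng.choice(np.array(["YR", "DEC", "DY"]), size=n, p=[0.92, 0.03, 0.05])
    age_val = np.round(
        np.where(age_unit == "YR", age_years,
                 np.where(age_unit == "DEC", age_years / 10, age_years * 365.25)),
        1,
    )
    wt_kg = np.clip(rng.normal(76, 18, size=n), 30, 200)
    wt_unit = rng.choice(np.array(["KG", "LBS"]), size=n, p=[0.8, 0.2])
    wt_val = np.round(np.where(wt_unit == "KG", wt_kg, wt_kg / 0.453592), 1)
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    occp = rng.choice(_OCCP, size=n, p=_OCCP_P)

    # --- string fields with missingness and partial dates -------------------
    miss = config.missingness

    def _blank(values: np.ndarray, key: str) -> np.ndarray:
        rate = miss.get(key, 0.0)
        out = values.astype(object)
        if rate > 0:
            out[rng.random(n) < rate] = ""
        return out

    def _partialize(date_str: np.ndarray, present: np.ndarray) -> np.ndarray:
        if config.partial_date_rate <= 0:
            return date_str
        u = rng.random(n)
        out = date_str.copy()
        to_month = present & (u < config.partial_date_rate / 2)
        to_year = present & (u >= config.partial_date_rate / 2) & (u < config.partial_date_rate)
        out[to_month] = [s[:6] for s in date_str[to_month]]
        out[to_year] = [s[:4] for s in date_str[to_year]]
        return out

    event_str = _blank(_dates_to_str(event_dt), "event_dt")
    start_str = _blank(_dates_to_str(start_dt), "start_dt")
    event_str = _partialize(event_str, event_str != "")
    start_str = _partialize(start_str, start_str != "")
    fda_str = _dates_to_str(fda_dt)

    sex_col = _blank(sex, "sex")
    age_miss = rng.random(n) < miss.get("age", 0.0)
    age_col = np.where(age_miss, "", age_val.astype(str))
    age_cod_col = np.where(age_miss, "", age_unit)
    wt_miss = rng.random(n) < miss.get("weight", 0.0)
    wt_col = np.where(wt_miss, "", wt_val.astype(str))
    wt_cod_col = np.where(wt_miss, "", wt_unit)
    country_col = _blank(country, "reporter_country")
    occp_col = _blank(occp, "occp_cod")

    # verbatim drug names: brand spelling where configured, else upper-case
    verbatim = drug_names[ps_drug].astype(object)
    for d, brand_list in config.brands.items():
        if d not in drug_index or not brand_list:
            continue
        hit = np.flatnonzero(ps_drug == drug_index[d])
        use_brand = hit[rng.random(hit.size) < 0.5]
        verbatim[use_brand] = rng.choice(np.array(brand_list, dtype=object), size=use_brand.size)
    verbatim = np.char.upper(verbatim.astype(str))

    demo = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "caseversion": np.full(n, 2, dtype=np.int64),
            "fda_dt": fda_str,
            "event_dt": event_str,
            "age": age_col,
            "age_cod": age_cod_col,
            "sex": sex_col,
            "wt": wt_col,
            "wt_cod": wt_cod_col,
            "reporter_country": country_col,
            "occp_cod": occp_col,
        }
    )

    drug_tbl = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "drug_seq": np.ones(n, dtype=np.int64),
            "role_cod": np.full(n, "PS"),
            "drugname": verbatim,
        }
    )
    # non-PS noise mentions exist purely to exercise role filtering
    noise_hit = np.flatnonzero(rng.random(n) < config.nonps_mention_rate)
    if noise_hit.size:
        noise = pd.DataFrame(
            {
                "primaryid": primaryids[noise_hit],
                "caseid": caseids[noise_hit],
                "drug_seq": np.full(noise_hit.size, 2, dtype=np.int64),
                "role_cod": rng.choice(np.array(["SS", "C", "I"]), size=noise_hit.size),
                "drugname": np.char.upper(
                    drug_names[rng.choice(n_drugs, size=noise_hit.size)].astype(str)
                ),
            }
        )
        drug_tbl = pd.concat([drug_tbl, noise], ignore_index=True)

    reac = pd.DataFrame(
        {
            "primaryid": primaryids[case_rows],
            "caseid": caseids[case_rows],
            "pt": pts[pt_rows],
        }
    )

    ther = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "drug_seq": np.ones(n, dtype=np.int64),
            "start_dt": start_str,
            "end_dt": _dates_to_str(event_dt + rng.integers(0, 30, size=n).astype("timedelta64[D]")),
        }
    )

    outc_hit = np.flatnonzero(rng.random(n) < 0.4)
    outc = pd.DataFrame(
        {
            "primaryid": primaryids[outc_hit],
            "caseid": caseids[outc_hit],
            "outc_cod": rng.choice(_OUTC, size=outc_hit.size, p=_OUTC_P),
        }
    )
    indi = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "drug_seq": np.ones(n, dtype=np.int64),
            "indi_pt": np.full(n, "Product used for unknown indication"),
        }
    )

    # --- duplicate (older) case versions ------------------------------------
    duplicate_map: dict[int, int] = {}
    if config.duplicate_rate > 0:
        dup_hit = np.flatnonzero(rng.random(n) < config.duplicate_rate)
        if dup_hit.size:
            old_pid = caseids[dup_hit] * 10 + 1
            back = rng.integers(1, 181, size=dup_hit.size)
            same_day = rng.random(dup_hit.size) < 0.2  # exercise the PRIMARYID tie-break
            back[same_day] = 0
            old_fda = fda_dt[dup_hit] - back.astype("timedelta64[D]")
            dup_demo = demo.iloc[dup_hit].copy()
            dup_demo["primaryid"] = old_pid
            dup_demo["caseversion"] = 1
            dup_demo["fda_dt"] = _dates_to_str(old_fda)
            demo = pd.concat([demo, dup_demo], ignore_index=True)

            pid_map = dict(zip(primaryids[dup_hit].tolist(), old_pid.tolist()))
            for name, tbl in (("DRUG", drug_tbl), ("REAC", reac), ("THER", ther)):
                mask = tbl["primaryid"].isin(pid_map)
                dup_rows = tbl.loc[mask].copy()
                dup_rows["primaryid"] = dup_rows["primaryid"].map(pid_map)
                if name == "DRUG":
                    drug_tbl = pd.concat([drug_tbl, dup_rows], ignore_index=True)
                elif name == "REAC":
                    reac = pd.concat([reac, dup_rows], ignore_index=True)
                else:
                    ther = pd.concat([ther, dup_rows], ignore_index=True)
            duplicate_map = dict(zip(old_pid.tolist(), primaryids[dup_hit].tolist()))

    tables = {
        "DEMO": demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True),
        "DRUG": drug_tbl.sort_values(["primaryid", "drug_seq"], kind="mergesort").reset_index(drop=True),
        "REAC": reac.sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True),
        "THER": ther.sort_values("primaryid", kind="mergesort").reset_index(drop=True),
        "OUTC": outc.reset_index(drop=True),
        "INDI": indi.reset_index(drop=True),
    }
    ledger = GroundTruthLedger(
        injected_pairs=list(config.signals),
        true_tto_params=list(config.tto_models),
        duplicate_map=duplicate_map,
        surviving_primaryids=primaryids.tolist(),
        seed=config.seed,
    )
    return FaersDataset(tables=tables), ledger


def write_ascii_quarter(
    dataset: FaersDataset | dict[str, pd.DataFrame],
    directory: str | Path,
    quarter: str = "24Q1",
) -> list[Path]:
    """Write tables as '$'-delimited ASCII files (DEMO24Q1.txt, ...).

    The dialect has no quoting, so any field containing the delimiter is
    rejected with a :class:`ValueError`.  Missing values become empty
    strings; files round-trip through :func:`pvsignal.io.read_quarter`.
    """
    tables = dataset.tables if isinstance(dataset, FaersDataset) else dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        out = df.astype(str).replace({"<NA>": "", "nan": "", "None": ""})
        for col in out.columns:
            if out[col].str.contains(r"\$", regex=True).any():
                raise ValueError(f"table {name} column {col} contains the '$' delimiter")
        path = directory / f"{name}{quarter}.txt"
        lines = ["$".join(out.columns)]
        lines.extend("$".join(row) for row in out.itertuples(index=False, name=None))
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# the default study scenario

DEFAULT_TARGETS = ("duloxetine", "venlafaxine")

_DEFAULT_BRANDS = {
    "duloxetine": ["Cymbalta", "Drizalma"],
    "venlafaxine": ["Effexor", "Effexor XR"],
}

_REPRO_SOC = "Reproductive system and breast disorders"

# (PT, SOC, baseline weight); reproductive-SOC terms plus common background
# terms from other organ classes, so per-SOC screening has a real family
_DEFAULT_EVENTS: list[tuple[str, str, float]] = [
    ("Erectile dysfunction", _REPRO_SOC, 0.012),
    ("Sexual dysfunction", _REPRO_SOC, 0.008),
    ("Libido decreased", _REPRO_SOC, 0.008),
    ("Ejaculation failure", _REPRO_SOC, 0.004),
    ("Orgasm abnormal", _REPRO_SOC, 0.004),
    ("Menstrual disorder", _REPRO_SOC, 0.006),
    ("Amenorrhoea", _REPRO_SOC, 0.004),
    ("Menorrhagia", _REPRO_SOC, 0.004),
    ("Galactorrhoea", _REPRO_SOC, 0.003),
    ("Gynaecomastia", _REPRO_SOC, 0.003),
    ("Breast pain", _REPRO_SOC, 0.004),
    ("Breast enlargement", _REPRO_SOC, 0.003),
    ("Pelvic pain", _REPRO_SOC, 0.004),
    ("Infertility", _REPRO_SOC, 0.002),
    ("Priapism", _REPRO_SOC, 0.001),
    ("Nausea", "Gastrointestinal disorders", 0.09),
    ("Vomiting", "Gastrointestinal disorders", 0.05),
    ("Diarrhoea", "Gastrointestinal disorders", 0.05),
    ("Constipation", "Gastrointestinal disorders", 0.03),
    ("Headache", "Nervous system disorders", 0.08),
    ("Dizziness", "Nervous system disorders", 0.07),
    ("Somnolence", "Nervous system disorders", 0.04),
    ("Tremor", "Nervous system disorders", 0.03),
    ("Seizure", "Nervous system disorders", 0.01),
    ("Insomnia", "Psychiatric disorders", 0.05),
    ("Anxiety", "Psychiatric disorders", 0.05),
    ("Depression", "Psychiatric disorders", 0.04),
    ("Suicidal ideation", "Psychiatric disorders", 0.02),
    ("Fatigue", "General disorders", 0.07),
    ("Asthenia", "General disorders", 0.04),
    ("Drug ineffective", "General disorders", 0.08),
    ("Rash", "Skin disorders", 0.04),
    ("Pruritus", "Skin disorders", 0.03),
    ("Hyperhidrosis", "Skin disorders", 0.03),
    ("Weight increased", "Investigations", 0.03),
    ("Weight decreased", "Investigations", 0.02),
    ("Blood pressure increased", "Investigations", 0.03),
    ("Palpitations", "Cardiac disorders", 0.03),
    ("Tachycardia", "Cardiac disorders", 0.02),
    ("Vision blurred", "Eye disorders", 0.02),
    ("Dry mouth", "Gastrointestinal disorders", 0.03),
    ("Arthralgia", "Musculoskeletal disorders", 0.04),
    ("Myalgia", "Musculoskeletal disorders", 0.03),
    ("Back pain", "Musculoskeletal disorders", 0.03),
    ("Dyspnoea", "Respiratory disorders", 0.03),
    ("Cough", "Respiratory disorders", 0.02),
    ("Urinary retention", "Renal and urinary disorders", 0.01),
    ("Hyponatraemia", "Metabolism disorders", 0.01),
    ("Fall", "Injury and procedural complications", 0.03),
]

_BACKGROUND_DRUGS = [
    "metformin", "lisinopril", "atorvastatin", "omeprazole", "amlodipine",
    "sertraline", "fluoxetine", "gabapentin", "ibuprofen", "paracetamol",
    "levothyroxine", "amoxicillin", "prednisone", "warfarin", "insulin",
    "albuterol", "losartan", "simvastatin", "tramadol", "alprazolam",
    "citalopram", "bupropion", "quetiapine", "aripiprazole", "pregabalin",
    "hydrochlorothiazide", "furosemide", "clopidogrel",
]

#: PTs from the EMA important-medical-event style of list, for flag tests
DEFAULT_IME_TERMS = [
    "Erectile dysfunction",
    "Sexual dysfunction",
    "Amenorrhoea",
    "Priapism",
    "Infertility",
    "Seizure",
    "Suicidal ideation",
]


def default_config(seed: int = 0, n_cases: int = 50_000, *, signals=None, tto_models=None) -> GeneratorConfig:
    """The default synthetic study: two SNRI-like target drugs in a large
    background database, with reproductive-system signals injected for the
    targets and Weibull onset laws for the erectile-dysfunction pairs.

    Target marginals of 4%/3% over ~30 drugs give a few thousand PS reports
    per target at the 50,000-case default, enough to realize pair counts in
    the hundreds for the injected signals.
    """
    drugs = [("duloxetine", 0.04), ("venlafaxine", 0.03)]
    drugs += [(d, 0.93 / len(_BACKGROUND_DRUGS)) for d in _BACKGROUND_DRUGS]
    if signals is None:
        signals = [
            ("duloxetine", "Erectile dysfunction", 5.0),
            ("duloxetine", "Sexual dysfunction", 7.0),
            ("duloxetine", "Libido decreased", 4.0),
            ("venlafaxine", "Erectile dysfunction", 6.0),
            ("venlafaxine", "Ejaculation failure", 8.0),
            ("venlafaxine", "Orgasm abnormal", 5.0),
        ]
    if tto_models is None:
        tto_models = [
            ("duloxetine", "Erectile dysfunction", 110.0, 0.65),
            ("venlafaxine", "Erectile dysfunction", 500.55, 0.49),
        ]
    return GeneratorConfig(
        n_cases=n_cases,
        drugs=drugs,
        events=list(_DEFAULT_EVENTS),
        signals=list(signals),
        tto_models=list(tto_models),
        duplicate_rate=0.10,
        missingness={
            "sex": 0.05,
            "age": 0.15,
            "weight": 0.40,
            "reporter_country": 0.05,
            "occp_cod": 0.10,
            "event_dt": 0.20,
            "start_dt": 0.30,
        },
        date_window=("2004-01-01", "2023-12-31"),
        partial_date_rate=0.10,
        brands=dict(_DEFAULT_BRANDS),
        seed=seed,
    )


def default_synonym_map() -> dict[str, str]:
    """Generic + brand spellings for the default target drugs."""
    mapping = {}
    for generic, brand_list in _DEFAULT_BRANDS.items():
        mapping[generic] = generic
        for b in brand_list:
            mapping[b] = generic
    return mapping


def default_pt_soc_map() -> dict[str, str]:
    """PT -> SOC assignment of the default event list (case-insensitive keys)."""
    return {pt.casefold(): soc for pt, soc, _ in _DEFAULT_EVENTS}
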