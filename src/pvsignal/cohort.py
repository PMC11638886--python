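"""Analytic cohorts and 2x2 contingency tables for disproportionality.

Starting from a deduplicated, role-filtered FAERS dataset, this module
builds a tidy drug–reaction pair table joined to demographics, computes
descriptive summaries (sex, age bands, weight bands, reporters, outcomes,
countries, annual counts), and assembles the 2x2 tables

        | target PT | other PTs
    drug|     a     |     b
   other|     c     |     d

per (drug, PT) overall or within sex/age strata.  The counting unit is an
explicit switch: ``records`` counts each distinct case–PT pair once (the
default), ``cases`` counts distinct reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import (
    FaersDataset,
    _clean_drug_name,
    normalize_age,
    normalize_sex,
    normalize_weight,
)

__all__ = [
    "SubgroupKey",
    "ContingencyTable",
    "AnalyticData",
    "DescriptiveSummary",
    "build_analytic_dataset",
    "build_contingency",
    "contingency_all_pts",
    "all_pairs_2x2",
    "descriptive_summary",
    "annual_counts",
    "round_half_up",
    "AGE_BANDS",
    "WEIGHT_BANDS",
]

AGE_BANDS = ("under45", "45to59", "over59")
WEIGHT_BANDS = ("under50", "50to100", "over100")


@dataclass(frozen=True)
class SubgroupKey:
    """A sex/age stratum; records with unknown sex or age are excluded from
    the respective stratified analyses but retained overall."""

    sex: str = "all"  # all | female | male
    age_band: str = "all"  # all | under45 | 45to59 | over59

    def __post_init__(self) -> None:
        if self.sex not in ("all", "female", "male"):
            raise ValueError(f"invalid sex stratum {self.sex!r}")
        if self.age_band not in ("all",) + AGE_BANDS:
            raise ValueError(f"invalid age band {self.age_band!r}")

    def label(self) -> str:
        parts = []
        if self.sex != "all":
            parts.append(self.sex)
        if self.age_band != "all":
            parts.append(self.age_band)
        return "_".join(parts) or "overall"


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 counts for one (drug, PT) in one stratum.

    ``a`` = target drug & target PT, ``b`` = target drug & other PTs,
    ``c`` = other drugs & target PT, ``d`` = everything else.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str
    pt: str
    stratum: SubgroupKey = SubgroupKey()

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the null-expected count for cell a."""
        n = self.n_total
        return (self.a + self.b) * (self.a + self.c) / n if n else float("nan")

    @property
    def degenerate(self) -> bool:
        """No drug records in the stratum (a = b = 0)."""
        return self.a + self.b == 0

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def _age_band(age_years: float) -> str:
    # literal reading of the "< 45 / 45-59 / > 59" bands
    if np.isnan(age_years):
        return "unknown"
    if age_years < 45:
        return "under45"
    if age_years <= 59:
        return "45to59"
    return "over59"


def _weight_band(kg: float) -> str:
    if np.isnan(kg):
        return "unknown"
    if kg < 50:
        return "under50"
    if kg <= 100:
        return "50to100"
    return "over100"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AnalyticData:
    """The tidy analysis container.

    ``pairs`` holds one row per distinct (primaryid, drug, pt) across the
    whole cleaned database — target drugs carry their generic name, other
    drugs their cleaned verbatim name — joined to sex and age band so
    contingency tables for any stratum are recounts of this one frame.
    ``cases`` holds one row per (primaryid, target drug) with demographics
    for descriptive summaries.
    """

    pairs: pd.DataFrame
    cases: pd.DataFrame
    targets: list[str]
    counting_unit: str = "records"

    @property
    def metadata(self) -> dict:
        return {
            "counting_unit": self.counting_unit,
            "targets": list(self.targets),
            "n_pairs": int(len(self.pairs)),
            "n_cases": int(self.pairs["primaryid"].nunique()),
        }


def build_analytic_dataset(
    dataset: FaersDataset,
    synonym_map: dict[str, str],
    counting_unit: str = "records",
) -> AnalyticData:
    """Join deduplicated DEMO/DRUG/REAC/THER into the analytic container.

    ``dataset`` must already be deduplicated.  All PS drug mentions enter the
    pair table (the full-database comparator); mentions matching the synonym
    map are renamed to their generic target name.  A target absent from the
    data yields an empty ``cases`` slice, not an error.
    """
    if counting_unit not in ("records", "cases"):
        raise ValueError(f"counting_unit must be 'records' or 'cases', got {counting_unit!r}")
    demo = dataset["DEMO"].copy()
    drug = dataset["DRUG"]
    reac = dataset["REAC"]

    # normalized demographics, one row per case
    age = pd.to_numeric(demo.get("age", pd.Series(index=demo.index, dtype=float)), errors="coerce")
    age_cod = demo.get("age_cod", pd.Series("", index=demo.index)).astype(str)
    demo["age_years"] = [normalize_age(v, u) for v, u in zip(age, age_cod)]
    wt = pd.to_numeric(demo.get("wt", pd.Series(index=demo.index, dtype=float)), errors="coerce")
    wt_cod = demo.get("wt_cod", pd.Series("", index=demo.index)).astype(str)
    demo["weight_kg"] = [normalize_weight(v, u) for v, u in zip(wt, wt_cod)]
    demo["sex_norm"] = demo.get("sex", pd.Series("", index=demo.index)).map(normalize_sex)
    demo["age_band"] = demo["age_years"].map(_age_band)
    demo["weight_band"] = demo["weight_kg"].map(_weight_band)
    fda = demo.get("fda_dt", pd.Series("", index=demo.index)).astype(str)
    year = pd.to_numeric(fda.str.slice(0, 4), errors="coerce")
    demo["report_year"] = year.where((year >= 1900) & (year <= 2100)).astype("Int64")

    # PS mentions across the whole database; targets get generic names
    ps = drug.loc[drug["role_cod"].astype(str).str.strip().str.upper() == "PS"].copy()
    cleaned = ps["drugname"].map(_clean_drug_name)
    cleaned_map = {_clean_drug_name(k): v for k, v in synonym_map.items()}
    mapped = cleaned.map(cleaned_map)
    ps["drug"] = mapped.fillna(cleaned)
    ps["is_target"] = mapped.notna()
    ps = ps[["primaryid", "drug_seq", "drug", "is_target"]].drop_duplicates(
        ["primaryid", "drug"]
    )

    demo_cols = demo[
        [
            "primaryid",
            "sex_norm",
            "age_years",
            "age_band",
            "weight_kg",
            "weight_band",
            "report_year",
        ]
        + [c for c in ("event_dt", "fda_dt", "reporter_country", "occp_cod") if c in demo.columns]
    ]

    pairs = ps.merge(reac[["primaryid", "pt"]], on="primaryid", how="inner")
    pairs = pairs.drop_duplicates(["primaryid", "drug", "pt"])
    pairs = pairs.merge(demo_cols, on="primaryid", how="left")
    pairs = pairs.sort_values(["drug", "pt", "primaryid"], kind="mergesort").reset_index(drop=True)

    targets = sorted(set(synonym_map.values()))
    cases = ps.loc[ps["is_target"]].merge(demo_cols, on="primaryid", how="left")
    if "THER" in dataset:
        ther = dataset["THER"]
        first_start = (
            ther.assign(_s=ther["start_dt"].astype(str))
            .sort_values(["primaryid", "_s"], kind="mergesort")
            .drop_duplicates(["primaryid", "drug_seq"])[["primaryid", "drug_seq", "start_dt"]]
        )
        cases = cases.merge(first_start, on=["primaryid", "drug_seq"], how="left")
    if "OUTC" in dataset:
        outc = dataset["OUTC"]
        codes = (
            outc.groupby("primaryid")["outc_cod"]
            .apply(lambda s: ",".join(sorted(set(map(str, s)))))
            .rename("outcomes")
        )
        cases = cases.merge(codes, on="primaryid", how="left")
    cases = cases.sort_values(["drug", "primaryid"], kind="mergesort").reset_index(drop=True)

    return AnalyticData(pairs=pairs, cases=cases, targets=targets, counting_unit=counting_unit)


def _stratum_pairs(analytic: AnalyticData, stratum: SubgroupKey) -> pd.DataFrame:
    df = analytic.pairs
    if stratum.sex != "all":
        df = df.loc[df["sex_norm"] == stratum.sex]
    if stratum.age_band != "all":
        df = df.loc[df["age_band"] == stratum.age_band]
    return df


def build_contingency(
    analytic: AnalyticData,
    drug: str,
    pt: str,
    stratum: SubgroupKey = SubgroupKey(),
    counting_unit: str | None = None,
) -> ContingencyTable:
    """2x2 table for (drug, pt) against the full database in one stratum.

    The comparator (cells c, d) is every other drug in the cleaned database,
    and both margins are restricted to the stratum.
    """
    unit = counting_unit or analytic.counting_unit
    df = _stratum_pairs(analytic, stratum)
    is_drug = df["drug"] == drug
    is_pt = df["pt"] == pt
    if unit == "records":
        n = len(df)
        a = int((is_drug & is_pt).sum())
        drug_total = int(is_drug.sum())
        pt_total = int(is_pt.sum())
    else:
        n = int(df["primaryid"].nunique())
        drug_cases = set(df.loc[is_drug, "primaryid"])
        pt_cases = set(df.loc[is_pt, "primaryid"])
        a = len(drug_cases & pt_cases)
        drug_total = len(drug_cases)
        pt_total = len(pt_cases)
    b = drug_total - a
    c = pt_total - a
    d = n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d, drug=drug, pt=pt, stratum=stratum)


def contingency_all_pts(
    analytic: AnalyticData,
    drug: str,
    stratum: SubgroupKey = SubgroupKey(),
    counting_unit: str | None = None,
) -> pd.DataFrame:
    """Vectorized 2x2 counts for one drug against every PT in the stratum.

    Returns a frame indexed by PT with columns a, b, c, d; identical to
    calling :func:`build_contingency` per PT, but one pass over the pairs.
    """
    unit = counting_unit or analytic.counting_unit
    df = _stratum_pairs(analytic, stratum)
    is_drug = df["drug"] == drug
    if unit == "records":
        n = len(df)
        drug_total = int(is_drug.sum())
        a = df.loc[is_drug].groupby("pt").size()
        pt_total = df.groupby("pt").size()
    else:
        n = int(df["primaryid"].nunique())
        drug_total = int(df.loc[is_drug, "primaryid"].nunique())
        a = df.loc[is_drug].groupby("pt")["primaryid"].nunique()
        pt_total = df.groupby("pt")["primaryid"].nunique()
    out = pd.DataFrame({"a": a}).reindex(pt_total.index).fillna(0).astype(int)
    out["b"] = drug_total - out["a"]
    out["c"] = pt_total - out["a"]
    out["d"] = n - out["a"] - out["b"] - out["c"]
    out.index.name = "pt"
    return out.sort_index()


def all_pairs_2x2(
    analytic: AnalyticData,
    stratum: SubgroupKey = SubgroupKey(),
    counting_unit: str | None = None,
) -> pd.DataFrame:
    """2x2 counts for every (drug, PT) pair observed in the stratum.

    One vectorized pass; columns a, b, c, d and expected = (a+b)(a+c)/N.
    This is the frame the empirical-Bayes prior is fitted on and the one
    database-wide calibration checks recount.
    """
    unit = counting_unit or analytic.counting_unit
    df = _stratum_pairs(analytic, stratum)
    if df.empty:
        return pd.DataFrame(columns=["drug", "pt", "a", "b", "c", "d", "expected"])
    if unit == "records":
        n = len(df)
        a = df.groupby(["drug", "pt"]).size().rename("a")
        drug_tot = df.groupby("drug").size()
        pt_tot = df.groupby("pt").size()
    else:
        n = int(df["primaryid"].nunique())
        a = df.groupby(["drug", "pt"])["primaryid"].nunique().rename("a")
        drug_tot = df.groupby("drug")["primaryid"].nunique()
        pt_tot = df.groupby("pt")["primaryid"].nunique()
    out = a.reset_index()
    out["b"] = out["drug"].map(drug_tot).to_numpy() - out["a"].to_numpy()
    out["c"] = out["pt"].map(pt_tot).to_numpy() - out["a"].to_numpy()
    out["d"] = n - out["a"] - out["b"] - out["c"]
    out["expected"] = (out["a"] + out["b"]) * (out["a"] + out["c"]) / n
    return out.sort_values(["drug", "pt"], kind="mergesort").reset_index(drop=True)


@dataclass
class DescriptiveSummary:
    """Per-drug clinical-characteristics aggregation.

    ``blocks`` maps block name (sex, age_band, weight_band, occupation,
    outcomes) to ``{category: (count, percent)}``; within single-choice
    blocks the counts (including unknown) sum to ``total``.  Outcome codes
    are multi-select per report, so that block does not sum.  Percentages are
    count/total x 100, half-up rounded to one decimal.
    """

    drug: str
    total: int
    blocks: dict[str, dict[str, tuple[int, float]]]
    top_countries: list[tuple[str, int, float]]
    annual: dict[int, int] = field(default_factory=dict)


def _block(series: pd.Series, total: int, order: list[str] | None = None) -> dict:
    counts = series.fillna("unknown").replace("", "unknown").value_counts()
    if order:
        keys = [k for k in order if k in counts.index]
        keys += [k for k in counts.index if k not in keys]
    else:
        keys = list(counts.index)
    return {
        str(k): (int(counts[k]), round_half_up(100.0 * counts[k] / total)) for k in keys
    }


def descriptive_summary(analytic: AnalyticData, drug: str, top_k: int = 5) -> DescriptiveSummary:
    """Table-1-style summary for one target drug (report counting)."""
    cases = analytic.cases.loc[analytic.cases["drug"] == drug]
    if cases.empty:
        raise ValueError(f"no analytic records for drug {drug!r}")
    total = len(cases)
    blocks = {
        "sex": _block(cases["sex_norm"], total, ["female", "male", "unknown"]),
        "age_band": _block(cases["age_band"], total, list(AGE_BANDS) + ["unknown"]),
        "weight_band": _block(cases["weight_band"], total, list(WEIGHT_BANDS) + ["unknown"]),
        "occupation": _block(cases.get("occp_cod", pd.Series(index=cases.index)), total),
    }
    if "outcomes" in cases.columns:
        exploded = (
            cases["outcomes"].dropna().loc[lambda s: s != ""].str.split(",").explode()
        )
        counts = exploded.value_counts()
        blocks["outcomes"] = {
            str(k): (int(v), round_half_up(100.0 * v / total)) for k, v in counts.items()
        }
    country = cases.get("reporter_country", pd.Series(index=cases.index))
    ccounts = country.fillna("unknown").replace("", "unknown").value_counts()
    top = [
        (str(k), int(v), round_half_up(100.0 * v / total))
        for k, v in ccounts.head(top_k).items()
    ]
    annual = annual_counts(analytic, drug)
    return DescriptiveSummary(drug=drug, total=total, blocks=blocks, top_countries=top, annual=annual)


def annual_counts(analytic: AnalyticData, drug: str) -> dict[int, int]:
    """Report counts per calendar year of FDA receipt (year precision suffices)."""
    cases = analytic.cases.loc[analytic.cases["drug"] == drug]
    years = cases["report_year"].dropna()
    return {int(y): int(c) for y, c in years.value_counts().sort_index().items()}
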