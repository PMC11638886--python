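"""End-to-end orchestration: ingest -> dedup -> PS filter -> cohort ->
disproportionality -> time-to-onset, from one seeded configuration.

The pipeline consumes either an on-disk FAERS ASCII directory or the
synthetic generator, logs record counts at every stage boundary (raw ->
deduplicated -> PS-filtered -> analytic), and writes delimited text tables
shaped like a pharmacovigilance report: per-drug descriptive summaries,
annual counts, per-SOC volcano and signal tables (overall and by sex/age
stratum), TTO summaries with Weibull fits and failure types, Kaplan–Meier
step tables, and a between-drug log-rank comparison, all indexed by a JSON
run manifest carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    AnalyticData,
    SubgroupKey,
    all_pairs_2x2,
    annual_counts,
    build_analytic_dataset,
    descriptive_summary,
)
from .disproportionality import (
    MgpsPrior,
    SignalCriteria,
    fit_mgps_prior,
    screen_soc,
)
from .io import (
    FaersDataset,
    deduplicate_dataset,
    load_synonym_map,
    load_term_map,
    read_quarter,
)
from .synthetic import (
    DEFAULT_IME_TERMS,
    GeneratorConfig,
    default_config,
    default_pt_soc_map,
    default_synonym_map,
    generate_dataset,
)
from .tto import compute_tto, fit_weibull, km_curve, logrank_test, tto_summary

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "DEFAULT_BREAST_EXCLUSIONS"]

logger = logging.getLogger("pvsignal")

#: breast-related PTs removed from signal tables (kept in volcano output)
DEFAULT_BREAST_EXCLUSIONS = [
    "Breast pain",
    "Breast enlargement",
    "Gynaecomastia",
    "Galactorrhoea",
]

_REPRO_SOC = "Reproductive system and breast disorders"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one input mode is active: ``faers`` reads
    an ASCII directory, ``synthetic`` generates data from ``generator`` (or
    the default study scenario when omitted)."""

    mode: str = "synthetic"  # synthetic | faers
    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    synonym_map: dict[str, str] | str | None = None
    pt_soc_map: dict[str, str] | str | None = None
    soc: str = _REPRO_SOC
    ime_terms: list[str] | str | None = None
    exclusions: list[str] | str | None = None
    counting_unit: str = "records"
    subgroups: bool = True
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    tto_pt: str = "Erectile dysfunction"
    zero_day: str = "map_to_1"
    outdir: str = "pvsignal_out"
    seed: int = 0

    def resolve(self) -> "RunConfig":
        """Validate paths and fill scenario defaults; raises before any
        computation when a referenced file is missing."""
        if self.mode not in ("synthetic", "faers"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.mode == "faers" and (self.input_dir is None or not Path(self.input_dir).is_dir()):
            raise PipelineError(f"config: input_dir {self.input_dir!r} is not a directory")
        for attr in ("synonym_map", "pt_soc_map", "ime_terms", "exclusions"):
            v = getattr(self, attr)
            if isinstance(v, str) and not Path(v).is_file():
                raise PipelineError(f"config: {attr} path {v!r} does not exist")
        return self


def _as_map(value, default: dict, loader) -> dict:
    if value is None:
        return dict(default)
    if isinstance(value, str):
        return loader(value)
    return dict(value)


def _as_terms(value, default: list) -> list[str]:
    if value is None:
        return list(default)
    if isinstance(value, str):
        return [
            ln.strip()
            for ln in Path(value).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    return list(value)


def _config_hash(config: RunConfig) -> str:
    def _default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def _strata(subgroups: bool) -> list[SubgroupKey]:
    keys = [SubgroupKey()]
    if subgroups:
        keys += [SubgroupKey(sex=s) for s in ("female", "male")]
        keys += [SubgroupKey(age_band=b) for b in ("under45", "45to59", "over59")]
    return keys


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``outdir/manifest.json``)."""
    config = config.resolve()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "mode": config.mode,
        "stages": {},
        "outputs": [],
    }

    # --- stage: ingest ------------------------------------------------------
    try:
        if config.mode == "synthetic":
            gen = config.generator or default_config(seed=config.seed)
            dataset, ledger = generate_dataset(gen)
            manifest["ledger"] = {
                "n_injected_pairs": len(ledger.injected_pairs),
                "n_duplicates": len(ledger.duplicate_map),
                "n_surviving": len(ledger.surviving_primaryids),
            }
        else:
            dataset = read_quarter(config.input_dir)
            ledger = None
    except Exception as exc:
        raise PipelineError(f"stage ingest failed: {exc}") from exc
    manifest["stages"]["raw"] = dataset.row_counts()
    logger.info("raw counts: %s", manifest["stages"]["raw"])

    # --- stage: deduplicate -------------------------------------------------
    try:
        clean = deduplicate_dataset(dataset)
    except Exception as exc:
        raise PipelineError(f"stage deduplicate failed: {exc}") from exc
    manifest["stages"]["deduplicated"] = clean.row_counts()

    # --- stage: cohort ------------------------------------------------------
    synonyms = _as_map(config.synonym_map, default_synonym_map(), load_synonym_map)
    pt_soc = _as_map(config.pt_soc_map, default_pt_soc_map(), load_term_map)
    ime = _as_terms(config.ime_terms, DEFAULT_IME_TERMS)
    exclusions = _as_terms(config.exclusions, DEFAULT_BREAST_EXCLUSIONS)
    try:
        analytic = build_analytic_dataset(clean, synonyms, counting_unit=config.counting_unit)
    except Exception as exc:
        raise PipelineError(f"stage cohort failed: {exc}") from exc
    manifest["stages"]["analytic"] = analytic.metadata

    # --- stage: empirical-Bayes prior ---------------------------------------
    try:
        pairs = all_pairs_2x2(analytic)
        prior = fit_mgps_prior(
            pairs["a"].to_numpy(float), pairs["expected"].to_numpy(float), seed=config.seed
        )
    except Exception as exc:
        raise PipelineError(f"stage mgps_prior failed: {exc}") from exc
    manifest["mgps_prior"] = {
        "alpha1": prior.alpha1,
        "beta1": prior.beta1,
        "alpha2": prior.alpha2,
        "beta2": prior.beta2,
        "p_mix": prior.p_mix,
        "loglik": prior.loglik,
    }

    # --- stage: per-drug outputs --------------------------------------------
    present = [d for d in analytic.targets if (analytic.cases["drug"] == d).any()]
    for d in analytic.targets:
        if d not in present:
            logger.warning("target drug %s absent from data; skipping", d)
    tto_samples = {}
    for drug in present:
        try:
            summary = descriptive_summary(analytic, drug)
            rows = []
            for block, cats in summary.blocks.items():
                for cat, (cnt, pct) in cats.items():
                    rows.append({"block": block, "category": cat, "count": cnt, "percent": pct})
            for country, cnt, pct in summary.top_countries:
                rows.append({"block": "country", "category": country, "count": cnt, "percent": pct})
            manifest["outputs"].append(
                str(_write_tsv(pd.DataFrame(rows), outdir / f"descriptive_{drug}.tsv"))
            )
            ann = annual_counts(analytic, drug)
            manifest["outputs"].append(
                str(
                    _write_tsv(
                        pd.DataFrame({"year": list(ann), "reports": list(ann.values())}),
                        outdir / f"annual_{drug}.tsv",
                    )
                )
            )
            for stratum in _strata(config.subgroups):
                volcano, signals = screen_soc(
                    analytic,
                    drug,
                    pt_soc,
                    soc=config.soc,
                    exclusions=exclusions,
                    stratum=stratum,
                    prior=prior,
                    criteria=config.criteria,
                    ime_terms=ime,
                )
                label = stratum.label()
                if label == "overall":
                    manifest["outputs"].append(
                        str(_write_tsv(volcano, outdir / f"volcano_{drug}.tsv"))
                    )
                manifest["outputs"].append(
                    str(_write_tsv(signals, outdir / f"signals_{drug}_{label}.tsv"))
                )
        except Exception as exc:
            raise PipelineError(f"stage disproportionality({drug}) failed: {exc}") from exc

        # --- TTO ------------------------------------------------------------
        try:
            sample = compute_tto(analytic, drug, config.tto_pt, zero_day=config.zero_day)
            tto_samples[drug] = sample
            record: dict = {"drug": drug, "pt": config.tto_pt, **sample.exclusions}
            if sample.n:
                record.update(tto_summary(sample))
            if sample.n >= 3 and len(set(sample.days.tolist())) > 1:
                fit = fit_weibull(sample)
                record.update(
                    {
                        "weibull_scale": fit.scale,
                        "scale_lo95": fit.scale_lo95,
                        "scale_hi95": fit.scale_hi95,
                        "weibull_shape": fit.shape,
                        "shape_lo95": fit.shape_lo95,
                        "shape_hi95": fit.shape_hi95,
                        "failure_type": fit.failure_type,
                    }
                )
                curve = km_curve(sample)
                km_df = pd.DataFrame(
                    {"day": curve.times, "cumulative_incidence": curve.cumulative_incidence}
                )
                manifest["outputs"].append(str(_write_tsv(km_df, outdir / f"km_{drug}.tsv")))
            manifest.setdefault("tto", []).append(record)
        except Exception as exc:
            raise PipelineError(f"stage tto({drug}) failed: {exc}") from exc

    # --- stage: between-drug comparison -------------------------------------
    with_onsets = [d for d in present if tto_samples.get(d) is not None and tto_samples[d].n > 0]
    if len(with_onsets) >= 2:
        a, b = with_onsets[:2]
        stat, p = logrank_test(tto_samples[a], tto_samples[b])
        manifest["logrank"] = {"drugs": [a, b], "pt": config.tto_pt, "statistic": stat, "p": p}

    tto_df = pd.DataFrame(manifest.get("tto", []))
    if not tto_df.empty:
        manifest["outputs"].append(str(_write_tsv(tto_df, outdir / "tto_summary.tsv")))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
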