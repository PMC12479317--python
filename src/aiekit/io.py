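"""Readers, writers, run configuration and batch orchestration.

A run is described by a YAML configuration naming the cohort table, the
outcome / treatment / confounder columns, a study template (``custom``,
``phewas`` or ``gwas_lite``), the estimator and learners, the positivity
threshold, and optional sieve-variance settings.  ``run_study`` expands the
template into estimand components, prunes, estimates, applies joint and
delta-method post-estimands where requested, adjusts p-values within the
declared FDR scope, and returns (and optionally writes) a results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimands import Contrast, EstimandSpec, TreatmentLevels
from .inference import allelic_difference, bh_adjust, joint_test, positivity_prune
from .nuisance import LearnerSpec
from .sieve import compute_grm, corrected_inference, read_grm, sieve_curve
from .targeting import EmptySupportError, estimate_components

logger = logging.getLogger("aiekit")

__all__ = [
    "SchemaError",
    "UnsupportedSiteError",
    "CohortSchema",
    "read_cohort",
    "read_genotypes_vcf",
    "read_dosage_tsv",
    "load_config",
    "run_study",
    "write_results",
]


class SchemaError(ValueError):
    pass


class UnsupportedSiteError(ValueError):
    pass


@dataclass
class CohortSchema:
    outcome: str
    outcome_family: str = "gaussian"
    treatments: Mapping[str, Sequence | None] = field(default_factory=dict)
    confounders: tuple = ()
    covariates: tuple = ()
    extra_outcomes: tuple = ()  # additional outcome columns (phewas)

    def columns(self) -> list[str]:
        return (
            [self.outcome]
            + [c for c in self.extra_outcomes if c != self.outcome]
            + list(self.treatments)
            + list(self.confounders)
            + list(self.covariates)
        )


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_cohort(path, schema: CohortSchema) -> tuple[pd.DataFrame, dict]:
    """Read a delimited cohort table, type the declared columns, and apply
    listwise deletion over them.  Returns (table, report)."""
    df = _read_delimited(path)
    missing = [c for c in schema.columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing declared column(s): {missing}")
    df = df[schema.columns()].copy()
    for out_col in [schema.outcome, *schema.extra_outcomes]:
        df[out_col] = pd.to_numeric(df[out_col], errors="coerce")
        if schema.outcome_family == "binomial":
            bad = ~df[out_col].isin([0, 1]) & df[out_col].notna()
            df.loc[bad, out_col] = np.nan
    for c in list(schema.confounders) + list(schema.covariates):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for t, levels in schema.treatments.items():
        if levels is not None:
            df.loc[~df[t].isin(levels), t] = np.nan
    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, n_before)
    report = {"n_read": n_before, "n_dropped": n_dropped, "n_kept": len(df)}
    return df, report


def read_genotypes_vcf(
    path, variant_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read biallelic genotypes from a VCF.

    Returns ``(categories, dosages)`` indexed by sample id: categories are
    allele-string genotypes (e.g. "TT", "TC", "CC", heterozygote spelled
    ref-then-alt); dosages count alternate alleles in {0, 1, 2}.  Phased
    and unphased calls are treated identically; missing calls become NaN.
    Requesting a multi-allelic site raises UnsupportedSiteError.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cats: dict[str, list] = {}
    doses: dict[str, list] = {}
    wanted = set(variant_ids) if variant_ids is not None else None
    for record in vcf:
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if len(record.ALT) != 1:
            raise UnsupportedSiteError(
                f"site {vid} is not biallelic (ALT={record.ALT})"
            )
        ref, alt = record.REF, record.ALT[0]
        names = {0: ref + ref, 1: ref + alt, 2: alt + alt}
        cat_col, dose_col = [], []
        for g in record.genotypes:  # [allele0, allele1, phased]
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                cat_col.append(np.nan)
                dose_col.append(np.nan)
            else:
                d = int(a > 0) + int(b > 0)
                cat_col.append(names[d])
                dose_col.append(d)
        cats[vid] = cat_col
        doses[vid] = dose_col
    if wanted is not None:
        absent = wanted - set(cats)
        if absent:
            raise SchemaError(f"variant id(s) not found in VCF: {sorted(absent)}")
    idx = pd.Index(samples, name="sample")
    return pd.DataFrame(cats, index=idx), pd.DataFrame(doses, index=idx)


def read_dosage_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix import (individuals x variants, first column = id)."""
    df = _read_delimited(path)
    ids = df.iloc[:, 0].to_numpy()
    return ids, df.iloc[:, 1:].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# run configuration and batch orchestration
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "estimator": "wtmle",
    "k_folds": 3,
    "positivity_threshold": 0.01,
    "positivity_per_treatment": False,
    "alpha": 0.05,
    "fdr_scope": "batch",
    "joint_tests": False,
    "allelic_difference": False,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key, value in _DEFAULTS.items():
        cfg.setdefault(key, value)
    thr = cfg["positivity_threshold"]
    if not 0 <= thr <= 0.5:
        raise SchemaError(f"positivity threshold must be in [0, 0.5], got {thr}")
    return cfg


def _learner_from_config(entry) -> LearnerSpec:
    if entry is None:
        return LearnerSpec("glm")
    if isinstance(entry, str):
        return LearnerSpec(entry)
    entry = dict(entry)
    name = entry.pop("name")
    base = tuple(_learner_from_config(b) for b in entry.pop("base_learners", ()))
    selection = entry.pop("selection", "convex")
    return LearnerSpec(name, params=entry, base_learners=base, selection=selection)


def _schema_from_config(cfg: dict) -> CohortSchema:
    treatments = {}
    for name, sub in (cfg.get("treatments") or {}).items():
        treatments[name] = None if sub is None else sub.get("levels")
    out = cfg["outcome"]
    study = cfg.get("study") or {}
    return CohortSchema(
        outcome=out["name"],
        outcome_family=out.get("family", "gaussian"),
        treatments=treatments,
        confounders=tuple(cfg.get("confounders", ())),
        covariates=tuple(cfg.get("covariates", ())),
        extra_outcomes=tuple(study.get("outcomes", ())),
    )


def _treatment_levels(data: pd.DataFrame, name: str, declared) -> TreatmentLevels:
    if declared is not None:
        return TreatmentLevels(name, tuple(declared))
    return TreatmentLevels(name, tuple(sorted(pd.unique(data[name]))))


def _component_specs(cfg: dict, schema: CohortSchema, data: pd.DataFrame):
    """Expand the study template into per-component estimand specs,
    grouped so that components sharing (outcome, treatments) can share
    nuisance fits.  Yields (group_key, [specs])."""
    study = cfg.get("study", {"template": "custom"})
    template = study.get("template", "custom")
    fam = schema.outcome_family

    def variant_components(outcome, variant):
        tl = _treatment_levels(data, variant, schema.treatments.get(variant))
        specs = []
        for base, target in tl.adjacent_contrasts():
            specs.append(
                EstimandSpec(
                    kind="ate", outcome=outcome, treatments=(variant,),
                    contrast=Contrast(pairs=((base, target),)),
                    confounders=schema.confounders, covariates=schema.covariates,
                    outcome_family=fam, treatment_levels={variant: tl},
                )
            )
        return specs

    if template == "phewas":
        variant = study["variant"]
        for outcome in study["outcomes"]:
            yield (outcome, (variant,)), variant_components(outcome, variant)
    elif template == "gwas_lite":
        outcome = study.get("outcome", schema.outcome)
        for variant in study["variants"]:
            yield (outcome, (variant,)), variant_components(outcome, variant)
    elif template == "custom":
        for ent in study["estimands"]:
            treatments = tuple(ent["treatments"])
            levels = {
                t: _treatment_levels(data, t, schema.treatments.get(t))
                for t in treatments
            }
            spec = EstimandSpec(
                kind=ent["kind"], outcome=ent.get("outcome", schema.outcome),
                treatments=treatments,
                contrast=Contrast(
                    pairs=tuple(tuple(p) for p in ent["contrast"])
                ),
                confounders=schema.confounders, covariates=schema.covariates,
                outcome_family=fam, treatment_levels=levels,
            )
            yield (spec.outcome, treatments), [spec]
    else:
        raise SchemaError(f"unknown study template {template!r}")


def run_study(cfg: dict | str, data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Execute a full batch run from a configuration mapping or YAML path.

    Per-estimand failures are recorded as rows with a non-"ok" status
    rather than aborting the batch.  Deterministic given (config, seed).
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    schema = _schema_from_config(cfg)
    if data is None:
        data, report = read_cohort(cfg["cohort"], schema)
        logger.info("cohort: %s", report)

    q_learner = _learner_from_config((cfg.get("learners") or {}).get("q"))
    g_learner = _learner_from_config((cfg.get("learners") or {}).get("g"))
    estimator = cfg["estimator"]
    alpha = cfg["alpha"]
    seed = cfg["seed"]
    threshold = cfg["positivity_threshold"]

    rows = []
    records = []
    for (outcome, treatments), specs in _component_specs(cfg, schema, data):
        prune_report, kept = positivity_prune(
            data, specs, threshold,
            per_treatment=cfg["positivity_per_treatment"],
        )
        for label in prune_report.dropped:
            rows.append(
                {"estimand": label, "estimator": estimator, "status": "pruned"}
            )
        if not kept:
            continue
        try:
            recs = estimate_components(
                data, kept, estimator=estimator, q_learner=q_learner,
                g_learner=g_learner, alpha=alpha, seed=seed,
                k_folds=cfg["k_folds"],
            )
        except EmptySupportError as exc:
            for spec in kept:
                rows.append(
                    {"estimand": spec.label(), "estimator": estimator,
                     "status": f"empty-support: {exc}"}
                )
            continue
        except Exception as exc:  # noqa: BLE001 - per-row failure policy
            logger.warning("estimation failed for %s: %s", outcome, exc)
            for spec in kept:
                rows.append(
                    {"estimand": spec.label(), "estimator": estimator,
                     "status": f"error: {exc}"}
                )
            continue
        for rec in recs:
            records.append(rec)
            rows.append(_row_from_record(rec))
        if len(recs) >= 2 and cfg["joint_tests"]:
            jt = joint_test(
                [r.psi for r in recs], np.vstack([r.eif for r in recs])
            )
            rows.append(
                {"estimand": f"joint:{outcome}~{'*'.join(treatments)}",
                 "estimator": estimator, "psi": np.nan, "n": jt.n,
                 "pvalue": jt.pvalue, "status": "ok",
                 "notes": f"hotelling_t2={jt.t2:.6g}"}
            )
        if len(recs) == 2 and cfg["allelic_difference"]:
            value, eif, sigma2, ci, p = allelic_difference(
                [recs[0].psi, recs[1].psi],
                np.vstack([recs[0].eif, recs[1].eif]), alpha=alpha,
            )
            rows.append(
                {"estimand": f"allelic_diff:{outcome}~{'*'.join(treatments)}",
                 "estimator": estimator, "psi": value,
                 "se": float(np.sqrt(sigma2 / len(eif))), "n": len(eif),
                 "ci_low": ci[0], "ci_high": ci[1], "pvalue": p, "status": "ok"}
            )

    results = pd.DataFrame(rows)
    if "pvalue" in results.columns:
        mask = results["pvalue"].notna()
        adjusted = np.full(len(results), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = bh_adjust(results.loc[mask, "pvalue"])
        results["p_adjusted"] = adjusted

    sieve_cfg = cfg.get("sieve") or {}
    if sieve_cfg.get("enabled"):
        results = _apply_sieve(cfg, sieve_cfg, results, records, data)

    out_dir = cfg.get("output_dir")
    if out_dir:
        write_results(results, Path(out_dir) / "results.tsv")
    return results


def _apply_sieve(cfg, sieve_cfg, results, records, data):
    """SVP-correct records whose raw p-value is under the trigger."""
    trigger = sieve_cfg.get("p_trigger", 0.07)
    if "grm_prefix" in sieve_cfg:
        grm = read_grm(sieve_cfg["grm_prefix"])
    else:
        ids, dosages = read_dosage_tsv(sieve_cfg["dosages"])
        grm = compute_grm(dosages, ids=ids)
    taus = sieve_cfg.get("taus")
    taus = None if taus is None else np.asarray(taus, dtype=float)
    by_label = {r.estimand: r for r in records}
    for col in ("svp_sigma2", "svp_tau0", "svp_pvalue"):
        results[col] = np.nan
    for i, row in results.iterrows():
        rec = by_label.get(row.get("estimand"))
        if rec is None or not (row.get("pvalue", 1.0) < trigger):
            continue
        curve = sieve_curve(rec.eif, grm, taus=taus)
        corrected = corrected_inference(rec, curve)
        results.loc[i, "svp_sigma2"] = corrected.sigma2
        results.loc[i, "svp_tau0"] = curve.tau0
        results.loc[i, "svp_pvalue"] = corrected.pvalue
    return results


def _row_from_record(rec) -> dict:
    return {
        "estimand": rec.estimand,
        "estimator": rec.estimator,
        "psi": rec.psi,
        "se": rec.se,
        "n": rec.n,
        "ci_low": rec.ci[0],
        "ci_high": rec.ci[1],
        "pvalue": rec.pvalue,
        "status": "ok" if rec.notes.get("converged", True) else "not-converged",
    }


def write_results(results: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d result rows to %s", len(results), path)
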