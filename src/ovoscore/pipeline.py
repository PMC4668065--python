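"""End-to-end orchestration: tables in (or simulated), results bundle out.

Stage order mirrors the analysis: score oocytes, grade embryos, summarize,
fit the embryo-level GEE models (univariate per characteristic, the
multivariate six-characteristic model, and the TOS models, each unadjusted
and age-adjusted), fit the cycle-level pregnancy / mean-grade / tertile
models, and finish with the paired ROC comparison of PTOS against the mean
transferred-embryo grade (unweighted and weighted by embryos transferred,
overall and restricted to good-quality transfers).

Every artifact is a CSV (models are written in a tidy Table-3/4-style
layout) plus a JSON manifest carrying the config hash, seed, package
versions and per-stage status.  A fixed seed makes the bundle
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association_models, embryo_grading, oocyte_scoring, roc_analysis
from .association_models import ModelSpec
from .oocyte_scoring import ValidationError
from .synthetic_data import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

CHARACTERISTICS = [
    ("morphology_score", "Overall morphology"),
    ("size_score", "Size of oocyte"),
    ("cytoplasm_score", "Patterns of cytoplasm"),
    ("pvs_score", "Size of PVS and presence of granules"),
    ("zp_score", "Thickness of zona pellucida"),
    ("pb_score", "Morphology of polar body"),
]


@dataclass
class RunConfig:
    """Either input CSV paths or a synthetic cohort config; not both."""

    out_dir: str | Path
    oocyte_table: str | Path | None = None
    embryo_table: str | Path | None = None
    cycle_table: str | Path | None = None
    synthetic: CohortConfig | None = None
    seed: int | None = None
    transferred_only_ptos: bool = False
    weighting: bool = True
    good_quality_mode: str = "any"
    embryo_aggregation: str = "mean"  # or "max"
    write_plot: bool = True

    def __post_init__(self):
        has_paths = self.oocyte_table is not None
        if has_paths == (self.synthetic is not None):
            raise ValidationError(
                "exactly one of input tables or a synthetic config must be supplied"
            )
        if self.synthetic is not None and self.seed is not None:
            self.synthetic = self.synthetic.replace(seed=self.seed)


def _config_hash(cfg: RunConfig) -> str:
    payload = {k: v for k, v in dataclasses.asdict(cfg).items()}
    payload["out_dir"] = None  # output location does not identify a run
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(cfg: RunConfig) -> SyntheticCohort:
    if cfg.synthetic is not None:
        return generate_cohort(cfg.synthetic)
    oocytes = oocyte_scoring.read_oocyte_table(cfg.oocyte_table)
    embryos = embryo_grading.read_embryo_table(cfg.embryo_table)
    cycles = pd.read_csv(cfg.cycle_table, dtype={"patient_id": str}) \
        if cfg.cycle_table else None
    return SyntheticCohort(oocytes, embryos, cycles, {"source": "files"})


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed if cfg.seed is not None else (
            cfg.synthetic.seed if cfg.synthetic else None),
        "versions": {"ovoscore": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {}, "artifacts": [],
    }
    stages = manifest["stages"]

    def artifact(name):
        manifest["artifacts"].append(name)

    cohort = _load_tables(cfg)
    if len(cohort.oocytes) == 0:
        raise ValidationError("empty patient set: no oocytes to analyse")

    # --- stage: score ---------------------------------------------------
    scored = cohort.oocytes
    if "tos" not in scored.columns:
        scored = oocyte_scoring.score_oocyte_table(scored)
    _write_csv(scored, out / "scored_oocytes.csv")
    artifact("scored_oocytes.csv")
    stages["score"] = "ok"

    # --- stage: grade ---------------------------------------------------
    embryos = cohort.embryos
    if "grade" not in embryos.columns:
        embryos = embryo_grading.grade_embryo_table(embryos)
    _write_csv(embryos, out / "embryos_graded.csv")
    artifact("embryos_graded.csv")
    stages["grade"] = "ok"

    # --- stage: cycle table ----------------------------------------------
    if cohort.cycles is not None and "ptos" in getattr(cohort.cycles, "columns", []):
        cycles = cohort.cycles
    else:
        scored_t = scored.merge(
            embryos[["patient_id", "oocyte_id", "transferred"]],
            on=["patient_id", "oocyte_id"], how="left")
        ptos = oocyte_scoring.ptos_from_scored_table(
            scored_t, transferred_only=cfg.transferred_only_ptos)
        cycles = cohort.cycles.merge(ptos, on="patient_id") \
            if cohort.cycles is not None else ptos
    _write_csv(cycles, out / "cycles.csv")
    artifact("cycles.csv")
    stages["cycles"] = "ok"

    # --- stage: descriptive marginals ------------------------------------
    marg = pd.DataFrame({
        label: scored[col].value_counts(normalize=True)
        for col, label in CHARACTERISTICS
    }).T.reindex(columns=[-1, 0, 1]).fillna(0.0).reset_index(names="characteristic")
    _write_csv(marg, out / "oocyte_marginals.csv")
    artifact("oocyte_marginals.csv")
    stages["summaries"] = "ok"

    merged = embryos.merge(scored, on=["patient_id", "oocyte_id"], suffixes=("", "_ooc"))
    merged["eight_cell"] = merged["eight_cell_flag"].astype(int)
    merged = merged.merge(cycles[["patient_id", "age"]], on="patient_id", how="left") \
        if "age" in cycles.columns else merged.assign(age=np.nan)

    # --- stage: embryo-level GEE models -----------------------------------
    try:
        rows = []
        for col, label in CHARACTERISTICS:
            for adjust in (False, True):
                if adjust and merged["age"].isna().all():
                    continue
                spec = ModelSpec(outcome="eight_cell", predictors=[col],
                                 categorical=[col], adjust_age=adjust)
                fit = association_models.fit_gee_binary(merged, spec)
                frame = fit.to_frame()
                frame["characteristic"] = label
                rows.append(frame)
        univariate = pd.concat(rows, ignore_index=True)
        _write_csv(univariate, out / "gee_univariate_8cell.csv")
        artifact("gee_univariate_8cell.csv")

        cols = [c for c, _ in CHARACTERISTICS]
        multi = association_models.fit_gee_binary(merged, ModelSpec(
            outcome="eight_cell", predictors=cols, categorical=cols,
            adjust_age=not merged["age"].isna().all()))
        _write_csv(multi.to_frame(), out / "gee_multivariate_8cell.csv")
        artifact("gee_multivariate_8cell.csv")

        tos_bin = association_models.fit_gee_binary(merged, ModelSpec(
            outcome="eight_cell", predictors=["tos"],
            adjust_age=not merged["age"].isna().all()))
        tos_ord = association_models.fit_gee_ordinal(merged, ModelSpec(
            outcome="grade", predictors=["tos"], adjust_age=False))
        _write_csv(pd.concat([tos_bin.to_frame(), tos_ord.to_frame()],
                             ignore_index=True), out / "gee_tos_models.csv")
        artifact("gee_tos_models.csv")
        stages["gee"] = "ok"
    except Exception as exc:  # pragma: no cover - defensive stage isolation
        stages["gee"] = f"failed: {exc}"

    # --- stage: cycle-level models ----------------------------------------
    cycle_ok = {"pregnancy", "ptos", "age"} <= set(cycles.columns)
    if cycle_ok:
        try:
            fits = [association_models.fit_pregnancy_logistic(cycles, adjust_age=True)]
            if "all_transferred_eight_cell" in cycles.columns and \
                    cycles["all_transferred_eight_cell"].astype(bool).any():
                try:
                    fits.append(association_models.fit_pregnancy_logistic(
                        cycles, adjust_age=True, eight_cell_transfers_only=True))
                except association_models.DegenerateOutcomeError:
                    pass
            preg = pd.concat([f.to_frame().assign(subset=f.extras["subset"])
                              for f in fits], ignore_index=True)
            _write_csv(preg, out / "pregnancy_models.csv")
            artifact("pregnancy_models.csv")

            lin = association_models.fit_mean_grade_linear(cycles)
            _write_csv(lin.to_frame(), out / "mean_grade_linear.csv")
            artifact("mean_grade_linear.csv")

            tert = association_models.tertile_implantation(cycles)
            rates = tert.rates.copy()
            rates["p_overall"] = tert.p_overall
            _write_csv(rates, out / "tertile_implantation.csv")
            artifact("tertile_implantation.csv")
            stages["cycle_models"] = "ok"
        except Exception as exc:
            stages["cycle_models"] = f"failed: {exc}"
    else:
        stages["cycle_models"] = "skipped: no cycle outcomes"

    # --- stage: ROC comparison --------------------------------------------
    grade_col = ("mean_grade_transferred" if cfg.embryo_aggregation == "mean"
                 else "max_grade_transferred")
    roc_ok = cycle_ok and grade_col in cycles.columns
    if roc_ok:
        try:
            rows = []
            for restricted in (False, True):
                table = (roc_analysis.restrict_good_quality(
                            cycles, embryos, mode=cfg.good_quality_mode)
                         if restricted else cycles)
                for weighted in ([False, True] if cfg.weighting else [False]):
                    w = table["n_transferred"].to_numpy(float) if weighted else None
                    inp_a = roc_analysis.RocInput.from_arrays(
                        table["ptos"], table["pregnancy"], w)
                    inp_b = roc_analysis.RocInput.from_arrays(
                        table[grade_col], table["pregnancy"], w)
                    cmp_ = roc_analysis.compare_auc_paired(inp_a, inp_b)
                    rows.append({
                        "restricted_good_quality": restricted, "weighted": weighted,
                        "n_cycles": len(table),
                        "auc_oocyte_score": cmp_.auc_a, "se_oocyte_score": cmp_.se_a,
                        "auc_embryo_grade": cmp_.auc_b, "se_embryo_grade": cmp_.se_b,
                        "z": cmp_.z, "p": cmp_.p,
                    })
                    if not restricted and not weighted and cfg.write_plot:
                        roc_analysis.plot_roc_comparison(
                            inp_a, inp_b, out / "roc_comparison.png")
                        artifact("roc_comparison.png")
            _write_csv(pd.DataFrame(rows), out / "roc_comparison.csv")
            artifact("roc_comparison.csv")
            stages["roc"] = "ok"
        except Exception as exc:
            stages["roc"] = f"failed: {exc}"
    else:
        stages["roc"] = "skipped: no cycle outcomes"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
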