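"""Seeded hierarchical cohort generator: patients -> oocytes -> embryos ->
transfer -> pregnancy.

The generator emulates the structure of a ~94-patient ICSI cohort in which
each patient contributes >= 2 mature oocytes, every oocyte is scored on six
morphologic parameters (TOS), each oocyte yields a day-3 embryo whose
cell count and fragmentation are graded 1-5, the best-graded embryos are
transferred, and the cycle ends in clinical pregnancy or not.

Calibration defaults (age 36.6 +/- 7.3 y; oocyte yield 7.97 +/- 5.76
truncated at 2; per-parameter score marginals; odds ratios 1.12 per TOS
point for the >=8-cell outcome, 1.19 for the ordinal grade, 1.58 per PTOS
point for pregnancy; 31% pregnancy prevalence; 2.53 +/- 1.06 embryos
transferred in [1, 7]) reproduce the study conditions the analysis
pipeline assumes.

Generative mechanics
--------------------
* The six parameter levels share a per-oocyte latent quality (Gaussian
  copula, loading `quality_loading`), itself loaded on a per-patient
  latent (`patient_loading`), so parameters correlate within oocyte and
  oocytes within patient while each parameter keeps its exact configured
  marginal.
* Diameter and ZP thickness are drawn uniformly inside the micron band of
  their drawn score level, so measured scores reproduce the drawn levels.
* Embryo outcomes are drawn from *marginal* models: the >=8-cell flag from
  logit P = b0 + ln(or_tos_8cell) * TOS + age_slope * (age - age_mean), the
  grade from a proportional-odds cumulative logit with slope
  ln(or_tos_grade) * TOS.  Within-patient dependence is induced through a
  Gaussian copula on the outcome draws (knob `cluster_sd`), not through a
  logit-scale random intercept, so the configured odds ratios hold exactly
  as the population-averaged effects a GEE estimates.  The two outcomes
  share one uniform per embryo (comonotone coupling: good embryos are good
  on both scales).
* Cell count and fragmentation are back-filled consistently with the drawn
  grade and >=8-cell flag, so re-running the grading cascade on the table
  regenerates the drawn grade exactly.  The one infeasible combination
  (grade 5 with < 8 cells) is resolved by promoting the embryo to 8 cells;
  default calibration makes this combination essentially impossible and
  occurrences are counted in the ground truth.
* Intercepts b0 (eight-cell) and gamma0 (pregnancy) are calibrated by
  root-finding so the mean predicted probability over the realized
  covariates equals the configured base rate / prevalence target.
* Gestational sacs: 0 if not pregnant, else 1 + Binomial(transferred - 1,
  p) with p increasing in PTOS (sanity-level calibration only).

Identical config + seed regenerates every table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit

from . import embryo_grading, oocyte_scoring
from .embryo_grading import _grade_vectorized

__all__ = ["CohortConfig", "SyntheticCohort", "ConfigurationError",
           "generate_cohort", "summarize_cohort"]


class ConfigurationError(ValueError):
    """Infeasible or inconsistent generator configuration."""


#: per-parameter marginal probabilities over scores (-1, 0, +1)
DEFAULT_MARGINALS = {
    "morphology": (0.237, 0.409, 0.354),
    "size": (0.221, 0.364, 0.416),
    "cytoplasm": (0.679, 0.263, 0.059),
    "pvs": (0.650, 0.207, 0.143),
    "zp": (0.147, 0.322, 0.532),
    "pb": (0.301, 0.315, 0.385),
}

#: micron bands per size score: (-1 low, -1 high split), 0 bands, +1 band
_SIZE_BANDS = {-1: ((104.0, 119.9), (160.1, 176.0)),
               0: ((120.0, 130.0), (150.0, 160.0)),
               1: ((130.1, 149.9),)}
_ZP_BANDS = {-1: ((4.0, 9.9), (20.1, 26.0)),
             0: ((10.0, 12.0), (18.0, 20.0)),
             1: ((12.1, 17.9),)}

#: day-3 cell-count distribution among >=8-cell embryos (8/10/12 cells)
_EIGHT_CELL_COUNTS = np.array([8, 10, 12])
_EIGHT_CELL_PROBS = np.array([343, 29, 11]) / 383.0


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_patients: int = 94
    seed: int = 0
    age_mean: float = 36.6
    age_sd: float = 7.3
    age_range: tuple[float, float] = (18.0, 52.0)
    yield_mean: float = 7.97
    yield_sd: float = 5.76
    category_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    or_tos_8cell: float = 1.12
    or_tos_grade: float = 1.19
    or_ptos_pregnancy: float = 1.58
    pregnancy_prevalence_target: float = 0.31
    eight_cell_base_rate: float = 0.645     # 383/594 embryos reached 8 cells
    grade_cutpoints: tuple[float, ...] = (-2.05, -1.06, -0.20, 0.79)
    transfer_mean: float = 2.53
    transfer_sd: float = 1.06
    transfer_range: tuple[int, int] = (1, 7)
    cluster_sd: float = 0.5          # latent patient component of outcome copula
    age_slope: float = -0.03         # log-odds of >=8 cells per year of age
    pregnancy_age_slope: float = -0.05
    quality_loading: float = 0.5     # within-oocyte correlation of the six parameters
    patient_loading: float = 0.3     # within-patient correlation of oocyte quality
    yield_quality_loading: float = 0.0  # optional yield/quality correlation, off
    implant_base: float = -1.5       # extra-sac model intercept (logit)
    implant_slope: float = 0.4       # extra-sac log-odds per PTOS point

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        for name, probs in self.category_marginals.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
                raise ConfigurationError(f"marginals for {name!r} must be 3 probabilities")
            if abs(p.sum() - 1.0) > 0.02:
                raise ConfigurationError(f"marginals for {name!r} must sum to 1 (got {p.sum()})")
        for name in ("or_tos_8cell", "or_tos_grade", "or_ptos_pregnancy"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive odds ratio")
        if not 0.0 < self.pregnancy_prevalence_target < 1.0:
            raise ConfigurationError("pregnancy_prevalence_target must lie in (0, 1)")
        lo, hi = self.transfer_range
        if not (1 <= lo <= hi <= 7):
            raise ConfigurationError("transfer_range must lie within [1, 7]")
        if not np.all(np.diff(self.grade_cutpoints) > 0) or len(self.grade_cutpoints) != 4:
            raise ConfigurationError("grade_cutpoints must be 4 increasing values")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("age_range", "transfer_range", "grade_cutpoints"):
            if key in d:
                d[key] = tuple(d[key])
        if "category_marginals" in d:
            d["category_marginals"] = {
                k: tuple(v) for k, v in d["category_marginals"].items()
            }
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticCohort:
    """The three generated tables plus the latent ground truth."""

    oocytes: pd.DataFrame
    embryos: pd.DataFrame
    cycles: pd.DataFrame
    ground_truth: dict


def _empty_cohort(config: CohortConfig) -> SyntheticCohort:
    oocytes = pd.DataFrame(
        columns=oocyte_scoring.OOCYTE_COLUMNS + oocyte_scoring.SCORE_COLUMNS)
    embryos = pd.DataFrame(
        columns=embryo_grading.EMBRYO_COLUMNS + ["grade", "eight_cell_flag"])
    cycles = pd.DataFrame(columns=_CYCLE_COLUMNS)
    return SyntheticCohort(oocytes, embryos, cycles,
                           {"config": dataclasses.asdict(config)})


_CYCLE_COLUMNS = [
    "patient_id", "age", "n_oocytes", "ptos", "n_transferred",
    "mean_grade_available", "mean_grade_transferred", "max_grade_transferred",
    "all_transferred_eight_cell", "sacs", "pregnancy",
]


def _draw_yields(rng, n, mean, sd) -> np.ndarray:
    """Overdispersed oocyte counts, negative binomial truncated at >= 2."""
    var = sd**2
    if var <= mean:  # fall back to Poisson when not overdispersed
        draw = lambda size: rng.poisson(mean, size)
    else:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        draw = lambda size: rng.negative_binomial(r, p, size)
    out = draw(n)
    for _ in range(1000):
        low = out < 2
        if not low.any():
            return out.astype(int)
        out[low] = draw(int(low.sum()))
    raise ConfigurationError("could not draw oocyte yields >= 2")


def _levels_from_uniform(u: np.ndarray, marginals) -> np.ndarray:
    """Map copula uniforms to scores -1/0/+1: low quality -> worst."""
    p = np.asarray(marginals, dtype=float)
    p = p / p.sum()
    return np.select([u < p[0], u < p[0] + p[1]], [-1, 0], default=1)


def _microns_from_level(rng, levels: np.ndarray, bands) -> np.ndarray:
    out = np.empty(levels.shape, dtype=float)
    for lev, intervals in bands.items():
        mask = levels == lev
        k = int(mask.sum())
        if k == 0:
            continue
        iv = np.array(intervals)
        side = rng.integers(0, len(iv), size=k)
        lo, hi = iv[side, 0], iv[side, 1]
        out[mask] = rng.uniform(lo, hi)
    return np.round(out, 2)


def _calibrate_intercept(offset: np.ndarray, target: float) -> float:
    """Solve mean(expit(c + offset)) = target for c."""
    f = lambda c: expit(c + offset).mean() - target
    return float(optimize.brentq(f, -30.0, 30.0, xtol=1e-10))


def _clustered_uniforms(rng, patient_idx, n, cluster_sd) -> np.ndarray:
    """U(0,1) margins with exchangeable within-patient Gaussian dependence."""
    n_patients = patient_idx.max() + 1 if n else 0
    z_p = rng.normal(size=n_patients)
    eps = rng.normal(size=n)
    z = (cluster_sd * z_p[patient_idx] + eps) / np.sqrt(1.0 + cluster_sd**2)
    return stats.norm.cdf(z)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one seeded cohort (see module docstring for the mechanics)."""
    config.validate()
    if config.n_patients == 0:
        return _empty_cohort(config)
    rng = np.random.default_rng(config.seed)

    # ---- patients -----------------------------------------------------
    n_pat = config.n_patients
    patient_ids = np.array([f"P{i:04d}" for i in range(n_pat)])
    a = (config.age_range[0] - config.age_mean) / config.age_sd
    b = (config.age_range[1] - config.age_mean) / config.age_sd
    ages = np.round(stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n_pat,
        random_state=rng), 1)
    yields = _draw_yields(rng, n_pat, config.yield_mean, config.yield_sd)

    # ---- oocytes ------------------------------------------------------
    n_ooc = int(yields.sum())
    pidx = np.repeat(np.arange(n_pat), yields)
    ooc_num = np.concatenate([np.arange(1, k + 1) for k in yields])

    z_patient = rng.normal(size=n_pat)
    eta = rng.normal(size=n_ooc)
    pl = config.patient_loading
    quality = pl * z_patient[pidx] + np.sqrt(max(0.0, 1 - pl**2)) * eta
    if config.yield_quality_loading:
        y_std = (yields - yields.mean()) / (yields.std() or 1.0)
        quality = quality + config.yield_quality_loading * y_std[pidx]

    ql = config.quality_loading
    levels = {}
    for name in ("morphology", "size", "cytoplasm", "pvs", "zp", "pb"):
        z = ql * quality + np.sqrt(max(0.0, 1 - ql**2)) * rng.normal(size=n_ooc)
        levels[name] = _levels_from_uniform(
            stats.norm.cdf(z), config.category_marginals[name])
    diameter = _microns_from_level(rng, levels["size"], _SIZE_BANDS)
    zp_um = _microns_from_level(rng, levels["zp"], _ZP_BANDS)

    oocytes = pd.DataFrame({
        "patient_id": patient_ids[pidx],
        "oocyte_id": [f"O{j:03d}" for j in ooc_num],
        "morphology": levels["morphology"], "cytoplasm": levels["cytoplasm"],
        "pvs": levels["pvs"], "pb": levels["pb"],
        "diameter_um": diameter, "zp_um": zp_um,
    })
    oocytes = oocyte_scoring.score_oocyte_table(oocytes)
    tos = oocytes["tos"].to_numpy()
    ptos_patient = np.array([tos[pidx == i].mean() for i in range(n_pat)])

    # ---- embryo outcomes (marginal models + outcome copula) -----------
    u_out = _clustered_uniforms(rng, pidx, n_ooc, config.cluster_sd)
    offset8 = (np.log(config.or_tos_8cell) * tos
               + config.age_slope * (ages[pidx] - config.age_mean))
    b0 = _calibrate_intercept(offset8, config.eight_cell_base_rate)
    p8 = expit(b0 + offset8)
    eight = u_out > 1.0 - p8

    slope_g = np.log(config.or_tos_grade)
    grade = np.ones(n_ooc, dtype=int)
    for k, cut in enumerate(config.grade_cutpoints):  # P(grade >= k+2)
        p_ge = expit(slope_g * tos - cut)
        grade += (u_out > 1.0 - p_ge).astype(int)
    coerced = int(((grade == 5) & ~eight).sum())
    eight |= grade == 5

    # ---- back-fill cell count and fragmentation -----------------------
    cells = np.empty(n_ooc, dtype=int)
    frag = np.empty(n_ooc, dtype=float)
    m8 = eight
    cells[m8] = rng.choice(_EIGHT_CELL_COUNTS, size=int(m8.sum()),
                           p=_EIGHT_CELL_PROBS)
    m = ~m8 & (grade >= 3)
    cells[m] = rng.choice([6, 7], size=int(m.sum()), p=[0.45, 0.55])
    m = ~m8 & (grade == 2)
    cells[m] = rng.choice([4, 5, 6, 7], size=int(m.sum()), p=[0.3, 0.3, 0.2, 0.2])
    m = ~m8 & (grade == 1)
    cells[m] = rng.choice([2, 3, 4, 5, 6, 7], size=int(m.sum()),
                          p=[0.15, 0.2, 0.2, 0.15, 0.15, 0.15])
    frag_bands = {5: (0.0, 4.9), 4: (0.1, 4.9), 3: (5.5, 19.9),
                  2: (20.5, 39.9), 1: (41.0, 95.0)}
    for g, (lo, hi) in frag_bands.items():
        mask = grade == g
        frag[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), 1)
    # under the cascade, grade 4 with >= 8 cells requires exactly 5% frag
    frag[(grade == 4) & m8] = 5.0
    regraded = _grade_vectorized(cells, frag)
    if not np.array_equal(regraded, grade):  # pragma: no cover - internal check
        raise RuntimeError("generator produced cells/fragmentation inconsistent "
                           "with the grading cascade")

    # ---- transfer selection -------------------------------------------
    n_transfer = np.clip(
        np.rint(rng.normal(config.transfer_mean, config.transfer_sd, size=n_pat)),
        config.transfer_range[0], config.transfer_range[1]).astype(int)
    n_transfer = np.minimum(n_transfer, yields)

    embryos = pd.DataFrame({
        "patient_id": oocytes["patient_id"], "oocyte_id": oocytes["oocyte_id"],
        "cell_count": cells, "fragmentation_pct": frag,
        "transferred": False, "grade": grade, "eight_cell_flag": eight,
    })
    rank = embryos.sort_values(
        ["patient_id", "grade", "cell_count", "fragmentation_pct", "oocyte_id"],
        ascending=[True, False, False, True, True], kind="stable",
    ).groupby("patient_id").cumcount()
    quota = pd.Series(n_transfer, index=patient_ids)
    embryos["transferred"] = (
        rank.sort_index() < embryos["patient_id"].map(quota)).to_numpy()
    oocytes["transferred"] = embryos["transferred"]

    # ---- cycle outcomes ----------------------------------------------
    offset_p = (np.log(config.or_ptos_pregnancy) * ptos_patient
                + config.pregnancy_age_slope * (ages - config.age_mean))
    gamma0 = _calibrate_intercept(offset_p, config.pregnancy_prevalence_target)
    p_preg = expit(gamma0 + offset_p)
    pregnancy = rng.uniform(size=n_pat) < p_preg
    p_extra = expit(config.implant_base + config.implant_slope * ptos_patient)
    sacs = np.where(
        pregnancy,
        1 + rng.binomial(np.maximum(n_transfer - 1, 0), p_extra),
        0).astype(int)

    transferred = embryos[embryos["transferred"]]
    by_pat = transferred.groupby("patient_id")
    mean_tr = by_pat["grade"].mean().reindex(patient_ids)
    max_tr = by_pat["grade"].max().reindex(patient_ids)
    all8 = by_pat["eight_cell_flag"].all().reindex(patient_ids).astype(bool)
    mean_avail = embryos.groupby("patient_id")["grade"].mean().reindex(patient_ids)

    cycles = pd.DataFrame({
        "patient_id": patient_ids, "age": ages, "n_oocytes": yields,
        "ptos": ptos_patient, "n_transferred": n_transfer,
        "mean_grade_available": mean_avail.to_numpy(),
        "mean_grade_transferred": mean_tr.to_numpy(),
        "max_grade_transferred": max_tr.to_numpy(),
        "all_transferred_eight_cell": all8.to_numpy(),
        "sacs": sacs, "pregnancy": pregnancy.astype(int),
    })

    ground_truth = {
        "config": dataclasses.asdict(config),
        "eight_cell_intercept": b0,
        "pregnancy_intercept": gamma0,
        "n_oocytes_total": n_ooc,
        "grade5_coerced_to_eight_cell": coerced,
    }
    return SyntheticCohort(oocytes, embryos, cycles[_CYCLE_COLUMNS], ground_truth)


def summarize_cohort(cohort: SyntheticCohort) -> dict:
    """Cohort summary mirroring the study's descriptive tables: parameter
    score marginals, TOS/PTOS moments, grade distribution, prevalences."""
    ooc, emb, cyc = cohort.oocytes, cohort.embryos, cohort.cycles
    if len(ooc) == 0:
        return {
            "n_patients": 0, "n_oocytes": 0, "n_embryos": 0,
            "score_marginals": pd.DataFrame(
                0.0, index=list(DEFAULT_MARGINALS), columns=[-1, 0, 1]),
            "tos_mean": np.nan, "tos_sd": np.nan,
            "ptos_mean": np.nan, "ptos_sd": np.nan,
            "grade_distribution": pd.Series(0, index=range(1, 6)),
            "eight_cell_rate": np.nan, "pregnancy_prevalence": np.nan,
            "mean_embryos_transferred": np.nan,
        }
    marg = pd.DataFrame({
        name: ooc[f"{name}_score"].value_counts(normalize=True)
        for name in DEFAULT_MARGINALS
    }).T.reindex(columns=[-1, 0, 1]).fillna(0.0)
    marg.index.name = "parameter"
    return {
        "n_patients": int(cyc.shape[0]),
        "n_oocytes": int(ooc.shape[0]),
        "n_embryos": int(emb.shape[0]),
        "score_marginals": marg,
        "tos_mean": float(ooc["tos"].mean()),
        "tos_sd": float(ooc["tos"].std()),
        "ptos_mean": float(cyc["ptos"].mean()),
        "ptos_sd": float(cyc["ptos"].std()),
        "grade_distribution": emb["grade"].value_counts(normalize=True)
                                 .reindex(range(1, 6)).fillna(0.0),
        "eight_cell_rate": float(emb["eight_cell_flag"].mean()),
        "pregnancy_prevalence": float(cyc["pregnancy"].mean()),
        "mean_embryos_transferred": float(cyc["n_transferred"].mean()),
    }
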