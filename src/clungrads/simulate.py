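"""Synthetic screening-cohort generator and confusion-cell calibration.

Emulates the statistical structure of a two-set pGGN screening study:
patients carry one to three nodules; each nodule gets a GVR type, a
lognormal mean diameter (moment-matched to the configured mean +/- SD), a
suspicious-features flag, and a pathology label drawn from a
(GVR, flag)-conditional invasiveness table. A single integer seed drives
one ``numpy.random.Generator`` stream; no global state.

``calibrate_to_cells`` solves, in closed form, for the flag probabilities
and per-stratum invasiveness that make the *expected* confusion cells of a
chosen rule system equal a target TP/FP/FN/TN exactly;
``fixture_exact_cohort`` builds a deterministic cohort hitting the cells
exactly, nodule for nodule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from .errors import CalibrationError, ValidationError
from .nodules import Cohort, GVRType, Nodule, Patient
from .stratify import SystemId

__all__ = [
    "GeneratorConfig",
    "CalibrationTarget",
    "generate_cohort",
    "calibrate_to_cells",
    "fixture_exact_cohort",
    "study_config",
    "training_config",
    "validation_config",
    "lognormal_params",
]

AGE_RANGE = (18.0, 90.0)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(logmean, logsd) of the lognormal with the given arithmetic moments."""
    if mean <= 0 or sd <= 0:
        raise ValidationError("diameter mean and sd must be positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


InvasiveTable = Mapping[tuple[GVRType, bool], float]


@dataclass(frozen=True)
class GeneratorConfig:
    """All sampling distributions for a synthetic cohort.

    ``n_nodules``, when set, pins the total nodule count exactly (the
    per-patient multiplicity vector is resampled until it sums to it).
    ``suspicious_floor_mm``, when set, restricts the suspicious-features
    flag to nodules at or above that diameter.
    """

    n_patients: int
    multiplicity_probs: tuple[float, float, float]
    gvr_probs: tuple[float, float, float, float]
    diameter_logmean: float
    diameter_logsd: float
    age_mean: float
    age_sd: float
    female_prob: float
    p_suspicious_given_gvr: tuple[float, float, float, float]
    p_invasive_given_gvr_and_flag: dict[tuple[GVRType, bool], float]
    seed: int = 0
    n_nodules: int | None = None
    suspicious_floor_mm: float | None = None
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name, probs, k in (
            ("multiplicity_probs", self.multiplicity_probs, 3),
            ("gvr_probs", self.gvr_probs, 4),
        ):
            if len(probs) != k or any(p < 0 for p in probs):
                raise ValidationError(f"{name} must be {k} nonnegative values")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValidationError(f"{name} must sum to 1 (got {sum(probs)!r})")
        for name, value in (("female_prob", self.female_prob),):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.p_suspicious_given_gvr):
            raise ValidationError("p_suspicious_given_gvr entries must be in [0, 1]")
        for key in ((g, f) for g in GVRType for f in (False, True)):
            p = self.p_invasive_given_gvr_and_flag.get(key)
            if p is None:
                raise ValidationError(
                    f"p_invasive_given_gvr_and_flag missing entry {key}"
                )
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"p_invasive_given_gvr_and_flag[{key}] must be in [0, 1]"
                )
        if self.diameter_logsd <= 0:
            raise ValidationError("diameter_logsd must be positive")
        if self.n_nodules is not None and not (
            self.n_patients <= self.n_nodules <= 3 * self.n_patients
        ):
            raise ValidationError(
                "n_nodules must lie in [n_patients, 3*n_patients]"
            )

    # --- moments implied by the configuration -----------------------------

    @property
    def diameter_mean_mm(self) -> float:
        return math.exp(self.diameter_logmean + self.diameter_logsd**2 / 2.0)

    @property
    def diameter_sd_mm(self) -> float:
        m = self.diameter_mean_mm
        return m * math.sqrt(math.expm1(self.diameter_logsd**2))

    def prob_diameter_ge(self, threshold_mm: float) -> float:
        """P(diameter >= t) under the configured lognormal."""
        from scipy.stats import norm

        z = (math.log(threshold_mm) - self.diameter_logmean) / self.diameter_logsd
        return float(norm.sf(z))

    def expected_invasive_fraction(self) -> float:
        """Expected fraction of invasive nodules under the configuration."""
        total = 0.0
        floor = self.suspicious_floor_mm
        p_large = 1.0 if floor is None else self.prob_diameter_ge(floor)
        for g, gp in zip(GVRType, self.gvr_probs):
            s = self.p_suspicious_given_gvr[g - 1] * p_large
            total += gp * (
                s * self.p_invasive_given_gvr_and_flag[(g, True)]
                + (1 - s) * self.p_invasive_given_gvr_and_flag[(g, False)]
            )
        return total

    # --- JSON (de)serialization for the CLI -------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_patients": self.n_patients,
            "multiplicity_probs": list(self.multiplicity_probs),
            "gvr_probs": list(self.gvr_probs),
            "diameter_logmean": self.diameter_logmean,
            "diameter_logsd": self.diameter_logsd,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "female_prob": self.female_prob,
            "p_suspicious_given_gvr": list(self.p_suspicious_given_gvr),
            "p_invasive_given_gvr_and_flag": {
                f"{g.name}:{'suspicious' if f else 'plain'}": p
                for (g, f), p in sorted(self.p_invasive_given_gvr_and_flag.items())
            },
            "seed": self.seed,
            "n_nodules": self.n_nodules,
            "suspicious_floor_mm": self.suspicious_floor_mm,
            "label": self.label,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        inv = {}
        for key, p in d["p_invasive_given_gvr_and_flag"].items():
            gname, fname = key.split(":")
            inv[(GVRType[gname], fname == "suspicious")] = float(p)
        return cls(
            n_patients=int(d["n_patients"]),
            multiplicity_probs=tuple(d["multiplicity_probs"]),
            gvr_probs=tuple(d["gvr_probs"]),
            diameter_logmean=float(d["diameter_logmean"]),
            diameter_logsd=float(d["diameter_logsd"]),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
            female_prob=float(d["female_prob"]),
            p_suspicious_given_gvr=tuple(d["p_suspicious_given_gvr"]),
            p_invasive_given_gvr_and_flag=inv,
            seed=int(d.get("seed", 0)),
            n_nodules=d.get("n_nodules"),
            suspicious_floor_mm=d.get("suspicious_floor_mm"),
            label=d.get("label", "synthetic"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class CalibrationTarget:
    """Target confusion cells for one rule system on a cohort of ``n`` nodules."""

    system: SystemId
    tp: int
    fp: int
    fn: int
    tn: int
    n: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise CalibrationError("confusion cells must be nonnegative")
        if sum(cells) != self.n:
            raise CalibrationError(
                f"cells sum to {sum(cells)}, not the cohort size n={self.n}"
            )
        if self.n == 0:
            raise CalibrationError("cohort size must be positive")


# ---------------------------------------------------------------------------
# generation


def _draw_multiplicities(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    probs = np.asarray(config.multiplicity_probs, dtype=float)
    if config.n_nodules is None:
        return rng.choice([1, 2, 3], size=config.n_patients, p=probs)
    # pin the exact nodule count by resampling the multiplicity vector
    for _ in range(100_000):
        m = rng.choice([1, 2, 3], size=config.n_patients, p=probs)
        if int(m.sum()) == config.n_nodules:
            return m
    raise CalibrationError(
        f"could not realise {config.n_nodules} nodules from "
        f"{config.n_patients} patients with the given multiplicity_probs"
    )


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Sample a synthetic cohort; bit-identical for a given (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mult = _draw_multiplicities(config, rng)

    lo = (AGE_RANGE[0] - config.age_mean) / config.age_sd
    hi = (AGE_RANGE[1] - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(
        lo, hi, loc=config.age_mean, scale=config.age_sd,
        size=config.n_patients, random_state=rng,
    )
    female = rng.random(config.n_patients) < config.female_prob

    gvr_values = list(GVRType)
    patients: list[Patient] = []
    nodules: list[Nodule] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        ids = []
        for j in range(int(mult[i])):
            nid = f"{pid}-N{j + 1}"
            ids.append(nid)
            gvr = gvr_values[rng.choice(4, p=np.asarray(config.gvr_probs))]
            diameter = float(
                np.exp(rng.normal(config.diameter_logmean, config.diameter_logsd))
            )
            suspicious = bool(
                rng.random() < config.p_suspicious_given_gvr[gvr - 1]
            )
            if (
                config.suspicious_floor_mm is not None
                and diameter < config.suspicious_floor_mm
            ):
                suspicious = False
            invasive = bool(
                rng.random()
                < config.p_invasive_given_gvr_and_flag[(gvr, suspicious)]
            )
            # axes consistent with the mean: short/long ratio in [0.7, 1]
            ratio = float(rng.uniform(0.7, 1.0))
            long_axis = diameter * 2.0 / (1.0 + ratio)
            short_axis = diameter * 2.0 * ratio / (1.0 + ratio)
            nodules.append(
                Nodule(
                    nodule_id=nid,
                    patient_id=pid,
                    mean_diameter_mm=diameter,
                    long_axis_mm=long_axis,
                    short_axis_mm=short_axis,
                    gvr=gvr,
                    suspicious_features=suspicious,
                    pathology="invasive" if invasive else "noninvasive",
                )
            )
        patients.append(
            Patient(
                patient_id=pid,
                age_years=float(ages[i]),
                sex="female" if female[i] else "male",
                nodule_ids=tuple(ids),
            )
        )
    return Cohort(patients=patients, nodules=nodules, label=config.label)


# ---------------------------------------------------------------------------
# calibration


def calibrate_to_cells(
    target: CalibrationTarget, base: GeneratorConfig
) -> GeneratorConfig:
    """Closed-form calibration of flag and invasiveness probabilities.

    Returns a config whose *expected* confusion cells under ``target.system``
    equal the target exactly. The predicted-positive stratum is made exact:

    * baselines: flags are drawn only at/above the size threshold, so the
      positive stratum is {flagged} with mass P(D >= t) * s;
    * cLung-RADS v2022: only GVR II nodules are flagged, so the positive
      stratum is {GVR III, GVR IV, flagged GVR II}.

    Per-stratum invasiveness is TP/(TP+FP) and FN/(FN+TN).
    """
    pos_frac = (target.tp + target.fp) / target.n
    neg_frac = 1.0 - pos_frac
    p_pos = target.tp / (target.tp + target.fp) if target.tp + target.fp else 0.0
    p_neg = target.fn / (target.fn + target.tn) if target.fn + target.tn else 0.0

    if target.system in (SystemId.LUNGRADS10, SystemId.LUNGRADS2022):
        threshold = 20.0 if target.system is SystemId.LUNGRADS10 else 30.0
        p_large = base.prob_diameter_ge(threshold)
        if pos_frac > 0 and p_large <= 0:
            raise CalibrationError(
                f"no diameter mass at/above {threshold} mm; cannot place "
                f"{target.tp + target.fp} positives"
            )
        s = 0.0 if pos_frac == 0 else pos_frac / p_large
        if s > 1.0 + 1e-12:
            raise CalibrationError(
                f"target positive fraction {pos_frac:.4f} exceeds "
                f"P(diameter >= {threshold} mm) = {p_large:.4f}; "
                "infeasible under the configured diameter distribution"
            )
        s = min(s, 1.0)
        inv = {(g, True): p_pos for g in GVRType}
        inv.update({(g, False): p_neg for g in GVRType})
        return replace(
            base,
            p_suspicious_given_gvr=(s, s, s, s),
            suspicious_floor_mm=threshold,
            p_invasive_given_gvr_and_flag=inv,
        )

    # cLung-RADS v2022: GVR III+IV are always positive
    g1, g2, g3, g4 = base.gvr_probs
    floor = g3 + g4
    if pos_frac < floor - 1e-12:
        raise CalibrationError(
            f"target positive fraction {pos_frac:.4f} is below the GVR III+IV "
            f"mass {floor:.4f}; every GVR III/IV nodule maps to category "
            "4a/4b/4x and is positive"
        )
    if pos_frac > floor + g2 + 1e-12:
        raise CalibrationError(
            f"target positive fraction {pos_frac:.4f} exceeds the reachable "
            f"mass {floor + g2:.4f} (GVR III+IV plus flagged GVR II)"
        )
    s2 = 0.0 if g2 == 0 else min(max((pos_frac - floor) / g2, 0.0), 1.0)
    inv = {
        (GVRType.I, False): p_neg,
        (GVRType.I, True): p_neg,
        (GVRType.II, False): p_neg,
        (GVRType.II, True): p_pos,
        (GVRType.III, False): p_pos,
        (GVRType.III, True): p_pos,
        (GVRType.IV, False): p_pos,
        (GVRType.IV, True): p_pos,
    }
    s3, s4 = base.p_suspicious_given_gvr[2], base.p_suspicious_given_gvr[3]
    return replace(
        base,
        p_suspicious_given_gvr=(0.0, s2, s3, s4),
        suspicious_floor_mm=None,
        p_invasive_given_gvr_and_flag=inv,
    )


# ---------------------------------------------------------------------------
# deterministic fixtures


def fixture_exact_cohort(target: CalibrationTarget, system: SystemId | None = None) -> Cohort:
    """Deterministic minimal cohort whose stratification under the system
    yields exactly the target cells (one patient per nodule, no randomness)."""
    system = target.system if system is None else system
    if system is SystemId.CLUNGRADS2022:
        pos = dict(gvr=GVRType.IV, mean_diameter_mm=12.0, suspicious_features=False)
        neg = dict(gvr=GVRType.I, mean_diameter_mm=10.0, suspicious_features=False)
    else:
        big = 25.0 if system is SystemId.LUNGRADS10 else 35.0
        pos = dict(gvr=GVRType.IV, mean_diameter_mm=big, suspicious_features=True)
        neg = dict(gvr=GVRType.I, mean_diameter_mm=10.0, suspicious_features=False)

    blocks = [
        (target.tp, pos, "invasive"),
        (target.fp, pos, "noninvasive"),
        (target.fn, neg, "invasive"),
        (target.tn, neg, "noninvasive"),
    ]
    patients, nodules = [], []
    idx = 0
    for count, attrs, pathology in blocks:
        for _ in range(count):
            idx += 1
            pid = f"F{idx:04d}"
            nid = f"{pid}-N1"
            patients.append(Patient(patient_id=pid, nodule_ids=(nid,)))
            nodules.append(
                Nodule(
                    nodule_id=nid, patient_id=pid, pathology=pathology, **attrs
                )
            )
    return Cohort(patients=patients, nodules=nodules, label=f"fixture-{system}")


# ---------------------------------------------------------------------------
# study-like default configurations


def _solve_invasive_table(
    gvr_probs: tuple[float, float, float, float],
    p_suspicious: tuple[float, float, float, float],
    prevalence: float,
) -> dict[tuple[GVRType, bool], float]:
    """Monotone-in-GVR invasiveness table with the GVR-IV plain-flag rate
    solved so the expected invasive fraction equals ``prevalence``."""
    table = {
        (GVRType.I, False): 0.20,
        (GVRType.I, True): 0.50,
        (GVRType.II, False): 0.30,
        (GVRType.II, True): 0.85,
        (GVRType.III, False): 0.82,
        (GVRType.III, True): 0.90,
        (GVRType.IV, False): 0.0,  # solved below
        (GVRType.IV, True): 0.95,
    }
    known = 0.0
    for g, gp in zip(GVRType, gvr_probs):
        s = p_suspicious[g - 1]
        if g is GVRType.IV:
            known += gp * s * table[(g, True)]
        else:
            known += gp * (s * table[(g, True)] + (1 - s) * table[(g, False)])
    g4 = gvr_probs[3]
    s4 = p_suspicious[3]
    coeff = g4 * (1 - s4)
    if coeff <= 0:
        raise CalibrationError("no GVR IV plain mass to absorb the prevalence target")
    q = (prevalence - known) / coeff
    if not 0.0 <= q <= 1.0:
        raise CalibrationError(
            f"prevalence {prevalence:.4f} unreachable with the fixed table (q={q:.4f})"
        )
    table[(GVRType.IV, False)] = q
    return table


def study_config(seed: int = 0) -> GeneratorConfig:
    """Combined-study defaults: 526 patients / 572 nodules, multiplicity
    487/32/7, pooled GVR margins (50, 60, 70, 392)/572, pooled diameter and
    age moments, and invasiveness calibrated to 421/572 expected invasive."""
    gvr_probs = (50 / 572, 60 / 572, 70 / 572, 392 / 572)
    p_susp = (0.02, 0.17, 0.03, 0.03)
    logmean, logsd = lognormal_params(13.6, 6.1)
    return GeneratorConfig(
        n_patients=526,
        multiplicity_probs=(487 / 526, 32 / 526, 7 / 526),
        gvr_probs=gvr_probs,
        diameter_logmean=logmean,
        diameter_logsd=logsd,
        age_mean=56.6,
        age_sd=9.5,
        female_prob=341 / 526,
        p_suspicious_given_gvr=p_susp,
        p_invasive_given_gvr_and_flag=_solve_invasive_table(
            gvr_probs, p_susp, 421 / 572
        ),
        seed=seed,
        n_nodules=572,
        label="study-synthetic",
    )


def training_config(seed: int = 0) -> GeneratorConfig:
    """Training-set defaults: 157 patients / 169 nodules, GVR margins
    (15, 19, 19, 116)/169, diameter 13.8 +/- 6.4 mm, age 57.5 +/- 9.1 y;
    flag and invasiveness probabilities calibrated to the training
    cLung-RADS v2022 cells (131, 14, 7, 17)."""
    gvr_probs = (15 / 169, 19 / 169, 19 / 169, 116 / 169)
    logmean, logsd = lognormal_params(13.8, 6.4)
    base = GeneratorConfig(
        n_patients=157,
        multiplicity_probs=(146 / 157, 10 / 157, 1 / 157),
        gvr_probs=gvr_probs,
        diameter_logmean=logmean,
        diameter_logsd=logsd,
        age_mean=57.5,
        age_sd=9.1,
        female_prob=99 / 157,
        p_suspicious_given_gvr=(0.02, 0.17, 0.03, 0.03),
        p_invasive_given_gvr_and_flag=_solve_invasive_table(
            gvr_probs, (0.02, 0.17, 0.03, 0.03), 138 / 169
        ),
        seed=seed,
        n_nodules=169,
        label="training-synthetic",
    )
    return calibrate_to_cells(
        CalibrationTarget(SystemId.CLUNGRADS2022, 131, 14, 7, 17, 169), base
    )


def validation_config(seed: int = 0) -> GeneratorConfig:
    """Validation-set defaults: 369 patients / 403 nodules, GVR margins
    (35, 41, 51, 276)/403, diameter 13.5 +/- 6.0 mm, age 56.2 +/- 9.7 y,
    invasiveness solved for prevalence 283/403."""
    gvr_probs = (35 / 403, 41 / 403, 51 / 403, 276 / 403)
    p_susp = (0.02, 0.17, 0.03, 0.03)
    logmean, logsd = lognormal_params(13.5, 6.0)
    return GeneratorConfig(
        n_patients=369,
        multiplicity_probs=(340 / 369, 23 / 369, 6 / 369),
        gvr_probs=gvr_probs,
        diameter_logmean=logmean,
        diameter_logsd=logsd,
        age_mean=56.2,
        age_sd=9.7,
        female_prob=242 / 369,
        p_suspicious_given_gvr=p_susp,
        p_invasive_given_gvr_and_flag=_solve_invasive_table(
            gvr_probs, p_susp, 283 / 403
        ),
        seed=seed,
        n_nodules=403,
        label="validation-synthetic",
    )
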