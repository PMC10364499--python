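"""Synthetic multicentre SPDP registry generator with derivable ground truth.

The generator emulates the statistical structure the benchmark analysis
assumes: centres of heterogeneous size and quality, with centre-level true
event rates drawn from Beta laws (so the pooled data are beta-binomial
overdispersed, and the best-patient-in-best-centre recovery target — the
75th quantile of the centre-rate distribution — is analytic), lognormal
continuous outcomes with a normally distributed per-centre location shift,
covariates matching a 2006-2019 European registry's marginals, and MCAR
missingness applied field by field as the final step.

Internal consistency is enforced by construction: major morbidity implies
overall morbidity, 90-day mortality implies Clavien-Dindo grade V, and
failure to preserve the spleen corresponds exactly to a splenectomy
preservation method.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import registry as reg
from . import schema
from .abc_benchmark import CentreSummary, abc_binary, adjusted_fraction
from .outcomes import BINARY_OUTCOMES, CONTINUOUS_OUTCOMES
from .registry import RegistryTable


@dataclass(frozen=True)
class BetaLaw:
    """Beta(a, b) law for a centre-level true event rate."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")

    @classmethod
    def from_mean_concentration(cls, mean: float, concentration: float) -> "BetaLaw":
        if not 0 < mean < 1:
            raise ValueError("mean must lie in (0, 1)")
        return cls(a=mean * concentration, b=(1 - mean) * concentration)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def quantile(self, q: float) -> float:
        return float(stats.beta.ppf(q, self.a, self.b))


@dataclass(frozen=True)
class LognormalLaw:
    """Lognormal outcome law: log-median mu, log-sd sigma, and a per-centre
    normal location shift with sd centre_sd; robotic records get an extra
    fixed log-shift (robotic operations run longer)."""

    mu: float
    sigma: float
    centre_sd: float = 0.0
    robotic_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.centre_sd < 0:
            raise ValueError("sigma must be > 0 and centre_sd >= 0")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def _default_binary_laws() -> dict[str, BetaLaw]:
    conc = 25.0
    marginals = {
        "conversion": 0.082,
        "spleen_preservation_failure": 0.182,
        "overall_morbidity": 0.506,
        "major_morbidity": 0.139,
        "cr_popf": 0.182,
        "readmission": 0.132,
        "mortality": 0.007,
    }
    return {k: BetaLaw.from_mean_concentration(v, conc) for k, v in marginals.items()}


def _default_continuous_laws() -> dict[str, LognormalLaw]:
    return {
        "op_duration": LognormalLaw(mu=math.log(195), sigma=0.39,
                                    centre_sd=0.12,
                                    robotic_shift=math.log(262.5 / 195)),
        "blood_loss": LognormalLaw(mu=math.log(100), sigma=1.1, centre_sd=0.25),
        "hospital_stay": LognormalLaw(mu=math.log(7), sigma=0.53,
                                      centre_sd=0.10,
                                      robotic_shift=math.log(8 / 7)),
    }


@dataclass(frozen=True)
class CovariateLaws:
    female_share: float = 0.62
    age_mean: float = 57.0
    age_sd: float = 15.0
    age_min: float = 18.0
    age_max: float = 92.0
    bmi_median: float = 25.0
    bmi_sigma: float = 0.18
    asa_probs: tuple[float, ...] = (0.25, 0.555, 0.17, 0.02, 0.005)
    # exclusion-relevant flags; prevalences chosen so the independent-flag
    # product leaves roughly three-fifths of patients low-risk
    flag_prevalence: dict[str, float] = field(default_factory=lambda: {
        "prev_abdominal_surgery": 0.37,
        "prev_major_abdominal_surgery": 0.04,
        "extended_or_multivisceral": 0.04,
        "chf_recent": 0.005,
        "angina_recent": 0.01,
        "mi_recent": 0.005,
        "pci_or_cardiac_surgery": 0.015,
        "atrial_fibrillation": 0.02,
        "chronic_renal_failure": 0.02,
        "copd_fev1_lt80": 0.025,
        "noac": 0.015,
        "vka": 0.02,
        "clopidogrel": 0.01,
        "diabetes_2plus_oad_or_insulin": 0.04,
        "tumour_size_gt5cm": 0.113,
    })
    kimura_share: dict[str, float] = field(default_factory=lambda: {
        "laparoscopic": 0.67, "robotic": 0.90,
    })


def _default_missingness() -> dict[str, float]:
    out: dict[str, float] = {}
    outcome_cols = ("op_duration_min", "blood_loss_ml", "conversion",
                    "spleen_preservation_failed", "clavien_dindo",
                    "popf_grade", "los_days", "readmission_90d",
                    "mortality_90d")
    for fdef in schema.FIELDS:
        if fdef.required or fdef.name in ("approach", "preservation_method"):
            out[fdef.name] = 0.0
        elif fdef.name in outcome_cols:
            out[fdef.name] = 0.02
        else:
            out[fdef.name] = 0.005
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    n_centres: int = 32
    volume_mean: float = 38.0       # per-centre caseload, negative binomial
    volume_dispersion: float = 1.5  # NB shape k; smaller = more size spread
    volume_min: int = 2
    year_start: int = 2006
    year_end: int = 2019
    centre_span_mean: float = 3.5   # mean distinct contributing years
    robotic_share: float = 0.227
    robotic_concentration: float = 4.0  # centre robotic-propensity Beta conc.
    binary_outcome_laws: dict[str, BetaLaw] = field(default_factory=_default_binary_laws)
    continuous_outcome_laws: dict[str, LognormalLaw] = field(default_factory=_default_continuous_laws)
    covariates: CovariateLaws = field(default_factory=CovariateLaws)
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    seed: int = 42

    def validate(self) -> None:
        if self.n_centres < 1:
            raise ValueError("need at least one centre")
        if self.volume_mean <= 0 or self.volume_dispersion <= 0:
            raise ValueError("volume law parameters must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        for p in (self.robotic_share, *self.missingness.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        expected = {s.name for s in BINARY_OUTCOMES}
        if set(self.binary_outcome_laws) != expected:
            raise ValueError(
                f"binary_outcome_laws must cover exactly {sorted(expected)}")
        if set(self.continuous_outcome_laws) != {s.name for s in CONTINUOUS_OUTCOMES}:
            raise ValueError("continuous_outcome_laws must cover the three "
                             "continuous outcomes")
        unknown = set(self.missingness) - set(schema.COLUMNS)
        if unknown:
            raise ValueError(f"missingness for unknown fields: {sorted(unknown)}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Per-centre generating parameters stored alongside the registry."""

    centre_n: pd.Series                  # realized caseload per centre
    centre_rates: pd.DataFrame           # centre x binary outcome true rate
    centre_log_shift: pd.DataFrame       # centre x continuous outcome shift
    seed_hash: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "seed_hash": self.seed_hash,
            "centre_n": self.centre_n.to_dict(),
            "centre_rates": self.centre_rates.to_dict(),
            "centre_log_shift": self.centre_log_shift.to_dict(),
        }, indent=2, sort_keys=True)


_CD_MAJOR = (("IIIa", 0.55), ("IIIb", 0.25), ("IVa", 0.15), ("IVb", 0.05))
_CD_MINOR = (("I", 0.5), ("II", 0.5))


def generate_registry(config: SyntheticConfig) -> tuple[RegistryTable, GroundTruth]:
    """Draw one synthetic registry; deterministic for a fixed config/seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_years = config.year_end - config.year_start + 1
    width = max(2, len(str(config.n_centres)))
    centre_ids = [f"C{i + 1:0{width}d}" for i in range(config.n_centres)]

    # centre-level structure
    k = config.volume_dispersion
    caseload = rng.negative_binomial(k, k / (k + config.volume_mean),
                                     size=config.n_centres)
    caseload = np.maximum(caseload, config.volume_min)
    spans = np.minimum(n_years, 1 + rng.poisson(
        max(config.centre_span_mean - 1, 0), size=config.n_centres))
    span_start = rng.integers(0, n_years - spans + 1)
    rob_law = BetaLaw.from_mean_concentration(
        min(max(config.robotic_share, 1e-6), 1 - 1e-6),
        config.robotic_concentration)
    robotic_propensity = rng.beta(rob_law.a, rob_law.b, size=config.n_centres)

    rates = {}
    for name, law in config.binary_outcome_laws.items():
        rates[name] = rng.beta(law.a, law.b, size=config.n_centres)
    # hierarchy: mortality <= major morbidity <= overall morbidity
    rates["major_morbidity"] = np.minimum(rates["major_morbidity"],
                                          rates["overall_morbidity"])
    rates["mortality"] = np.minimum(rates["mortality"], rates["major_morbidity"])
    shifts = {name: rng.normal(0.0, law.centre_sd, size=config.n_centres)
              for name, law in config.continuous_outcome_laws.items()}

    cov = config.covariates
    asa_probs = np.asarray(cov.asa_probs, dtype=float)
    asa_probs = asa_probs / asa_probs.sum()

    rows: list[dict] = []
    pid = 0
    for ci, centre in enumerate(centre_ids):
        m = int(caseload[ci])
        years = config.year_start + span_start[ci] + rng.integers(0, spans[ci], size=m)
        robotic = rng.random(m) < robotic_propensity[ci]
        for j in range(m):
            pid += 1
            stratum = "robotic" if robotic[j] else "laparoscopic"
            row: dict = {
                "patient_id": f"P{pid:06d}",
                "centre_id": centre,
                "year": int(years[j]),
                "approach": stratum,
                "sex": "female" if rng.random() < cov.female_share else "male",
                "age": float(np.clip(rng.normal(cov.age_mean, cov.age_sd),
                                     cov.age_min, cov.age_max)),
                "bmi": float(np.exp(rng.normal(math.log(cov.bmi_median),
                                               cov.bmi_sigma))),
                "asa_grade": schema.ASA_LEVELS[rng.choice(5, p=asa_probs)],
            }
            for flag, prev in cov.flag_prevalence.items():
                row[flag] = bool(rng.random() < prev)

            # postoperative course, hierarchical so the invariants hold
            p_mort = rates["mortality"][ci]
            p_maj = rates["major_morbidity"][ci]
            p_ov = rates["overall_morbidity"][ci]
            dead = rng.random() < p_mort
            major = dead or rng.random() < (p_maj - p_mort) / max(1 - p_mort, 1e-12)
            overall = major or rng.random() < (p_ov - p_maj) / max(1 - p_maj, 1e-12)
            if dead:
                cd = "V"
            elif major:
                cd = _weighted_choice(rng, _CD_MAJOR)
            elif overall:
                cd = _weighted_choice(rng, _CD_MINOR)
            else:
                cd = "0"
            row["clavien_dindo"] = cd
            row["mortality_90d"] = dead

            popf = rng.random() < rates["cr_popf"][ci]
            if popf:
                row["popf_grade"] = "B" if rng.random() < 0.8 else "C"
            else:
                row["popf_grade"] = "BL" if rng.random() < 0.1 else "none"
            row["conversion"] = bool(rng.random() < rates["conversion"][ci])
            row["readmission_90d"] = bool(rng.random() < rates["readmission"][ci])

            failed = rng.random() < rates["spleen_preservation_failure"][ci]
            row["spleen_preservation_failed"] = bool(failed)
            if failed:
                row["preservation_method"] = "splenectomy"
            else:
                row["preservation_method"] = (
                    "kimura" if rng.random() < cov.kimura_share[stratum]
                    else "warshaw")

            for name, col, rounder in (
                ("op_duration", "op_duration_min", lambda v: max(30.0, round(v))),
                ("blood_loss", "blood_loss_ml", lambda v: max(0.0, round(v))),
                ("hospital_stay", "los_days", lambda v: max(1.0, round(v))),
            ):
                law = config.continuous_outcome_laws[name]
                loc = law.mu + shifts[name][ci] + (law.robotic_shift if robotic[j] else 0.0)
                row[col] = float(rounder(float(rng.lognormal(loc, law.sigma))))
            rows.append(row)

    df = schema.coerce_frame(pd.DataFrame(rows))
    # MCAR missingness, applied last so the complete data stay consistent
    for col in schema.COLUMNS:
        p = config.missingness.get(col, 0.0)
        if p > 0:
            df.loc[rng.random(len(df)) < p, col] = pd.NA

    seed_hash = config.content_hash()
    table = reg.from_frame(df, provenance=f"synthetic:{seed_hash}")
    truth = GroundTruth(
        centre_n=pd.Series(caseload, index=centre_ids, name="n"),
        centre_rates=pd.DataFrame(rates, index=centre_ids),
        centre_log_shift=pd.DataFrame(shifts, index=centre_ids),
        seed_hash=seed_hash,
    )
    return table, truth


def _weighted_choice(rng: np.random.Generator, pairs) -> str:
    labels = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def ground_truth_benchmarks(truth: GroundTruth, config: SyntheticConfig) -> dict:
    """Analytic / oracle benchmark targets implied by the generating laws.

    For each binary outcome: the Beta law's 75th quantile (the large-n limit
    of the BPBC cut-off across centres), the generating marginal rate, and an
    oracle ABC computed from the true centre rates with the realized
    per-centre caseloads (expected events = rate x n).
    """
    if truth.seed_hash != config.content_hash():
        raise ValueError("ground truth does not match this config (seed hash "
                         "mismatch)")
    out: dict[str, dict[str, float]] = {}
    for name, law in config.binary_outcome_laws.items():
        rates = truth.centre_rates[name]
        summaries = [
            CentreSummary(centre_id=str(c), n=int(truth.centre_n[c]),
                          events=int(round(rates[c] * truth.centre_n[c])),
                          crude_value=float(rates[c]),
                          adjusted_fraction=adjusted_fraction(
                              int(round(rates[c] * truth.centre_n[c])),
                              int(truth.centre_n[c])))
            for c in truth.centre_rates.index
        ]
        oracle = abc_binary(summaries, pool_fraction=0.10,
                            exclude_zero_event=False)
        out[name] = {
            "beta_q75": law.quantile(0.75),
            "marginal_rate": law.mean,
            "oracle_abc_pct": oracle.benchmark_value,
        }
    for name, law in config.continuous_outcome_laws.items():
        out[name] = {"median": law.median}
    return out
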