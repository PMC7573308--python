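"""Seeded synthetic CHNS-like cohort generation.

The generator emulates the statistical structure of the 2009 China Health and
Nutrition Survey adult sample as used in sex-stratified hyperuricemia
analyses: a ~53.6% female sex ratio, the published sex-specific distribution
of the six metabolic-obesity phenotypes, and sex- and phenotype-conditional
hyperuricemia prevalences.  Records are built *phenotype-first*: each
subject's phenotype label is drawn, then the raw anthropometric and
biochemical measurements are drawn from laws conditioned on that label (BMI
within the phenotype's class, ATP-III component measurements on the correct
side of each cut-off), so that re-deriving phenotypes from the raw columns
reproduces the generating labels exactly.

Serum uric acid follows a sex-specific log-normal (optionally normal) law
whose location parameter varies by phenotype; :func:`calibrate_prevalence`
bisects the location so the analytic tail mass above the sex-specific
hyperuricemia threshold matches any target prevalence.  Alternatively a
:class:`LogisticOutcome` generates hyperuricemia from an explicit log-odds
model (with phenotype effects and covariate coefficients), for
odds-ratio-recovery studies; uric acid is then drawn from the stratum law
truncated to the matching side of the threshold.

Everything is driven by one master seed, stream-split per field, so adding
or reordering columns never perturbs other columns' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .phenotypes import PHENOTYPES, Thresholds
from .infer import sample_bn as _sample_bn

__all__ = [
    "GeneratorSpec",
    "UricAcidLaw",
    "LogisticOutcome",
    "SpecValidationError",
    "CalibrationError",
    "DegenerateTargetError",
    "sample_cohort",
    "calibrate_prevalence",
    "calibrate_all_strata",
    "sample_from_bn",
    "COHORT_COLUMNS",
    "FEMALE_FRACTION",
    "PHENOTYPE_PROBS",
    "HYPERURICEMIA_PREV",
]

SEXES = ("male", "female")

#: Canonical cohort column order (the CSV interchange contract).
COHORT_COLUMNS = (
    "id", "sex", "age", "weight", "height", "waist_circumference",
    "sbp", "dbp", "fpg", "tg", "hdl_c", "ldl_c", "tc", "uric_acid",
    "fasting_insulin", "hs_crp", "white_blood_cell",
    "smoker", "alcohol", "urban", "diabetes",
    "antihypertensive_drug", "lipid_drug", "diabetes_drug",
)

#: CHNS 2009 adult sample: 3,945 women of 7,364 participants.
FEMALE_FRACTION = 3945 / 7364  # 0.5357...

#: Sex-specific six-phenotype distribution (ATP-III metabolic health).
PHENOTYPE_PROBS: dict[str, dict[str, float]] = {
    "male": {"MHNW": 0.4305, "MHOW": 0.1696, "MHO": 0.0266,
             "MUNW": 0.1489, "MUOW": 0.1603, "MUO": 0.0641},
    "female": {"MHNW": 0.4297, "MHOW": 0.1767, "MHO": 0.0360,
               "MUNW": 0.1531, "MUOW": 0.1343, "MUO": 0.0702},
}

#: Hyperuricemia prevalence per (sex, phenotype) stratum.
HYPERURICEMIA_PREV: dict[str, dict[str, float]] = {
    "male": {"MHNW": 0.114, "MHOW": 0.166, "MHO": 0.154,
             "MUNW": 0.236, "MUOW": 0.394, "MUO": 0.384},
    "female": {"MHNW": 0.040, "MHOW": 0.055, "MHO": 0.085,
               "MUNW": 0.187, "MUOW": 0.230, "MUO": 0.307},
}

#: ATP-III component prevalence by sex, used to weight which components are
#: abnormal once a subject's component count is fixed (order bp, tg, fpg, hdl).
_COMPONENT_WEIGHTS = {
    "male": np.array([0.461, 0.359, 0.262, 0.177]),
    "female": np.array([0.376, 0.299, 0.230, 0.328]),
}

#: Component-count distribution given metabolic health status.
_COUNT_PROBS = {
    True: {0: 0.55, 1: 0.45},            # healthy: fewer than 2 components
    False: {2: 0.55, 3: 0.30, 4: 0.15},  # unhealthy
}

#: Self-reported diabetes probability per phenotype (monotone in metabolic
#: burden; implies ~5% overall, matching the survey).
_DIABETES_PROBS = {"MHNW": 0.02, "MHOW": 0.03, "MHO": 0.04,
                   "MUNW": 0.08, "MUOW": 0.10, "MUO": 0.14}


class SpecValidationError(ValueError):
    """A generator-spec field violates its invariant (named in the message)."""


class DegenerateTargetError(ValueError):
    """Calibration target is 0 or 1 (no finite location achieves it)."""


class CalibrationError(RuntimeError):
    """No bracket found for the calibration root within 100 doublings."""


@dataclass
class UricAcidLaw:
    """Serum uric-acid sampling law.

    ``family`` is ``"lognormal"`` (strictly positive, right-skewed; location
    is the log-scale mean) or ``"normal"`` (location is the mean).  ``sigma``
    is the per-sex scale; ``location`` holds the per (sex, phenotype)
    location parameters filled in by calibration.
    """

    family: str = "lognormal"
    sigma: dict[str, float] = field(default_factory=lambda: {"male": 0.30, "female": 0.28})
    location: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise SpecValidationError("uric_acid_law.family must be 'lognormal' or 'normal'")

    def tail_mass(self, loc: float, sex: str, threshold: float) -> float:
        """P(uric acid >= threshold) under the law with the given location."""
        s = self.sigma[sex]
        if self.family == "lognormal":
            return float(stats.norm.sf((np.log(threshold) - loc) / s))
        return float(stats.norm.sf((threshold - loc) / s))

    def natural_location(self, sex: str, threshold: float) -> float:
        """Location whose median sits at the threshold (bisection start)."""
        return float(np.log(threshold)) if self.family == "lognormal" else float(threshold)

    def sample(self, rng, loc, sex: str, size: int, side: str | None = None, threshold=None):
        """Draw uric acid; ``side`` ('above'/'below') truncates at threshold."""
        s = self.sigma[sex]
        if side is None:
            z = rng.standard_normal(size)
        else:
            t = np.log(threshold) if self.family == "lognormal" else threshold
            zcut = (t - np.asarray(loc)) / s
            if side == "above":
                z = stats.truncnorm.rvs(zcut, np.inf, size=size, random_state=rng)
            else:
                z = stats.truncnorm.rvs(-np.inf, zcut, size=size, random_state=rng)
        x = np.asarray(loc) + s * z
        return np.exp(x) if self.family == "lognormal" else x


@dataclass
class LogisticOutcome:
    """Explicit log-odds generator for hyperuricemia.

    ``eta = logit(baseline_prevalence) + phenotype_logodds[phenotype]
    + sum_c covariate_coefs[c] * (x_c - covariate_refs[c])``; the outcome is
    Bernoulli(expit(eta)).  The reference phenotype (MHNW) has log-odds 0.
    """

    baseline_prevalence: float
    phenotype_logodds: dict[str, float]
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    covariate_refs: dict[str, float] = field(default_factory=dict)


def default_covariate_models() -> dict:
    """Plausible sampling laws for the free (non-phenotype-constrained)
    covariates, loosely matched to the published sex-specific survey moments.

    Values are (mean, sd) pairs with hard bounds; flags are Bernoulli
    probabilities.  These only need plausibility — no quantitative target
    depends on their exact moments.
    """
    return {
        "age": {"by_sex": {"male": (50.3, 14.6), "female": (50.3, 14.3)}, "bounds": (18.0, 95.0)},
        "height": {"by_sex": {"male": (1.6704, 0.066), "female": (1.5591, 0.0637)}, "bounds": (1.40, 1.95)},
        "bmi": {
            "normal": (21.6, 1.5), "overweight": (25.4, 1.1), "obese": (29.6, 1.6),
            "bounds": {"normal": (18.5, 24.0), "overweight": (24.0, 28.0), "obese": (28.0, 42.0)},
        },
        "waist": {"by_sex": {"male": 85.0, "female": 81.9}, "bmi_slope": 1.7, "sd": 4.5, "bounds": (55.0, 150.0)},
        "sbp": {"normal": (118.0, 8.0), "abnormal": (142.0, 10.0), "bounds": (85.0, 210.0)},
        "dbp": {"normal": (76.0, 6.0), "abnormal": (90.0, 8.0), "bounds": (50.0, 130.0)},
        "tg": {"normal": (1.15, 0.30), "abnormal": (2.60, 0.90), "bounds": (0.30, 15.0)},
        "fpg": {"normal": (5.00, 0.45), "abnormal": (6.80, 1.60), "bounds": (3.50, 20.0)},
        "hdl_c": {"normal": (1.62, 0.30), "abnormal": {"male": (0.92, 0.10), "female": (1.12, 0.13)},
                  "bounds": (0.40, 3.50)},
        "ldl_c": {"by_sex": {"male": (2.94, 0.97), "female": (3.05, 0.99)}, "bounds": (0.50, 10.0)},
        "tc_noise_sd": 0.30,
        "fasting_insulin": {"by_sex": {"male": (14.0, 8.0), "female": (13.5, 8.0)}, "bounds": (0.5, 80.0)},
        "hs_crp": {"lognormal": (0.2, 1.0), "bounds": (0.01, 80.0)},
        "white_blood_cell": {"by_sex": {"male": (6.6, 1.7), "female": (6.4, 1.7)}, "bounds": (2.0, 20.0)},
        "smoker": {"male": 0.62, "female": 0.038},
        "alcohol": {"male": 0.611, "female": 0.087},
        "urban": {"male": 0.686, "female": 0.681},
        "antihypertensive_given_bp": 0.25,
        "lipid_drug_given_tg": 0.05,
        "diabetes_drug_given_fpg_and_diabetes": 0.5,
    }


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort.

    Probabilities are validated on construction; phenotype vectors must sum
    to 1 within 1e-9 per sex.  ``uric_acid_law.location`` may be left empty
    and filled by :func:`calibrate_all_strata` (the :meth:`default` factory
    does this automatically).
    """

    n_subjects: int
    female_fraction: float = FEMALE_FRACTION
    phenotype_probs_by_sex: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(PHENOTYPE_PROBS[s]) for s in SEXES}
    )
    hyperuricemia_prev_by_phenotype_sex: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(HYPERURICEMIA_PREV[s]) for s in SEXES}
    )
    covariate_models: dict = field(default_factory=default_covariate_models)
    uric_acid_law: UricAcidLaw = field(default_factory=UricAcidLaw)
    diabetes_probs_by_phenotype: dict[str, float] = field(
        default_factory=lambda: dict(_DIABETES_PROBS)
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    logistic_outcome: LogisticOutcome | None = None
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise SpecValidationError("female_fraction must be a probability in [0, 1]")
        for sex in SEXES:
            probs = self.phenotype_probs_by_sex[sex]
            if set(probs) != set(PHENOTYPES):
                raise SpecValidationError(
                    f"phenotype_probs_by_sex[{sex!r}] must cover exactly {PHENOTYPES}"
                )
            vec = np.array([probs[p] for p in PHENOTYPES])
            if np.any(vec < 0) or np.any(vec > 1):
                raise SpecValidationError(
                    f"phenotype_probs_by_sex[{sex!r}] entries must be probabilities"
                )
            if abs(vec.sum() - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"phenotype_probs_by_sex[{sex!r}] must sum to 1 (got {vec.sum()!r})"
                )
            for p, v in self.hyperuricemia_prev_by_phenotype_sex[sex].items():
                if not (0.0 <= v <= 1.0):
                    raise SpecValidationError(
                        f"hyperuricemia_prev_by_phenotype_sex[{sex!r}][{p!r}] must be in [0, 1]"
                    )
        for p, v in self.diabetes_probs_by_phenotype.items():
            if not (0.0 <= v <= 1.0):
                raise SpecValidationError(f"diabetes_probs_by_phenotype[{p!r}] must be in [0, 1]")

    @classmethod
    def default(cls, n_subjects: int = 7364, seed: int = 0, **overrides) -> "GeneratorSpec":
        """The standard survey-calibrated spec, with uric-acid locations
        bisected to the published stratum prevalences."""
        spec = cls(n_subjects=n_subjects, seed=seed, **overrides)
        return calibrate_all_strata(spec)

    def restricted_to(self, phenotype: str, sex: str) -> "GeneratorSpec":
        """A copy generating only the given (phenotype, sex) stratum."""
        probs = {s: {p: 0.0 for p in PHENOTYPES} for s in SEXES}
        probs[sex][phenotype] = 1.0
        probs["male" if sex == "female" else "female"]["MHNW"] = 1.0  # unused mass
        return replace(
            self,
            female_fraction=1.0 if sex == "female" else 0.0,
            phenotype_probs_by_sex=probs,
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        return plain(asdict(self))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GeneratorSpec":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source, encoding="utf-8") as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        law = UricAcidLaw(**d.pop("uric_acid_law"))
        thr = Thresholds(**d.pop("thresholds"))
        lo = d.pop("logistic_outcome", None)
        return cls(
            uric_acid_law=law,
            thresholds=thr,
            logistic_outcome=LogisticOutcome(**lo) if lo else None,
            **d,
        )


def calibrate_prevalence(
    spec: GeneratorSpec,
    stratum: tuple[str, str],
    target: float,
    tol: float = 1e-6,
) -> GeneratorSpec:
    """Set the uric-acid location of one (phenotype, sex) stratum by bisection.

    Finds the location whose analytic tail mass above the sex-specific
    hyperuricemia threshold is within ``tol`` of ``target`` (the tail mass is
    strictly increasing in location).  Raises
    :class:`DegenerateTargetError` for targets of 0 or 1 and
    :class:`CalibrationError` if no bracket is found within 100 doublings.
    """
    phenotype, sex = stratum
    if not (0.0 < target < 1.0):
        raise DegenerateTargetError("target prevalence must be strictly between 0 and 1")
    law = spec.uric_acid_law
    threshold = spec.thresholds.sua[sex]
    mid0 = law.natural_location(sex, threshold)
    step = max(law.sigma[sex], 1e-3)
    lo = hi = mid0
    for _ in range(100):
        if law.tail_mass(lo, sex, threshold) <= target:
            break
        lo -= step
        step *= 2
    else:
        raise CalibrationError("no lower bracket within 100 doublings")
    step = max(law.sigma[sex], 1e-3)
    for _ in range(100):
        if law.tail_mass(hi, sex, threshold) >= target:
            break
        hi += step
        step *= 2
    else:
        raise CalibrationError("no upper bracket within 100 doublings")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = law.tail_mass(mid, sex, threshold)
        if abs(p - target) <= tol:
            break
        if p < target:
            lo = mid
        else:
            hi = mid
    location = {s: dict(law.location.get(s, {})) for s in SEXES}
    location.setdefault(sex, {})[phenotype] = float(mid)
    new_law = replace(law, location=location)
    return replace(spec, uric_acid_law=new_law)


def calibrate_all_strata(spec: GeneratorSpec, tol: float = 1e-8) -> GeneratorSpec:
    """Calibrate every (phenotype, sex) uric-acid location to the spec's
    stratum prevalence table."""
    out = spec
    for sex in SEXES:
        for p in PHENOTYPES:
            out = calibrate_prevalence(
                out, (p, sex), out.hyperuricemia_prev_by_phenotype_sex[sex][p], tol
            )
    return out


def _field_rng(seed: int, name: str) -> np.random.Generator:
    """Per-field random stream derived from the master seed and field name."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _by_sex_truncnorm(rng, female, model, size_key="by_sex"):
    out = np.empty(female.shape)
    lo, hi = model["bounds"]
    for sex, mask in ("male", ~female), ("female", female):
        if mask.any():
            m, s = model[size_key][sex]
            out[mask] = _truncnorm(rng, m, s, lo, hi, int(mask.sum()))
    return out


def sample_cohort(spec: GeneratorSpec) -> pd.DataFrame:
    """Generate a complete synthetic cohort table.

    Exactly ``spec.n_subjects`` records in canonical column order; identical
    specs and seeds give identical tables.  Phenotype labels drive the raw
    measurements, so re-deriving phenotypes from the output reproduces the
    generating labels (see module docstring).
    """
    spec.validate()
    if not spec.uric_acid_law.location and spec.logistic_outcome is None:
        spec = calibrate_all_strata(spec)
    n = spec.n_subjects
    cm = spec.covariate_models
    t = spec.thresholds

    female = _field_rng(spec.seed, "sex").random(n) < spec.female_fraction
    sex = np.where(female, "female", "male").astype(object)

    # phenotype per sex
    phenotype = np.empty(n, dtype=object)
    rng_ph = _field_rng(spec.seed, "phenotype")
    u = rng_ph.random(n)
    for s, mask in ("male", ~female), ("female", female):
        probs = np.array([spec.phenotype_probs_by_sex[s][p] for p in PHENOTYPES])
        edges = np.cumsum(probs)
        phenotype[mask] = np.asarray(PHENOTYPES, dtype=object)[
            np.searchsorted(edges, u[mask], side="right").clip(0, 5)
        ]
    healthy = np.isin(phenotype, ("MHNW", "MHOW", "MHO"))
    bmi_class = np.select(
        [np.isin(phenotype, ("MHNW", "MUNW")), np.isin(phenotype, ("MHOW", "MUOW"))],
        ["normal", "overweight"],
        default="obese",
    ).astype(object)

    # anthropometrics
    rng_bmi = _field_rng(spec.seed, "bmi")
    bmi = np.empty(n)
    for cls in ("normal", "overweight", "obese"):
        mask = bmi_class == cls
        if mask.any():
            m, s = cm["bmi"][cls]
            lo, hi = cm["bmi"]["bounds"][cls]
            bmi[mask] = _truncnorm(rng_bmi, m, s, lo, hi, int(mask.sum()))
    height = _by_sex_truncnorm(_field_rng(spec.seed, "height"), female, cm["height"])
    weight = bmi * height**2
    rng_wc = _field_rng(spec.seed, "waist")
    base = np.where(female, cm["waist"]["by_sex"]["female"], cm["waist"]["by_sex"]["male"])
    wc = base + cm["waist"]["bmi_slope"] * (bmi - 23.7) + rng_wc.normal(0, cm["waist"]["sd"], n)
    wc = np.clip(wc, *cm["waist"]["bounds"])

    # ATP-III component count and membership
    rng_cnt = _field_rng(spec.seed, "component_count")
    count = np.empty(n, dtype=int)
    for h in (True, False):
        mask = healthy == h
        if mask.any():
            ks = np.array(sorted(_COUNT_PROBS[h]))
            ps = np.array([_COUNT_PROBS[h][k] for k in ks])
            count[mask] = rng_cnt.choice(ks, size=int(mask.sum()), p=ps / ps.sum())
    rng_mem = _field_rng(spec.seed, "component_membership")
    w = np.where(female[:, None], _COMPONENT_WEIGHTS["female"], _COMPONENT_WEIGHTS["male"])
    gumbel = rng_mem.gumbel(size=(n, 4))
    scores = np.log(w) + gumbel
    ranks = np.argsort(np.argsort(-scores, axis=1), axis=1)  # 0 = strongest
    flags = ranks < count[:, None]  # columns: bp, tg, fpg, hdl
    f_bp, f_tg, f_fpg, f_hdl = flags.T

    # measurements on the flagged side of each cut-off
    def two_sided(name, rng, flag, lo_model, hi_model, cut_lo, cut_hi):
        out = np.empty(n)
        lo, hi = cm[name]["bounds"]
        if (~flag).any():
            m, s = lo_model
            out[~flag] = _truncnorm(rng, m, s, lo, min(cut_hi, hi), int((~flag).sum()))
        if flag.any():
            m, s = hi_model
            out[flag] = _truncnorm(rng, m, s, max(cut_lo, lo), hi, int(flag.sum()))
        return out

    rng_sbp = _field_rng(spec.seed, "sbp")
    sbp = two_sided("sbp", rng_sbp, f_bp, cm["sbp"]["normal"], cm["sbp"]["abnormal"], t.sbp, t.sbp)
    rng_dbp = _field_rng(spec.seed, "dbp")
    dbp = np.empty(n)
    lo, hi = cm["dbp"]["bounds"]
    m, s = cm["dbp"]["normal"]
    dbp[:] = _truncnorm(rng_dbp, m, s, lo, t.dbp, n)  # below cut unless flagged draw says otherwise
    if f_bp.any():
        m, s = cm["dbp"]["abnormal"]
        elevated_dbp = _field_rng(spec.seed, "dbp_side").random(n) < 0.5
        pick = f_bp & elevated_dbp
        if pick.any():
            dbp[pick] = _truncnorm(rng_dbp, m, s, t.dbp, hi, int(pick.sum()))
    rng_tg = _field_rng(spec.seed, "tg")
    tg = two_sided("tg", rng_tg, f_tg, cm["tg"]["normal"], cm["tg"]["abnormal"], t.tg, t.tg)
    rng_fpg = _field_rng(spec.seed, "fpg")
    fpg = two_sided("fpg", rng_fpg, f_fpg, cm["fpg"]["normal"], cm["fpg"]["abnormal"], t.fpg, t.fpg)
    rng_hdl = _field_rng(spec.seed, "hdl_c")
    hdl = np.empty(n)
    lo, hi = cm["hdl_c"]["bounds"]
    for s_, mask_sex in ("male", ~female), ("female", female):
        cut = t.hdl[s_]
        m_ab, sd_ab = cm["hdl_c"]["abnormal"][s_]
        m_no, sd_no = cm["hdl_c"]["normal"]
        mask = mask_sex & f_hdl
        if mask.any():
            hdl[mask] = _truncnorm(rng_hdl, m_ab, sd_ab, lo, cut, int(mask.sum()))
        mask = mask_sex & ~f_hdl
        if mask.any():
            hdl[mask] = _truncnorm(rng_hdl, m_no, sd_no, cut, hi, int(mask.sum()))

    # free covariates
    age = _by_sex_truncnorm(_field_rng(spec.seed, "age"), female, cm["age"])
    ldl = _by_sex_truncnorm(_field_rng(spec.seed, "ldl_c"), female, cm["ldl_c"])
    tc = np.clip(
        ldl + hdl + 0.2 * tg + _field_rng(spec.seed, "tc").normal(0, cm["tc_noise_sd"], n),
        1.0, None,
    )
    insulin = _by_sex_truncnorm(_field_rng(spec.seed, "fasting_insulin"), female, cm["fasting_insulin"])
    mu, sg = cm["hs_crp"]["lognormal"]
    crp = np.clip(
        np.exp(_field_rng(spec.seed, "hs_crp").normal(mu, sg, n)), *cm["hs_crp"]["bounds"]
    )
    wbc = _by_sex_truncnorm(_field_rng(spec.seed, "white_blood_cell"), female, cm["white_blood_cell"])

    def flag_by_sex(name):
        r = _field_rng(spec.seed, name)
        p = np.where(female, cm[name]["female"], cm[name]["male"])
        return (r.random(n) < p).astype(int)

    smoker = flag_by_sex("smoker")
    alcohol = flag_by_sex("alcohol")
    urban = flag_by_sex("urban")
    p_diab = np.vectorize(spec.diabetes_probs_by_phenotype.__getitem__)(phenotype)
    diabetes = (_field_rng(spec.seed, "diabetes").random(n) < p_diab).astype(int)

    # drug flags only where the matching component is already abnormal, so
    # phenotype re-derivation is unchanged by them
    aht = (f_bp & (_field_rng(spec.seed, "antihypertensive_drug").random(n)
                   < cm["antihypertensive_given_bp"])).astype(int)
    lipid = (f_tg & (_field_rng(spec.seed, "lipid_drug").random(n)
                     < cm["lipid_drug_given_tg"])).astype(int)
    ddrug = (f_fpg & (diabetes == 1)
             & (_field_rng(spec.seed, "diabetes_drug").random(n)
                < cm["diabetes_drug_given_fpg_and_diabetes"])).astype(int)

    # uric acid / hyperuricemia
    rng_ua = _field_rng(spec.seed, "uric_acid")
    threshold = np.where(female, t.sua["female"], t.sua["male"])
    law = spec.uric_acid_law
    if spec.logistic_outcome is None:
        loc = np.empty(n)
        for s_ in SEXES:
            for p in PHENOTYPES:
                mask = (sex == s_) & (phenotype == p)
                if mask.any():
                    loc[mask] = law.location[s_][p]
        ua = np.empty(n)
        for s_, mask_sex in ("male", ~female), ("female", female):
            if mask_sex.any():
                ua[mask_sex] = law.sample(rng_ua, loc[mask_sex], s_, int(mask_sex.sum()))
    else:
        lo_model = spec.logistic_outcome
        eta = np.full(n, np.log(lo_model.baseline_prevalence / (1 - lo_model.baseline_prevalence)))
        eta += np.vectorize(lambda p: lo_model.phenotype_logodds.get(p, 0.0))(phenotype)
        covs = {
            "age": age, "urban": urban, "smoker": smoker, "alcohol": alcohol,
            "white_blood_cell": wbc, "tc": tc, "ldl_c": ldl, "hs_crp": crp,
            "diabetes": diabetes,
        }
        for c, beta in lo_model.covariate_coefs.items():
            eta += beta * (covs[c] - lo_model.covariate_refs.get(c, 0.0))
        hyper = _field_rng(spec.seed, "hyperuricemia").random(n) < expit(eta)
        if law.location:
            loc_map = law.location
        else:
            loc_map = calibrate_all_strata(replace(spec, logistic_outcome=None)).uric_acid_law.location
        loc = np.empty(n)
        for s_ in SEXES:
            for p in PHENOTYPES:
                mask = (sex == s_) & (phenotype == p)
                if mask.any():
                    loc[mask] = loc_map[s_][p]
        ua = np.empty(n)
        for s_, mask_sex in ("male", ~female), ("female", female):
            thr_s = t.sua[s_]
            for side, mask in ("above", mask_sex & hyper), ("below", mask_sex & ~hyper):
                if mask.any():
                    ua[mask] = law.sample(
                        rng_ua, loc[mask], s_, int(mask.sum()), side=side, threshold=thr_s
                    )

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "weight": weight,
            "height": height,
            "waist_circumference": wc,
            "sbp": sbp,
            "dbp": dbp,
            "fpg": fpg,
            "tg": tg,
            "hdl_c": hdl,
            "ldl_c": ldl,
            "tc": tc,
            "uric_acid": ua,
            "fasting_insulin": insulin,
            "hs_crp": crp,
            "white_blood_cell": wbc,
            "smoker": smoker,
            "alcohol": alcohol,
            "urban": urban,
            "diabetes": diabetes,
            "antihypertensive_drug": aht,
            "lipid_drug": lipid,
            "diabetes_drug": ddrug,
        },
        columns=list(COHORT_COLUMNS),
    )
    return df


def sample_from_bn(bn, n: int, seed: int) -> pd.DataFrame:
    """Forward-sample ``n`` discrete records from a fitted or hand-built
    Bayesian network (ancestral sampling in topological order)."""
    return _sample_bn(bn, n, seed)
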