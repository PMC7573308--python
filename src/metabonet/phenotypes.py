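"""Derivation of metabolic-obesity phenotypes and the hyperuricemia outcome.

Every categorical variable used downstream is a deterministic function of the
raw anthropometric/biochemical measurements in a cohort table:

* hyperuricemia from serum uric acid with sex-specific cut-offs
  (>= 420 umol/L in men, >= 360 umol/L in women);
* BMI and the Chinese BMI classes (normal 18.5-23.9, overweight 24.0-27.9,
  obese >= 28.0 kg/m^2; below 18.5 is underweight and excluded from
  phenotype-stratified output);
* the four ATP-III metabolic-syndrome components with waist circumference
  dropped (elevated BP, elevated TG, elevated FPG, reduced HDL-C, each also
  satisfied by the matching drug flag);
* the Visceral Adiposity Index (VAI) with its sex-specific published formula
  and the 1.59 metabolic-health cut-off;
* HOMA-IR = fasting insulin (uIU/mL) x FPG (mmol/L) / 22.5;
* the six metabolic-obesity phenotypes (MHNW, MHOW, MHO, MUNW, MUOW, MUO)
  from crossing metabolic health with BMI class;
* abdominal obesity from waist circumference (default 90/80 cm cut-offs).

All thresholds are collected in :class:`Thresholds` so a study can override
any of them; comparisons happen at full floating precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "PHENOTYPES",
    "BMI_CLASSES",
    "classify_hyperuricemia",
    "classify_bmi",
    "metabolic_health_atp3",
    "compute_homa_ir",
    "compute_vai",
    "metabolic_health_vai",
    "assign_phenotype",
    "abdominal_obesity",
    "derive_phenotypes",
]

#: The six phenotypes in reporting order (reference level first).
PHENOTYPES = ("MHNW", "MHOW", "MHO", "MUNW", "MUOW", "MUO")

BMI_CLASSES = ("underweight", "normal", "overweight", "obese")

#: Derived columns appended by :func:`derive_phenotypes`, in stable order.
DERIVED_COLUMNS = (
    "bmi",
    "bmi_class",
    "atp3_elevated_bp",
    "atp3_elevated_tg",
    "atp3_elevated_fpg",
    "atp3_reduced_hdl",
    "atp3_component_count",
    "metabolically_healthy_atp3",
    "vai",
    "metabolically_healthy_vai",
    "homa_ir",
    "phenotype",
    "abdominal_obesity",
    "hyperuricemia",
)


class DomainError(ValueError):
    """A measurement is outside its physiological domain (e.g. non-positive)."""


@dataclass(frozen=True)
class Thresholds:
    """All cut-offs used in phenotype derivation.

    Defaults follow the Chinese adult criteria used throughout the package:
    hyperuricemia at 420/360 umol/L (men/women), BMI classes at 18.5/24/28,
    ATP-III components at SBP/DBP 130/85 mmHg, TG 1.7 mmol/L, FPG 5.6 mmol/L,
    HDL-C 1.04/1.3 mmol/L (men/women), VAI health below 1.59, abdominal
    obesity at waist >= 90/80 cm (men/women).  ``unhealthy_min_components``
    is the smallest ATP-III component count labelled metabolically unhealthy
    (2 by the usual ATP-III convention once waist is dropped; set 3 for a
    stricter reading).
    """

    sua: dict[str, float] = field(
        default_factory=lambda: {"male": 420.0, "female": 360.0}
    )
    bmi_normal: float = 18.5
    bmi_overweight: float = 24.0
    bmi_obese: float = 28.0
    sbp: float = 130.0
    dbp: float = 85.0
    tg: float = 1.7
    fpg: float = 5.6
    hdl: dict[str, float] = field(
        default_factory=lambda: {"male": 1.04, "female": 1.3}
    )
    vai: float = 1.59
    waist: dict[str, float] = field(
        default_factory=lambda: {"male": 90.0, "female": 80.0}
    )
    unhealthy_min_components: int = 2

    def with_overrides(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


def _check_sex(sex) -> None:
    bad = set(np.unique(np.asarray(sex, dtype=object))) - {"male", "female"}
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")


def classify_hyperuricemia(sua, sex, thresholds: Thresholds | None = None):
    """Flag hyperuricemia from serum uric acid (umol/L), inclusive cut-off.

    Vectorised: accepts scalars or arrays of equal shape.
    """
    t = thresholds or Thresholds()
    sua = np.asarray(sua, dtype=float)
    if np.any(sua <= 0):
        raise DomainError("serum uric acid must be positive")
    _check_sex(sex)
    cut = np.where(np.asarray(sex, dtype=object) == "male", t.sua["male"], t.sua["female"])
    out = sua >= cut
    return bool(out) if out.ndim == 0 else out


def classify_bmi(weight, height, thresholds: Thresholds | None = None):
    """BMI (kg/m^2) and BMI class from weight (kg) and height (m).

    Classes are half-open bins [18.5, 24), [24, 28), [28, inf); below 18.5 is
    underweight.
    """
    t = thresholds or Thresholds()
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise DomainError("weight and height must be positive")
    bmi = weight / height**2
    edges = [t.bmi_normal, t.bmi_overweight, t.bmi_obese]
    idx = np.digitize(bmi, edges)  # 0 underweight .. 3 obese
    cls = np.asarray(BMI_CLASSES, dtype=object)[idx]
    if bmi.ndim == 0:
        return float(bmi), str(cls)
    return bmi, cls


def metabolic_health_atp3(
    sex,
    sbp,
    dbp,
    tg,
    fpg,
    hdl,
    antihypertensive_drug=0,
    lipid_drug=0,
    diabetes_drug=0,
    thresholds: Thresholds | None = None,
):
    """ATP-III component flags, component count, and metabolic-health flag.

    The four components (waist circumference excluded) are: elevated blood
    pressure (SBP >= 130 or DBP >= 85 mmHg or antihypertensive drugs),
    elevated triglycerides (TG >= 1.7 mmol/L or lipid-lowering drugs),
    elevated fasting glucose (FPG >= 5.6 mmol/L or diabetes medication), and
    reduced HDL-C (< 1.04 men / < 1.3 women mmol/L).  ``healthy`` is True when
    the count is below ``thresholds.unhealthy_min_components``.

    Returns ``(flags, count, healthy)`` where ``flags`` is a dict of the four
    boolean arrays keyed bp/tg/fpg/hdl.
    """
    t = thresholds or Thresholds()
    _check_sex(sex)
    arrs = {}
    for name, v in ("sbp", sbp), ("dbp", dbp), ("tg", tg), ("fpg", fpg), ("hdl", hdl):
        v = np.asarray(v, dtype=float)
        if np.any(np.isnan(v)):
            raise ValueError(f"missing value in required field {name!r}")
        arrs[name] = v
    hdl_cut = np.where(
        np.asarray(sex, dtype=object) == "male", t.hdl["male"], t.hdl["female"]
    )
    flags = {
        "bp": (arrs["sbp"] >= t.sbp)
        | (arrs["dbp"] >= t.dbp)
        | (np.asarray(antihypertensive_drug, dtype=bool)),
        "tg": (arrs["tg"] >= t.tg) | (np.asarray(lipid_drug, dtype=bool)),
        "fpg": (arrs["fpg"] >= t.fpg) | (np.asarray(diabetes_drug, dtype=bool)),
        "hdl": arrs["hdl"] < hdl_cut,
    }
    count = sum(f.astype(int) for f in flags.values())
    healthy = count < t.unhealthy_min_components
    return flags, count, healthy


def compute_homa_ir(insulin, fpg):
    """HOMA-IR = fasting insulin (uIU/mL) x FPG (mmol/L) / 22.5."""
    insulin = np.asarray(insulin, dtype=float)
    fpg = np.asarray(fpg, dtype=float)
    if np.any(insulin < 0):
        raise DomainError("fasting insulin must be non-negative")
    if np.any(fpg <= 0):
        raise DomainError("fasting plasma glucose must be positive")
    out = insulin * fpg / 22.5
    return float(out) if out.ndim == 0 else out


def compute_vai(sex, wc, bmi, tg, hdl):
    """Sex-specific Visceral Adiposity Index.

    men:   (WC / (39.68 + 1.88 BMI)) * (TG / 1.03) * (1.31 / HDL)
    women: (WC / (36.58 + 1.89 BMI)) * (TG / 0.81) * (1.52 / HDL)

    WC in cm, TG and HDL-C in mmol/L.
    """
    _check_sex(sex)
    wc = np.asarray(wc, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    tg = np.asarray(tg, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    if np.any(wc <= 0) or np.any(bmi <= 0) or np.any(tg <= 0) or np.any(hdl <= 0):
        raise DomainError("VAI inputs must be positive")
    male = np.asarray(sex, dtype=object) == "male"
    vai_m = (wc / (39.68 + 1.88 * bmi)) * (tg / 1.03) * (1.31 / hdl)
    vai_f = (wc / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl)
    out = np.where(male, vai_m, vai_f)
    return float(out) if out.ndim == 0 else out


def metabolic_health_vai(sex, wc, bmi, tg, hdl, thresholds: Thresholds | None = None):
    """VAI value and the VAI-based metabolic-health flag (healthy iff VAI < 1.59)."""
    t = thresholds or Thresholds()
    vai = compute_vai(sex, wc, bmi, tg, hdl)
    healthy = np.asarray(vai) < t.vai
    if np.ndim(vai) == 0:
        return vai, bool(healthy)
    return vai, healthy


def assign_phenotype(bmi_class, healthy):
    """Cross-classify BMI class with metabolic health into the six phenotypes.

    Underweight records map to ``"excluded"`` (phenotype-stratified analyses
    start at BMI 18.5).
    """
    bmi_class = np.asarray(bmi_class, dtype=object)
    healthy = np.asarray(healthy, dtype=bool)
    table = {
        ("normal", True): "MHNW",
        ("overweight", True): "MHOW",
        ("obese", True): "MHO",
        ("normal", False): "MUNW",
        ("overweight", False): "MUOW",
        ("obese", False): "MUO",
    }
    out = np.empty(bmi_class.shape, dtype=object)
    flat_cls, flat_h, flat_out = bmi_class.ravel(), healthy.ravel(), out.ravel()
    for i in range(flat_out.size):
        c = flat_cls[i]
        if c == "underweight":
            flat_out[i] = "excluded"
        else:
            try:
                flat_out[i] = table[(c, bool(flat_h[i]))]
            except KeyError:
                raise ValueError(f"unknown BMI class {c!r}") from None
    if out.ndim == 0:
        return str(out[()])
    return out


def abdominal_obesity(wc, sex, thresholds: Thresholds | None = None):
    """Abdominal obesity: waist circumference at or above the sex cut-off."""
    t = thresholds or Thresholds()
    wc = np.asarray(wc, dtype=float)
    if np.any(wc <= 0):
        raise DomainError("waist circumference must be positive")
    _check_sex(sex)
    cut = np.where(
        np.asarray(sex, dtype=object) == "male", t.waist["male"], t.waist["female"]
    )
    out = wc >= cut
    return bool(out) if out.ndim == 0 else out


def derive_phenotypes(
    cohort: pd.DataFrame,
    thresholds: Thresholds | None = None,
    health_criterion: str = "atp3",
) -> pd.DataFrame:
    """Append every derived column to a cohort table.

    ``health_criterion`` selects which metabolic-health definition feeds the
    six-way phenotype: ``"atp3"`` (default) or ``"vai"`` (the sensitivity
    definition).  The input is not modified; the result carries the original
    columns followed by :data:`DERIVED_COLUMNS` in stable order.
    """
    t = thresholds or Thresholds()
    if health_criterion not in ("atp3", "vai"):
        raise ValueError("health_criterion must be 'atp3' or 'vai'")
    df = cohort.copy()
    sex = df["sex"].to_numpy(dtype=object)
    bmi, bmi_class = classify_bmi(df["weight"], df["height"], t)
    flags, count, healthy_atp3 = metabolic_health_atp3(
        sex,
        df["sbp"],
        df["dbp"],
        df["tg"],
        df["fpg"],
        df["hdl_c"],
        df["antihypertensive_drug"],
        df["lipid_drug"],
        df["diabetes_drug"],
        t,
    )
    vai, healthy_vai = metabolic_health_vai(sex, df["waist_circumference"], bmi, df["tg"], df["hdl_c"], t)
    healthy = healthy_atp3 if health_criterion == "atp3" else healthy_vai
    df["bmi"] = bmi
    df["bmi_class"] = bmi_class
    df["atp3_elevated_bp"] = flags["bp"].astype(int)
    df["atp3_elevated_tg"] = flags["tg"].astype(int)
    df["atp3_elevated_fpg"] = flags["fpg"].astype(int)
    df["atp3_reduced_hdl"] = flags["hdl"].astype(int)
    df["atp3_component_count"] = np.asarray(count, dtype=int)
    df["metabolically_healthy_atp3"] = np.asarray(healthy_atp3, dtype=int)
    df["vai"] = vai
    df["metabolically_healthy_vai"] = np.asarray(healthy_vai, dtype=int)
    df["homa_ir"] = compute_homa_ir(df["fasting_insulin"], df["fpg"])
    df["phenotype"] = assign_phenotype(bmi_class, healthy)
    df["abdominal_obesity"] = np.asarray(
        abdominal_obesity(df["waist_circumference"], sex, t), dtype=int
    )
    df["hyperuricemia"] = np.asarray(
        classify_hyperuricemia(df["uric_acid"], sex, t), dtype=int
    )
    return df
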