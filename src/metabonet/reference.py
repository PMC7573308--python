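"""Ground-truth models for recovery studies.

These synthetic reference objects define the conditions under which the
package validates itself:

* :func:`reasoning_reference_network` — a five-node discrete network
  (sex, BMI group, ATP-III component count, diabetes, hyperuricemia) whose
  hyperuricemia CPT encodes the conditional probabilities reported for
  Chinese adults (e.g. 0.05 for metabolically healthy normal weight, 0.076 /
  0.124 for metabolically healthy obese men / women, 0.606 for
  metabolically unhealthy obese with diabetes).  Forward-sampling it,
  refitting CPTs and querying should recover those values.
* :func:`recovery_reference_network` — a six-node binary network with
  strong dependencies, the target of structure-recovery experiments
  (bootstrap-averaged skeleton vs. the true skeleton).
* :func:`association_recovery_spec` — a women-only cohort spec whose
  hyperuricemia is generated from an explicit log-odds model with the
  published fully-adjusted phenotype odds ratios (MHO OR 1.95 etc.), for
  odds-ratio-recovery experiments.
"""

from __future__ import annotations

import numpy as np

from .cohort import GeneratorSpec, LogisticOutcome
from .graphs import Dag
from .infer import BnModel

__all__ = [
    "reasoning_reference_network",
    "recovery_reference_network",
    "association_recovery_spec",
    "REASONING_SCENARIOS",
]

#: The eight standard reasoning scenarios (BMI group, component count,
#: optional sex or diabetes evidence) used in the conditional-probability
#: report.
REASONING_SCENARIOS = [
    {"bmi_group": "normal", "components": 0},
    {"bmi_group": "obese", "components": 0},
    {"bmi_group": "obese", "components": 1},
    {"bmi_group": "obese", "components": 2},
    {"bmi_group": "obese", "components": 4},
    {"bmi_group": "obese", "components": 0, "sex": "male"},
    {"bmi_group": "obese", "components": 0, "sex": "female"},
    {"bmi_group": "obese", "components": 4, "diabetes": "yes"},
]


def reasoning_reference_network() -> BnModel:
    """Five-node ground truth for conditional-probability recovery.

    Structure: sex, bmi_group and components are roots; diabetes depends on
    components; hyperuricemia depends on all four.  Marginals give every
    queried evidence cell a few thousand expected records per 100,000
    samples, so refitted CPTs answer the standard queries to within about
    one percentage point of truth.

    The hyperuricemia CPT is sex-specific only where the reported
    probabilities distinguish sex (obese with zero components: 0.076 men,
    0.124 women) and diabetes-specific only where they distinguish diabetes
    (obese with four components: 0.606 with diabetes, 0.514 without, mixing
    to the reported 0.56 at the 50% diabetes rate of that cell).
    """
    nodes = ("sex", "bmi_group", "components", "diabetes", "hyperuricemia")
    dag = Dag(
        nodes=nodes,
        arcs=frozenset({
            ("components", "diabetes"),
            ("sex", "hyperuricemia"),
            ("bmi_group", "hyperuricemia"),
            ("components", "hyperuricemia"),
            ("diabetes", "hyperuricemia"),
        }),
    )
    levels = {
        "sex": ["male", "female"],
        "bmi_group": ["normal", "overweight", "obese"],
        "components": [0, 1, 2, 3, 4],
        "diabetes": ["no", "yes"],
        "hyperuricemia": [0, 1],
    }
    p_female = 0.536
    p_bmi = np.array([0.40, 0.30, 0.30])
    p_comp = np.array([0.28, 0.18, 0.16, 0.14, 0.24])
    p_diab = np.array([0.05, 0.08, 0.12, 0.20, 0.50])  # per component count

    # base P(hyperuricemia=1 | bmi, components), sex/diabetes-free cells
    base = np.array([
        [0.05, 0.07, 0.155, 0.22, 0.28],   # normal weight
        [0.07, 0.10, 0.22, 0.32, 0.42],    # overweight
        [0.10, 0.14, 0.31, 0.43, 0.56],    # obese
    ])
    # axes: sex, bmi, components, diabetes, hyperuricemia-level
    hu = np.zeros((2, 3, 5, 2, 2))
    for si in range(2):
        for bi in range(3):
            for ci in range(5):
                for di in range(2):
                    p = base[bi, ci]
                    if bi == 2 and ci == 0:
                        p = 0.076 if si == 0 else 0.124
                    if bi == 2 and ci == 4:
                        p = 0.606 if di == 1 else 0.514
                    hu[si, bi, ci, di] = [1 - p, p]
    cpts = {
        "sex": np.array([1 - p_female, p_female]),
        "bmi_group": p_bmi,
        "components": p_comp,
        "diabetes": np.stack([1 - p_diab, p_diab], axis=1),
        "hyperuricemia": hu,
    }
    return BnModel(dag=dag, levels=levels, cpts=cpts)


def recovery_reference_network() -> BnModel:
    """Six binary nodes with strong monotone dependencies.

    Structure A->B, B->C, A->D, C->E, D->E, E->F mixes a chain, a fork and a
    collider.  Conditional probabilities of 0.15/0.85 (and a graded collider
    row) make every arc easily detectable at moderate sample sizes while
    keeping non-adjacent pairs conditionally independent.
    """
    nodes = ("A", "B", "C", "D", "E", "F")
    dag = Dag(
        nodes=nodes,
        arcs=frozenset({("A", "B"), ("B", "C"), ("A", "D"), ("C", "E"),
                        ("D", "E"), ("E", "F")}),
    )
    levels = {v: [0, 1] for v in nodes}
    one_parent = np.array([[0.85, 0.15], [0.15, 0.85]])
    collider = np.array([
        [[0.90, 0.10], [0.55, 0.45]],
        [[0.55, 0.45], [0.10, 0.90]],
    ])  # axes: C, D, E
    cpts = {
        "A": np.array([0.5, 0.5]),
        "B": one_parent,
        "C": one_parent,
        "D": one_parent,
        "E": collider,
        "F": one_parent,
    }
    return BnModel(dag=dag, levels=levels, cpts=cpts)


#: Fully-adjusted (model-2) women's phenotype odds ratios used as generating
#: effects in odds-ratio-recovery experiments.
WOMEN_MODEL2_ORS = {"MHOW": 1.28, "MHO": 1.95, "MUNW": 3.34, "MUOW": 4.45, "MUO": 6.31}


def association_recovery_spec(n_subjects: int = 200_000, seed: int = 0,
                              sex: str = "female") -> GeneratorSpec:
    """Cohort spec generating hyperuricemia from explicit log-odds effects.

    Single-sex cohort with the survey phenotype distribution for that sex;
    the outcome follows a logistic model with phenotype log-odds set to the
    published fully-adjusted odds ratios (MHNW reference, baseline
    prevalence 4% in women / 11.4% in men) plus modest covariate effects
    centred at typical covariate values, so a correctly specified
    fully-adjusted refit recovers the generating odds ratios.
    """
    baseline = 0.04 if sex == "female" else 0.114
    outcome = LogisticOutcome(
        baseline_prevalence=baseline,
        phenotype_logodds={k: float(np.log(v)) for k, v in WOMEN_MODEL2_ORS.items()},
        covariate_coefs={
            "age": 0.02, "urban": 0.10, "smoker": 0.15, "alcohol": 0.15,
            "white_blood_cell": 0.05, "tc": 0.10, "ldl_c": 0.05,
            "hs_crp": 0.01, "diabetes": 0.30,
        },
        covariate_refs={
            "age": 50.3, "urban": 0.68, "smoker": 0.31, "alcohol": 0.33,
            "white_blood_cell": 6.5, "tc": 4.88, "ldl_c": 3.0,
            "hs_crp": 2.4, "diabetes": 0.05,
        },
    )
    return GeneratorSpec(
        n_subjects=n_subjects,
        female_fraction=1.0 if sex == "female" else 0.0,
        logistic_outcome=outcome,
        seed=seed,
    )
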