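"""Formats, configuration, discretization and the end-to-end pipeline.

``run_pipeline`` chains: simulate (or read) a cohort -> derive phenotypes ->
descriptives -> stratum prevalences -> sequentially-adjusted association
models -> Bayesian-network structure learning (bootstrap arc strengths,
averaged network at 0.5, simplified network at 0.85) -> CPT fitting ->
conditional-probability reasoning table.  Every stage writes plain-text
artifacts (CSV/TSV/DOT/JSON) into the output directory and the run log
records the seed, package versions and every threshold in force, so a run
is self-describing and byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import COHORT_COLUMNS, GeneratorSpec, sample_cohort
from .epi import describe_cohort, prevalence_by_phenotype, run_association_models
from .graphs import ConstraintSet, Dag, layering_constraints
from .infer import BnModel, fit_cpts, reasoning_table
from .learn import ArcStrengthTable, SearchParams, bootstrap_arc_strengths, average_network
from .phenotypes import Thresholds, derive_phenotypes

logger = logging.getLogger("metabonet")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_cohort",
    "export_graph",
    "import_graph",
    "discretize_for_bn",
    "default_roles",
    "run_pipeline",
]

_NUMERIC = [c for c in COHORT_COLUMNS if c not in ("id", "sex")]

#: Default discretization cut points for the network variables.
DEFAULT_CUTPOINTS = {"ldl_c": 3.37, "tc": 5.2, "hs_crp": 3.0}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SchemaError(ValueError):
    """Input CSV does not match the cohort column dictionary."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    ``input_csv`` reads an existing cohort; when None a synthetic cohort of
    ``n_subjects`` is generated.  The BN block sets the bootstrap count
    ``bootstrap_R``, the averaged/simplified strength thresholds and the
    tabu-search parameters; ``cutpoints`` override the dichotomisation cut
    points for LDL-C, total cholesterol and hs-CRP (white blood cell always
    splits at the cohort median).
    """

    out_dir: str = "metabonet_out"
    input_csv: str | None = None
    n_subjects: int = 7364
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    ci_method: str = "wilson"
    level: float = 0.95
    bootstrap_R: int = 300
    averaged_threshold: float = 0.5
    simplified_threshold: float = 0.85
    search: SearchParams = field(default_factory=SearchParams)
    cutpoints: dict = field(default_factory=lambda: dict(DEFAULT_CUTPOINTS))
    cpt_alpha: float = 0.0

    def __post_init__(self):
        if not (0 < self.averaged_threshold <= 1 and 0 < self.simplified_threshold <= 1):
            raise ValueError("BN strength thresholds must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "search" in d:
            d["search"] = SearchParams(**d["search"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o))


def read_cohort(path, schema: tuple[str, ...] = COHORT_COLUMNS) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    The header must match the column dictionary exactly (order-insensitive);
    numeric columns must parse; rows with any missing required field are
    dropped (complete-case contract) with the exclusion count logged.
    """
    df = pd.read_csv(path)
    missing = set(schema) - set(df.columns)
    extra = set(df.columns) - set(schema)
    if missing or extra:
        raise SchemaError(
            f"column mismatch: missing {sorted(missing)}, unknown {sorted(extra)}"
        )
    for c in _NUMERIC:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[c], errors="coerce")
            row = int(np.where(bad.isna() & df[c].notna())[0][0])
            raise SchemaError(f"non-numeric value in column {c!r} at data row {row}") from None
    n0 = len(df)
    df = df.dropna()
    excluded = n0 - len(df)
    logger.info("read %d records from %s; excluded %d incomplete", n0, path, excluded)
    if excluded:
        logger.info("complete-case rule removed %d record(s)", excluded)
    df.attrs["excluded_incomplete"] = excluded
    return df[list(schema)].reset_index(drop=True)


def export_graph(dag: Dag, path, fmt: str = "dot", strengths: ArcStrengthTable | None = None) -> None:
    """Write a DAG as DOT (optionally strength-labelled arcs) or adjacency JSON.

    Node and arc order is deterministic; the JSON form round-trips through
    :func:`import_graph` to an identical DAG.
    """
    path = Path(path)
    if fmt == "dot":
        lines = ["digraph bn {"]
        for v in dag.nodes:
            lines.append(f'  "{v}";')
        for a, b in sorted(dag.arcs):
            label = ""
            if strengths is not None:
                label = f' [label="{strengths.strength(a, b):.2f}"]'
            lines.append(f'  "{a}" -> "{b}"{label};')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "json":
        payload = {"nodes": list(dag.nodes), "arcs": sorted(map(list, dag.arcs))}
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown graph format {fmt!r} (expected 'dot' or 'json')")


def import_graph(path) -> Dag:
    """Read a DAG from the adjacency-JSON form written by :func:`export_graph`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return Dag(tuple(payload["nodes"]), frozenset(map(tuple, payload["arcs"])))


#: The fourteen network variables and their layering roles.
def default_roles() -> dict[str, str]:
    return {
        "hyperuricemia": "outcome",
        "mets": "exposure",
        "bmi_level": "exposure",
        "sex": "demographic",
        "age_group": "covariate",
        "diabetes": "covariate",
        "smoker": "covariate",
        "alcohol": "covariate",
        "urban": "covariate",
        "abdominal_obesity": "covariate",
        "ldl_high": "covariate",
        "tc_high": "covariate",
        "hscrp_high": "covariate",
        "wbc_high": "covariate",
    }


def discretize_for_bn(
    phenotyped: pd.DataFrame,
    cutpoints: dict | None = None,
    components_as_count: bool = False,
) -> pd.DataFrame:
    """Code the phenotyped cohort into the network's discrete variables.

    Fourteen variables: sex; age group (18-39/40-59/60+); BMI level
    (normal/overweight/obese, underweight dropped); metabolic syndrome
    (binary ATP-III, or the 0-4 component count when
    ``components_as_count``); hyperuricemia; diabetes; smoking; alcohol;
    urban residence; abdominal obesity; and LDL-C, total cholesterol,
    hs-CRP and white blood cell dichotomised at 3.37 / 5.2 / 3.0 and the
    cohort median respectively (config-overridable).
    """
    cp = dict(DEFAULT_CUTPOINTS)
    cp.update(cutpoints or {})
    df = phenotyped[phenotyped["bmi_class"] != "underweight"]
    out = pd.DataFrame(index=df.index)
    out["sex"] = df["sex"]
    out["age_group"] = pd.cut(
        df["age"], bins=[18, 40, 60, np.inf], right=False, labels=["18-39", "40-59", "60+"]
    ).astype(str)
    out["bmi_level"] = df["bmi_class"]
    if components_as_count:
        out["mets"] = df["atp3_component_count"].astype(int)
    else:
        out["mets"] = (1 - df["metabolically_healthy_atp3"]).astype(int)
    out["hyperuricemia"] = df["hyperuricemia"].astype(int)
    out["diabetes"] = df["diabetes"].astype(int)
    out["smoker"] = df["smoker"].astype(int)
    out["alcohol"] = df["alcohol"].astype(int)
    out["urban"] = df["urban"].astype(int)
    out["abdominal_obesity"] = df["abdominal_obesity"].astype(int)
    out["ldl_high"] = (df["ldl_c"] >= cp["ldl_c"]).astype(int)
    out["tc_high"] = (df["tc"] >= cp["tc"]).astype(int)
    out["hscrp_high"] = (df["hs_crp"] >= cp["hs_crp"]).astype(int)
    out["wbc_high"] = (df["white_blood_cell"] >= df["white_blood_cell"].median()).astype(int)
    return out.reset_index(drop=True)


def _write_failure(out: Path, stage: str, cause: Exception) -> None:
    (out / "FAILED").write_text(f"stage: {stage}\ncause: {cause}\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict of the in-memory artifacts (tables, graphs, model).  On a
    stage failure, partial outputs are retained next to a ``FAILED`` marker
    naming the stage, and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "init"
    try:
        stage = "cohort"
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv)
        else:
            spec = GeneratorSpec.default(n_subjects=config.n_subjects, seed=config.seed,
                                         thresholds=config.thresholds)
            cohort = sample_cohort(spec)
            spec.to_yaml(out / "generator_spec.yaml")
        cohort.to_csv(out / "cohort.csv", index=False)
        artifacts["cohort"] = cohort

        stage = "phenotype"
        phen = derive_phenotypes(cohort, config.thresholds)
        phen.to_csv(out / "phenotyped.csv", index=False)
        artifacts["phenotyped"] = phen

        stage = "describe"
        desc = describe_cohort(phen, "sex")
        desc.to_csv(out / "descriptives.csv", index=False)
        artifacts["descriptives"] = desc

        stage = "prevalence"
        prev = prevalence_by_phenotype(phen, level=config.level, method=config.ci_method)
        prev.to_csv(out / "prevalence.csv", index=False)
        artifacts["prevalence"] = prev

        stage = "associate"
        ors = run_association_models(phen, config.thresholds, config.level)
        ors.to_csv(out / "odds_ratios.csv", index=False)
        artifacts["odds_ratios"] = ors

        stage = "learn-bn"
        disc = discretize_for_bn(phen, config.cutpoints)
        constraints = layering_constraints(default_roles())
        strengths = bootstrap_arc_strengths(
            disc, constraints, config.search, R=config.bootstrap_R
        )
        strengths.to_tsv(out / "arc_strengths.tsv")
        averaged = average_network(strengths, config.averaged_threshold)
        simplified = average_network(strengths, config.simplified_threshold)
        for name, dag in ("averaged", averaged), ("simplified", simplified):
            export_graph(dag, out / f"{name}_dag.dot", "dot", strengths)
            export_graph(dag, out / f"{name}_dag.json", "json")
        artifacts.update(strengths=strengths, averaged=averaged, simplified=simplified)

        stage = "fit-cpts"
        bn = fit_cpts(averaged, disc, alpha=config.cpt_alpha)
        bn.to_json(out / "bn_model.json")
        artifacts["bn"] = bn

        stage = "query-bn"
        # the reasoning network conditions on the 0-4 component count rather
        # than the binary syndrome flag, so count-specific scenarios are
        # expressible; structure is carried over from the averaged network
        disc_count = discretize_for_bn(phen, config.cutpoints, components_as_count=True)
        bn_count = fit_cpts(averaged, disc_count, alpha=config.cpt_alpha)
        scenarios = [
            {"bmi_level": "normal", "mets": 0},
            {"bmi_level": "obese", "mets": 0},
            {"bmi_level": "obese", "mets": 1},
            {"bmi_level": "obese", "mets": 2},
            {"bmi_level": "obese", "mets": 4},
            {"bmi_level": "obese", "mets": 0, "sex": "male"},
            {"bmi_level": "obese", "mets": 0, "sex": "female"},
            {"bmi_level": "obese", "mets": 4, "diabetes": 1},
        ]
        reasoning = reasoning_table(bn_count, scenarios, target="hyperuricemia", event_level=1)
        reasoning.to_csv(out / "reasoning.csv", index=False)
        artifacts["reasoning"] = reasoning

        stage = "report"
        log = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "defaults_in_force": {
                "metabolic_health": "ATP-III, unhealthy at >= "
                f"{config.thresholds.unhealthy_min_components} of 4 components (waist excluded)",
                "vai_threshold": config.thresholds.vai,
                "abdominal_obesity_cm": config.thresholds.waist,
                "prevalence_ci": config.ci_method,
                "or_ci": "Wald on the log-odds scale",
                "stepwise": "backward AIC, phenotype indicators as a block",
                "bic": "natural log, penalty (ln N)/2 per free parameter",
                "tabu": asdict(config.search),
                "bootstrap_m": "n (resampling with replacement)",
                "averaged_orientation": "majority bootstrap direction, ties to "
                "lexicographically smaller source; weakest arcs dropped on cycles",
                "cpt_estimator": f"pseudo-count alpha={config.cpt_alpha}",
                "exact_inference": "full-state-space enumeration",
                "discretization_cutpoints": config.cutpoints,
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1) + "\n", encoding="utf-8")
        report = [
            f"metabonet {__version__} pipeline report (seed {config.seed})",
            f"records: {len(cohort)}",
            f"female share: {100 * (cohort['sex'] == 'female').mean():.1f}%",
            f"hyperuricemia prevalence: {100 * phen['hyperuricemia'].mean():.1f}%",
            f"averaged network: {len(averaged.arcs)} arcs at strength >= {config.averaged_threshold}",
            f"simplified network: {len(simplified.arcs)} arcs at strength >= {config.simplified_threshold}",
        ]
        (out / "report.txt").write_text("\n".join(report) + "\n", encoding="utf-8")
        return artifacts
    except Exception as e:
        _write_failure(out, stage, e)
        raise PipelineError(stage, e) from e
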