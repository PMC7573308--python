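"""Model/Results front-end for the Bayesian-network analysis.

:class:`BayesianNetworkModel` bundles discrete data with layering
constraints and search parameters; :meth:`fit` runs the bootstrap
structure-learning pipeline (tabu + BIC per resample, arc-strength
averaging, consensus thresholding, CPT estimation) and returns a
:class:`BayesianNetworkResults` carrying the averaged network, the arc
strengths as its uncertainty summary, and query methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .graphs import ConstraintSet, Dag
from .infer import BnModel, QueryResult, exact_query, fit_cpts, reasoning_table, sample_bn
from .learn import ArcStrengthTable, SearchParams, average_network, bootstrap_arc_strengths

__all__ = ["BayesianNetworkModel", "BayesianNetworkResults"]


@dataclass
class BayesianNetworkResults:
    """Fitted network: consensus DAG, CPTs, and bootstrap arc stabilities."""

    bn: BnModel
    strengths: ArcStrengthTable
    threshold: float

    @property
    def dag(self) -> Dag:
        return self.bn.dag

    def query(self, target: str, evidence: dict | None = None) -> QueryResult:
        """Exact conditional distribution of ``target`` given ``evidence``."""
        return exact_query(self.bn, target, evidence)

    def reasoning_table(self, scenarios, target: str = "hyperuricemia", event_level=1) -> pd.DataFrame:
        return reasoning_table(self.bn, scenarios, target, event_level)

    def simulate(self, n: int, seed: int = 0) -> pd.DataFrame:
        """Forward-sample records from the fitted network."""
        return sample_bn(self.bn, n, seed)

    def summary(self) -> str:
        lines = [
            f"Averaged Bayesian network ({len(self.dag.nodes)} nodes, "
            f"{len(self.dag.arcs)} arcs at strength >= {self.threshold}, "
            f"R = {self.strengths.R} bootstraps)",
            "",
            f"{'arc':<40}{'strength':>9}{'direction':>10}",
        ]
        for a, b in sorted(self.dag.arcs):
            lines.append(
                f"{a + ' -> ' + b:<40}"
                f"{self.strengths.strength(a, b):>9.3f}"
                f"{self.strengths.direction(a, b):>10.3f}"
            )
        return "\n".join(lines)


class BayesianNetworkModel:
    """Structure-and-parameter learning for a discrete variable set.

    Parameters
    ----------
    data : DataFrame of discrete columns (one record per subject).
    constraints : layering blacklist/whitelist, optional.
    search : tabu-search parameters (seed drives bootstrap resampling).
    """

    def __init__(self, data: pd.DataFrame, constraints: ConstraintSet | None = None,
                 search: SearchParams | None = None):
        self.data = data
        self.constraints = constraints or ConstraintSet()
        self.search = search or SearchParams()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BayesianNetworkModel":
        return cls(data, **kwargs)

    def fit(self, R: int = 300, threshold: float = 0.5, alpha: float = 0.0,
            m: int | None = None) -> BayesianNetworkResults:
        """Bootstrap-learn the consensus network and estimate its CPTs."""
        strengths = bootstrap_arc_strengths(self.data, self.constraints, self.search, R=R, m=m)
        dag = average_network(strengths, threshold)
        bn = fit_cpts(dag, self.data, alpha=alpha)
        return BayesianNetworkResults(bn=bn, strengths=strengths, threshold=threshold)
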