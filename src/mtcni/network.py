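"""Treatment-network construction, connectivity and study filters.

Each study in an MTC dataset connects the treatments it compares: every
within-study treatment pair contributes one unit of weight to the
corresponding network edge, so edge weight counts the studies providing
direct evidence for a comparison. The arm-based hierarchical model can draw
inference even from weak or disconnected networks (cross-component contrasts
are then prior-driven), so disconnection is reported rather than rejected
here; the fitting layer demands an explicit override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .data import TrialDataset

logger = logging.getLogger("mtcni")


@dataclass
class TreatmentNetwork:
    """Treatments as nodes, studies as (weighted) edges."""

    graph: nx.Graph
    components: list[frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.components = [
            frozenset(c) for c in nx.connected_components(self.graph)
        ]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        """Unordered treatment pairs (sorted tuples) -> study-count weight."""
        return {
            tuple(sorted((a, b))): d["weight"]
            for a, b, d in self.graph.edges(data=True)
        }

    @property
    def is_connected(self) -> bool:
        return len(self.components) <= 1

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"treatment_a": a, "treatment_b": b, "n_studies": w}
            for (a, b), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "n_studies"])

    def write_edge_list(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, index=False)

    def to_dot(self) -> str:
        """DOT serialisation; edge penwidth proportional to study count."""
        lines = ["graph treatments {"]
        for node in sorted(self.graph.nodes):
            lines.append(f'  "{node}";')
        for (a, b), w in sorted(self.edges.items()):
            lines.append(f'  "{a}" -- "{b}" [label={w}, penwidth={w}];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_dot(self, path: str | Path) -> None:
        Path(path).write_text(self.to_dot())


def build_network(dataset: TrialDataset) -> TreatmentNetwork:
    """Build the treatment network of a dataset.

    Every within-study treatment pair adds 1 to its edge weight (a 3-arm
    study contributes all three pairwise edges). A disconnected network is
    reported via ``components``, not rejected.
    """
    g = nx.Graph()
    g.add_nodes_from(dataset.treatment_ids)
    for study in dataset.study_ids:
        arms = dataset.arms_of_study(study)
        for a, b in combinations(sorted({x.treatment_id for x in arms}), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    net = TreatmentNetwork(g)
    if not net.is_connected:
        logger.warning(
            "treatment network is disconnected: %d components %s",
            len(net.components),
            [sorted(c) for c in net.components],
        )
    return net


@dataclass(frozen=True)
class StudyFilter:
    """Sensitivity-analysis study selection.

    ``require_history`` keeps only studies that required an explicit
    exacerbation history for entry; ``rates_adjusted`` keeps only studies
    whose reported rates were adjusted for follow-up; ``exclude_studies``
    removes named studies.
    """

    require_history: bool = False
    rates_adjusted: bool = False
    exclude_studies: tuple[str, ...] = ()

    @classmethod
    def from_token(cls, token: str) -> "StudyFilter":
        if token in ("none", "", None):
            return cls()
        if token == "require_history":
            return cls(require_history=True)
        if token == "rates_adjusted":
            return cls(rates_adjusted=True)
        raise ValueError(f"unknown filter token {token!r}")


def filter_studies(dataset: TrialDataset, criteria: StudyFilter) -> TrialDataset:
    """Apply a sensitivity-analysis filter, reporting removals and the
    filtered network's connectivity. An empty result is an error."""
    keep: list[str] = []
    for study in dataset.study_ids:
        flags = dataset.study_flags.get(study)
        if criteria.require_history and not (
            flags and flags.explicit_history_required
        ):
            continue
        if criteria.rates_adjusted and not (
            flags and flags.rates_follow_up_adjusted
        ):
            continue
        if study in criteria.exclude_studies:
            continue
        keep.append(study)
    removed = [s for s in dataset.study_ids if s not in keep]
    if not keep:
        raise ValueError("study filter removed every study; nothing to fit")
    if removed:
        logger.info(
            "filter removed %d of %d studies: %s",
            len(removed), dataset.n_studies, removed,
        )
    subset = dataset.subset(keep)
    net = build_network(subset)
    if not net.is_connected:
        logger.warning("filtered network is disconnected")
    return subset
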