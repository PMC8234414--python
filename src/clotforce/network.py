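"""Signed directed graph of the MLCK/MLCP signaling cascade.

The cascade controlling myosin light chain phosphorylation (pMLC, the output
node) is encoded as a signed directed graph: MLCK phosphorylates MLC (+) while
MLCP dephosphorylates it (-); upstream kinases, phosphatase regulators and
second messengers carry activation (+1) or inhibition (-1) edges. A reagent
perturbation binds to one node as an activator or inhibitor, and the predicted
direction of pMLC change is obtained by static sign propagation: for every
simple path from the target to pMLC, the effect is the perturbation sign times
the product of edge signs; unanimous paths give "up" or "down", disagreeing
paths "ambiguous". No kinetics are simulated.

The default perturbation bindings cover the eight reagents assayed: sign
propagation matches the observed force/pMLC direction for seven of them.
Sildenafil is the documented exception — as a PDE5 inhibitor it is predicted
to lower pMLC (PDE5 -| PKG -| PKC chain), yet the observed force and pMLC both
rise, a paradox attributed to off-pathway effects (fibrinogen depletion,
ATP-mediated secondary activation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Optional

import networkx as nx
import pandas as pd

from .errors import DomainError, NoPathToOutputError, UnknownReagentError

__all__ = [
    "Direction",
    "Perturbation",
    "SignedNetwork",
    "build_default_network",
    "predict_pmlc_direction",
    "compare_predictions",
    "DEFAULT_PERTURBATIONS",
    "OBSERVED_DIRECTIONS",
]

Direction = Literal["up", "down", "ambiguous"]

OUTPUT_NODE = "pMLC"


@dataclass(frozen=True)
class Perturbation:
    """A reagent acting on one node as an activator or inhibitor."""

    reagent: str
    target_node: str
    mode: Literal["inhibit", "activate"]

    def __post_init__(self) -> None:
        if self.mode not in ("inhibit", "activate"):
            raise DomainError(f"mode must be 'inhibit' or 'activate', got {self.mode!r}")

    @property
    def sign(self) -> int:
        return -1 if self.mode == "inhibit" else +1


@dataclass
class SignedNetwork:
    """Directed graph whose edges carry a sign attribute in {+1, -1}."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    output: str = OUTPUT_NODE

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if source == target:
            raise DomainError(f"self-loop {source!r} not allowed")
        if sign not in (+1, -1):
            raise DomainError(f"edge sign must be +1 or -1, got {sign!r}")
        self.graph.add_edge(source, target, sign=int(sign))

    def edge_sign(self, source: str, target: str) -> int:
        return int(self.graph.edges[source, target]["sign"])

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, int(d["sign"])) for u, v, d in self.graph.edges(data=True)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["source", "target", "sign"])


# Activation (+1) / inhibition (-1) edges of the cascade. The MLCP arm:
# CPI-17 and ROCK inhibit the phosphatase; PKG suppresses PKC; PDE5 degrades
# the cGMP pool that sustains PKG, hence PDE5 -| PKG. The endothelial inputs
# (NO activating PKG; PGI2 acting through cAMP/PKA/PDE5) complete the branch.
_DEFAULT_EDGES: list[tuple[str, str, int]] = [
    ("MLCK", "pMLC", +1),
    ("MLCP", "pMLC", -1),
    ("Ca-calmodulin", "MLCK", +1),
    ("ERK", "MLCK", +1),
    ("MEK", "ERK", +1),
    ("RAF-1", "MEK", +1),
    ("Ras", "RAF-1", +1),
    ("PKC", "ERK", +1),
    ("PKC", "CPI-17", +1),
    ("CPI-17", "MLCP", -1),
    ("PKG", "PKC", -1),
    ("PDE5", "PKG", -1),
    ("ROCK", "MLCP", -1),
    ("RhoA", "ROCK", +1),
    ("RAF-1", "RhoA", +1),
    ("TNFa", "RhoA", +1),
    ("NO", "PKG", +1),
    ("PLC", "PKC", +1),
    ("PGI2", "cAMP", +1),
    ("cAMP", "PKA", +1),
    ("PKA", "PDE5", +1),
]

#: Reagent -> node binding for the eight assayed compounds.
DEFAULT_PERTURBATIONS: dict[str, Perturbation] = {
    p.reagent: p
    for p in [
        Perturbation("U46619", "ERK", "activate"),
        Perturbation("PMA", "PKC", "activate"),
        Perturbation("okadaic_acid", "MLCP", "inhibit"),
        Perturbation("sildenafil", "PDE5", "inhibit"),
        Perturbation("Cpd7a", "PDE5", "inhibit"),
        Perturbation("ML-7", "MLCK", "inhibit"),
        Perturbation("K252d", "PKC", "inhibit"),
        Perturbation("Y27632", "ROCK", "inhibit"),
    ]
}

#: Observed direction of force / pMLC change for each reagent versus control.
OBSERVED_DIRECTIONS: dict[str, Direction] = {
    "U46619": "up",
    "PMA": "up",
    "okadaic_acid": "up",
    "sildenafil": "up",  # observed rise despite the predicted fall
    "Cpd7a": "down",
    "ML-7": "down",
    "K252d": "down",
    "Y27632": "down",
}


def build_default_network() -> SignedNetwork:
    """The default MLCK/MLCP cascade graph (20 nodes, 21 signed edges)."""
    net = SignedNetwork()
    for source, target, sign in _DEFAULT_EDGES:
        net.add_edge(source, target, sign)
    return net


def predict_pmlc_direction(net: SignedNetwork, pert: Perturbation) -> Direction:
    """Predicted direction of pMLC change under a perturbation.

    Enumerates every simple path from the perturbed node to the output and
    multiplies edge signs; the perturbation's own sign (inhibit = -1) flips
    the result. Returns "ambiguous" when paths disagree.
    """
    if pert.target_node not in net.graph:
        raise NoPathToOutputError(f"target node {pert.target_node!r} not in network")
    if pert.target_node == net.output:
        effects = {pert.sign}
    else:
        effects = set()
        for path in nx.all_simple_paths(net.graph, pert.target_node, net.output):
            effect = pert.sign
            for u, v in zip(path[:-1], path[1:]):
                effect *= net.edge_sign(u, v)
            effects.add(effect)
        if not effects:
            raise NoPathToOutputError(
                f"no directed path from {pert.target_node!r} to {net.output!r}"
            )
    if effects == {+1}:
        return "up"
    if effects == {-1}:
        return "down"
    return "ambiguous"


class ComparisonResult(NamedTuple):
    """Per-reagent prediction table and overall concordance count."""

    table: pd.DataFrame
    concordant: int
    total: int


def compare_predictions(
    net: SignedNetwork,
    perturbations: Optional[Mapping[str, Perturbation]] = None,
    observed_directions: Optional[Mapping[str, Direction]] = None,
) -> ComparisonResult:
    """Tabulate predicted versus observed pMLC directions per reagent.

    With the defaults, seven of the eight reagents are concordant and
    sildenafil is the single mismatch.
    """
    perts = DEFAULT_PERTURBATIONS if perturbations is None else dict(perturbations)
    observed = OBSERVED_DIRECTIONS if observed_directions is None else dict(observed_directions)
    rows = []
    for reagent, obs in observed.items():
        if reagent not in perts:
            raise UnknownReagentError(reagent)
        pert = perts[reagent]
        pred = predict_pmlc_direction(net, pert)
        rows.append(
            {
                "reagent": reagent,
                "target": pert.target_node,
                "mode": pert.mode,
                "predicted": pred,
                "observed": obs,
                "match": pred == obs,
            }
        )
    table = pd.DataFrame(
        rows, columns=["reagent", "target", "mode", "predicted", "observed", "match"]
    )
    return ComparisonResult(table=table, concordant=int(table["match"].sum()), total=len(table))
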