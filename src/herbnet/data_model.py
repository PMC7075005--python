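"""Domain types shared by all pipeline stages.

The central object is :class:`BipartiteMap`, the two-mode target-pathway
membership relation from which everything downstream is derived: the one-mode
targets-pathways-targets (TPT) projection, pathway sizes ``N_j`` used by the
knockout-perturbation model, and the targets-pathways-diseases (TPD) network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple


@dataclass
class CompoundRecord:
    """One herbal compound with the two Veber oral-bioavailability descriptors.

    ``rotatable_bonds`` and ``tpsa`` (topological polar surface area, in
    square angstroms) come from the input table; the package never computes
    them from structure.
    """

    compound_id: str
    name: str = ""
    smiles: Optional[str] = None
    herbs: Set[str] = field(default_factory=set)
    rotatable_bonds: Optional[int] = None
    tpsa: Optional[float] = None

    def merge(self, other: "CompoundRecord") -> "CompoundRecord":
        """Merge a duplicate entry for the same compound_id.

        Herb provenance is unioned (source chemical databases overlap); the
        first non-empty value wins for the remaining fields.
        """
        if other.compound_id != self.compound_id:
            raise ValueError("cannot merge records with different compound_id")
        return CompoundRecord(
            compound_id=self.compound_id,
            name=self.name or other.name,
            smiles=self.smiles or other.smiles,
            herbs=set(self.herbs) | set(other.herbs),
            rotatable_bonds=self.rotatable_bonds
            if self.rotatable_bonds is not None
            else other.rotatable_bonds,
            tpsa=self.tpsa if self.tpsa is not None else other.tpsa,
        )


class BipartiteMap:
    """Two-mode target-pathway membership relation.

    Stores the set of (target_id, pathway_id) pairs with duplicate pairs
    collapsed, and provides the member / pathway lookups and the pathway
    sizes ``N_j`` the perturbation model needs. Identifiers are opaque,
    case-sensitive strings.
    """

    def __init__(
        self,
        pairs: Iterable[Tuple[str, str]],
        pathway_names: Optional[Mapping[str, str]] = None,
    ):
        self._pairs: FrozenSet[Tuple[str, str]] = frozenset(
            (str(t), str(p)) for t, p in pairs
        )
        members: Dict[str, Set[str]] = {}
        per_target: Dict[str, Set[str]] = {}
        for t, p in self._pairs:
            members.setdefault(p, set()).add(t)
            per_target.setdefault(t, set()).add(p)
        self._members = {p: frozenset(ts) for p, ts in members.items()}
        self._per_target = {t: frozenset(ps) for t, ps in per_target.items()}
        self.pathway_names: Dict[str, str] = dict(pathway_names or {})

    @property
    def pairs(self) -> FrozenSet[Tuple[str, str]]:
        return self._pairs

    @property
    def targets(self) -> FrozenSet[str]:
        return frozenset(self._per_target)

    @property
    def pathways(self) -> FrozenSet[str]:
        return frozenset(self._members)

    def members(self, pathway_id: str) -> FrozenSet[str]:
        """Targets annotated to ``pathway_id`` (empty set if unknown)."""
        return self._members.get(pathway_id, frozenset())

    def pathways_of(self, target_id: str) -> FrozenSet[str]:
        """Pathways containing ``target_id`` (empty set if unknown)."""
        return self._per_target.get(target_id, frozenset())

    def pathway_size(self, pathway_id: str) -> int:
        """N_j, the number of targets annotated to the pathway."""
        return len(self.members(pathway_id))

    def pathway_name(self, pathway_id: str) -> str:
        return self.pathway_names.get(pathway_id, pathway_id)

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, BipartiteMap) and self._pairs == other._pairs

    def __hash__(self):
        return hash(self._pairs)

    def __repr__(self) -> str:
        return (
            f"BipartiteMap({len(self.targets)} targets, "
            f"{len(self.pathways)} pathways, {len(self._pairs)} pairs)"
        )


@dataclass(frozen=True)
class EdgeState:
    """State of one TPT edge under a knockout.

    ``n_affected`` is t, the number of the edge's pathways that contain the
    knocked-out target; ``efficacy`` is the product of their pathway
    efficacies (EE); ``length`` is 1/EE, kept as an exact fraction.
    """

    n_affected: int
    efficacy: Fraction
    length: Fraction


@dataclass
class PerturbationResult:
    """Outcome of setting off one target in the TPT network.

    ``ned = ne_baseline - ne_perturbed`` is the ranking statistic: the drop
    in global network efficiency caused by assuming the target undruggable.
    The knocked node stays in the graph; only edge lengths change.
    """

    knocked_target: str
    pathway_efficacies: Dict[str, Fraction]
    edge_states: Dict[Tuple[str, str], EdgeState]
    ne_baseline: float
    ne_perturbed: float
    ned: float


@dataclass
class EnrichmentResult:
    """One pathway's over-representation statistics for a target query."""

    pathway_id: str
    overlap: int          # k: query genes annotated to the pathway
    pathway_size: int     # K: annotated pathway size within the universe
    query_size: int       # n: query genes within the universe
    universe_size: int    # N
    p_value: float
    q_value: float
    pathway_name: str = ""


@dataclass
class ScreenReport:
    """Summary of an oral-bioavailability screen.

    ``failing_criterion`` maps compound_id to one of "none", "bonds",
    "tpsa", "both"; a compound passes iff its label is "none".
    """

    n_input: int
    n_pass: int
    failing_criterion: Dict[str, str]

    @property
    def n_fail(self) -> int:
        return self.n_input - self.n_pass


def display_percent(x: Fraction) -> int:
    """Efficacy fraction as the rounded integer percentage (2/3 -> 67)."""
    return int(round(float(x) * 100))
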