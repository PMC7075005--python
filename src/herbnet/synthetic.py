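"""Synthetic inputs: the worked-example fixture and seeded random generators.

Three generators make every stage testable without external downloads:

* :func:`sample_network` — the 7-target / 6-pathway demonstration network
  used throughout the docs to trace the knockout calculation by hand.
* :func:`random_bipartite` — Erdos-Renyi-style bipartite target-pathway
  memberships with controllable size and density, emulating the structure
  of a real enrichment table (many small-to-medium overlapping pathways).
* :func:`synthetic_cooccurrence` — Poisson literature-co-occurrence counts
  whose log-mean rises linearly with a standardized score, the simplest
  monotone count model; slope 0 gives the independence null.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .data_model import BipartiteMap
from .errors import GenerationError

# Membership of the demonstration network: 6 pathways over targets A..G.
# Pathway sizes: a, b have 3 members; c, d, e, f have 2.
SAMPLE_PATHWAYS = {
    "a": frozenset({"A", "B", "C"}),
    "b": frozenset({"B", "C", "E"}),
    "c": frozenset({"B", "E"}),
    "d": frozenset({"C", "D"}),
    "e": frozenset({"C", "F"}),
    "f": frozenset({"F", "G"}),
}


def sample_network() -> BipartiteMap:
    """The 7-target, 6-pathway worked-example map (11 membership pairs)."""
    pairs = [(t, p) for p, members in SAMPLE_PATHWAYS.items() for t in members]
    return BipartiteMap(pairs)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random bipartite target-pathway map.

    Each (target, pathway) pair is included independently with probability
    ``membership_prob``. Pathways that end up below ``min_pathway_size``
    (default 2 — smaller pathways contribute no TPT edges) are redrawn or
    dropped according to ``on_small``.
    """

    n_targets: int
    n_pathways: int
    membership_prob: float
    min_pathway_size: int = 2
    seed: int = 0
    on_small: str = "redraw"  # or "drop"

    def __post_init__(self):
        if self.n_targets < 1 or self.n_pathways < 1:
            raise ValueError("n_targets and n_pathways must be >= 1")
        if not (0 < self.membership_prob <= 1):
            raise ValueError("membership_prob must be in (0, 1]")
        if self.on_small not in ("redraw", "drop"):
            raise ValueError("on_small must be 'redraw' or 'drop'")


_MAX_REDRAWS = 1000


def random_bipartite(spec: SyntheticSpec) -> BipartiteMap:
    """Draw a random bipartite map; identical spec+seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    t_ids = [f"T{i + 1:03d}" for i in range(spec.n_targets)]
    p_ids = [f"P{j + 1:02d}" for j in range(spec.n_pathways)]
    pairs = []
    for p in p_ids:
        members: List[str] = []
        for _ in range(_MAX_REDRAWS):
            draw = rng.random(spec.n_targets) < spec.membership_prob
            members = [t for t, hit in zip(t_ids, draw) if hit]
            if len(members) >= spec.min_pathway_size:
                break
        else:
            if spec.on_small == "drop":
                continue
            raise GenerationError(
                f"pathway {p} never reached size {spec.min_pathway_size} "
                f"in {_MAX_REDRAWS} draws (membership_prob too low?)"
            )
        pairs.extend((t, p) for t in members)
    return BipartiteMap(pairs)


def synthetic_cooccurrence(
    scores: Sequence[float],
    beta: float = 1.0,
    baseline: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Poisson counts with log-mean = baseline + beta * standardized(score).

    ``beta = 0`` makes the counts independent of the scores (the null for
    the Spearman validation); larger beta produces a stronger monotone
    association. Scores with zero variance standardize to zero.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rng = np.random.default_rng(seed)
    return rng.poisson(np.exp(baseline + beta * z))
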