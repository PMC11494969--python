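"""De-confounding: flagging coarse-network edges explained away by a common cause.

Causal discovery on a reduced omic subset implicitly assumes causal
sufficiency — that no unmeasured common cause drives two measured variables.
Adding an omic layer tests that assumption: if an edge A -> B from the coarse
network disappears in the finer network while a newly measured entity C has
edges into both A and B there, the coarse edge is plausibly spurious, with C
as the confounder.  The classic instances are a metabolite confounding a
taxon -> taxon edge and a taxon confounding a gene -> gene edge; the rule here
is generic over whichever types the finer subset adds.

A de-confounding can itself rest on edges that a still-richer network later
de-confounds; :func:`chain_deconfoundings` links such discoveries across
refinement levels into chains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DynomicsError
from .network import Edge, EntityRef, TwoSliceNetwork, entity_adjacency, subset_types


@dataclass(frozen=True)
class DeconfoundingRecord:
    """A coarse edge flagged as spurious, with the common cause that explains it.

    ``in_edges`` are the fine-network edges deconfounder -> A and
    deconfounder -> B; the overall score is the product of their bootstrap
    scores.  The confounded edge keeps its original coarse-network direction.
    """

    confounded_src: EntityRef
    confounded_dst: EntityRef
    confounded_score: float
    deconfounder: EntityRef
    in_edges: tuple[Edge, Edge]
    per_edge_scores: tuple[float, float]
    overall_score: float
    coarse_label: str
    fine_label: str

    def confounded_edge(self) -> tuple[EntityRef, EntityRef]:
        return (self.confounded_src, self.confounded_dst)


def find_deconfoundings(
    coarse: TwoSliceNetwork, fine: TwoSliceNetwork
) -> list[DeconfoundingRecord]:
    """All de-confoundings of coarse edges by newly measured common causes.

    One record per (ordered entity pair (A, B), candidate C) with A != B such
    that: (1) the coarse network has the entity-level edge A -> B; (2) the
    fine network does not; (3) the fine network has edges C -> A and C -> B
    for an entity C whose omic type the fine subset newly adds.
    """
    coarse_t = subset_types(coarse.subset_label)
    fine_t = subset_types(fine.subset_label)
    if not coarse_t < fine_t:
        raise DynomicsError(
            f"subset {coarse.subset_label!r} is not strictly nested in {fine.subset_label!r}"
        )
    added = fine_t - coarse_t
    coarse_adj = entity_adjacency(coarse)
    fine_adj = entity_adjacency(fine)
    candidates = sorted(
        {e for pair in fine_adj for e in pair if e.omic_type in added}
    )
    out: list[DeconfoundingRecord] = []
    for (a, b), coarse_edge in sorted(coarse_adj.items()):
        if a == b:
            continue  # a self-loop has no distinct pair to confound
        if (a, b) in fine_adj:
            continue  # condition 2 fails
        for c in candidates:
            e1 = fine_adj.get((c, a))
            e2 = fine_adj.get((c, b))
            if e1 is None or e2 is None:
                continue
            scores = (e1.bootstrap_score, e2.bootstrap_score)
            out.append(
                DeconfoundingRecord(
                    confounded_src=a,
                    confounded_dst=b,
                    confounded_score=coarse_edge.bootstrap_score,
                    deconfounder=c,
                    in_edges=(e1, e2),
                    per_edge_scores=scores,
                    overall_score=scores[0] * scores[1],
                    coarse_label=coarse.subset_label,
                    fine_label=fine.subset_label,
                )
            )
    return out


def deconfounding_report(rec: DeconfoundingRecord) -> dict:
    """The five reported fields of a discovery, in order:

    (i) the confounded edge, (ii) the de-confounder, (iii) the bootstrap
    scores of the edges involved, (iv) the overall score (product of the two
    in-edge scores), and (v) the two data sets used.
    """
    return {
        "confounded_edge": (
            (rec.confounded_src.name, rec.confounded_src.omic_type),
            (rec.confounded_dst.name, rec.confounded_dst.omic_type),
        ),
        "deconfounder": (rec.deconfounder.name, rec.deconfounder.omic_type),
        "edge_scores": {
            "confounded": rec.confounded_score,
            "in_edges": list(rec.per_edge_scores),
        },
        "overall_score": rec.per_edge_scores[0] * rec.per_edge_scores[1],
        "datasets": (rec.coarse_label, rec.fine_label),
    }


def parse_deconfounding_report(row: dict, in_edges: tuple[Edge, Edge]) -> DeconfoundingRecord:
    """Rebuild a record from its report row (in-edges supplied separately)."""
    (sa, ta), (sb, tb) = row["confounded_edge"]
    dn, dt = row["deconfounder"]
    scores = tuple(row["edge_scores"]["in_edges"])
    return DeconfoundingRecord(
        confounded_src=EntityRef(sa, ta),
        confounded_dst=EntityRef(sb, tb),
        confounded_score=row["edge_scores"]["confounded"],
        deconfounder=EntityRef(dn, dt),
        in_edges=in_edges,
        per_edge_scores=scores,  # type: ignore[arg-type]
        overall_score=row["overall_score"],
        coarse_label=row["datasets"][0],
        fine_label=row["datasets"][1],
    )


def chain_deconfoundings(
    discovery_sets: list[tuple[str, str, list[DeconfoundingRecord]]],
) -> list[list[DeconfoundingRecord]]:
    """Chains of de-confoundings across strictly nested refinement levels.

    ``discovery_sets`` is ordered coarsest-first; a record at one level links
    to a record at the next level when one of its in-edges (as an entity
    pair) is that record's confounded edge.  Maximal chains of length >= 2
    are returned; no chain revisits an edge.
    """
    for (c1, f1, _), (c2, f2, _) in zip(discovery_sets, discovery_sets[1:]):
        t_prev = subset_types(f1)
        t_next = subset_types(f2)
        if not t_prev < t_next:
            raise DynomicsError(
                f"refinement levels must be strictly nested: {f1!r} then {f2!r}"
            )

    def in_pairs(rec: DeconfoundingRecord) -> list[tuple[EntityRef, EntityRef]]:
        return [
            (rec.deconfounder, rec.confounded_src),
            (rec.deconfounder, rec.confounded_dst),
        ]

    chains: list[list[DeconfoundingRecord]] = []

    def extend(chain: list[DeconfoundingRecord], level: int, used: set) -> None:
        extended = False
        if level + 1 < len(discovery_sets):
            last = chain[-1]
            for nxt in discovery_sets[level + 1][2]:
                pair = nxt.confounded_edge()
                if pair in in_pairs(last) and pair not in used:
                    extend(chain + [nxt], level + 1, used | {pair})
                    extended = True
        if not extended and len(chain) >= 2:
            chains.append(chain)

    for level, (_, _, records) in enumerate(discovery_sets):
        for rec in records:
            extend([rec], level, {rec.confounded_edge()})
    # keep only maximal chains (drop chains that are suffixes of longer ones)
    keyed = [tuple(id(r) for r in c) for c in chains]
    maximal = []
    for i, c in enumerate(chains):
        if not any(i != j and _is_infix(keyed[i], keyed[j]) for j in range(len(chains))):
            maximal.append(c)
    return maximal


def _is_infix(short: tuple, long: tuple) -> bool:
    if len(short) >= len(long):
        return False
    return any(long[i : i + len(short)] == short for i in range(len(long) - len(short) + 1))
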