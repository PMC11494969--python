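"""Unrolling: explaining coarse-network edges by mediator paths in finer networks.

Networks learned from nested omic subsets see the same system at different
resolutions.  When a taxon -> taxon edge in the taxa-only network disappears
in a network that also measures metabolites, but a path
taxon -> metabolite -> taxon appears there instead, the metabolite is a
putative intermediary that *explains* the interaction.  An unrolling is
emitted for an ordered entity pair (A, B) and a mediator path when

1. the coarse network has an entity-level edge A -> B,
2. the fine network has no entity-level edge A -> B, and
3. the fine network contains a path from A to B through one mediator (or two,
   when the fine subset adds two omic layers) whose omic types are absent
   from the coarse subset.

Self-pairs (A == B) are included by default: a self-loop can unroll into a
cycle through a mediator back to the same entity.  Each discovery carries the
bootstrap scores of its replacement edges and an overall score, the product
of those scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

from .errors import DynomicsError
from .network import (
    Edge,
    EntityRef,
    TwoSliceNetwork,
    entity_adjacency,
    subset_types,
)


@dataclass(frozen=True)
class UnrollingRecord:
    """A coarse edge replaced by a mediator path in a finer network."""

    coarse_src: EntityRef
    coarse_dst: EntityRef
    coarse_score: float
    chain: tuple[Edge, ...]
    mediators: tuple[EntityRef, ...]
    coarse_label: str
    fine_label: str
    per_edge_scores: tuple[float, ...]
    overall_score: float
    support_count: int = 1

    def endpoints(self) -> tuple[EntityRef, EntityRef]:
        return (self.coarse_src, self.coarse_dst)


def score_unrolling(rec: UnrollingRecord) -> float:
    """Overall score: the product of the replacement edges' bootstrap scores.

    Two edges for a one-mediator unrolling; the product rule extends
    multiplicatively to the three edges of a full taxon -> gene ->
    metabolite -> taxon chain.
    """
    if not rec.per_edge_scores:
        raise DynomicsError("unrolling has no replacement-edge scores")
    if any(not 0.0 <= s <= 1.0 for s in rec.per_edge_scores):
        raise DynomicsError("replacement-edge scores must lie in [0, 1]")
    return float(math.prod(rec.per_edge_scores))


def _check_nested(coarse: TwoSliceNetwork, fine: TwoSliceNetwork) -> frozenset[str]:
    coarse_t = subset_types(coarse.subset_label)
    fine_t = subset_types(fine.subset_label)
    if not coarse_t < fine_t:
        raise DynomicsError(
            f"subset {coarse.subset_label!r} is not strictly nested in {fine.subset_label!r}"
        )
    return fine_t - coarse_t


def _make_record(
    pair: tuple[EntityRef, EntityRef],
    coarse_score: float,
    chain: tuple[Edge, ...],
    mediators: tuple[EntityRef, ...],
    coarse_label: str,
    fine_label: str,
) -> UnrollingRecord:
    scores = tuple(e.bootstrap_score for e in chain)
    rec = UnrollingRecord(
        coarse_src=pair[0],
        coarse_dst=pair[1],
        coarse_score=coarse_score,
        chain=chain,
        mediators=mediators,
        coarse_label=coarse_label,
        fine_label=fine_label,
        per_edge_scores=scores,
        overall_score=1.0,
    )
    return replace(rec, overall_score=score_unrolling(rec))


def find_unrollings(
    coarse: TwoSliceNetwork,
    fine: TwoSliceNetwork,
    include_self_loops: bool = True,
) -> list[UnrollingRecord]:
    """All unrollings of coarse entity-level edges by mediator paths in the fine network.

    One record per (ordered entity pair, mediator path).  Mediators must come
    from omic layers the fine subset adds; two-mediator paths are considered
    only when two layers are added, and then the two mediators must come from
    the two distinct added layers.
    """
    added = _check_nested(coarse, fine)
    coarse_adj = entity_adjacency(coarse)
    fine_adj = entity_adjacency(fine)
    fine_entities = sorted({e for pair in fine_adj for e in pair})
    mediators = [e for e in fine_entities if e.omic_type in added]

    # successor map over the fine entity graph, restricted to mediator hops
    out: list[UnrollingRecord] = []
    for (a, b), coarse_edge in sorted(coarse_adj.items()):
        if a == b and not include_self_loops:
            continue
        if (a, b) in fine_adj:
            continue  # condition 2 fails
        # one-mediator paths
        for x in mediators:
            e1 = fine_adj.get((a, x))
            e2 = fine_adj.get((x, b))
            if e1 is not None and e2 is not None:
                out.append(
                    _make_record(
                        (a, b), coarse_edge.bootstrap_score, (e1, e2), (x,),
                        coarse.subset_label, fine.subset_label,
                    )
                )
        # two-mediator paths, only when the fine subset adds two layers
        if len(added) >= 2:
            for x, y in itertools.permutations(mediators, 2):
                if x.omic_type == y.omic_type:
                    continue
                e1 = fine_adj.get((a, x))
                e2 = fine_adj.get((x, y))
                e3 = fine_adj.get((y, b))
                if e1 is not None and e2 is not None and e3 is not None:
                    out.append(
                        _make_record(
                            (a, b), coarse_edge.bootstrap_score, (e1, e2, e3), (x, y),
                            coarse.subset_label, fine.subset_label,
                        )
                    )
    return out


def find_full_chain_unrollings(
    nets: dict[str, TwoSliceNetwork],
    include_self_loops: bool = True,
) -> list[UnrollingRecord]:
    """Fully unrolled taxon -> gene -> metabolite -> taxon chains.

    Requires the T and TGM networks.  A chain Ti -> Gy -> Mx -> Tj in the TGM
    network is reported when the taxa-only network carries the collapsed edge
    Ti -> Tj (and the TGM network does not).  Each additional coarser network
    consistent with the chain increments ``support_count``: the TM network via
    the one-mediator chain Ti -> Mx -> Tj, the TG network via Ti -> Gy -> Tj
    (in both cases with the direct edge absent there as well).
    """
    missing = [k for k in ("T", "TGM") if k not in nets]
    if missing:
        raise DynomicsError(f"full-chain unrolling requires networks {missing}")
    records = [
        rec
        for rec in find_unrollings(nets["T"], nets["TGM"], include_self_loops)
        if len(rec.mediators) == 2
        and rec.mediators[0].omic_type == "gene"
        and rec.mediators[1].omic_type == "metabolite"
    ]
    out: list[UnrollingRecord] = []
    adj = {label: entity_adjacency(net) for label in ("TM", "TG") if (net := nets.get(label))}
    for rec in records:
        a, b = rec.endpoints()
        gene, metab = rec.mediators
        support = 1
        for label, mediator in (("TM", metab), ("TG", gene)):
            if label not in adj:
                continue
            fadj = adj[label]
            if (a, b) not in fadj and (a, mediator) in fadj and (mediator, b) in fadj:
                support += 1
        out.append(replace(rec, support_count=support))
    return out


def rank_unrollings(records: list[UnrollingRecord]) -> list[UnrollingRecord]:
    """Stable sort: overall score desc, support count desc, then endpoints."""
    return sorted(
        records,
        key=lambda r: (
            -r.overall_score,
            -r.support_count,
            r.coarse_src.name,
            r.coarse_dst.name,
            [m.name for m in r.mediators],
        ),
    )
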