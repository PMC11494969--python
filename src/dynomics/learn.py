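"""Structure learning for constrained two-time-slice dynamic Bayesian networks.

Each next-slice variable gets an independent family selection: every subset of
allowed parents up to the parent bound is scored with a penalized
linear-Gaussian likelihood (-BIC/2 of the OLS fit with intercept), and the
best family is kept.  The typed skeleton makes same-slice edges acyclic by
construction (taxon -> gene -> metabolite, never back), so per-child choices
compose into a valid network.  Confidence comes from bootstrap over subjects:
networks are learned on subject-level resamples with replacement, and an edge
enters the consensus network when it appears in at least a minimum fraction
of repetitions, carrying its appearance fraction as a bootstrap score and the
mean of its fitted coefficients (over the repetitions where it appeared) as
its weight.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DynomicsError
from .network import (
    Edge,
    EntityRef,
    NodeRef,
    SkeletonConstraint,
    TwoSliceNetwork,
    allowed_entity_types,
    derive_subset_skeleton,
    is_allowed_edge,
)
from .preprocess import OmicsDataset

logger = logging.getLogger(__name__)

#: Candidate pools up to this size are searched exhaustively; larger pools use
#: greedy forward selection with one backward pass.
EXHAUSTIVE_POOL_LIMIT = 20


@dataclass(frozen=True)
class LearnConfig:
    """Settings for one structure-learning run."""

    subset_label: str = "TGM"
    skeleton_variant: str = "skeleton"
    max_parents: int = 3
    n_bootstrap: int = 100
    min_support: float = 0.10
    seed: int = 0
    #: Scale on which conditional models are fitted.  "clr" (centered
    #: log-ratio per omic type per sample) is the standard choice for
    #: compositional abundance data: it cancels the common log-total term
    #: that per-sample normalization injects into every entity of a type.
    #: "log" keeps plain log abundances; "none" fits the raw values.
    transform: str = "clr"
    #: Floor applied before the log so clipped zeros stay finite.
    log_floor: float = 1e-6

    def __post_init__(self):
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must lie in (0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.transform not in ("none", "log", "clr"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def constraint(self) -> SkeletonConstraint:
        return derive_subset_skeleton(self.skeleton_variant, self.subset_label)


def candidate_parent_sets(
    child: NodeRef,
    constraint: SkeletonConstraint,
    entities: list[EntityRef],
    max_parents: int,
):
    """Yield every allowed parent set of the child, sizes 0..max_parents.

    The pool holds each entity at either slice whose (type, type, lag)
    signature the skeleton permits for this child; the child's own-entity
    self-loop parent (previous slice) is always in the pool.  Sets are emitted
    in a deterministic order: by size, then lexicographically by parent.
    """
    pool: list[NodeRef] = []
    for ent in sorted(set(entities)):
        for src_slice in (0, 1):
            lag = child.slice - src_slice
            if lag not in (0, 1):
                continue
            if ent == child.entity and not (lag == 1):
                continue  # no instantaneous self edge
            if is_allowed_edge(
                constraint,
                ent.omic_type,
                child.entity.omic_type,
                lag,
                is_self=ent == child.entity,
            ):
                pool.append(NodeRef(ent, src_slice))
    pool.sort()
    for size in range(0, max_parents + 1):
        for combo in itertools.combinations(pool, size):
            yield combo


def score_family(child_values: np.ndarray, parent_values: np.ndarray | None) -> float:
    """Penalized-likelihood score (-BIC/2) of a linear-Gaussian family; higher is better.

    The child is regressed on its parents with an intercept by ordinary least
    squares; the empty parent set scores the mean-only model.  The parameter
    count charges one slot per coefficient, the intercept, and the residual
    variance.  Rank-deficient designs fall back to the pseudoinverse fit with
    a logged warning.
    """
    y = np.asarray(child_values, dtype=float)
    n = y.shape[0]
    if parent_values is None or (hasattr(parent_values, "shape") and np.size(parent_values) == 0):
        X = np.ones((n, 1))
        p = 0
    else:
        P = np.asarray(parent_values, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        p = P.shape[1]
        X = np.column_stack([np.ones(n), P])
    if n <= p + 1:
        raise DynomicsError(f"need more than {p + 1} rows to score a {p}-parent family, got {n}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient design (%d < %d); scoring pseudoinverse fit", rank, X.shape[1])
    resid = y - X @ beta
    return _penalized_loglik(float(resid @ resid), n, p)


def _penalized_loglik(rss: float, n: int, p: int) -> float:
    """-BIC/2 of a Gaussian fit with ``p`` coefficients, an intercept, and a variance."""
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = p + 2
    return float(loglik - 0.5 * k * np.log(n))


@dataclass
class _TransitionData:
    """Pooled (t, t+1) rows: column per node, one row per consecutive grid pair."""

    columns: dict[NodeRef, np.ndarray] = field(default_factory=dict)
    n_rows: int = 0


def build_transition_rows(
    ds: OmicsDataset,
    rel_tol: float = 1e-6,
    transform: str = "none",
    log_floor: float = 1e-6,
) -> _TransitionData:
    """Stack consecutive same-spacing time-point pairs across subjects.

    Within each subject the modal spacing of its (sorted) time grid defines a
    "consecutive" pair; rows with any missing entity value are dropped.
    ``transform`` is "none", "log" (values floored at ``log_floor``), or
    "clr" (log values centered per omic type within each row).
    """
    blocks = subject_transition_blocks(ds, rel_tol=rel_tol, transform=transform, log_floor=log_floor)
    return _stack_blocks(ds.entities(), [blocks[s] for s in sorted(blocks)])


def subject_transition_blocks(
    ds: OmicsDataset,
    rel_tol: float = 1e-6,
    transform: str = "none",
    log_floor: float = 1e-6,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-subject (X0, X1) transition matrices, transform already applied."""
    entities = ds.entities()
    names = [(e.name, e.omic_type) for e in entities]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for subject in ds.subjects():
        wide = (
            ds.subject_frame(subject)
            .pivot_table(index="time", columns=["entity", "omic_type"], values="value")
            .sort_index()
        )
        try:
            wide = wide.loc[:, names]
        except KeyError:
            wide = wide.reindex(columns=pd.MultiIndex.from_tuples(names))
        times = wide.index.to_numpy(float)
        x0_rows: list[np.ndarray] = []
        x1_rows: list[np.ndarray] = []
        if len(times) >= 2:
            diffs = np.diff(times)
            step = np.median(diffs)
            consecutive = np.abs(diffs - step) <= rel_tol * max(abs(step), 1.0)
            vals = wide.to_numpy(float)
            for i in np.flatnonzero(consecutive):
                row0, row1 = vals[i], vals[i + 1]
                if np.isnan(row0).any() or np.isnan(row1).any():
                    continue
                x0_rows.append(row0)
                x1_rows.append(row1)
        if not x0_rows:
            out[subject] = (np.empty((0, len(entities))), np.empty((0, len(entities))))
            continue
        X0 = np.vstack(x0_rows)
        X1 = np.vstack(x1_rows)
        if transform in ("log", "clr"):
            # clinical covariates (e.g., week number) stay on their native scale
            meas = [j for j, e in enumerate(entities) if e.omic_type != "clinical"]
            X0[:, meas] = np.log(np.maximum(X0[:, meas], log_floor))
            X1[:, meas] = np.log(np.maximum(X1[:, meas], log_floor))
            if transform == "clr":
                for omic in {entities[j].omic_type for j in meas}:
                    cols = [j for j, e in enumerate(entities) if e.omic_type == omic]
                    X0[:, cols] -= X0[:, cols].mean(axis=1, keepdims=True)
                    X1[:, cols] -= X1[:, cols].mean(axis=1, keepdims=True)
        out[subject] = (X0, X1)
    return out


def _stack_blocks(
    entities: list[EntityRef], blocks: list[tuple[np.ndarray, np.ndarray]]
) -> _TransitionData:
    data = _TransitionData()
    blocks = [b for b in blocks if b[0].shape[0]]
    if not blocks:
        return data
    X0 = np.vstack([b[0] for b in blocks])
    X1 = np.vstack([b[1] for b in blocks])
    for j, ent in enumerate(entities):
        data.columns[NodeRef(ent, 0)] = X0[:, j]
        data.columns[NodeRef(ent, 1)] = X1[:, j]
    data.n_rows = X0.shape[0]
    return data


class _FamilyScorer:
    """Gram-matrix OLS scorer over a fixed candidate pool.

    Computes the same penalized-likelihood score as :func:`score_family`
    (shared closed form) but reuses X'X / X'y across the many families of an
    exhaustive search.
    """

    def __init__(self, y: np.ndarray, pool: list[NodeRef], data: _TransitionData):
        self.n = len(y)
        Z = np.column_stack([np.ones(self.n)] + [data.columns[p] for p in pool])
        self.G = Z.T @ Z
        self.gy = Z.T @ y
        self.yy = float(y @ y)
        self.pool = pool
        self.index = {p: i + 1 for i, p in enumerate(pool)}

    def score(self, parents: tuple[NodeRef, ...]) -> float:
        idx = [0] + [self.index[p] for p in parents]
        G = self.G[np.ix_(idx, idx)]
        gy = self.gy[idx]
        try:
            beta = np.linalg.solve(G, gy)
        except np.linalg.LinAlgError:
            logger.warning("rank-deficient design; scoring pseudoinverse fit")
            beta = np.linalg.pinv(G) @ gy
        rss = max(self.yy - float(beta @ gy), 0.0)
        return _penalized_loglik(rss, self.n, len(parents))

    def coefficients(self, parents: tuple[NodeRef, ...]) -> dict[NodeRef, float]:
        idx = [0] + [self.index[p] for p in parents]
        G = self.G[np.ix_(idx, idx)]
        gy = self.gy[idx]
        try:
            beta = np.linalg.solve(G, gy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(G) @ gy
        return {p: float(beta[i + 1]) for i, p in enumerate(parents)}


def _select_family(
    y: np.ndarray,
    pool: list[NodeRef],
    data: _TransitionData,
    max_parents: int,
) -> tuple[tuple[NodeRef, ...], float, _FamilyScorer]:
    """Best-scoring parent set; ties go to smaller sets, then lexicographic order."""
    scorer = _FamilyScorer(y, pool, data)

    if len(pool) <= EXHAUSTIVE_POOL_LIMIT:
        best: tuple[NodeRef, ...] = ()
        best_score = scorer.score(())
        for size in range(1, max_parents + 1):
            for combo in itertools.combinations(pool, size):
                s = scorer.score(combo)
                if s > best_score:
                    best, best_score = combo, s
        return best, best_score, scorer

    # Greedy forward selection with one backward pass for large pools.
    current: list[NodeRef] = []
    current_score = scorer.score(())
    remaining = list(pool)
    while len(current) < max_parents and remaining:
        gains = [(scorer.score(tuple(sorted(current + [c]))), c) for c in remaining]
        best_gain, best_cand = max(gains, key=lambda t: (t[0], t[1]))
        if best_gain <= current_score:
            break
        current.append(best_cand)
        current.sort()
        current_score = best_gain
        remaining.remove(best_cand)
    for cand in list(current):
        trial = tuple(sorted(c for c in current if c != cand))
        s = scorer.score(trial)
        if s > current_score:
            current = list(trial)
            current_score = s
    return tuple(sorted(current)), current_score, scorer


def learn_dbn(ds: OmicsDataset, config: LearnConfig) -> TwoSliceNetwork:
    """Learn a single two-time-slice network by per-child family selection.

    Every edge weight is the fitted regression coefficient of that parent in
    the child's selected family; the returned network is compliant with the
    subset-adapted skeleton by construction.
    """
    if len(ds) == 0:
        raise DynomicsError("cannot learn from an empty dataset")
    allowed = allowed_entity_types(config.subset_label)
    extraneous = sorted(set(ds.omic_types()) - allowed)
    if extraneous:
        raise DynomicsError(
            f"dataset contains omic types {extraneous} outside subset {config.subset_label!r}; "
            "restrict the dataset first"
        )
    data = build_transition_rows(
        ds, transform=config.transform, log_floor=config.log_floor
    )
    return _learn_from_transitions(data, ds.entities(), config)


def _learn_from_transitions(
    data: _TransitionData, entities: list[EntityRef], config: LearnConfig
) -> TwoSliceNetwork:
    if data.n_rows == 0:
        raise DynomicsError("no consecutive time-point pairs; is the data resampled on a grid?")
    if data.n_rows <= config.max_parents + 1:
        raise DynomicsError(
            f"only {data.n_rows} transition rows; need more than {config.max_parents + 1}"
        )
    constraint = config.constraint()
    net = TwoSliceNetwork(config.subset_label, metadata={"method": "dbn", **_config_meta(config)})
    for ent in entities:
        child = NodeRef(ent, 1)
        net.add_node(child)
        net.add_node(NodeRef(ent, 0))
        y = data.columns[child]
        pool = _candidate_pool(child, constraint, entities)
        parents, _, scorer = _select_family(y, pool, data, config.max_parents)
        coefs = scorer.coefficients(parents) if parents else {}
        for p in parents:
            net.add_edge(Edge(src=p, dst=child, weight=coefs[p], bootstrap_score=1.0))
    return net


def _candidate_pool(
    child: NodeRef, constraint: SkeletonConstraint, entities: list[EntityRef]
) -> list[NodeRef]:
    return sorted(
        {p for combo in candidate_parent_sets(child, constraint, entities, 1) for p in combo}
    )


def _config_meta(config: LearnConfig) -> dict:
    return {
        "skeleton_variant": config.skeleton_variant,
        "max_parents": config.max_parents,
    }


def combine_bootstrap_networks(
    networks: list[TwoSliceNetwork],
    min_support: float = 0.10,
    metadata: dict | None = None,
) -> TwoSliceNetwork:
    """Combine repetition networks into a consensus network.

    An edge is kept iff it appears in at least ``min_support`` of the
    repetitions; its bootstrap score is the appearance fraction and its
    weight the mean of its weights over the repetitions in which it appeared.
    """
    if not networks:
        raise DynomicsError("cannot combine an empty list of networks")
    labels = {n.subset_label for n in networks}
    if len(labels) > 1:
        raise DynomicsError(f"repetition networks carry mixed subset labels {sorted(labels)}")
    n_rep = len(networks)
    counts: dict[tuple[NodeRef, NodeRef], int] = {}
    weight_sums: dict[tuple[NodeRef, NodeRef], float] = {}
    for net in networks:
        for e in net.edges:
            key = (e.src, e.dst)
            counts[key] = counts.get(key, 0) + 1
            weight_sums[key] = weight_sums.get(key, 0.0) + e.weight
    consensus = TwoSliceNetwork(labels.pop(), metadata=metadata or {})
    for net in networks:
        for node in net.nodes:
            consensus.add_node(node)
    for key in sorted(counts, key=lambda k: (k[0], k[1])):
        support = counts[key] / n_rep
        if support >= min_support:
            src, dst = key
            consensus.add_edge(
                Edge(src=src, dst=dst, weight=weight_sums[key] / counts[key], bootstrap_score=support)
            )
    return consensus


def bootstrap_consensus(ds: OmicsDataset, config: LearnConfig) -> TwoSliceNetwork:
    """Bootstrap-over-subjects consensus network.

    ``n_bootstrap`` subject-level resamples with replacement are drawn
    (repetition r is seeded with ``seed + r``); repetitions are combined by
    :func:`combine_bootstrap_networks` with the configured support threshold.
    """
    subjects = ds.subjects()
    if len(subjects) < 2:
        raise DynomicsError("bootstrap over subjects needs at least 2 subjects")
    allowed = allowed_entity_types(config.subset_label)
    extraneous = sorted(set(ds.omic_types()) - allowed)
    if extraneous:
        raise DynomicsError(
            f"dataset contains omic types {extraneous} outside subset {config.subset_label!r}; "
            "restrict the dataset first"
        )
    entities = ds.entities()
    # per-subject transition blocks are resample-invariant: compute them once
    blocks = subject_transition_blocks(
        ds, transform=config.transform, log_floor=config.log_floor
    )
    reps = []
    for r in range(config.n_bootstrap):
        rng = np.random.default_rng(config.seed + r)
        draw = rng.choice(len(subjects), size=len(subjects), replace=True)
        data = _stack_blocks(entities, [blocks[subjects[i]] for i in draw])
        reps.append(_learn_from_transitions(data, entities, config))
    return combine_bootstrap_networks(
        reps,
        min_support=config.min_support,
        metadata={
            "method": "dbn-bootstrap",
            "n_bootstrap": config.n_bootstrap,
            "min_support": config.min_support,
            **_config_meta(config),
        },
    )
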