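"""Ground-truth two-time-slice models and synthetic longitudinal cohorts.

The generator plants the two causal motifs the analysis is built to find:

* mediation chains  taxonA -> gene -> metabolite -> taxonB  (same-slice
  taxon -> gene and gene -> metabolite edges, plus a next-slice
  metabolite -> taxonB edge), and
* common causes     metabolite -> taxonA, metabolite -> taxonB  (two
  next-slice edges and *no* direct taxonA -> taxonB edge, so that a network
  learned from taxa alone is expected to infer the spurious direct edge).

Dynamics are linear-Gaussian on a latent log scale; every entity carries a
stable self-loop.  Observed taxa are exponentiated and renormalized to
relative abundances (compositional, like real sequencing-derived profiles);
genes and metabolites are exponentiated intensities.  Each subject is an
independent realization of the same process on a regular internal grid;
observation times are stretched by a per-subject linear time warp and
jittered, emulating irregular sampling at subject-specific speeds.  An
optional ``trajectory_sharing`` fraction makes part of the innovation
variance common to all subjects (a cohort-level environmental drive); note
that such a shared component acts as an unmeasured confounder for pooled
structure learning and visibly inflates false edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconfound import DeconfoundingRecord
from .errors import DynomicsError
from .network import Edge, EntityRef, NodeRef, TwoSliceNetwork
from .preprocess import OmicsDataset
from .unroll import UnrollingRecord

#: Internal sampling cadence of the latent process, in days.
STEP_DAYS = 7.0

#: Steps discarded before recording, so trajectories start near stationarity.
BURN_IN_STEPS = 50

#: Coefficient magnitude range for planted cross edges (sign random).
CROSS_COEF_RANGE = (0.3, 0.8)

#: Self-loop coefficient range (always positive: abundances persist).
SELF_COEF_RANGE = (0.4, 0.9)

#: Model-acceptance bound on any entity's stationary latent (log-scale) sd.
#: Chains of strong coefficients can compound innovation variance far beyond
#: biological plausibility (near-integrated log abundances); models are
#: redrawn until week-to-week fluctuations stay within a few fold.
MAX_STATIONARY_SD = 0.75


@dataclass(frozen=True)
class GroundTruthModel:
    """A planted 2TBN: entities, lagged linear structure, and noise level.

    ``structure`` holds (src entity, dst entity, lag, coefficient) tuples;
    lag 0 edges are same-slice, lag 1 edges span adjacent slices.
    """

    taxa: tuple[EntityRef, ...]
    genes: tuple[EntityRef, ...]
    metabolites: tuple[EntityRef, ...]
    structure: tuple[tuple[EntityRef, EntityRef, int, float], ...]
    planted_chains: tuple[tuple[EntityRef, EntityRef, EntityRef, EntityRef], ...]
    planted_confounders: tuple[tuple[EntityRef, EntityRef, EntityRef], ...]
    noise_sd: float = 0.1
    baselines: dict = field(default_factory=dict, hash=False)

    def entities(self) -> tuple[EntityRef, ...]:
        return self.taxa + self.genes + self.metabolites

    def to_network(self, subset_label: str = "TGM") -> TwoSliceNetwork:
        """The implied two-slice network (bootstrap score 1 on every edge)."""
        net = TwoSliceNetwork(subset_label, metadata={"method": "ground-truth"})
        for ent in self.entities():
            net.add_node(NodeRef(ent, 0))
            net.add_node(NodeRef(ent, 1))
        for src, dst, lag, coef in self.structure:
            src_node = NodeRef(src, 1 - lag)
            net.add_edge(Edge(src=src_node, dst=NodeRef(dst, 1), weight=coef, bootstrap_score=1.0))
        return net

    def entity_edges(self) -> set[tuple[str, str, int]]:
        """(src name, dst name, lag) triples of the planted structure."""
        return {(s.name, d.name, lag) for s, d, lag, _ in self.structure}


def _draw_cross_coef(rng: np.random.Generator) -> float:
    mag = rng.uniform(*CROSS_COEF_RANGE)
    return float(mag if rng.random() < 0.5 else -mag)


def sample_ground_truth(
    n_taxa: int = 27,
    n_genes: int = 34,
    n_metabolites: int = 19,
    n_chains: int = 3,
    n_confounders: int = 2,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> GroundTruthModel:
    """Draw a compliant ground-truth model with the requested planted motifs.

    The default panel sizes (27 taxa, 34 genes, 19 metabolites) mirror the
    dimensionality of a curated longitudinal IBD multi-omics panel; at these
    sizes the compositional closure introduced by relative-abundance
    normalization is weak (each entity contributes ~1/n of its type's total).

    Every entity gets a positive self-loop; each chain uses its own gene and
    metabolite, each confounder its own metabolite, and no two planted motifs
    share an (ordered) taxon pair.  There are no direct taxonA -> taxonB
    shortcut edges.  Deterministic per seed; coefficients are redrawn (still
    deterministically) if the implied linear system is not clearly stable.
    """
    if min(n_taxa, n_genes, n_metabolites) < 1 or n_chains < 0 or n_confounders < 0:
        raise DynomicsError("entity counts must be >= 1 and motif counts >= 0")
    if n_taxa < 2 and (n_chains or n_confounders):
        raise DynomicsError("planted motifs need at least 2 taxa")
    if n_genes < n_chains:
        raise DynomicsError(f"{n_chains} chains need {n_chains} genes, have {n_genes}")
    if n_metabolites < n_chains + n_confounders:
        raise DynomicsError(
            f"{n_chains} chains + {n_confounders} confounders need "
            f"{n_chains + n_confounders} metabolites, have {n_metabolites}"
        )
    if n_chains + 2 * n_confounders > n_taxa:
        raise DynomicsError(
            "motifs need distinct receiving taxa: n_chains + 2*n_confounders must "
            f"be <= n_taxa ({n_chains} + 2*{n_confounders} > {n_taxa})"
        )

    taxa = tuple(EntityRef(f"Taxon_{i:02d}", "taxon") for i in range(1, n_taxa + 1))
    genes = tuple(EntityRef(f"Gene_{i:02d}", "gene") for i in range(1, n_genes + 1))
    mets = tuple(EntityRef(f"Metabolite_{i:02d}", "metabolite") for i in range(1, n_metabolites + 1))

    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        structure: list[tuple[EntityRef, EntityRef, int, float]] = []
        for ent in taxa + genes + mets:
            structure.append((ent, ent, 1, float(rng.uniform(*SELF_COEF_RANGE))))

        # Each taxon receives at most one planted motif edge, so no child's
        # true in-degree exceeds the learner's default parent bound
        # (self-loop + one planted parent) and motifs stay identifiable.
        receivers = [int(i) for i in rng.permutation(n_taxa)]
        n_recv = n_chains + 2 * n_confounders
        used: set[int] = set(receivers[len(receivers) - n_recv :]) if n_recv else set()

        free_genes = list(genes)
        free_mets = list(mets)
        chains = []
        for k in range(n_chains):
            b = taxa[receivers.pop()]
            # prefer taxa not involved in any motif as sources, so motifs do
            # not accidentally share ancestors (which would plant unintended
            # common-cause patterns)
            fresh = [i for i in range(n_taxa) if i not in used and taxa[i] != b]
            candidates = fresh or [i for i in range(n_taxa) if taxa[i] != b]
            a = taxa[int(rng.choice(candidates))]
            used.add(taxa.index(a))
            g = free_genes.pop(0)
            m = free_mets.pop(0)
            structure.append((a, g, 0, _draw_cross_coef(rng)))
            structure.append((g, m, 0, _draw_cross_coef(rng)))
            structure.append((m, b, 1, _draw_cross_coef(rng)))
            chains.append((a, g, m, b))
        confounders = []
        for k in range(n_confounders):
            a = taxa[receivers.pop()]
            b = taxa[receivers.pop()]
            m = free_mets.pop(0)
            structure.append((m, a, 1, _draw_cross_coef(rng)))
            structure.append((m, b, 1, _draw_cross_coef(rng)))
            confounders.append((m, a, b))

        model = GroundTruthModel(
            taxa=taxa,
            genes=genes,
            metabolites=mets,
            structure=tuple(structure),
            planted_chains=tuple(chains),
            planted_confounders=tuple(confounders),
            noise_sd=noise_sd,
            baselines={e: float(rng.normal(0.0, 0.3)) for e in taxa + genes + mets},
        )
        if _spectral_radius(model) < 0.98 and _max_stationary_sd(model) <= MAX_STATIONARY_SD:
            return model
    raise DynomicsError("could not draw a stable, bounded-variance model in 100 attempts")


def _index(model: GroundTruthModel) -> dict[EntityRef, int]:
    return {e: i for i, e in enumerate(model.entities())}


def _system_matrices(model: GroundTruthModel) -> tuple[np.ndarray, np.ndarray]:
    """(A_inter, B_intra) with z(t+1) = (I - B)^-1 (A z(t) + eps)."""
    idx = _index(model)
    n = len(idx)
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for src, dst, lag, coef in model.structure:
        if lag == 1:
            A[idx[dst], idx[src]] = coef
        else:
            B[idx[dst], idx[src]] = coef
    return A, B


def _spectral_radius(model: GroundTruthModel) -> float:
    A, B = _system_matrices(model)
    n = A.shape[0]
    M = np.linalg.solve(np.eye(n) - B, A)
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def _max_stationary_sd(model: GroundTruthModel) -> float:
    """Largest stationary latent sd implied by the linear system (Lyapunov)."""
    from scipy.linalg import solve_discrete_lyapunov

    A, B = _system_matrices(model)
    n = A.shape[0]
    inv = np.linalg.inv(np.eye(n) - B)
    M = inv @ A
    Q = inv @ (model.noise_sd**2 * np.eye(n)) @ inv.T
    S = solve_discrete_lyapunov(M, Q)
    return float(np.sqrt(np.max(np.diag(S))))


def simulate_cohort(
    gt: GroundTruthModel,
    n_subjects: int = 20,
    n_timepoints: int = 30,
    warp_slope_range: tuple[float, float] = (0.8, 1.25),
    sampling_jitter_days: float = 1.0,
    trajectory_sharing: float = 0.0,
    seed: int = 0,
) -> OmicsDataset:
    """Simulate a longitudinal multi-omic cohort from a planted model.

    Latent trajectories follow the linear-Gaussian 2TBN on a regular internal
    grid (:data:`STEP_DAYS` apart, burn-in discarded).  ``trajectory_sharing``
    optionally makes that fraction of the innovation variance common to all
    subjects (default 0: independent realizations); each subject's
    observation times are the grid times scaled by a subject-specific slope
    drawn from ``warp_slope_range`` plus uniform jitter of up to
    ``sampling_jitter_days``.  Taxa are exponentiated and normalized
    to per-sample compositions; genes and metabolites are exponentiated
    intensities.  Deterministic per seed.
    """
    if n_subjects < 1 or n_timepoints < 4:
        raise DynomicsError("need n_subjects >= 1 and n_timepoints >= 4")
    if not 0.0 <= trajectory_sharing <= 1.0:
        raise DynomicsError("trajectory_sharing must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    entities = gt.entities()
    n_ent = len(entities)
    idx = _index(gt)
    A, B = _system_matrices(gt)
    solve = np.linalg.inv(np.eye(n_ent) - B)

    n_steps = BURN_IN_STEPS + n_timepoints
    w_shared = np.sqrt(trajectory_sharing)
    w_own = np.sqrt(1.0 - trajectory_sharing)
    shared_eps = rng.normal(0.0, gt.noise_sd, size=(n_steps, n_ent))

    slopes = rng.uniform(warp_slope_range[0], warp_slope_range[1], size=n_subjects)
    taxa_idx = np.array([idx[e] for e in gt.taxa])
    gene_idx = np.array([idx[e] for e in gt.genes])
    met_idx = np.array([idx[e] for e in gt.metabolites])
    base = np.array([gt.baselines.get(e, 0.0) for e in entities])

    frames = []
    for s in range(n_subjects):
        own_eps = rng.normal(0.0, gt.noise_sd, size=(n_steps, n_ent))
        eps = w_shared * shared_eps + w_own * own_eps
        z = np.zeros(n_ent)
        traj = np.empty((n_timepoints, n_ent))
        for t in range(n_steps):
            z = solve @ (A @ z + eps[t])
            if t >= BURN_IN_STEPS:
                traj[t - BURN_IN_STEPS] = z

        grid = STEP_DAYS * np.arange(n_timepoints)
        jitter = rng.uniform(-sampling_jitter_days, sampling_jitter_days, size=n_timepoints)
        times = slopes[s] * grid + jitter
        times = np.maximum.accumulate(times)  # keep time strictly non-decreasing
        times += 1e-6 * np.arange(n_timepoints)  # break exact ties

        latent = base + traj
        values = np.exp(latent)
        taxa_vals = values[:, taxa_idx]
        values[:, taxa_idx] = taxa_vals / taxa_vals.sum(axis=1, keepdims=True)

        subject = f"S{s + 1:03d}"
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "time": np.repeat(times, n_ent),
                    "entity": np.tile([e.name for e in entities], n_timepoints),
                    "omic_type": np.tile([e.omic_type for e in entities], n_timepoints),
                    "value": values.ravel(),
                    "has_compound_id": True,
                }
            )
        )
    return OmicsDataset(pd.concat(frames, ignore_index=True))


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of planted-motif recovery; None where undefined."""

    chain_precision: float | None
    chain_recall: float | None
    confounder_precision: float | None
    confounder_recall: float | None


def evaluate_recovery(
    unrollings: list[UnrollingRecord],
    deconfoundings: list[DeconfoundingRecord],
    gt: GroundTruthModel,
    min_edge_support: float = 0.0,
) -> RecoveryMetrics:
    """Match discoveries to planted motifs by entity identity.

    An unrolling matches a planted chain (A, G, M, B) when its endpoints are
    (A, B) and every mediator is the chain's gene or metabolite.  A
    de-confounding matches a planted confounder (C, A, B) when its
    de-confounder is C and its confounded pair is {A, B} in either direction.
    Precision is computed over unique discoveries; recall over planted motifs
    with at least one matching discovery.

    ``min_edge_support`` restricts the evaluation to discoveries whose
    replacement edges all reach that bootstrap support — the stability-
    selection convention for calling a bootstrap-supported edge reliable.
    """
    if min_edge_support > 0:
        unrollings = [r for r in unrollings if min(r.per_edge_scores) >= min_edge_support]
        deconfoundings = [
            r for r in deconfoundings if min(r.per_edge_scores) >= min_edge_support
        ]
    uniq_unroll = {(r.coarse_src, r.coarse_dst, r.mediators): r for r in unrollings}
    uniq_deconf = {
        (r.confounded_src, r.confounded_dst, r.deconfounder): r for r in deconfoundings
    }

    def chain_match(key, chain) -> bool:
        src, dst, meds = key
        a, g, m, b = chain
        return src == a and dst == b and all(x in (g, m) for x in meds)

    def conf_match(key, conf) -> bool:
        src, dst, c = key
        cause, ea, eb = conf
        return c == cause and {src, dst} == {ea, eb}

    chain_hits = sum(
        1 for key in uniq_unroll if any(chain_match(key, ch) for ch in gt.planted_chains)
    )
    chain_found = sum(
        1
        for ch in gt.planted_chains
        if any(chain_match(key, ch) for key in uniq_unroll)
    )
    conf_hits = sum(
        1 for key in uniq_deconf if any(conf_match(key, cf) for cf in gt.planted_confounders)
    )
    conf_found = sum(
        1
        for cf in gt.planted_confounders
        if any(conf_match(key, cf) for key in uniq_deconf)
    )
    return RecoveryMetrics(
        chain_precision=chain_hits / len(uniq_unroll) if uniq_unroll else None,
        chain_recall=chain_found / len(gt.planted_chains) if gt.planted_chains else None,
        confounder_precision=conf_hits / len(uniq_deconf) if uniq_deconf else None,
        confounder_recall=conf_found / len(gt.planted_confounders)
        if gt.planted_confounders
        else None,
    )


def ground_truth_to_json(gt: GroundTruthModel) -> dict:
    """JSON-serializable description of a ground-truth model."""
    return {
        "taxa": [e.name for e in gt.taxa],
        "genes": [e.name for e in gt.genes],
        "metabolites": [e.name for e in gt.metabolites],
        "noise_sd": gt.noise_sd,
        "structure": [
            {"src": s.name, "dst": d.name, "lag": lag, "coef": coef}
            for s, d, lag, coef in gt.structure
        ],
        "planted_chains": [[e.name for e in ch] for ch in gt.planted_chains],
        "planted_confounders": [[e.name for e in cf] for cf in gt.planted_confounders],
        "baselines": {e.name: v for e, v in gt.baselines.items()},
    }
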