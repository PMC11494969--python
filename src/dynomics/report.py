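"""Summary metrics over discovery runs and experiment-grid enumeration.

The headline diagnostic for an unrolling analysis is the *proportion
unrolled*: out of the taxon -> taxon interactions in the taxa-only network,
how many could be explained by a mediator path in a given finer network.
Tables collect that proportion against the TGM, TG, and TM refinements plus
the mean overall bootstrap score of the discoveries, per experimental cell
(method x parameter x alignment); grids of such cells are enumerated
deterministically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .errors import DynomicsError, UndefinedMetricError
from .network import TwoSliceNetwork, entity_adjacency
from .unroll import UnrollingRecord, find_unrollings

#: Column order of the proportion-unrolled table.
HEATMAP_COLUMNS = ("TGM<-T", "TG<-T", "TM<-T", "mean_overall_score")


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of a network-learning experiment sweep.

    ``axis2`` is the method-specific axis: parent bounds for DBN runs, or
    significance thresholds (optionally crossed with conditional-independence
    tests) for constraint-based runs.  ``skeleton_variants`` applies to DBN
    runs only and may be None.
    """

    subsets: tuple[str, ...]
    axis2: tuple
    alignment: tuple[bool, ...] = (False, True)
    skeleton_variants: tuple[str, ...] | None = None

    def __post_init__(self):
        axes = [self.subsets, self.axis2, self.alignment]
        if self.skeleton_variants is not None:
            axes.append(self.skeleton_variants)
        if any(len(a) == 0 for a in axes):
            raise DynomicsError("experiment grid axes must all be nonempty")


def enumerate_experiment_grid(grid: ExperimentGrid) -> list[tuple]:
    """Cartesian product of the grid's axes in deterministic lexicographic order."""
    axes: list[tuple] = [tuple(grid.subsets), tuple(grid.axis2), tuple(grid.alignment)]
    if grid.skeleton_variants is not None:
        axes.append(tuple(grid.skeleton_variants))
    return list(itertools.product(*axes))


def dbn_grid() -> ExperimentGrid:
    """The DBN sweep: 7 subsets x 4 parent bounds x 2 alignments x 2 skeletons = 112."""
    return ExperimentGrid(
        subsets=("T", "G", "M", "TG", "TM", "GM", "TGM"),
        axis2=(3, 4, 5, 6),
        alignment=(False, True),
        skeleton_variants=("skeleton", "augmented"),
    )


def fci_style_grid() -> ExperimentGrid:
    """A tsGFCI-style sweep: 4 significance thresholds x 7 subsets x 2 alignments = 56."""
    return ExperimentGrid(
        subsets=("T", "G", "M", "TG", "TM", "GM", "TGM"),
        axis2=(0.0001, 0.001, 0.01, 0.1),
        alignment=(False, True),
    )


def pcmci_style_grid() -> ExperimentGrid:
    """A PCMCI-style sweep: 4 thresholds x 3 CI tests x 7 subsets x 2 alignments = 168."""
    thresholds = (0.0001, 0.001, 0.01, 0.1)
    ci_tests = ("ParCorr", "GPDC", "CMIknn")
    return ExperimentGrid(
        subsets=("T", "G", "M", "TG", "TM", "GM", "TGM"),
        axis2=tuple(itertools.product(thresholds, ci_tests)),
        alignment=(False, True),
    )


def _taxon_taxon_pairs(net: TwoSliceNetwork, include_self_loops: bool):
    adj = entity_adjacency(net)
    return [
        pair
        for pair in adj
        if pair[0].omic_type == "taxon"
        and pair[1].omic_type == "taxon"
        and (include_self_loops or pair[0] != pair[1])
    ]


def proportion_unrolled(
    coarse: TwoSliceNetwork,
    fine: TwoSliceNetwork,
    include_self_loops: bool = True,
) -> float:
    """Fraction of coarse taxon -> taxon entity-level edges with >= 1 unrolling in fine.

    Self-loops count as eligible edges by default.  Raises when the coarse
    network has no eligible edge (the metric is undefined, not zero).
    """
    eligible = _taxon_taxon_pairs(coarse, include_self_loops)
    if not eligible:
        raise UndefinedMetricError(
            f"network {coarse.subset_label!r} has no taxon->taxon entity-level edges"
        )
    records = find_unrollings(coarse, fine, include_self_loops=include_self_loops)
    unrolled_pairs = {r.endpoints() for r in records}
    hit = sum(1 for pair in eligible if pair in unrolled_pairs)
    return hit / len(eligible)


def mean_overall_score(records: list[UnrollingRecord]) -> float:
    """Arithmetic mean of the discoveries' overall scores."""
    if not records:
        raise DynomicsError("cannot average an empty set of discoveries")
    return sum(r.overall_score for r in records) / len(records)


def heatmap_table(
    cells: dict[str, dict[str, TwoSliceNetwork]],
    include_self_loops: bool = True,
) -> pd.DataFrame:
    """One row per experiment cell: proportions unrolled against TGM/TG/TM, plus score.

    ``cells`` maps a cell identifier to that cell's learned networks keyed by
    subset label (must include "T"; fine networks among "TGM", "TG", "TM").
    Cells whose required networks are missing are skipped; undefined metrics
    (no eligible edges, or no unrollings to average) are left blank (NA),
    which distinguishes "nothing eligible" from "nothing unrolled".
    """
    rows = {}
    for cell_id in sorted(cells):
        nets = cells[cell_id]
        if "T" not in nets or not any(k in nets for k in ("TGM", "TG", "TM")):
            import logging

            logging.getLogger(__name__).warning("cell %r lacks required networks; skipped", cell_id)
            continue
        row: dict[str, float | None] = {}
        all_records: list[UnrollingRecord] = []
        for column, fine_label in (("TGM<-T", "TGM"), ("TG<-T", "TG"), ("TM<-T", "TM")):
            if fine_label not in nets:
                row[column] = None
                continue
            try:
                row[column] = proportion_unrolled(
                    nets["T"], nets[fine_label], include_self_loops=include_self_loops
                )
            except UndefinedMetricError:
                row[column] = None
            all_records.extend(
                find_unrollings(nets["T"], nets[fine_label], include_self_loops=include_self_loops)
            )
        row["mean_overall_score"] = mean_overall_score(all_records) if all_records else None
        rows[cell_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if not frame.empty:
        frame = frame.loc[:, list(HEATMAP_COLUMNS)]
        frame.index.name = "cell"
    return frame


def render_heatmap(table: pd.DataFrame, path) -> None:
    """Render the proportion-unrolled table as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.9 * len(table.columns), 1 + 0.45 * max(len(table), 1))
    )
    data = table.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="viridis", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(table)), [str(i) for i in table.index])
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if data[i, j] == data[i, j]:  # not NaN
                ax.text(j, i, f"{data[i, j]:.2f}", ha="center", va="center", fontsize=8, color="w")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
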