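"""Fitness objectives: module activity score and pathway coverage count.

A candidate module A is judged on two axes that the search maximises
simultaneously:

* ``S_A`` — the sum of the per-gene activity scores over the module;
* ``R_A`` — the number of pathways whose cover rate
  ``R_i = |V_i ∩ V_A| / |V_i|`` strictly exceeds a threshold ``r_ratio``.

The evolutionary engine minimises, so objective vectors are carried
internally as ``(-S_A, -R_A)``; everything user-facing reports the
maximisation scale.

By default the cover-rate denominator is the full annotated pathway, even
if some of its genes are absent from the network; pass
``restrict_to_network=True`` to restrict pathways to network nodes instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .graph import ScoredNetwork

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ObjectiveVector",
    "PathwayIndex",
    "module_score",
    "pathway_cover_rate",
    "pathway_coverage_count",
    "evaluate",
]


class GeneSetCollection:
    """Named pathways (gene sets), the prior-knowledge input.

    Pathway ids are unique and no pathway is empty; iteration order is the
    insertion order of the source file.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        self._desc: dict[str, str] = {}
        for name, genes in sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if name in self._sets:
                raise ValueError(f"duplicate pathway id {name!r}")
            self._sets[name] = genes
            self._desc[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def items(self):
        return self._sets.items()

    def description(self, name: str) -> str:
        return self._desc[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``pathway_id<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, list[str]] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need id, description and "
                    f"at least one gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            sets[name] = genes
            descs[name] = desc
    return GeneSetCollection(sets, descs)


def write_gmt(col: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in col.items():
            fh.write("\t".join([name, col.description(name), *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class ObjectiveVector:
    """Objective values of one module, on the maximisation scale."""

    s_a: float
    r_a: int

    @property
    def minimized(self) -> tuple[float, float]:
        """The internal minimisation view ``(-S_A, -R_A)``."""
        return (-self.s_a, -float(self.r_a))


class PathwayIndex:
    """Pathways bound to a network's node order for vectorised evaluation.

    Precomputes, per pathway, the member node indices present in the
    network and the cover-rate denominator (full annotated size by
    default, or the in-network size when restricted).
    """

    def __init__(
        self,
        col: GeneSetCollection,
        net: ScoredNetwork,
        restrict_to_network: bool = False,
    ):
        self.collection = col
        self.restrict_to_network = restrict_to_network
        self.names = col.names
        n = net.n_nodes
        rows = []
        denoms = []
        member_mask = np.zeros(n, dtype=bool)
        for name in self.names:
            genes = col[name]
            idx = np.array(
                sorted(net.index_of(g) for g in genes if g in net._index),
                dtype=np.int64,
            )
            member_mask[idx] = True
            rows.append(idx)
            denoms.append(len(idx) if restrict_to_network else len(genes))
        self._rows = rows
        self._denoms = np.array(denoms, dtype=float)
        #: boolean mask over network nodes: belongs to >= 1 pathway
        self.member_mask = member_mask
        # indicator matrix (P x V) for fast batched cover rates
        self._mat = np.zeros((len(rows), n), dtype=float)
        for i, idx in enumerate(rows):
            self._mat[i, idx] = 1.0

    def cover_rates(self, sel: np.ndarray) -> np.ndarray:
        """Cover rate R_i of every pathway for one membership vector.

        Pathways with a zero denominator (restricted mode, no member in the
        network) get rate 0.
        """
        sel = np.asarray(sel, dtype=float)
        inter = self._mat @ sel
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(self._denoms > 0, inter / self._denoms, 0.0)
        return rates

    def coverage_count(self, sel: np.ndarray, r_ratio: float) -> int:
        """Number of pathways with cover rate strictly above ``r_ratio``."""
        if not 0.0 < r_ratio < 1.0:
            raise ValueError(f"r_ratio must lie in (0, 1), got {r_ratio}")
        return int(np.sum(self.cover_rates(sel) > r_ratio))


def module_score(net: ScoredNetwork, sel: np.ndarray) -> float:
    """Activity score S_A: sum of node scores over the selection."""
    if net.scores is None:
        raise ValueError("network nodes are not scored yet")
    sel = np.asarray(sel, dtype=bool)
    return float(net.scores[sel].sum())


def pathway_cover_rate(pathway: Iterable[str], module_genes: Iterable[str]) -> float:
    """Cover rate ``|V_i ∩ V_A| / |V_i|`` of one pathway by one module."""
    pathway = set(pathway)
    if not pathway:
        raise ValueError("pathway is empty")
    return len(pathway & set(module_genes)) / len(pathway)


def pathway_coverage_count(
    col: GeneSetCollection | PathwayIndex,
    net: ScoredNetwork,
    sel: np.ndarray,
    r_ratio: float,
) -> int:
    """Coverage count R_A: pathways covered strictly beyond ``r_ratio``."""
    index = col if isinstance(col, PathwayIndex) else PathwayIndex(col, net)
    return index.coverage_count(sel, r_ratio)


def evaluate(
    net: ScoredNetwork,
    col: GeneSetCollection | PathwayIndex,
    sel: np.ndarray,
    r_ratio: float,
) -> ObjectiveVector:
    """Both objectives for one membership vector (maximisation scale)."""
    index = col if isinstance(col, PathwayIndex) else PathwayIndex(col, net)
    return ObjectiveVector(
        s_a=module_score(net, sel),
        r_a=index.coverage_count(sel, r_ratio),
    )
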