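"""All-vs-all similarity graph and seeded force-directed embedding.

A lightweight sequence-space clustering in the CLANS style: every unordered
pair of sequences gets a local-alignment score and an E-value-derived p-value;
attraction in the embedding is proportional to -log10(p), capped to avoid
identical-pair singularities, while a distance-squared repulsion keeps
unrelated sequences apart. Connected components of the thresholded graph give
discrete cluster labels independent of the embedding.

BLOSUM45 is the default matrix for this module (it tolerates the deep
divergence typical of cross-phylum precursor comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import LayoutDiverged, TooFew
from .search import ScoringScheme, evalue, smith_waterman
from .sequence_io import SequenceRecord

#: Default scheme for all-vs-all comparisons.
CLUSTER_SCHEME = ScoringScheme(matrix_name="BLOSUM45")


@dataclass(frozen=True)
class SimilarityEdge:
    i: int
    j: int
    score: int
    pvalue: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("edges are stored with i < j")


@dataclass(frozen=True)
class LayoutParams:
    attract_weight: float = 1.0
    repulse_weight: float = 1.0
    damping: float = 0.9
    max_step: float = 0.1
    pvalue_cutoff: float = 1e-3

    def to_dict(self) -> dict:
        return {
            "attract_weight": self.attract_weight,
            "repulse_weight": self.repulse_weight,
            "damping": self.damping,
            "max_step": self.max_step,
            "pvalue_cutoff": self.pvalue_cutoff,
        }


@dataclass(frozen=True)
class LayoutState:
    coordinates: np.ndarray
    iteration: int
    seed: int
    params: LayoutParams


_EPS = 1e-6  # repulsion distance-squared floor
_LOGP_CAP = 20.0


def all_vs_all(
    seqs: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
) -> list[SimilarityEdge]:
    """Score every unordered pair; pvalue = min(1, E-value)."""
    if len(seqs) < 2:
        raise TooFew("all_vs_all needs at least 2 sequences")
    scheme = scheme or CLUSTER_SCHEME
    edges: list[SimilarityEdge] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            aln = smith_waterman(seqs[i].residues, seqs[j].residues, scheme)
            ev = evalue(aln.score, len(seqs[i].residues), len(seqs[j].residues), scheme)
            edges.append(SimilarityEdge(i=i, j=j, score=aln.score, pvalue=min(1.0, ev)))
    return edges


def force_layout(
    edges: Sequence[SimilarityEdge],
    n_nodes: int,
    dims: int = 2,
    seed: int = 0,
    iterations: int = 1000,
    params: LayoutParams | None = None,
    initial: np.ndarray | None = None,
) -> LayoutState:
    """Seeded deterministic force-directed embedding.

    Initial coordinates are uniform in [-1, 1]^dims from the seed. Per
    iteration each node receives attraction ``a_ij * (x_j - x_i)`` over edges
    passing the p-value cutoff, with ``a_ij = min(-log10(p), 20) *
    attract_weight``, and repulsion ``repulse_weight * (x_i - x_j) /
    max(|x_i - x_j|^2, eps)`` over all pairs. The summed displacement is
    damped and clipped to ``max_step``. The trajectory depends only on
    coordinate differences, so it is translation-equivariant.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    params = params or LayoutParams()
    if initial is not None:
        X = np.array(initial, dtype=float, copy=True)
        if X.shape != (n_nodes, dims):
            raise ValueError("initial coordinates must have shape (n_nodes, dims)")
    else:
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1.0, 1.0, size=(n_nodes, dims))
    return _run_layout(X, edges, seed, iterations, params)


def _run_layout(
    X: np.ndarray,
    edges: Sequence[SimilarityEdge],
    seed: int,
    iterations: int,
    params: LayoutParams,
) -> LayoutState:
    n_nodes = X.shape[0]
    active = [e for e in edges if e.pvalue <= params.pvalue_cutoff]
    src = np.array([e.i for e in active], dtype=int)
    dst = np.array([e.j for e in active], dtype=int)
    attr = np.array(
        [min(-math.log10(max(e.pvalue, 1e-300)), _LOGP_CAP) * params.attract_weight for e in active]
    )

    for it in range(iterations):
        disp = np.zeros_like(X)
        if len(active) and n_nodes > 1:
            delta = X[dst] - X[src]
            pull = attr[:, None] * delta
            np.add.at(disp, src, pull)
            np.add.at(disp, dst, -pull)
        if n_nodes > 1:
            diff = X[:, None, :] - X[None, :, :]
            d2 = np.maximum((diff ** 2).sum(axis=2), _EPS)
            np.fill_diagonal(d2, np.inf)
            disp += params.repulse_weight * (diff / d2[:, :, None]).sum(axis=1)
        disp *= params.damping
        norms = np.linalg.norm(disp, axis=1)
        over = norms > params.max_step
        if over.any():
            disp[over] *= (params.max_step / norms[over])[:, None]
        X = X + disp
        if not np.isfinite(X).all():
            raise LayoutDiverged(it)
    return LayoutState(coordinates=X, iteration=iterations, seed=seed, params=params)


def components_at_cutoff(
    edges: Sequence[SimilarityEdge],
    n_nodes: int,
    pvalue_cutoff: float,
) -> dict[int, int]:
    """Connected components of the thresholded graph.

    Labels are assigned in order of each component's smallest member index.
    """
    if pvalue_cutoff <= 0:
        raise ValueError("pvalue_cutoff must be positive")
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.pvalue <= pvalue_cutoff:
            ra, rb = find(e.i), find(e.j)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    labels: dict[int, int] = {}
    next_label = 0
    out: dict[int, int] = {}
    for node in range(n_nodes):
        root = find(node)
        if root not in labels:
            labels[root] = next_label
            next_label += 1
        out[node] = labels[root]
    return out


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------


def write_edges_tsv(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\tpvalue\n")
        for e in edges:
            fh.write(f"{e.i}\t{e.j}\t{e.score}\t{e.pvalue!r}\n")


def read_edges_tsv(path: str | Path) -> list[SimilarityEdge]:
    edges: list[SimilarityEdge] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            i, j, score, pvalue = line.rstrip("\r\n").split("\t")
            edges.append(SimilarityEdge(int(i), int(j), int(score), float(pvalue)))
    return edges


def write_coordinates_tsv(
    state: LayoutState, ids: Sequence[str], path: str | Path
) -> None:
    dims = state.coordinates.shape[1]
    cols = ["x", "y", "z"][:dims]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(cols) + "\n")
        for name, row in zip(ids, state.coordinates):
            fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def write_components_tsv(
    components: dict[int, int], ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcomponent\n")
        for node, label in sorted(components.items()):
            fh.write(f"{ids[node]}\t{label}\n")
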