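"""Aligning mimotopes to patch graphs.

A mimotope (an affinity-selected peptide from a phage-display library) is
aligned to simple paths of a patch graph: consecutive matched residues must be
graph-adjacent and no residue may repeat.  The search is a dynamic programme
over states identified by the path's end vertex and its visited-vertex set, so
permutations of the same support ending at the same vertex collapse to the one
best-scoring representative.  Alignment semantics are local with free ends:

* a matched pair (query residue, path vertex) scores the substitution matrix;
* an internal skipped query position (deletion) or an internal unmatched path
  vertex (insertion) each cost the gap penalty δ (negative);
* query positions before the first and after the last matched one are free;
* the overall best score is floored at zero (the empty alignment).

Branch-and-bound pruning (upper bound: current score plus remaining query
length times the maximum matrix entry, against the best complete alignment
found so far) never changes the returned score — it only shrinks the explored
state set, which matters once queries approach 10 residues.

By default gaps are deletion-type only — each DP step consumes one query
position, matched to a vertex or to a path gap — mirroring the recursion's
one-query-residue-per-step growth.  Insertion-type gaps (an unmatched path
vertex bridging two matched ones) are supported exactly behind
``allow_insertions=True``; they enlarge the visited-set state space
substantially and are off in the default pipeline.

The default substitution matrix is a BLOSUM62 variant whose query-side
background frequencies are replaced by the amino-acid frequencies implied by
the NNK codon scheme (N = any base, K = G/T; 32 codons) used by random peptide
libraries, since library peptides are not drawn from the proteomic background
BLOSUM62 assumes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .patches import PatchGraph
from .structure import AA_INDEX, AMINO_ACIDS, ResidueKey

__all__ = [
    "Mimotope",
    "SubstitutionModel",
    "PathAlignment",
    "derive_nnk_matrix",
    "nnk_codon_counts",
    "nnk_frequencies",
    "nnk_adjusted_logodds",
    "blosum62_model",
    "default_substitution_model",
    "align_query_to_graph",
    "brute_force_best_path",
    "bb_upper_bound",
    "batch_best_scores",
    "read_mimotopes",
    "write_matrix_text",
    "read_matrix_text",
    "BLOSUM62_BACKGROUND",
    "DEFAULT_GAP_PENALTY",
]

DEFAULT_GAP_PENALTY = -5.0

#: Background amino-acid frequencies underlying BLOSUM62 (Henikoff counts).
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


@dataclass(frozen=True)
class Mimotope:
    sequence: str
    label: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("empty mimotope sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"mimotope {self.label or self.sequence!r} contains "
                f"non-standard letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def indices(self) -> np.ndarray:
        return np.array([AA_INDEX[c] for c in self.sequence], dtype=np.int64)


@dataclass
class SubstitutionModel:
    """A 20x20 score matrix (rows: query aa, cols: antigen aa) plus gap penalty.

    The matrix need not be symmetric: the NNK-modified BLOSUM62 adjusts only
    the query-side background and is therefore asymmetric by construction.
    """

    matrix: np.ndarray
    gap_penalty: float = DEFAULT_GAP_PENALTY
    name: str = "custom"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20 in ACDEFGHIKLMNPQRSTVWY order")
        if not self.gap_penalty < 0:
            raise ValueError("gap penalty must be negative")
        if self.gap_penalty >= self.matrix.max():
            raise ValueError("gap penalty must lie below the maximum matrix entry")

    @property
    def max_entry(self) -> float:
        return float(self.matrix.max())

    def score(self, query_aa: str, target_aa: str) -> float:
        return float(self.matrix[AA_INDEX[query_aa], AA_INDEX[target_aa]])


# ---------------------------------------------------------------------------
# NNK-modified BLOSUM62
# ---------------------------------------------------------------------------

def nnk_codon_counts() -> dict[str, int]:
    """Codon counts per amino acid among the 32 NNK codons ('*' = stop)."""
    counts: dict[str, int] = {}
    for b1, b2, b3 in itertools.product("ACGT", "ACGT", "GT"):
        codon = b1 + b2 + b3
        aa = "*" if codon in standard_dna_table.stop_codons else standard_dna_table.forward_table[codon]
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def nnk_frequencies() -> np.ndarray:
    """NNK amino-acid frequencies normalised over the 20 coding letters."""
    counts = nnk_codon_counts()
    vec = np.array([counts.get(aa, 0) for aa in AMINO_ACIDS], dtype=float)
    return vec / vec.sum()


def _blosum62_array() -> np.ndarray:
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, qa in enumerate(AMINO_ACIDS):
        for j, ta in enumerate(AMINO_ACIDS):
            out[i, j] = b62[qa, ta]
    return out


def nnk_adjusted_logodds(
    base_matrix: np.ndarray,
    base_freqs: np.ndarray,
    query_freqs: np.ndarray,
    bits_per_unit: float = 0.5,
) -> np.ndarray:
    """Replace the query-side background of a log-odds matrix.

    A BLOSUM-style entry is s(q,t) = log2(p(q,t) / (f_q f_t)) / bits_per_unit
    (BLOSUM62 is in half-bits, bits_per_unit = 0.5).  Substituting a new
    query-side background f'_q changes each row by the constant
    log2(f_q / f'_q) / bits_per_unit; the result is rounded back to the same
    integer scale.  Substituting the original background reproduces the
    original matrix exactly.
    """
    base_matrix = np.asarray(base_matrix, float)
    base_freqs = np.asarray(base_freqs, float)
    query_freqs = np.asarray(query_freqs, float)
    if np.any(query_freqs <= 0) or np.any(base_freqs <= 0):
        raise ValueError("background frequencies must be positive")
    shift = np.log2(base_freqs / query_freqs) / bits_per_unit
    return np.rint(base_matrix + shift[:, None])


def derive_nnk_matrix(
    blosum62_frequencies: dict[str, float] | None = None,
    codon_counts: dict[str, int] | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> SubstitutionModel:
    """BLOSUM62 with query-side background replaced by NNK frequencies.

    ``codon_counts`` are the per-amino-acid codon counts among the 32 NNK
    codons (31 coding plus the TAG stop); ``f_q = codons_q / 32``.
    """
    counts = dict(codon_counts) if codon_counts is not None else nnk_codon_counts()
    total = sum(counts.values())
    if "*" not in counts:
        total += 1  # the TAG stop codon is implied when only aa counts are given
    if total != 32:
        raise ValueError(f"NNK codon counts must cover the 32 NNK codons, got {total}")
    missing = [aa for aa in AMINO_ACIDS if counts.get(aa, 0) <= 0]
    if missing:
        raise ValueError(f"NNK codon counts missing amino acids: {missing}")

    bg = blosum62_frequencies or BLOSUM62_BACKGROUND
    base_freqs = np.array([bg[aa] for aa in AMINO_ACIDS], float)
    query_freqs = np.array([counts[aa] / 32.0 for aa in AMINO_ACIDS], float)
    matrix = nnk_adjusted_logodds(_blosum62_array(), base_freqs, query_freqs)
    return SubstitutionModel(matrix=matrix, gap_penalty=gap_penalty, name="BLOSUM62-NNK")


def blosum62_model(gap_penalty: float = DEFAULT_GAP_PENALTY) -> SubstitutionModel:
    return SubstitutionModel(_blosum62_array(), gap_penalty, name="BLOSUM62")


def default_substitution_model(gap_penalty: float = DEFAULT_GAP_PENALTY) -> SubstitutionModel:
    """The packaged NNK-modified BLOSUM62 (see data/nnk_blosum62.txt)."""
    from importlib.resources import files

    path = files("mimomap").joinpath("data/nnk_blosum62.txt")
    with path.open() as handle:
        model = read_matrix_text(handle, gap_penalty=gap_penalty)
    model.name = "BLOSUM62-NNK"
    return model


def write_matrix_text(model: SubstitutionModel, handle, comment: str = "") -> None:
    """Write the matrix in NCBI/EMBOSS plain-text format (rows = query aa)."""
    if comment:
        for line in comment.splitlines():
            handle.write(f"# {line}\n")
    handle.write("   " + "  ".join(AMINO_ACIDS) + "\n")
    for i, aa in enumerate(AMINO_ACIDS):
        row = " ".join(f"{int(v):2d}" for v in model.matrix[i])
        handle.write(f"{aa} {row}\n")


def read_matrix_text(handle, gap_penalty: float = DEFAULT_GAP_PENALTY) -> SubstitutionModel:
    """Read an NCBI/EMBOSS plain-text matrix (rows = query aa)."""
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.read(handle)
    rows = "".join(arr.alphabet)
    out = np.empty((20, 20))
    for i, qa in enumerate(AMINO_ACIDS):
        for j, ta in enumerate(AMINO_ACIDS):
            out[i, j] = arr[rows.index(qa), rows.index(ta)]
    return SubstitutionModel(out, gap_penalty=gap_penalty, name="from-file")


def read_mimotopes(source: str | Path | Iterable[str]) -> list[Mimotope]:
    """Read mimotopes from FASTA or one-peptide-per-line text."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = "\n".join(source)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("no mimotope sequences found")
    out: list[Mimotope] = []
    if lines[0].startswith(">"):
        label, seq = None, []
        for ln in lines:
            if ln.startswith(">"):
                if label is not None and seq:
                    out.append(Mimotope("".join(seq).upper(), label))
                label, seq = ln[1:].strip(), []
            else:
                seq.append(ln)
        if label is not None and seq:
            out.append(Mimotope("".join(seq).upper(), label))
    else:
        for i, ln in enumerate(lines):
            out.append(Mimotope(ln.split()[0].upper(), f"mimotope_{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# Dynamic programming over (end vertex, visited set) states
# ---------------------------------------------------------------------------

GAP = None  # marker in alignment steps


@dataclass
class PathAlignment:
    """Best simple-path alignment of one mimotope in one patch graph.

    ``steps`` is the explicit alignment: (query position or None, vertex index
    or None); None on the query side marks an insertion (unmatched path
    vertex), None on the vertex side a deletion (skipped query position).
    Leading/trailing query positions outside the aligned window do not appear.
    """

    query: Mimotope
    graph: PatchGraph
    raw_score: float
    steps: list[tuple[int | None, int | None]] = field(default_factory=list)
    n_states: int = 0
    used_bb: bool = False

    @property
    def path_vertices(self) -> list[int]:
        return [v for _, v in self.steps if v is not None]

    @property
    def path_keys(self) -> list[ResidueKey | None]:
        return [None if v is None else self.graph.vertices[v] for _, v in self.steps]

    @property
    def path_string(self) -> str:
        out = []
        for _, v in self.steps:
            if v is None:
                out.append("-")
            else:
                c, n, ic = self.graph.vertices[v]
                out.append(f"{self.graph.vertex_aa[v]}{n}{ic}")
        return "_".join(out) if out else "(empty)"

    def recomputed_score(self, model: SubstitutionModel) -> float:
        """Score implied by the explicit steps; must equal ``raw_score``."""
        total = 0.0
        for q, v in self.steps:
            if q is not None and v is not None:
                total += model.matrix[
                    AA_INDEX[self.query.sequence[q]], AA_INDEX[self.graph.vertex_aa[v]]
                ]
            else:
                total += model.gap_penalty
        return max(total, 0.0)


def bb_upper_bound(score: float, remaining: int, model: SubstitutionModel) -> float:
    """Admissible bound: no completion can beat one max-entry per remaining position."""
    if remaining < 0:
        raise ValueError("remaining must be non-negative")
    return score + remaining * model.max_entry


def _greedy_lower_bound(
    q_idx: np.ndarray, v_aa: np.ndarray, adj: list[list[int]], model: SubstitutionModel
) -> float:
    """A quick feasible alignment score: best start pair extended greedily."""
    M = model.matrix
    k = len(q_idx)
    best = 0.0
    scores0 = M[np.ix_(q_idx, v_aa)]  # (k, n_vertices)
    i0, v0 = np.unravel_index(np.argmax(scores0), scores0.shape)
    total = scores0[i0, v0]
    best = max(best, total)
    visited = {int(v0)}
    m = int(v0)
    for i in range(i0 + 1, k):
        cands = [j for j in adj[m] if j not in visited]
        if not cands:
            break
        j = max(cands, key=lambda j: M[q_idx[i], v_aa[j]])
        total += M[q_idx[i], v_aa[j]]
        visited.add(j)
        m = j
        best = max(best, total)
    return max(best, 0.0)


def align_query_to_graph(
    graph: PatchGraph,
    query: Mimotope,
    model: SubstitutionModel,
    use_bb: bool = True,
    allow_insertions: bool = False,
    beam_width: int | None = None,
) -> PathAlignment:
    """Best free-end alignment of ``query`` to simple paths of ``graph``.

    Exact unless ``beam_width`` is set.  With ``use_bb`` the branch-and-bound
    pruning discards states that provably cannot reach the best known complete
    alignment; the returned score is identical with pruning on or off.
    """
    if graph.n_vertices == 0:
        raise ValueError("cannot align to an empty graph")
    q_idx = query.indices
    v_aa = [AA_INDEX[a] for a in graph.vertex_aa]
    adj = graph.adjacency()
    M = model.matrix.tolist()  # plain floats: much faster dict DP
    max_entry = model.max_entry
    delta = float(model.gap_penalty)
    k = len(q_idx)

    lb = _greedy_lower_bound(query.indices, np.array(v_aa), adj, model) if use_bb else -math.inf

    # states[(m, mask)] = (score, parent, op); parent = (step, m, mask) or None
    prev: dict[tuple[int, int], tuple[float, tuple | None, str]] = {}
    n_states = 0
    best_score = 0.0
    best_ref: tuple[int, int, int] | None = None  # (step, m, mask)
    trace: list[dict[tuple[int, int], tuple[float, tuple | None, str]]] = []

    for i in range(k):
        cur: dict[tuple[int, int], tuple[float, tuple | None, str]] = {}
        row = M[q_idx[i]]
        # a state at step i can gain at most max_entry per remaining position;
        # states provably unable to reach the best known alignment are dropped
        # as they are generated (exact: lb is always an achieved score)
        slack = (k - 1 - i) * max_entry

        def offer(key, score, parent, op):
            nonlocal lb, best_score, best_ref
            if use_bb and score + slack < lb:
                return False
            old = cur.get(key)
            if old is None or score > old[0]:
                cur[key] = (score, parent, op)
                if score > best_score:
                    best_score = score
                    best_ref = (i, key[0], key[1])
                if use_bb and score > lb:
                    lb = score
                return True
            return False

        # transitions from the previous step
        for (m, mask), (w, _, _) in prev.items():
            offer((m, mask), w + delta, (i - 1, m, mask), "del")
            for j in adj[m]:
                if not (mask >> j) & 1:
                    offer((j, mask | (1 << j)), w + row[v_aa[j]], (i - 1, m, mask), "match")
        # fresh starts: leading query positions are free
        for v in range(graph.n_vertices):
            offer((v, 1 << v), row[v_aa[v]], None, "match")

        if beam_width is not None and len(cur) > beam_width:
            kept = sorted(cur.items(), key=lambda kv: kv[1][0], reverse=True)[:beam_width]
            cur = dict(kept)

        # insertion relaxation within this step (unmatched path vertices)
        if allow_insertions:
            stack = list(cur.keys())
            while stack:
                m, mask = stack.pop()
                entry = cur.get((m, mask))
                if entry is None:
                    continue
                w = entry[0]
                for j in adj[m]:
                    if not (mask >> j) & 1:
                        if offer((j, mask | (1 << j)), w + delta, (i, m, mask), "ins"):
                            stack.append((j, mask | (1 << j)))

        if use_bb:
            cur = {
                key: val for key, val in cur.items() if not val[0] + slack < lb
            }

        n_states += len(cur)
        trace.append(cur)
        prev = cur

    steps: list[tuple[int | None, int | None]] = []
    if best_ref is not None and best_score > 0:
        i, m, mask = best_ref
        while True:
            score, parent, op = trace[i][(m, mask)]
            if op == "match":
                steps.append((i, m))
            elif op == "del":
                steps.append((i, None))
            else:  # ins
                steps.append((None, m))
            if parent is None:
                break
            i, m, mask = parent
        steps.reverse()
    return PathAlignment(
        query=query,
        graph=graph,
        raw_score=max(best_score, 0.0),
        steps=steps,
        n_states=n_states,
        used_bb=use_bb,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def _all_simple_paths(adj: list[list[int]], n: int) -> Iterable[tuple[int, ...]]:
    """Every directed simple path (both orientations), all lengths ≥ 1."""
    def extend(path: list[int], visited: set[int]):
        yield tuple(path)
        for j in adj[path[-1]]:
            if j not in visited:
                path.append(j)
                visited.add(j)
                yield from extend(path, visited)
                visited.remove(j)
                path.pop()

    for start in range(n):
        yield from extend([start], {start})


def brute_force_best_path(
    graph: PatchGraph,
    query: Mimotope,
    model: SubstitutionModel,
    max_vertices: int = 12,
    allow_insertions: bool = False,
) -> PathAlignment:
    """Exhaustive reference: enumerate every simple path and gap placement.

    For each simple path the first and last vertices must be matched (an
    unmatched terminal vertex is covered by the shorter path without it);
    interior skipped query positions and — with ``allow_insertions`` —
    interior unmatched vertices each cost the gap penalty, query ends are
    free.  Guarded to ≤ ``max_vertices``.
    """
    n = graph.n_vertices
    if n > max_vertices:
        raise ValueError(f"brute force limited to {max_vertices} vertices, got {n}")
    q_idx = query.indices
    v_aa = np.array([AA_INDEX[a] for a in graph.vertex_aa], dtype=np.int64)
    M = model.matrix
    delta = model.gap_penalty
    k = len(q_idx)

    best_score = 0.0
    best_combo: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]] | None = None

    for path in _all_simple_paths(graph.adjacency(), n):
        L = len(path)
        interior = list(range(1, L - 1))
        m_values = range(1, min(L, k) + 1) if allow_insertions else ([L] if L <= k else [])
        for m in m_values:
            if m < 2 and L > 1:
                continue  # both endpoints of a multi-vertex path must be matched
            # choose matched path positions: endpoints forced, rest from interior
            p_choices = (
                [(0,)] if L == 1 else
                [(0, *mid, L - 1) for mid in itertools.combinations(interior, m - 2)]
            )
            for p_pos in p_choices:
                path_gap = delta * (L - m)
                for q_pos in itertools.combinations(range(k), m):
                    score = path_gap + delta * (q_pos[-1] - q_pos[0] + 1 - m)
                    for qp, pp in zip(q_pos, p_pos):
                        score += M[q_idx[qp], v_aa[path[pp]]]
                    if score > best_score:
                        best_score = score
                        best_combo = (path, p_pos, q_pos)

    steps: list[tuple[int | None, int | None]] = []
    if best_combo is not None:
        path, p_pos, q_pos = best_combo
        matched = dict(zip(p_pos, q_pos))
        qs = iter(range(q_pos[0], q_pos[-1] + 1))
        # interleave: walk the path; emit deletions for skipped query positions
        next_q = q_pos[0]
        for pp, vertex in enumerate(path):
            if pp in matched:
                while next_q < matched[pp]:
                    steps.append((next_q, None))
                    next_q += 1
                steps.append((matched[pp], vertex))
                next_q = matched[pp] + 1
            else:
                steps.append((None, vertex))
    return PathAlignment(
        query=query, graph=graph, raw_score=best_score, steps=steps, n_states=0
    )


# ---------------------------------------------------------------------------
# Batch scoring (shared state-space sweep over many queries)
# ---------------------------------------------------------------------------

def _expand_csr(ends: np.ndarray, indptr: np.ndarray, indices: np.ndarray):
    """Rows and neighbour vertices for expanding each state by its end's edges."""
    counts = indptr[ends + 1] - indptr[ends]
    rows = np.repeat(np.arange(len(ends)), counts)
    total = int(counts.sum())
    if total == 0:
        return rows, np.empty(0, dtype=indices.dtype)
    starts = indptr[ends]
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    js = indices[np.repeat(starts, counts) + offsets]
    return rows, js


def _dedup_max(keys: np.ndarray, ends: np.ndarray, masks: np.ndarray, S: np.ndarray):
    order = np.argsort(keys, kind="stable")
    keys, ends, masks, S = keys[order], ends[order], masks[order], S[order]
    group_starts = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1]])
    S = np.maximum.reduceat(S, group_starts, axis=0)
    return keys[group_starts], ends[group_starts], masks[group_starts], S


def batch_best_scores(
    graph: PatchGraph,
    queries_idx: np.ndarray,
    model: SubstitutionModel,
    allow_insertions: bool = False,
    chunk_size: int = 256,
) -> np.ndarray:
    """Exact best alignment scores for many equal-length queries at once.

    All queries share the graph, so the reachable (end vertex, visited set)
    state space is query-independent; one sweep carries a score vector per
    state (one entry per query) and takes elementwise maxima at deduplication.
    States whose admissible upper bound (score plus the query's remaining
    match potential) cannot reach the best score already achieved for any
    query are dropped, which is what keeps insertion-gap chains from
    enumerating every connected vertex subset.  With insertions enabled a
    cheap insertion-free sweep runs first to seed those per-query lower
    bounds.  Semantics are identical to :func:`align_query_to_graph`; used
    for extreme-value calibration where only score distributions are needed.
    """
    queries_idx = np.asarray(queries_idx, dtype=np.int64)
    if queries_idx.ndim != 2:
        raise ValueError("queries_idx must be (n_queries, length)")
    n_q, k = queries_idx.shape
    if n_q > chunk_size:
        return np.concatenate(
            [
                batch_best_scores(graph, queries_idx[i : i + chunk_size], model,
                                  allow_insertions, chunk_size)
                for i in range(0, n_q, chunk_size)
            ]
        )
    best = _batch_sweep(graph, queries_idx, model, False, np.zeros(n_q))
    if allow_insertions:
        best = _batch_sweep(graph, queries_idx, model, True, best)
    return best.astype(float)


def _batch_sweep(
    graph: PatchGraph,
    queries_idx: np.ndarray,
    model: SubstitutionModel,
    allow_insertions: bool,
    best_init: np.ndarray,
) -> np.ndarray:
    n_q, k = queries_idx.shape
    n_v = graph.n_vertices
    v_aa = np.array([AA_INDEX[a] for a in graph.vertex_aa], dtype=np.int64)
    adj = graph.adjacency()
    indptr = np.zeros(n_v + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(a) for a in adj])
    indices = np.array([j for a in adj for j in a], dtype=np.int64) if indptr[-1] else np.empty(0, np.int64)
    # scores are small integer-valued sums: float32 is exact and halves the
    # memory traffic of the state-score matrix, the sweep's bottleneck
    M = model.matrix.astype(np.float32)
    delta = np.float32(model.gap_penalty)

    best = np.asarray(best_init, np.float32).copy()
    ends = np.empty(0, dtype=np.int64)
    masks = np.empty(0, dtype=np.int64)
    S = np.empty((0, n_q), dtype=np.float32)

    # per-query remaining match potential after each position (suffix sums of
    # the best matrix entry available to each query residue)
    row_max = M.max(axis=1)[queries_idx]  # (n_q, k)
    pot = np.zeros((k, n_q), dtype=np.float32)
    if k > 1:
        pot[:-1] = np.cumsum(row_max[:, :0:-1], axis=1)[:, ::-1].T

    all_v = np.arange(n_v, dtype=np.int64)
    for i in range(k):
        Mq = M[queries_idx[:, i]]  # (n_q, 20): per-query row at this position
        # states that provably cannot reach the best score already achieved for
        # any query are dropped (exact branch-and-bound, elementwise over queries)
        ceiling = best[None, :] - pot[i][None, :]

        def useful(scores: np.ndarray) -> np.ndarray:
            return (scores >= ceiling).any(axis=1)

        parts_e, parts_m, parts_s = [], [], []
        if len(ends):
            # deletion: skip this query position on every surviving state
            parts_e.append(ends)
            parts_m.append(masks)
            parts_s.append(S + delta)
            # match: extend to an unvisited neighbour
            rows, js = _expand_csr(ends, indptr, indices)
            if len(js):
                ok = (masks[rows] >> js) & 1 == 0
                rows, js = rows[ok], js[ok]
                parts_e.append(js)
                parts_m.append(masks[rows] | (np.int64(1) << js))
                parts_s.append(S[rows] + Mq[:, v_aa[js]].T)
        # fresh start at this position (free leading query gap)
        parts_e.append(all_v)
        parts_m.append(np.int64(1) << all_v)
        parts_s.append(Mq[:, v_aa].T.copy())

        ends = np.concatenate(parts_e)
        masks = np.concatenate(parts_m)
        S = np.vstack(parts_s)
        keys = masks * np.int64(64) + ends
        keys, ends, masks, S = _dedup_max(keys, ends, masks, S)
        np.maximum(best, S.max(axis=0), out=best)
        ceiling = best[None, :] - pot[i][None, :]
        keep = useful(S)
        keys, ends, masks, S = keys[keep], ends[keep], masks[keep], S[keep]

        if allow_insertions and len(indices):
            while len(ends):
                rows, js = _expand_csr(ends, indptr, indices)
                if not len(js):
                    break
                ok = (masks[rows] >> js) & 1 == 0
                rows, js = rows[ok], js[ok]
                if not len(js):
                    break
                cand_s = S[rows] + delta
                ok = useful(cand_s)
                rows, js, cand_s = rows[ok], js[ok], cand_s[ok]
                if not len(js):
                    break
                ne = np.concatenate([ends, js])
                nm = np.concatenate([masks, masks[rows] | (np.int64(1) << js)])
                nS = np.vstack([S, cand_s])
                nk = nm * np.int64(64) + ne
                nk, ne, nm, nS = _dedup_max(nk, ne, nm, nS)
                if (
                    len(nk) == len(keys)
                    and np.array_equal(nk, keys)
                    and np.array_equal(nS, S)
                ):
                    break
                keys, ends, masks, S = nk, ne, nm, nS
    return np.maximum(best, 0.0)
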