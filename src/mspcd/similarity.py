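"""The five base similarity models.

* sequence similarity — weighted Levenshtein distance between circRNA
  nucleotide sequences, normalised to [0, 1];
* functional similarity — mean of three Jaccard coefficients over a
  circRNA's disease, GO-term and miRNA association profiles;
* Gaussian interaction-profile (GIP) kernel similarity for circRNAs
  (rows of the association matrix) and for diseases (columns);
* two DAG-based disease semantic models: level-decay contributions
  (model 1) and rarity-weighted contributions (model 2).

Two formula conventions are deliberately configurable.  The GIP bandwidth
is by default the *mean squared profile norm* used as a multiplier
(``as_printed``); the ``reciprocal`` option instead divides by that mean,
which is the convention of the original GIP-kernel literature.  The
second semantic model by default normalises by the rarity-weighted
contribution sums (``primed``), which keeps scores in [0, 1] with a unit
diagonal; ``as_printed`` normalises by the level-decay sums instead and
can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataio import AssociationMatrix, DiseaseDAG, SequenceSet, SimilarityMatrix
from .errors import CoverageError, ParameterError, ValidationError

__all__ = [
    "EditCosts",
    "SemanticParams",
    "GipParams",
    "levenshtein_distance",
    "sequence_similarity",
    "sequence_similarity_matrix",
    "jaccard",
    "jaccard_matrix",
    "functional_similarity",
    "gip_bandwidth",
    "gip_kernel",
    "circ_gip_similarity",
    "disease_gip_similarity",
    "semantic_contribution",
    "semantic_similarity_1",
    "semantic_similarity_2",
]


@dataclass(frozen=True)
class EditCosts:
    """Per-operation costs for the weighted Levenshtein distance.

    The defaults (insert 1, delete 1, substitute 2) make the distance
    equal to ``len(a) + len(b) - 2 * LCS(a, b)``.
    """

    insert: float = 1.0
    delete: float = 1.0
    substitute: float = 2.0

    def __post_init__(self) -> None:
        if min(self.insert, self.delete, self.substitute) < 0:
            raise ParameterError("edit costs must be non-negative")


@dataclass(frozen=True)
class SemanticParams:
    """Parameters of the DAG semantic similarity models.

    mu is the per-level decay of a term's contribution (0 < mu <= 1).
    log_base is the base of the rarity weight logarithm; ``None`` means
    natural log.  ds2_denominator selects the model-2 normaliser.
    """

    mu: float = 0.5
    log_base: float | None = None
    ds2_denominator: str = "primed"

    def __post_init__(self) -> None:
        if not (0.0 < self.mu <= 1.0):
            raise ParameterError("mu must lie in (0, 1]")
        if self.ds2_denominator not in ("primed", "as_printed"):
            raise ParameterError("ds2_denominator must be 'primed' or 'as_printed'")
        if self.log_base is not None and self.log_base <= 1.0:
            raise ParameterError("log_base must exceed 1")


@dataclass(frozen=True)
class GipParams:
    bandwidth_convention: str = "as_printed"

    def __post_init__(self) -> None:
        if self.bandwidth_convention not in ("as_printed", "reciprocal"):
            raise ParameterError(
                "bandwidth_convention must be 'as_printed' or 'reciprocal'"
            )


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not a or not callable(a[0]) else a[0]


@njit(cache=True)
def _lev_dp(a: np.ndarray, b: np.ndarray, ci: float, cd: float, cs: float) -> float:
    """Two-row DP over byte arrays; transforms a into b."""
    n = b.shape[0]
    prev = np.empty(n + 1, dtype=np.float64)
    cur = np.empty(n + 1, dtype=np.float64)
    for j in range(n + 1):
        prev[j] = ci * j
    for i in range(a.shape[0]):
        cur[0] = cd * (i + 1)
        for j in range(n):
            sub = prev[j] + (0.0 if a[i] == b[j] else cs)
            dele = prev[j + 1] + cd
            ins = cur[j] + ci
            best = sub
            if dele < best:
                best = dele
            if ins < best:
                best = ins
            cur[j + 1] = best
        prev, cur = cur, prev
    return prev[n]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("utf-8"), dtype=np.uint8)


def levenshtein_distance(a: str, b: str, costs: EditCosts = EditCosts()) -> float:
    """Minimum total cost of an insert/delete/substitute script turning
    *a* into *b*.  Symmetric whenever insert and delete costs agree."""
    return float(
        _lev_dp(_encode(a), _encode(b), costs.insert, costs.delete, costs.substitute)
    )


def sequence_similarity(a: str, b: str, costs: EditCosts = EditCosts()) -> float:
    """Normalised edit similarity ``(l(a)+l(b)-cost_min) / (l(a)+l(b))``."""
    la, lb = len(a), len(b)
    if la + lb == 0:
        raise ParameterError("sequence similarity of two empty strings is undefined")
    return (la + lb - levenshtein_distance(a, b, costs)) / (la + lb)


def sequence_similarity_matrix(
    seqs: SequenceSet,
    ids: Sequence[str],
    costs: EditCosts = EditCosts(),
) -> SimilarityMatrix:
    """Pairwise sequence similarity over *ids* (association-matrix order).

    Pairs with a missing sequence get placeholder 0; the fusion stage
    masks them out with the sequence flag matrix, so the placeholder value
    is never consumed.  The diagonal is 1 for circRNAs with a sequence.
    """
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    encoded = {i: _encode(seqs.sequences[i]) for i in ids if i in seqs}
    covered = [i for i in ids if i in encoded]
    ci, cd, cs = costs.insert, costs.delete, costs.substitute
    pos = {cid: k for k, cid in enumerate(ids)}
    for x, cm in enumerate(covered):
        am = encoded[cm]
        values[pos[cm], pos[cm]] = 1.0
        for cn in covered[x + 1 :]:
            an = encoded[cn]
            tot = am.shape[0] + an.shape[0]
            sim = (tot - _lev_dp(am, an, ci, cd, cs)) / tot
            values[pos[cm], pos[cn]] = sim
            values[pos[cn], pos[cm]] = sim
    return SimilarityMatrix(values, list(ids), "CS")


# ---------------------------------------------------------------------------
# functional similarity
# ---------------------------------------------------------------------------


def jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """Jaccard coefficient of two binary profiles; 0 when the union is
    empty (keeps the score defined for annotation-free entities)."""
    u = np.asarray(u).astype(bool)
    v = np.asarray(v).astype(bool)
    if u.shape != v.shape:
        raise ParameterError(f"profile lengths differ: {u.shape} vs {v.shape}")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(u, v).sum() / union)


def jaccard_matrix(profiles: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard over the rows of a binary matrix."""
    m = np.asarray(profiles, dtype=float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return out


def functional_similarity(
    Sd: AssociationMatrix, Sg: AssociationMatrix, Sm: AssociationMatrix
) -> SimilarityMatrix:
    """CircRNA functional similarity: the mean of the disease-, GO- and
    miRNA-profile Jaccard coefficients for each circRNA pair."""
    if not (Sd.row_ids == Sg.row_ids == Sm.row_ids):
        raise ValidationError("association tables disagree on circRNA row ids")
    cf = (
        jaccard_matrix(Sd.values) + jaccard_matrix(Sg.values) + jaccard_matrix(Sm.values)
    ) / 3.0
    return SimilarityMatrix(cf, list(Sd.row_ids), "CF")


# ---------------------------------------------------------------------------
# GIP kernel similarity
# ---------------------------------------------------------------------------


def gip_bandwidth(profiles: np.ndarray, params: GipParams = GipParams()) -> float:
    """Bandwidth of the interaction-profile Gaussian kernel.

    ``as_printed`` returns the mean squared profile norm; ``reciprocal``
    returns its reciprocal (the classic normalisation).
    """
    m = np.asarray(profiles, dtype=float)
    mean_sq = float((m * m).sum() / m.shape[0])
    if mean_sq == 0.0:
        raise ParameterError(
            "all interaction profiles are zero: GIP bandwidth is degenerate"
        )
    return mean_sq if params.bandwidth_convention == "as_printed" else 1.0 / mean_sq


def gip_kernel(
    profiles: np.ndarray, ids: Sequence[str], params: GipParams = GipParams(), name: str = ""
) -> SimilarityMatrix:
    """Gaussian kernel ``exp(-delta * ||p_m - p_n||^2)`` between binary
    interaction profiles (one profile per row)."""
    delta = gip_bandwidth(profiles, params)
    m = np.asarray(profiles, dtype=float)
    sq = squareform(pdist(m, metric="sqeuclidean")) if m.shape[0] > 1 else np.zeros((1, 1))
    values = np.exp(-delta * sq)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, list(ids), name)


def circ_gip_similarity(Sd: AssociationMatrix, params: GipParams = GipParams()) -> SimilarityMatrix:
    """GIP kernel between circRNAs: profiles are rows of the association
    matrix (a circRNA's disease interaction profile)."""
    return gip_kernel(Sd.values, Sd.row_ids, params, "CG")


def disease_gip_similarity(Sd: AssociationMatrix, params: GipParams = GipParams()) -> SimilarityMatrix:
    """GIP kernel between diseases: profiles are columns of the
    association matrix."""
    return gip_kernel(Sd.values.T, Sd.col_ids, params, "DG")


# ---------------------------------------------------------------------------
# DAG semantic similarity
# ---------------------------------------------------------------------------


def semantic_contribution(
    dag: DiseaseDAG, d: str, params: SemanticParams = SemanticParams()
) -> dict[str, float]:
    """Contribution G_d(k) of every term k in the DAG of disease d.

    The disease's own contribution is 1; each ancestor contributes
    ``max(mu * G_d(child))`` over its children inside the DAG of d, which
    equals mu raised to the length of the shortest directed path from the
    ancestor down to d.
    """
    if d not in dag:
        raise CoverageError(f"disease {d!r} is not in the DAG")
    nd = dag.ancestor_set(d)
    sub = dag.graph.subgraph(nd)
    contrib: dict[str, float] = {d: 1.0}
    # reverse topological order: every node's children are scored first
    for k in reversed(list(nx.topological_sort(sub))):
        if k == d:
            continue
        contrib[k] = max(
            params.mu * contrib[c] for c in sub.successors(k) if c in contrib
        )
    return contrib


def _contributions(
    dag: DiseaseDAG, ids: Sequence[str], params: SemanticParams
) -> dict[str, dict[str, float]]:
    return {d: semantic_contribution(dag, d, params) for d in dag.covered(ids)}


def semantic_similarity_1(
    dag: DiseaseDAG, ids: Sequence[str], params: SemanticParams = SemanticParams()
) -> SimilarityMatrix:
    """First semantic model: shared-ancestor contributions normalised by
    the two diseases' total contributions.  Uncovered diseases get 0 rows
    (masked later by the semantic flag matrix)."""
    contribs = _contributions(dag, ids, params)
    # sums run in sorted key order so results do not depend on the
    # process's hash randomization (float addition is not associative)
    totals = {d: sum(c[k] for k in sorted(c)) for d, c in contribs.items()}
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    for i, dm in enumerate(ids):
        if dm not in contribs:
            continue
        gm = contribs[dm]
        for j in range(i, n):
            dn = ids[j]
            if dn not in contribs:
                continue
            gn = contribs[dn]
            shared = sorted(gm.keys() & gn.keys())
            num = sum(gm[k] + gn[k] for k in shared)
            den = totals[dm] + totals[dn]
            s = num / den if den > 0 else 0.0
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values, list(ids), "DS1")


def semantic_similarity_2(
    dag: DiseaseDAG, ids: Sequence[str], params: SemanticParams = SemanticParams()
) -> SimilarityMatrix:
    """Second semantic model: term contributions weighted by rarity,
    ``G'(k) = log(n_dis / n_DAGs(k))`` where n_dis counts DAG-covered
    diseases and n_DAGs(k) counts those whose DAG contains k."""
    contribs = _contributions(dag, ids, params)
    covered = list(contribs)
    n_dis = len(covered)
    counts: dict[str, int] = {}
    for c in contribs.values():
        for k in c:
            counts[k] = counts.get(k, 0) + 1
    log = np.log if params.log_base is None else (
        lambda x: np.log(x) / np.log(params.log_base)
    )
    gprime = {k: float(log(n_dis / c)) for k, c in counts.items()}
    # sorted iteration: see semantic_similarity_1
    prime_tot = {
        d: sum(gprime[k] for k in sorted(contribs[d])) for d in covered
    }
    decay_tot = {d: sum(contribs[d][k] for k in sorted(contribs[d])) for d in covered}
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    for i, dm in enumerate(ids):
        if dm not in contribs:
            continue
        for j in range(i, n):
            dn = ids[j]
            if dn not in contribs:
                continue
            shared = sorted(contribs[dm].keys() & contribs[dn].keys())
            num = sum(2.0 * gprime[k] for k in shared)
            if params.ds2_denominator == "primed":
                den = prime_tot[dm] + prime_tot[dn]
            else:
                den = decay_tot[dm] + decay_tot[dn]
            s = num / den if den > 0 else 0.0
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values, list(ids), "DS2")
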