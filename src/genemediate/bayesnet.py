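"""Bayesian-network structure MCMC over discrete variables.

Families are scored with the Dirichlet(1,...,1) marginal likelihood (the
Cooper-Herskovits / K2 score); the structure prior is uniform over DAGs
satisfying the constraints (exogenous variables have no incoming edges and
no edges among themselves; a cap on the number of parents).  A
Metropolis-Hastings chain over single-edge add/delete/reverse moves, with
the proposal-neighborhood-size correction, yields posterior edge, relation
(either-direction adjacency), and category-level probabilities.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class DiscreteDataset:
    """Complete-case categorical data matrix with per-variable arities."""

    data: np.ndarray  # (n, V) integer codes 0..arity-1
    names: list[str]
    arities: list[int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=int)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.names):
            raise ValueError("data shape inconsistent with variable names")
        if len(self.arities) != len(self.names):
            raise ValueError("arity list inconsistent with variable names")
        if any(r < 2 for r in self.arities):
            raise ValueError("every variable needs arity >= 2")
        for j, r in enumerate(self.arities):
            col = self.data[:, j]
            if self.data.shape[0] and (col.min() < 0 or col.max() >= r):
                raise ValueError(f"codes of {self.names[j]!r} outside 0..{r - 1}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DiscreteDataset":
        if df.isna().any(axis=None):
            raise ValueError("dataset must be complete-case (no missing values)")
        codes = []
        arities = []
        for c in df.columns:
            cat = pd.Categorical(df[c])
            codes.append(np.asarray(cat.codes))
            arities.append(len(cat.categories))
        return cls(np.column_stack(codes), list(df.columns), arities)

    @property
    def V(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class StructureConstraints:
    """Exogenous variables (sources only) and the parent-count cap."""

    exogenous: frozenset = frozenset()
    max_parents: int = 4

    def __post_init__(self) -> None:
        self.exogenous = frozenset(self.exogenous)

    def allows_edge(self, u_name: str, v_name: str) -> bool:
        if v_name in self.exogenous:
            return False  # no incoming edges on exogenous variables
        return True


def ch_family_score(target: int, parents: tuple, data: DiscreteDataset) -> float:
    """Log marginal likelihood of one node given its parent set.

    log prod_j [ Gamma(r) / Gamma(N_j + r) * prod_k Gamma(N_jk + 1) ]
    over parent configurations j, for a target with r states.
    """
    r = data.arities[target]
    x = data.data[:, target]
    if data.data.shape[0] == 0:
        return 0.0
    if parents:
        stride = 1
        pconf = np.zeros(data.data.shape[0], dtype=np.int64)
        for p in parents:
            pconf += stride * data.data[:, p]
            stride *= data.arities[p]
        n_conf = stride
        counts = np.bincount(pconf * r + x, minlength=n_conf * r).reshape(n_conf, r)
    else:
        counts = np.bincount(x, minlength=r).reshape(1, r)
    nj = counts.sum(axis=1)
    score = (gammaln(r) - gammaln(nj + r)).sum() + gammaln(counts + 1.0).sum()
    return float(score)


def _is_acyclic(adj: np.ndarray) -> bool:
    """Kahn's algorithm on a boolean adjacency matrix (adj[u, v] = u -> v)."""
    indeg = adj.sum(axis=0).astype(int)
    stack = list(np.flatnonzero(indeg == 0))
    seen = 0
    indeg = indeg.copy()
    while stack:
        u = stack.pop()
        seen += 1
        for v in np.flatnonzero(adj[u]):
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == adj.shape[0]


def _satisfies(adj: np.ndarray, data: DiscreteDataset, cons: StructureConstraints) -> bool:
    exo = [data.index(e) for e in cons.exogenous]
    if adj[:, exo].any():
        return False
    if any(adj[u, v] for u in exo for v in exo):
        return False
    if (adj.sum(axis=0) > cons.max_parents).any():
        return False
    return _is_acyclic(adj)


def dag_score(adj: np.ndarray, data: DiscreteDataset, cons: StructureConstraints) -> float:
    """Sum of family scores; raises on cycles, -inf on constraint violation."""
    adj = np.asarray(adj, dtype=bool)
    if not _is_acyclic(adj):
        raise ValueError("graph has a cycle")
    if not _satisfies(adj, data, cons):
        return -np.inf
    return sum(
        ch_family_score(v, tuple(np.flatnonzero(adj[:, v])), data)
        for v in range(data.V)
    )


@dataclass
class BayesNetPosterior:
    """Posterior summaries from structure samples."""

    names: list[str]
    edge: np.ndarray  # (V, V) directed-edge posterior
    relation: np.ndarray  # (V, V) either-direction adjacency posterior
    samples: list  # packed boolean adjacency samples (np.packbits)
    V: int
    acceptance_rate: float
    score_trace: dict

    def _unpack(self, packed: np.ndarray) -> np.ndarray:
        return np.unpackbits(packed, count=self.V * self.V).reshape(self.V, self.V).astype(bool)

    def relation_posterior(self, a: str, b: str) -> float:
        return float(self.relation[self.names.index(a), self.names.index(b)])

    def category_posterior(
        self, target: str, category, method: str = "adjacency"
    ) -> float:
        """Posterior that the target relates to >= 1 category member.

        ``method='adjacency'`` counts samples where the target is adjacent
        (either direction) to some member; ``method='markov_blanket'``
        counts samples where some member lies in the target's Markov
        blanket (parents, children, co-parents).
        """
        members = [self.names.index(c) for c in category]
        if not members:
            raise ValueError("category must be nonempty")
        t = self.names.index(target)
        if t in members:
            raise ValueError("target must not belong to the category")
        weights = getattr(self, "_weights", None)
        if weights is None:
            weights = np.full(len(self.samples), 1.0 / len(self.samples))
        hits = 0.0
        for packed, wi in zip(self.samples, weights):
            adj = self._unpack(packed)
            if method == "adjacency":
                hit = bool(adj[t, members].any() or adj[members, t].any())
            elif method == "markov_blanket":
                mb = set(np.flatnonzero(adj[:, t])) | set(np.flatnonzero(adj[t]))
                for child in np.flatnonzero(adj[t]):
                    mb |= set(np.flatnonzero(adj[:, child]))
                mb.discard(t)
                hit = bool(mb & set(members))
            else:
                raise ValueError(f"unknown method {method!r}")
            hits += wi * hit
        return float(hits)


def _valid_moves(adj, parents_count, desc, exo_idx, max_parents):
    """List of admissible single-edge moves: ('a'dd|'d'el|'r'ev, u, v)."""
    V = adj.shape[0]
    moves = []
    for u in range(V):
        for v in range(V):
            if u == v:
                continue
            if adj[u, v]:
                moves.append(("d", u, v))
                # reverse u->v: v->u; u gains a parent
                if u not in exo_idx and parents_count[u] < max_parents:
                    adj[u, v] = False
                    if not _reachable(adj, u, v):
                        moves.append(("r", u, v))
                    adj[u, v] = True
            else:
                if v in exo_idx:
                    continue
                if u in exo_idx and v in exo_idx:
                    continue
                if parents_count[v] >= max_parents:
                    continue
                if u in desc[v]:  # adding u->v would close a cycle
                    continue
                moves.append(("a", u, v))
    return moves


def _reachable(adj: np.ndarray, src: int, dst: int) -> bool:
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in np.flatnonzero(adj[u]):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _descendants(adj: np.ndarray) -> list:
    V = adj.shape[0]
    desc = []
    for v in range(V):
        seen: set = set()
        stack = list(np.flatnonzero(adj[v]))
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(np.flatnonzero(adj[u]))
        desc.append(seen)
    return desc


def structure_mcmc(
    data: DiscreteDataset,
    constraints: StructureConstraints | None = None,
    burn_in: int = 10_000,
    n_samples: int = 100_000,
    thin: int = 10,
    seed: int = 0,
) -> BayesNetPosterior:
    """Metropolis-Hastings over DAGs with add/delete/reverse moves.

    The acceptance ratio includes the |N(G)| / |N(G')| neighborhood-size
    correction for the uniform proposal over admissible moves.  Thinned
    samples are retained (packed) so category posteriors can be evaluated
    afterwards for arbitrary variable groups.
    """
    cons = constraints or StructureConstraints()
    rng = np.random.default_rng(seed)
    V = data.V
    if V < 2:
        raise ValueError("need at least 2 variables")
    exo_idx = {data.index(e) for e in cons.exogenous}

    adj = np.zeros((V, V), dtype=bool)
    parents: list[tuple] = [() for _ in range(V)]
    cache: dict = {}

    def family(v: int, pa: tuple) -> float:
        key = (v, pa)
        if key not in cache:
            cache[key] = ch_family_score(v, pa, data)
        return cache[key]

    score = sum(family(v, ()) for v in range(V))

    edge_sum = np.zeros((V, V))
    rel_sum = np.zeros((V, V))
    samples: list = []
    scores: list = []
    accepted = 0
    proposed = 0

    pcount = np.zeros(V, dtype=int)
    total_steps = burn_in + n_samples
    for step in range(total_steps):
        desc = _descendants(adj)
        moves = _valid_moves(adj, pcount, desc, exo_idx, cons.max_parents)
        if not moves:
            raise RuntimeError("no admissible move: chain is fully constrained")
        kind, u, v = moves[rng.integers(len(moves))]
        proposed += 1

        if kind == "a":
            new_parents_v = tuple(sorted(parents[v] + (u,)))
            delta = family(v, new_parents_v) - family(v, parents[v])
            changes = [(v, new_parents_v)]
            edits = [((u, v), True)]
        elif kind == "d":
            new_parents_v = tuple(p for p in parents[v] if p != u)
            delta = family(v, new_parents_v) - family(v, parents[v])
            changes = [(v, new_parents_v)]
            edits = [((u, v), False)]
        else:  # reverse u->v  =>  v->u
            new_parents_v = tuple(p for p in parents[v] if p != u)
            new_parents_u = tuple(sorted(parents[u] + (v,)))
            delta = (
                family(v, new_parents_v)
                - family(v, parents[v])
                + family(u, new_parents_u)
                - family(u, parents[u])
            )
            changes = [(v, new_parents_v), (u, new_parents_u)]
            edits = [((u, v), False), ((v, u), True)]

        for (a, b), val in edits:
            adj[a, b] = val
        pcount_new = adj.sum(axis=0)
        desc_new = _descendants(adj)
        n_moves_new = len(_valid_moves(adj, pcount_new, desc_new, exo_idx, cons.max_parents))
        log_alpha = delta + np.log(len(moves)) - np.log(n_moves_new)
        if np.log(rng.random()) < log_alpha:
            accepted += 1
            score += delta
            for node, pa in changes:
                parents[node] = pa
            pcount = pcount_new
        else:
            for (a, b), val in edits:
                adj[a, b] = not val

        if step >= burn_in and (step - burn_in) % thin == 0:
            edge_sum += adj
            rel_sum += adj | adj.T
            samples.append(np.packbits(adj))
            scores.append(score)

    n_kept = len(samples)
    return BayesNetPosterior(
        names=list(data.names),
        edge=edge_sum / n_kept,
        relation=rel_sum / n_kept,
        samples=samples,
        V=V,
        acceptance_rate=accepted / max(proposed, 1),
        score_trace={
            "mean": float(np.mean(scores)),
            "min": float(np.min(scores)),
            "max": float(np.max(scores)),
        },
    )


def enumerate_posterior(
    data: DiscreteDataset, constraints: StructureConstraints | None = None
) -> BayesNetPosterior:
    """Exact posterior by exhaustive enumeration of admissible DAGs.

    Practical for 3-5 variables; serves as the oracle for the MCMC
    estimates and for category posteriors.
    """
    cons = constraints or StructureConstraints()
    V = data.V
    pairs = list(itertools.combinations(range(V), 2))
    adjs = []
    log_scores = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((V, V), dtype=bool)
        for (u, v), st in zip(pairs, states):
            if st == 1:
                adj[u, v] = True
            elif st == 2:
                adj[v, u] = True
        if not _satisfies(adj, data, cons):
            continue
        s = sum(
            ch_family_score(v, tuple(np.flatnonzero(adj[:, v])), data)
            for v in range(V)
        )
        adjs.append(adj)
        log_scores.append(s)
    log_scores = np.array(log_scores)
    w = np.exp(log_scores - log_scores.max())
    w /= w.sum()
    edge = np.zeros((V, V))
    rel = np.zeros((V, V))
    for adj, wi in zip(adjs, w):
        edge += wi * adj
        rel += wi * (adj | adj.T)
    # weighted "samples" are not stored; emulate category posteriors by
    # keeping the weighted graphs
    post = BayesNetPosterior(
        names=list(data.names),
        edge=edge,
        relation=rel,
        samples=[np.packbits(a) for a in adjs],
        V=V,
        acceptance_rate=1.0,
        score_trace={
            "mean": float(np.mean(log_scores)),
            "min": float(np.min(log_scores)),
            "max": float(np.max(log_scores)),
        },
    )
    post._weights = w  # type: ignore[attr-defined]
    return post


def exact_category_posterior(
    post: BayesNetPosterior, target: str, category, method: str = "adjacency"
) -> float:
    """Category posterior for an enumeration-based posterior (weighted)."""
    if getattr(post, "_weights", None) is None:
        raise ValueError("posterior lacks enumeration weights")
    return post.category_posterior(target, category, method=method)


def relevance_filter(
    post: BayesNetPosterior, pairs, threshold: float = 0.5
) -> pd.DataFrame:
    """Flag pairs/categories whose posterior strictly exceeds the threshold.

    ``pairs`` entries are (target, other) with ``other`` a variable name or
    a list of names (a category).
    """
    rows = []
    for target, other in pairs:
        if isinstance(other, str):
            prob = post.relation_posterior(target, other)
            label = other
        else:
            prob = post.category_posterior(target, other)
            label = "+".join(other)
        rows.append(
            {"target": target, "other": label, "posterior": prob, "relevant": bool(prob > threshold)}
        )
    return pd.DataFrame(rows)
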