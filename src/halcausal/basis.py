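"""Tensor-product spline bases for the Highly Adaptive LASSO.

A HAL basis term is indexed by a nonempty subset ``s`` of covariate
coordinates and a knot vector ``u`` of the same length.  The zeroth-order
term is the tensor-product indicator

    phi(x) = prod_{l in s} 1{x_l >= u_l},

and the first-order term replaces each indicator with the hinge
``max(x_l - u_l, 0)``.  Any cadlag function of bounded sectional variation
is approximated arbitrarily well by linear combinations of such indicators
with knots at observed data points, and the sectional variation norm of the
combination equals the L1 norm of its coefficients — which is why the
fitting module penalizes the plain L1 norm without column standardization.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "BasisFunction",
    "BasisDictionary",
    "enumerate_knots",
    "evaluate_basis",
]

# default cap on candidate columns before quantile reduction kicks in
DEFAULT_COLUMN_BUDGET = 100_000


@dataclass(frozen=True, order=True)
class BasisFunction:
    """One tensor-product term: coordinate subset, knot vector, spline order.

    ``cols`` holds 0-based covariate indices, sorted ascending; ``knots``
    aligns with ``cols`` and is expressed in original covariate units.
    """

    cols: tuple[int, ...]
    knots: tuple[float, ...]
    order: int = 0

    def __post_init__(self) -> None:
        if len(self.cols) < 1:
            raise ValueError("basis term needs a nonempty coordinate subset")
        if len(self.knots) != len(self.cols):
            raise ValueError("knot vector length must match subset size")
        if self.order not in (0, 1):
            raise ValueError("only spline orders 0 and 1 are supported")
        if tuple(sorted(self.cols)) != self.cols:
            raise ValueError("cols must be sorted ascending")

    @property
    def degree(self) -> int:
        return len(self.cols)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the term on an (m, d) matrix, returning a length-m column."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.ones(X.shape[0])
        for c, u in zip(self.cols, self.knots):
            if self.order == 0:
                out *= X[:, c] >= u  # right-closed: equals 1 at the knot
            else:
                out *= np.maximum(X[:, c] - u, 0.0)
        return out


@dataclass
class BasisDictionary:
    """An ordered, deduplicated collection of basis terms sharing one order."""

    terms: list[BasisFunction]
    n_features: int
    max_degree: int
    order: int = 0
    #: duplicate candidate -> retained representative (by training columns)
    dedup_map: dict[BasisFunction, BasisFunction] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def evaluate(self, X: np.ndarray) -> sparse.csc_matrix:
        return evaluate_basis(self, X)

    def subset(self, idx: np.ndarray | list[int]) -> "BasisDictionary":
        """Dictionary restricted to the terms at positions ``idx``."""
        return BasisDictionary(
            terms=[self.terms[i] for i in np.asarray(idx, dtype=int)],
            n_features=self.n_features,
            max_degree=self.max_degree,
            order=self.order,
        )

    # -- plain-text serialization so fitted models are portable ------------
    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "max_degree": self.max_degree,
            "order": self.order,
            "terms": [
                {"cols": list(t.cols), "knots": list(map(float, t.knots))}
                for t in self.terms
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "BasisDictionary":
        terms = [
            BasisFunction(tuple(t["cols"]), tuple(t["knots"]), d["order"])
            for t in d["terms"]
        ]
        return cls(
            terms=terms,
            n_features=d["n_features"],
            max_degree=d["max_degree"],
            order=d["order"],
        )

    @classmethod
    def from_json(cls, s: str) -> "BasisDictionary":
        return cls.from_dict(json.loads(s))


def _parse_policy(policy) -> tuple[str, int | None]:
    """Accept 'all', 'auto', 'quantiles(m)', 'kmeans(m)', or (name, m) tuples."""
    if isinstance(policy, tuple):
        return policy[0], int(policy[1])
    if policy in ("all", "auto"):
        return policy, None
    m = re.fullmatch(r"(quantiles|kmeans)\((\d+)\)", str(policy))
    if m is None:
        raise ValueError(f"unknown knot reduction policy: {policy!r}")
    return m.group(1), int(m.group(2))


def _candidate_knots(
    X: np.ndarray, subsets: list[tuple[int, ...]], name: str, m: int | None, n: int
) -> list[tuple[tuple[int, ...], tuple[float, ...]]]:
    cands: list[tuple[tuple[int, ...], tuple[float, ...]]] = []
    if name == "all":
        for s in subsets:
            rows = np.unique(X[:, s], axis=0)
            cands.extend((s, tuple(map(float, r))) for r in rows)
    elif name == "quantiles":
        # per-coordinate quantile knots, then tensor products within subsets
        per_coord = {}
        for c in sorted({c for s in subsets for c in s}):
            qs = np.quantile(X[:, c], np.linspace(0, 1, m), method="lower")
            per_coord[c] = np.unique(qs)
        for s in subsets:
            for combo in itertools.product(*(per_coord[c] for c in s)):
                cands.append((s, tuple(map(float, combo))))
    elif name == "kmeans":
        from sklearn.cluster import KMeans

        for s in subsets:
            pts = np.unique(X[:, s], axis=0)
            if len(pts) <= m:
                cands.extend((s, tuple(map(float, r))) for r in pts)
                continue
            km = KMeans(n_clusters=m, n_init=1, random_state=0).fit(pts)
            for r in km.cluster_centers_:
                cands.append((s, tuple(map(float, r))))
    else:  # pragma: no cover
        raise ValueError(name)
    return cands


def enumerate_knots(
    X: np.ndarray,
    max_degree: int | None = None,
    knot_reduction="auto",
    order: int = 0,
    column_budget: int = DEFAULT_COLUMN_BUDGET,
) -> BasisDictionary:
    """Tabulate data-dependent knots and build a deduplicated basis dictionary.

    For policy ``all`` every observed point contributes a knot vector to each
    coordinate subset of size <= ``max_degree`` — the exhaustive construction,
    up to ``n * (2^d - 1)`` candidate columns.  ``quantiles(m)`` reduces to
    ``m`` per-coordinate empirical quantiles before forming tensor products;
    ``kmeans(m)`` uses ``m`` cluster centroids per subset.  ``auto`` picks
    ``all`` while the candidate count stays within ``column_budget`` and
    otherwise falls back to quantiles with the largest ``m`` that fits.

    Candidates whose columns on the training data coincide are collapsed to
    the lexicographically smallest ``(cols, knots)`` representative, recorded
    in ``dedup_map``, so retained columns are pairwise distinct.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 1 or d < 1:
        raise ValueError("X must be a nonempty n x d matrix")
    if max_degree is None:
        max_degree = d
    if not 1 <= max_degree <= d:
        raise ValueError(f"max_degree must be in [1, {d}], got {max_degree}")

    name, m = _parse_policy(knot_reduction)
    if m is not None and m > n:
        raise ValueError("knot reduction size m cannot exceed n")

    subsets = [
        tuple(s)
        for k in range(1, max_degree + 1)
        for s in itertools.combinations(range(d), k)
    ]
    if name == "auto":
        n_cand = n * len(subsets)
        if n_cand <= column_budget:
            name = "all"
        else:
            name = "quantiles"
            m = max(2, int(column_budget / max(1, len(subsets))) )
            # tensor products inflate |s|>1 subsets; shrink m until the
            # worst-case product count fits the budget
            while m > 2 and sum(min(m ** len(s), n) for s in subsets) > column_budget:
                m -= 1

    cands = _candidate_knots(X, subsets, name, m, n)
    cands.sort()  # lexicographic: dedup keeps the smallest representative

    terms: list[BasisFunction] = []
    dedup: dict[BasisFunction, BasisFunction] = {}
    seen: dict[bytes, BasisFunction] = {}
    for s, u in cands:
        bf = BasisFunction(s, u, order)
        key = bf.evaluate(X).tobytes()
        if key in seen:
            dedup[bf] = seen[key]
        else:
            seen[key] = bf
            terms.append(bf)
    return BasisDictionary(
        terms=terms,
        n_features=d,
        max_degree=max_degree,
        order=order,
        dedup_map=dedup,
    )


def evaluate_basis(dictionary: BasisDictionary, X: np.ndarray) -> sparse.csc_matrix:
    """Design matrix of the dictionary on new points, as sparse CSC.

    Entry (i, j) is the tensor product of the j-th term's per-coordinate
    splines at row i; order-0 entries are exactly 0 or 1, with the
    right-closed convention ``1{x >= u} = 1`` at the knot itself.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != dictionary.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, dictionary expects {dictionary.n_features}"
        )
    n, p = X.shape[0], len(dictionary)
    if p == 0:
        return sparse.csc_matrix((n, 0))
    # build in column blocks to avoid one big dense allocation when p is large
    block = max(1, min(p, int(5e7 // max(n, 1))))
    parts = []
    for lo in range(0, p, block):
        cols = [t.evaluate(X) for t in dictionary.terms[lo : lo + block]]
        parts.append(sparse.csc_matrix(np.column_stack(cols)))
    return sparse.hstack(parts, format="csc") if len(parts) > 1 else parts[0]
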