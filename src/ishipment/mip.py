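"""Minimal algebraic MILP container.

Variables are declared in named, index-keyed families (e.g. ``Y1[p,c,m,j,t]``)
and constraints are registered under string tags so that the assembled model can
report exactly which constraint families it contains.  The container compiles to
the matrix form consumed by :func:`scipy.optimize.milp` (HiGHS).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint


class LinearModel:
    def __init__(self) -> None:
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[int] = []
        self._families: dict[str, dict] = {}
        # rows as parallel lists: (cols, coefs, lower, upper, tag)
        self._rows_cols: list[list[int]] = []
        self._rows_coefs: list[list[float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._row_tags: list[str] = []
        self._objective_col: int | None = None

    # ------------------------------------------------------------------ vars
    def add_var(self, family: str, index=None, lb: float = 0.0, ub: float = 1.0,
                binary: bool = False) -> int:
        col = len(self._lb)
        if binary:
            self._lb.append(0.0)
            self._ub.append(1.0)
            self._integer.append(1)
        else:
            self._lb.append(lb)
            self._ub.append(ub)
            self._integer.append(0)
        self._families.setdefault(family, {})[index] = col
        return col

    def var(self, family: str, index=None) -> int:
        return self._families[family][index]

    def family(self, family: str) -> Mapping:
        return self._families.get(family, {})

    def fix(self, col: int, value: float) -> None:
        self._lb[col] = value
        self._ub[col] = value

    def set_bounds(self, col: int, lb: float, ub: float) -> None:
        self._lb[col] = lb
        self._ub[col] = ub

    # ----------------------------------------------------------- constraints
    def add_constr(self, tag: str, terms: Iterable[tuple[int, float]],
                   lb: float, ub: float) -> int:
        cols, coefs = [], []
        for c, a in terms:
            if a != 0.0:
                cols.append(c)
                coefs.append(a)
        self._rows_cols.append(cols)
        self._rows_coefs.append(coefs)
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._row_tags.append(tag)
        return len(self._row_tags) - 1

    def set_objective_var(self, col: int) -> None:
        """Minimise a single (already constrained) variable."""
        self._objective_col = col

    # ------------------------------------------------------------ statistics
    @property
    def n_vars(self) -> int:
        return len(self._lb)

    @property
    def n_binary(self) -> int:
        return int(sum(self._integer))

    @property
    def n_continuous(self) -> int:
        return self.n_vars - self.n_binary

    @property
    def n_constraints(self) -> int:
        return len(self._row_tags)

    @property
    def tags(self) -> set[str]:
        return set(self._row_tags)

    def tag_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self._row_tags:
            out[t] = out.get(t, 0) + 1
        return out

    # -------------------------------------------------------------- compile
    def to_scipy(self):
        n = self.n_vars
        if self._objective_col is None:
            raise ValueError("objective not set")
        c = np.zeros(n)
        c[self._objective_col] = 1.0
        nnz = sum(len(r) for r in self._rows_cols)
        data = np.empty(nnz)
        ci = np.empty(nnz, dtype=np.int64)
        ri = np.empty(nnz, dtype=np.int64)
        k = 0
        for i, (cols, coefs) in enumerate(zip(self._rows_cols, self._rows_coefs)):
            m = len(cols)
            ri[k:k + m] = i
            ci[k:k + m] = cols
            data[k:k + m] = coefs
            k += m
        a = sparse.csr_matrix((data, (ri, ci)),
                              shape=(self.n_constraints, n))
        constraint = LinearConstraint(a, np.array(self._row_lb),
                                      np.array(self._row_ub))
        bounds = Bounds(np.array(self._lb), np.array(self._ub))
        integrality = np.array(self._integer)
        return c, constraint, bounds, integrality
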