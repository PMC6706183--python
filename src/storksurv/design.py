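"""Model terms and design matrices for the survival models.

Supports the small term language the stage models need:

* ``"x"`` — a numeric column used linearly;
* ``"C(x)"`` — a categorical column, dummy-coded against its first
  (sorted) level;
* ``"rcs(x)"`` / ``"rcs(x, k)"`` — a restricted cubic spline in ``x``
  with ``k`` knots (default 4, i.e. three degrees of freedom);
* ``"a:rcs(b)"`` / ``"a:b"`` — the product of a linear term with every
  column of the other term (used for the fledging-date x distance
  interaction).

Each term expands to one *group* of design columns; the grouping is what
the elastic-net selection rule ("selecting any spline column selects the
whole spline") operates on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplineBasis", "rcs_basis", "DesignInfo", "build_design"]

#: quantiles used to place knots, by knot count (Harrell's defaults)
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass
class SplineBasis:
    """Restricted (natural) cubic spline basis.

    The basis is linear beyond the boundary knots; ``k`` knots give
    ``k - 1`` columns (the linear column plus ``k - 2`` nonlinear ones),
    i.e. ``k - 1`` degrees of freedom.
    """

    knots: np.ndarray
    fallback_linear: bool = False

    @property
    def df(self) -> int:
        return 1 if self.fallback_linear else len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.fallback_linear:
            return x[:, None]
        t = self.knots
        k = len(t)
        cols = [x]
        # truncated-power natural-spline basis, normalised by (t_k - t_1)^2
        norm = (t[-1] - t[0]) ** 2
        for j in range(k - 2):
            term = (
                _pos3(x - t[j])
                - _pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + _pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
            )
            cols.append(term / norm)
        return np.column_stack(cols)


def _pos3(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def rcs_basis(x, n_knots: int = 4, knots=None) -> SplineBasis:
    """Build a restricted cubic spline basis for the values ``x``.

    Knots sit at the quantiles Harrell recommends (for four knots:
    0.05, 0.35, 0.65, 0.95).  If there are fewer distinct values than
    knots the basis degrades to plain linear with a warning.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if knots is not None:
        knots = np.sort(np.asarray(knots, dtype=float))
        return SplineBasis(knots=knots)
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError(f"unsupported knot count {n_knots}")
    qs = _KNOT_QUANTILES[n_knots]
    knots = np.quantile(x, qs)
    if len(np.unique(x)) < n_knots or len(np.unique(knots)) < n_knots:
        import warnings

        warnings.warn(
            "fewer distinct values than knots; spline degraded to linear",
            stacklevel=2,
        )
        return SplineBasis(knots=np.array([]), fallback_linear=True)
    return SplineBasis(knots=knots)


_RCS_RE = re.compile(r"^rcs\(\s*([^,()\s]+)\s*(?:,\s*(\d+)\s*)?\)$")
_CAT_RE = re.compile(r"^C\(\s*([^,()\s]+)\s*\)$")


@dataclass
class _TermCols:
    term: str
    names: list
    matrix: np.ndarray


@dataclass
class DesignInfo:
    """Frozen expansion of a term list against a fitted data frame.

    Remembers spline knots and categorical levels so the same design can
    be applied to a prediction grid.
    """

    terms: list
    column_names: list = field(default_factory=list)
    groups: list = field(default_factory=list)  # term index per column
    _splines: dict = field(default_factory=dict)
    _levels: dict = field(default_factory=dict)
    _centers: dict = field(default_factory=dict)

    def term_of(self, column: str) -> str:
        return self.terms[self.groups[self.column_names.index(column)]]

    def columns_of(self, term: str) -> list:
        ti = self.terms.index(term)
        return [c for c, g in zip(self.column_names, self.groups) if g == ti]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        blocks = [self._expand(t, data).matrix for t in self.terms]
        if not blocks:
            return np.empty((len(data), 0))
        return np.column_stack(blocks)

    # -- expansion ---------------------------------------------------------

    def _expand(self, term: str, data: pd.DataFrame, fit: bool = False) -> _TermCols:
        if ":" in term:
            left, right = term.split(":", 1)
            a = self._expand(left.strip(), data, fit)
            b = self._expand(right.strip(), data, fit)
            if len(a.names) > 1 and len(b.names) > 1:
                raise ValueError(f"interaction {term!r}: one side must be linear")
            if fit:
                self._centers[term] = (
                    a.matrix.mean(axis=0), b.matrix.mean(axis=0)
                )
            ca, cb = self._centers[term]
            # products of mean-centred sides: keeps the interaction columns
            # interpretable (and nearly orthogonal to the main effects)
            am, bm = a.matrix - ca, b.matrix - cb
            names = [f"{na}:{nb}" for na in a.names for nb in b.names]
            mats = [
                am[:, i] * bm[:, j]
                for i in range(am.shape[1])
                for j in range(bm.shape[1])
            ]
            return _TermCols(term, names, np.column_stack(mats))

        m = _RCS_RE.match(term)
        if m:
            col, nk = m.group(1), int(m.group(2) or 4)
            if fit:
                self._splines[term] = rcs_basis(data[col].to_numpy(float), nk)
            basis = self._splines[term]
            mat = basis.transform(data[col].to_numpy(float))
            names = [col if i == 0 else col + "'" * i
                     for i in range(mat.shape[1])]
            return _TermCols(term, names, mat)

        m = _CAT_RE.match(term)
        is_cat = bool(m)
        col = m.group(1) if m else term
        series = data[col]
        if is_cat or series.dtype == object or isinstance(
            series.dtype, pd.CategoricalDtype
        ):
            if fit:
                self._levels[term] = sorted(pd.unique(series.dropna()).tolist())
            levels = self._levels[term]
            ref, rest = levels[0], levels[1:]
            mat = np.column_stack(
                [(series == lv).to_numpy(float) for lv in rest]
            ) if rest else np.empty((len(series), 0))
            return _TermCols(term, [f"{col}[{lv}]" for lv in rest], mat)

        return _TermCols(term, [col], series.to_numpy(float)[:, None])


def build_design(data: pd.DataFrame, terms) -> tuple[np.ndarray, DesignInfo]:
    """Expand ``terms`` against ``data``; return (matrix, design info)."""
    info = DesignInfo(terms=list(terms))
    blocks = []
    for ti, term in enumerate(info.terms):
        tc = info._expand(term, data, fit=True)
        blocks.append(tc.matrix)
        info.column_names.extend(tc.names)
        info.groups.extend([ti] * len(tc.names))
    X = np.column_stack(blocks) if blocks else np.empty((len(data), 0))
    return X, info
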