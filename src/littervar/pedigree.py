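"""Pedigree container and pedigree-based relationship machinery.

The additive (numerator) relationship matrix ``A`` never needs to be formed
explicitly: BLUP and REML only require its sparse inverse, which Henderson's
rules build directly from sire/dam links and per-animal inbreeding
coefficients.  Inbreeding is computed with the Meuwissen & Luo tracing
algorithm, so the package handles arbitrarily deep, inbred pedigrees without
a dense ``n x n`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import PedigreeError

__all__ = ["Pedigree"]

UNKNOWN = 0  # external code for an unknown parent


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and within-family variances D.

    ``sire``/``dam`` are 1-based with 0 = unknown, parents before offspring.
    Returns per-animal ``F`` and the Mendelian-sampling variance diagonal
    ``D`` of the decomposition A = T D T'.
    """
    n = len(sire)
    F = np.zeros(n + 1)
    F[0] = -1.0  # so that D = 0.5 - 0.25 (F_s + F_d) covers unknown parents
    D = np.zeros(n + 1)
    point = np.zeros(n + 1, dtype=np.int64)
    L = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, d = sire[i - 1], dam[i - 1]
        D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == 0 or d == 0:
            F[i] = 0.0
            continue
        fi = -1.0
        L[i] = 1.0
        j = i
        # walk the ancestor list ordered by descending id (linked via `point`)
        while j != 0:
            k = j
            r = 0.5 * L[k]
            ks, kd = sire[k - 1], dam[k - 1]
            # larger parent id first: the list is scanned downward only
            for parent in ((ks, kd) if ks >= kd else (kd, ks)):
                if parent == 0:
                    continue
                while point[k] > parent:
                    k = point[k]
                L[parent] += r
                if parent != point[k]:
                    point[parent] = point[k]
                    point[k] = parent
            fi += L[j] * L[j] * D[j]
            L[j] = 0.0
            k = j
            j = point[j]
            point[k] = 0
        F[i] = fi
    return F[1:], D[1:]


@dataclass
class Pedigree:
    """Ordered pedigree: ``sire``/``dam`` hold 0-based positions, -1 = unknown.

    Animals must be ordered so parents precede offspring (the constructor
    verifies this); ``from_frame`` reorders automatically.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    meta: pd.DataFrame | None = field(default=None, repr=False)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == n):
            raise PedigreeError("ids, sire and dam must have equal length")
        if len(np.unique(self.ids)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        for arr, what in ((self.sire, "sire"), (self.dam, "dam")):
            if arr.max(initial=-1) >= n:
                raise PedigreeError(f"{what} index out of range")
            bad = np.nonzero(arr >= np.arange(n))[0]
            if bad.size:
                raise PedigreeError(
                    f"animal at position {bad[0]} does not follow its {what}: "
                    "parents must precede offspring (cycles are impossible in "
                    "a valid ordering)"
                )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: pd.DataFrame | None = None) -> "Pedigree":
        """Build from columns (id, sire, dam); 0/NaN = unknown parent.

        Rows are topologically sorted so parents precede offspring; a cycle
        (an animal its own ancestor) raises :class:`PedigreeError`.
        """
        if not {"id", "sire", "dam"}.issubset(frame.columns):
            raise PedigreeError("pedigree frame needs columns id, sire, dam")
        ids = frame["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(ids)}

        def code(col):
            out = np.full(len(ids), -1, dtype=np.int64)
            for i, v in enumerate(frame[col].to_numpy()):
                if pd.isna(v) or v == 0 or v == "0" or v == "":
                    continue
                if v not in pos:
                    raise PedigreeError(f"parent {v!r} has no own pedigree row")
                out[i] = pos[v]
            return out

        sire, dam = code("sire"), code("dam")
        order = _toposort(sire, dam)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        remap = np.where(sire >= 0, inv[np.maximum(sire, 0)], -1)[order]
        remap_d = np.where(dam >= 0, inv[np.maximum(dam, 0)], -1)[order]
        m = meta.iloc[order].reset_index(drop=True) if meta is not None else None
        return cls(ids[order], remap, remap_d, meta=m)

    def to_frame(self) -> pd.DataFrame:
        """Tabular (id, sire, dam) form with 0 = unknown."""
        def back(arr):
            return np.where(arr >= 0, self.ids[np.maximum(arr, 0)], 0)
        return pd.DataFrame({"id": self.ids, "sire": back(self.sire), "dam": back(self.dam)})

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animals) -> np.ndarray:
        """0-based pedigree positions of the given animal ids."""
        pos = self._cache.get("pos")
        if pos is None:
            pos = {a: i for i, a in enumerate(self.ids)}
            self._cache["pos"] = pos
        try:
            return np.fromiter((pos[a] for a in np.asarray(animals)), dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    @property
    def inbreeding(self) -> np.ndarray:
        """Meuwissen-Luo inbreeding coefficients F (in [0, 1))."""
        return self._fd()[0]

    @property
    def mendelian_variance(self) -> np.ndarray:
        """Diagonal D of A = T D T' (within-family variance scale)."""
        return self._fd()[1]

    def _fd(self):
        if "fd" not in self._cache:
            self._cache["fd"] = _meuwissen_luo(self.sire + 1, self.dam + 1)
        return self._cache["fd"]

    def a_inverse(self, inbreeding: bool = True) -> sp.csr_matrix:
        """Sparse inverse of the numerator relationship matrix (Henderson).

        With ``inbreeding=False`` the classical rules with D based on number
        of known parents only are used.
        """
        key = ("ainv", inbreeding)
        if key in self._cache:
            return self._cache[key]
        n = self.n
        if inbreeding:
            d = self.mendelian_variance
        else:
            d = 1.0 - 0.25 * (self.sire >= 0) - 0.25 * (self.dam >= 0)
        alpha = 1.0 / d
        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(n):
            s, dm = self.sire[i], self.dam[i]
            a = alpha[i]
            add(i, i, a)
            for p in (s, dm):
                if p >= 0:
                    add(i, p, -0.5 * a)
                    add(p, i, -0.5 * a)
            for p in (s, dm):
                for q in (s, dm):
                    if p >= 0 and q >= 0:
                        add(p, q, 0.25 * a)
        ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        self._cache[key] = ainv
        return ainv

    @property
    def logdet_a(self) -> float:
        """log |A| = sum log D_i (from A = T D T', |T| = 1)."""
        return float(np.log(self.mendelian_variance).sum())

    @property
    def depth(self) -> np.ndarray:
        """Generation depth: founders 0, else 1 + max(parent depths)."""
        n = self.n
        out = np.zeros(n, dtype=np.int64)
        for i in range(n):
            ds = out[self.sire[i]] if self.sire[i] >= 0 else -1
            dd = out[self.dam[i]] if self.dam[i] >= 0 else -1
            out[i] = max(ds, dd) + 1
        return out

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)


def _toposort(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn topological order (parents first); raises on cycles."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    stack = list(np.nonzero(indeg == 0)[0])
    order = []
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle (animal is its own ancestor)")
    return np.asarray(order, dtype=np.int64)
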