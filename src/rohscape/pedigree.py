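"""Pedigree-based inbreeding: Meuwissen–Luo F, generation-truncated F,
and equivalent complete generations (ECG).

A pedigree is a table of (individual, sire, dam) with 0/None for unknown
parents.  F_i is the kinship between the parents of i; the Meuwissen–Luo
algorithm computes it in O(pedigree size) per individual via the
L-matrix decomposition A = L D L' of the numerator relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = 0


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree.

    frame columns: id, sire, dam (integers internally; 0 = unknown).
    String identifiers are accepted and mapped; `labels` recovers them.
    """

    frame: pd.DataFrame
    labels: dict[int, str]

    @classmethod
    def from_records(cls, records) -> "PedigreeTable":
        """records: iterable of (id, sire, dam); '0', 0, None, '' = unknown."""
        raw = [(str(i), str(s) if s not in (None, 0, "0", "") else None,
                str(d) if d not in (None, 0, "0", "") else None)
               for i, s, d in records]
        ids = [r[0] for r in raw]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        order = _topological_order(raw)
        code = {label: k + 1 for k, label in enumerate(order)}
        rows = sorted(raw, key=lambda r: code[r[0]])
        frame = pd.DataFrame(
            {"id": [code[r[0]] for r in rows],
             "sire": [code[r[1]] if r[1] is not None else UNKNOWN for r in rows],
             "dam": [code[r[2]] if r[2] is not None else UNKNOWN for r in rows]})
        return cls(frame, {v: k for k, v in code.items()})

    @classmethod
    def from_tsv(cls, path: str) -> "PedigreeTable":
        f = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(f.columns[:3])
        return cls.from_records(f[cols].itertuples(index=False, name=None))

    def to_tsv(self, path: str) -> None:
        out = pd.DataFrame({
            "id": [self.labels[i] for i in self.frame["id"]],
            "sire": [self.labels.get(s, "0") for s in self.frame["sire"]],
            "dam": [self.labels.get(d, "0") for d in self.frame["dam"]]})
        out.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def individual_labels(self) -> list[str]:
        return [self.labels[i] for i in self.frame["id"]]

    def parents_of(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam arrays indexed by coded id (index 0 unused)."""
        n = len(self.frame)
        sire = np.zeros(n + 1, dtype=np.int64)
        dam = np.zeros(n + 1, dtype=np.int64)
        sire[self.frame["id"]] = self.frame["sire"]
        dam[self.frame["id"]] = self.frame["dam"]
        return sire, dam


def _topological_order(raw) -> list[str]:
    ids = {r[0] for r in raw}
    parents = {r[0]: [p for p in r[1:] if p is not None] for r in raw}
    state: dict[str, int] = {}
    order: list[str] = []

    for root in parents:
        if root in state:
            continue
        stack = [(root, iter(parents.get(root, ())))]
        state[root] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in ids:
                    continue  # parent genotyped elsewhere; treat as founder
                s = state.get(p)
                if s == 1:
                    chain = [n for n, _ in stack] + [p]
                    raise ValueError(f"pedigree cycle: {' -> '.join(chain)}")
                if s is None:
                    state[p] = 1
                    stack.append((p, iter(parents.get(p, ()))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 2
                order.append(node)
                stack.pop()
    return order


def f_ped(P: PedigreeTable) -> pd.Series:
    """Inbreeding coefficient per individual (Meuwissen–Luo algorithm).

    Equals Wright's path-counting coefficient; founders get 0.
    """
    sire, dam = P.parents_of()
    n = len(P)
    # F[0] = -1 is the unknown-parent sentinel: it makes the within-family
    # variance D_j = 0.5 - 0.25*(F_sire + F_dam) come out right for founders
    F = np.zeros(n + 1)
    F[0] = -1.0
    point = np.zeros(n + 1)
    for i in range(1, n + 1):
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # A_ii = sum_j L_ij^2 D_j over ancestors j (incl. i), youngest first
        point[:i + 1] = 0.0
        point[i] = 1.0
        a_ii = 0.0
        for j in range(i, 0, -1):
            lij = point[j]
            if lij == 0.0:
                continue
            d_j = 0.5 - 0.25 * (F[sire[j]] + F[dam[j]])
            a_ii += lij * lij * d_j
            if sire[j] != UNKNOWN:
                point[sire[j]] += 0.5 * lij
            if dam[j] != UNKNOWN:
                point[dam[j]] += 0.5 * lij
        F[i] = a_ii - 1.0
    return pd.Series(F[1:], index=P.individual_labels, name="F_PED")


def kinship(P: PedigreeTable) -> np.ndarray:
    """Full kinship matrix by the recursive definition,
    f(i,j) = (f(sire_i, j) + f(dam_i, j)) / 2 for i younger than j,
    f(i,i) = (1 + f(sire_i, dam_i)) / 2.

    O(n^2); intended for moderate pedigrees and as an independent route
    to F (F_i = f(sire_i, dam_i)).  Row/column 0 is the unknown parent.
    """
    sire, dam = P.parents_of()
    n = len(P)
    f = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        f[i, i] = 0.5 * (1.0 + f[s, d])
        for j in range(1, i):
            f[i, j] = f[j, i] = 0.5 * (f[s, j] + f[d, j])
    return f


def f_ped_truncated(P: PedigreeTable, g: int) -> pd.Series:
    """F computed on the pedigree restricted to ancestors within g
    parent-steps of each focal individual (parents = generation 1);
    ancestors at depth g become unknown-parent founders."""
    if g < 1:
        raise ValueError("g must be >= 1")
    sire, dam = P.parents_of()
    n = len(P)
    values = np.zeros(n)
    for i in range(1, n + 1):
        depth = {i: 0}
        frontier = [i]
        d = 0
        while frontier and d < g:
            d += 1
            nxt = []
            for x in frontier:
                for p in (sire[x], dam[x]):
                    if p != UNKNOWN and depth.get(p, g + 1) > d:
                        depth[p] = d
                        nxt.append(p)
            frontier = nxt
        records = []
        for x in sorted(depth):
            if depth[x] < g:
                records.append((x, sire[x] or 0, dam[x] or 0))
            else:
                records.append((x, 0, 0))
        sub = PedigreeTable.from_records(records)
        values[i - 1] = f_ped(sub)[str(i)]
    return pd.Series(values, index=P.individual_labels, name=f"F_PED{g}")


def ecg(P: PedigreeTable) -> pd.Series:
    """Equivalent complete generations: sum over known ancestors of
    (1/2)^generation, via ECG_i = sum over known parents of (1+ECG_p)/2."""
    sire, dam = P.parents_of()
    n = len(P)
    e = np.zeros(n + 1)
    for i in range(1, n + 1):  # coded ids are topologically ordered
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                e[i] += 0.5 * (1.0 + e[p])
    return pd.Series(e[1:], index=P.individual_labels, name="ECG")
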