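"""Self-contained nearest-neighbor MFE folding (Zuker-style dynamic program).

The free-energy model is additive over loops: helix stacking energies,
length-dependent initiation penalties for hairpin, bulge and internal loops
(with an asymmetry term), and an affine multiloop cost
``a + b * branches + c * unpaired``. Parameters ship with the package as a
JSON table of Turner-style 37 degC values; dangles, terminal-AU penalties and
sequence-dependent loop bonuses are deliberately omitted so that the dynamic
program and the structure evaluator implement the identical model.

Energies are handled internally as integers in 0.1 kcal/mol to keep the DP
exact; public results are floats in kcal/mol. Co-optimal structures are
resolved by a fixed traceback candidate order (hairpin, then two-loops by
ascending 5' inner index, then multiloop splits by ascending split point),
so folding is fully deterministic.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources
from typing import Optional

from .pairs import MIN_HAIRPIN_LOOP, can_pair

INF = 10**9


def _decacal(x: float) -> int:
    return round(x * 10)


class EnergyParams:
    """Nearest-neighbor parameter set, converted to integer 0.1 kcal/mol."""

    def __init__(self, raw: dict):
        self.stack = {
            p1: {p2: _decacal(v) for p2, v in inner.items()}
            for p1, inner in raw["stack"].items()
        }
        self._hairpin = {int(k): _decacal(v) for k, v in raw["hairpin"].items()}
        self._bulge = {int(k): _decacal(v) for k, v in raw["bulge"].items()}
        self._internal = {int(k): _decacal(v) for k, v in raw["internal"].items()}
        self.internal_asym = _decacal(raw["internal_asym"])
        self.internal_asym_max = _decacal(raw["internal_asym_max"])
        self.ml_closing = _decacal(raw["ml_closing"])
        self.ml_branch = _decacal(raw["ml_branch"])
        self.ml_unpaired = _decacal(raw["ml_unpaired"])
        self.lxc = raw["lxc"]  # kcal/mol coefficient for log extrapolation
        self.max_interior_loop = int(raw.get("max_interior_loop", 30))

    @classmethod
    def default(cls) -> "EnergyParams":
        with resources.files("mirsnp.data").joinpath(
            "loop_energy_params.json"
        ).open() as fh:
            return cls(json.load(fh))

    @classmethod
    def from_file(cls, path) -> "EnergyParams":
        with open(path) as fh:
            return cls(json.load(fh))

    def _extrapolate(self, table: dict, size: int) -> int:
        nmax = max(table)
        if size <= nmax:
            return table[size]
        return table[nmax] + _decacal(self.lxc * math.log(size / nmax))

    @lru_cache(maxsize=None)
    def hairpin_energy(self, size: int) -> int:
        if size < MIN_HAIRPIN_LOOP:
            return INF
        return self._extrapolate(self._hairpin, size)

    @lru_cache(maxsize=None)
    def bulge_energy(self, size: int) -> int:
        return self._extrapolate(self._bulge, size)

    @lru_cache(maxsize=None)
    def internal_energy(self, l1: int, l2: int) -> int:
        init = self._extrapolate(self._internal, l1 + l2)
        asym = min(self.internal_asym * abs(l1 - l2), self.internal_asym_max)
        return init + asym

    def two_loop_energy(self, seq: str, i: int, j: int, p: int, q: int) -> int:
        """Energy of the loop closed by (i,j) with inner helix pair (p,q)."""
        l1, l2 = p - i - 1, j - q - 1
        if l1 == 0 and l2 == 0:
            outer = seq[i] + seq[j]
            inner = seq[p] + seq[q]
            return self.stack[outer][inner]
        if l1 == 0 or l2 == 0:
            return self.bulge_energy(l1 + l2)
        return self.internal_energy(l1, l2)


def evaluate_structure(seq: str, pairs, params: Optional[EnergyParams] = None) -> float:
    """Free energy (kcal/mol) of an explicit structure under the loop model.

    Used both by the deliverable fold path (to report helix-level detail) and
    by the exhaustive test oracle; it performs the standard loop decomposition
    independently of any dynamic-program table.
    """
    params = params or EnergyParams.default()
    pair_list = sorted(pairs)
    partner = {}
    for i, j in pair_list:
        partner[i] = j
        partner[j] = i
    total = 0
    for i, j in pair_list:
        # children: maximal pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += params.hairpin_energy(j - i - 1)
        elif len(children) == 1:
            p, q = children[0]
            total += params.two_loop_energy(seq, i, j, p, q)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in children)
            total += (
                params.ml_closing
                + params.ml_branch * (1 + len(children))
                + params.ml_unpaired * unpaired
            )
    return total / 10.0


def fold(seq: str, params: Optional[EnergyParams] = None) -> tuple[float, frozenset]:
    """MFE fold; returns (energy kcal/mol, base-pair set)."""
    params = params or EnergyParams.default()
    n = len(seq)
    maxloop = params.max_interior_loop
    b = params.ml_branch
    c = params.ml_unpaired

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]  # >=1 branch inside a multiloop
    WM2 = [[INF] * n for _ in range(n)]  # >=2 branches

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            # --- V(i, j): energy given i pairs j ---
            if can_pair(seq[i], seq[j]):
                best = params.hairpin_energy(j - i - 1)
                pmax = min(i + maxloop + 1, j - 1 - MIN_HAIRPIN_LOOP)
                for p in range(i + 1, pmax + 1):
                    l1 = p - i - 1
                    qmin = max(p + MIN_HAIRPIN_LOOP + 1, j - 1 - (maxloop - l1))
                    for q in range(qmin, j):
                        if V[p][q] >= INF:
                            continue
                        e = params.two_loop_energy(seq, i, j, p, q) + V[p][q]
                        if e < best:
                            best = e
                if WM2[i + 1][j - 1] < INF:
                    e = params.ml_closing + b + WM2[i + 1][j - 1]
                    if e < best:
                        best = e
                V[i][j] = best
            # --- WM / WM2 ---
            wm = INF
            if WM[i + 1][j] < INF:
                wm = min(wm, WM[i + 1][j] + c)
            if WM[i][j - 1] < INF:
                wm = min(wm, WM[i][j - 1] + c)
            if V[i][j] < INF:
                wm = min(wm, V[i][j] + b)
            wm2 = INF
            for k in range(i + 1, j + 1):
                left, right = WM[i][k - 1], WM[k][j]
                if left < INF and right < INF:
                    s = left + right
                    if s < wm:
                        wm = s
                    if s < wm2:
                        wm2 = s
            WM[i][j] = wm
            WM2[i][j] = wm2

    # --- exterior loop ---
    W = [0] * (n + 1)  # W[k] = MFE of prefix seq[:k]
    for k in range(1, n + 1):
        j = k - 1
        best = W[k - 1]
        for i in range(0, j - MIN_HAIRPIN_LOOP):
            if V[i][j] < INF:
                e = W[i] + V[i][j]
                if e < best:
                    best = e
        W[k] = best

    pairs: set[tuple[int, int]] = set()
    _trace_exterior(seq, params, V, WM, WM2, W, n, pairs)
    return W[n] / 10.0, frozenset(pairs)


def _trace_exterior(seq, params, V, WM, WM2, W, n, pairs):
    k = n
    while k > 0:
        j = k - 1
        if W[k] == W[k - 1]:
            k -= 1
            continue
        for i in range(0, j - MIN_HAIRPIN_LOOP):
            if V[i][j] < INF and W[k] == W[i] + V[i][j]:
                _trace_v(seq, params, V, WM, WM2, i, j, pairs)
                k = i
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("exterior traceback failed")


def _trace_v(seq, params, V, WM, WM2, i, j, pairs):
    pairs.add((i, j))
    target = V[i][j]
    if target == params.hairpin_energy(j - i - 1):
        return
    maxloop = params.max_interior_loop
    pmax = min(i + maxloop + 1, j - 1 - MIN_HAIRPIN_LOOP)
    for p in range(i + 1, pmax + 1):
        l1 = p - i - 1
        qmin = max(p + MIN_HAIRPIN_LOOP + 1, j - 1 - (maxloop - l1))
        for q in range(qmin, j):
            if V[p][q] < INF and target == params.two_loop_energy(seq, i, j, p, q) + V[p][q]:
                _trace_v(seq, params, V, WM, WM2, p, q, pairs)
                return
    if WM2[i + 1][j - 1] < INF and target == params.ml_closing + params.ml_branch + WM2[i + 1][j - 1]:
        _trace_wm2(seq, params, V, WM, WM2, i + 1, j - 1, pairs)
        return
    raise AssertionError("V traceback failed")  # pragma: no cover


def _trace_wm2(seq, params, V, WM, WM2, i, j, pairs):
    for k in range(i + 1, j + 1):
        if WM[i][k - 1] < INF and WM[k][j] < INF and WM2[i][j] == WM[i][k - 1] + WM[k][j]:
            _trace_wm(seq, params, V, WM, WM2, i, k - 1, pairs)
            _trace_wm(seq, params, V, WM, WM2, k, j, pairs)
            return
    raise AssertionError("WM2 traceback failed")  # pragma: no cover


def _trace_wm(seq, params, V, WM, WM2, i, j, pairs):
    c = params.ml_unpaired
    while True:
        target = WM[i][j]
        if V[i][j] < INF and target == V[i][j] + params.ml_branch:
            _trace_v(seq, params, V, WM, WM2, i, j, pairs)
            return
        if i + 1 <= j and WM[i + 1][j] < INF and target == WM[i + 1][j] + c:
            i += 1
            continue
        if i <= j - 1 and WM[i][j - 1] < INF and target == WM[i][j - 1] + c:
            j -= 1
            continue
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] < INF and WM[k][j] < INF and target == WM[i][k - 1] + WM[k][j]:
                _trace_wm(seq, params, V, WM, WM2, i, k - 1, pairs)
                _trace_wm(seq, params, V, WM, WM2, k, j, pairs)
                return
        raise AssertionError("WM traceback failed")  # pragma: no cover
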