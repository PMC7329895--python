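"""RNA secondary-structure prediction (minimum free energy).

The built-in folder is a Zuker-style dynamic program over a reduced
nearest-neighbor parameter set: Watson-Crick and G:U stacking energies,
length-dependent hairpin / bulge / internal-loop penalties (with a linear
asymmetry term and a 30-nt interior-loop cap), and a linear multibranch
penalty.  No dangling ends, coaxial stacks, or special tetraloops.  All
energies are handled internally as integer tenths of kcal/mol, so the
dynamic program and the exhaustive enumeration oracle
(:func:`enumerate_structures` + :func:`structure_energy`) are exactly
comparable with no floating-point ambiguity.

An external ViennaRNA ``RNAfold`` backend can be selected where the full
Turner model is wanted; MFE thresholds are calibrated per backend.
"""

from __future__ import annotations

import math
import subprocess
from functools import lru_cache

import numpy as np
from numba import njit

INF = 1 << 28
MIN_HAIRPIN = 3
MAXLOOP = 30  # interior/bulge loops with more unpaired bases are disallowed

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair type indices: CG GC GU UG AU UA
_PAIR_TYPE = np.full((4, 4), -1, dtype=np.int8)
for _i, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PAIR_TYPE[_a, _b] = _i

# stacking energies, deci-kcal/mol; row closes (i,j), column is (i+1,j-1)
_STACK = np.array(
    [
        # CG   GC   GU   UG   AU   UA
        [-33, -34, -22, -21, -21, -21],  # CG
        [-34, -33, -25, -14, -22, -24],  # GC
        [-21, -25, -14, -6, -14, -13],  # GU
        [-22, -14, -5, -13, -10, -10],  # UG
        [-21, -22, -14, -10, -9, -11],  # AU
        [-24, -21, -13, -10, -13, -9],  # UA
    ],
    dtype=np.int32,
)

_MULTI_CLOSE = 34  # multibranch closing penalty (deci-kcal)
_MULTI_BRANCH = 4  # per branch, closing pair included
_ASYM = 5  # per unit of interior-loop asymmetry
_ASYM_MAX = 30

_MAXSPAN = 2048


def _loop_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hp = np.full(_MAXSPAN, INF, dtype=np.int32)
    base_hp = {3: 54, 4: 56, 5: 57, 6: 54, 7: 60, 8: 55, 9: 64}
    for l in range(3, _MAXSPAN):
        hp[l] = base_hp.get(l, 64 + round(11 * math.log(l / 9)))
    bulge = np.full(_MAXSPAN, INF, dtype=np.int32)
    base_b = {1: 38, 2: 28, 3: 32, 4: 36, 5: 40, 6: 44}
    for l in range(1, _MAXSPAN):
        bulge[l] = base_b.get(l, 44 + round(11 * math.log(l / 6)))
    internal = np.full(_MAXSPAN, INF, dtype=np.int32)
    base_i = {2: 15, 3: 18, 4: 20, 5: 22, 6: 25}
    for l in range(2, _MAXSPAN):
        internal[l] = base_i.get(l, 25 + round(11 * math.log(l / 6)))
    return hp, bulge, internal


_HAIRPIN, _BULGE, _INTERNAL = _loop_tables()


class FoldingError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise FoldingError(f"non-ACGTU symbol in sequence: {exc}") from None


@njit(cache=True)
def _fill(enc, pair_type, stack, hairpin, bulge, internal):
    n = enc.shape[0]
    V = np.full((n, n), INF, np.int32)
    WM = np.full((n, n), INF, np.int32)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            # --- V: (i, j) paired ---
            pt = pair_type[enc[i], enc[j]]
            if pt >= 0 and d > MIN_HAIRPIN:
                best = hairpin[d - 1]
                # stacks / bulges / interior loops
                for k in range(i + 1, j - 1):
                    n1 = k - i - 1
                    if n1 > MAXLOOP:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        if n1 + n2 > MAXLOOP:
                            break
                        if V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            pt2 = pair_type[enc[k], enc[l]]
                            cost = stack[pt, pt2]
                        elif n1 == 0 or n2 == 0:
                            cost = bulge[n1 + n2]
                        else:
                            asym = _ASYM * abs(n1 - n2)
                            if asym > _ASYM_MAX:
                                asym = _ASYM_MAX
                            cost = internal[n1 + n2] + asym
                        e = cost + V[k, l]
                        if e < best:
                            best = e
                # multibranch closing
                for k in range(i + 2, j):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        e = _MULTI_CLOSE + _MULTI_BRANCH + WM[i + 1, k - 1] + WM[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # --- WM: >=1 branch inside a multiloop (unpaired bases free) ---
            best = WM[i + 1, j] if i + 1 <= j else INF
            if WM[i, j - 1] < best:
                best = WM[i, j - 1]
            if V[i, j] < INF and V[i, j] + _MULTI_BRANCH < best:
                best = V[i, j] + _MULTI_BRANCH
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    e = WM[i, k - 1] + WM[k, j]
                    if e < best:
                        best = e
            WM[i, j] = best
    # external loop
    W = np.zeros(n + 1, np.int32)  # W[j+1] = best for prefix [0, j]
    for j in range(0, n):
        best = W[j]
        for i in range(0, j + 1):
            if V[i, j] < INF:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        W[j + 1] = best
    return V, WM, W


def _traceback(enc, V, WM, W) -> list[tuple[int, int]]:
    n = enc.shape[0]
    pairs: list[tuple[int, int]] = []
    tasks: list[tuple[str, int, int]] = []
    # external loop
    j = n - 1
    while j >= 0:
        if W[j + 1] == W[j]:
            j -= 1
            continue
        for i in range(0, j + 1):
            if V[i, j] < INF and W[i] + V[i, j] == W[j + 1]:
                tasks.append(("V", i, j))
                j = i - 1
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("external traceback failed")
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "V":
            pairs.append((i, j))
            pt = _PAIR_TYPE[enc[i], enc[j]]
            target = V[i, j]
            if target == _HAIRPIN[j - i - 1]:
                continue
            found = False
            for k in range(i + 1, j - 1):
                n1 = k - i - 1
                if n1 > MAXLOOP:
                    break
                for l in range(j - 1, k, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAXLOOP:
                        break
                    if V[k, l] >= INF:
                        continue
                    if n1 == 0 and n2 == 0:
                        cost = _STACK[pt, _PAIR_TYPE[enc[k], enc[l]]]
                    elif n1 == 0 or n2 == 0:
                        cost = _BULGE[n1 + n2]
                    else:
                        cost = _INTERNAL[n1 + n2] + min(_ASYM_MAX, _ASYM * abs(n1 - n2))
                    if cost + V[k, l] == target:
                        tasks.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j):
                if (
                    WM[i + 1, k - 1] < INF
                    and WM[k, j - 1] < INF
                    and _MULTI_CLOSE + _MULTI_BRANCH + WM[i + 1, k - 1] + WM[k, j - 1]
                    == target
                ):
                    tasks.append(("WM", i + 1, k - 1))
                    tasks.append(("WM", k, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise AssertionError("V traceback failed")
        else:  # WM
            target = WM[i, j]
            if i + 1 <= j and WM[i + 1, j] == target:
                tasks.append(("WM", i + 1, j))
            elif WM[i, j - 1] == target:
                tasks.append(("WM", i, j - 1))
            elif V[i, j] < INF and V[i, j] + _MULTI_BRANCH == target:
                tasks.append(("V", i, j))
            else:
                for k in range(i + 1, j + 1):
                    if (
                        WM[i, k - 1] < INF
                        and WM[k, j] < INF
                        and WM[i, k - 1] + WM[k, j] == target
                    ):
                        tasks.append(("WM", i, k - 1))
                        tasks.append(("WM", k, j))
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError("WM traceback failed")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldingError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise FoldingError("unbalanced dot-bracket string")
    return sorted(pairs)


def fold(seq: str, backend: str = "builtin") -> tuple[str, float]:
    """Fold ``seq`` and return ``(dot_bracket, mfe_kcal_per_mol)``.

    ``backend="builtin"`` uses the packaged reduced-parameter dynamic
    program; ``backend="rnafold"`` shells out to ViennaRNA's RNAfold.
    """
    if len(seq) < 10:
        raise FoldingError("sequence shorter than 10 nt")
    if backend == "rnafold":
        return _fold_rnafold(seq)
    if backend != "builtin":
        raise FoldingError(f"unknown folding backend {backend!r}")
    enc = encode(seq)
    V, WM, W = _fill(enc, _PAIR_TYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL)
    mfe = int(W[len(seq)])
    pairs = _traceback(enc, V, WM, W)
    return pairs_to_dotbracket(pairs, len(seq)), mfe / 10.0


def _fold_rnafold(seq: str) -> tuple[str, float]:
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=seq.replace("T", "U") + "\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout.splitlines()
    structure, _, energy = out[1].rpartition(" (")
    return structure.strip(), float(energy.rstrip(")"))


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (independent of the dynamic program)
# ---------------------------------------------------------------------------

def loop_energy(enc: np.ndarray, i: int, j: int, children: list[tuple[int, int]]) -> int:
    """Energy (deci-kcal) of the loop closed by pair (i, j) given its
    directly nested child pairs."""
    if not children:
        return int(_HAIRPIN[j - i - 1])
    if len(children) == 1:
        k, l = children[0]
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            return int(_STACK[_PAIR_TYPE[enc[i], enc[j]], _PAIR_TYPE[enc[k], enc[l]]])
        if n1 + n2 > MAXLOOP:
            return INF
        if n1 == 0 or n2 == 0:
            return int(_BULGE[n1 + n2])
        return int(_INTERNAL[n1 + n2]) + min(_ASYM_MAX, _ASYM * abs(n1 - n2))
    return _MULTI_CLOSE + _MULTI_BRANCH * (len(children) + 1)


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Loop-decomposition energy (kcal/mol) of an explicit structure."""
    enc = encode(seq)
    pairs = sorted(pairs)
    total = 0
    for i, j in pairs:
        children = []
        # direct children: pairs nested in (i,j) not nested in a sibling
        inner = [(k, l) for k, l in pairs if i < k and l < j]
        for k, l in inner:
            if not any(k2 < k and l < l2 for k2, l2 in inner):
                children.append((k, l))
        e = loop_energy(enc, i, j, children)
        if e >= INF:
            return math.inf
        total += e
    return total / 10.0


def enumerate_structures(seq: str):
    """Yield every nested secondary structure of ``seq`` as a sorted tuple
    of pairs (canonical pairs only, terminal loops >= 3 nt).

    Intended as a brute-force oracle for short sequences; the number of
    structures grows exponentially with length.
    """
    enc = encode(seq)
    n = len(enc)

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        # list of (all_pairs, top_level_pairs) for [i, j] inclusive
        if j - i < 0:
            return (((), ()),)
        out = list(region(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if _PAIR_TYPE[enc[i], enc[k]] < 0:
                continue
            for lp, _lt in region(i + 1, k - 1):
                for rp, rt in region(k + 1, j):
                    out.append((((i, k),) + lp + rp, ((i, k),) + rt))
        return tuple(out)

    for pairs, _top in region(0, n - 1):
        yield tuple(sorted(pairs))
    region.cache_clear()


def enumerate_mfe(seq: str) -> float:
    """Exhaustive minimum over all structures of :func:`loop_energy`
    decomposition sums (kcal/mol).  Energies accumulate as each loop
    closes during enumeration; independent cross-check for :func:`fold`.
    """
    enc = encode(seq)
    n = len(enc)

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        # all structures of [i, j] as (top_level_children, internal_energy)
        if j - i < 0:
            return (((), 0),)
        out = list(region(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if _PAIR_TYPE[enc[i], enc[k]] < 0:
                continue
            right = region(k + 1, j)
            for lt, le in region(i + 1, k - 1):
                close = loop_energy(enc, i, k, list(lt))
                if close >= INF:
                    continue
                e_left = le + close
                for rt, re_ in right:
                    out.append((((i, k),) + rt, e_left + re_))
        return tuple(out)

    best = min(e for _t, e in region(0, n - 1))
    region.cache_clear()
    return min(best, 0) / 10.0


__all__ = [
    "fold",
    "FoldingError",
    "encode",
    "structure_energy",
    "enumerate_structures",
    "enumerate_mfe",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "loop_energy",
]
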