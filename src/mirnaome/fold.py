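"""Minimum-free-energy RNA secondary-structure prediction.

The bundled engine is a simplified Zuker-style dynamic program over a
nearest-neighbor model: Watson-Crick and G:U wobble stacking energies,
size-dependent hairpin / bulge / internal-loop penalties with logarithmic
extrapolation, and an affine multiloop penalty.  It deliberately omits
dangling ends, coaxial stacking, terminal-AU penalties and tetraloop
bonuses, so its absolute energies are systematically slightly lower in
magnitude than a full Turner-model folder; the hairpin acceptance
thresholds used downstream are configurable for that reason.

An external thermodynamic folder (ViennaRNA, if importable) can be
selected with ``backend="vienna"``; the structure contract (dot-bracket,
pseudoknot-free, MFE <= 0) is identical.

Energies are handled internally in centi-kcal/mol integers and reported
in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np
from numba import njit

INF = 1 << 40
MAXLOOP = 30
MIN_HAIRPIN = 3

# base encoding: A=0 C=1 G=2 U=3
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair types: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA, -1 unpairable
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _pt, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PAIR_TYPE[_a, _b] = _pt

# stacking free energies (kcal/mol), outer pair x inner pair, 37 C.
# Values follow the familiar nearest-neighbor magnitudes for WC and
# wobble stacks; order of both axes: CG GC GU UG AU UA.
_STACK_KCAL = np.array(
    [
        [-3.3, -2.4, -1.4, -2.1, -2.1, -2.1],  # CG
        [-3.4, -3.3, -1.5, -2.5, -2.4, -2.2],  # GC
        [-2.5, -2.1, -0.5, +1.3, -1.3, -1.4],  # GU
        [-1.5, -1.4, +0.3, -0.5, -1.0, -0.6],  # UG
        [-2.2, -2.1, -0.6, -1.4, -0.9, -1.1],  # AU
        [-2.4, -2.1, -1.0, -1.3, -1.3, -0.9],  # UA
    ]
)
_STACK = np.rint(_STACK_KCAL * 100).astype(np.int64)

_RT_LOG = 1.08  # 1.75 * RT at 37 C, kcal/mol, for loop-size extrapolation


def _loop_table(values: dict[int, float], max_size: int) -> np.ndarray:
    """Size-indexed loop penalty table with log extrapolation (centi-kcal)."""
    last = max(values)
    out = np.full(max_size + 1, INF, dtype=np.int64)
    for size, kcal in values.items():
        out[size] = round(kcal * 100)
    for size in range(last + 1, max_size + 1):
        out[size] = round((values[last] + _RT_LOG * math.log(size / last)) * 100)
    return out


_HAIRPIN = _loop_table(
    {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}, 2048
)
_BULGE = _loop_table({1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}, MAXLOOP)
_INTERNAL = _loop_table({2: 1.5, 3: 2.2, 4: 2.0, 5: 2.1, 6: 2.2}, MAXLOOP)
_ASYM_PENALTY = 60  # centi-kcal per unpaired-length asymmetry unit
_ASYM_MAX = 300
_ML_CLOSE = 340  # multiloop closing penalty
_ML_BRANCH = 40  # per-branch penalty
_DUPLEX_INIT = 4.1  # kcal/mol intermolecular initiation


@njit(cache=True)
def _interior_energy(u1, u2, pt_out, pt_in, stack, bulge, internal):
    if u1 == 0 and u2 == 0:
        return stack[pt_out, pt_in]
    if u1 == 0 or u2 == 0:
        return bulge[u1 + u2]
    asym = abs(u1 - u2) * _ASYM_PENALTY
    if asym > _ASYM_MAX:
        asym = _ASYM_MAX
    return internal[u1 + u2] + asym


@njit(cache=True)
def _fill(code, pt_tab, stack, hairpin, bulge, internal):
    n = code.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    WM2 = np.full((n, n), INF, dtype=np.int64)
    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(n - d):
            j = i + d
            pt = pt_tab[code[i], code[j]]
            if pt >= 0:
                best = hairpin[j - i - 1]
                kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = k + MIN_HAIRPIN + 1
                    llo = j - 1 - (MAXLOOP - u1)
                    if llo > lmin:
                        lmin = llo
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        pt_in = pt_tab[code[k], code[l]]
                        e = (
                            _interior_energy(u1, j - l - 1, pt, pt_in, stack, bulge, internal)
                            + V[k, l]
                        )
                        if e < best:
                            best = e
                    # (unpairable k,l skipped via V == INF)
                if j - i >= 2 and WM2[i + 1, j - 1] < INF:
                    e = _ML_CLOSE + _ML_BRANCH + WM2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # multiloop segment matrices (unpaired bases cost 0)
            m = WM[i + 1, j]
            if WM[i, j - 1] < m:
                m = WM[i, j - 1]
            if V[i, j] < INF and V[i, j] + _ML_BRANCH < m:
                m = V[i, j] + _ML_BRANCH
            s = INF
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    cand = WM[i, k] + WM[k + 1, j]
                    if cand < s:
                        s = cand
            WM2[i, j] = s
            if s < m:
                m = s
            WM[i, j] = m
    # external loop
    W = np.zeros(n, dtype=np.int64)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF:
                prev = W[i - 1] if i > 0 else 0
                if prev + V[i, j] < best:
                    best = prev + V[i, j]
        W[j] = best
    return V, WM, WM2, W


@njit(cache=True)
def _traceback(code, pt_tab, stack, hairpin, bulge, internal, V, WM, WM2, W):
    n = code.shape[0]
    pairs = np.full(n, -1, dtype=np.int64)
    # stack of (i, j, matrix) with matrix 0=V 1=WM
    st_i = np.empty(4 * n, dtype=np.int64)
    st_j = np.empty(4 * n, dtype=np.int64)
    st_m = np.empty(4 * n, dtype=np.int64)
    top = 0
    j = n - 1
    while j >= 0:
        if j > 0 and W[j] == W[j - 1]:
            j -= 1
            continue
        if W[j] == 0 and j == 0:
            break
        found = False
        for i in range(0, j - MIN_HAIRPIN):
            prev = W[i - 1] if i > 0 else 0
            if V[i, j] < INF and prev + V[i, j] == W[j]:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 0
                top += 1
                j = i - 1
                found = True
                break
        if not found:
            j -= 1
    while top > 0:
        top -= 1
        i = st_i[top]
        j = st_j[top]
        m = st_m[top]
        if m == 0:
            pairs[i] = j
            pairs[j] = i
            pt = pt_tab[code[i], code[j]]
            e = V[i, j]
            if e == hairpin[j - i - 1]:
                continue
            done = False
            kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1)
            for k in range(i + 1, kmax + 1):
                if done:
                    break
                u1 = k - i - 1
                lmin = k + MIN_HAIRPIN + 1
                llo = j - 1 - (MAXLOOP - u1)
                if llo > lmin:
                    lmin = llo
                for l in range(lmin, j):
                    if V[k, l] >= INF:
                        continue
                    pt_in = pt_tab[code[k], code[l]]
                    if (
                        _interior_energy(u1, j - l - 1, pt, pt_in, stack, bulge, internal)
                        + V[k, l]
                        == e
                    ):
                        st_i[top] = k
                        st_j[top] = l
                        st_m[top] = 0
                        top += 1
                        done = True
                        break
            if done:
                continue
            # multiloop: split WM2[i+1, j-1]
            ii = i + 1
            jj = j - 1
            for k in range(ii, jj):
                if (
                    WM[ii, k] < INF
                    and WM[k + 1, jj] < INF
                    and _ML_CLOSE + _ML_BRANCH + WM[ii, k] + WM[k + 1, jj] == e
                ):
                    st_i[top] = ii
                    st_j[top] = k
                    st_m[top] = 1
                    top += 1
                    st_i[top] = k + 1
                    st_j[top] = jj
                    st_m[top] = 1
                    top += 1
                    break
        else:
            e = WM[i, j]
            if e >= INF:
                continue
            if WM[i + 1, j] == e:
                st_i[top] = i + 1
                st_j[top] = j
                st_m[top] = 1
                top += 1
            elif WM[i, j - 1] == e:
                st_i[top] = i
                st_j[top] = j - 1
                st_m[top] = 1
                top += 1
            elif V[i, j] < INF and V[i, j] + _ML_BRANCH == e:
                st_i[top] = i
                st_j[top] = j
                st_m[top] = 0
                top += 1
            else:
                for k in range(i, j):
                    if WM[i, k] < INF and WM[k + 1, j] < INF and WM[i, k] + WM[k + 1, j] == e:
                        st_i[top] = i
                        st_j[top] = k
                        st_m[top] = 1
                        top += 1
                        st_i[top] = k + 1
                        st_j[top] = j
                        st_m[top] = 1
                        top += 1
                        break
    return pairs


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of one RNA sequence."""

    rna_sequence: str
    structure: str
    mfe: float  # kcal/mol

    @property
    def pair_table(self) -> np.ndarray:
        return pairs_from_dotbracket(self.structure)


def pairs_from_dotbracket(structure: str) -> np.ndarray:
    """0-based partner index per position, -1 if unpaired."""
    pairs = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def dotbracket_from_pairs(pairs: np.ndarray) -> str:
    out = []
    for i, j in enumerate(pairs):
        if j < 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def _encode(rna: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in rna], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-RNA character in sequence: {exc.args[0]!r}") from None


def fold_mfe(rna: str, backend: str = "bundled") -> FoldResult:
    """Fold one RNA (or DNA-alphabet) sequence to its MFE structure.

    Parameters
    ----------
    rna:
        Sequence over A/C/G/U (T accepted and treated as U).
    backend:
        ``"bundled"`` for the built-in nearest-neighbor engine,
        ``"vienna"`` for ViennaRNA if its Python bindings are installed.
    """
    rna = rna.upper().replace("T", "U")
    if backend == "vienna":
        return _fold_vienna(rna)
    if backend != "bundled":
        raise ValueError(f"unknown folding backend {backend!r}")
    code = _encode(rna)
    n = code.shape[0]
    if n < MIN_HAIRPIN + 2:
        return FoldResult(rna, "." * n, 0.0)
    V, WM, WM2, W = _fill(code, _PAIR_TYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL)
    mfe_ckal = int(W[n - 1])
    if mfe_ckal >= 0:
        return FoldResult(rna, "." * n, 0.0)
    pairs = _traceback(code, _PAIR_TYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL, V, WM, WM2, W)
    return FoldResult(rna, dotbracket_from_pairs(pairs), mfe_ckal / 100.0)


def _fold_vienna(rna: str) -> FoldResult:
    import RNA  # ViennaRNA python bindings

    structure, mfe = RNA.fold(rna)
    return FoldResult(rna, structure, float(mfe))


@lru_cache(maxsize=100_000)
def _pair_type(a: str, b: str) -> int:
    pa, pb = _BASE_CODE.get(a, -1), _BASE_CODE.get(b, -1)
    if pa < 0 or pb < 0:
        return -1
    return int(_PAIR_TYPE[pa, pb])


def is_complementary(a: str, b: str, allow_gu: bool = True) -> bool:
    """Can bases a and b pair (Watson-Crick, optionally G:U)?"""
    pt = _pair_type(a.upper().replace("T", "U"), b.upper().replace("T", "U"))
    if pt < 0:
        return False
    return allow_gu or pt < 2


def duplex_energy(columns: list[tuple[str, str]]) -> float:
    """Nearest-neighbor hybridization energy of an intermolecular duplex.

    ``columns`` is the miRNA:target alignment 5'->3' on the first strand;
    each column is ``(base_a, base_b)`` with ``"-"`` marking a gap.  Paired
    columns contribute stacking energies with their paired neighbor;
    mismatch or gap columns between helices contribute an internal-loop /
    bulge penalty.  Includes the intermolecular initiation term; no
    intramolecular structure is considered.
    """
    energy = _DUPLEX_INIT * 100
    prev_pt = -1
    u1 = u2 = 0
    for a, b in columns:
        a = a.upper().replace("T", "U")
        b = b.upper().replace("T", "U")
        pt = _pair_type(a, b) if (a != "-" and b != "-") else -1
        if pt >= 0:
            if prev_pt >= 0:
                if u1 == 0 and u2 == 0:
                    energy += _STACK[prev_pt, pt]
                elif u1 == 0 or u2 == 0:
                    energy += _BULGE[min(u1 + u2, MAXLOOP)]
                else:
                    asym = min(abs(u1 - u2) * _ASYM_PENALTY, _ASYM_MAX)
                    energy += _INTERNAL[min(u1 + u2, MAXLOOP)] + asym
            prev_pt = pt
            u1 = u2 = 0
        else:
            if a != "-":
                u1 += 1
            if b != "-":
                u2 += 1
    return energy / 100.0
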