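"""Array-backed search engine for bounded rearrangement distances.

Orders live here as length-13 ``int8`` rows: entry ``+-(gene_index+1)`` with
the sign giving the coding strand, always in canonical frame (cox1 first,
positive).  Rows pack into base-26 ``uint64`` codes for hashing and set
arithmetic.

Single-event neighbourhoods are generated by precomputed index tables:

* T / I / iT — every linear segment of the canonical linearization with
  every insertion point.  Linear segments are exhaustive for the circular
  molecule: a circular transposition is a swap of two adjacent arcs, at
  most one of which contains the anchor, so the other (linear) arc can be
  taken as the moved segment; an inversion of an anchor-spanning arc equals
  the inversion of its complementary (linear) arc on the canonicalized
  molecule.
* TDRL — tandem-duplicate an arc, keep one copy of each gene.  Any
  arc-TDRL equals a whole-circle TDRL in which the genes outside the arc
  are assigned to the copy that keeps them in place, so enumerating the 13
  rotations x 2^13 loss masks of the whole circle is exhaustive (and only
  ~106k rows, generated in one fancy-indexing pass).

Two further primitives make bidirectional search to depth 3 complete:

* ``tdrl_feasible`` — exact one-TDRL reachability: b is one TDRL from a
  iff strands agree gene-wise and, for some rotation r of a, the circular
  trace of a-positions along b has at most 2 circular descents (the
  kept-first/kept-second blocks are two increasing runs, and one descent
  may be absorbed by cutting the circle there).
* ``pred_tdrl`` — TDRL predecessors by riffling: y maps to b by one TDRL
  iff y interleaves the two blocks of some rotation/cut of b, again an
  indexed 13 x 2^13 enumeration.

T, I and iT are self-inverse as event classes, so their successor sets
double as predecessor sets; TDRL is the asymmetric one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genes import GENES, GENE_INDEX

N = 13
_ARANGE = np.arange(N)
_COX1_VAL = GENE_INDEX["cox1"] + 1
_POW26 = (26 ** np.arange(N, dtype=np.uint64)).astype(np.uint64)

# ---------------------------------------------------------------------------
# row <-> order conversions


def row_from_pairs(pairs) -> np.ndarray:
    row = np.empty(N, dtype=np.int8)
    for k, (label, strand) in enumerate(pairs):
        row[k] = strand * (GENE_INDEX[label] + 1)
    return canon_rows(row[None, :])[0]


def pairs_from_row(row: np.ndarray) -> tuple[tuple[str, int], ...]:
    return tuple(
        (GENES[abs(int(v)) - 1], 1 if v > 0 else -1) for v in row
    )


def canon_rows(R: np.ndarray) -> np.ndarray:
    """Canonicalize rows in place-free fashion: cox1 first on + strand."""
    R = np.ascontiguousarray(R, dtype=np.int8).copy()
    ci = np.argmax(np.abs(R) == _COX1_VAL, axis=1)
    sign = np.take_along_axis(R, ci[:, None], axis=1)[:, 0]
    neg = sign < 0
    if neg.any():
        R[neg] = -R[neg, ::-1]
        ci = np.where(neg, N - 1 - ci, ci)
    cols = (ci[:, None] + _ARANGE[None, :]) % N
    return np.take_along_axis(R, cols, axis=1)


def codes_of(R: np.ndarray) -> np.ndarray:
    """Pack canonical rows into base-26 uint64 codes."""
    digits = ((np.abs(R.astype(np.int64)) - 1) * 2 + (R < 0)).astype(np.uint64)
    return (digits * _POW26[None, :]).sum(axis=1)


def code_of(row: np.ndarray) -> int:
    return int(codes_of(row[None, :])[0])


def strand_key(row: np.ndarray) -> bytes:
    """Gene-indexed strand vector, hashable; TDRL edges require equality."""
    sv = np.zeros(N, dtype=np.int8)
    labs = np.abs(row.astype(np.int64)) - 1
    sv[labs] = np.sign(row)
    return sv.tobytes()


# ---------------------------------------------------------------------------
# event tables


@dataclass(frozen=True)
class PositionalEvent:
    """An event in the coordinate frame of a specific source linearization.

    T / I: ``i..j`` is the moved/inverted linear segment (inclusive) and
    ``g`` the insertion gap among the remaining genes (I: g is unused).
    iT: ``i`` is the circular arc start, ``j`` the arc *length*, ``g``
    means "insert after the g-th gene of the remainder (read from the arc
    end)".
    TDRL (as emitted by :func:`reduce_tdrl_witness`): ``i`` is the start
    position of the duplicated arc, ``j`` its length, and ``g`` the loss
    mask (bit k set => arc gene k survives in the *second* copy).
    """

    kind: str
    i: int
    j: int
    g: int


class _Tables:
    """Precomputed index/sign tables.

    Tables are *canonical-composed*: applying a table row to a canonical
    source row yields an already-canonical result (the destination and
    orientation of the gene at source position 0 are known per event, so
    the rotation / reverse-complement is folded into the indices at build
    time).  This keeps successor generation to one fancy-index plus one
    multiply.
    """

    def __init__(self) -> None:
        self._build_tiit()
        self._build_tdrl()
        self._build_riffle()
        self.TIIT_IDX, self.TIIT_SGN = _compose_canonical(
            self.TIIT_IDX, self.TIIT_SGN
        )
        ones = np.ones_like(self.TDRL_IDX)
        self.TDRL_IDX, _ = _compose_canonical(self.TDRL_IDX, ones)
        self.RIFFLE_IDX, _ = _compose_canonical(
            self.RIFFLE_IDX, np.ones_like(self.RIFFLE_IDX)
        )

    # T / I / iT -----------------------------------------------------------
    def _build_tiit(self) -> None:
        idx_rows: list[np.ndarray] = []
        sgn_rows: list[np.ndarray] = []
        desc: list[PositionalEvent] = []
        base = _ARANGE
        # T and I over linear segments are circularly exhaustive: a circular
        # transposition swaps two adjacent arcs, at most one containing the
        # anchor (move the other); an anchor-spanning inversion equals the
        # inversion of its complementary linear arc.
        for L in range(1, N):  # segment length 1..12
            for i in range(0, N - L + 1):
                j = i + L - 1
                seg = base[i : j + 1]
                rem = np.concatenate([base[:i], base[j + 1 :]])
                # inversion in place
                idx_rows.append(np.concatenate([base[:i], seg[::-1], base[j + 1 :]]))
                sgn_rows.append(_seg_sign(i, j))
                desc.append(PositionalEvent("I", i, j, -1))
                for g in range(0, N - L + 1):
                    if g == i:
                        continue  # same slot: identity
                    moved = np.concatenate([rem[:g], seg, rem[g:]])
                    idx_rows.append(moved)
                    sgn_rows.append(np.ones(N, dtype=np.int8))
                    desc.append(PositionalEvent("T", i, j, g))
        # iT has no such reduction (the flipped copy of an anchor-spanning
        # arc cannot be produced by moving any linear arc), so it is
        # enumerated over all circular arcs: i = arc start, j = arc length,
        # g = insertion after the g-th remaining gene; g = 13-L-1 would be
        # in place (that is I) and is skipped.
        for s in range(N):
            for L in range(1, N):
                arc = (s + np.arange(L)) % N
                rem = (s + L + np.arange(N - L)) % N
                for g in range(0, N - L - 1):
                    row = np.concatenate([rem[: g + 1], arc[::-1], rem[g + 1 :]])
                    sg = np.ones(N, dtype=np.int8)
                    sg[g + 1 : g + 1 + L] = -1
                    idx_rows.append(row)
                    sgn_rows.append(sg)
                    desc.append(PositionalEvent("iT", s, L, g))
        self.TIIT_IDX = np.array(idx_rows, dtype=np.int8)
        self.TIIT_SGN = np.array(sgn_rows, dtype=np.int8)
        self.TIIT_DESC = tuple(desc)

    # TDRL successors ------------------------------------------------------
    def _build_tdrl(self) -> None:
        masks = np.arange(8192, dtype=np.int64)
        B = ((masks[:, None] >> _ARANGE[None, :]) & 1).astype(bool)  # (8192, 13)
        # stable partition: mask-0 positions first, then mask-1, in order
        P = np.argsort(B * (N + 1) + _ARANGE[None, :], axis=1, kind="stable")
        idx = np.empty((N * 8192, N), dtype=np.int8)
        for s in range(N):
            rot = (_ARANGE + s) % N
            idx[s * 8192 : (s + 1) * 8192] = rot[P]
        self.TDRL_IDX = idx
        self._B = B

    # TDRL predecessors (riffle merges of the two blocks of b) -------------
    def _build_riffle(self) -> None:
        B = self._B
        nb = ~B
        c0 = np.cumsum(nb, axis=1) - nb  # zeros strictly before j
        c1 = np.cumsum(B, axis=1) - B
        t0 = nb.sum(axis=1)
        rank = np.where(nb, c0, t0[:, None] + c1)
        idx = np.empty((N * 8192, N), dtype=np.int8)
        for c in range(N):
            idx[c * 8192 : (c + 1) * 8192] = (c + rank) % N
        self.RIFFLE_IDX = idx


@lru_cache(maxsize=1)
def tables() -> _Tables:
    return _Tables()


def _seg_sign(i: int, j: int) -> np.ndarray:
    s = np.ones(N, dtype=np.int8)
    s[i : j + 1] = -1
    return s


def _compose_canonical(IDX: np.ndarray, SGN: np.ndarray):
    """Fold canonicalization of the result into index/sign tables.

    Source rows are canonical (position 0 holds cox1, +).  Row-wise, find
    where source position 0 lands; roll there, reverse-complementing first
    when the event flipped its sign.
    """
    K = _ARANGE[None, :]
    k0 = np.argmax(IDX == 0, axis=1)
    flip = np.take_along_axis(SGN, k0[:, None], axis=1)[:, 0] < 0
    offs = np.where(flip[:, None], (k0[:, None] - K) % N, (k0[:, None] + K) % N)
    cidx = np.take_along_axis(IDX, offs, axis=1)
    csgn = np.take_along_axis(SGN, offs, axis=1) * np.where(flip[:, None], -1, 1)
    return cidx.astype(np.int8), csgn.astype(np.int8)


# ---------------------------------------------------------------------------
# neighbourhood generation


def succ_tiit_rows(row: np.ndarray) -> np.ndarray:
    t = tables()
    return row[t.TIIT_IDX] * t.TIIT_SGN


def succ_tdrl_rows(row: np.ndarray) -> np.ndarray:
    t = tables()
    return row[t.TDRL_IDX]


def pred_tdrl_rows(row: np.ndarray) -> np.ndarray:
    t = tables()
    return row[t.RIFFLE_IDX]


def _unique(rows: np.ndarray, drop: int | None = None):
    """Unique rows by code, sorted by code; optionally drop one code."""
    codes = codes_of(rows)
    uc, first = np.unique(codes, return_index=True)
    urows = rows[first]
    if drop is not None:
        keep = uc != np.uint64(drop)
        uc, urows = uc[keep], urows[keep]
    return uc, urows


def successors(row: np.ndarray, include_tdrl: bool = True):
    """All distinct one-event results (self excluded): (codes, rows)."""
    parts = [succ_tiit_rows(row)]
    if include_tdrl:
        parts.append(succ_tdrl_rows(row))
    rows = np.concatenate(parts, axis=0)
    return _unique(rows, drop=code_of(row))


def predecessors(row: np.ndarray, include_tdrl: bool = True):
    """All distinct rows one event *away from* ``row`` (self excluded)."""
    parts = [succ_tiit_rows(row)]  # T/I/iT are self-inverse classes
    if include_tdrl:
        parts.append(pred_tdrl_rows(row))
    rows = np.concatenate(parts, axis=0)
    return _unique(rows, drop=code_of(row))


# ---------------------------------------------------------------------------
# one-TDRL reachability predicate


def _label_positions(x_rows: np.ndarray) -> np.ndarray:
    """inv[k, lab] = position of gene ``lab`` in x_rows[k]."""
    labs = np.abs(x_rows.astype(np.int16)) - 1  # (n, 13)
    inv = np.empty_like(labs)
    np.put_along_axis(
        inv, labs, _ARANGE.astype(np.int16)[None, :].repeat(len(labs), 0), axis=1
    )
    return inv


def _tdrl_feasible_from_inv(inv: np.ndarray, z_row: np.ndarray) -> np.ndarray:
    zl = np.abs(z_row.astype(np.int16)) - 1
    V = inv[:, zl]  # (n, 13): position in x of each z gene, in z order
    W = (V[:, None, :] - _ARANGE.astype(np.int16)[None, :, None]) % N
    nxt = np.roll(W, -1, axis=2)
    desc = (W > nxt).sum(axis=2)  # circular descents per rotation
    return desc.min(axis=1) <= 2


def tdrl_feasible_many(x_rows: np.ndarray, z_row: np.ndarray) -> np.ndarray:
    """Boolean mask: which x_rows reach z_row by exactly one TDRL.

    Callers must pre-filter on strand equality (``strand_key``); this tests
    only the order condition.  Identity rows test True and should be
    excluded upstream.
    """
    if len(x_rows) == 0:
        return np.zeros(0, dtype=bool)
    return _tdrl_feasible_from_inv(_label_positions(x_rows), z_row)


def tdrl_feasible(x_row: np.ndarray, z_row: np.ndarray) -> bool:
    if strand_key(x_row) != strand_key(z_row):
        return False
    if code_of(x_row) == code_of(z_row):
        return False
    return bool(tdrl_feasible_many(x_row[None, :], z_row)[0])


# ---------------------------------------------------------------------------
# witness enumeration between adjacent orders


def tiit_events_between(x_row: np.ndarray, z_code: int) -> list[PositionalEvent]:
    t = tables()
    codes = codes_of(succ_tiit_rows(x_row))
    hits = np.nonzero(codes == np.uint64(z_code))[0]
    return [t.TIIT_DESC[h] for h in hits]


def reduce_tdrl_witness(table_index: int) -> PositionalEvent | None:
    """Turn a raw (rotation, whole-circle mask) table index into a minimal-
    arc TDRL witness, or None for the identity patterns."""
    s, mask = divmod(int(table_index), 8192)
    bits = [(mask >> k) & 1 for k in range(N)]
    ones = [k for k in range(N) if bits[k]]
    zeros = [k for k in range(N) if not bits[k]]
    if not ones or not zeros:
        return None  # identity
    start = min(ones)               # leading kept-first genes do not move
    end = max(zeros)                # trailing kept-second genes do not move
    if end < start:
        return None  # pure rotation of the circle: identity
    sub_mask = 0
    for k in range(start, end + 1):
        sub_mask |= bits[k] << (k - start)
    return PositionalEvent("TDRL", (s + start) % N, end - start + 1, sub_mask)


def tdrl_events_between(x_row: np.ndarray, z_code: int) -> list[PositionalEvent]:
    """All one-TDRL witnesses x -> z, reduced to minimal duplicated arcs."""
    codes = codes_of(succ_tdrl_rows(x_row))
    hits = np.nonzero(codes == np.uint64(z_code))[0]
    reduced: dict[tuple[int, int, int], PositionalEvent] = {}
    for h in hits:
        pe = reduce_tdrl_witness(int(h))
        if pe is not None:
            reduced.setdefault((pe.i, pe.j, pe.g), pe)
    return sorted(
        reduced.values(), key=lambda e: (e.j, e.i, e.g)
    )  # shortest duplicated arc first


def events_between(x_row: np.ndarray, z_row: np.ndarray) -> list[PositionalEvent]:
    z_code = code_of(z_row)
    out = tiit_events_between(x_row, z_code)
    if strand_key(x_row) == strand_key(z_row):
        out += tdrl_events_between(x_row, z_code)
    return out


# ---------------------------------------------------------------------------
# bounded bidirectional search


@dataclass
class SearchResult:
    distance: int | None          # minimal steps, or None if > max_steps
    midpoints: np.ndarray | None  # rows, for distance == 2
    pairs: list | None            # (x_row, z_row) pairs, for distance == 3
    exceeded: bool


def _bucket_by_strand(rows: np.ndarray) -> dict[bytes, np.ndarray]:
    buckets: dict[bytes, list[int]] = {}
    for k in range(len(rows)):
        buckets.setdefault(strand_key(rows[k]), []).append(k)
    return {k: rows[np.array(v)] for k, v in buckets.items()}


_CHUNK = 256


def _tiit_mid_pairs(F1_codes, F1_rows, B1_rows, need_all: bool,
                    max_pairs: int = 128):
    """Edges x -> z with x in F1, z in B1 and the edge a T/I/iT event.

    Uses class self-inverseness: x in succ_tiit(z).  Returns (x_row, z_row)
    pairs.
    """
    t = tables()
    order = np.argsort(F1_codes)
    sorted_codes = F1_codes[order]
    pairs = []
    for lo in range(0, len(B1_rows), _CHUNK):
        chunk = B1_rows[lo : lo + _CHUNK]
        R = chunk[:, t.TIIT_IDX] * t.TIIT_SGN[None, :, :]  # (c, E, 13)
        c, E, _ = R.shape
        codes = codes_of(R.reshape(c * E, N)).reshape(c, E)
        pos = np.searchsorted(sorted_codes, codes)
        pos[pos == len(sorted_codes)] = 0
        hit = sorted_codes[pos] == codes
        if not hit.any():
            continue
        zi, _ei = np.nonzero(hit)
        seen = set()
        for k in range(len(zi)):
            code = int(codes[zi[k], _ei[k]])
            key = (code, lo + int(zi[k]))
            if key in seen:
                continue
            seen.add(key)
            x_row = F1_rows[order[np.searchsorted(sorted_codes, np.uint64(code))]]
            pairs.append((x_row, chunk[zi[k]]))
            if not need_all or len(pairs) >= max_pairs:
                return pairs
    return pairs


def _tdrl_mid_pairs(F1_rows, B1_rows, need_all: bool, max_pairs: int = 128):
    """Edges x -> z with the edge a TDRL; strand-bucketed descent test."""
    fb = _bucket_by_strand(F1_rows)
    bb = _bucket_by_strand(B1_rows)
    pairs = []
    for key, fx in fb.items():
        bz = bb.get(key)
        if bz is None:
            continue
        f_codes = codes_of(fx)
        inv = _label_positions(fx)
        for z in bz:
            ok = _tdrl_feasible_from_inv(inv, z)
            ok &= f_codes != np.uint64(code_of(z))  # exclude identity edges
            for x in fx[ok]:
                pairs.append((x, z))
                if not need_all:
                    return pairs
                if len(pairs) >= max_pairs:
                    return pairs
    return pairs


def search(a_row: np.ndarray, b_row: np.ndarray, max_steps: int = 3,
           need_all: bool = True) -> SearchResult:
    """Minimal number of events from a to b, bounded by ``max_steps`` <= 3.

    Complete for the four event classes.  With ``need_all=False`` the
    depth-3 stage stops at the first witness pair (the distance is still
    exact; only the enumeration of alternative paths is abridged).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if max_steps > 3:
        raise ValueError("bounded search supports max_steps <= 3")
    a_code, b_code = code_of(a_row), code_of(b_row)
    if a_code == b_code:
        return SearchResult(0, None, None, False)

    F1_codes, F1_rows = successors(a_row)
    if np.uint64(b_code) in F1_codes:
        return SearchResult(1, None, None, False)
    if max_steps == 1:
        return SearchResult(None, None, None, True)

    B1_codes, B1_rows = predecessors(b_row)
    common = np.intersect1d(F1_codes, B1_codes)
    common = common[(common != np.uint64(a_code)) & (common != np.uint64(b_code))]
    if len(common):
        sel = np.isin(F1_codes, common)
        return SearchResult(2, F1_rows[sel], None, False)
    if max_steps == 2:
        return SearchResult(None, None, None, True)

    pairs = _tiit_mid_pairs(F1_codes, F1_rows, B1_rows, need_all)
    if pairs and not need_all:
        return SearchResult(3, None, pairs, False)
    pairs += _tdrl_mid_pairs(F1_rows, B1_rows, need_all)
    if pairs:
        return SearchResult(3, None, pairs, False)
    return SearchResult(None, None, None, True)


def min_steps_with_tdrl(a_row: np.ndarray, b_row: np.ndarray,
                        max_steps: int = 3) -> int | None:
    """Length of the shortest a -> b scenario containing >= 1 TDRL event.

    Used for ancestry polarization: TDRL is the one asymmetric event class.
    """
    a_code, b_code = code_of(a_row), code_of(b_row)
    if a_code == b_code:
        return None
    same_strand = strand_key(a_row) == strand_key(b_row)
    if same_strand and tdrl_feasible(a_row, b_row):
        return 1
    if max_steps < 2:
        return None

    Ft_codes, Ft_rows = _unique(succ_tdrl_rows(a_row), drop=a_code)
    B1_codes, B1_rows = predecessors(b_row)
    Bt_codes, Bt_rows = _unique(pred_tdrl_rows(b_row), drop=b_code)
    F1_codes, F1_rows = successors(a_row)
    if len(np.intersect1d(Ft_codes, B1_codes)) or len(
        np.intersect1d(F1_codes, Bt_codes)
    ):
        return 2
    if max_steps < 3:
        return None

    # depth 3 with >= 1 TDRL edge: TDRL first, TDRL last, or TDRL middle
    if _tiit_mid_pairs(Ft_codes, Ft_rows, B1_rows, need_all=False):
        return 3
    if _tdrl_mid_pairs(Ft_rows, B1_rows, need_all=False):
        return 3
    if _tiit_mid_pairs(F1_codes, F1_rows, Bt_rows, need_all=False):
        return 3
    if _tdrl_mid_pairs(F1_rows, Bt_rows, need_all=False):
        return 3
    if _tdrl_mid_pairs(F1_rows, B1_rows, need_all=False):
        return 3
    return None
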