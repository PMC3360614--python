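"""Single-hairpin RNA secondary-structure prediction.

Pre-miRNA validation only asks whether a window folds into one classical
stem-loop, so the structure space here is deliberately restricted to
non-branching folds: a nested chain of pairs (i0,j0) > (i1,j1) > ... closed
by one terminal loop of at least 3 nt.  Energies are nearest-neighbor stack
terms between adjacent pairs, bulge/internal-loop initiation between
non-adjacent consecutive pairs, and a hairpin-loop initiation at the
closing pair.  The open chain has dG = 0 and is returned whenever no
negative-energy hairpin exists.

:func:`fold_single_hairpin` is an O(n^2 * L^2) dynamic program (L = largest
interior loop); :func:`enumerate_structures` is the exhaustive oracle over
the identical structure space for short sequences, used to verify the DP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, INF, default_model, encode
from .seq import gc_fraction

__all__ = [
    "HairpinStructure",
    "fold_single_hairpin",
    "enumerate_structures",
    "structure_energy",
]

_TOL = 1e-9


@dataclass
class HairpinStructure:
    """A (possibly empty) single-hairpin fold of one sequence.

    ``pairs`` is the nested chain ordered outermost to innermost, 0-based.
    The mature-region statistics (``paired_fraction_mature``, ``core_mfe``,
    ``ch_ratio``) are filled in by candidate evaluation, which knows where
    the mature sits inside the window.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    mfe: float
    dot_bracket: str = ""
    loop_size: int = 0
    stem_pairs: int = 0
    gc_content: float = 0.0
    paired_fraction_mature: float | None = None
    core_mfe: float | None = None
    ch_ratio: float | None = None
    fail_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not self.dot_bracket:
            db = ["."] * n
            for i, j in self.pairs:
                db[i], db[j] = "(", ")"
            self.dot_bracket = "".join(db)
        self.stem_pairs = len(self.pairs)
        if self.pairs:
            ik, jk = self.pairs[-1]
            self.loop_size = jk - ik - 1
        self.gc_content = gc_fraction(self.sequence)

    @property
    def paired_indices(self) -> set[int]:
        out = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


def _validate(seq: str, max_len: int = 200) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len} nt")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"illegal RNA character(s) {sorted(bad)}")


def _energy_terms(seq: str, pairs, model: EnergyModel) -> list[float]:
    """Decompose a chain's energy: one interior/stack term per consecutive
    pair of pairs plus the closing hairpin term (last element)."""
    terms: list[float] = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            raise ValueError("pairs do not form a nested chain")
        d1, d2 = i2 - i1 - 1, j1 - j2 - 1
        if d1 == 0 and d2 == 0:
            terms.append(model.stack((seq[i1], seq[j1]), (seq[i2], seq[j2])))
        else:
            terms.append(model.interior(d1, d2))
    ik, jk = pairs[-1]
    terms.append(model.hairpin(jk - ik - 1))
    return terms


def structure_energy(seq: str, pairs, model: EnergyModel | None = None) -> float:
    """Recompute the free energy of an explicit chain of pairs (used for
    the additivity check and for core-region energies)."""
    model = model or default_model()
    if not pairs:
        return 0.0
    return float(sum(_energy_terms(seq, tuple(pairs), model)))


def fold_single_hairpin(seq: str, model: EnergyModel | None = None) -> HairpinStructure:
    """Minimum-free-energy single-hairpin structure of ``seq``.

    Returns the open chain (no pairs, dG = 0) when no hairpin has negative
    free energy.  Ties are broken deterministically (outermost pair with
    the smallest 5' index, then smallest 3' index; stack preferred over
    wider interior loops during traceback).
    """
    model = model or default_model()
    _validate(seq)
    n = len(seq)
    codes = encode(seq)
    cap = model.max_interior
    pen = model.interior_penalty_matrix        # (cap+1, cap+1)
    pen_flip = pen[:, ::-1]                    # columns reversed: d2 descends
    pair_ok = model.pair_ok
    stack4 = model.stack4

    E = np.full((n, n), INF)
    for span in range(4, n):                   # j - i; loop >= 3
        for i in range(0, n - span):
            j = i + span
            if not pair_ok[codes[i], codes[j]]:
                continue
            best = model.hairpin(span - 1)
            # stacked inner pair
            e_in = E[i + 1, j - 1]
            if e_in < INF:
                best = min(
                    best,
                    e_in + stack4[codes[i], codes[j],
                                  codes[i + 1], codes[j - 1]],
                )
            # interior loops: inner pair (i+1+d1, j-1-d2)
            k1 = min(i + 1 + cap, j - 5)       # inner width >= 5
            l0 = max(j - 1 - cap, i + 5)
            if k1 >= i + 1 and j - 1 >= l0:
                sub = E[i + 1:k1 + 1, l0:j]
                if np.isfinite(sub).any():
                    w = j - l0                 # columns; d2 = j-1-l
                    p = pen_flip[: sub.shape[0], cap + 1 - w:]
                    best = min(best, float(np.min(sub + p)))
            E[i, j] = best

    mfe = float(E.min()) if n >= 5 else INF
    if not mfe < -_TOL:
        return HairpinStructure(seq, (), 0.0)

    # outermost pair: smallest (i, j) achieving the minimum
    ii, jj = np.argwhere(np.abs(E - mfe) <= _TOL)[0]
    chain = [(int(ii), int(jj))]
    i, j = int(ii), int(jj)
    while True:
        target = E[i, j]
        if abs(model.hairpin(j - i - 1) - target) <= _TOL:
            break
        moved = False
        e_in = E[i + 1, j - 1]
        if e_in < INF:
            st = stack4[codes[i], codes[j], codes[i + 1], codes[j - 1]]
            if abs(e_in + st - target) <= _TOL:
                i, j = i + 1, j - 1
                chain.append((i, j))
                moved = True
        if not moved:
            done = False
            for d1 in range(cap + 1):
                k = i + 1 + d1
                if k > j - 5:
                    break
                for d2 in range(cap + 1 - d1):
                    if d1 == 0 and d2 == 0:
                        continue
                    l = j - 1 - d2
                    if l < k + 4:
                        break
                    if E[k, l] < INF and abs(
                        E[k, l] + pen[d1, d2] - target
                    ) <= _TOL:
                        i, j = k, l
                        chain.append((i, j))
                        done = True
                        break
                if done:
                    break
            if not done:   # pragma: no cover - DP/traceback mismatch guard
                raise AssertionError("traceback failed")
    return HairpinStructure(seq, tuple(chain), mfe)


def enumerate_structures(
    seq: str, model: EnergyModel | None = None, max_len: int = 18
) -> HairpinStructure:
    """Exhaustive minimum over the same single-hairpin structure space.

    Brute-force verification oracle for :func:`fold_single_hairpin`;
    restricted to short sequences (``len(seq) <= max_len``).
    """
    model = model or default_model()
    _validate(seq, max_len=max_len)
    n = len(seq)
    codes = encode(seq)
    cap = model.max_interior
    best = {"e": 0.0, "chain": ()}

    def recurse(i: int, j: int, e: float, chain: tuple) -> None:
        hp = model.hairpin(j - i - 1)
        total = e + hp
        if total < best["e"] - _TOL:
            best["e"], best["chain"] = total, chain
        for k in range(i + 1, j - 4 + 1):
            d1 = k - i - 1
            if d1 > cap:
                break
            for l in range(j - 1, k + 4 - 1, -1):
                d2 = j - 1 - l
                if d1 + d2 > cap:
                    break
                if not model.pair_ok[codes[k], codes[l]]:
                    continue
                if d1 == 0 and d2 == 0:
                    term = model.stack((seq[i], seq[j]), (seq[k], seq[l]))
                else:
                    term = model.interior(d1, d2)
                recurse(k, l, e + term, chain + ((k, l),))

    for i in range(n):
        for j in range(i + 4, n):
            if model.pair_ok[codes[i], codes[j]]:
                recurse(i, j, 0.0, ((i, j),))

    if not best["chain"]:
        return HairpinStructure(seq, (), 0.0)
    return HairpinStructure(seq, best["chain"], float(best["e"]))
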