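"""Intermolecular RNA-RNA duplex minimum free energy.

Hybridization of a query (5'->3') against a target read 3'->5', scored
with the same nearest-neighbor stack table as hairpin folding plus
bulge/internal-loop penalties and a single duplex-initiation constant; no
intramolecular pairs.  The dynamic program is local on both strands (any
number of unpaired terminal bases is free), so the result is the best
duplex anywhere along the target.  dG = 0 (no pairs) is returned when no
duplex is net-stabilizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel, INF, default_model, encode

__all__ = ["DuplexFold", "duplex_mfe"]

_TOL = 1e-9


@dataclass(frozen=True)
class DuplexFold:
    """Result of a duplex calculation.

    ``pairs`` maps query indices to target indices in the *original*
    (5'->3') orientation of both inputs; empty with ``dg == 0`` when no
    stabilizing duplex exists.
    """

    dg: float
    pairs: tuple[tuple[int, int], ...]

    @property
    def target_span(self) -> tuple[int, int] | None:
        """0-based half-open extent of the duplex on the target."""
        if not self.pairs:
            return None
        js = [j for _i, j in self.pairs]
        return min(js), max(js) + 1


def _check_rna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"empty {what} sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"illegal RNA character(s) {sorted(bad)} in {what}")


def duplex_mfe(
    a: str, b: str, model: EnergyModel | None = None
) -> DuplexFold:
    """Minimum free energy of the intermolecular duplex of ``a`` and ``b``.

    Both inputs are 5'->3'; pairing is antiparallel.  Gaps between
    consecutive pairs are capped at ``model.duplex_max_gap`` per strand
    (the cap is the same on both strands, which makes the energy invariant
    under swapping the strands with reversal).
    """
    model = model or default_model()
    _check_rna(a, "query")
    _check_rna(b, "target")
    am = encode(a)
    br = b[::-1]
    bm = encode(br)
    m, n = len(a), len(b)
    cap = model.duplex_max_gap
    init = model.duplex_init
    pair_ok = model.pair_ok
    stack4 = model.stack4

    # loop transitions (d1 on a, d2 on b), excluding the stack (0,0)
    trans = [
        (d1, d2, model.interior(d1, d2))
        for d1 in range(cap + 1)
        for d2 in range(cap + 1)
        if 0 < d1 + d2 <= cap
    ]

    M = np.full((m, n), INF)
    for i in range(m):
        pairable = pair_ok[am[i], bm]
        if not pairable.any():
            continue
        best = np.full(n, init)           # open a new duplex at (i, j)
        if i >= 1:
            # stack on the previous pair
            srow = stack4[am[i - 1], bm[: n - 1], am[i], bm[1:]]
            cand = np.concatenate(([INF], M[i - 1, : n - 1] + srow))
            best = np.minimum(best, cand)
            # bulge / internal loop from an earlier pair
            for d1, d2, penalty in trans:
                ip = i - 1 - d1
                if ip < 0:
                    continue
                shift = 1 + d2
                if shift >= n:
                    continue
                cand = np.concatenate(
                    (np.full(shift, INF), M[ip, : n - shift] + penalty)
                )
                best = np.minimum(best, cand)
        M[i] = np.where(pairable, best, INF)

    if not np.isfinite(M).any():
        return DuplexFold(0.0, ())
    dg = float(M.min())
    if not dg < -_TOL:
        return DuplexFold(0.0, ())

    # deterministic traceback from the first cell achieving the minimum
    i, j = map(int, np.unravel_index(int(np.argmin(M)), M.shape))
    rev_pairs = [(i, j)]
    while abs(M[i, j] - init) > _TOL:
        target = M[i, j]
        moved = False
        if i >= 1 and j >= 1 and M[i - 1, j - 1] < INF:
            st = stack4[am[i - 1], bm[j - 1], am[i], bm[j]]
            if abs(M[i - 1, j - 1] + st - target) <= _TOL:
                i, j = i - 1, j - 1
                rev_pairs.append((i, j))
                moved = True
        if not moved:
            for d1, d2, penalty in trans:
                ip, jp = i - 1 - d1, j - 1 - d2
                if ip < 0 or jp < 0 or M[ip, jp] >= INF:
                    continue
                if abs(M[ip, jp] + penalty - target) <= _TOL:
                    i, j = ip, jp
                    rev_pairs.append((i, j))
                    moved = True
                    break
        if not moved:   # pragma: no cover - DP/traceback mismatch guard
            raise AssertionError("duplex traceback failed")

    pairs = tuple(
        sorted((ia, n - 1 - jb) for ia, jb in rev_pairs)
    )
    return DuplexFold(dg, pairs)
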