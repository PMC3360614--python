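"""Nearest-neighbor RNA energy model shared by hairpin folding and
intermolecular duplex scoring.

The model is loaded from a packaged YAML parameter table
(``data/nn_params.yaml``): Watson-Crick and G:U stack free energies
(kcal/mol at 37 degC), hairpin/bulge/internal loop initiation by length
with Jacobson-Stockmayer extrapolation beyond the tabulated sizes, an
internal-loop asymmetry penalty, and a duplex initiation constant.  The
table is data: swapping parameter files must never require code changes.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

#: base encoding used by the vectorized scanners and folders
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: canonical pairs (Watson-Crick plus G:U wobble)
CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}

# gas constant * 310.15 K, kcal/mol
_RT37 = 0.0019872 * 310.15
INF = float("inf")


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as a uint8 array (A=0 C=1 G=2 U=3 N=4)."""
    return np.frombuffer(
        seq.encode().translate(_ENC_TABLE), dtype=np.uint8
    ).copy()


_ENC_TABLE = bytes(
    BASE_INDEX.get(chr(c), 3 if chr(c) == "T" else 4) for c in range(256)
)


class EnergyModel:
    """Parameter container with fast lookups.

    ``stack4[x1, y1, x2, y2]`` is the stack free energy of the motif
    5'-x1 x2-3' / 3'-y1 y2-5' (outer pair x1:y1, inner pair x2:y2), +inf
    when either pair is non-canonical.  Loop methods accept any length and
    extrapolate beyond their tables.
    """

    def __init__(self, params: dict):
        self.params = params
        self.max_interior = int(params.get("max_interior", 30))
        self.duplex_init = float(params.get("duplex_init", 4.09))
        self.duplex_max_gap = int(params.get("duplex_max_gap", 10))
        self._asym = float(params.get("internal_asymmetry", 0.6))
        self._asym_max = float(params.get("internal_asymmetry_max", 3.0))
        self._hairpin = {int(k): float(v)
                         for k, v in params["hairpin_loop"].items()}
        self._bulge = {int(k): float(v)
                       for k, v in params["bulge_loop"].items()}
        self._internal = {int(k): float(v)
                          for k, v in params["internal_loop"].items()}

        # pairability lookup over the 5-letter encoded alphabet
        self.pair_ok = np.zeros((5, 5), dtype=bool)
        for a, b in CANONICAL_PAIRS:
            self.pair_ok[BASE_INDEX[a], BASE_INDEX[b]] = True

        # 4-D stack table with rotational symmetry expansion + validation
        self.stack4 = np.full((5, 5, 5, 5), INF)
        for key, val in params["stacks"].items():
            top, bottom = key.split("/")
            x1, x2 = top[0], top[1]
            y1, y2 = bottom[0], bottom[1]
            # rotational symmetry: E(XY/ZW) == E(WZ/YX)
            for (a1, b1, a2, b2) in ((x1, y1, x2, y2), (y2, x2, y1, x1)):
                idx = (BASE_INDEX[a1], BASE_INDEX[b1],
                       BASE_INDEX[a2], BASE_INDEX[b2])
                cur = self.stack4[idx]
                if math.isfinite(cur) and abs(cur - float(val)) > 1e-9:
                    raise ValueError(
                        f"stack table symmetry conflict at {key}"
                    )
                self.stack4[idx] = float(val)
        # every canonical pair-on-pair combination must be covered
        pairs = [(BASE_INDEX[a], BASE_INDEX[b]) for a, b in CANONICAL_PAIRS]
        for (a1, b1) in pairs:
            for (a2, b2) in pairs:
                if not math.isfinite(self.stack4[a1, b1, a2, b2]):
                    raise ValueError(
                        "stack table is missing a canonical combination"
                    )

    # ---- loop terms -----------------------------------------------------

    def _extrapolate(self, table: dict[int, float], n: int) -> float:
        nmax = max(table)
        if n <= nmax:
            return table[n]
        return table[nmax] + 1.75 * _RT37 * math.log(n / nmax)

    def hairpin(self, loop_len: int) -> float:
        """Hairpin-loop initiation; loops shorter than 3 are sterically
        forbidden (+inf)."""
        if loop_len < 3:
            return INF
        return self._extrapolate(self._hairpin, loop_len)

    def bulge(self, n: int) -> float:
        if n < 1:
            return INF
        return self._extrapolate(self._bulge, n)

    def internal(self, n1: int, n2: int) -> float:
        if n1 < 1 or n2 < 1:
            return INF
        size = self._extrapolate(self._internal, n1 + n2)
        asym = min(self._asym * abs(n1 - n2), self._asym_max)
        return size + asym

    def interior(self, d1: int, d2: int) -> float:
        """Energy of the loop between consecutive helix pairs with ``d1``
        unpaired bases on one strand and ``d2`` on the other.  (0,0) is a
        stack and must be scored with :meth:`stack` instead."""
        if d1 == 0 and d2 == 0:
            return INF
        if d1 == 0 or d2 == 0:
            return self.bulge(d1 + d2)
        return self.internal(d1, d2)

    # ---- helix terms ----------------------------------------------------

    def is_pair(self, a: str, b: str) -> bool:
        return (a, b) in CANONICAL_PAIRS

    def stack(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        """Stack energy for inner pair stacked directly on outer pair."""
        return float(self.stack4[
            BASE_INDEX[outer[0]], BASE_INDEX[outer[1]],
            BASE_INDEX[inner[0]], BASE_INDEX[inner[1]],
        ])

    # matrix of interior penalties used by the vectorized folder
    @property
    def interior_penalty_matrix(self) -> np.ndarray:
        if not hasattr(self, "_ipm"):
            cap = self.max_interior
            pen = np.full((cap + 1, cap + 1), INF)
            for d1 in range(cap + 1):
                for d2 in range(cap + 1):
                    if 0 < d1 + d2 <= cap:
                        pen[d1, d2] = self.interior(d1, d2)
            self._ipm = pen
        return self._ipm


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    """The packaged parameter table, loaded once."""
    path = resources.files("mirest") / "data" / "nn_params.yaml"
    with open(str(path)) as fh:
        return EnergyModel(yaml.safe_load(fh))


def load_model(path) -> EnergyModel:
    with open(str(path)) as fh:
        return EnergyModel(yaml.safe_load(fh))
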