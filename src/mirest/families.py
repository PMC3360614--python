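"""miRNA nomenclature parsing, family grouping and pairwise identity.

A miRNA family is the set of matures sharing a numeric identifier core:
miR-33a, miR-33b and miR-33b-2 all belong to family "33" (variant letters
mark sequence variants, trailing ``-N`` marks genomic copies, and the
species prefix is ignored for grouping).  "let" names keep a ``let-``
marker in the key so let-7 never merges with miR-7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import MatureMiRNA
from .seq import FormatError

__all__ = ["MiRNAFamily", "parse_name", "group_families", "pairwise_identity"]

_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Za-z][A-Za-z0-9]*)-(?P<tag>miR|let)-?(?P<core>\d+)"
    r"(?P<variant>[a-z]*)(?:-(?P<copy>\d+))?$"
)


@dataclass(frozen=True)
class MiRNAFamily:
    family_key: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def parse_name(name: str):
    """Split ``<species>-miR-<core>[letters][-copy]`` into its parts.

    Returns ``(species_prefix, core, variant_letter_or_None,
    copy_number_or_None)``; e.g. ``"sli-miR-928c-1"`` gives
    ``("sli", "928", "c", 1)``.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise FormatError(f"unparseable miRNA name {name!r}")
    variant = m.group("variant") or None
    copy = int(m.group("copy")) if m.group("copy") else None
    return m.group("prefix"), m.group("core"), variant, copy


def _family_key(name: str) -> str:
    m = _NAME_RE.match(name)
    if not m:
        raise FormatError(f"unparseable miRNA name {name!r}")
    core = m.group("core")
    return f"let-{core}" if m.group("tag") == "let" else core


def group_families(mirnas: list[MatureMiRNA]) -> list[MiRNAFamily]:
    """Partition matures into families by numeric core.

    Members keep multiplicity (a duplicated name appears twice), so family
    member counts always sum to the input count.  Output is sorted by
    numeric core and is independent of input order.
    """
    groups: dict[str, list[str]] = {}
    for m in mirnas:
        groups.setdefault(_family_key(m.name), []).append(m.name)
    fams = [
        MiRNAFamily(key, tuple(sorted(names)))
        for key, names in groups.items()
    ]
    fams.sort(key=lambda f: (f.family_key.startswith("let-"),
                             int(f.family_key.removeprefix("let-"))))
    return fams


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two RNA sequences by ungapped sliding.

    The shorter sequence slides along the longer over every offset with at
    least one overlapping position (overhangs allowed); identity is the
    best match count divided by the shorter length, as a percentage
    reported to one decimal.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ls, ll = len(short), len(long_)
    best = 0
    for off in range(-(ls - 1), ll):
        matches = 0
        for i in range(ls):
            j = off + i
            if 0 <= j < ll and short[i] == long_[j]:
                matches += 1
        best = max(best, matches)
    return round(100.0 * best / ls, 1)


def families_to_tsv(families: list[MiRNAFamily]) -> str:
    lines = ["family\tmember"]
    for f in families:
        for m in f.members:
            lines.append(f"{f.family_key}\t{m}")
    return "\n".join(lines) + "\n"
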