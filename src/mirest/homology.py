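"""Bounded-mismatch homology scanning of ESTs against mature miRNAs and
extraction of candidate precursor windows.

The scan is pure Hamming matching (no indels) of every reference-length
window on both EST strands; positions containing N count as mismatches.
Overlapping hits of one reference are reduced to the local-minimum-mismatch
hit (ties to the leftmost), and hits of different references are
deduplicated by (EST, coordinates, strand).  Around each hit, up to three
~``window_len`` nt windows are cut, placing the mature region in the 5'
arm, centered, and in the 3' arm — a mature miRNA sits in one arm of its
hairpin, so downstream folding keeps whichever placement folds best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .energy import encode
from .io import ESTRecord, MatureMiRNA
from .seq import revcomp_dna, transcribe

__all__ = [
    "HomologyHit",
    "PrecursorWindow",
    "count_mismatches",
    "scan_est",
    "extract_windows",
    "hits_to_bed",
]

#: 5' flank kept before the mature region in the arm-placed windows
_ARM_PAD = 2
#: a clipped window is dropped when shorter than mature length + this
_MIN_FLANK = 15


@dataclass(frozen=True)
class HomologyHit:
    """A reference-length match on the EST forward strand (0-based,
    half-open); ``mismatches`` is the Hamming distance."""

    est_id: str
    ref_name: str
    start: int
    end: int
    strand: str
    mismatches: int
    mature_seq: str = ""


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor window read 5'->3' in the sense of the hit.

    ``win_start``/``win_end`` are EST forward-strand coordinates;
    ``sequence`` is RNA (reverse-complemented for '-' hits) and the mature
    region occupies ``[mature_offset, mature_offset + mature_length)``
    inside it.
    """

    est_id: str
    win_start: int
    win_end: int
    strand: str
    sequence: str
    mature_offset: int
    mature_length: int
    arm_hint: str = "unknown"


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences (N never matches)."""
    if len(a) != len(b):
        raise ValueError(
            f"unequal lengths {len(a)} vs {len(b)} for mismatch count"
        )
    return sum(
        1 for x, y in zip(a, b) if x != y or x == "N"
    )


def _reduce_local(positions: list[tuple[int, int]], L: int) -> list[tuple[int, int]]:
    """Within one (reference, strand), keep the local-minimum-mismatch hit
    of each overlapping run (ties to the leftmost in scan orientation).

    ``positions`` are (start, mismatches) in strand-local coordinates,
    already sorted by start.
    """
    out: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    run_end = -1
    for p, m in positions:
        if run and p < run_end:
            run.append((p, m))
            run_end = max(run_end, p + L)
        else:
            if run:
                out.append(min(run, key=lambda t: (t[1], t[0])))
            run = [(p, m)]
            run_end = p + L
    if run:
        out.append(min(run, key=lambda t: (t[1], t[0])))
    return out


def scan_est(
    est: ESTRecord,
    refs: list[MatureMiRNA],
    max_mm: int = 5,
    dedupe: bool = True,
) -> list[HomologyHit]:
    """All bounded-mismatch hits of ``refs`` on both strands of ``est``.

    Emits a hit wherever a reference-length window has Hamming distance
    <= ``max_mm``; see the module docstring for the reduction rules.
    References longer than the EST are skipped.
    """
    if not refs:
        raise ValueError("empty reference set")
    n = est.length
    fwd = encode(transcribe(est.sequence))
    rc_dna = revcomp_dna(est.sequence)
    rev = encode(transcribe(rc_dna))

    all_hits: list[HomologyHit] = []
    for ref in refs:
        L = ref.length
        if L > n:
            continue
        rcodes = encode(ref.sequence)
        for strand, arr, src in (
            ("+", fwd, est.sequence),
            ("-", rev, rc_dna),
        ):
            win = sliding_window_view(arr, L)
            # N encodes to a non-base value, so it never equals a reference
            mm = (win != rcodes).sum(axis=1)
            # reduce overlapping runs in strand-local coordinates so the
            # leftmost tie-break mirrors correctly under reverse complement
            local = [(int(p), int(mm[p]))
                     for p in np.nonzero(mm <= max_mm)[0]]
            for p, m in _reduce_local(local, L):
                if strand == "+":
                    start, end = p, p + L
                else:
                    start, end = n - (p + L), n - p
                all_hits.append(HomologyHit(
                    est.id, ref.name, start, end, strand, m,
                    transcribe(src[p:p + L]),
                ))

    if dedupe:
        best: dict[tuple[int, int, str], HomologyHit] = {}
        for h in all_hits:
            key = (h.start, h.end, h.strand)
            if key not in best or h.mismatches < best[key].mismatches:
                best[key] = h
        all_hits = list(best.values())
    all_hits.sort(key=lambda h: (h.start, h.end, h.strand, h.ref_name))
    return all_hits


def extract_windows(
    est: ESTRecord, hit: HomologyHit, window_len: int = 100
) -> list[PrecursorWindow]:
    """Up to three precursor windows around a hit (5' arm, centered, 3'
    arm placements), clipped at EST boundaries; a window shorter than
    mature length + 15 nt after clipping is dropped."""
    n = est.length
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit {hit.start}..{hit.end} outside EST {est.id}")
    L = hit.end - hit.start
    if hit.strand == "+":
        s_local = hit.start
        seq_local = transcribe(est.sequence)
    else:
        s_local = n - hit.end
        seq_local = transcribe(revcomp_dna(est.sequence))

    placements = [
        ("5p", s_local - _ARM_PAD),
        ("unknown", s_local - (window_len - L) // 2),
        ("3p", s_local - (window_len - L - _ARM_PAD)),
    ]
    windows: list[PrecursorWindow] = []
    seen: set[tuple[int, int]] = set()
    for arm, start in placements:
        a = max(0, start)
        b = min(n, start + window_len)
        a = min(a, s_local)
        b = max(b, s_local + L)
        if b - a < L + _MIN_FLANK or (a, b) in seen:
            continue
        seen.add((a, b))
        if hit.strand == "+":
            ws, we = a, b
        else:
            ws, we = n - b, n - a
        windows.append(PrecursorWindow(
            est.id, ws, we, hit.strand, seq_local[a:b],
            s_local - a, L, arm,
        ))
    return windows


def hits_to_bed(hits: list[HomologyHit]) -> str:
    """BED6 export: EST as contig, score = mismatch count."""
    lines = [
        "\t".join([
            h.est_id, str(h.start), str(h.end), h.ref_name,
            str(h.mismatches), h.strand,
        ])
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
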