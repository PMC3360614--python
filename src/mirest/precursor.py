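"""Precursor candidate filtering, best-precursor selection and detection of
same-transcript miRNA clusters.

A folded ~100 nt window passes when it satisfies, in order: the free-energy
threshold (dG <= -20 kcal/mol by default), a single stem-loop of at least
``min_stem`` pairs, the mature region sitting in one arm (at most
``max_loop_overlap`` nt outside it), at least ``min_mature_paired`` of the
mature bases paired, GC content inside [gc_min, gc_max], and a
core-to-total energy ratio (``ch_ratio``) of at least ``min_ch_ratio``.
``core_mfe`` is the energy of the stem-loop from the outermost pair that
flanks the mature arm inward; ``ch_ratio = core_mfe / dG``.  Every failed
criterion is recorded, so relaxing any threshold can only grow the passing
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import EnergyModel, default_model
from .fold import HairpinStructure, _energy_terms
from .homology import PrecursorWindow

__all__ = [
    "FilterThresholds",
    "PrecursorCandidate",
    "MiRNACluster",
    "AcceptedMature",
    "evaluate_candidate",
    "select_best_precursor",
    "detect_clusters",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Precursor acceptance thresholds (defaults follow the pipeline's
    published operating point)."""

    dg_max: float = -20.0
    min_stem: int = 14
    max_loop_overlap: int = 4
    min_mature_paired: float = 0.6
    gc_min: float = 0.20
    gc_max: float = 0.80
    min_ch_ratio: float = 0.8


@dataclass
class PrecursorCandidate:
    window: PrecursorWindow
    structure: HairpinStructure
    verdict: bool = False
    fail_reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AcceptedMature:
    """Coordinates of an accepted mature region on its source EST."""

    est_id: str
    name: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MiRNACluster:
    """Two or more accepted mature miRNAs on one EST and strand, separated
    by short spacers (polycistronic pri-miRNA signature)."""

    est_id: str
    member_names: tuple[str, ...]
    spacers: tuple[int, ...]

    @property
    def spacer_nt(self) -> int:
        return self.spacers[0]


def evaluate_candidate(
    cand: PrecursorCandidate,
    thresholds: FilterThresholds | None = None,
    model: EnergyModel | None = None,
) -> PrecursorCandidate:
    """Apply the filter criteria in order, recording every failure."""
    thr = thresholds or FilterThresholds()
    model = model or default_model()
    st = cand.structure
    win = cand.window
    reasons: list[str] = []

    if not st.pairs:
        # without a stem the arm/pairing/core criteria are not evaluable
        reasons = ["free_energy", "stem_loop"]
        st.paired_fraction_mature = 0.0
        st.core_mfe = 0.0
        st.ch_ratio = 0.0
        cand.fail_reasons = reasons
        cand.verdict = False
        return cand

    if not st.mfe <= thr.dg_max:
        reasons.append("free_energy")
    if st.stem_pairs < thr.min_stem:
        reasons.append("stem_loop")

    mo, ml = win.mature_offset, win.mature_length
    mature_idx = range(mo, mo + ml)
    ik, jk = st.pairs[-1]
    five = sum(1 for p in mature_idx if p <= ik)
    three = sum(1 for p in mature_idx if p >= jk)
    outside_arm = ml - max(five, three)
    if outside_arm > thr.max_loop_overlap:
        reasons.append("mature_in_arm")

    paired = st.paired_indices
    frac = sum(1 for p in mature_idx if p in paired) / ml
    st.paired_fraction_mature = frac
    if frac < thr.min_mature_paired:
        reasons.append("mature_paired")

    if not thr.gc_min <= st.gc_content <= thr.gc_max:
        reasons.append("gc_content")

    # core energy: from the outermost pair flanking the mature arm inward
    terms = _energy_terms(st.sequence, st.pairs, model)
    arm5 = five >= three
    t = None
    for idx, (i, j) in enumerate(st.pairs):
        if (arm5 and i >= mo) or (not arm5 and j <= mo + ml - 1):
            t = idx
            break
    if t is None:
        core = 0.0
    else:
        core = float(sum(terms[t:]))
    st.core_mfe = core
    st.ch_ratio = core / st.mfe if st.mfe < 0 else 0.0
    if st.ch_ratio < thr.min_ch_ratio:
        reasons.append("ch_ratio")

    cand.fail_reasons = reasons
    cand.verdict = not reasons
    return cand


def select_best_precursor(candidates) -> PrecursorCandidate | None:
    """Among passing candidates for one homology hit, the lowest-energy
    window wins; ties go to the smaller window start; None if none pass."""
    passing = [c for c in candidates if c.verdict]
    if not passing:
        return None
    return min(passing, key=lambda c: (c.structure.mfe, c.window.win_start))


def detect_clusters(accepted, max_spacer: int = 1000) -> list[MiRNACluster]:
    """Group accepted mature regions on the same EST and strand whose
    consecutive gaps are at most ``max_spacer`` nt.

    Overlapping mature regions (e.g. hits of several family members on the
    same locus) are first merged into one locus, so spacers are always
    non-negative and a cluster means genuinely distinct loci.
    """
    by_key: dict[tuple[str, str], list[AcceptedMature]] = {}
    for a in accepted:
        by_key.setdefault((a.est_id, a.strand), []).append(a)
    clusters = []
    for (est_id, strand), members in sorted(by_key.items()):
        members.sort(key=lambda a: (a.start, a.end, a.name))
        # merge overlapping matures into loci
        loci: list[AcceptedMature] = []
        for m in members:
            if loci and m.start < loci[-1].end:
                prev = loci[-1]
                loci[-1] = AcceptedMature(
                    est_id, prev.name, prev.start,
                    max(prev.end, m.end), strand,
                )
            else:
                loci.append(m)
        run = [loci[0]]
        for m in loci[1:]:
            if m.start - run[-1].end <= max_spacer:
                run.append(m)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(est_id, run))
                run = [m]
        if len(run) >= 2:
            clusters.append(_make_cluster(est_id, run))
    return clusters


def _make_cluster(est_id: str, run) -> MiRNACluster:
    spacers = tuple(b.start - a.end for a, b in zip(run, run[1:]))
    return MiRNACluster(est_id, tuple(m.name for m in run), spacers)
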