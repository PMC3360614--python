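"""miRNA target prediction in 3'UTR sets and Table-style bookkeeping.

Two site classes are predicted:

* **Class I** — a canonical 7mer seed site: the UTR contains the exact
  Watson-Crick reverse complement of miRNA positions 2-8 (no G:U in the
  seed), and the duplex of the *full* miRNA with the surrounding UTR
  window is below the free-energy threshold (dG < -20 kcal/mol).
* **Class II** — the miRNA 3'-region fragment (1-based positions 12
  through x-2, where x is the mature length) hybridizes somewhere in the
  UTR with duplex dG below the same threshold.

Counting is per gene (best site only), mirroring per-gene target tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .duplex import duplex_mfe
from .energy import EnergyModel, default_model
from .io import MatureMiRNA, TargetCountRow, UTRRecord
from .seq import revcomp_rna

__all__ = [
    "DuplexResult",
    "TargetSummary",
    "seed_fragment",
    "fragment_12_to_xminus2",
    "find_class1_sites",
    "find_class2_targets",
    "summarize_targets",
    "tf_ratio",
]


@dataclass(frozen=True)
class DuplexResult:
    """A miRNA-3'UTR pairing below the energy threshold."""

    mirna_name: str
    gene_id: str
    site_start: int
    site_end: int
    dg: float
    site_class: str


@dataclass(frozen=True)
class TargetSummary:
    per_mirna: tuple[TargetCountRow, ...]
    total: int
    class1: int
    class2: int


def seed_fragment(m: MatureMiRNA) -> str:
    """The 7-nt seed, 1-based mature positions 2-8."""
    if m.length < 8:
        raise ValueError(f"{m.name}: too short ({m.length} nt) for a seed")
    return m.sequence[1:8]


def fragment_12_to_xminus2(m: MatureMiRNA) -> str:
    """The 3'-region fragment, 1-based positions 12 through x-2 inclusive
    (length x-13)."""
    x = m.length
    if x < 14:
        raise ValueError(
            f"{m.name}: length {x} leaves an empty 12..(x-2) fragment"
        )
    return m.sequence[11:x - 2]


def find_class1_sites(
    m: MatureMiRNA,
    utr: UTRRecord,
    model: EnergyModel | None = None,
    dg_max: float = -20.0,
    pad: int = 3,
) -> list[DuplexResult]:
    """Seed-matched, energy-filtered Class I sites in one UTR.

    Every exact reverse-complement occurrence of the seed is a candidate;
    the full miRNA is then hybridized against the UTR window covering the
    whole putative site (plus ``pad`` nt context) and the candidate is
    kept iff its duplex dG is below ``dg_max``.
    """
    model = model or default_model()
    motif = revcomp_rna(seed_fragment(m))
    x = m.length
    seq = utr.sequence
    out: list[DuplexResult] = []
    p = seq.find(motif)
    while p != -1:
        # seed occupies positions x-8..x-2 of the reverse-complemented site
        site_start = p - (x - 8)
        site_end = site_start + x
        a = max(0, site_start - pad)
        b = min(len(seq), site_end + pad)
        fold = duplex_mfe(m.sequence, seq[a:b], model)
        if fold.dg < dg_max:
            span = fold.target_span
            out.append(DuplexResult(
                m.name, utr.gene_id, a + span[0], a + span[1], fold.dg, "I",
            ))
        p = seq.find(motif, p + 1)
    return out


def find_class2_targets(
    m: MatureMiRNA,
    utrs: list[UTRRecord],
    model: EnergyModel | None = None,
    dg_max: float = -20.0,
    mode: str = "fragment",
) -> list[DuplexResult]:
    """Class II targets: best fragment-UTR duplex per gene below threshold.

    ``mode="fragment"`` (default) hybridizes the 12..(x-2) fragment alone;
    ``mode="full"`` hybridizes the whole mature sequence instead.  The
    duplex search is local along the UTR with capped inter-pair gaps, so
    it is equivalent to sliding a fragment-length + gap-cap window at
    single-nt steps and keeping each gene's best window.  One result per
    gene; output sorted by gene id, so it is independent of input order.
    """
    model = model or default_model()
    query = fragment_12_to_xminus2(m) if mode == "fragment" else m.sequence
    out: list[DuplexResult] = []
    for utr in utrs:
        fold = duplex_mfe(query, utr.sequence, model)
        if fold.dg < dg_max:
            span = fold.target_span
            out.append(DuplexResult(
                m.name, utr.gene_id, span[0], span[1], fold.dg, "II",
            ))
    out.sort(key=lambda r: r.gene_id)
    return out


def summarize_targets(rows: list[TargetCountRow]) -> TargetSummary:
    """Grand totals over per-miRNA target counts (Class I = total - II)."""
    total = sum(r.n_targets for r in rows)
    class2 = sum(r.n_class2 for r in rows)
    return TargetSummary(tuple(rows), total, total - class2, class2)


def tf_ratio(n_tf: int, n_total: int) -> float:
    """Percentage of transcription-factor targets, half-up to one decimal."""
    if n_total < 1:
        raise ValueError("denominator must be at least 1")
    if not 0 <= n_tf <= n_total:
        raise ValueError("numerator must be within [0, denominator]")
    pct = Decimal(100 * n_tf) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def results_to_tsv(results: list[DuplexResult]) -> str:
    lines = ["mirna\tgene\tstart\tend\tdG\tclass"]
    for r in results:
        lines.append(
            f"{r.mirna_name}\t{r.gene_id}\t{r.site_start}\t{r.site_end}"
            f"\t{r.dg:.2f}\t{r.site_class}"
        )
    return "\n".join(lines) + "\n"


def summary_to_tsv(summary: TargetSummary) -> str:
    lines = ["mirna\tn_targets\tn_class2"]
    for r in summary.per_mirna:
        lines.append(f"{r.mirna_name}\t{r.n_targets}\t{r.n_class2}")
    lines.append(f"TOTAL\t{summary.total}\t{summary.class2}")
    return "\n".join(lines) + "\n"
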