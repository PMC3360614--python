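"""Synthetic inputs with known ground truth.

The study's EST libraries were never published, so every full-pipeline test
runs on generated data: ESTs carrying planted precursor hairpins among
random decoys, 3'UTRs with planted target sites, and band-intensity tables
with intended fold classes.  All generators are pure functions of their
parameters and seed; the truth object is serializable and sufficient to
score any pipeline output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .energy import EnergyModel, default_model
from .fold import fold_single_hairpin
from .homology import PrecursorWindow
from .io import ESTRecord, MatureMiRNA, UTRRecord
from .precursor import FilterThresholds, PrecursorCandidate, evaluate_candidate
from .seq import revcomp_rna
from .targets import fragment_12_to_xminus2

__all__ = [
    "PlantedPrecursor",
    "PlantedSite",
    "SyntheticTruth",
    "plant_precursor",
    "generate_est_dataset",
    "generate_utr_set",
    "generate_intensity_table",
    "score_recovery",
    "RecoveryScore",
]

#: background base frequencies at the default 0.42 GC (typical lepidopteran
#: transcript composition)
_RNA = "ACGU"
_DNA = "ACGT"

#: ratio planted for each intended fold class (miRNA/control)
CLASS_RATIOS = {
    "high": 5.0,
    "moderate": 0.5,
    "very_low": 0.005,
    "intermediate": 1.5,
}


@dataclass(frozen=True)
class PlantedPrecursor:
    est_id: str
    start: int
    end: int
    mature_name: str
    arm: str
    mature_start: int
    mature_end: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    mirna_name: str
    start: int
    end: int
    site_class: str


@dataclass
class SyntheticTruth:
    seed: int
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    intensity_classes: dict = field(default_factory=dict)
    n_decoys: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            planted_precursors=[
                PlantedPrecursor(**p) for p in d["planted_precursors"]
            ],
            planted_sites=[PlantedSite(**s) for s in d["planted_sites"]],
            intensity_classes=d["intensity_classes"],
            n_decoys=d["n_decoys"],
        )

    @property
    def planted_est_ids(self) -> set[str]:
        return {p.est_id for p in self.planted_precursors}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _random_seq(rng, n: int, alphabet: str, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(alphabet), size=n, p=p))


def plant_precursor(
    mature: MatureMiRNA,
    rng_seed,
    arm: str = "5p",
    mutations: int = 0,
    model: EnergyModel | None = None,
    thresholds: FilterThresholds | None = None,
    total_len: int = 100,
    max_tries: int = 30,
):
    """Build a ~``total_len`` nt RNA window containing a hairpin precursor.

    The construct is mature arm + random loop (8-12 nt) + reverse
    complement of the mature carrying 2-4 planted G:U wobbles (or
    mismatches where no wobble is possible) + random flanks.  ``mutations``
    substitutions are then applied to the mature copy — the *unmutated*
    construct must pass candidate evaluation (regenerated up to
    ``max_tries`` times, then an error).

    Returns ``(sequence, mature_offset, loop_len)``.
    """
    if mature.length > 30:
        raise ValueError("mature longer than 30 nt")
    if mutations > 10:
        raise ValueError("at most 10 mutations supported")
    rng = _rng(rng_seed)
    model = model or default_model()
    thr = thresholds or FilterThresholds()
    m = mature.sequence
    L = len(m)

    for _ in range(max_tries):
        loop_len = int(rng.integers(8, 13))
        loop = _random_seq(rng, loop_len, _RNA)
        comp = list(revcomp_rna(m))
        # wobble/mismatch positions on the complementary arm; comp index c
        # faces mature index L-1-c
        n_wob = int(rng.integers(2, 5))
        order = rng.permutation(L)
        order = sorted(order, key=lambda c: m[L - 1 - int(c)] not in "GU")
        for c in [int(c) for c in order[:n_wob]]:
            base = m[L - 1 - c]
            if base == "G":
                comp[c] = "U"      # G:U wobble
            elif base == "U":
                comp[c] = "G"      # U:G wobble
            elif base == "A":
                comp[c] = "C"      # mismatch
            else:
                comp[c] = "A"      # mismatch
        comp_arm = "".join(comp)
        core5 = m + loop + comp_arm if arm == "5p" else \
            comp_arm + loop + m
        rem = max(0, total_len - len(core5))
        f5 = int(rng.integers(0, rem + 1))
        flank5 = _random_seq(rng, f5, _RNA)
        flank3 = _random_seq(rng, rem - f5, _RNA)
        seq = flank5 + core5 + flank3
        offset = f5 if arm == "5p" else f5 + len(comp_arm) + loop_len

        window = PrecursorWindow(
            "synthetic", 0, len(seq), "+", seq, offset, L, arm,
        )
        cand = evaluate_candidate(
            PrecursorCandidate(window, fold_single_hairpin(seq, model)),
            thr, model,
        )
        if not cand.verdict:
            continue
        if mutations:
            mat = list(m)
            for p in rng.choice(L, size=mutations, replace=False):
                p = int(p)
                mat[p] = rng.choice([b for b in _RNA if b != mat[p]])
            seq = seq[:offset] + "".join(mat) + seq[offset + L:]
        return seq, offset, loop_len
    raise RuntimeError(
        f"could not build a passing precursor for {mature.name} "
        f"in {max_tries} tries"
    )


def generate_est_dataset(
    refs: list[MatureMiRNA],
    n_planted: int = 20,
    n_decoys: int = 200,
    decoy_len: int | None = None,
    seed: int = 0,
    gc: float = 0.42,
    model: EnergyModel | None = None,
    thresholds: FilterThresholds | None = None,
):
    """ESTs with one planted precursor each plus random decoys.

    Planted ESTs are random background (lengths 300-900 nt, configurable
    GC) with a passing precursor construct inserted at a random position;
    decoys are pure background of ``decoy_len`` (random 300-900 when
    None).  Returns ``(ests, truth)``; byte-identical for equal seeds.
    """
    if n_planted < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    rng = _rng(seed)
    model = model or default_model()
    truth = SyntheticTruth(seed=int(seed), n_decoys=n_decoys)
    ests: list[ESTRecord] = []

    if n_planted:
        replace = n_planted > len(refs)
        chosen = rng.choice(len(refs), size=n_planted, replace=replace)
        for i, ri in enumerate([int(r) for r in chosen]):
            ref = refs[ri]
            arm = str(rng.choice(["5p", "3p"]))
            prec, offset, _ = plant_precursor(
                ref, rng, arm=arm, model=model, thresholds=thresholds,
            )
            est_len = int(rng.integers(300, 901))
            pos = int(rng.integers(0, est_len - len(prec) + 1))
            bg = _random_seq(rng, est_len, _DNA, gc)
            prec_dna = prec.replace("U", "T")
            est_seq = bg[:pos] + prec_dna + bg[pos + len(prec):]
            est_id = f"est_p{i + 1:04d}"
            ests.append(ESTRecord(est_id, est_seq))
            truth.planted_precursors.append(PlantedPrecursor(
                est_id, pos, pos + len(prec), ref.name, arm,
                pos + offset, pos + offset + ref.length,
            ))
    for i in range(n_decoys):
        n = decoy_len or int(rng.integers(300, 901))
        ests.append(ESTRecord(f"est_d{i + 1:04d}", _random_seq(rng, n, _DNA, gc)))
    return ests, truth


def generate_utr_set(
    mirnas: list[MatureMiRNA],
    n_genes: int,
    sites_per_mirna: int = 1,
    seed: int = 0,
    site_class: str = "I",
    gc: float = 0.42,
):
    """Random 3'UTRs (200-1500 nt) with planted target sites.

    Class I sites are the exact reverse complement of the full mature
    sequence; Class II sites are the reverse complement of the 12..(x-2)
    fragment.  Returns ``(utrs, truth)``.
    """
    if n_genes < 0 or sites_per_mirna < 0:
        raise ValueError("counts must be non-negative")
    rng = _rng(seed)
    truth = SyntheticTruth(seed=int(seed))
    seqs = [
        list(_random_seq(rng, int(rng.integers(200, 1501)), _RNA, gc))
        for _ in range(n_genes)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_genes)]
    if n_genes:
        for m in mirnas:
            insert = revcomp_rna(
                m.sequence if site_class == "I"
                else fragment_12_to_xminus2(m)
            )
            for _ in range(sites_per_mirna):
                g = int(rng.integers(0, n_genes))
                for _try in range(50):
                    p = int(rng.integers(0, len(seqs[g]) - len(insert) + 1))
                    span = (p, p + len(insert))
                    if all(span[1] <= a or span[0] >= b
                           for a, b in occupied[g]):
                        break
                else:   # pragma: no cover - dense plant fallback
                    continue
                seqs[g][span[0]:span[1]] = list(insert)
                occupied[g].append(span)
                truth.planted_sites.append(PlantedSite(
                    f"gene{g + 1:04d}", m.name, span[0], span[1], site_class,
                ))
    utrs = [
        UTRRecord(f"gene{g + 1:04d}", "".join(s))
        for g, s in enumerate(seqs)
    ]
    return utrs, truth


def generate_intensity_table(
    class_spec: dict[str, str],
    samples=("pooled",),
    noise_cv: float = 0.0,
    seed: int = 0,
    control: str = "U6snRNA",
    control_level: float = 1000.0,
):
    """Band-intensity table realizing intended per-miRNA fold classes.

    The control row is constant; each miRNA value is its class-
    representative ratio times the control level times multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` (mean 1).
    Returns ``(DataFrame, truth)``.
    """
    import pandas as pd

    rng = _rng(seed)
    truth = SyntheticTruth(seed=int(seed), intensity_classes=dict(class_spec))
    rows = {}
    sigma = float(np.sqrt(np.log(1.0 + noise_cv ** 2)))
    for name, label in class_spec.items():
        if label not in CLASS_RATIOS:
            raise ValueError(f"unknown fold class {label!r} for {name}")
        base = CLASS_RATIOS[label] * control_level
        if sigma > 0:
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(samples))
        else:
            noise = np.ones(len(samples))
        rows[name] = base * noise
    rows[control] = np.full(len(samples), control_level)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    return df, truth


@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    precision: float
    decoy_false_accept: float
    n_recovered: int
    n_planted: int
    n_accepted: int


def score_recovery(accepted, truth: SyntheticTruth) -> RecoveryScore:
    """Score pipeline output against planted truth.

    A planted precursor is recovered iff an accepted candidate on the same
    EST overlaps its window by at least 50% of the planted length;
    ``decoy_false_accept`` is the fraction of decoy ESTs carrying any
    accepted candidate.
    """
    planted_ids = truth.planted_est_ids
    known = planted_ids | {
        f"est_d{i + 1:04d}" for i in range(truth.n_decoys)
    }
    for a in accepted:
        if a.est_id not in known:
            raise ValueError(f"unknown EST id {a.est_id!r} in output")

    recovered = 0
    matched_accepted: set[int] = set()
    for p in truth.planted_precursors:
        need = 0.5 * (p.end - p.start)
        hit = False
        for k, a in enumerate(accepted):
            if a.est_id != p.est_id:
                continue
            ov = min(a.win_end, p.end) - max(a.win_start, p.start)
            if ov >= need:
                hit = True
                matched_accepted.add(k)
        recovered += hit
    n_planted = len(truth.planted_precursors)
    n_acc = len(accepted)
    sens = recovered / n_planted if n_planted else 1.0
    prec = len(matched_accepted) / n_acc if n_acc else 1.0
    decoy_ests = {
        a.est_id for a in accepted if a.est_id not in planted_ids
    }
    dfa = len(decoy_ests) / truth.n_decoys if truth.n_decoys else 0.0
    return RecoveryScore(sens, prec, dfa, recovered, n_planted, n_acc)


def score_site_recovery(results, truth: SyntheticTruth) -> float:
    """Fraction of planted sites recovered (exact gene, >= 1 nt overlap)."""
    if not truth.planted_sites:
        return 1.0
    hit = 0
    for s in truth.planted_sites:
        for r in results:
            if (r.gene_id == s.gene_id and r.mirna_name == s.mirna_name
                    and min(r.site_end, s.end) > max(r.site_start, s.start)):
                hit += 1
                break
    return hit / len(truth.planted_sites)
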