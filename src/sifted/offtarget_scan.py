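"""Off-target pipeline: site enumeration, genome scanning, candidate ranking.

Given an anchored energy matrix, every DNA sequence whose total ddG stays
under ln(relative-Kd threshold) is enumerated by a bounded breadth-first
search over site positions, pruning any prefix whose accumulated energy plus
the best-case (column-minimum) remainder already exceeds the bound.  All
exact genomic occurrences of the enumerated sites are then located on both
strands.  A candidate TALE is summarized by the occupancy-proportional score

    summary = sum over off-target hits of 1 / relative_Kd,

which grows with both the number and the strength of genomic off-targets
(lower is better); the intended locus is excluded by coordinate identity.
TALEN pairs are scored with the negative-log-PWM ratio scheme: per monomer,
partial = (S_optimal / S_site) ** 0.6 with S(site) = sum_j -ln p_j(base_j),
and the pair total is the sum of the two partials (optimal-vs-optimal = 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy_model import BASES, EnergyMatrix, PWM, relative_kd, site_ddg
from .tale_core import TALEProtein, TargetSite, protein_from_site

__all__ = [
    "EnumeratedSite",
    "GenomicHit",
    "CandidateReport",
    "PairScore",
    "enumerate_sites",
    "scan_genome",
    "naive_scan",
    "summary_score",
    "design_pipeline",
    "talen_pair_score",
    "roc_curve",
    "correlation_metrics",
    "reverse_complement",
    "hits_to_bed",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnumeratedSite:
    sequence: str
    ddg: float
    rel_kd: float


@dataclass(frozen=True)
class GenomicHit:
    chrom: str
    start: int          # 0-based half-open
    end: int
    strand: str         # "+" | "-"
    matched_sequence: str
    rel_kd: float


@dataclass
class CandidateReport:
    protein: TALEProtein
    intended_site: str
    location: tuple[str, int, str]      # (chrom, start, strand) within the region's genome
    summary_score: float
    hits: list[GenomicHit]


@dataclass(frozen=True)
class PairScore:
    left_score: float
    right_score: float

    @property
    def total(self) -> float:
        return self.left_score + self.right_score


# ---- enumeration --------------------------------------------------------

def enumerate_sites(em: EnergyMatrix, kd_threshold: float = 10.0) -> list[EnumeratedSite]:
    """All sites with relative Kd <= threshold, i.e. ddG <= ln(threshold).

    Bounded breadth-first search position by position; a partial prefix is
    pruned when its energy plus the sum of the remaining column minima
    exceeds the bound.  Sites exactly at the threshold are included.
    """
    if not em.is_anchored:
        raise ValueError("energy matrix must be anchored (canonical site at 0)")
    if kd_threshold < 1:
        raise ValueError("kd_threshold must be >= 1")
    bound = float(np.log(kd_threshold))
    suffix_min = em.column_min_sumsuffix()
    # frontier of (prefix, energy-so-far), expanded one column at a time
    frontier: list[tuple[str, float]] = [("", 0.0)]
    eps = 1e-12  # absorb FP summation error at the exact threshold boundary
    for j in range(em.length):
        nxt = []
        col = em.values[j]
        rest = suffix_min[j + 1]
        for prefix, e in frontier:
            for bi, base in enumerate(BASES):
                e2 = e + col[bi]
                if e2 + rest <= bound + eps:
                    nxt.append((prefix + base, e2))
        frontier = nxt
    out = [
        EnumeratedSite(sequence=s, ddg=e, rel_kd=relative_kd(e))
        for s, e in frontier
        if e <= bound + eps
    ]
    out.sort(key=lambda s: (s.ddg, s.sequence))
    return out


# ---- genome scan --------------------------------------------------------

def scan_genome(
    sites: list[EnumeratedSite] | list[str],
    genome: dict[str, str],
) -> list[GenomicHit]:
    """Every exact occurrence of every site on both strands of the genome.

    Coordinates are 0-based half-open on the forward strand; minus-strand
    hits report the forward-strand footprint, with ``matched_sequence``
    equal to the reverse complement of the genomic substring (the site as
    bound).  Non-ACGT genome characters never match.  Implemented as a
    rolling fixed-width window with hash-set lookup (all sites share one
    length), which is exact multi-pattern matching; :func:`naive_scan` is
    the independent oracle.
    """
    kd_map, length = _site_map(sites)
    fwd = set(kd_map)
    rc_map = {reverse_complement(s): s for s in kd_map}
    hits: list[GenomicHit] = []
    for chrom, seq in genome.items():
        s = seq.upper()
        for i in range(len(s) - length + 1):
            window = s[i : i + length]
            if window in fwd:
                hits.append(
                    GenomicHit(chrom, i, i + length, "+", window, kd_map[window])
                )
            if window in rc_map:
                site = rc_map[window]
                hits.append(
                    GenomicHit(chrom, i, i + length, "-", site, kd_map[site])
                )
    return hits


def naive_scan(
    sites: list[EnumeratedSite] | list[str],
    genome: dict[str, str],
) -> list[GenomicHit]:
    """Reference sliding-window scan, one pattern at a time (test oracle)."""
    kd_map, length = _site_map(sites)
    hits = []
    for chrom, seq in genome.items():
        s = seq.upper()
        for site, kd in kd_map.items():
            rc = reverse_complement(site)
            for i in range(len(s) - length + 1):
                if s[i : i + length] == site:
                    hits.append(GenomicHit(chrom, i, i + length, "+", site, kd))
                if s[i : i + length] == rc:
                    hits.append(GenomicHit(chrom, i, i + length, "-", site, kd))
    return hits


def _site_map(sites) -> tuple[dict[str, float], int]:
    if not sites:
        raise ValueError("empty site set")
    kd_map: dict[str, float] = {}
    for s in sites:
        if isinstance(s, EnumeratedSite):
            kd_map[s.sequence.upper()] = s.rel_kd
        else:
            kd_map[str(s).upper()] = float("nan")
    lengths = {len(s) for s in kd_map}
    if len(lengths) != 1:
        raise ValueError(f"site sequences must all have equal length, got {sorted(lengths)}")
    return kd_map, lengths.pop()


def hits_to_bed(hits: list[GenomicHit]) -> str:
    """BED6: score = min(1000, round(1000 / rel_kd)), name = site sequence."""
    lines = []
    for h in hits:
        score = 1000 if not np.isfinite(h.rel_kd) else min(1000, round(1000 / h.rel_kd))
        lines.append(
            f"{h.chrom}\t{h.start}\t{h.end}\t{h.matched_sequence}\t{score}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---- scoring ------------------------------------------------------------

def summary_score(hits: list[GenomicHit]) -> float:
    """Occupancy-proportional off-target burden: sum of 1 / rel_kd.

    Each term lies in (0, 1] (for rel_kd >= 1); the empty hit set scores 0;
    every added hit strictly increases the score.  Intended-site hits must
    already be excluded.
    """
    return float(sum(1.0 / h.rel_kd for h in hits))


def design_pipeline(
    region: dict[str, str],
    genome: dict[str, str],
    model,
    repeat_count: int,
    kd_threshold: float = 10.0,
    region_location: tuple[str, int] | None = None,
) -> list[CandidateReport]:
    """Rank every candidate TALE that can target the region by off-target burden.

    Candidate sites are all windows of length ``repeat_count + 1`` starting
    with T, on both strands of the region.  For each, the targeting protein
    is derived by the canonical code, its energy matrix predicted from the
    context model, near-optimal sites enumerated under the relative-Kd
    threshold and located in the genome; the candidate's intended locus is
    excluded from the summary score by coordinate identity (sequence-
    identical loci elsewhere still count).  Candidates are returned sorted
    ascending by score (best first).

    ``region_location`` maps the region's first sequence to genome
    coordinates (chrom, start); when omitted, a unique exact match of the
    region in the genome is searched for.  Without any location the
    intended locus cannot be excluded and a warning is logged.
    """
    from .sifted_model import predict_em

    if not region:
        raise ValueError("empty region")
    region_name, region_seq = next(iter(region.items()))
    region_seq = region_seq.upper()
    site_len = repeat_count + 1
    loc = region_location or _locate_region(region_seq, genome)
    if loc is None:
        logger.warning(
            "region not located in genome; intended loci cannot be excluded"
        )

    reports: list[CandidateReport] = []
    for strand in "+-":
        seq = region_seq if strand == "+" else reverse_complement(region_seq)
        for off in range(len(seq) - site_len + 1):
            window = seq[off : off + site_len]
            if not window.startswith("T") or any(c not in "ACGT" for c in window):
                continue
            protein = protein_from_site(window, protein_id=f"cand_{strand}{off}")
            em, _ = predict_em(protein, model)
            sites = enumerate_sites(em.anchored(), kd_threshold)
            hits = scan_genome(sites, genome)
            if loc is not None:
                chrom0, start0 = loc
                if strand == "+":
                    g_start = start0 + off
                else:
                    g_start = start0 + len(region_seq) - site_len - off
                hits = [
                    h for h in hits
                    if not (h.chrom == chrom0 and h.start == g_start and h.strand == strand)
                ]
                location = (chrom0, g_start, strand)
            else:
                location = (region_name, off, strand)
            reports.append(
                CandidateReport(
                    protein=protein,
                    intended_site=window,
                    location=location,
                    summary_score=summary_score(hits),
                    hits=hits,
                )
            )
    if not reports:
        logger.warning("no candidate sites (no T-initiated window on either strand)")
    reports.sort(key=lambda r: (r.summary_score, r.location))
    return reports


def _locate_region(region_seq: str, genome: dict[str, str]) -> tuple[str, int] | None:
    matches = []
    for chrom, seq in genome.items():
        s = seq.upper()
        start = s.find(region_seq)
        while start != -1:
            matches.append((chrom, start))
            start = s.find(region_seq, start + 1)
    if len(matches) == 1:
        return matches[0]
    return None


def talen_pair_score(
    pwm_left: PWM,
    pwm_right: PWM,
    site_left: str,
    site_right: str,
    exponent: float = 0.6,
    optimal: str = "argmax",
) -> PairScore:
    """Pair score: per monomer (S_optimal / S_site) ** exponent, summed.

    S(site) = sum_j -ln p_j(base_j); the optimal site is the PWM's
    max-probability sequence (``optimal="argmax"``).  Both partials lie in
    (0, 1] and the optimal-vs-optimal total is exactly 2.
    """

    def partial(pwm: PWM, site: str) -> float:
        if len(site) != pwm.length:
            raise ValueError("site length does not match PWM length")
        if np.any(pwm.probs <= 0):
            raise ValueError("zero-probability PWM entry; log score undefined")
        if optimal == "argmax":
            opt = pwm.consensus()
        else:
            opt = optimal  # caller-supplied optimal site
        s_opt = pwm.neg_log_score(opt)
        s_site = pwm.neg_log_score(site)
        return float((s_opt / s_site) ** exponent)

    return PairScore(partial(pwm_left, site_left), partial(pwm_right, site_right))


# ---- evaluation ---------------------------------------------------------

def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Sensitivity/specificity at every distinct score threshold, plus AUC.

    Higher scores predict the positive class; tied scores are grouped.
    Returns (sensitivity, specificity, auc), the curve ordered from the
    strictest to the loosest threshold, endpoints included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    distinct = np.r_[np.diff(s) != 0, True]  # last index of each tie group
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return tpr, 1.0 - fpr, auc


def correlation_metrics(predicted, observed, mode: str = "log_pearson") -> float:
    """Pearson r on natural-log values, or Spearman rho with average ranks.

    The log mode suits relative-Kd comparisons spanning orders of magnitude;
    the rank mode suits nonlinear readouts such as reporter expression.
    """
    from scipy import stats

    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if mode == "log_pearson":
        if np.any(predicted <= 0) or np.any(observed <= 0):
            raise ValueError("log mode requires strictly positive values")
        return float(stats.pearsonr(np.log(predicted), np.log(observed))[0])
    if mode == "spearman":
        return float(stats.spearmanr(predicted, observed)[0])
    raise ValueError(f"unknown mode {mode!r}")


# ---- FASTA helpers ------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) as an ordered name->sequence map."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
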