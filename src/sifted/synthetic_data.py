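"""Synthetic panels, energy matrices, PBM tables and genomes.

Everything the inference stack consumes can be simulated with the
statistical structure the models assume, so the full pipeline is testable
without microarray downloads:

* ``simulate_panel`` draws TALE proteins over a repeat-length range; with
  pair coverage on, the panel is guaranteed to contain all 16 ordered
  adjacent RVD pairs (an Eulerian circuit over the complete 4-node digraph
  is threaded through the first proteins), mirroring how measurement panels
  are chosen so every direct neighbour effect is observable.
* ``TruthContextModel`` holds planted ground-truth coefficients in the same
  vocabulary as the predictive context model (baseline per (type, base),
  linear/log position and length slopes, per-side neighbour adjustments);
  ``truth_em`` assembles a protein's anchored energy matrix from them.
  Default directions follow what quantitative TALE profiling shows: longer
  proteins and 3'-positioned repeats are less specific, NN and NG respond
  more strongly to length than NI and HD.
* ``simulate_pbm`` turns a probe set into replicate two-channel intensity
  records: occupancy -> z -> spot intensity with replicate Gaussian noise,
  optional outlier spikes, a Cy3 channel generated from a known
  trinucleotide linear model modulated by per-spot dsDNA abundance, and a
  block of unbound background probes.
* ``simulate_genome`` writes i.i.d. background sequence at a chosen GC
  content with known sites planted at known loci and strands.

All randomness flows from a single seed through a splittable generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import BASE_INDEX, BASES, EnergyMatrix, canonical_anchors
from .pbm_quantify import MAD_TO_SD, ProbeRecord, trinucleotide_counts
from .probe_design import ProbeSet, dinuc_substitution_probes, embed_in_flanks
from .sifted_model import ANCHOR_BASE, RowSpec, element_rows, _nonanchored
from .tale_core import CTR, NTR, RVD_CODES, TALEProtein
from .ddg_inference import _sigmoid

__all__ = [
    "TruthContextModel",
    "SimulationConfig",
    "simulate_panel",
    "truth_em",
    "simulate_pbm",
    "simulate_experiment",
    "simulate_genome",
    "default_truth",
]


@dataclass
class TruthContextModel:
    """Planted ground-truth coefficients for generating energy matrices.

    Keys of ``baseline`` are (element_type, base); position/length slopes are
    per (repeat type, base); ``neighbour`` maps (type, base, neighbour, side)
    to an additive ddG adjustment.  ``noise_sd`` is per-entry Gaussian
    scatter; entries are clipped below at ``floor`` (non-anchored bases stay
    disfavoured relative to the anchor unless a planted effect drives them
    down deliberately).
    """

    baseline: dict[tuple[str, str], float]
    pos_coef: dict[tuple[str, str], float] = field(default_factory=dict)
    lnpos_coef: dict[tuple[str, str], float] = field(default_factory=dict)
    len_coef: dict[tuple[str, str], float] = field(default_factory=dict)
    lnlen_coef: dict[tuple[str, str], float] = field(default_factory=dict)
    neighbour: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.25
    floor: float = 0.3

    def expected_ddg(self, row: RowSpec) -> float:
        """Noise-free ddG for one (element, base) slot, before flooring."""
        t, b = row.element_type, row.base
        v = self.baseline[(t, b)]
        if t != NTR and row.position is not None:
            p, L = row.position, row.site_length
            v += self.pos_coef.get((t, b), 0.0) * p
            v += self.lnpos_coef.get((t, b), 0.0) * np.log(p)
            v += self.len_coef.get((t, b), 0.0) * L
            v += self.lnlen_coef.get((t, b), 0.0) * np.log(L)
        if row.n_neighbour is not None:
            v += self.neighbour.get((t, b, row.n_neighbour, "N"), 0.0)
        if row.c_neighbour is not None:
            v += self.neighbour.get((t, b, row.c_neighbour, "C"), 0.0)
        return float(v)


def default_truth(noise_sd: float = 0.25) -> TruthContextModel:
    """Plausible planted coefficients (RT units).

    Baselines: every repeat disfavours non-anchored bases by ~2-4 RT, with
    HD strongly rejecting G and NN only weakly rejecting A (it can target
    both G and A).  Length and position slopes are negative (longer proteins
    and 3' repeats are less specific), stronger for NN and NG.  A handful of
    neighbour adjustments are planted, including reduced NN specificity at
    the C-terminal end and increased NI specificity next to NI.
    """
    baseline = {
        (NTR, "A"): 2.0, (NTR, "C"): 2.2, (NTR, "G"): 2.4,
        ("NI", "C"): 2.6, ("NI", "G"): 2.9, ("NI", "T"): 2.4,
        ("HD", "A"): 2.8, ("HD", "G"): 4.2, ("HD", "T"): 2.3,
        ("NN", "A"): 1.0, ("NN", "C"): 2.7, ("NN", "T"): 2.9,
        ("NG", "A"): 2.3, ("NG", "C"): 2.2, ("NG", "G"): 2.7,
    }
    pos_coef = {}
    len_coef = {}
    for t, slope_p, slope_l in (
        ("NI", -0.03, -0.03),
        ("HD", -0.03, -0.03),
        ("NN", -0.07, -0.08),
        ("NG", -0.06, -0.07),
    ):
        for b in _nonanchored(t):
            pos_coef[(t, b)] = slope_p
            len_coef[(t, b)] = slope_l
    neighbour = {}
    for b in _nonanchored("NN"):
        neighbour[("NN", b, CTR, "C")] = -0.6   # NN loses specificity at the C end
        neighbour[("NN", b, "NI", "N")] = 0.5   # and gains it next to NI
        neighbour[("NN", b, "NI", "C")] = 0.4
    for b in _nonanchored("NI"):
        neighbour[("NI", b, "NI", "N")] = 0.4   # A-runs are targeted specifically
        neighbour[("NI", b, "NG", "N")] = -0.4  # NG as N-neighbour hurts
    for b in _nonanchored(NTR):
        neighbour[(NTR, b, "NN", "C")] = 0.5    # 5' T matters more before NN
    return TruthContextModel(
        baseline=baseline, pos_coef=pos_coef, len_coef=len_coef,
        neighbour=neighbour, noise_sd=noise_sd,
    )


@dataclass
class SimulationConfig:
    """Study conditions for simulated PBM experiments.

    The occupancy-model truth places the optimal site near saturation
    (mu = 3, i.e. [TF] ~ 20x the optimal-site Kd, as for a strong TALE at
    assay concentrations) with z-scores spanning roughly a = 0 (unbound) to
    b = 30 (saturated).  Replicate noise of 1 z-score unit per spot and 8
    replicate spots per probe reflect clean custom arrays.
    """

    panel_size: int = 6
    min_repeats: float = 8.5
    max_repeats: float = 18.5
    pair_coverage: bool = True
    mu: float = 3.0
    a: float = 0.0
    b: float = 30.0
    z_noise_sd: float = 1.0
    replicates: int = 8
    outlier_rate: float = 0.01
    outlier_scale: float = 10.0        # spike size in replicate-noise robust sd units
    n_background: int = 60
    bsi_baseline: float = 1000.0       # background spot intensity level
    bsi_scale: float = 100.0           # intensity units per z-score unit
    dsdna_sd: float = 0.05             # lognormal sd of per-spot dsDNA abundance
    cy3_noise_sd: float = 0.02         # relative Cy3 measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.panel_size < 2:
            raise ValueError("panel_size must be >= 2")
        for name in ("bsi_scale", "outlier_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---- protein panels -----------------------------------------------------

def _eulerian_pair_circuit(rng: np.random.Generator) -> list[str]:
    """A repeat-type sequence traversing all 16 ordered adjacent pairs once.

    Hierholzer's algorithm on the complete digraph (with self-loops) over the
    four RVDs; every node has in-degree = out-degree = 4, so an Eulerian
    circuit of 17 node visits exists.
    """
    remaining = {t: [u for u in RVD_CODES] for t in RVD_CODES}
    for t in remaining:
        rng.shuffle(remaining[t])
    start = RVD_CODES[int(rng.integers(4))]
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if remaining[v]:
            stack.append(remaining[v].pop())
        else:
            circuit.append(stack.pop())
    return circuit[::-1]


def simulate_panel(config: SimulationConfig) -> list[TALEProtein]:
    """Draw a protein panel; with pair coverage, all 16 ordered RVD pairs occur."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lo = int(config.min_repeats + 0.5)          # element count includes the half-repeat
    hi = int(config.max_repeats + 0.5)
    if hi < lo:
        raise ValueError("max_repeats < min_repeats")

    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.panel_size)]
    proteins: list[list[str]] = [
        [RVD_CODES[i] for i in rng.integers(0, 4, size=k)] for k in lengths
    ]
    if config.pair_coverage:
        capacity = sum(k - 1 for k in lengths)
        if capacity < 16:
            need = 2
            raise ValueError(
                f"pair coverage infeasible: panel offers {capacity} adjacent "
                f"pairs < 16; need at least {need} proteins of "
                f"{config.max_repeats} repeats (or a larger panel)"
            )
        circuit = _eulerian_pair_circuit(rng)    # 17 elements, 16 pairs
        i = 0                                    # thread the circuit through the panel
        pos = 0
        while pos < len(circuit) - 1:
            k = lengths[i]
            chunk = circuit[pos : pos + k]
            proteins[i][: len(chunk)] = chunk
            pos += len(chunk) - 1                # overlap one element to keep the seam pair
            i += 1
    return [
        TALEProtein(id=f"sim{i:02d}", repeats=tuple(reps))
        for i, reps in enumerate(proteins)
    ]


# ---- truth energy matrices ----------------------------------------------

def truth_em(
    protein: TALEProtein,
    truth: TruthContextModel,
    seed: int = 0,
) -> EnergyMatrix:
    """Anchored EM assembled from planted coefficients plus seeded noise."""
    rng = np.random.default_rng(seed)
    values = np.zeros((protein.site_length, 4))
    for row in element_rows(protein):
        v = truth.expected_ddg(row)
        if truth.noise_sd > 0:
            v += truth.noise_sd * rng.standard_normal()
        values[row.element_index, BASE_INDEX[row.base]] = max(v, truth.floor)
    return EnergyMatrix(values=values, anchors=canonical_anchors(protein))


# ---- PBM simulation -----------------------------------------------------

def _normalized_scatter(n: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal draws rescaled to exact median 0 and robust sd 1, so
    simulated background probes define the z-score origin and unit exactly."""
    x = rng.standard_normal(n)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return (x - med) / (MAD_TO_SD * mad)


def simulate_pbm(
    protein: TALEProtein,
    em: EnergyMatrix,
    config: SimulationConfig,
    probe_set: ProbeSet | None = None,
    seed: int | None = None,
) -> tuple[list[ProbeRecord], dict[str, str]]:
    """Replicate two-channel probe records for one protein/array experiment.

    Foreground probes come from ``probe_set`` (dinucleotide-substitution set
    by default), back-transformed from the occupancy model through the
    intensity scale; a background block of unrelated 60-mers (designed for
    other proteins, unbound by this one) is appended.  Returns the records
    and a probe_id -> variant site map for the foreground probes.
    """
    from .energy_model import site_ddg
    from .tale_core import canonical_target_site

    rng = np.random.default_rng(config.seed if seed is None else seed)
    if probe_set is None:
        probe_set = dinuc_substitution_probes(canonical_target_site(protein))
    n_site = len(probe_set.reference)
    pad = 60 - n_site
    flank5 = "".join(rng.choice(list("ACGT"), size=pad // 2))
    flank3 = "".join(rng.choice(list("ACGT"), size=pad - pad // 2))
    probe_set = embed_in_flanks(probe_set, flank5, flank3, probe_length=60)

    # known trinucleotide linear model for the Cy3 (dsDNA) channel
    cy3_coef = 8.0 + 4.0 * rng.random(64)

    sd_rep = config.bsi_scale * config.z_noise_sd
    records: list[ProbeRecord] = []
    variant_map: dict[str, str] = {}

    def make_record(pid: str, seq: str, z_true: float, role: str) -> ProbeRecord:
        r_ds = float(np.exp(config.dsdna_sd * rng.standard_normal())) if config.dsdna_sd > 0 else 1.0
        base_bsi = config.bsi_baseline + config.bsi_scale * z_true
        alexa = r_ds * base_bsi + sd_rep * rng.standard_normal(config.replicates)
        if config.outlier_rate > 0 and sd_rep > 0:
            spikes = rng.random(config.replicates) < config.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=config.replicates)
            alexa = alexa + spikes * signs * config.outlier_scale * sd_rep
        cy3_expected = float(trinucleotide_counts(seq) @ cy3_coef)
        cy3 = r_ds * cy3_expected * (
            1.0 + config.cy3_noise_sd * rng.standard_normal(config.replicates)
        )
        return ProbeRecord(pid, seq, alexa, cy3, role)

    for entry in probe_set.entries:
        e = site_ddg(em, entry.site_sequence)
        occ = float(_sigmoid(config.mu - e))
        z_true = config.a + (config.b - config.a) * occ
        pid = f"{protein.id}_{entry.probe_id}"
        records.append(make_record(pid, entry.probe_sequence, z_true, "foreground"))
        variant_map[pid] = entry.site_sequence

    bg_eps = _normalized_scatter(config.n_background, rng)
    for i in range(config.n_background):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        records.append(make_record(f"bg{i:03d}", seq, float(bg_eps[i]), "background"))
    return records, variant_map


def simulate_experiment(
    protein: TALEProtein,
    em: EnergyMatrix,
    config: SimulationConfig,
    seed: int | None = None,
    **quantify_kwargs,
) -> dict[str, float]:
    """Simulate + quantify in one step: variant site -> z-score map."""
    from .pbm_quantify import quantify_experiment

    records, variant_map = simulate_pbm(protein, em, config, seed=seed)
    quantified, _removed = quantify_experiment(records, **quantify_kwargs)
    out = {}
    for q in quantified:
        site = variant_map.get(q.probe_id)
        if site is not None and np.isfinite(q.zscore):
            out[site] = q.zscore
    return out


# ---- genomes ------------------------------------------------------------

def simulate_genome(
    length: int,
    gc: float = 0.5,
    planted: list[tuple[str, int, str]] | None = None,
    seed: int = 0,
    name: str = "chrSim",
) -> dict[str, str]:
    """i.i.d. background at the given GC content with sites planted at loci.

    ``planted`` holds (sequence, start, strand) triples; minus-strand plants
    write the reverse complement at the forward coordinates.  Overlapping
    plants are rejected.
    """
    from .offtarget_scan import reverse_complement

    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(list("ACGT"), size=length, p=p)
    occupied: list[tuple[int, int]] = []
    for site, start, strand in planted or []:
        end = start + len(site)
        if start < 0 or end > length:
            raise ValueError(f"planted site at {start} does not fit in length {length}")
        for s0, e0 in occupied:
            if start < e0 and s0 < end:
                raise ValueError(f"planted sites overlap at [{start}, {end})")
        occupied.append((start, end))
        written = site if strand == "+" else reverse_complement(site)
        seq[start:end] = list(written.upper())
    return {name: "".join(seq)}
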