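"""Robust quantification of raw PBM spot intensities into per-probe z-scores.

Pipeline (per experiment):

1. ``apply_pseudocount`` — if any background-subtracted intensity (BSI) in a
   channel is negative, shift every BSI in that channel by one constant so
   the minimum becomes +1.
2. ``cy3_normalize`` — the Cy3 channel tracks double-stranded DNA content per
   spot, but Cy3 incorporation depends on local sequence; an OLS regression
   of observed Cy3 on the 64 trinucleotide counts of each probe gives the
   expected Cy3, and the expected/observed ratio rescales the Alexa488 BSIs.
   Probes corrected by more than twofold (factor > 2 or < 0.5), or whose
   adjusted BSI would be negative, are removed.
3. ``aggregate_replicates`` — per probe, median and MAD of replicate BSIs;
   robust sd = 1.4826 * MAD; replicates further than 3 robust sd from the
   median are dropped and the median recomputed over survivors.
4. ``background_zscores`` — z = (median_bsi - m) / s where m and s are the
   median and 1.4826 * MAD of the background probe set (probes designed for
   other proteins).  The z-scores are a positive affine transform of the
   median intensities, so the downstream energy fit (which does its own
   linear scaling) is unaffected by the choice of units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "ProbeRecord",
    "QuantifiedProbe",
    "apply_pseudocount",
    "cy3_normalize",
    "aggregate_replicates",
    "background_zscores",
    "quantify_experiment",
    "load_probe_table",
    "quantified_to_frame",
    "MAD_TO_SD",
]

#: Asymptotic Normal-consistency factor: sd ~= 1.4826 * MAD.
MAD_TO_SD = 1.4826

TRINUCS = ["".join(t) for t in product("ACGT", repeat=3)]
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCS)}


@dataclass
class ProbeRecord:
    probe_id: str
    sequence: str
    alexa_bsi: np.ndarray
    cy3_bsi: np.ndarray
    role: str = "foreground"  # "foreground" | "background"

    def __post_init__(self) -> None:
        self.alexa_bsi = np.asarray(self.alexa_bsi, dtype=float)
        self.cy3_bsi = np.asarray(self.cy3_bsi, dtype=float)
        if self.alexa_bsi.size < 1:
            raise ValueError(f"probe {self.probe_id}: need >= 1 replicate")
        if self.role not in ("foreground", "background"):
            raise ValueError(f"probe {self.probe_id}: unknown role {self.role!r}")


@dataclass
class QuantifiedProbe:
    probe_id: str
    sequence: str
    role: str
    median_bsi: float
    mad: float
    robust_sd: float
    n_used: int
    zscore: float = np.nan


def apply_pseudocount(records: list[ProbeRecord]) -> list[ProbeRecord]:
    """Shift all BSIs of a channel by one constant if any are negative.

    The shift makes the channel minimum +1; applied per experiment (the whole
    record list) and per channel, never per probe, so ordering is preserved.
    """
    if not records:
        return records
    out = [replace(r) for r in records]
    for channel in ("alexa_bsi", "cy3_bsi"):
        values = [getattr(r, channel) for r in out if getattr(r, channel).size]
        if not values:
            continue
        lo = min(float(v.min()) for v in values)
        if lo < 0:
            shift = 1.0 - lo
            for r in out:
                setattr(r, channel, getattr(r, channel) + shift)
    return out


def trinucleotide_counts(sequence: str) -> np.ndarray:
    """Counts of each of the 64 trinucleotides in a probe sequence."""
    counts = np.zeros(len(TRINUCS))
    seq = sequence.upper()
    for i in range(len(seq) - 2):
        idx = TRINUC_INDEX.get(seq[i : i + 3])
        if idx is not None:
            counts[idx] += 1
    return counts


def cy3_normalize(
    records: list[ProbeRecord],
    fold_limit: float = 2.0,
    min_probes: int = 64,
) -> tuple[list[ProbeRecord], list[str]]:
    """Correct Alexa BSIs for dsDNA content via the Cy3 trinucleotide model.

    The per-probe correction factor is f = expected / observed Cy3, where the
    expected value comes from an OLS fit of observed Cy3 on trinucleotide
    counts.  Alexa replicates are multiplied by f.  Probes with f > 2 or
    f < 0.5, or whose adjustment would make the BSI negative, are removed and
    their ids returned.
    """
    with_cy3 = [r for r in records if r.cy3_bsi.size]
    if len(with_cy3) < min_probes:
        raise ValueError(
            f"Cy3 regression needs >= {min_probes} probes with Cy3 values for "
            f"identifiability; got {len(with_cy3)} — use a larger probe set"
        )
    X = np.array([trinucleotide_counts(r.sequence) for r in with_cy3])
    y = np.array([float(np.median(r.cy3_bsi)) for r in with_cy3])
    # min-norm least squares; trinucleotide counts are collinear (they sum to
    # len(seq)-2 for fixed-length probes) so coefficients are identified only
    # up to the null space, but fitted values are unique
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    expected = {r.probe_id: float(x @ coef) for r, x in zip(with_cy3, X)}

    kept: list[ProbeRecord] = []
    removed: list[str] = []
    for r in records:
        if not r.cy3_bsi.size:
            kept.append(replace(r))
            continue
        observed = float(np.median(r.cy3_bsi))
        exp = expected[r.probe_id]
        if observed == 0:
            removed.append(r.probe_id)
            continue
        f = exp / observed
        adjusted = r.alexa_bsi * f
        if f > fold_limit or f < 1.0 / fold_limit or np.any(adjusted < 0):
            removed.append(r.probe_id)
            continue
        kept.append(replace(r, alexa_bsi=adjusted))
    return kept, removed


def aggregate_replicates(
    record: ProbeRecord,
    n_sd: float = 3.0,
    use_robust_sd: bool = True,
    zero_mad: str = "strict",
) -> QuantifiedProbe:
    """Median / MAD summary with a 3-sd replicate outlier filter.

    Replicates further than ``n_sd`` robust sd (1.4826 * MAD) from the median
    are dropped and the median recomputed over the survivors.  When MAD = 0
    the rule is undefined; ``zero_mad="strict"`` drops every replicate that
    differs from the median, ``zero_mad="sd"`` falls back to the plain
    standard deviation.  ``use_robust_sd=False`` uses the plain sd throughout.
    """
    x = record.alexa_bsi
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    robust_sd = MAD_TO_SD * mad
    scale = robust_sd if use_robust_sd else float(np.std(x))
    if scale == 0:
        if zero_mad == "strict":
            keep = x == med
        elif zero_mad == "sd":
            sd = float(np.std(x))
            keep = np.abs(x - med) <= n_sd * sd if sd > 0 else np.ones_like(x, bool)
        else:
            raise ValueError(f"unknown zero_mad mode {zero_mad!r}")
    else:
        keep = np.abs(x - med) <= n_sd * scale
    n_used = int(keep.sum())
    median_bsi = float(np.median(x[keep])) if n_used else np.nan
    return QuantifiedProbe(
        probe_id=record.probe_id,
        sequence=record.sequence,
        role=record.role,
        median_bsi=median_bsi,
        mad=mad,
        robust_sd=robust_sd,
        n_used=n_used,
    )


def background_zscores(
    quantified: list[QuantifiedProbe],
    background_ids: set[str] | None = None,
    min_background: int = 20,
) -> list[QuantifiedProbe]:
    """z-score every probe against the background probe distribution.

    m and s are the median and 1.4826 * MAD of the background probes'
    median BSIs; z = (median_bsi - m) / s.  Positive affine rescaling of the
    raw intensities leaves the z-scores unchanged.
    """
    if background_ids is None:
        background_ids = {q.probe_id for q in quantified if q.role == "background"}
    bg = [q.median_bsi for q in quantified if q.probe_id in background_ids]
    bg = [b for b in bg if np.isfinite(b)]
    if len(bg) < min_background:
        raise ValueError(
            f"need >= {min_background} background probes, got {len(bg)}"
        )
    bg_arr = np.array(bg)
    m = float(np.median(bg_arr))
    s = MAD_TO_SD * float(np.median(np.abs(bg_arr - m)))
    if s == 0:
        raise ValueError("background robust sd is zero; z-scores undefined")
    out = []
    for q in quantified:
        z = (q.median_bsi - m) / s if np.isfinite(q.median_bsi) else np.nan
        out.append(replace_quant(q, zscore=z))
    return out


def replace_quant(q: QuantifiedProbe, **kw) -> QuantifiedProbe:
    d = dict(
        probe_id=q.probe_id,
        sequence=q.sequence,
        role=q.role,
        median_bsi=q.median_bsi,
        mad=q.mad,
        robust_sd=q.robust_sd,
        n_used=q.n_used,
        zscore=q.zscore,
    )
    d.update(kw)
    return QuantifiedProbe(**d)


def quantify_experiment(
    records: list[ProbeRecord],
    n_sd: float = 3.0,
    use_robust_sd: bool = True,
    zero_mad: str = "strict",
    skip_cy3: bool = False,
) -> tuple[list[QuantifiedProbe], list[str]]:
    """Full pipeline: pseudocount -> Cy3 normalization -> replicate
    aggregation -> background z-scores.  Returns quantified probes and the
    ids removed by the Cy3 twofold rule."""
    recs = apply_pseudocount(records)
    if skip_cy3 or not any(r.cy3_bsi.size for r in recs):
        removed: list[str] = []
    else:
        recs, removed = cy3_normalize(recs)
    quantified = [
        aggregate_replicates(r, n_sd=n_sd, use_robust_sd=use_robust_sd, zero_mad=zero_mad)
        for r in recs
    ]
    quantified = background_zscores(quantified)
    return quantified, removed


# ---- tabular I/O --------------------------------------------------------

def load_probe_table(path_or_buf) -> list[ProbeRecord]:
    """Read the long-format TSV: probe_id, sequence, channel, replicate, bsi,
    and an optional ``role`` column (foreground/background)."""
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"probe_id", "sequence", "channel", "replicate", "bsi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    records = []
    for (pid, seq), grp in df.groupby(["probe_id", "sequence"], sort=False):
        role = "foreground"
        if "role" in grp.columns:
            role = str(grp["role"].iloc[0])
        alexa = grp.loc[grp["channel"] == "alexa", "bsi"].to_numpy(float)
        cy3 = grp.loc[grp["channel"] == "cy3", "bsi"].to_numpy(float)
        records.append(ProbeRecord(str(pid), str(seq), alexa, cy3, role))
    return records


def quantified_to_frame(quantified: list[QuantifiedProbe]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [q.probe_id for q in quantified],
            "sequence": [q.sequence for q in quantified],
            "role": [q.role for q in quantified],
            "median_bsi": [q.median_bsi for q in quantified],
            "mad": [q.mad for q in quantified],
            "robust_sd": [q.robust_sd for q in quantified],
            "n_used": [q.n_used for q in quantified],
            "zscore": [q.zscore for q in quantified],
        }
    )
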