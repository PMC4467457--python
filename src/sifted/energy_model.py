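"""Energy matrices, Boltzmann PWMs, site energies and relative-Kd conversion.

An energy matrix (EM) stores, for every binding-site position and base, the
binding free-energy change ddG relative to the preferred (anchor) base, in RT
units.  Column 0 is the 5'-T / NTR contact.  An *anchored* matrix has the
anchor base at exactly 0 in every column; because anchoring is the canonical-
code base rather than the fitted argmin, other entries may be negative (NN
repeats can genuinely prefer A over G).

The Boltzmann counterpart is a position weight matrix (PWM) of per-position
base probabilities p(b) = exp(-ddG_b) / sum_b' exp(-ddG_b'); the PWM is
invariant to adding a per-column constant to the EM (gauge invariance).
Relative Kd of a site with energy ddG (RT units) is exp(ddG), with the
optimal site fixed at 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .tale_core import TALEProtein, TargetSite, RVD_TO_BASE, canonical_target_site

__all__ = [
    "BASES",
    "EnergyMatrix",
    "PWM",
    "normalize_em",
    "em_to_pwm",
    "site_ddg",
    "relative_kd",
    "canonical_anchors",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def canonical_anchors(protein: TALEProtein) -> np.ndarray:
    """Anchor base index per column: 5' T, then the canonical base per repeat."""
    site = canonical_target_site(protein).sequence
    return np.array([BASE_INDEX[b] for b in site], dtype=int)


@dataclass
class EnergyMatrix:
    """Per-position, per-base ddG values in RT units.

    ``values`` has shape (L, 4) with base order A, C, G, T; ``anchors`` holds
    the anchor (canonical-code) base index per column.
    """

    values: np.ndarray
    anchors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.anchors = np.asarray(self.anchors, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"EM values must be (L, 4), got {self.values.shape}")
        if self.anchors.shape != (self.values.shape[0],):
            raise ValueError("one anchor base per column required")
        if not np.all((self.anchors >= 0) & (self.anchors < 4)):
            raise ValueError("anchor indices must be in 0..3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EM entries must be finite")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def is_anchored(self) -> bool:
        return bool(
            np.allclose(self.values[np.arange(self.length), self.anchors], 0.0)
        )

    def anchored(self) -> "EnergyMatrix":
        return normalize_em(self)

    def to_pwm(self) -> "PWM":
        return em_to_pwm(self)

    def column_min_sumsuffix(self) -> np.ndarray:
        """Suffix sums of per-column minima; used to prune site enumeration."""
        mins = self.values.min(axis=1)
        out = np.zeros(self.length + 1)
        out[:-1] = np.cumsum(mins[::-1])[::-1]
        return out

    # ---- text I/O -------------------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# units=RT anchors=" + "".join(BASES[a] for a in self.anchors) + "\n")
        buf.write("pos\t" + "\t".join(str(j) for j in range(self.length)) + "\n")
        for i, b in enumerate(BASES):
            buf.write(b + "\t" + "\t".join(f"{v:.6g}" for v in self.values[:, i]) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "EnergyMatrix":
        anchors = None
        rows: dict[str, list[float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("anchors="):
                        anchors = np.array([BASE_INDEX[c] for c in tok[8:]])
                continue
            parts = line.split("\t")
            if parts[0] == "pos":
                continue
            if parts[0] in BASE_INDEX:
                rows[parts[0]] = [float(x) for x in parts[1:]]
        if set(rows) != set(BASES):
            raise ValueError("EM text must contain one row per base A,C,G,T")
        values = np.array([rows[b] for b in BASES]).T
        if anchors is None:
            anchors = np.argmin(values, axis=1)
        return cls(values=values, anchors=anchors)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "EnergyMatrix":
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass
class PWM:
    """Per-position base probabilities; each column sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM must be (L, 4), got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.probs <= 0) or np.any(self.probs > 1):
            raise ValueError("PWM entries must lie in (0, 1]")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Max-probability base per position (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def neg_log_score(self, site: str | TargetSite) -> float:
        """S(site) = sum_j -ln p_j(base_j); grows with disfavoured bases."""
        seq = str(site)
        if len(seq) != self.length:
            raise ValueError("site length does not match PWM length")
        idx = [BASE_INDEX[b] for b in seq]
        return float(-np.log(self.probs[np.arange(self.length), idx]).sum())

    def to_meme_minimal(self, name: str = "pwm") -> str:
        """MEME-minimal text block for logo/scanning tools."""
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "strands: + -", "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.length}",
        ]
        for row in self.probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


def normalize_em(em: EnergyMatrix, anchors: np.ndarray | None = None) -> EnergyMatrix:
    """Shift each column so its anchor base sits at ddG = 0 exactly.

    The derived PWM is unchanged (gauge invariance).  Idempotent.
    """
    anchors = em.anchors if anchors is None else np.asarray(anchors, dtype=int)
    if anchors.shape != (em.length,) or np.any((anchors < 0) | (anchors > 3)):
        raise ValueError("anchors must give one valid base index per column")
    shift = em.values[np.arange(em.length), anchors]
    return EnergyMatrix(values=em.values - shift[:, None], anchors=anchors)


def em_to_pwm(em: EnergyMatrix) -> PWM:
    """Boltzmann conversion: p(b) proportional to exp(-ddG_b) per column."""
    # subtract the column minimum before exponentiating for numerical safety;
    # the PWM is shift-invariant so this does not change the result
    v = em.values - em.values.min(axis=1, keepdims=True)
    w = np.exp(-v)
    return PWM(probs=w / w.sum(axis=1, keepdims=True))


def site_ddg(em: EnergyMatrix, site: str | TargetSite) -> float:
    """Total ddG of a site: the sum of per-position entries (additive model).

    On an anchored matrix the canonical site scores exactly 0.
    """
    seq = str(site)
    if len(seq) != em.length:
        raise ValueError(
            f"site length {len(seq)} does not match EM length {em.length}"
        )
    idx = [BASE_INDEX[b] for b in seq]
    return float(em.values[np.arange(em.length), idx].sum())


def relative_kd(ddg: float) -> float:
    """Relative Kd = exp(ddG) with ddG in RT units; the optimal site gives 1."""
    return float(np.exp(ddg))
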