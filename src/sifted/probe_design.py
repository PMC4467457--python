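"""Custom PBM probe-set generation for TALE specificity measurements.

Three variant classes around a reference target site are produced:

* ``dinuc``: the reference, every single-base substitution (3n) and every
  adjacent-pair substitution in which both positions carry non-reference
  bases (9(n-1)); 12n - 8 unique sequences in total.  This is the minimal
  set from which all mononucleotide and adjacent-dinucleotide energy terms
  are identifiable.
* ``nonadjacent``: sampled variants with exactly k pairwise-nonadjacent
  substituted positions (k = 2..max_mm), used to probe mononucleotide
  independence beyond adjacent pairs.
* ``terminal``: all 27 three-base substitution combinations in a window
  anchored at the 5' end and at the 3' end of the site, probing binding
  polarity.

Variants are embedded at a fixed offset between constant flanks to form
full-length (default 60-mer) probes, each printed in >= 8 replicate spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .tale_core import TargetSite

__all__ = [
    "ProbeEntry",
    "ProbeSet",
    "dinuc_substitution_probes",
    "nonadjacent_mismatch_probes",
    "terminal_cluster_probes",
    "embed_in_flanks",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ProbeEntry:
    probe_id: str
    variant_class: str
    mutated_positions: tuple[int, ...]
    site_sequence: str
    probe_sequence: str | None = None  # set by embed_in_flanks


@dataclass
class ProbeSet:
    reference: str
    entries: list[ProbeEntry]
    flank5: str = ""
    flank3: str = ""
    replicate_count: int = 8

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        seqs = [e.site_sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("probe-set site sequences must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def site_sequences(self) -> list[str]:
        return [e.site_sequence for e in self.entries]

    def merge(self, other: "ProbeSet") -> "ProbeSet":
        """Union of two sets over the same reference, dropping duplicates."""
        if other.reference != self.reference:
            raise ValueError("can only merge probe sets with the same reference")
        seen = {e.site_sequence for e in self.entries}
        extra = [e for e in other.entries if e.site_sequence not in seen]
        return ProbeSet(
            reference=self.reference,
            entries=self.entries + extra,
            flank5=self.flank5,
            flank3=self.flank3,
            replicate_count=self.replicate_count,
        )

    # ---- export ---------------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["probe_id\tclass\tmutated_positions\tsite_sequence\tfull_probe_sequence"]
        for e in self.entries:
            lines.append(
                "\t".join(
                    [
                        e.probe_id,
                        e.variant_class,
                        ",".join(map(str, e.mutated_positions)),
                        e.site_sequence,
                        e.probe_sequence or "",
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        recs = []
        for e in self.entries:
            seq = e.probe_sequence or e.site_sequence
            recs.append(f">{e.probe_id}\n{seq}")
        return "\n".join(recs) + "\n"


def _substitute(ref: str, positions: tuple[int, ...], bases: tuple[str, ...]) -> str:
    out = list(ref)
    for p, b in zip(positions, bases):
        out[p] = b
    return "".join(out)


def dinuc_substitution_probes(site: TargetSite | str) -> ProbeSet:
    """Reference + all single and all adjacent-double substitutions.

    For site length n >= 3 the set has exactly 12n - 8 unique members:
    1 reference + 3n singles + 9(n-1) adjacent doubles.
    """
    ref = str(site)
    n = len(ref)
    if n < 2:
        raise ValueError("site must have length >= 2")
    entries = [ProbeEntry("ref", "reference", (), ref)]
    k = 0
    for p in range(n):
        for b in _BASES:
            if b == ref[p]:
                continue
            entries.append(ProbeEntry(f"s{k:04d}", "single", (p,), _substitute(ref, (p,), (b,))))
            k += 1
    k = 0
    seen = {e.site_sequence for e in entries}
    for p in range(n - 1):
        for b1, b2 in product(_BASES, _BASES):
            if b1 == ref[p] or b2 == ref[p + 1]:
                continue
            seq = _substitute(ref, (p, p + 1), (b1, b2))
            if seq in seen:  # only possible for n = 2 style saturation overlaps
                continue
            seen.add(seq)
            entries.append(ProbeEntry(f"d{k:04d}", "adjacent_double", (p, p + 1), seq))
            k += 1
    return ProbeSet(reference=ref, entries=entries)


def nonadjacent_mismatch_probes(
    site: TargetSite | str,
    max_mm: int = 5,
    per_level: int = 20,
    seed: int = 0,
) -> ProbeSet:
    """Sampled variants with exactly k substitutions, no two adjacent.

    For each k in 2..max_mm, draws ``per_level`` distinct variants whose
    substituted positions form an independent set on the path graph of site
    positions.  Reproducible for a fixed seed.
    """
    ref = str(site)
    n = len(ref)
    max_indep = (n + 1) // 2
    if max_mm > max_indep:
        raise ValueError(
            f"no {max_mm} pairwise-nonadjacent positions exist in a site of "
            f"length {n} (maximum {max_indep})"
        )
    if max_mm < 2:
        raise ValueError("max_mm must be >= 2")
    if per_level < 1:
        raise ValueError("per_level must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[ProbeEntry] = []
    seen: set[str] = set()
    for k in range(2, max_mm + 1):
        made = 0
        attempts = 0
        while made < per_level:
            attempts += 1
            if attempts > 200 * per_level:
                # tiny sites can exhaust the variant space; keep what we have
                break
            pos = np.sort(rng.choice(n, size=k, replace=False))
            if np.any(np.diff(pos) < 2):
                continue
            bases = tuple(
                rng.choice([b for b in _BASES if b != ref[p]]) for p in pos
            )
            seq = _substitute(ref, tuple(int(p) for p in pos), bases)
            if seq in seen:
                continue
            seen.add(seq)
            entries.append(
                ProbeEntry(
                    f"m{k}_{made:04d}",
                    f"nonadjacent_{k}",
                    tuple(int(p) for p in pos),
                    seq,
                )
            )
            made += 1
    return ProbeSet(reference=ref, entries=entries)


def terminal_cluster_probes(site: TargetSite | str) -> ProbeSet:
    """All-three-substituted windows anchored at the 5' and 3' site ends.

    Each end contributes 27 variants (3 non-reference bases at each of the
    3 window positions); the reference is excluded by construction.
    """
    ref = str(site)
    n = len(ref)
    if n < 6:
        raise ValueError("site must have length >= 6 for terminal clusters")
    entries: list[ProbeEntry] = []
    for label, start in (("cluster5", 0), ("cluster3", n - 3)):
        positions = (start, start + 1, start + 2)
        k = 0
        for combo in product(*[[b for b in _BASES if b != ref[p]] for p in positions]):
            seq = _substitute(ref, positions, combo)
            entries.append(ProbeEntry(f"{label}_{k:02d}", label, positions, seq))
            k += 1
    return ProbeSet(reference=ref, entries=entries)


def embed_in_flanks(
    probe_set: ProbeSet,
    flank5: str,
    flank3: str,
    probe_length: int = 60,
) -> ProbeSet:
    """Place every variant between constant flanks at a fixed offset.

    The flanks must size the probes to ``probe_length`` exactly.  If any
    probe-set site occurs within the flanks a warning is emitted: flanking
    sequence is meant to carry no binding sites.
    """
    n = len(probe_set.reference)
    if len(flank5) + n + len(flank3) != probe_length:
        raise ValueError(
            f"|flank5| + site + |flank3| = {len(flank5) + n + len(flank3)} "
            f"!= probe_length {probe_length}"
        )
    flanks = flank5 + flank3
    for e in probe_set.entries:
        if e.site_sequence in flanks:
            warnings.warn(
                f"probe-set site {e.site_sequence} occurs in the constant flanks",
                stacklevel=2,
            )
            break
    entries = [
        ProbeEntry(
            e.probe_id,
            e.variant_class,
            e.mutated_positions,
            e.site_sequence,
            flank5 + e.site_sequence + flank3,
        )
        for e in probe_set.entries
    ]
    return ProbeSet(
        reference=probe_set.reference,
        entries=entries,
        flank5=flank5,
        flank3=flank3,
        replicate_count=probe_set.replicate_count,
    )
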