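"""TALE proteins and the canonical one-to-one TALE-DNA recognition code.

A TALE DNA-binding domain is an array of ~34-aa repeats, each contacting one
base of the target site; the repeat variable diresidue (RVD, amino acids
12-13) sets the base preference.  The four RVDs handled here follow the
canonical code NI->A, HD->C, NN->G, NG->T.  The N-terminal region (NTR)
contacts a thymine 5' of the repeat-targeted bases, so a protein with k
repeat elements has a target site of k + 1 bases starting with T.  The final
repeat is a truncated "half-repeat", counted as 0.5 in the conventional
x.5 repeat-length bookkeeping but treated as a base-contacting repeat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "RVD_CODES",
    "RVD_TO_BASE",
    "BASE_TO_RVD",
    "TALEProtein",
    "TargetSite",
    "parse_rvd_string",
    "canonical_target_site",
    "protein_from_site",
]

#: Supported RVDs and the base each targets under the canonical code.
RVD_TO_BASE = {"NI": "A", "HD": "C", "NN": "G", "NG": "T"}
BASE_TO_RVD = {b: r for r, b in RVD_TO_BASE.items()}
RVD_CODES = tuple(RVD_TO_BASE)

#: Element labels used by the context model: position 0 is the NTR contact.
NTR = "NTR"
CTR = "CTR"


class RVDError(ValueError):
    """Raised for unknown RVD codes or malformed repeat arrays."""


@dataclass(frozen=True)
class TALEProtein:
    """An ordered TALE repeat (RVD) array.

    The last element is the C-terminal half-repeat; ``nominal_length``
    follows the x.5 convention (number of elements minus 0.5).
    """

    id: str
    repeats: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.repeats) < 2:
            raise RVDError(
                f"protein {self.id!r}: need at least 2 repeat elements, "
                f"got {len(self.repeats)}"
            )
        for i, code in enumerate(self.repeats):
            if code not in RVD_TO_BASE:
                raise RVDError(
                    f"protein {self.id!r}: unsupported RVD {code!r} at index {i}"
                )

    @property
    def n_elements(self) -> int:
        return len(self.repeats)

    @property
    def nominal_length(self) -> float:
        """Repeat count in the conventional x.5 notation."""
        return self.n_elements - 0.5

    @property
    def site_length(self) -> int:
        """Target-site length: 5' T plus one base per repeat element."""
        return self.n_elements + 1

    @property
    def half_repeat(self) -> str:
        return self.repeats[-1]

    def format(self, sep: str = "-") -> str:
        return sep.join(self.repeats)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.id}[{self.format()}]"


@dataclass(frozen=True)
class TargetSite:
    """A DNA binding site; position 0 is the 5'-T position contacted by the NTR."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 3:
            raise ValueError(f"target site too short: {self.sequence!r}")
        if not re.fullmatch(r"[ACGT]+", seq):
            raise ValueError(f"non-ACGT characters in site: {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def parse_rvd_string(text: str, protein_id: str = "tale") -> TALEProtein:
    """Parse a delimiter-separated RVD string such as ``"NI-HD-NN-NG"``.

    Accepts ``-`` or whitespace delimiters; the last token is the half-repeat.
    Unknown tokens raise :class:`RVDError` naming the token and its index.
    """
    if not text or not text.strip():
        raise RVDError("empty RVD string")
    tokens = [t for t in re.split(r"[-\s]+", text.strip()) if t]
    for i, tok in enumerate(tokens):
        if tok.upper() not in RVD_TO_BASE:
            raise RVDError(f"unsupported RVD {tok!r} at index {i}")
    if len(tokens) < 2:
        raise RVDError(f"need at least 2 repeat elements, got {len(tokens)}")
    return TALEProtein(id=protein_id, repeats=tuple(t.upper() for t in tokens))


def canonical_target_site(protein: TALEProtein) -> TargetSite:
    """The optimal site under the canonical code, preceded by the 5' T."""
    return TargetSite("T" + "".join(RVD_TO_BASE[r] for r in protein.repeats))


def protein_from_site(site: str | TargetSite, protein_id: str = "tale") -> TALEProtein:
    """Inverse of :func:`canonical_target_site`: design the TALE that targets
    ``site`` under the canonical code.  ``site`` must start with T."""
    seq = str(site).upper()
    if not seq.startswith("T"):
        raise ValueError(f"canonical target sites start with T, got {seq!r}")
    if len(seq) < 3:
        raise ValueError("site too short to design a TALE (need >= 3 bases)")
    if not re.fullmatch(r"[ACGT]+", seq):
        raise ValueError(f"non-ACGT characters in site: {seq!r}")
    return TALEProtein(id=protein_id, repeats=tuple(BASE_TO_RVD[b] for b in seq[1:]))
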