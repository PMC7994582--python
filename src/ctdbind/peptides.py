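"""CTD heptad-repeat phosphopeptides.

The carboxy-terminal domain (CTD) of RNA polymerase II's largest subunit is a
tandem array of Y1-S2-P3-T4-S5-P6-S7 heptad repeats.  Synthetic CTD peptides
are written in a compact repeat notation: each parenthesized group is one
heptad unit, ``pS`` marks a phosphoserine, and optional flanking residues or
an N-terminal label (``FITC-``, ``biotin-``) surround the repeats, e.g.
``AS(YSPTpSPS)(YSPTSPS)(YSPTpSPS)YS``.

This module parses that notation into :class:`CTDPeptide` and computes the
bookkeeping quantities the binding analyses need: pSer-Pro motif positions,
the residue spacing between the outermost motifs (the geometric lever for
bivalent engagement by the WW and PPIase domains), and the 280-nm molar
extinction coefficient used to quantify peptide stocks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "CTDPeptide",
    "PeptideParseError",
    "CTD_PEPTIDES",
    "parse_peptide_spec",
    "serialize_peptide",
    "locate_psp_motifs",
    "motif_spacing",
    "extinction_coefficient",
]

#: Residue alphabet appearing in CTD peptide specs (one-letter codes).
RESIDUE_ALPHABET = frozenset("YSPTAG")

#: Molar extinction at 280 nm contributed by one tyrosine (M^-1 cm^-1).
TYR_EXTINCTION_280 = 1280.0

#: Recognized N-terminal label prefixes and the cap they imply.
_LABEL_CAPS = {"FITC": "FITC-linker", "biotin": "biotin-linker"}

HEPTAD_LENGTH = 7


class PeptideParseError(ValueError):
    """Raised when a peptide spec string is malformed."""


@dataclass(frozen=True)
class CTDPeptide:
    """A synthesized CTD peptide in repeat notation.

    Indices are 1-based over the full synthesized sequence, flanking residues
    included.  Caps and fluorophore/affinity labels are metadata only and do
    not occupy sequence positions.
    """

    name: str
    sequence: str                       # one-letter residues, no phospho marks
    phospho_positions: tuple[int, ...]  # 1-based indices of phosphoserines
    n_repeats: int
    repeat_starts: tuple[int, ...] = ()  # 1-based index of each unit's Tyr1
    n_term_cap: str = "free"            # free | acetyl | biotin-linker | FITC-linker
    c_term_cap: str = "free"            # free | amide

    def __post_init__(self) -> None:
        for i in self.phospho_positions:
            if not 1 <= i <= len(self.sequence):
                raise ValueError(f"phospho position {i} outside sequence")
            if self.sequence[i - 1] != "S":
                raise ValueError(
                    f"phospho position {i} is {self.sequence[i - 1]!r}, not S"
                )
        if self.n_repeats < 1:
            raise ValueError("peptide must contain at least one heptad unit")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_tyr(self) -> int:
        return self.sequence.count("Y")


_SPEC_RE = re.compile(r"^(?:(?P<label>[A-Za-z]+)-)?(?P<body>[A-Za-z()]+)$")


def _tokenize(segment: str, origin: str) -> tuple[str, tuple[int, ...]]:
    """Expand a run of residue letters, returning (sequence, 0-based pS offsets)."""
    seq = []
    phospho = []
    i = 0
    while i < len(segment):
        if segment[i] == "p":
            if i + 1 >= len(segment) or segment[i + 1] != "S":
                raise PeptideParseError(
                    f"'p' not followed by S in {origin!r}"
                )
            phospho.append(len(seq))
            seq.append("S")
            i += 2
            continue
        ch = segment[i]
        if ch not in RESIDUE_ALPHABET:
            raise PeptideParseError(f"unknown residue letter {ch!r} in {origin!r}")
        seq.append(ch)
        i += 1
    return "".join(seq), tuple(phospho)


def parse_peptide_spec(
    spec: str,
    name: str | None = None,
    c_term_cap: str = "free",
    n_term_cap: str | None = None,
) -> CTDPeptide:
    """Parse a repeat-notation spec string into a :class:`CTDPeptide`.

    Parameters
    ----------
    spec
        Peptide string such as ``"AS(YSPTpSPS)YS"`` or
        ``"FITC-AS(YSPTpSPS)(YSPTSPS)YS"``.  Each parenthesized unit must be
        exactly seven residues; ``pS`` marks phosphoserine.
    name
        Optional label; defaults to the spec string itself.
    c_term_cap, n_term_cap
        Cap metadata.  When *n_term_cap* is None it is inferred from a label
        prefix (``FITC-`` / ``biotin-``) or left ``"free"``.
    """
    spec = spec.strip()
    m = _SPEC_RE.match(spec)
    if m is None:
        raise PeptideParseError(f"cannot parse peptide spec {spec!r}")
    label = m.group("label")
    body = m.group("body")
    if label is not None and label not in _LABEL_CAPS:
        # not a recognized label: treat the whole string as malformed rather
        # than silently swallowing e.g. a typo'd fluorophore name
        raise PeptideParseError(f"unknown label prefix {label!r} in {spec!r}")
    if n_term_cap is None:
        n_term_cap = _LABEL_CAPS[label] if label else "free"

    seq_parts: list[str] = []
    phospho: list[int] = []
    repeat_starts: list[int] = []
    pos = 0  # residues consumed so far
    n_repeats = 0
    for piece in re.split(r"(\([A-Za-z]+\))", body):
        if not piece:
            continue
        if piece.startswith("("):
            unit = piece[1:-1]
            seq, offs = _tokenize(unit, piece)
            if len(seq) != HEPTAD_LENGTH:
                raise PeptideParseError(
                    f"heptad unit {piece!r} has {len(seq)} residues, expected 7"
                )
            n_repeats += 1
            repeat_starts.append(pos + 1)
        else:
            seq, offs = _tokenize(piece, piece)
        seq_parts.append(seq)
        phospho.extend(pos + 1 + o for o in offs)
        pos += len(seq)
    if n_repeats == 0:
        raise PeptideParseError(f"no parenthesized heptad unit in {spec!r}")

    return CTDPeptide(
        name=name if name is not None else spec,
        sequence="".join(seq_parts),
        phospho_positions=tuple(phospho),
        n_repeats=n_repeats,
        repeat_starts=tuple(repeat_starts),
        n_term_cap=n_term_cap,
        c_term_cap=c_term_cap,
    )


def serialize_peptide(p: CTDPeptide) -> str:
    """Render *p* back to canonical repeat notation (round-trips with the parser)."""
    phospho = set(p.phospho_positions)

    def run(lo: int, hi: int) -> str:  # 1-based inclusive
        out = []
        for i in range(lo, hi + 1):
            res = p.sequence[i - 1]
            out.append("pS" if i in phospho else res)
        return "".join(out)

    parts = []
    cursor = 1
    for start in p.repeat_starts:
        if start > cursor:
            parts.append(run(cursor, start - 1))
        parts.append("(" + run(start, start + HEPTAD_LENGTH - 1) + ")")
        cursor = start + HEPTAD_LENGTH
    if cursor <= len(p.sequence):
        parts.append(run(cursor, len(p.sequence)))
    label = {"FITC-linker": "FITC-", "biotin-linker": "biotin-"}.get(p.n_term_cap, "")
    return label + "".join(parts)


def locate_psp_motifs(p: CTDPeptide) -> list[tuple[int, int]]:
    """Return (pSer index, Pro index) pairs for every pSer-Pro motif, N→C.

    A phosphoserine not immediately followed by proline is not a
    parvulin-recognition motif; it is skipped with a warning.
    """
    motifs = []
    for i in sorted(p.phospho_positions):
        if i < len(p.sequence) and p.sequence[i] == "P":
            motifs.append((i, i + 1))
        else:
            warnings.warn(
                f"{p.name}: phosphoserine at {i} not followed by Pro; "
                "not a pSer-Pro motif",
                stacklevel=2,
            )
    return motifs


def motif_spacing(p: CTDPeptide) -> int | None:
    """Residue spacing between the first and last pSer-Pro motifs.

    Measured pSer-to-pSer as an index difference; for an nR peptide
    phosphorylated on the Ser5 of its outermost repeats this is 7·(n−1).
    Returns None when the peptide carries fewer than two motifs (spacing is
    undefined, not zero).
    """
    motifs = locate_psp_motifs(p)
    if len(motifs) < 2:
        return None
    return motifs[-1][0] - motifs[0][0]


def extinction_coefficient(p: CTDPeptide) -> float:
    """Molar extinction at 280 nm (M⁻¹ cm⁻¹): 1280 per tyrosine.

    Label chromophores (FITC absorbs at 495 nm) are excluded from the
    280-nm estimate.
    """
    return TYR_EXTINCTION_280 * p.n_tyr


def _study_peptides() -> dict[str, CTDPeptide]:
    specs = {
        "BLI-1R": ("biotin-GGSGGS(YSPTpSPS)YS", "free"),
        "FITC-1R": ("FITC-AS(YSPTpSPS)YS", "amide"),
        "FITC-2R": ("FITC-AS(YSPTpSPS)(YSPTpSPS)YS", "amide"),
        "FITC-3R": ("FITC-AS(YSPTpSPS)(YSPTSPS)(YSPTpSPS)YS", "amide"),
        "FITC-4R": ("FITC-AS(YSPTpSPS)(YSPTSPS)(YSPTSPS)(YSPTpSPS)YS", "amide"),
        "FITC-5R": ("FITC-AS(YSPTpSPS)(YSPTSPS)(YSPTSPS)(YSPTSPS)(YSPTpSPS)YS", "amide"),
        "NMR-1R": ("AS(YSPTpSPS)YS", "amide"),
        "NMR-2R": ("(YSPTpSPS)(YSPTpSPS)", "amide"),
        "NMR-3R": ("(YSPTpSPS)(YSPTSPS)(YSPTpSPS)", "amide"),
        "NMR-4R": ("AS(YSPTpSPS)(YSPTSPS)(YSPTSPS)(YSPTpSPS)YS", "amide"),
        "NMR-5R": ("AS(YSPTpSPS)(YSPTSPS)(YSPTSPS)(YSPTSPS)(YSPTpSPS)YS", "amide"),
    }
    out = {}
    for nm, (spec, ccap) in specs.items():
        ncap = None if spec.split("-")[0] in _LABEL_CAPS else "acetyl"
        if nm.startswith("NMR"):
            ncap = "acetyl"
        out[nm] = parse_peptide_spec(spec, name=nm, c_term_cap=ccap, n_term_cap=ncap)
    return out


#: The study's synthesized peptide panel: FITC-labeled peptides for
#: anisotropy/AUC, unlabeled (NMR-) peptides for HSQC titrations, and the
#: biotinylated 1R used for co-crystallization.  Phosphorylation sits on the
#: Ser5-Pro6 motif of the outermost repeats only.
CTD_PEPTIDES: dict[str, CTDPeptide] = _study_peptides()
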