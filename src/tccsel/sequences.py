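"""Pore-segment alignment handling and channel-type signature classification.

Voltage-gated Ca²⁺ channel α1 subunits have four homologous domains, each
contributing an outer helix (S5), a re-entrant P-loop and an inner helix
(S6) to the pore.  Residues are addressed by the KcsA-aligned label
``<domain><segment><position>`` — e.g. ``3p49`` is domain III, P-loop,
aligned position 49.  Helices number from 1; P-loops number from 33.

The selectivity filter is the ring of four acidic p50 residues (one per
domain): EEEE in L-type channels (LCC, e.g. α1C) and EEDD in T-type
channels (TCC, e.g. α1G/α1H/α1I).  All T-type channels additionally carry
a lysine at 3p49, immediately adjacent to the domain-III filter
aspartate; that K³ᵖ⁴⁹/D³ᵖ⁵⁰ pair is the sequence signature this module
classifies on.
"""

from __future__ import annotations

import io
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SequenceError",
    "ResidueLabel",
    "SegmentSequence",
    "ChannelClassification",
    "normalize_channel",
    "load_alignment",
    "dump_alignment",
    "to_fasta",
    "residue_at",
    "classify_channel",
    "formal_charge_tally",
    "apply_substitutions",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
SEGMENTS = ("o", "p", "i")  # S5 outer helix, P-loop, S6 inner helix
SEGMENT_START = {"o": 1, "p": 33, "i": 1}
P_LOOP_RANGE = (33, 57)
KNOWN_CHANNELS = ("α1C", "α1G", "α1H", "α1I")

# side-chain formal charge at pH ~7.35 (His treated as neutral)
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1, "H": 0}

_LABEL_RE = re.compile(r"^([1-4])([opi])(\d+)$")
_CHANNEL_RE = re.compile(r"^(?:α|a|alpha)?1?([CGHI])$", re.IGNORECASE)


class SequenceError(ValueError):
    """Malformed alignment data, label or lookup."""


def normalize_channel(name: str) -> str:
    """Canonicalise a channel name: a1G / alpha1G / α1g → ``α1G``."""
    token = unicodedata.normalize("NFKC", str(name)).strip()
    m = _CHANNEL_RE.match(token.replace("_", ""))
    if not m:
        raise SequenceError(f"unrecognised channel name {name!r}")
    return "α1" + m.group(1).upper()


@dataclass(frozen=True, order=True)
class ResidueLabel:
    """Aligned residue address ``<domain><segment><position>``."""

    domain: int
    segment: str
    position: int

    def __post_init__(self) -> None:
        if self.domain not in (1, 2, 3, 4):
            raise SequenceError(f"domain must be 1-4, got {self.domain}")
        if self.segment not in SEGMENTS:
            raise SequenceError(f"segment must be one of o/p/i, got {self.segment!r}")
        if self.position < 1:
            raise SequenceError(f"position must be >= 1, got {self.position}")
        if self.segment == "p" and not P_LOOP_RANGE[0] <= self.position <= P_LOOP_RANGE[1]:
            raise SequenceError(
                f"P-loop positions run {P_LOOP_RANGE[0]}-{P_LOOP_RANGE[1]}, "
                f"got {self.position}"
            )

    @classmethod
    def parse(cls, text: str) -> "ResidueLabel":
        m = _LABEL_RE.match(str(text).strip())
        if not m:
            raise SequenceError(f"cannot parse residue label {text!r}")
        return cls(int(m.group(1)), m.group(2), int(m.group(3)))

    def render(self) -> str:
        return f"{self.domain}{self.segment}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


@dataclass(frozen=True)
class SegmentSequence:
    """One channel/domain/segment row of the pore alignment."""

    channel: str
    domain: int
    segment: str
    start_position: int
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", normalize_channel(self.channel))
        object.__setattr__(self, "residues", re.sub(r"\s+", "", self.residues))
        if self.segment not in SEGMENTS:
            raise SequenceError(f"bad segment {self.segment!r}")
        if self.start_position != SEGMENT_START[self.segment]:
            raise SequenceError(
                f"{self.channel} {self.domain}{self.segment}: segment "
                f"{self.segment!r} must start at {SEGMENT_START[self.segment]}, "
                f"got {self.start_position}"
            )
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"{self.channel} {self.domain}{self.segment}: "
                f"non-amino-acid letters {sorted(bad)}"
            )

    @property
    def end_position(self) -> int:
        return self.start_position + len(self.residues) - 1

    def residue(self, position: int) -> str:
        if not self.start_position <= position <= self.end_position:
            raise SequenceError(
                f"position {position} outside {self.channel} "
                f"{self.domain}{self.segment} range "
                f"[{self.start_position}, {self.end_position}]"
            )
        return self.residues[position - self.start_position]


@dataclass(frozen=True)
class ChannelClassification:
    """Channel family call from the domain-III lysine signature.

    ``family`` is TCC iff the residue at 3p49 is lysine and the filter
    residue at 3p50 is acidic (D or E); otherwise LCC.  ``filter_motif``
    collects the p50 residues of domains I-IV (EEDD for T-type, EEEE for
    L-type).
    """

    channel: str
    family: str  # "TCC" | "LCC"
    residue_3p49: str
    residue_3p50: str
    filter_motif: str


def _read_rows(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def load_alignment(source: str | Path | io.IOBase | pd.DataFrame) -> list[SegmentSequence]:
    """Read a pore-segment alignment from TSV (or a DataFrame).

    Expected columns: channel, domain, segment, start, sequence.
    Embedded spaces in printed sequences are stripped.  Duplicate
    (channel, domain, segment) keys, unknown residue letters and wrong
    start positions are reported as :class:`SequenceError` naming the row.
    """
    df = _read_rows(source)
    if df.empty:
        return []
    required = {"channel", "domain", "segment", "start", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceError(f"alignment file missing columns {sorted(missing)}")
    rows: list[SegmentSequence] = []
    seen: set[tuple[str, int, str]] = set()
    for idx, rec in df.iterrows():
        try:
            row = SegmentSequence(
                channel=rec["channel"],
                domain=int(rec["domain"]),
                segment=str(rec["segment"]).strip(),
                start_position=int(rec["start"]),
                residues=str(rec["sequence"]),
            )
        except (SequenceError, ValueError) as exc:
            raise SequenceError(f"alignment row {idx}: {exc}") from exc
        key = (row.channel, row.domain, row.segment)
        if key in seen:
            raise SequenceError(f"alignment row {idx}: duplicate key {key}")
        seen.add(key)
        rows.append(row)
    return rows


def dump_alignment(rows: Sequence[SegmentSequence]) -> pd.DataFrame:
    """Inverse of :func:`load_alignment` (modulo stripped whitespace)."""
    return pd.DataFrame(
        {
            "channel": [r.channel for r in rows],
            "domain": [r.domain for r in rows],
            "segment": [r.segment for r in rows],
            "start": [r.start_position for r in rows],
            "sequence": [r.residues for r in rows],
        }
    )


def to_fasta(rows: Sequence[SegmentSequence]) -> str:
    """Render segments as FASTA with ``>channel|d<domain>|<segment>|<start>`` headers."""
    out = []
    for r in rows:
        out.append(f">{r.channel}|d{r.domain}|{r.segment}|{r.start_position}")
        out.append(r.residues)
    return "\n".join(out) + ("\n" if out else "")


def _index(rows: Iterable[SegmentSequence]) -> dict[tuple[str, int, str], SegmentSequence]:
    return {(r.channel, r.domain, r.segment): r for r in rows}


def residue_at(
    rows: Sequence[SegmentSequence],
    label: ResidueLabel | str,
    channel: str,
) -> str:
    """One-letter residue at an aligned label for one channel."""
    if isinstance(label, str):
        label = ResidueLabel.parse(label)
    chan = normalize_channel(channel)
    seg = _index(rows).get((chan, label.domain, label.segment))
    if seg is None:
        raise SequenceError(f"no {label.domain}{label.segment} segment stored for {chan}")
    return seg.residue(label.position)


def classify_channel(rows: Sequence[SegmentSequence], channel: str) -> ChannelClassification:
    """Call TCC vs LCC from the domain-III K/D signature.

    Requires the channel's domain-III P-loop; the filter motif uses
    whichever of the four P-loops are stored ('?' for missing ones).
    """
    chan = normalize_channel(channel)
    idx = _index(rows)
    if (chan, 3, "p") not in idx:
        raise SequenceError(f"cannot classify {chan}: domain-III P-loop missing")
    r49 = residue_at(rows, ResidueLabel(3, "p", 49), chan)
    r50 = residue_at(rows, ResidueLabel(3, "p", 50), chan)
    motif = "".join(
        idx[(chan, d, "p")].residue(50) if (chan, d, "p") in idx else "?"
        for d in (1, 2, 3, 4)
    )
    family = "TCC" if (r49 == "K" and r50 in ("D", "E")) else "LCC"
    return ChannelClassification(
        channel=chan,
        family=family,
        residue_3p49=r49,
        residue_3p50=r50,
        filter_motif=motif,
    )


def formal_charge_tally(sequence: str) -> int:
    """Net side-chain formal charge of a one-letter sequence at pH ~7.

    Asp/Glu count −1, Lys/Arg +1, His 0 (neutral at the extracellular
    pH 7.35 convention), all other standard residues 0.  This is a crude
    charge bookkeeping of reduced filter sequences, not an estimator of
    solvated electrostatic energies.
    """
    seq = re.sub(r"\s+", "", sequence).upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise SequenceError(f"unknown residue letters {sorted(bad)}")
    return sum(RESIDUE_CHARGE.get(aa, 0) for aa in seq)


def apply_substitutions(
    rows: Sequence[SegmentSequence],
    channel: str,
    substitutions: Mapping[str, str] | Iterable[tuple[str, str]],
    new_channel: str,
) -> tuple[list[SegmentSequence], list[str]]:
    """Derive a channel's segments from a template by point substitutions.

    ``substitutions`` maps residue labels to one-letter replacements,
    e.g. ``{"3p47": "S"}``.  Substitutions whose position falls outside
    the stored segment are skipped and reported (second return value) —
    these correspond to typeset labels that cannot be placed reliably.
    Returns the patched rows for ``new_channel`` plus the skip log.
    """
    chan = normalize_channel(channel)
    subs = dict(substitutions.items() if isinstance(substitutions, Mapping) else substitutions)
    template = [r for r in rows if r.channel == chan]
    if not template:
        raise SequenceError(f"no template rows for {chan}")
    mutable = {
        (r.domain, r.segment): list(r.residues) for r in template
    }
    skipped: list[str] = []
    for text, aa in subs.items():
        label = ResidueLabel.parse(text)
        if aa not in AMINO_ACIDS:
            raise SequenceError(f"substitution {text} -> {aa!r} is not an amino acid")
        key = (label.domain, label.segment)
        seq = mutable.get(key)
        offset = label.position - SEGMENT_START[label.segment]
        if seq is None or not 0 <= offset < len(seq):
            skipped.append(f"{aa}^{text}: position outside stored segment")
            continue
        seq[offset] = aa
    patched = [
        SegmentSequence(
            channel=new_channel,
            domain=r.domain,
            segment=r.segment,
            start_position=r.start_position,
            residues="".join(mutable[(r.domain, r.segment)]),
        )
        for r in template
    ]
    return patched, skipped


#: Table-footnote point substitutions deriving α1H and α1I pore segments
#: from the α1G template.  Labels originally typeset as e.g. "Y4^o16^"
#: are normalised to 4o16; the 4o29 entries address position 29 of a
#: 27-residue helix and are skipped (logged) by apply_substitutions.
ALPHA1H_SUBSTITUTIONS: dict[str, str] = {
    "3o7": "L",
    "4o16": "Y",
    "4o29": "R",
    "2p54": "V",
    "3p47": "S",
    "3p54": "N",
    "2i8": "V",
    "3i15": "S",
    "4i1": "A",
    "4i2": "L",
    "4i5": "V",
    "4i9": "T",
    "4i13": "V",
    "4i23": "V",
}

ALPHA1I_SUBSTITUTIONS: dict[str, str] = {
    "1o19": "I",
    "1p42": "V",
    "1p54": "E",
    "2p54": "V",
    "2i1": "P",
    "2i4": "S",
    "2i8": "V",
    "3o7": "L",
    "3p54": "N",
    "3i15": "S",
    "4o16": "Y",
    "4o29": "K",
    "4p45": "Q",
    "4i1": "F",
    "4i2": "V",
    "4i19": "I",
    "4i23": "V",
}
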