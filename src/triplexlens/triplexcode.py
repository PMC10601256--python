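"""Canonical-code prediction of parallel RNA:DNA triplex binding sites.

The third (RNA) strand is modelled in the parallel pyrimidine motif: it runs
5'→3' parallel to the purine strand of the duplex and reads each purine
through a Hoogsteen triplet.  Only the two canonical triplets are accepted as
a match:

* ``U·A`` — RNA uracil reading the adenine of an A–T pair;
* ``C·G`` — (protonated) RNA cytosine reading the guanine of a G–C pair.

Every other RNA/purine combination is annotated as a mismatch (``*``).
Coordinates on the public interfaces are 1-based and inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from triplexlens.errors import AmbiguityError, BoundsError, ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

#: Canonical parallel-motif triplets, as (RNA base, duplex purine base).
CANONICAL_TRIPLETS = frozenset({("U", "A"), ("C", "G")})

_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

MATCH_CHAR = "|"
MISMATCH_CHAR = "*"


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, 5'→3'.

    Parameters
    ----------
    id
        Text label (FASTA id).
    sequence
        Bases over ``{A, C, G, U}`` for RNA or ``{A, C, G, T}`` for DNA.
    kind
        Either ``"rna"`` or ``"dna"``.
    """

    id: str
    sequence: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("rna", "dna"):
            raise ValidationError(f"kind must be 'rna' or 'dna', got {self.kind!r}")
        if not self.sequence:
            raise ValidationError(f"sequence {self.id!r} is empty")
        alphabet = RNA_ALPHABET if self.kind == "rna" else DNA_ALPHABET
        seq = self.sequence.upper()
        for pos, base in enumerate(seq, start=1):
            if base not in alphabet:
                raise ValidationError(
                    f"invalid {self.kind.upper()} symbol {base!r} at position "
                    f"{pos} of {self.id!r} (allowed: {''.join(sorted(alphabet))})"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> "SequenceRecord":
        """Return the 1-based inclusive slice ``[start, end]`` as a new record."""
        if not (1 <= start <= end <= len(self)):
            raise BoundsError(
                f"slice {start}..{end} out of range for {self.id!r} "
                f"(length {len(self)})"
            )
        return SequenceRecord(
            id=f"{self.id}:{start}-{end}",
            sequence=self.sequence[start - 1 : end],
            kind=self.kind,
        )


def read_fasta(path, kind: str, dna_as_rna: bool = False) -> list[SequenceRecord]:
    """Read FASTA records as :class:`SequenceRecord` of the given kind.

    ``dna_as_rna=True`` transliterates T→U before validation, for RNA
    sequences that were deposited in DNA alphabet.  Without the flag a T in
    an RNA input is rejected rather than silently converted.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if kind == "rna" and dna_as_rna:
            seq = seq.replace("T", "U")
        records.append(SequenceRecord(id=rec.id, sequence=seq, kind=kind))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def choose_purine_strand(
    strand_a: SequenceRecord, strand_b: SequenceRecord
) -> SequenceRecord:
    """Pick the purine strand of a duplex: the strand with more purines."""
    purines = frozenset("AG")

    def frac(rec: SequenceRecord) -> float:
        return sum(b in purines for b in rec.sequence) / len(rec)

    return strand_a if frac(strand_a) >= frac(strand_b) else strand_b


def complement_dna(record: SequenceRecord) -> SequenceRecord:
    """Watson–Crick complement of a DNA record (per-position, same order)."""
    if record.kind != "dna":
        raise ValidationError("complement_dna expects a DNA record")
    seq = "".join(_DNA_COMPLEMENT[b] for b in record.sequence)
    return SequenceRecord(id=f"{record.id}|comp", sequence=seq, kind="dna")


# ---------------------------------------------------------------------------
# Canonical code
# ---------------------------------------------------------------------------


def canonical_triplet_match(
    rna_base: str, purine_base: str, position: int | None = None
) -> bool:
    """True iff (rna_base, purine_base) is a canonical parallel-motif triplet.

    Raises :class:`ValidationError` naming the offending symbol (and 1-based
    position if given) for out-of-alphabet input.
    """
    where = "" if position is None else f" at position {position}"
    if rna_base not in RNA_ALPHABET:
        raise ValidationError(f"invalid RNA base {rna_base!r}{where}")
    if purine_base not in DNA_ALPHABET:
        raise ValidationError(f"invalid DNA base {purine_base!r}{where}")
    return (rna_base, purine_base) in CANONICAL_TRIPLETS


def pairing_string(rna_window: str, purine_window: str) -> str:
    """Per-position annotation over ``{'|', '*'}`` for two equal-length windows."""
    if len(rna_window) != len(purine_window):
        raise ValidationError(
            f"window length mismatch: {len(rna_window)} vs {len(purine_window)}"
        )
    return "".join(
        MATCH_CHAR if canonical_triplet_match(r, d, pos) else MISMATCH_CHAR
        for pos, (r, d) in enumerate(zip(rna_window, purine_window), start=1)
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriplexAlignment:
    """A parallel RNA window paired against a duplex purine-strand window.

    Coordinates are 1-based inclusive on the source sequences.  ``pairing``
    holds one ``|`` (canonical triplet) or ``*`` (mismatch) per position.
    """

    rna_id: str
    rna_window: str
    rna_start: int
    rna_end: int
    purine_id: str
    purine_window: str
    purine_start: int
    purine_end: int
    pairing: str = field(default="")
    orientation: str = field(default="parallel", init=False)

    def __post_init__(self) -> None:
        if len(self.rna_window) != len(self.purine_window):
            raise ValidationError("RNA and purine windows differ in length")
        if self.rna_end - self.rna_start + 1 != len(self.rna_window):
            raise ValidationError("rna_start/rna_end inconsistent with window")
        if self.purine_end - self.purine_start + 1 != len(self.purine_window):
            raise ValidationError("purine_start/purine_end inconsistent with window")
        expected = pairing_string(self.rna_window, self.purine_window)
        if self.pairing == "":
            object.__setattr__(self, "pairing", expected)
        elif self.pairing != expected:
            raise ValidationError(
                f"pairing annotation {self.pairing!r} inconsistent with the "
                f"canonical code ({expected!r})"
            )

    def __len__(self) -> int:
        return len(self.rna_window)

    @property
    def mismatch_positions(self) -> list[int]:
        """1-based window-local positions annotated as mismatches."""
        return [i + 1 for i, c in enumerate(self.pairing) if c == MISMATCH_CHAR]

    @property
    def n_mismatch(self) -> int:
        return self.pairing.count(MISMATCH_CHAR)

    @property
    def mismatch_pairs(self) -> list[tuple[str, str]]:
        """(RNA base, purine base) at each mismatch position."""
        return [
            (self.rna_window[i - 1], self.purine_window[i - 1])
            for i in self.mismatch_positions
        ]

    def to_dict(self) -> dict:
        return {
            "rna_id": self.rna_id,
            "rna_window": self.rna_window,
            "rna_start": self.rna_start,
            "rna_end": self.rna_end,
            "purine_id": self.purine_id,
            "purine_window": self.purine_window,
            "purine_start": self.purine_start,
            "purine_end": self.purine_end,
            "pairing": self.pairing,
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TriplexAlignment":
        return cls(
            rna_id=d["rna_id"],
            rna_window=d["rna_window"],
            rna_start=int(d["rna_start"]),
            rna_end=int(d["rna_end"]),
            purine_id=d["purine_id"],
            purine_window=d["purine_window"],
            purine_start=int(d["purine_start"]),
            purine_end=int(d["purine_end"]),
            pairing=d.get("pairing", ""),
        )


def align_windows(
    rna: SequenceRecord,
    rna_start: int,
    purine: SequenceRecord,
    purine_start: int,
    window_len: int,
) -> TriplexAlignment:
    """Build the parallel alignment of two windows of equal length."""
    rna_slice = rna.slice(rna_start, rna_start + window_len - 1)
    pur_slice = purine.slice(purine_start, purine_start + window_len - 1)
    return TriplexAlignment(
        rna_id=rna.id,
        rna_window=rna_slice.sequence,
        rna_start=rna_start,
        rna_end=rna_start + window_len - 1,
        purine_id=purine.id,
        purine_window=pur_slice.sequence,
        purine_start=purine_start,
        purine_end=purine_start + window_len - 1,
    )


def scan_tts(
    rna: SequenceRecord,
    purine_strand: SequenceRecord,
    window_len: int = 15,
    max_mismatch: int = 2,
) -> list[TriplexAlignment]:
    """Scan every (RNA offset, purine offset) window pair in parallel
    orientation and keep those with at most ``max_mismatch`` mismatches.

    Results are sorted by (n_mismatch asc, purine offset asc, rna offset asc)
    and are deterministic.  Sequences shorter than the window yield an empty
    result with a logged warning.
    """
    if window_len < 4:
        raise ValidationError(f"window_len must be >= 4, got {window_len}")
    if max_mismatch < 0:
        raise ValidationError(f"max_mismatch must be >= 0, got {max_mismatch}")
    if rna.kind != "rna" or purine_strand.kind != "dna":
        raise ValidationError("scan_tts expects (rna, dna) records")
    if len(rna) < window_len or len(purine_strand) < window_len:
        logger.warning(
            "sequence shorter than window (%d): rna=%d, purine=%d — empty scan",
            window_len,
            len(rna),
            len(purine_strand),
        )
        return []

    hits: list[TriplexAlignment] = []
    for p0 in range(len(purine_strand) - window_len + 1):
        pur_win = purine_strand.sequence[p0 : p0 + window_len]
        for r0 in range(len(rna) - window_len + 1):
            rna_win = rna.sequence[r0 : r0 + window_len]
            nmm = sum(
                (r, d) not in CANONICAL_TRIPLETS for r, d in zip(rna_win, pur_win)
            )
            if nmm <= max_mismatch:
                hits.append(
                    align_windows(rna, r0 + 1, purine_strand, p0 + 1, window_len)
                )
    hits.sort(key=lambda a: (a.n_mismatch, a.purine_start, a.rna_start))
    return hits


# ---------------------------------------------------------------------------
# Rendering / parsing
# ---------------------------------------------------------------------------


def render_alignment(a: TriplexAlignment) -> str:
    """Render an alignment as a three-line text block.

    Line 1: duplex purine strand 5'→3' with its id and 1-based span.
    Line 2: annotation over ``{'|', '*'}``.
    Line 3: RNA strand 5'→3' with its id and span.

    The block round-trips through :func:`parse_alignment`.
    """
    return (
        f"5'-{a.purine_window}-3'  DNA:{a.purine_id} {a.purine_start}..{a.purine_end}\n"
        f"   {a.pairing}\n"
        f"5'-{a.rna_window}-3'  RNA:{a.rna_id} {a.rna_start}..{a.rna_end}\n"
    )


def parse_alignment(block: str) -> TriplexAlignment:
    """Inverse of :func:`render_alignment`."""
    lines = [ln for ln in block.splitlines() if ln.strip()]
    if len(lines) != 3:
        raise ValidationError("alignment block must have exactly three lines")

    def parse_seq_line(line: str, tag: str) -> tuple[str, str, int, int]:
        body, meta = line.split("  ", 1)
        if not (body.startswith("5'-") and body.endswith("-3'")):
            raise ValidationError(f"malformed sequence line: {line!r}")
        seq = body[3:-3]
        meta = meta.strip()
        if not meta.startswith(tag + ":"):
            raise ValidationError(f"expected {tag} metadata in {line!r}")
        name, span = meta[len(tag) + 1 :].rsplit(" ", 1)
        start_s, end_s = span.split("..")
        return seq, name, int(start_s), int(end_s)

    pur_seq, pur_id, pur_start, pur_end = parse_seq_line(lines[0], "DNA")
    rna_seq, rna_id, rna_start, rna_end = parse_seq_line(lines[2], "RNA")
    pairing = lines[1].strip()
    return TriplexAlignment(
        rna_id=rna_id,
        rna_window=rna_seq,
        rna_start=rna_start,
        rna_end=rna_end,
        purine_id=pur_id,
        purine_window=pur_seq,
        purine_start=pur_start,
        purine_end=pur_end,
        pairing=pairing,
    )


# ---------------------------------------------------------------------------
# Binding-domain extraction and clipping
# ---------------------------------------------------------------------------


def extract_dbd(
    rna_full: SequenceRecord, start: int = 1896, end: int = 1925
) -> SequenceRecord:
    """Extract the DNA-binding-domain window (1-based, inclusive both ends)."""
    if not (1 <= start <= end):
        raise BoundsError(f"invalid coordinates {start}..{end}")
    if end > len(rna_full):
        raise BoundsError(
            f"coordinates {start}..{end} exceed sequence length {len(rna_full)}"
        )
    return rna_full.slice(start, end)


def clip_alignment(
    extended: TriplexAlignment, core: TriplexAlignment
) -> TriplexAlignment:
    """Restrict an extended alignment to the span of its non-extended core.

    The core's RNA window must occur exactly once as a contiguous substring
    of the extended RNA window; anything else is an ambiguity error.
    """
    hay, needle = extended.rna_window, core.rna_window
    first = hay.find(needle)
    if first < 0:
        raise AmbiguityError(
            "core RNA window not found inside the extended alignment"
        )
    if hay.find(needle, first + 1) >= 0:
        raise AmbiguityError(
            "core RNA window occurs more than once in the extended alignment"
        )
    lo, hi = first, first + len(needle)  # 0-based half-open within the window
    return TriplexAlignment(
        rna_id=extended.rna_id,
        rna_window=hay[lo:hi],
        rna_start=extended.rna_start + lo,
        rna_end=extended.rna_start + hi - 1,
        purine_id=extended.purine_id,
        purine_window=extended.purine_window[lo:hi],
        purine_start=extended.purine_start + lo,
        purine_end=extended.purine_start + hi - 1,
        pairing=extended.pairing[lo:hi],
    )


def clip_levels(extended: TriplexAlignment, core: TriplexAlignment) -> list[int]:
    """Register levels (1-based) of the extended model covered by the core."""
    clipped = clip_alignment(extended, core)
    lo = clipped.rna_start - extended.rna_start
    return list(range(lo + 1, lo + len(clipped) + 1))


# ---------------------------------------------------------------------------
# Tabular / BED export
# ---------------------------------------------------------------------------


def alignments_to_table(alignments: Iterable[TriplexAlignment]) -> pd.DataFrame:
    """TSV-ready table of scan hits."""
    rows = [
        {
            "rna_start": a.rna_start,
            "rna_end": a.rna_end,
            "purine_start": a.purine_start,
            "purine_end": a.purine_end,
            "length": len(a),
            "n_mismatch": a.n_mismatch,
            "pairing": a.pairing,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rna_start",
            "rna_end",
            "purine_start",
            "purine_end",
            "length",
            "n_mismatch",
            "pairing",
        ],
    )


def alignments_to_bed6(
    alignments: Iterable[TriplexAlignment], strand: str = "+"
) -> Iterator[str]:
    """BED6 lines of target sites on the duplex (0-based half-open)."""
    for i, a in enumerate(alignments):
        score = max(0, 1000 - 250 * a.n_mismatch)
        yield (
            f"{a.purine_id}\t{a.purine_start - 1}\t{a.purine_end}\t"
            f"TTS_{i + 1}\t{score}\t{strand}"
        )


__all__ = [
    "SequenceRecord",
    "TriplexAlignment",
    "CANONICAL_TRIPLETS",
    "canonical_triplet_match",
    "pairing_string",
    "align_windows",
    "scan_tts",
    "render_alignment",
    "parse_alignment",
    "extract_dbd",
    "clip_alignment",
    "clip_levels",
    "read_fasta",
    "choose_purine_strand",
    "complement_dna",
    "alignments_to_table",
    "alignments_to_bed6",
]
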