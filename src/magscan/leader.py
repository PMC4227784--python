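"""Annotation of upstream ORFs and Kozak contexts in an mRNA 5'-leader.

A 5'-leader is analysed relative to a declared main-ORF start codon.
Coordinates are 1-based and inclusive throughout; an AUG's position is the
position of its A, and Kozak positions are counted with that A as +1 (so
the classical context spans -6..+4 and the critical positions are -3 and
+4).  Upstream AUGs (uAUGs) are located, extended in frame to their stop
codon — scanning the *whole* sequence, because a uORF may run past the
main start and overlap the main coding sequence — and classified by the
purine/pyrimidine identity of the -3/+4 positions:

* ``strong``    purine at both -3 and +4 (R-3 / R+4)
* ``weak``      pyrimidine at both
* ``adequate``  one of each

Only AUG is treated as an initiation codon; near-cognate starts
(CUG/GUG/...) are ignored.  uORF length includes both the start and the
stop codon, so it is always a multiple of 3 when a stop exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .errors import InputError

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
_ALPHABET = frozenset("ACGU")


def normalize_rna(raw: str) -> str:
    """Uppercase and convert T→U; validation happens in LeaderSequence."""
    return raw.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class LeaderSequence:
    """An mRNA (or its 5' portion) with a declared main-ORF start.

    Parameters
    ----------
    id : str
        Sequence identifier.
    bases : str
        RNA string, A/C/G/U uppercase.  ``T`` is accepted on input and
        normalized to ``U``.
    main_start : int
        1-based position of the A of the main-ORF AUG.
    """

    id: str
    bases: str
    main_start: int

    def __post_init__(self):
        object.__setattr__(self, "bases", normalize_rna(self.bases))
        bad = [i + 1 for i, b in enumerate(self.bases) if b not in _ALPHABET]
        if bad:
            raise InputError(
                f"{self.id}: non-AUGC base at position {bad[0]}"
                + (f" (and {len(bad) - 1} more)" if len(bad) > 1 else "")
            )
        n = len(self.bases)
        if not (1 <= self.main_start <= n - 2):
            raise InputError(
                f"{self.id}: main_start {self.main_start} outside sequence "
                f"of length {n}"
            )
        if self.codon(self.main_start) != "AUG":
            raise InputError(
                f"{self.id}: no AUG at declared main_start {self.main_start} "
                f"(found {self.codon(self.main_start)!r})"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """1-based single-base access."""
        return self.bases[pos - 1]

    def codon(self, pos: int) -> str:
        """Codon starting at 1-based ``pos``."""
        return self.bases[pos - 1 : pos + 2]


@dataclass(frozen=True)
class KozakContext:
    """The -6..+4 context of an AUG with its strength class.

    ``window`` is the 10-nt string covering positions -6..+4 (A of the
    AUG at +1, i.e. window[6:9] == "AUG"), padded with ``N`` where the
    sequence ends.  ``cls`` is a pure function of (minus3, plus4);
    padding counts as non-matching, so an AUG at the very 5' end can at
    best be ``adequate``.
    """

    window: str
    minus3: str
    plus4: str
    cls: str


def classify_context(leader: LeaderSequence, aug_pos: int) -> KozakContext:
    """Classify the Kozak context of the AUG at ``aug_pos``.

    strong iff both -3 and +4 are purines; weak iff both are
    pyrimidines (an ``N`` pad counts as pyrimidine-like, i.e.
    non-matching); adequate otherwise.
    """
    if leader.codon(aug_pos) != "AUG":
        raise InputError(
            f"{leader.id}: position {aug_pos} is not an AUG "
            f"({leader.codon(aug_pos)!r})"
        )

    def at(offset: int) -> str:
        # offset in Kozak numbering; +1 is the A of the AUG, no 0 position
        pos = aug_pos + offset - (1 if offset > 0 else 0)
        if 1 <= pos <= leader.length:
            return leader.base(pos)
        return "N"

    window = "".join(at(o) for o in (-6, -5, -4, -3, -2, -1, 1, 2, 3, 4))
    minus3, plus4 = at(-3), at(4)
    m3_pur, p4_pur = minus3 in PURINES, plus4 in PURINES
    if m3_pur and p4_pur:
        cls = "strong"
    elif not m3_pur and not p4_pur:
        cls = "weak"
    else:
        cls = "adequate"
    return KozakContext(window=window, minus3=minus3, plus4=plus4, cls=cls)


@dataclass(frozen=True)
class UORF:
    """One upstream open reading frame.

    ``length_nt`` runs from the A of the uAUG through the last base of
    the stop codon inclusive.  ``overlaps_main`` is true when the uORF
    has no stop before the sequence end or its stop codon ends at or
    past the main start; ``overlap_nt`` counts the bases shared with the
    main ORF (which extends from main_start to the sequence end for this
    purpose).  ``gap_to_main`` is the number of bases strictly between
    the stop codon and the main AUG ("ends N bases upstream").
    """

    start: int
    stop_start: Optional[int]
    length_nt: Optional[int]
    frame_vs_main: int
    overlaps_main: bool
    overlap_nt: int
    gap_to_main: Optional[int]
    context: KozakContext


@dataclass(frozen=True)
class LeaderAnnotation:
    """Full uORF architecture of one leader."""

    leader: LeaderSequence
    uorfs: tuple[UORF, ...]
    gc_fraction: float
    main_context: KozakContext = field(repr=False)

    def uorf_at(self, start: int) -> UORF:
        for u in self.uorfs:
            if u.start == start:
                return u
        raise InputError(f"{self.leader.id}: no uORF starting at {start}")


def find_uaugs(leader: LeaderSequence) -> list[int]:
    """1-based positions of every AUG strictly upstream of the main start."""
    return [
        p
        for p in range(1, leader.main_start)
        if leader.codon(p) == "AUG"
    ]


def gc_content(leader: LeaderSequence) -> float:
    """G+C fraction of the leader region (positions 1..main_start-1)."""
    if leader.main_start < 2:
        raise InputError(
            f"{leader.id}: leader region is empty (main_start == 1)"
        )
    region = leader.bases[: leader.main_start - 1]
    return (region.count("G") + region.count("C")) / len(region)


def _scan_stop(leader: LeaderSequence, aug_pos: int) -> Optional[int]:
    """First in-frame stop codon at/after aug_pos+3, over the full sequence."""
    for p in range(aug_pos + 3, leader.length - 1, 3):
        if leader.codon(p) in STOP_CODONS:
            return p
    return None


def _build_uorf(leader: LeaderSequence, start: int) -> UORF:
    stop_start = _scan_stop(leader, start)
    main = leader.main_start
    if stop_start is None:
        length = None
        overlaps = True
        last = leader.length  # runs to the end of the sequence
    else:
        length = stop_start + 2 - start + 1
        overlaps = stop_start + 2 >= main
        last = stop_start + 2
    overlap_nt = max(0, last - main + 1) if overlaps else 0
    gap = None if overlaps else main - (stop_start + 2) - 1
    return UORF(
        start=start,
        stop_start=stop_start,
        length_nt=length,
        frame_vs_main=(start - main) % 3,
        overlaps_main=overlaps,
        overlap_nt=overlap_nt,
        gap_to_main=gap,
        context=classify_context(leader, start),
    )


def annotate(leader: LeaderSequence) -> LeaderAnnotation:
    """Annotate every uORF of a leader.

    One UORF record per uAUG, in 5'→3' order; stop codons are found by
    an in-frame scan over the full sequence so that main-ORF-overlapping
    uORFs are handled; GC content is computed over the leader region
    only.
    """
    uorfs = tuple(_build_uorf(leader, p) for p in find_uaugs(leader))
    return LeaderAnnotation(
        leader=leader,
        uorfs=uorfs,
        gc_fraction=gc_content(leader),
        main_context=classify_context(leader, leader.main_start),
    )


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing

_MAIN_START_TAG = "main_start="


def read_leaders(
    fasta_path: str | Path,
    main_starts: Optional[dict[str, int]] = None,
) -> list[LeaderSequence]:
    """Read leaders from FASTA.

    The main-ORF start is taken from ``main_starts`` (id → position,
    e.g. parsed from a sidecar TSV) or, failing that, from a
    ``main_start=<int>`` tag in the record description.
    """
    leaders = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        start = (main_starts or {}).get(rec.id)
        if start is None:
            for tok in rec.description.split():
                if tok.startswith(_MAIN_START_TAG):
                    start = int(tok[len(_MAIN_START_TAG):])
                    break
        if start is None:
            raise SchemaErrorFor(rec.id)
        leaders.append(LeaderSequence(rec.id, str(rec.seq), start))
    return leaders


def SchemaErrorFor(rec_id: str) -> InputError:
    return InputError(
        f"{rec_id}: no main_start given (sidecar TSV or 'main_start=N' "
        "header tag required)"
    )


def read_main_starts(tsv_path: str | Path) -> dict[str, int]:
    """Sidecar TSV with columns id, main_start."""
    df = pd.read_csv(tsv_path, sep="\t")
    missing = {"id", "main_start"} - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(sorted(missing))
    return dict(zip(df["id"].astype(str), df["main_start"].astype(int)))


def annotation_table(annotations: Iterable[LeaderAnnotation]) -> pd.DataFrame:
    """One row per uORF, in the package's standard TSV layout."""
    rows = []
    for ann in annotations:
        for u in ann.uorfs:
            rows.append(
                {
                    "id": ann.leader.id,
                    "start": u.start,
                    "stop_start": u.stop_start,
                    "length_nt": u.length_nt,
                    "frame": u.frame_vs_main,
                    "overlaps_main": u.overlaps_main,
                    "overlap_nt": u.overlap_nt,
                    "gap_to_main": u.gap_to_main,
                    "minus3": u.context.minus3,
                    "plus4": u.context.plus4,
                    "cls": u.context.cls,
                    "gc_fraction": round(ann.gc_fraction, 6),
                }
            )
    cols = [
        "id", "start", "stop_start", "length_nt", "frame", "overlaps_main",
        "overlap_nt", "gap_to_main", "minus3", "plus4", "cls", "gc_fraction",
    ]
    return pd.DataFrame(rows, columns=cols)
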