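"""Tankyrase-binding-motif (TBM) scanning and cross-species conservation.

Tankyrases (TNKS-1/2) recognize their PARylation substrates through short
linear motifs bound by their ankyrin-repeat clusters.  Two patterns are
scanned here, written in the field's one-letter notation with 1-based
inclusive coordinates:

* canonical (hexamer):      ``R X X O X G``  — anchors at positions 1, 4, 6
* non-canonical (heptamer): ``R X X X O X G`` — anchors at positions 1, 5, 7

where ``X`` is any residue and ``O`` is one of G, P, A, C.  ``X`` as an
*input* character (unknown residue) matches the unconstrained positions but
never an anchor: the anchors are the motif definition.

Conservation across species is assessed on a *precomputed* multiple
alignment (aligned FASTA or Clustal; alignment computation is out of scope):
each motif locus of a chosen reference sequence is projected through its
alignment-column window onto every other row and classified as conserved,
degenerate (R…G frame intact, O-position violated) or absent.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import AlignIO, SeqIO

# 20 standard residues plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
O_RESIDUES = frozenset("GPAC")
GAP = "-"

MotifClass = Literal["canonical", "non_canonical"]

#: anchor layout per class: {0-based offset: allowed residues}; None length
_MOTIF_DEFS: dict[str, tuple[int, dict[int, frozenset[str]]]] = {
    "canonical": (6, {0: frozenset("R"), 3: O_RESIDUES, 5: frozenset("G")}),
    "non_canonical": (7, {0: frozenset("R"), 4: O_RESIDUES, 6: frozenset("G")}),
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: accession/label, species label, residues."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at offset {offset}"
                )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MotifHit:
    """One TBM match, 1-based inclusive coordinates."""

    record_id: str
    start: int
    end: int
    motif_class: str
    matched: str

    def __post_init__(self) -> None:
        length, anchors = _MOTIF_DEFS[self.motif_class]
        if self.end - self.start + 1 != length or len(self.matched) != length:
            raise ValueError(f"{self.motif_class} hit must span {length} residues")
        for off, allowed in anchors.items():
            if self.matched[off] not in allowed:
                raise ValueError(
                    f"anchor violation at offset {off} in {self.matched!r}"
                )


def _window_matches(window: str, motif_class: str) -> bool:
    length, anchors = _MOTIF_DEFS[motif_class]
    if len(window) != length:
        return False
    for off, ch in enumerate(window):
        allowed = anchors.get(off)
        if allowed is not None:
            if ch not in allowed:
                return False
        elif ch not in ALPHABET:
            return False
    return True


def scan_tbm(
    record: ProteinRecord,
    classes: Iterable[str] = ("canonical", "non_canonical"),
) -> list[MotifHit]:
    """Scan one sequence for TBMs of the requested classes.

    Every matching window is reported, including overlapping and nested hits
    (a hexamer inside a heptamer window is two hits); order is by start
    position, canonical before non-canonical at equal start.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    for cls in classes:
        if cls not in _MOTIF_DEFS:
            raise ValueError(f"unknown motif class {cls!r}")
    seq = record.sequence
    hits: list[MotifHit] = []
    for start0 in range(len(seq)):
        for cls in sorted(classes):  # canonical < non_canonical
            length, _ = _MOTIF_DEFS[cls]
            window = seq[start0 : start0 + length]
            if len(window) == length and _window_matches(window, cls):
                hits.append(
                    MotifHit(
                        record_id=record.id,
                        start=start0 + 1,
                        end=start0 + length,
                        motif_class=cls,
                        matched=window,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# FASTA / alignment I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read plain (ungapped) FASTA into validated :class:`ProteinRecord` s.

    Gap characters are stripped (use :func:`read_alignment` to keep them);
    sequences are upper-cased; order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).replace(GAP, ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


@dataclass(frozen=True)
class AlignedRecord:
    """One alignment row plus bidirectional residue<->column maps (1-based)."""

    id: str
    aligned: str  # residues and '-' gaps, upper-case
    col_of_residue: tuple[int, ...] = field(repr=False)  # residue i (1-based) -> column
    residue_of_col: tuple[int, ...] = field(repr=False)  # column c (1-based) -> residue or 0

    @property
    def sequence(self) -> str:
        return self.aligned.replace(GAP, "")


def _build_maps(aligned: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
    col_of_residue: list[int] = []
    residue_of_col: list[int] = []
    for col0, ch in enumerate(aligned):
        if ch == GAP:
            residue_of_col.append(0)
        else:
            col_of_residue.append(col0 + 1)
            residue_of_col.append(len(col_of_residue))
    return tuple(col_of_residue), tuple(residue_of_col)


class Alignment:
    """A read multiple alignment with per-row coordinate maps."""

    def __init__(self, records: Sequence[AlignedRecord]):
        if not records:
            raise ValueError("empty alignment")
        lengths = {len(r.aligned) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.records = list(records)
        self.n_columns = lengths.pop()

    def __getitem__(self, record_id: str) -> AlignedRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned-FASTA or Clustal file.

    ``fmt`` is inferred from the suffix when not given (``.aln``/``.clustal``
    -> clustal, otherwise aligned FASTA).  All rows must share one length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse as {fmt} alignment ({exc})") from exc
    rows = []
    for rec in msa:
        aligned = str(rec.seq).upper()
        ungapped = aligned.replace(GAP, "")
        ProteinRecord(id=rec.id, sequence=ungapped)  # residue validation
        col_map, res_map = _build_maps(aligned)
        rows.append(
            AlignedRecord(
                id=rec.id,
                aligned=aligned,
                col_of_residue=col_map,
                residue_of_col=res_map,
            )
        )
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

Presence = Literal["conserved", "degenerate", "absent"]


@dataclass(frozen=True)
class ConservationLocus:
    """One reference motif locus and its status in every species."""

    reference_id: str
    hit: MotifHit
    columns: tuple[int, int]  # inclusive alignment-column window
    presence: dict[str, Presence]


@dataclass(frozen=True)
class ConservationTable:
    reference_id: str
    loci: list[ConservationLocus]

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for locus in self.loci:
            for species_id, status in locus.presence.items():
                rows.append(
                    {
                        "reference_id": self.reference_id,
                        "motif_class": locus.hit.motif_class,
                        "ref_start": locus.hit.start,
                        "ref_end": locus.hit.end,
                        "ref_matched": locus.hit.matched,
                        "columns": f"{locus.columns[0]}-{locus.columns[1]}",
                        "species": species_id,
                        "presence": status,
                    }
                )
        return rows


def _classify_window(ungapped: str, motif_class: str) -> Presence:
    length, anchors = _MOTIF_DEFS[motif_class]
    if _window_matches(ungapped, motif_class):
        return "conserved"
    # degenerate: frame length intact with R...G termini, O-position failed
    if (
        len(ungapped) == length
        and ungapped[0] == "R"
        and ungapped[-1] == "G"
    ):
        return "degenerate"
    return "absent"


def conservation_report(
    reference_id: str,
    alignment: Alignment,
    classes: Iterable[str] = ("canonical", "non_canonical"),
) -> ConservationTable:
    """Classify each reference motif locus in every other alignment row.

    The locus's residue span is mapped to its alignment-column window; the
    other species' characters under those columns (gaps dropped) are tested
    against the same motif pattern.
    """
    ref = alignment[reference_id]
    hits = scan_tbm(ProteinRecord(id=reference_id, sequence=ref.sequence), classes)
    if not hits:
        warnings.warn(f"reference {reference_id!r} has no motif hits", stacklevel=2)
        return ConservationTable(reference_id=reference_id, loci=[])
    loci = []
    for hit in hits:
        col_start = ref.col_of_residue[hit.start - 1]
        col_end = ref.col_of_residue[hit.end - 1]
        presence: dict[str, Presence] = {}
        for rec in alignment.records:
            window = rec.aligned[col_start - 1 : col_end].replace(GAP, "")
            presence[rec.id] = _classify_window(window, hit.motif_class)
        assert presence[reference_id] == "conserved"
        loci.append(
            ConservationLocus(
                reference_id=reference_id,
                hit=hit,
                columns=(col_start, col_end),
                presence=presence,
            )
        )
    return ConservationTable(reference_id=reference_id, loci=loci)


def write_hits_csv(
    hits: Iterable[MotifHit], path: str | Path, species: dict[str, str] | None = None
) -> None:
    """Write motif hits as CSV (record_id, species, motif_class, start, end, matched)."""
    species = species or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "species", "motif_class", "start", "end", "matched"])
        for h in hits:
            writer.writerow(
                [h.record_id, species.get(h.record_id, ""), h.motif_class, h.start, h.end, h.matched]
            )


def write_conservation_csv(table: ConservationTable, path: str | Path) -> None:
    """Write the conservation table as a loci x species CSV matrix."""
    species_ids: list[str] = []
    for locus in table.loci:
        for sid in locus.presence:
            if sid not in species_ids:
                species_ids.append(sid)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["motif_class", "ref_start", "ref_end", "ref_matched", *species_ids])
        for locus in table.loci:
            writer.writerow(
                [
                    locus.hit.motif_class,
                    locus.hit.start,
                    locus.hit.end,
                    locus.hit.matched,
                    *[locus.presence.get(sid, "absent") for sid in species_ids],
                ]
            )
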