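"""Reading, filtering and indexing protein-family multiple sequence alignments.

Alignments come from Pfam-style Stockholm files or aligned FASTA. Sequence
names follow the UniProt/Pfam convention ``NAME_SPECIES/start-end``; the
``start-end`` suffix gives the 1-based, inclusive UniProt coordinates of the
aligned region and ``SPECIES`` identifies the organism (``HUMAN`` marks the
sequences that carry population variants). Columns are 1-based throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

GAP_CHARS = frozenset("-.")

_NAME_RE = re.compile(r"^(?P<body>.+?)/(?P<start>\d+)-(?P<end>\d+)$")


class AlignmentError(ValueError):
    """Raised for malformed or unusable alignments."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of a domain alignment with its UniProt coordinates."""

    accession: str
    species_tag: str
    is_human: bool
    start: int
    end: int
    gapped_sequence: str

    def __post_init__(self) -> None:
        n = self.ungapped_length
        if self.start < 1:
            raise AlignmentError(f"{self.accession}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AlignmentError(f"{self.accession}: end {self.end} < start {self.start}")
        if n != self.end - self.start + 1:
            raise AlignmentError(
                f"{self.accession}: {n} aligned residues but coordinate range "
                f"{self.start}-{self.end} spans {self.end - self.start + 1}"
            )

    @property
    def ungapped_length(self) -> int:
        return sum(1 for ch in self.gapped_sequence if ch not in GAP_CHARS)

    def column_of(self, uniprot_position: int) -> int | None:
        """1-based alignment column holding `uniprot_position`, or None if outside."""
        if uniprot_position < self.start or uniprot_position > self.end:
            return None
        pos = self.start - 1
        for i, ch in enumerate(self.gapped_sequence, start=1):
            if ch not in GAP_CHARS:
                pos += 1
                if pos == uniprot_position:
                    return i
        return None  # pragma: no cover - excluded by the range check

    def residue_at(self, column: int) -> tuple[int, str] | None:
        """(UniProt position, residue) at 1-based `column`, or None on a gap."""
        if column < 1 or column > len(self.gapped_sequence):
            return None
        ch = self.gapped_sequence[column - 1]
        if ch in GAP_CHARS:
            return None
        pos = self.start - 1
        for c in self.gapped_sequence[:column]:
            if c not in GAP_CHARS:
                pos += 1
        return pos, ch


@dataclass(frozen=True)
class DomainAlignment:
    """An aligned protein family with per-sequence coordinates."""

    family_id: str
    sequences: tuple[AlignedSequence, ...]
    n_columns: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.family_id}: alignment has no sequences")
        widths = {len(s.gapped_sequence) for s in self.sequences}
        if len(widths) != 1:
            raise AlignmentError(f"{self.family_id}: ragged alignment, widths {sorted(widths)}")
        object.__setattr__(self, "n_columns", widths.pop())

    @property
    def human_sequences(self) -> tuple[AlignedSequence, ...]:
        return tuple(s for s in self.sequences if s.is_human)

    def sequences_for(self, accession: str) -> tuple[AlignedSequence, ...]:
        return tuple(s for s in self.sequences if s.accession == accession)


@dataclass(frozen=True)
class ColumnOccupancy:
    """Non-gap residue counts for one alignment column."""

    column: int
    occupancy_all: int
    occupancy_human: int


def _parse_name(name: str) -> tuple[str, str, int | None, int | None]:
    """Split ``NAME_SPECIES/start-end`` into (accession, species_tag, start, end)."""
    start = end = None
    body = name
    m = _NAME_RE.match(name)
    if m:
        body = m.group("body")
        start, end = int(m.group("start")), int(m.group("end"))
    species = ""
    accession = body
    if "_" in body:
        stem, tail = body.rsplit("_", 1)
        # species suffixes are short all-caps mnemonics; anything else is part
        # of the accession (e.g. isoform ids like P12345-2)
        if tail.isupper() and tail.isalnum() and len(tail) <= 6:
            species = tail
            accession = stem
    return accession, species, start, end


def _records_from(path: str | Path, format: str) -> list[tuple[str, str]]:
    fmt = format.lower()
    if fmt not in {"stockholm", "fasta"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), fmt)]
    except ValueError:
        # Biopython rejects ragged Stockholm before yielding records; rescan
        # the raw lines so the error can name the offending sequence.
        _raise_named_ragged_error(path)
        raise
    return records


def _raise_named_ragged_error(path: str | Path) -> None:
    lengths: dict[str, int] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "//", ">")):
            continue
        parts = line.split()
        if len(parts) != 2:
            continue
        name, chunk = parts
        if name not in lengths:
            order.append(name)
        lengths[name] = lengths.get(name, 0) + len(chunk)
    if order:
        ref = lengths[order[0]]
        for idx, name in enumerate(order, start=1):
            if lengths[name] != ref:
                raise AlignmentError(
                    f"ragged alignment: sequence {idx} ({name}) has length "
                    f"{lengths[name]}, expected {ref}"
                )


def read_alignment(
    path: str | Path,
    format: str = "stockholm",
    family_id: str | None = None,
    species_map: Mapping[str, str] | None = None,
) -> DomainAlignment:
    """Read a domain alignment from a Stockholm or aligned-FASTA file.

    Sequence names of the form ``ACCESSION/start-end`` supply UniProt
    coordinates; names without the suffix get ``start=1`` and ``end`` equal to
    the number of non-gap residues. ``species_map`` (accession -> species tag)
    overrides the ``_SPECIES`` name suffix for human detection.

    Raises :class:`AlignmentError` on empty input or ragged rows, naming the
    first offending sequence.
    """
    records = _records_from(path, format)
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    widths = [len(seq) for _, seq in records]
    ref = widths[0]
    for idx, ((name, _), w) in enumerate(zip(records, widths), start=1):
        if w != ref:
            raise AlignmentError(
                f"ragged alignment: sequence {idx} ({name}) has length {w}, expected {ref}"
            )
    sequences = []
    for name, seq in records:
        seq = seq.upper()
        accession, species, start, end = _parse_name(name)
        if species_map and accession in species_map:
            species = species_map[accession]
        if start is None:
            n_res = sum(1 for ch in seq if ch not in GAP_CHARS)
            if n_res == 0:
                raise AlignmentError(f"{name}: sequence is all gaps")
            start, end = 1, n_res
        sequences.append(
            AlignedSequence(
                accession=accession,
                species_tag=species,
                is_human=species == "HUMAN",
                start=start,
                end=end,
                gapped_sequence=seq,
            )
        )
    fam = family_id or Path(path).stem
    return DomainAlignment(family_id=fam, sequences=tuple(sequences))


def filter_reviewed_human_bearing(
    alignment: DomainAlignment, reviewed_accessions: Iterable[str]
) -> DomainAlignment:
    """Keep only sequences whose accession is in the reviewed (SwissProt) set.

    An empty ``reviewed_accessions`` disables filtering. Column count is
    preserved; an empty result is a hard error.
    """
    reviewed = set(reviewed_accessions)
    if not reviewed:
        return alignment
    kept = tuple(s for s in alignment.sequences if s.accession in reviewed)
    if not kept:
        raise AlignmentError(
            f"{alignment.family_id}: no sequences left after reviewed-accession filter"
        )
    return replace(alignment, sequences=kept)


def occupancies(alignment: DomainAlignment) -> list[ColumnOccupancy]:
    """Per-column non-gap residue counts, overall and for human sequences only."""
    n = alignment.n_columns
    occ_all = [0] * n
    occ_human = [0] * n
    for seq in alignment.sequences:
        for i, ch in enumerate(seq.gapped_sequence):
            if ch not in GAP_CHARS:
                occ_all[i] += 1
                if seq.is_human:
                    occ_human[i] += 1
    return [
        ColumnOccupancy(column=i + 1, occupancy_all=occ_all[i], occupancy_human=occ_human[i])
        for i in range(n)
    ]


def column_residues(alignment: DomainAlignment, column: int, human_only: bool = False) -> list[str]:
    """Non-gap residue symbols in a 1-based column."""
    seqs: Sequence[AlignedSequence] = (
        alignment.human_sequences if human_only else alignment.sequences
    )
    out = []
    for s in seqs:
        ch = s.gapped_sequence[column - 1]
        if ch not in GAP_CHARS:
            out.append(ch)
    return out


def write_stockholm(alignment: DomainAlignment, path: str | Path) -> None:
    """Write a minimal Pfam-style Stockholm file."""
    lines = ["# STOCKHOLM 1.0", f"#=GF ID {alignment.family_id}"]
    width = max(
        len(f"{s.accession}_{s.species_tag}/{s.start}-{s.end}") for s in alignment.sequences
    )
    for s in alignment.sequences:
        tag = f"_{s.species_tag}" if s.species_tag else ""
        name = f"{s.accession}{tag}/{s.start}-{s.end}"
        lines.append(f"{name:<{width}}  {s.gapped_sequence}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")
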