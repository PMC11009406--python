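"""Per-residue structural features and their aggregation to alignment columns.

Relative solvent accessibility (RSA) is the DSSP accessible surface area of
a residue divided by the residue type's maximum ASA (Tien et al. 2013
normalisation; the "theoretical" table is the default, the "empirical" one
selectable). Exposure classes follow fixed RSA bounds: core (RSA < 5%),
partially exposed (5% <= RSA < 25%) and surface (RSA >= 25%). ASA values are
expected to have been computed per chain with non-protein atoms stripped, so
burial reflects the single biopolymer rather than bound partners.

Aggregation is two-stage to stay unbiased by PDB coverage: features are
first summarised per (accession, position) over all covering chains — the
modal exposure class, any-contact flags — and only then rolled up to column
level, so a sequence with many deposited structures counts once, exactly
like a sequence with one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .msa_io import DomainAlignment

ExposureClass = Literal["core", "partially_exposed", "surface"]

#: Maximum ASA (A^2) per residue, Tien et al. 2013, theoretical values.
MAX_ASA_THEORETICAL: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Maximum ASA (A^2) per residue, Tien et al. 2013, empirical values.
MAX_ASA_EMPIRICAL: dict[str, float] = {
    "A": 121.0, "R": 265.0, "N": 187.0, "D": 187.0, "C": 148.0,
    "E": 214.0, "Q": 214.0, "G": 97.0, "H": 216.0, "I": 195.0,
    "L": 191.0, "K": 230.0, "M": 203.0, "F": 228.0, "P": 154.0,
    "S": 143.0, "T": 163.0, "W": 264.0, "Y": 255.0, "V": 165.0,
}

#: Tie-break order for modal exposure classes: more buried wins.
_BURIAL_ORDER = {"core": 0, "partially_exposed": 1, "surface": 2}


@dataclass(frozen=True)
class ResidueStructuralRecord:
    """One residue observed in one PDB chain, mapped to UniProt coordinates."""

    pdb_id: str
    chain: str
    accession: str
    position: int
    residue_type: str = "X"
    rsa: float = float("nan")
    ligand_contact: bool = False
    domain_contact: bool = False


@dataclass(frozen=True)
class SequenceFeatureSummary:
    """Per-(accession, position) roll-up over all covering PDB chains."""

    accession: str
    position: int
    exposure_class: ExposureClass
    ligand_contact_any: bool
    domain_contact_any: bool
    pdb_coverage: int


@dataclass(frozen=True)
class ColumnStructuralSummary:
    column: int
    consensus_exposure: ExposureClass | None  # None = no structural data
    n_ligand_sequences: int
    n_domain_sequences: int
    pdb_sequence_coverage: int
    pdb_total_coverage: int


def rsa_from_asa(
    asa: float,
    residue_type: str,
    table: Literal["theoretical", "empirical"] = "theoretical",
) -> float:
    """RSA percent = 100 * ASA / maxASA(residue type). Not clipped at 100.

    Unknown residue types return NaN and are excluded downstream.
    """
    if asa < 0:
        raise ValueError(f"ASA must be nonnegative, got {asa}")
    ref = MAX_ASA_THEORETICAL if table == "theoretical" else MAX_ASA_EMPIRICAL
    max_asa = ref.get(residue_type.upper())
    if max_asa is None:
        return float("nan")
    return 100.0 * asa / max_asa


def exposure_class(rsa: float, bounds: tuple[float, float] = (5.0, 25.0)) -> ExposureClass:
    """Core (< 5%), partially exposed (5-25%) or surface (>= 25%)."""
    lo, hi = bounds
    if rsa >= hi:
        return "surface"
    if rsa >= lo:
        return "partially_exposed"
    return "core"


def _modal_exposure(classes: Iterable[str]) -> ExposureClass:
    counts = Counter(classes)
    best = max(counts.items(), key=lambda kv: (kv[1], -_BURIAL_ORDER[kv[0]]))
    return best[0]  # type: ignore[return-value]


def summarise_sequences(
    records: Iterable[ResidueStructuralRecord],
    bounds: tuple[float, float] = (5.0, 25.0),
) -> dict[tuple[str, int], SequenceFeatureSummary]:
    """Summarise structural records per (accession, position).

    The exposure class is the modal class across distinct (pdb_id, chain)
    observations, ties going to the more buried class; contact flags are
    logical-ORs, so a residue touching a ligand in 5 of 20 structures counts
    once. Records with undefined RSA contribute contacts and coverage but no
    exposure vote.
    """
    grouped: dict[tuple[str, int], list[ResidueStructuralRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.accession, rec.position), []).append(rec)
    out: dict[tuple[str, int], SequenceFeatureSummary] = {}
    for key, recs in grouped.items():
        by_chain: dict[tuple[str, str], ResidueStructuralRecord] = {}
        for r in recs:
            by_chain.setdefault((r.pdb_id, r.chain), r)
        chains = list(by_chain.values())
        votes = [
            exposure_class(r.rsa, bounds) for r in chains if r.rsa == r.rsa  # skip NaN
        ]
        if not votes:
            continue
        out[key] = SequenceFeatureSummary(
            accession=key[0],
            position=key[1],
            exposure_class=_modal_exposure(votes),
            ligand_contact_any=any(r.ligand_contact for r in chains),
            domain_contact_any=any(r.domain_contact for r in chains),
            pdb_coverage=len(chains),
        )
    return out


def summarise_columns(
    alignment: DomainAlignment,
    summaries: Mapping[tuple[str, int], SequenceFeatureSummary],
) -> list[ColumnStructuralSummary]:
    """Roll per-residue summaries up to alignment columns.

    The consensus exposure is the modal class of the residues in the column
    (same buried-preference tie rule). Interaction counts are numbers of
    sequences whose residue has any contact. Sequence coverage counts
    residues with at least one covering chain; total coverage sums the
    residue-level chain counts. Columns with no covered residue come back
    with consensus None.
    """
    out = []
    for col in range(1, alignment.n_columns + 1):
        votes: list[str] = []
        n_ligand = n_domain = n_seq_cov = n_total_cov = 0
        for seq in alignment.sequences:
            hit = seq.residue_at(col)
            if hit is None:
                continue
            summ = summaries.get((seq.accession, hit[0]))
            if summ is None:
                continue
            votes.append(summ.exposure_class)
            n_seq_cov += 1
            n_total_cov += summ.pdb_coverage
            if summ.ligand_contact_any:
                n_ligand += 1
            if summ.domain_contact_any:
                n_domain += 1
        out.append(
            ColumnStructuralSummary(
                column=col,
                consensus_exposure=_modal_exposure(votes) if votes else None,
                n_ligand_sequences=n_ligand,
                n_domain_sequences=n_domain,
                pdb_sequence_coverage=n_seq_cov,
                pdb_total_coverage=n_total_cov,
            )
        )
    return out


def summary_frame(summaries: Sequence[ColumnStructuralSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": [s.column for s in summaries],
            "consensus_exposure": [s.consensus_exposure or "uncovered" for s in summaries],
            "n_ligand_sequences": [s.n_ligand_sequences for s in summaries],
            "n_domain_sequences": [s.n_domain_sequences for s in summaries],
            "pdb_sequence_coverage": [s.pdb_sequence_coverage for s in summaries],
            "pdb_total_coverage": [s.pdb_total_coverage for s in summaries],
        }
    )


# ---------------------------------------------------------------------------
# File readers: classic DSSP output, structural-feature TSV, SIFTS-style map


def read_dssp(path: str | Path) -> list[tuple[str, int, str, float]]:
    """Parse a classic DSSP text file into (chain, resnum, residue, ASA) rows.

    Residue numbers are author numbering; chain-break rows ('!') are
    skipped. ASA is the integer ACC column in A^2.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path}: no DSSP residue table header ('#  RESIDUE ...') found")
    out = []
    for line in lines[start:]:
        if len(line) < 38:
            continue
        aa = line[13]
        if aa == "!":
            continue
        chain = line[11].strip()
        try:
            resnum = int(line[5:10])
            asa = float(line[34:38])
        except ValueError:
            continue
        if aa.islower():  # DSSP lower-case letters mark SS-bonded cysteines
            aa = "C"
        out.append((chain, resnum, aa, asa))
    return out


def read_sifts_tsv(path: str | Path) -> pd.DataFrame:
    """SIFTS-style residue mapping TSV: pdb_id, chain, pdb_resnum, accession, uniprot_pos."""
    df = pd.read_csv(path, sep="\t", dtype={"pdb_id": str, "chain": str})
    required = {"pdb_id", "chain", "pdb_resnum", "accession", "uniprot_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SIFTS mapping TSV lacks columns: {sorted(missing)}")
    return df


def records_from_dssp(
    dssp_rows: Sequence[tuple[str, int, str, float]],
    pdb_id: str,
    sifts: pd.DataFrame,
    asa_table: Literal["theoretical", "empirical"] = "theoretical",
) -> list[ResidueStructuralRecord]:
    """Join DSSP per-residue ASA with a SIFTS-style mapping into records."""
    key = sifts[sifts["pdb_id"] == pdb_id]
    lookup = {
        (row.chain, int(row.pdb_resnum)): (row.accession, int(row.uniprot_pos))
        for row in key.itertuples(index=False)
    }
    out = []
    for chain, resnum, aa, asa in dssp_rows:
        mapped = lookup.get((chain, resnum))
        if mapped is None:
            continue
        out.append(
            ResidueStructuralRecord(
                pdb_id=pdb_id,
                chain=chain,
                accession=mapped[0],
                position=mapped[1],
                residue_type=aa,
                rsa=rsa_from_asa(asa, aa, asa_table),
            )
        )
    return out


def read_structural_tsv(path: str | Path) -> list[ResidueStructuralRecord]:
    """Read a per-residue structural feature TSV.

    Columns: pdb_id, chain, accession, position, residue_type, then either
    rsa or asa (asa is converted via the theoretical max-ASA table), plus
    boolean ligand_contact and domain_contact.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pdb_id": str, "chain": str})
    out = []
    for row in df.itertuples(index=False):
        if hasattr(row, "rsa") and row.rsa == row.rsa:
            rsa = float(row.rsa)
        elif hasattr(row, "asa"):
            rsa = rsa_from_asa(float(row.asa), str(row.residue_type))
        else:
            rsa = float("nan")
        out.append(
            ResidueStructuralRecord(
                pdb_id=str(row.pdb_id),
                chain=str(row.chain),
                accession=str(row.accession),
                position=int(row.position),
                residue_type=str(getattr(row, "residue_type", "X")),
                rsa=rsa,
                ligand_contact=bool(getattr(row, "ligand_contact", False)),
                domain_contact=bool(getattr(row, "domain_contact", False)),
            )
        )
    return out


def write_structural_tsv(records: Sequence[ResidueStructuralRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pdb_id": r.pdb_id,
                "chain": r.chain,
                "accession": r.accession,
                "position": r.position,
                "residue_type": r.residue_type,
                "rsa": r.rsa,
                "ligand_contact": r.ligand_contact,
                "domain_contact": r.domain_contact,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
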