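"""Parsing variant inputs and tallying them onto alignment columns.

Variants arrive either as a VEP-annotated VCF (the ``CSQ`` INFO field must
carry ``SwissProt`` and ``Protein_position`` sub-fields) or as a pre-mapped
TSV with columns (accession, position, consequence, clinical_label,
allele_id). The unit of counting is one alternate allele at one protein
position; allele frequency plays no role. Every input variant ends up in
exactly one of three buckets: counted in a column, dropped (maps outside the
domain or to an absent accession), or skipped (unparseable annotation) — the
reports make that conservation auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .msa_io import DomainAlignment

Consequence = Literal["missense", "synonymous", "other"]
ClinicalLabel = Literal["pathogenic", "benign", "uncertain", "none"]

#: ClinVar significance strings treated as pathogenic by default.
DEFAULT_PATHOGENIC_LABELS = frozenset({"Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"})

_CONSEQUENCE_MAP = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
}


@dataclass(frozen=True)
class ProteinVariant:
    accession: str
    position: int
    consequence: Consequence
    clinical_label: ClinicalLabel = "none"
    allele_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ColumnVariantCounts:
    """Per-column variant tallies alongside human occupancy."""

    column: int
    n_missense: int = 0
    n_synonymous: int = 0
    n_pathogenic: int = 0
    n_human_residues: int = 0


@dataclass
class ParseReport:
    """Bookkeeping for variants that could not be used, by reason."""

    n_parsed: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)
    n_range_positions: int = 0

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] += 1


@dataclass
class TallyReport:
    n_counted: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)
    n_duplicates: int = 0

    def drop(self, reason: str) -> None:
        self.n_dropped += 1
        self.drop_reasons[reason] += 1


def _classify_consequence(term: str) -> Consequence:
    for sub in term.split("&"):
        if sub in _CONSEQUENCE_MAP:
            return _CONSEQUENCE_MAP[sub]  # type: ignore[return-value]
    return "other"


def _parse_protein_position(raw: str, report: ParseReport) -> int | None:
    """First integer of a Protein_position field; ranges take the start."""
    raw = raw.strip()
    if not raw:
        return None
    head = raw.split("-")[0]
    if "-" in raw:
        report.n_range_positions += 1
    try:
        pos = int(head)
    except ValueError:
        return None
    return pos if pos >= 1 else None


def parse_vep_vcf(
    path: str | Path,
    pathogenic_labels: Iterable[str] = DEFAULT_PATHOGENIC_LABELS,
    benign_labels: Iterable[str] = ("Benign", "Likely_benign"),
) -> tuple[list[ProteinVariant], ParseReport]:
    """Extract protein-level variants from a VEP-annotated VCF.

    Emits one :class:`ProteinVariant` per (record x alternate allele x
    distinct SwissProt mapping). CSQ entries without a SwissProt accession or
    a parseable integer protein position are skipped and tallied in the
    report. The clinical label is read from INFO/CLNSIG when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    csq_fields = _csq_field_index(vcf)
    pathogenic = set(pathogenic_labels)
    benign = set(benign_labels)
    report = ParseReport()
    variants: list[ProteinVariant] = []
    for rec in vcf:
        csq = rec.INFO.get("CSQ")
        if csq is None:
            report.skip("no_csq")
            continue
        clnsig = rec.INFO.get("CLNSIG")
        label = _clinical_label(clnsig, pathogenic, benign)
        alts = rec.ALT or [""]
        seen: set[tuple[str, int, str]] = set()
        for entry in csq.split(","):
            parts = entry.split("|")

            def get(name: str) -> str:
                idx = csq_fields[name]
                return parts[idx] if idx < len(parts) else ""

            swissprot = get("SwissProt").split("&")[0].split(".")[0]
            if not swissprot:
                report.skip("no_swissprot")
                continue
            pos = _parse_protein_position(get("Protein_position"), report)
            if pos is None:
                report.skip("bad_protein_position")
                continue
            allele = get("Allele") if "Allele" in csq_fields else (alts[0] or "")
            key = (swissprot, pos, allele)
            if key in seen:
                continue
            seen.add(key)
            variants.append(
                ProteinVariant(
                    accession=swissprot,
                    position=pos,
                    consequence=_classify_consequence(get("Consequence")),
                    clinical_label=label,
                    allele_id=f"{rec.CHROM}:{rec.POS}:{rec.REF}:{allele}",
                )
            )
            report.n_parsed += 1
    return variants, report


def _csq_field_index(vcf) -> dict[str, int]:
    try:
        desc = vcf.get_header_type("CSQ")["Description"]
    except KeyError as exc:
        raise ValueError("VCF lacks a CSQ header definition (not VEP-annotated?)") from exc
    fmt = desc.split("Format:")[-1].strip().strip('"')
    fields = {name.strip(): i for i, name in enumerate(fmt.split("|"))}
    for required in ("SwissProt", "Protein_position", "Consequence"):
        if required not in fields:
            raise ValueError(f"CSQ format lacks required sub-field {required!r}")
    return fields


def _clinical_label(clnsig, pathogenic: set[str], benign: set[str]) -> ClinicalLabel:
    if not clnsig:
        return "none"
    for part in str(clnsig).replace("|", ",").split(","):
        if part.strip() in pathogenic:
            return "pathogenic"
    for part in str(clnsig).replace("|", ",").split(","):
        if part.strip() in benign:
            return "benign"
    return "uncertain"


def read_variant_tsv(path: str | Path) -> list[ProteinVariant]:
    """Read the pre-mapped TSV alternative (accession, position, consequence,
    clinical_label, allele_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "position", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProteinVariant(
                accession=row.accession,
                position=int(row.position),
                consequence=row.consequence,
                clinical_label=getattr(row, "clinical_label", "none") or "none",
                allele_id=str(getattr(row, "allele_id", "") or ""),
            )
        )
    return out


def write_variant_tsv(variants: Sequence[ProteinVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": v.accession,
                "position": v.position,
                "consequence": v.consequence,
                "clinical_label": v.clinical_label,
                "allele_id": v.allele_id,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def tally_columns(
    variants: Iterable[ProteinVariant],
    alignment: DomainAlignment,
) -> tuple[list[ColumnVariantCounts], TallyReport]:
    """Map variants onto alignment columns via the human sequences.

    Variants are de-duplicated on (accession, position, allele_id) so a
    repeated annotation of the same allele is counted once. A variant whose
    accession has no human sequence in the alignment, or whose position falls
    outside every aligned range for that accession, is dropped and reported.
    Pathogenic tallies count missense variants carrying a pathogenic label.
    """
    from .msa_io import occupancies

    humans = [s for s in alignment.sequences if s.is_human]
    if not humans:
        raise ValueError(f"{alignment.family_id}: no human sequences to map variants onto")
    by_acc: dict[str, list] = {}
    for s in humans:
        by_acc.setdefault(s.accession, []).append(s)

    occ = occupancies(alignment)
    n_mis = [0] * alignment.n_columns
    n_syn = [0] * alignment.n_columns
    n_path = [0] * alignment.n_columns
    report = TallyReport()
    seen: set[tuple[str, int, str]] = set()
    for v in sorted(variants, key=lambda v: (v.accession, v.position, v.allele_id)):
        key = (v.accession, v.position, v.allele_id)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        seqs = by_acc.get(v.accession)
        if not seqs:
            report.drop("accession_not_in_alignment")
            continue
        col = None
        for s in seqs:
            col = s.column_of(v.position)
            if col is not None:
                break
        if col is None:
            report.drop("position_outside_domain")
            continue
        i = col - 1
        if v.consequence == "missense":
            n_mis[i] += 1
            if v.clinical_label == "pathogenic":
                n_path[i] += 1
        elif v.consequence == "synonymous":
            n_syn[i] += 1
        else:
            report.drop("consequence_other")
            continue
        report.n_counted += 1
    return (
        [
            ColumnVariantCounts(
                column=i + 1,
                n_missense=n_mis[i],
                n_synonymous=n_syn[i],
                n_pathogenic=n_path[i],
                n_human_residues=occ[i].occupancy_human,
            )
            for i in range(alignment.n_columns)
        ],
        report,
    )
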