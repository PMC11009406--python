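"""Synthetic domain families with known ground truth.

Every downstream stage — variant tallying, Shenkin ranking, MES calls, the
regression, structural aggregation and enrichment — can be exercised against
alignments, variant sets and structural tables whose generating truth is
known. Conserved truth columns draw from one or two residue types while
unconserved columns draw from six or more, so evolutionary diversity is
controllable per column. Missense counts are Poisson per human residue with
a per-column rate (depleted columns get a reduced rate, enriched columns an
elevated one); synonymous counts use a divergence-independent rate, mirroring
their role as a negative control. Structural tables emit several
pseudo-chains per residue with exposure noise around the truth class and
contact flags drawn once per residue, so chain-count manipulations test the
coverage-bias invariance of the aggregation.

Every generator is a pure function of its parameters and seed.

What this emulates — and what it does not: columns are independent, rates
are homogeneous within a truth class, and there is no phylogenetic
correlation between sequences, no allele-frequency structure and no
mutability variation between residue types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msa_io import AlignedSequence, DomainAlignment
from .struct_features import ResidueStructuralRecord
from .variant_map import ProteinVariant

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SPECIES = ("MOUSE", "BOVIN", "CHICK", "XENLA", "DANRE", "DROME", "CAEEL", "YEAST")

_RSA_BY_CLASS = {"core": 2.0, "partially_exposed": 15.0, "surface": 50.0}
_EXPOSURES = ("core", "partially_exposed", "surface")


@dataclass(frozen=True)
class DomainTruth:
    """Per-column generating parameters of a synthetic family."""

    true_rate: tuple[float, ...]
    true_class: tuple[str, ...]  # depleted | neutral | enriched
    true_conservation: tuple[str, ...]  # conserved | unconserved
    true_exposure: tuple[str, ...]
    ligand_prob: tuple[float, ...]
    domain_prob: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.true_rate):
            raise ValueError("rates must be nonnegative")
        for p in (*self.ligand_prob, *self.domain_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def make_alignment(
    n_sequences: int = 50,
    n_human: int = 10,
    n_columns: int = 40,
    conservation_profile: Sequence[int] | None = None,
    frac_conserved: float = 0.5,
    frac_depleted: float = 0.2,
    baseline_rate: float = 0.46,
    depleted_rate_ratio: float = 0.1,
    frac_enriched: float = 0.0,
    enriched_rate_ratio: float = 3.0,
    gap_fraction: float = 0.05,
    base_ligand_prob: float = 0.05,
    ligand_enrichment: float = 8.0,
    base_domain_prob: float = 0.05,
    domain_enrichment: float = 4.0,
    seed: int = 0,
) -> tuple[DomainAlignment, DomainTruth]:
    """Generate a family alignment plus its ground truth.

    ``conservation_profile`` optionally fixes the number of allowed residue
    types per column (1-2 => conserved truth, >= 6 => unconserved); by
    default ``frac_conserved`` of columns are conserved. Depleted truth
    columns (rate = baseline * depleted_rate_ratio) are drawn preferentially
    from the conserved set and biased towards buried exposure and elevated
    contact probabilities, echoing the structural correlates of constraint.
    Human sequences are generated gap-free so human occupancy is uniform
    across columns.
    """
    if n_human > n_sequences:
        raise ValueError("n_human cannot exceed n_sequences")
    rng = np.random.default_rng(seed)

    if conservation_profile is not None:
        profile = np.asarray(conservation_profile, dtype=int)
        if profile.size != n_columns:
            raise ValueError("conservation_profile length must equal n_columns")
        if profile.min() < 1 or profile.max() > len(AMINO_ACIDS):
            raise ValueError("per-column residue-type counts must lie in [1, 20]")
        conserved_mask = profile <= 2
    else:
        n_cons = int(round(frac_conserved * n_columns))
        conserved_mask = np.zeros(n_columns, dtype=bool)
        conserved_mask[rng.choice(n_columns, size=n_cons, replace=False)] = True
        profile = np.where(
            conserved_mask,
            rng.integers(1, 3, size=n_columns),
            rng.integers(6, 13, size=n_columns),
        )

    # constraint truth: depleted columns preferentially conserved
    n_dep = int(round(frac_depleted * n_columns))
    n_enr = int(round(frac_enriched * n_columns))
    order = np.lexsort((rng.random(n_columns), ~conserved_mask))
    depleted_idx = set(order[:n_dep])
    remaining = [i for i in order[::-1] if i not in depleted_idx]
    enriched_idx = set(remaining[:n_enr])
    classes, rates, exposures, lig_p, dom_p = [], [], [], [], []
    for j in range(n_columns):
        if j in depleted_idx:
            classes.append("depleted")
            rates.append(baseline_rate * depleted_rate_ratio)
            exposures.append(_EXPOSURES[rng.choice(3, p=[0.6, 0.25, 0.15])])
            lig_p.append(min(1.0, base_ligand_prob * ligand_enrichment))
            dom_p.append(min(1.0, base_domain_prob * domain_enrichment))
        elif j in enriched_idx:
            classes.append("enriched")
            rates.append(baseline_rate * enriched_rate_ratio)
            exposures.append(_EXPOSURES[rng.choice(3, p=[0.15, 0.25, 0.6])])
            lig_p.append(base_ligand_prob)
            dom_p.append(base_domain_prob)
        else:
            classes.append("neutral")
            rates.append(baseline_rate)
            exposures.append(_EXPOSURES[rng.choice(3, p=[0.25, 0.35, 0.4])])
            lig_p.append(base_ligand_prob)
            dom_p.append(base_domain_prob)

    # residue pools per column
    pools = [rng.choice(list(AMINO_ACIDS), size=int(k), replace=False) for k in profile]

    sequences = []
    for i in range(n_sequences):
        human = i < n_human
        residues = [pools[j][rng.integers(len(pools[j]))] for j in range(n_columns)]
        if not human and gap_fraction > 0:
            gap_mask = rng.random(n_columns) < gap_fraction
            # never gap out a whole sequence
            if gap_mask.all():
                gap_mask[rng.integers(n_columns)] = False
            chars = ["-" if g else r for r, g in zip(residues, gap_mask)]
        else:
            chars = residues
        seq = "".join(chars)
        n_res = sum(1 for ch in seq if ch != "-")
        if human:
            acc, species = f"HS{i:03d}", "HUMAN"
        else:
            acc, species = f"SQ{i:03d}", _SPECIES[i % len(_SPECIES)]
        start = int(rng.integers(1, 200))
        sequences.append(
            AlignedSequence(
                accession=acc,
                species_tag=species,
                is_human=human,
                start=start,
                end=start + n_res - 1,
                gapped_sequence=seq,
            )
        )
    alignment = DomainAlignment(family_id=f"SYN{seed:05d}", sequences=tuple(sequences))
    truth = DomainTruth(
        true_rate=tuple(rates),
        true_class=tuple(classes),
        true_conservation=tuple(
            "conserved" if c else "unconserved" for c in conserved_mask
        ),
        true_exposure=tuple(exposures),
        ligand_prob=tuple(lig_p),
        domain_prob=tuple(dom_p),
    )
    return alignment, truth


def make_variants(
    alignment: DomainAlignment,
    truth: DomainTruth,
    seed: int = 0,
    synonymous_rate: float = 0.5,
    pathogenic_prob: float = 0.0,
    pathogenic_columns: Sequence[int] | None = None,
) -> list[ProteinVariant]:
    """Draw per-residue variant counts from the truth rates.

    Missense counts are Poisson with the column's true rate per human
    residue; synonymous counts are Poisson with a flat, divergence-
    independent rate. If ``pathogenic_prob`` > 0, pathogenic missense
    variants are planted at ``pathogenic_columns`` (1-based; default: the
    truth-depleted columns) with that per-residue probability.
    """
    rng = np.random.default_rng(seed)
    if pathogenic_columns is None:
        path_cols = {j + 1 for j, c in enumerate(truth.true_class) if c == "depleted"}
    else:
        path_cols = set(pathogenic_columns)
    variants: list[ProteinVariant] = []
    for seq in alignment.sequences:
        if not seq.is_human:
            continue
        for col in range(1, alignment.n_columns + 1):
            hit = seq.residue_at(col)
            if hit is None:
                continue
            pos = hit[0]
            for k in range(rng.poisson(truth.true_rate[col - 1])):
                variants.append(
                    ProteinVariant(
                        accession=seq.accession,
                        position=pos,
                        consequence="missense",
                        allele_id=f"m{col}.{k}",
                    )
                )
            for k in range(rng.poisson(synonymous_rate)):
                variants.append(
                    ProteinVariant(
                        accession=seq.accession,
                        position=pos,
                        consequence="synonymous",
                        allele_id=f"s{col}.{k}",
                    )
                )
            if pathogenic_prob > 0 and col in path_cols and rng.random() < pathogenic_prob:
                variants.append(
                    ProteinVariant(
                        accession=seq.accession,
                        position=pos,
                        consequence="missense",
                        clinical_label="pathogenic",
                        allele_id=f"p{col}",
                    )
                )
    return variants


def make_structural_features(
    alignment: DomainAlignment,
    truth: DomainTruth,
    seed: int = 0,
    n_chains: int = 3,
    exposure_noise: float = 0.0,
    coverage_fraction: float = 1.0,
) -> list[ResidueStructuralRecord]:
    """Emit pseudo-chain structural records consistent with the truth.

    Contact flags are drawn once per residue and replicated across its
    chains (a real contact is a property of the residue, observed in
    whichever structures capture it); exposure is perturbed independently
    per chain with probability ``exposure_noise``. ``coverage_fraction``
    controls which sequences have structures at all.
    """
    rng = np.random.default_rng(seed)
    records: list[ResidueStructuralRecord] = []
    for si, seq in enumerate(alignment.sequences):
        if rng.random() > coverage_fraction:
            continue
        chain_ids = [(f"{1000 + si * 10 + c:04d}", "A") for c in range(n_chains)]
        for col in range(1, alignment.n_columns + 1):
            hit = seq.residue_at(col)
            if hit is None:
                continue
            pos, aa = hit
            lig = bool(rng.random() < truth.ligand_prob[col - 1])
            dom = bool(rng.random() < truth.domain_prob[col - 1])
            true_exp = truth.true_exposure[col - 1]
            for pdb_id, chain in chain_ids:
                exp = true_exp
                if exposure_noise > 0 and rng.random() < exposure_noise:
                    exp = _EXPOSURES[rng.integers(3)]
                records.append(
                    ResidueStructuralRecord(
                        pdb_id=pdb_id,
                        chain=chain,
                        accession=seq.accession,
                        position=pos,
                        residue_type=aa,
                        rsa=_RSA_BY_CLASS[exp],
                        ligand_contact=lig,
                        domain_contact=dom,
                    )
                )
    return records
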