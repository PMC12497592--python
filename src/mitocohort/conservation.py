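"""Conservation index (CI) from a multi-species alignment.

CI of a site is the proportion of non-reference species carrying the
reference (wild-type) symbol at that site: high CI marks strong evolutionary
constraint.  The reference (human) row is the first sequence of the
alignment and is excluded from both numerator and denominator by default;
gaps and ambiguity codes count as mismatches.  The prioritization filter
downstream requires CI strictly greater than 75%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio import AlignIO

from .genome import GenomeMap, Variant, VariantEffect

CI_THRESHOLD = 0.75

GAP_CHARS = set("-.")


@dataclass
class SpeciesAlignment:
    """A multi-species alignment, first row = reference (human)."""

    species_ids: list[str]
    rows: list[str]
    level: str  # "nucleotide" | "amino_acid"

    def __post_init__(self) -> None:
        if len(self.species_ids) != len(self.rows):
            raise ValueError("one id per row required")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    @classmethod
    def from_fasta(cls, path, level: str = "nucleotide") -> "SpeciesAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(
            species_ids=[rec.id for rec in aln],
            rows=[str(rec.seq) for rec in aln],
            level=level,
        )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]

    def reference_column_of(self, position: int) -> Optional[int]:
        """Alignment column (0-based) of the 1-based ungapped reference
        position; None if the position extends beyond the reference row."""
        seen = 0
        for i, ch in enumerate(self.rows[0]):
            if ch not in GAP_CHARS:
                seen += 1
                if seen == position:
                    return i
        return None


def conservation_index(
    aln: SpeciesAlignment,
    column: int,
    wild_type: str,
    include_reference: bool = False,
) -> float:
    """CI of one alignment column: fraction of (non-reference) species whose
    symbol equals the wild-type symbol.

    ``include_reference=True`` switches the denominator to all species, for
    users who prefer to count the reference row itself.
    """
    if not 0 <= column < aln.n_columns:
        raise IndexError(f"column {column} outside alignment")
    wild_type = wild_type.upper()
    col = aln.column(column)
    if col[0] != wild_type:
        raise ValueError(
            f"wild_type {wild_type!r} disagrees with reference symbol "
            f"{col[0]!r} at column {column}"
        )
    symbols = col if include_reference else col[1:]
    if not symbols:
        raise ValueError("alignment has no comparison species")
    matches = sum(1 for s in symbols if s == wild_type)
    return matches / len(symbols)


@dataclass
class CIResult:
    variant: Variant
    level: Optional[str]
    ci: Optional[float]
    status: str  # "pass" | "fail" | "no_ci"


def variant_ci(
    v: Variant,
    effect: VariantEffect,
    aln_nt: SpeciesAlignment,
    aln_aa_by_gene: Optional[Mapping[str, SpeciesAlignment]] = None,
    threshold: float = CI_THRESHOLD,
    include_reference: bool = False,
) -> CIResult:
    """CI for one variant at the appropriate level.

    Amino-acid-changing protein variants are scored on the per-gene protein
    alignment at the affected residue; everything else on the nucleotide
    alignment at the variant position.  Unalignable sites (reference gap,
    missing gene alignment) are flagged ``no_ci`` rather than passed.
    """
    protein_levels = {"nonsynonymous", "stop_gain"}
    if effect.coding_effect in protein_levels and effect.codon_index is not None:
        aln = (aln_aa_by_gene or {}).get(effect.region)
        if aln is None or effect.ref_aa is None:
            return CIResult(v, "amino_acid", None, "no_ci")
        col = aln.reference_column_of(effect.codon_index + 1)
        wild = effect.ref_aa
        level = "amino_acid"
    else:
        aln = aln_nt
        col = aln.reference_column_of(v.position)
        wild = v.ref[0]
        level = "nucleotide"
    if col is None:
        return CIResult(v, level, None, "no_ci")
    ci = conservation_index(aln, col, wild, include_reference=include_reference)
    status = "pass" if ci > threshold else "fail"
    return CIResult(v, level, ci, status)


def conserved_filter(
    variants: Iterable[Variant],
    effects: Mapping[tuple[int, str, str], VariantEffect],
    aln_nt: SpeciesAlignment,
    aln_aa_by_gene: Optional[Mapping[str, SpeciesAlignment]] = None,
    gm: Optional[GenomeMap] = None,
    threshold: float = CI_THRESHOLD,
    include_reference: bool = False,
) -> list[CIResult]:
    """Annotate each variant with its CI and pass/fail at the strict
    threshold (default CI > 75%)."""
    out = []
    for v in variants:
        eff = effects.get(v.key)
        if eff is None:
            out.append(CIResult(v, None, None, "no_ci"))
            continue
        out.append(variant_ci(v, eff, aln_nt, aln_aa_by_gene,
                              threshold=threshold,
                              include_reference=include_reference))
    return out
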