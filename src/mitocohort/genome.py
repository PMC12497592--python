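"""Mitochondrial genome map, variant representation and functional effect
prediction.

Coordinates are 1-based inclusive on the circular 16,569 bp human
mitochondrial reference (rCRS numbering).  The control region wraps the
origin (16024-576) and is represented with an explicit ``wrap`` flag.
Protein-coding features are translated with the vertebrate mitochondrial
genetic code (NCBI table 2), in which ATA encodes Met, TGA encodes Trp and
AGA/AGG are stop codons.  Several mitochondrial ORFs end in an incomplete
stop codon completed by polyadenylation of the mRNA; those features carry an
``incomplete_stop`` flag and their trailing partial codon is not translated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Optional

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GENOME_LENGTH = 16569

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

FEATURE_KINDS = ("protein", "tRNA", "rRNA", "control", "noncoding")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One annotated interval of the mitochondrial genome.

    ``start``/``end`` are 1-based inclusive.  ``wrap=True`` marks a feature
    spanning the circular origin, in which case membership is
    ``pos >= start or pos <= end``.
    """

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)
    kind: str
    wrap: bool = False
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not self.wrap and self.start > self.end:
            raise ValueError(
                f"feature {self.name}: start > end without wrap flag"
            )

    def contains(self, position: int) -> bool:
        if self.wrap:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def length(self, genome_length: int = GENOME_LENGTH) -> int:
        if self.wrap:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class GenomeMap:
    """Ordered collection of genome features (37 genes + control region).

    Overlapping features (e.g. ATP8/ATP6, ND4L/ND4) are permitted; position
    lookups attribute overlapped positions to the first feature in map order
    and log the alternatives.
    """

    features: list[Feature]
    genome_length: int = GENOME_LENGTH

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        for f in self.features:
            if not (1 <= f.start <= self.genome_length
                    and 1 <= f.end <= self.genome_length):
                raise ValueError(
                    f"feature {f.name} outside [1, {self.genome_length}]"
                )
            if f.kind == "protein":
                if f.length(self.genome_length) % 3 != 0 and not f.incomplete_stop:
                    raise ValueError(
                        f"protein feature {f.name} has length not divisible "
                        "by 3 and no incomplete_stop flag"
                    )

    @classmethod
    def from_tsv(cls, path, genome_length: int = GENOME_LENGTH) -> "GenomeMap":
        feats = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                row = line.rstrip("\n").split("\t")
                feats.append(Feature(
                    name=row[idx["name"]],
                    start=int(row[idx["start"]]),
                    end=int(row[idx["end"]]),
                    strand=row[idx["strand"]],
                    kind=row[idx["kind"]],
                    wrap=bool(int(row[idx.get("wrap", -1)])) if "wrap" in idx else False,
                    incomplete_stop=(bool(int(row[idx["incomplete_stop"]]))
                                     if "incomplete_stop" in idx else False),
                ))
        return cls(features=feats, genome_length=genome_length)

    @classmethod
    def default(cls) -> "GenomeMap":
        """The packaged rCRS gene-coordinate table."""
        return cls.from_tsv(files("mitocohort.data") / "rcrs_genes.tsv")

    def features_at(self, position: int) -> list[Feature]:
        if not (1 <= position <= self.genome_length):
            raise ValueError(
                f"position {position} outside [1, {self.genome_length}]"
            )
        return [f for f in self.features if f.contains(position)]

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(\d+)_([ACGTN]+)>([ACGTN]+)$")


@dataclass(frozen=True)
class Variant:
    """A site-level change on the mitochondrial reference.

    ``ref``/``alt`` follow VCF-style anchored notation: an insertion keeps
    the anchor base in both alleles (``302 A>AC``), a deletion keeps it in
    ``ref``.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        ref, alt = self.ref.upper(), self.alt.upper()
        if not set(ref) <= set("ACGTN") or not set(alt) <= set("ACGTN"):
            raise ValueError(f"non-nucleotide allele in {ref}>{alt}")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if len(ref) == len(alt) and len(ref) > 1:
            raise ValueError(
                "multi-nucleotide substitutions are not supported; "
                "decompose into single-base substitutions"
            )
        if ref == alt:
            raise ValueError("ref and alt are identical")

    @property
    def var_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "substitution"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def label(self) -> str:
        """MitoMap-style label, e.g. ``302_A>AC``."""
        return f"{self.position}_{self.ref}>{self.alt}"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


def parse_variant(label: str) -> Variant:
    """Parse a MitoMap-style ``pos_REF>ALT`` label into a :class:`Variant`."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse variant label {label!r}")
    return Variant(position=int(m.group(1)), ref=m.group(2), alt=m.group(3))


def assign_region(v: Variant, gm: GenomeMap) -> str:
    """Name of the feature containing the variant position, or "intergenic".

    Overlapping features are resolved to the first in map order; the
    alternatives are logged at DEBUG level.
    """
    hits = gm.features_at(v.position)
    if not hits:
        return "intergenic"
    if len(hits) > 1:
        logger.debug(
            "position %d overlaps features %s; attributing to %s",
            v.position, [f.name for f in hits], hits[0].name,
        )
    return hits[0].name


def classify_substitution(v: Variant) -> str:
    """Classify as transition, transversion or indel.

    Purine<->purine and pyrimidine<->pyrimidine single-base changes are
    transitions; purine<->pyrimidine changes are transversions; everything
    else (length-changing variants) is an indel.
    """
    if v.var_class != "substitution":
        return "indel"
    r, a = v.ref, v.alt
    if (r in PURINES and a in PURINES) or (r in PYRIMIDINES and a in PYRIMIDINES):
        return "transition"
    return "transversion"


# ---------------------------------------------------------------------------
# Effect prediction
# ---------------------------------------------------------------------------

MITO_CODON_TABLE_ID = 2  # vertebrate mitochondrial


@dataclass(frozen=True)
class VariantEffect:
    region: str
    coding_effect: str  # synonymous | nonsynonymous | frameshift | stop_gain | noncoding
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    substitution_class: str  # transition | transversion | indel
    codon_index: Optional[int] = None  # 0-based codon within the protein


def translate_codon(codon: str) -> str:
    """Translate one codon with the vertebrate mitochondrial code."""
    return str(Seq(codon).translate(table=MITO_CODON_TABLE_ID))


def _check_ref(v: Variant, ref_seq: str) -> None:
    obs = ref_seq[v.position - 1: v.position - 1 + len(v.ref)].upper()
    if obs != v.ref:
        raise ValueError(
            f"variant {v.label}: ref allele disagrees with reference "
            f"sequence ({obs!r} at position {v.position})"
        )


def predict_effect(v: Variant, gm: GenomeMap, ref_seq: str) -> VariantEffect:
    """Predict the functional effect of a variant.

    For protein features the affected codon is rebuilt in the feature's
    reading frame; light-strand genes are reverse-complemented before
    translation.  Indels whose net length change is not a multiple of three
    are frameshifts; in-frame indels are reported as nonsynonymous (amino
    acids unset).  Variants in the untranslated partial stop codon of
    incomplete-stop ORFs are reported with amino acids unset.
    """
    if len(ref_seq) != gm.genome_length:
        raise ValueError("reference sequence length does not match genome map")
    _check_ref(v, ref_seq)
    region = assign_region(v, gm)
    sub_class = classify_substitution(v)

    if region == "intergenic":
        return VariantEffect(region, "noncoding", None, None, sub_class)
    feat = gm.feature_by_name(region)
    if feat.kind != "protein":
        return VariantEffect(region, "noncoding", None, None, sub_class)

    if v.var_class != "substitution":
        shift = abs(len(v.ref) - len(v.alt)) % 3 != 0
        effect = "frameshift" if shift else "nonsynonymous"
        return VariantEffect(region, effect, None, None, "indel")

    # single-base substitution inside a protein feature
    if feat.strand == "H":
        offset = v.position - feat.start
    else:
        offset = feat.end - v.position
    codon_idx = offset // 3
    within = offset % 3
    n_full_codons = feat.length(gm.genome_length) // 3
    if codon_idx >= n_full_codons:
        # inside the trailing partial stop codon (completed by polyadenylation)
        return VariantEffect(region, "nonsynonymous", None, None, sub_class,
                             codon_index=codon_idx)

    if feat.strand == "H":
        cstart = feat.start - 1 + 3 * codon_idx
        codon = ref_seq[cstart:cstart + 3].upper()
        alt_codon = codon[:within] + v.alt + codon[within + 1:]
    else:
        gene = reverse_complement(ref_seq[feat.start - 1: feat.end])
        codon = gene[3 * codon_idx: 3 * codon_idx + 3]
        alt_codon = codon[:within] + COMPLEMENT[v.alt] + codon[within + 1:]

    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        effect = "stop_gain"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return VariantEffect(region, effect, ref_aa, alt_aa, sub_class,
                         codon_index=codon_idx)


def translate_gene(feat: Feature, ref_seq: str,
                   genome_length: int = GENOME_LENGTH) -> str:
    """Translate a whole protein feature from the reference sequence."""
    seq = ref_seq[feat.start - 1: feat.end].upper()
    if feat.strand == "L":
        seq = reverse_complement(seq)
    n = (len(seq) // 3) * 3
    return str(Seq(seq[:n]).translate(table=MITO_CODON_TABLE_ID))
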