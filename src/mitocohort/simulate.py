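"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analyses assume: a
two-group cohort (146 cases / 120 controls by default) in which each
individual carries

* the homoplasmic defining-variant closure of a haplogroup drawn from
  group-specific frequency vectors (defaults follow the published
  case/control haplogroup distribution, which encodes a protective
  D4 odds ratio of about 0.45),
* a Poisson number of private variants at uniform random non-defining
  positions, each heteroplasmic with a configurable probability, with
  heteroplasmy fractions drawn from Uniform(0.01, 0.98) — spanning the full
  observable band between the exclusion floor and the homoplasmy boundary,
* binomially sampled read support: depth ~ depth law, alternate reads ~
  Binomial(depth, f') with f' the true fraction perturbed by a symmetric
  per-read miscall rate (default 0.001), which is what makes the HF < 1%
  exclusion rule meaningful.

A single integer seed drives every draw through one NumPy generator, so
cohorts (and their VCF serializations) are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .calls import SampleCall, classify_state
from .genome import GENOME_LENGTH, Variant
from .haplotyping import Phylotree

# Default haplogroup frequencies: the published cohort's macro-haplogroup
# counts over 146 cases and 120 controls, with the "Others" mass placed on
# the N9a stand-in lineage of the packaged tree.
TABLE1_CASE_COUNTS = {
    "A": 14, "B": 25, "D4": 14, "D5": 7, "F": 29,
    "G": 12, "M7": 15, "R": 14, "Z": 3, "N9a": 13,
}
TABLE1_CONTROL_COUNTS = {
    "A": 5, "B": 16, "D4": 23, "D5": 2, "F": 22,
    "G": 6, "M7": 10, "R": 16, "Z": 7, "N9a": 13,
}


def _freqs(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def uniform_het_fraction(low: float = 0.01, high: float = 0.98
                         ) -> Callable[[np.random.Generator, int], np.ndarray]:
    def law(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size=size)
    return law


def poisson_depth(mean: float = 500.0
                  ) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Shifted Poisson depth law (support on positive integers)."""
    def law(rng: np.random.Generator, size: int) -> np.ndarray:
        return 1 + rng.poisson(mean - 1, size=size)
    return law


@dataclass
class CohortDesign:
    n_cases: int = 146
    n_controls: int = 120
    haplogroup_freq_cases: dict[str, float] = field(
        default_factory=lambda: _freqs(TABLE1_CASE_COUNTS))
    haplogroup_freq_controls: dict[str, float] = field(
        default_factory=lambda: _freqs(TABLE1_CONTROL_COUNTS))
    private_variant_rate: float = 5.0  # Poisson mean per individual
    het_probability: float = 0.5  # P(private variant is heteroplasmic)
    het_fraction_law: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=uniform_het_fraction)
    depth_law: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=poisson_depth)
    error_rate: float = 0.001  # symmetric per-read miscall probability
    seed: int = 0

    def __post_init__(self) -> None:
        for name, freqs in (("cases", self.haplogroup_freq_cases),
                            ("controls", self.haplogroup_freq_controls)):
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} haplogroup frequencies sum to {s}, not 1")
        if not 0.0 <= self.het_probability <= 1.0:
            raise ValueError("het_probability must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must lie in [0, 0.01)")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_cases + self.n_controls == 0:
            raise ValueError("cohort must contain at least one sample")


@dataclass
class SimCall:
    variant: Variant
    true_hf: float
    depth: int
    alt_reads: int

    def to_sample_call(self, sample_id: str) -> SampleCall:
        return SampleCall(sample_id, self.variant, self.alt_reads, self.depth)


@dataclass
class SimulatedSample:
    sample_id: str
    group: str  # "case" | "control"
    true_haplogroup: str
    calls: list[SimCall]

    def sample_calls(self) -> list[SampleCall]:
        return [c.to_sample_call(self.sample_id) for c in self.calls]

    def observed_variants(self) -> list[Variant]:
        """Variants whose observed state survives the HF < 1% exclusion."""
        out = []
        for c in self.calls:
            if c.alt_reads > 0 and classify_state(c.alt_reads / c.depth) != "excluded":
                out.append(c.variant)
        return out


def simulate_read_support(
    true_hf: np.ndarray,
    depth: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial alternate-read counts for given true fractions and depths.

    The per-read success probability is the true fraction perturbed by the
    symmetric miscall rate: f' = f(1-e) + (1-f)e.
    """
    true_hf = np.asarray(true_hf, dtype=float)
    depth = np.asarray(depth, dtype=int)
    p = true_hf * (1 - error_rate) + (1 - true_hf) * error_rate
    return rng.binomial(depth, p)


def simulate_cohort(
    design: CohortDesign,
    tree: Optional[Phylotree] = None,
    ref_seq: Optional[str] = None,
) -> list[SimulatedSample]:
    """Draw a full synthetic cohort; reproducible given ``design.seed``."""
    from .reference import synthetic_rcrs

    if tree is None:
        tree = Phylotree.default()
    if ref_seq is None:
        ref_seq = synthetic_rcrs()
    for label in set(design.haplogroup_freq_cases) | set(design.haplogroup_freq_controls):
        if label not in tree.parent:
            raise ValueError(f"haplogroup {label!r} not present in the phylotree")

    rng = np.random.default_rng(design.seed)
    tree_positions = {k[0] for k in tree.all_defining_variants()}
    bases = "ACGT"
    samples: list[SimulatedSample] = []

    specs = ([("case", design.haplogroup_freq_cases)] * design.n_cases
             + [("control", design.haplogroup_freq_controls)] * design.n_controls)
    width = len(str(len(specs)))
    for i, (group, freqs) in enumerate(specs):
        labels = sorted(freqs)
        probs = np.array([freqs[l] for l in labels])
        hap = labels[rng.choice(len(labels), p=probs)]

        calls: list[SimCall] = []
        defining = sorted(tree.closure(hap))
        hfs = [1.0] * len(defining)
        variants = [Variant(pos, ref, alt) for pos, ref, alt in defining]

        n_private = rng.poisson(design.private_variant_rate)
        used = set(tree_positions) | {v.position for v in variants}
        for _ in range(n_private):
            while True:
                pos = int(rng.integers(1, GENOME_LENGTH + 1))
                if pos not in used:
                    used.add(pos)
                    break
            ref = ref_seq[pos - 1]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            variants.append(Variant(pos, ref, alt))
            if rng.random() < design.het_probability:
                hfs.append(float(design.het_fraction_law(rng, 1)[0]))
            else:
                hfs.append(1.0)

        if variants:
            depths = design.depth_law(rng, len(variants)).astype(int)
            alts = simulate_read_support(np.array(hfs), depths,
                                         design.error_rate, rng)
            calls = [SimCall(v, hf, int(d), int(a))
                     for v, hf, d, a in zip(variants, hfs, depths, alts)]
        samples.append(SimulatedSample(
            sample_id=f"S{i + 1:0{width}d}", group=group,
            true_haplogroup=hap, calls=calls))
    return samples


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def cohort_vcf(samples: list[SimulatedSample],
               genome_length: int = GENOME_LENGTH) -> str:
    """Render a cohort as a multi-sample VCF string (GT:AD:DP).

    Pure deterministic text rendering: identical cohorts give byte-identical
    output.  Samples not carrying a variant get missing FORMAT values.
    """
    sample_ids = [s.sample_id for s in samples]
    by_variant: dict[tuple, dict[str, SimCall]] = {}
    for s in samples:
        for c in s.calls:
            by_variant.setdefault(c.variant.key, {})[s.sample_id] = c

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chrM,length={genome_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Read depth per allele (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for key in sorted(by_variant):
        pos, ref, alt = key
        carriers = by_variant[key]
        fields = []
        for sid in sample_ids:
            c = carriers.get(sid)
            if c is None:
                fields.append(".:.:.")
            else:
                gt = "1" if c.alt_reads / c.depth >= 0.5 else "0"
                fields.append(f"{gt}:{c.depth - c.alt_reads},{c.alt_reads}:{c.depth}")
        lines.append(
            f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t"
            + "\t".join(fields)
        )
    return "\n".join(lines) + "\n"


def write_vcf(samples: list[SimulatedSample], path) -> None:
    with open(path, "w") as fh:
        fh.write(cohort_vcf(samples))


def groups_frame(samples: list[SimulatedSample]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "group": [s.group for s in samples],
    })


def truth_frame(samples: list[SimulatedSample]) -> pd.DataFrame:
    """Per-sample, per-call truth table for parameter-recovery tests."""
    if not samples:
        raise ValueError("cohort is empty")
    rows = []
    for s in samples:
        for c in s.calls:
            rows.append({
                "sample_id": s.sample_id,
                "group": s.group,
                "true_haplogroup": s.true_haplogroup,
                "position": c.variant.position,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "true_hf": c.true_hf,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
            })
    cols = ["sample_id", "group", "true_haplogroup", "position", "ref",
            "alt", "true_hf", "depth", "alt_reads"]
    return pd.DataFrame(rows, columns=cols)


def write_truth(samples: list[SimulatedSample], path) -> None:
    truth_frame(samples).to_csv(path, sep="\t", index=False)
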