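"""Per-sample variant calls: heteroplasmy fractions, state classification,
cohort-level variant summaries and population-frequency bins.

Heteroplasmy fraction (HF) is the fraction of reads supporting the variant
allele at a site.  Calls with HF below 1% are excluded as likely artefacts;
1% <= HF < 98% is heteroplasmic; HF >= 98% is homoplasmic (boundary 0.01 is
heteroplasmic, boundary 0.98 is homoplasmic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from cyvcf2 import VCF

from .genome import Variant

logger = logging.getLogger(__name__)

HF_EXCLUDE_BELOW = 0.01
HF_HOMOPLASMIC_FROM = 0.98

STATE_EXCLUDED = "excluded"
STATE_HET = "heteroplasmic"
STATE_HOM = "homoplasmic"


def compute_hf(alt_reads: int, total_reads: int) -> float:
    """Heteroplasmy fraction: variant-supporting reads over total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive to compute HF")
    if alt_reads < 0 or alt_reads > total_reads:
        raise ValueError("alt_reads must lie in [0, total_reads]")
    return alt_reads / total_reads


def classify_state(hf: float) -> str:
    """Classify an HF value as excluded (<1%), heteroplasmic or homoplasmic."""
    if not 0.0 <= hf <= 1.0:
        raise ValueError("hf must lie in [0, 1]")
    if hf < HF_EXCLUDE_BELOW:
        return STATE_EXCLUDED
    if hf < HF_HOMOPLASMIC_FROM:
        return STATE_HET
    return STATE_HOM


def bin_frequency(af: float) -> str:
    """Bin a population allele frequency: common (>=5%),
    low_frequency (0.5%-5%) or rare (<0.5%); both boundaries inclusive in
    the higher bin."""
    if not 0.0 <= af <= 1.0:
        raise ValueError("af must lie in [0, 1]")
    if af >= 0.05:
        return "common"
    if af >= 0.005:
        return "low_frequency"
    return "rare"


@dataclass(frozen=True)
class SampleCall:
    """One variant observed in one individual, with read support."""

    sample_id: str
    variant: Variant
    alt_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.alt_reads > self.total_reads:
            raise ValueError("alt_reads must lie in [0, total_reads]")

    @property
    def hf(self) -> float:
        return compute_hf(self.alt_reads, self.total_reads)

    @property
    def state(self) -> str:
        return classify_state(self.hf)


@dataclass
class CohortVariantSummary:
    variant: Variant
    carriers_cases: int
    carriers_controls: int
    state_profile: str  # heteroplasmic_only | homoplasmic_only | both
    control_freq: float
    known: bool
    freq_bin: str
    known_af: float = 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> list[SampleCall]:
    """Read a multi-sample VCF with AD/DP FORMAT fields into SampleCalls.

    Multi-allelic records are split into biallelic calls; a call is emitted
    for every sample with at least one alternate-supporting read.  Total
    depth is taken from DP when present, else from the sum of AD.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[SampleCall] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        dp = rec.format("DP")
        if dp is not None:
            dp = dp.reshape(len(samples), -1)[:, 0]
        for j, alt in enumerate(rec.ALT):
            v = Variant(position=rec.POS, ref=rec.REF, alt=alt)
            for i, sid in enumerate(samples):
                alt_reads = int(ad[i, j + 1]) if ad.shape[1] > j + 1 else -1
                if alt_reads <= 0:
                    continue
                if dp is not None and int(dp[i]) > 0:
                    total = int(dp[i])
                else:
                    total = int(sum(x for x in ad[i] if x > 0))
                calls.append(SampleCall(sid, v, alt_reads, total))
    return calls


def calls_to_vcf(calls: Iterable[SampleCall],
                 genome_length: int = 16569) -> str:
    """Render SampleCalls as a multi-sample VCF string (GT:AD:DP).

    Inverse of :func:`read_vcf` up to record ordering: reading the output
    back yields the same set of calls.
    """
    calls = list(calls)
    sample_ids = sorted({c.sample_id for c in calls})
    by_variant: dict[tuple, dict[str, SampleCall]] = {}
    for c in calls:
        by_variant.setdefault(c.variant.key, {})[c.sample_id] = c
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
                gt = "1" if c.hf >= 0.5 else "0"
                fields.append(
                    f"{gt}:{c.total_reads - c.alt_reads},{c.alt_reads}:"
                    f"{c.total_reads}")
        lines.append(f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t"
                     + "\t".join(fields))
    return "\n".join(lines) + "\n"


def read_sample_groups(path) -> dict[str, str]:
    """Read a sample-metadata TSV (columns sample_id, group) into a map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("groups file needs columns sample_id, group")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return dict(zip(df["sample_id"], df["group"]))


def read_annotation(path) -> dict[tuple[int, str, str], dict]:
    """Read a variant annotation TSV (pos, ref, alt, known_af, disease_link).

    The table stands in for a catalogue of previously reported variants;
    presence of a variant marks it as known, absence as novel.
    """
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        key = (int(row.pos), str(row.ref).upper(), str(row.alt).upper())
        out[key] = {
            "known_af": float(getattr(row, "known_af", 0.0)),
            "disease_link": str(getattr(row, "disease_link", "")),
        }
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_variant(
    calls: Iterable[SampleCall],
    groups: Mapping[str, str],
    annotation: Optional[Mapping[tuple[int, str, str], dict]] = None,
    n_controls: Optional[int] = None,
) -> Optional[CohortVariantSummary]:
    """Summarize one variant across the cohort.

    Excluded calls (HF < 1%) are dropped first; returns None (with a log
    entry) if no carriers remain.  ``control_freq`` is the carrier frequency
    among control samples (mtDNA treated as haploid per individual).
    """
    calls = list(calls)
    keys = {c.variant.key for c in calls}
    if len(keys) != 1:
        raise ValueError("summarize_variant expects calls for a single variant")
    variant = calls[0].variant
    retained = [c for c in calls if c.state != STATE_EXCLUDED]
    if not retained:
        logger.info("variant %s dropped: no carriers after HF exclusion",
                    variant.label)
        return None
    if n_controls is None:
        n_controls = sum(1 for g in groups.values() if g == "control")
    states = {c.state for c in retained}
    if states == {STATE_HET}:
        profile = "heteroplasmic_only"
    elif states == {STATE_HOM}:
        profile = "homoplasmic_only"
    else:
        profile = "both"
    cc = sum(1 for c in retained if groups[c.sample_id] == "case")
    cn = sum(1 for c in retained if groups[c.sample_id] == "control")
    ann = (annotation or {}).get(variant.key)
    known = ann is not None
    known_af = ann["known_af"] if known else 0.0
    return CohortVariantSummary(
        variant=variant,
        carriers_cases=cc,
        carriers_controls=cn,
        state_profile=profile,
        control_freq=cn / n_controls if n_controls else 0.0,
        known=known,
        freq_bin=bin_frequency(known_af),
        known_af=known_af,
    )


def summarize_cohort(
    calls: Iterable[SampleCall],
    groups: Mapping[str, str],
    annotation: Optional[Mapping[tuple[int, str, str], dict]] = None,
) -> tuple[list[CohortVariantSummary], int]:
    """Summarize every distinct variant in the cohort.

    Returns the summaries plus the count of variants dropped entirely by the
    HF < 1% exclusion (logged, so the bookkeeping between "variants seen"
    and "variants analyzed" stays auditable).
    """
    by_variant: dict[tuple, list[SampleCall]] = {}
    for c in calls:
        by_variant.setdefault(c.variant.key, []).append(c)
    n_controls = sum(1 for g in groups.values() if g == "control")
    summaries = []
    n_dropped = 0
    for key in sorted(by_variant):
        s = summarize_variant(by_variant[key], groups, annotation,
                              n_controls=n_controls)
        if s is None:
            n_dropped += 1
        else:
            summaries.append(s)
    if n_dropped:
        logger.info("%d variant(s) excluded entirely (all carriers HF < 1%%)",
                    n_dropped)
    return summaries, n_dropped


def summaries_to_frame(summaries: Iterable[CohortVariantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "position": s.variant.position,
            "ref": s.variant.ref,
            "alt": s.variant.alt,
            "var_class": s.variant.var_class,
            "carriers_cases": s.carriers_cases,
            "carriers_controls": s.carriers_controls,
            "state_profile": s.state_profile,
            "control_freq": s.control_freq,
            "known": s.known,
            "known_af": s.known_af,
            "freq_bin": s.freq_bin,
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[SampleCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id,
            "position": c.variant.position,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "alt_reads": c.alt_reads,
            "total_reads": c.total_reads,
            "hf": c.hf,
            "state": c.state,
        })
    return pd.DataFrame(rows)
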