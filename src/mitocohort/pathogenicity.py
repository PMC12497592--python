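"""Variant-prioritization cascade.

A variant is prioritized when it survives, in order:

1. a control-population frequency filter (carrier frequency < 1% among
   healthy controls; anything at or above is treated as a polymorphism),
2. an evolutionary-conservation filter (CI strictly > 75%),
3. a region-appropriate classifier:
   - tRNA variants: MitoTIP raw-score quartile classes, with Likely
     Pathogenic (> 16.25) and Possibly Pathogenic (12.66-16.25) counted as
     deleterious;
   - nonsynonymous protein variants: a consensus vote over 13 independent
     deleteriousness predictors, requiring more than six deleterious calls
     (missing predictions count as non-deleterious votes).

The cascade consumes pre-computed scores; it never executes the external
predictors.  Every variant carries an audit trail recording the first stage
at which it stopped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .calls import CohortVariantSummary
from .conservation import CIResult
from .genome import Variant, VariantEffect

# MitoTIP raw-score quartile boundaries
MITOTIP_LP = 16.25
MITOTIP_PP = 12.66
MITOTIP_PB = 8.44

CONTROL_FREQ_MAX = 0.01


# ---------------------------------------------------------------------------
# Predictor registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolConfig:
    name: str
    threshold: float
    direction: str  # "higher" | "lower"

    def verdict(self, score: Optional[float]) -> str:
        if score is None:
            return "missing"
        if self.direction == "higher":
            return "deleterious" if score >= self.threshold else "benign"
        return "deleterious" if score <= self.threshold else "benign"


def load_tool_registry(path=None) -> dict[str, ToolConfig]:
    """Load the predictor registry (defaults to the packaged 13-tool file)."""
    if path is None:
        path = files("mitocohort.data") / "predictor_tools.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    reg = {}
    for name, spec in cfg["tools"].items():
        direction = spec["direction"]
        if direction not in ("higher", "lower"):
            raise ValueError(f"tool {name}: bad direction {direction!r}")
        reg[name] = ToolConfig(name, float(spec["threshold"]), direction)
    return reg


@dataclass(frozen=True)
class PredictorCall:
    tool: str
    score: Optional[float]
    verdict: str  # deleterious | benign | missing

    @classmethod
    def from_score(cls, tool: str, score: Optional[float],
                   registry: Mapping[str, ToolConfig]) -> "PredictorCall":
        if tool not in registry:
            raise ValueError(f"unknown predictor tool {tool!r}")
        return cls(tool, score, registry[tool].verdict(score))


def read_mitotip_scores(path) -> dict[tuple[int, str, str], float]:
    """Read a MitoTIP score TSV (columns: variant, score) keyed by
    ``pos_REF>ALT`` labels."""
    from .genome import parse_variant

    df = pd.read_csv(path, sep="\t")
    return {parse_variant(str(r.variant)).key: float(r.score)
            for r in df.itertuples(index=False)}


def read_predictor_matrix(
    path,
    registry: Optional[Mapping[str, ToolConfig]] = None,
) -> dict[tuple[int, str, str], list[PredictorCall]]:
    """Read a long-format predictor-score TSV (columns: variant, tool,
    score; empty score = missing) into per-variant predictor calls."""
    from .genome import parse_variant

    if registry is None:
        registry = load_tool_registry()
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[int, str, str], list[PredictorCall]] = {}
    for r in df.itertuples(index=False):
        key = parse_variant(str(r.variant)).key
        score = None if pd.isna(r.score) else float(r.score)
        out.setdefault(key, []).append(
            PredictorCall.from_score(str(r.tool), score, registry))
    return out


# ---------------------------------------------------------------------------
# Stage classifiers
# ---------------------------------------------------------------------------

def frequency_filter(summary: CohortVariantSummary,
                     threshold: float = CONTROL_FREQ_MAX) -> bool:
    """True when the control carrier frequency is below 1%."""
    return summary.control_freq < threshold


def mitotip_classify(score: Optional[float]) -> str:
    """Map a MitoTIP raw score to its quartile class.

    Boundaries at 12.66 and 8.44 go to the higher class (PP, PB); 16.25
    stays PP because only the LP bound is printed strictly.
    """
    if score is None:
        return "n/a"
    if score > MITOTIP_LP:
        return "LP"
    if score >= MITOTIP_PP:
        return "PP"
    if score >= MITOTIP_PB:
        return "PB"
    return "LB"


def consensus_vote(calls: Iterable[PredictorCall],
                   registry: Optional[Mapping[str, ToolConfig]] = None,
                   min_votes: Optional[int] = None) -> tuple[int, bool]:
    """Count deleterious verdicts and apply the more-than-half rule.

    With the default 13-tool registry the variant is deleterious when more
    than six tools call it deleterious; missing verdicts count as
    non-deleterious votes against the fixed denominator.
    """
    if registry is None:
        registry = load_tool_registry()
    calls = list(calls)
    seen = set()
    for c in calls:
        if c.tool not in registry:
            raise ValueError(f"unknown predictor tool {c.tool!r}")
        if c.tool in seen:
            raise ValueError(f"duplicate predictor call for tool {c.tool!r}")
        seen.add(c.tool)
    if min_votes is None:
        min_votes = len(registry) // 2 + 1  # "more than half"
    votes = sum(1 for c in calls if c.verdict == "deleterious")
    return votes, votes >= min_votes


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    variant: Variant
    region: Optional[str]
    passed_frequency: Optional[bool]
    passed_conservation: Optional[bool]
    mitotip_class: str  # LP | PP | PB | LB | n/a
    consensus_votes: Optional[int]
    final: str  # deleterious_tRNA | deleterious_protein | not_prioritized
    stage: str  # region | frequency | conservation | no_ci | classifier | no_data | passed


def run_cascade(
    summaries: Mapping[tuple[int, str, str], CohortVariantSummary],
    effects: Mapping[tuple[int, str, str], VariantEffect],
    ci_results: Mapping[tuple[int, str, str], CIResult],
    mitotip_scores: Mapping[tuple[int, str, str], float],
    predictor_calls: Mapping[tuple[int, str, str], list[PredictorCall]],
    region_kinds: Mapping[str, str],
    registry: Optional[Mapping[str, ToolConfig]] = None,
) -> list[CascadeResult]:
    """Run the full prioritization cascade over a cohort's variants.

    ``region_kinds`` maps feature names to their kinds (from the genome
    map).  Variants missing from a required input table stop at stage
    ``no_data``; nothing is silently dropped.
    """
    if registry is None:
        registry = load_tool_registry()
    results = []
    for key in sorted(summaries):
        s = summaries[key]
        v = s.variant
        eff = effects.get(key)
        if eff is None:
            results.append(CascadeResult(v, None, None, None, "n/a", None,
                                         "not_prioritized", "no_data"))
            continue
        kind = region_kinds.get(eff.region, "noncoding")
        is_trna = kind == "tRNA"
        is_protein_candidate = kind == "protein" and eff.coding_effect == "nonsynonymous"
        if not (is_trna or is_protein_candidate):
            results.append(CascadeResult(v, eff.region, None, None, "n/a",
                                         None, "not_prioritized", "region"))
            continue

        passed_freq = frequency_filter(s)
        if not passed_freq:
            results.append(CascadeResult(v, eff.region, False, None, "n/a",
                                         None, "not_prioritized", "frequency"))
            continue

        ci = ci_results.get(key)
        if ci is None:
            results.append(CascadeResult(v, eff.region, True, None, "n/a",
                                         None, "not_prioritized", "no_data"))
            continue
        if ci.status == "no_ci":
            results.append(CascadeResult(v, eff.region, True, None, "n/a",
                                         None, "not_prioritized", "no_ci"))
            continue
        if ci.status != "pass":
            results.append(CascadeResult(v, eff.region, True, False, "n/a",
                                         None, "not_prioritized", "conservation"))
            continue

        if is_trna:
            mclass = mitotip_classify(mitotip_scores.get(key))
            if mclass in ("LP", "PP"):
                results.append(CascadeResult(v, eff.region, True, True,
                                             mclass, None,
                                             "deleterious_tRNA", "passed"))
            else:
                results.append(CascadeResult(v, eff.region, True, True,
                                             mclass, None,
                                             "not_prioritized", "classifier"))
        else:
            pcalls = predictor_calls.get(key)
            if pcalls is None:
                results.append(CascadeResult(v, eff.region, True, True, "n/a",
                                             None, "not_prioritized", "no_data"))
                continue
            votes, deleterious = consensus_vote(pcalls, registry)
            final = "deleterious_protein" if deleterious else "not_prioritized"
            stage = "passed" if deleterious else "classifier"
            results.append(CascadeResult(v, eff.region, True, True, "n/a",
                                         votes, final, stage))
    return results


def cascade_to_frame(results: Iterable[CascadeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "variant": r.variant.label,
            "region": r.region,
            "passed_frequency": r.passed_frequency,
            "passed_conservation": r.passed_conservation,
            "mitotip_class": r.mitotip_class,
            "consensus_votes": r.consensus_votes,
            "final": r.final,
            "stage": r.stage,
        })
    return pd.DataFrame(rows)


def stage_counts(results: Iterable[CascadeResult]) -> dict[str, int]:
    """Audit-trail tally: how many variants stopped at each stage."""
    counts: dict[str, int] = {}
    for r in results:
        counts[r.stage] = counts.get(r.stage, 0) + 1
    return counts
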