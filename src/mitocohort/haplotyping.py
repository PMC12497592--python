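"""Haplogroup assignment against a phylotree of defining variants.

A haplogroup is a maternal lineage defined by a characteristic variant set;
lineages are arranged on a rooted tree and a node's *defining closure* is
the union of defining variants along its path from the root.  Samples are
assigned with a symmetric (Kulczynski-style) match score

    score(h) = 1/2 * ( |S ∩ D_h| / |D_h|  +  |S ∩ D_h| / |S_inf| )

where ``S`` is the sample's (mask-filtered) variant set, ``D_h`` the node's
defining closure and ``S_inf`` the informative subset of ``S`` — sample
variants occurring anywhere in the tree.  Variants absent from the tree thus
never affect the score.  Ties break toward the deeper node, then the
lexicographically smaller label.  This scorer is a deterministic,
simulation-validated stand-in for heavier weighted-rank classifiers; the
package's focus is the downstream case-control association.

Known hypervariable/hotspot positions (length-polymorphic control-region
runs and position 16519) are masked from scoring by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome import Variant, parse_variant

VariantKey = tuple[int, str, str]

#: positions excluded from haplogroup scoring by default
DEFAULT_HOTSPOT_MASK = frozenset({302, 309, 315, 523, 524, 16182, 16183, 16189, 16519})


@dataclass
class Phylotree:
    """Rooted haplogroup hierarchy with per-node defining variant sets."""

    parent: dict[str, Optional[str]]  # node -> parent (root maps to None)
    defining: dict[str, frozenset[VariantKey]]
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.parent or self.parent[self.root] is not None:
            raise ValueError("root must be present with no parent")
        for node, par in self.parent.items():
            if node == self.root:
                continue
            if par not in self.parent:
                raise ValueError(f"node {node}: unknown parent {par!r}")
        # acyclicity: every node must reach the root
        for node in self.parent:
            seen = set()
            cur: Optional[str] = node
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected at node {node}")
                seen.add(cur)
                cur = self.parent[cur]
            if self.root not in seen:
                raise ValueError(f"node {node} does not reach the root")
        self._closure_cache: dict[str, frozenset[VariantKey]] = {}

    @classmethod
    def from_tsv(cls, path) -> "Phylotree":
        """Read a phylotree TSV (haplogroup, parent, defining_variants)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        parent: dict[str, Optional[str]] = {}
        defining: dict[str, frozenset[VariantKey]] = {}
        root = None
        for row in df.itertuples(index=False):
            label = row.haplogroup
            par = row.parent or None
            if par is None:
                root = label
            parent[label] = par
            dv = frozenset(
                parse_variant(lbl).key
                for lbl in str(row.defining_variants).split(",") if lbl
            )
            defining[label] = dv
        if root is None:
            raise ValueError("phylotree has no root (empty parent field)")
        return cls(parent=parent, defining=defining, root=root)

    @classmethod
    def default(cls) -> "Phylotree":
        """The packaged synthetic phylotree (synthetic stand-in topology)."""
        return cls.from_tsv(files("mitocohort.data") / "phylotree_synthetic.tsv")

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def depth(self, label: str) -> int:
        d = 0
        cur = self.parent[label]
        while cur is not None:
            d += 1
            cur = self.parent[cur]
        return d

    def closure(self, label: str) -> frozenset[VariantKey]:
        """Defining-variant closure: union along the path to the root."""
        if label not in self.parent:
            raise KeyError(label)
        if label not in self._closure_cache:
            par = self.parent[label]
            base = self.closure(par) if par is not None else frozenset()
            self._closure_cache[label] = base | self.defining[label]
        return self._closure_cache[label]

    def all_defining_variants(self) -> frozenset[VariantKey]:
        out: set[VariantKey] = set()
        for dv in self.defining.values():
            out |= dv
        return frozenset(out)


@dataclass
class HaplogroupAssignment:
    sample_id: str
    best: str
    score: float
    runner_up: Optional[str]
    margin: float


def _as_keys(variants: Iterable) -> set[VariantKey]:
    keys = set()
    for v in variants:
        if isinstance(v, Variant):
            keys.add(v.key)
        elif isinstance(v, str):
            keys.add(parse_variant(v).key)
        else:
            keys.add(tuple(v))
    return keys


def assign_haplogroup(
    sample_variants: Iterable,
    tree: Phylotree,
    sample_id: str = "",
    mask: frozenset[int] = DEFAULT_HOTSPOT_MASK,
) -> HaplogroupAssignment:
    """Assign the best-scoring haplogroup for a sample's variant set.

    Accepts Variants, ``pos_REF>ALT`` labels or (pos, ref, alt) tuples.
    Samples with no tree-informative variant are returned as
    ``unclassified`` with score 0.
    """
    if not tree.parent:
        raise ValueError("empty phylotree")
    raw = _as_keys(sample_variants)
    if not raw:
        raise ValueError("sample variant set is empty")
    S = {k for k in raw if k[0] not in mask}
    informative = S & tree.all_defining_variants()
    if not informative:
        return HaplogroupAssignment(sample_id, "unclassified", 0.0, None, 0.0)

    scored = []
    for node in tree.nodes:
        D = tree.closure(node)
        if not D:
            continue  # the root has nothing to match against
        inter = len(informative & D)
        score = 0.5 * (inter / len(D) + inter / len(informative))
        scored.append((score, tree.depth(node), node))
    # best score, deeper node wins ties, then lexicographically smaller label
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_score, _, best = scored[0]
    if len(scored) > 1:
        runner_score, _, runner = scored[1][0], scored[1][1], scored[1][2]
    else:
        runner_score, runner = 0.0, None
    return HaplogroupAssignment(sample_id, best, best_score, runner,
                                best_score - runner_score)


def assignments_to_frame(
    assignments: Iterable[HaplogroupAssignment],
) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": a.sample_id,
        "haplogroup": a.best,
        "score": a.score,
        "runner_up": a.runner_up,
        "margin": a.margin,
    } for a in assignments])


#: macro-haplogroup labels reported in the association tables
DEFAULT_MAJOR_LABELS = ("A", "B", "D4", "D5", "F", "G", "M7", "R", "Z")


def pool_label(label: str, major_labels: Sequence[str]) -> str:
    """Truncate a haplogroup label to its major prefix, else "Others".

    The longest matching major label wins (so D4a -> D4 even when both D
    and D4 are listed)."""
    best = ""
    for m in major_labels:
        if label.startswith(m) and len(m) > len(best):
            best = m
    return best or "Others"


def pool_haplogroups(
    assignments: Iterable[HaplogroupAssignment],
    major_labels: Sequence[str] = DEFAULT_MAJOR_LABELS,
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Pool assignments into macro-haplogroup counts, optionally by group.

    Returns a DataFrame indexed by pooled label (majors in given order, then
    "Others") with either a single ``count`` column or ``case``/``control``
    columns when a group map is supplied.  Totals are conserved.
    """
    index = list(major_labels) + ["Others"]
    cols = ["case", "control"] if groups is not None else ["count"]
    counts = pd.DataFrame(0, index=index, columns=cols)
    for a in assignments:
        pooled = pool_label(a.best, major_labels)
        col = groups[a.sample_id] if groups is not None else "count"
        counts.loc[pooled, col] += 1
    return counts
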