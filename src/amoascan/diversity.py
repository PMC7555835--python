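"""Alpha-diversity accounting: rarefaction, RA-threshold OTU richness,
Shannon index and Faith's phylogenetic diversity.

The Shannon index defaults to natural log (nats); pass ``log_base=2`` for
bits - pipelines built on different QIIME generations disagree on the base,
so it is explicit here.  Faith's PD is the rooted form: the sum of branch
lengths of the minimal subtree connecting the observed tips to the root of
a user-supplied tree (tree inference is out of scope; the synthetic
generator emits a matching truth tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "OTUCountVector",
    "DiversitySummary",
    "DEFAULT_RA_THRESHOLDS",
    "rarefy",
    "richness_at_thresholds",
    "shannon",
    "faith_pd",
    "summarize_sample",
]

#: RA thresholds (percent) used for the richness profile.
DEFAULT_RA_THRESHOLDS: tuple[float, ...] = (0.0, 0.01, 0.1, 0.5, 1.0)


@dataclass
class OTUCountVector:
    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"sample {self.sample_id}: negative counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DiversitySummary:
    sample_id: str
    richness_at: dict[float, int]
    shannon: float
    pd: Optional[float] = None


def rarefy(counts: OTUCountVector, depth: int, seed: int) -> OTUCountVector:
    """Uniform subsample without replacement to a fixed depth.

    Reproducible under a fixed seed (multivariate hypergeometric draw).
    """
    total = counts.total
    if depth > total:
        raise ValueError(
            f"sample {counts.sample_id}: rarefaction depth {depth} exceeds total {total}"
        )
    if depth < 0:
        raise ValueError("depth must be non-negative")
    ids = sorted(counts.counts)
    vec = np.array([counts.counts[i] for i in ids], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(vec, depth)
    return OTUCountVector(
        sample_id=counts.sample_id,
        counts={i: int(c) for i, c in zip(ids, sub) if c > 0},
    )


def richness_at_thresholds(
    counts: OTUCountVector | Mapping[str, int],
    thresholds: Sequence[float] = DEFAULT_RA_THRESHOLDS,
) -> dict[float, int]:
    """Number of OTUs whose RA (percent of sample total) meets each threshold.

    At threshold 0.0 this is the count of OTUs with positive count.
    """
    cmap = counts.counts if isinstance(counts, OTUCountVector) else dict(counts)
    total = sum(cmap.values())
    if total == 0:
        raise ValueError("empty sample: richness undefined")
    out: dict[float, int] = {}
    for thr in thresholds:
        out[thr] = sum(1 for c in cmap.values() if c > 0 and 100.0 * c / total >= thr)
    return out


def shannon(counts: OTUCountVector | Mapping[str, int], log_base: float = math.e) -> float:
    """Shannon index H = -sum p_i log(p_i) over OTUs with p_i > 0."""
    cmap = counts.counts if isinstance(counts, OTUCountVector) else dict(counts)
    total = sum(cmap.values())
    if total == 0:
        raise ValueError("all-zero count vector: Shannon undefined")
    h = 0.0
    for c in cmap.values():
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h / math.log(log_base)


def faith_pd(tree: TreeNode, observed_otus: Iterable[str]) -> float:
    """Faith's phylogenetic diversity (rooted).

    Sum of branch lengths of edges whose subtree contains at least one
    observed tip, i.e. the minimal subtree spanning the observed tips and
    the root.  Branches without a stated length count as 0.
    """
    observed = set(observed_otus)
    if not observed:
        return 0.0
    tips = {t.name for t in tree.tips()}
    missing = sorted(observed - tips)
    if missing:
        raise ValueError(f"observed OTUs absent from tree: {missing}")
    total = 0.0
    # post-order: a branch is on the spanning subtree iff its clade holds
    # an observed tip
    has_observed: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            flag = node.name in observed
        else:
            flag = any(has_observed[id(c)] for c in node.children)
        has_observed[id(node)] = flag
        if flag and node.parent is not None and node.length:
            total += node.length
    return total


def summarize_sample(
    counts: OTUCountVector,
    tree: Optional[TreeNode] = None,
    thresholds: Sequence[float] = DEFAULT_RA_THRESHOLDS,
    log_base: float = math.e,
) -> DiversitySummary:
    """Richness profile, Shannon index and (with a tree) Faith's PD."""
    pd_val = None
    if tree is not None:
        observed = [o for o, c in counts.counts.items() if c > 0]
        pd_val = faith_pd(tree, observed)
    return DiversitySummary(
        sample_id=counts.sample_id,
        richness_at=richness_at_thresholds(counts, thresholds),
        shannon=shannon(counts, log_base),
        pd=pd_val,
    )
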