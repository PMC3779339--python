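"""Serial (heterochronous) coalescent simulation of genealogies.

Backwards-in-time, event-driven simulation over a realized
:class:`~paleoabc.demography.Demography`.  Tips activate when simulation
time reaches their age; within a deme of size ``N(t)`` each pair of active
lineages coalesces at rate ``1/N(t)`` (so ``k`` lineages coalesce at total
rate ``k(k-1)/(2 N(t))``); under piecewise-exponential size trajectories the
waiting time is drawn by analytic inversion of the time-transformed rate.
Lineages move between demes at the per-generation probabilities of the
migration matrix, and at a merge event all lineages of the source demes
transfer to the destination deme.  ``N`` is the haploid (female, mtDNA)
effective size throughout.

Candidate event times are cached next-reaction style: a deme's pending
coalescence draw stays valid until its lineage count changes, which keeps
the number of random draws linear in the number of events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .demography import Demography, Epoch

__all__ = [
    "SampleDesign",
    "Genealogy",
    "simulate_genealogy",
    "tmrca",
    "total_branch_length",
]


@dataclass(frozen=True)
class SampleTip:
    id: str
    deme: str
    age: float  # generations BP
    age_years: float | None = None  # original calendar age, if known


class SampleDesign:
    """The sampling structure a simulation is conditioned on."""

    def __init__(self, tips: Iterable[SampleTip]):
        self.tips = list(tips)
        if any(t.age < 0 for t in self.tips):
            raise ValueError("tip ages must be >= 0")

    @classmethod
    def from_counts(
        cls, entries: Sequence[tuple[str, float, int]]
    ) -> "SampleDesign":
        """Build from (deme, age-in-generations, count) triples."""
        tips = []
        for deme, age, count in entries:
            if count < 1:
                raise ValueError("counts must be >= 1")
            for _ in range(count):
                tips.append(SampleTip(id=f"{deme}_{len(tips)}", deme=deme, age=float(age)))
        return cls(tips)

    @classmethod
    def from_alignment(cls, alignment, generation_time: float) -> "SampleDesign":
        """Condition on an observed dataset: one tip per sample.

        Backward time 0 is anchored at the youngest sample; the offset (in
        years) is stored as :attr:`time_offset_years`.
        """
        ages = alignment.ages
        offset = float(ages.min()) if len(ages) else 0.0
        tips = [
            SampleTip(
                id=s.id,
                deme=s.deme,
                age=(s.age - offset) / generation_time,
                age_years=s.age,
            )
            for s in alignment
        ]
        design = cls(tips)
        design.time_offset_years = offset
        return design

    time_offset_years: float = 0.0

    @property
    def n(self) -> int:
        return len(self.tips)

    @property
    def demes(self) -> list[str]:
        return list(dict.fromkeys(t.deme for t in self.tips))


class Genealogy:
    """A dated binary coalescent tree over heterochronous tips.

    Nodes ``0..n-1`` are tips (in sampling-design order), nodes
    ``n..2n-2`` internal; ``times`` are generations BP and
    ``parent[root] == -1``.
    """

    def __init__(
        self,
        times: np.ndarray,
        parent: np.ndarray,
        tip_ids: Sequence[str],
        tip_demes: Sequence[str],
        tip_ages_years: Sequence[float] | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.tip_ids = list(tip_ids)
        self.tip_demes = list(tip_demes)
        self.tip_ages_years = (
            np.asarray(tip_ages_years, dtype=float) if tip_ages_years is not None else None
        )
        n = len(self.tip_ids)
        if len(self.times) != 2 * n - 1:
            raise ValueError("a binary tree over n tips has 2n-1 nodes")
        has_parent = self.parent >= 0
        if (self.times[self.parent[has_parent]] <= self.times[has_parent]).any():
            raise ValueError("parent times must exceed child times")

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def tmrca(self) -> float:
        return float(self.times[self.root])

    def total_branch_length(self) -> float:
        has_parent = self.parent >= 0
        return float((self.times[self.parent[has_parent]] - self.times[has_parent]).sum())

    # -- newick serialization ---------------------------------------------
    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for child, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(child)

        def label(node: int) -> str:
            if node < self.n_tips:
                age = (
                    self.tip_ages_years[node]
                    if self.tip_ages_years is not None
                    else self.times[node]
                )
                return f"{self.tip_ids[node]}|{self.tip_demes[node]}|{age:g}"
            return ""

        def rec(node: int) -> str:
            if node < self.n_tips:
                body = label(node)
            else:
                body = "(" + ",".join(rec(c) for c in children[node]) + ")"
            p = self.parent[node]
            if p < 0:
                return body
            return f"{body}:{self.times[p] - self.times[node]:.10g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Genealogy":
        """Parse a tree serialized by :meth:`to_newick` (labels ``id|deme|age``)."""
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        leaves = list(tree.leaf_node_iter())
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        n = len(leaves)
        index = {id(nd): i for i, nd in enumerate(leaves)}
        index.update({id(nd): n + i for i, nd in enumerate(internal)})

        # depths from root, then convert to ages using max depth at tips
        depth: dict[int, float] = {id(tree.seed_node): 0.0}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        max_depth = max(depth.values())

        times = np.zeros(2 * n - 1)
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        tip_ids, tip_demes, tip_ages = [""] * n, [""] * n, [0.0] * n
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            times[i] = max_depth - depth[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.is_leaf():
                parts = str(nd.taxon.label).split("|")
                tip_ids[i] = parts[0]
                tip_demes[i] = parts[1] if len(parts) > 1 else ""
                tip_ages[i] = float(parts[2]) if len(parts) > 2 else times[i]
        return cls(times, parent, tip_ids, tip_demes, tip_ages)


def tmrca(genealogy: Genealogy) -> float:
    """Root time of the genealogy in generations BP."""
    return genealogy.tmrca()


def total_branch_length(genealogy: Genealogy) -> float:
    """Sum of all branch lengths in generations."""
    return genealogy.total_branch_length()


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

_INF = math.inf


def _coal_candidate(
    epochs: list[Epoch], starts: list[float], t0: float, k: int, rng: np.random.Generator
) -> float:
    """Absolute time of the deme's next coalescence, drawn from ``t0``.

    Integrates the pair rate ``k(k-1)/(2N(t))`` across the piecewise
    exponential epochs and inverts it at a unit-exponential deviate.
    """
    if k < 2:
        return _INF
    E = rng.standard_exponential()
    pairs = 0.5 * k * (k - 1)
    # epoch containing t0
    i = 0
    for j in range(len(starts) - 1, -1, -1):
        if starts[j] <= t0:
            i = j
            break
    t = t0
    while True:
        e = epochs[i]
        end = starts[i + 1] if i + 1 < len(epochs) else _INF
        n_here = e.size * math.exp(e.rate * (t - e.start))
        g = e.rate
        seg = end - t
        if g == 0.0:
            lam = pairs / n_here
            if E <= lam * seg:
                return t + E / lam
            E -= lam * seg
        else:
            # lambda(u) = (pairs / n_here) * exp(-g u) on u in [0, seg]
            coef = pairs / (n_here * g)
            if seg == _INF:
                hazard = coef if g > 0 else _INF
            else:
                hazard = coef * (1.0 - math.exp(-g * seg))
            if E <= hazard:
                return t - math.log(1.0 - E * g * n_here / pairs) / g
            E -= hazard
        if i + 1 >= len(epochs):
            return _INF
        i += 1
        t = end


def simulate_genealogy(
    demography: Demography,
    design: SampleDesign,
    rng: np.random.Generator | int,
) -> Genealogy:
    """Simulate one genealogy for ``design`` under a realized demography.

    Tips older than a merge time simply enter the post-merge (destination)
    deme.  Simultaneous events are processed tips first, then
    migration/coalescence, then scheduled demographic events.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = design.n
    if n < 2:
        raise ValueError("need at least 2 tips")
    deme_names = list(demography.demes)
    deme_index = {d: i for i, d in enumerate(deme_names)}
    for t in design.tips:
        if t.deme not in deme_index:
            raise ValueError(f"design references unknown deme {t.deme!r}")
    epochs = [demography.demes[d] for d in deme_names]
    epoch_starts = [[e.start for e in eps] for eps in epochs]
    n_demes = len(deme_names)

    # migration row rates (per lineage)
    mig_rows = np.zeros(n_demes)
    mig_matrix = np.zeros((n_demes, n_demes))
    if demography.migration is not None:
        for a, src in enumerate(demography.migration.demes):
            for b, dst in enumerate(demography.migration.demes):
                mig_matrix[deme_index[src], deme_index[dst]] = demography.migration.rates[a, b]
        mig_rows = mig_matrix.sum(axis=1)
    mig_until = (
        demography.migration.active_until if demography.migration is not None else 0.0
    )

    merges = [
        (t, tuple(deme_index[s] for s in sources), deme_index[dest])
        for t, sources, dest in demography.merges
    ]

    # tips sorted by age (stable: preserves design order within an age)
    tip_order = sorted(range(n), key=lambda i: design.tips[i].age)
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    for i, tip in enumerate(design.tips):
        times[i] = tip.age

    active: list[list[int]] = [[] for _ in range(n_demes)]
    redirect = list(range(n_demes))  # deme -> post-merge deme

    def resolve(d: int) -> int:
        while redirect[d] != d:
            d = redirect[d]
        return d

    t_now = 0.0
    tip_ptr = 0
    merge_ptr = 0
    next_node = n
    n_active = 0
    cand = [_INF] * n_demes  # cached coalescence candidates
    stale = [True] * n_demes

    while n_active + (n - tip_ptr) > 1 or n_active > 1:
        for d in range(n_demes):
            if stale[d]:
                cand[d] = _coal_candidate(
                    epochs[d], epoch_starts[d], t_now, len(active[d]), rng
                )
                stale[d] = False
        t_coal = min(cand)
        d_coal = cand.index(t_coal) if t_coal < _INF else -1
        t_tip = times[tip_order[tip_ptr]] if tip_ptr < n else _INF
        t_merge = merges[merge_ptr][0] if merge_ptr < len(merges) else _INF
        # migration: constant per-lineage rates -> memoryless, redraw each step
        mig_total = 0.0
        if t_now < mig_until:
            mig_total = sum(len(active[d]) * mig_rows[d] for d in range(n_demes))
        t_mig = t_now + rng.standard_exponential() / mig_total if mig_total > 0 else _INF
        if t_mig > mig_until:
            t_mig = _INF

        t_next = min(t_coal, t_tip, t_merge, t_mig)
        if t_next == _INF:
            raise RuntimeError("no further events possible before the grand MRCA")

        if t_tip <= t_next:  # ties: tips first
            node = tip_order[tip_ptr]
            d = resolve(deme_index[design.tips[node].deme])
            active[d].append(node)
            n_active += 1
            tip_ptr += 1
            t_now = t_tip
            stale[d] = True
            continue
        if t_next == t_merge and (t_coal > t_merge or t_coal == _INF) and t_mig > t_merge:
            _, sources, dest = merges[merge_ptr]
            dest_r = resolve(dest)
            for s in sources:
                s_r = resolve(s)
                if s_r != dest_r:
                    active[dest_r].extend(active[s_r])
                    active[s_r] = []
                    redirect[s_r] = dest_r
                    stale[s_r] = True
            stale[dest_r] = True
            merge_ptr += 1
            t_now = t_merge
            continue
        if t_mig < t_coal:
            # choose source deme proportional to lineage-count * row rate
            weights = np.array([len(active[d]) * mig_rows[d] for d in range(n_demes)])
            d_src = int(rng.choice(n_demes, p=weights / weights.sum()))
            row = mig_matrix[d_src]
            d_dst = int(rng.choice(n_demes, p=row / row.sum()))
            j = int(rng.integers(len(active[d_src])))
            lineage = active[d_src].pop(j)
            active[resolve(d_dst)].append(lineage)
            t_now = t_mig
            stale[d_src] = True
            stale[resolve(d_dst)] = True
            continue
        # coalescence in deme d_coal
        lin = active[d_coal]
        i1 = int(rng.integers(len(lin)))
        i2 = int(rng.integers(len(lin) - 1))
        if i2 >= i1:
            i2 += 1
        a, b = lin[i1], lin[i2]
        node = next_node
        next_node += 1
        times[node] = t_coal
        parent[a] = node
        parent[b] = node
        if i1 < i2:
            i1, i2 = i2, i1
        lin.pop(i1)
        lin.pop(i2)
        lin.append(node)
        n_active -= 1
        t_now = t_coal
        stale[d_coal] = True

    return Genealogy(
        times,
        parent,
        [t.id for t in design.tips],
        [t.deme for t in design.tips],
        [t.age_years if t.age_years is not None else t.age for t in design.tips],
    )
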