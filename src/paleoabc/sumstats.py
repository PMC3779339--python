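"""Arlequin-style summary statistics for the ABC feature vector.

Per deme and pooled: sample size ``n``, segregating sites ``S``, number of
haplotypes ``K``, haplotype (gene) diversity ``H``, mean pairwise
differences ``Pi``, per-site nucleotide diversity ``pi``, and Tajima's D;
between demes: Hudson-style pairwise F_ST from mean pairwise differences.

``N`` characters are excluded pairwise from difference counts and the count
is rescaled to the full alignment length (pairwise deletion).  Statistics
that are undefined on a given dataset (Tajima's D with ``S = 0`` or
``n < 4``; F_ST with no between-group differences; any statistic on a group
with ``n < 2``) are returned as NaN from the scalar functions and encoded as
0 with a mask bit in the assembled vector, so that distance computations can
skip them consistently.

Exactly the same code path serves observed and simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import HeterochronousAlignment, N_CODE

GROUP_STATS = ("n", "S", "K", "H", "Pi", "pi", "tajd")
POOLED = "pooled"


def _interesting_columns(matrix: np.ndarray) -> np.ndarray:
    """Columns that can contribute differences or carry an N."""
    if matrix.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    differs = (matrix != matrix[0]).any(axis=0)
    has_n = (matrix == N_CODE).any(axis=0)
    return np.flatnonzero(differs | has_n)


def pairwise_difference_matrix(matrix: np.ndarray, L: int) -> np.ndarray:
    """Per-pair difference counts with pairwise N-deletion, rescaled to L."""
    n = matrix.shape[0]
    cols = _interesting_columns(matrix)
    sub = np.ascontiguousarray(matrix[:, cols])
    is_n = sub == N_CODE
    if not is_n.any():
        # fast path: complete sequences, differences are plain Hamming counts
        diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        return diff.astype(float)
    diff = (
        (sub[:, None, :] != sub[None, :, :]) & ~is_n[:, None, :] & ~is_n[None, :, :]
    ).sum(axis=2)
    valid = L - (is_n[:, None, :] | is_n[None, :, :]).sum(axis=2)
    out = np.zeros((n, n))
    ok = valid > 0
    out[ok] = diff[ok] * (L / valid[ok])
    np.fill_diagonal(out, 0.0)
    return out


def _seg_sites_cols(matrix: np.ndarray, cols: np.ndarray) -> int:
    """Count segregating columns among ``cols`` (>= 2 distinct non-N states)."""
    if len(cols) == 0:
        return 0
    sub = matrix[:, cols]
    is_n = sub == N_CODE
    hi = np.where(is_n, -1, sub.astype(np.int16)).max(axis=0)
    lo = np.where(is_n, 99, sub.astype(np.int16)).min(axis=0)
    return int((hi > lo).sum())


def segregating_sites(alignment: HeterochronousAlignment) -> int:
    """Number of sites with at least two distinct non-N states."""
    m = alignment.matrix
    # columns outside the interesting set are monomorphic and N-free
    return _seg_sites_cols(m, _interesting_columns(m))


def _haplotype_counts(matrix: np.ndarray) -> np.ndarray:
    """Haplotype frequencies under pairwise-N-deletion equality.

    With N characters present, sequences are assigned greedily to the first
    earlier cluster whose representative matches at all mutually non-N sites
    (pairwise-deletion equality is not transitive; the greedy order is the
    documented convention).  Without Ns this is exact sequence identity,
    computed over the variable columns only.
    """
    n = matrix.shape[0]
    if (matrix == N_CODE).any():
        reps: list[np.ndarray] = []
        counts: list[int] = []
        for i in range(n):
            row = matrix[i]
            for j, rep in enumerate(reps):
                both = (row != N_CODE) & (rep != N_CODE)
                if not (row[both] != rep[both]).any():
                    counts[j] += 1
                    break
            else:
                reps.append(row)
                counts.append(1)
        return np.array(counts)
    cols = _interesting_columns(matrix)
    sub = np.ascontiguousarray(matrix[:, cols])
    tally: dict[bytes, int] = {}
    for i in range(n):
        key = sub[i].tobytes()
        tally[key] = tally.get(key, 0) + 1
    return np.array(list(tally.values()))


def n_haplotypes(alignment: HeterochronousAlignment) -> int:
    return len(_haplotype_counts(alignment.matrix))


def haplotype_diversity(alignment: HeterochronousAlignment) -> float:
    """Gene diversity H = n/(n-1) (1 - sum p_k^2)."""
    n = alignment.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    counts = _haplotype_counts(alignment.matrix)
    p = counts / n
    return n / (n - 1) * (1.0 - float(p @ p))


def mean_pairwise_differences(alignment: HeterochronousAlignment) -> float:
    """Pi: mean over all pairs of (N-deleted, rescaled) difference counts."""
    n = alignment.n
    if n < 2:
        raise ValueError("pairwise differences require n >= 2")
    d = pairwise_difference_matrix(alignment.matrix, alignment.L)
    iu = np.triu_indices(n, 1)
    return float(d[iu].mean())


def nucleotide_diversity(alignment: HeterochronousAlignment) -> float:
    """Per-site nucleotide diversity pi = Pi / L."""
    return mean_pairwise_differences(alignment) / alignment.L


def tajimas_d(alignment: HeterochronousAlignment) -> float:
    """Tajima's D; NaN when undefined (n < 4 or S = 0)."""
    if alignment.n < 4:
        return float("nan")
    return _tajima_from(
        mean_pairwise_differences(alignment),
        segregating_sites(alignment),
        alignment.n,
    )


def pairwise_fst(
    group_a: HeterochronousAlignment, group_b: HeterochronousAlignment
) -> float:
    """Hudson-style F_ST = 1 - Hw/Hb from mean pairwise differences.

    Hw is the average of the two within-group means, Hb the between-group
    mean; the value is clipped to [-1, 1] and NaN when Hb = 0.
    """
    if group_a.n < 2 or group_b.n < 2:
        raise ValueError("F_ST requires n >= 2 in both groups")
    if group_a.L != group_b.L:
        raise ValueError("groups must share the alignment length")
    joint = np.concatenate([group_a.matrix, group_b.matrix])
    d = pairwise_difference_matrix(joint, group_a.L)
    na = group_a.n
    iu_a = np.triu_indices(na, 1)
    iu_b = np.triu_indices(group_b.n, 1)
    hw = 0.5 * (d[:na, :na][iu_a].mean() + d[na:, na:][iu_b].mean())
    between = d[:na, na:]
    # a sample is never compared against itself: when the two groups share
    # ids (e.g. a group compared with a copy of itself) drop those pairs
    ids_a, ids_b = group_a.ids, group_b.ids
    if set(ids_a) & set(ids_b):
        keep = np.array(
            [[ia != ib for ib in ids_b] for ia in ids_a], dtype=bool
        )
        if not keep.any():
            return float("nan")
        hb = between[keep].mean()
    else:
        hb = between.mean()
    if hb == 0:
        return float("nan")
    return float(np.clip(1.0 - hw / hb, -1.0, 1.0))


@dataclass(frozen=True)
class StatVector:
    """Fixed-order named statistic vector with a mask for undefined entries."""

    names: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray  # True where the statistic is undefined (encoded as 0)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values) or len(self.names) != len(self.mask):
            raise ValueError("names, values and mask must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "masked": self.mask}, index=list(self.names)
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame([self.values], columns=list(self.names)).to_csv(
            path, sep="\t", index=False
        )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _seg_sites_matrix(matrix: np.ndarray) -> int:
    return _seg_sites_cols(matrix, _interesting_columns(matrix))


def _tajima_from(pi_abs: float, S: int, n: int) -> float:
    if n < 4 or S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_abs - S / a1) / np.sqrt(var))


def _group_stats(
    matrix: np.ndarray, diff: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seven group statistics from an encoded sub-matrix and its diff matrix."""
    n = matrix.shape[0]
    values = np.zeros(len(GROUP_STATS))
    mask = np.zeros(len(GROUP_STATS), dtype=bool)
    values[0] = n
    if n < 2:
        mask[1:] = True
        return values, mask
    iu = np.triu_indices(n, 1)
    pi_abs = float(diff[iu].mean())
    S = _seg_sites_matrix(matrix)
    counts = _haplotype_counts(matrix)
    p = counts / n
    values[1] = S
    values[2] = len(counts)
    values[3] = n / (n - 1) * (1.0 - float(p @ p))
    values[4] = pi_abs
    values[5] = pi_abs / L
    td = _tajima_from(pi_abs, S, n)
    if np.isnan(td):
        values[6] = 0.0
        mask[6] = True
    else:
        values[6] = td
    return values, mask


def compute_stat_vector(
    alignment: HeterochronousAlignment,
    grouping: Mapping[str, Sequence[int]] | None = None,
    extended: bool = False,
) -> StatVector:
    """Assemble the ABC feature vector: per-group stats, pairwise F_ST, pooled.

    ``grouping`` maps group label to sample indices; by default samples are
    grouped by deme label in first-appearance order.  The ordering of the
    vector is fixed and documented: for each group the seven statistics of
    :data:`GROUP_STATS`, then F_ST for each group pair (i < j), then the
    pooled statistics.

    With ``extended=True`` three further between-group statistics are
    appended per group pair: the mean (``dxy``), the minimum (``dmin``) and
    the mean of the smallest decile (``dlow``) of pairwise differences
    between the groups.  The minimum/low-decile between-population distance
    tracks the first post-divergence coalescences and is the classic
    low-variance dating statistic for population splits (the decile mean
    averages out mutational Poisson noise); the mean separates divergence
    time from ancestral population size.
    """
    if grouping is None:
        groups: dict[str, list[int]] = {}
        for i, d in enumerate(alignment.deme_labels):
            groups.setdefault(d, []).append(i)
    else:
        groups = {k: list(v) for k, v in grouping.items()}
        all_idx = sorted(i for ix in groups.values() for i in ix)
        if all_idx != list(range(alignment.n)):
            raise ValueError("grouping must partition the samples")

    L = alignment.L
    full_matrix = alignment.matrix
    full_diff = pairwise_difference_matrix(full_matrix, L)

    names: list[str] = []
    values: list[float] = []
    mask: list[bool] = []
    labels = list(groups)
    for g in labels:
        ix = groups[g]
        v, m = _group_stats(full_matrix[ix], full_diff[np.ix_(ix, ix)], L)
        names.extend(f"{g}_{s}" for s in GROUP_STATS)
        values.extend(v)
        mask.extend(m)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            ia, ib = groups[a], groups[b]
            names.append(f"fst_{a}_{b}")
            fst = float("nan")
            if len(ia) >= 2 and len(ib) >= 2:
                iu_a = np.triu_indices(len(ia), 1)
                iu_b = np.triu_indices(len(ib), 1)
                hw = 0.5 * (
                    full_diff[np.ix_(ia, ia)][iu_a].mean()
                    + full_diff[np.ix_(ib, ib)][iu_b].mean()
                )
                hb = full_diff[np.ix_(ia, ib)].mean()
                if hb > 0:
                    fst = float(np.clip(1.0 - hw / hb, -1.0, 1.0))
            if np.isnan(fst):
                values.append(0.0)
                mask.append(True)
            else:
                values.append(fst)
                mask.append(False)
    v, m = _group_stats(full_matrix, full_diff, L)
    names.extend(f"{POOLED}_{s}" for s in GROUP_STATS)
    values.extend(v)
    mask.extend(m)
    if extended:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                between = full_diff[np.ix_(groups[a], groups[b])]
                defined = between.size > 0
                names.append(f"dxy_{a}_{b}")
                values.append(float(between.mean()) if defined else 0.0)
                mask.append(not defined)
                names.append(f"dmin_{a}_{b}")
                values.append(float(between.min()) if defined else 0.0)
                mask.append(not defined)
                names.append(f"dlow_{a}_{b}")
                if defined:
                    flat = np.sort(between, axis=None)
                    k = max(1, flat.size // 10)
                    values.append(float(flat[:k].mean()))
                else:
                    values.append(0.0)
                mask.append(not defined)
    return StatVector(tuple(names), np.asarray(values, float), np.asarray(mask, bool))
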