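"""Subconsomic block mapping: strain ordering, block partition,
neighbor Welch tests and QTL assignment.

A subconsomic panel is a set of strains each carrying one or more
donor-derived intervals on a single chromosome, on an otherwise host
background.  Strains are aligned so that neighboring strains differ as
little as possible in their donor content (minimum total symmetric-
difference length, exact for small panels), the chromosome is
partitioned into blocks — the atoms generated by all recombination
breakpoints, merged where no strain distinguishes them — and each
adjacent strain pair is compared by Welch's t-test with a Bonferroni
family threshold of alpha divided by the realized number of pairs.
A significant pair whose genotypes differ in exactly one block
localizes a QTL to that block, with the donor-allele effect direction
given by the sign of the mean difference on the donor-carrying side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMap",
    "BlockPartition",
    "NeighborTestReport",
    "QtlCall",
    "order_by_similarity",
    "partition_blocks",
    "neighbor_tests",
    "assign_qtl",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class GenotypeMap:
    """Per-strain donor-allele intervals on one chromosome.

    Intervals are half-open ``[start_mb, end_mb)`` in Mb from the
    centromeric end; endpoints lie on the marker grid or at the
    chromosome ends.  The host parent maps to an empty interval set and
    the full-donor parent to the whole chromosome.
    """

    chrom_length_mb: float
    marker_positions_mb: tuple[float, ...]
    intervals: dict[str, tuple[Interval, ...]]
    host: str | None = "B6"
    donor: str | None = "C15"

    def __post_init__(self) -> None:
        if self.chrom_length_mb <= 0:
            raise ValueError("chromosome length must be positive")
        if list(self.marker_positions_mb) != sorted(self.marker_positions_mb):
            raise ValueError("marker positions must be sorted")
        if not self.intervals:
            raise ValueError("genotype map has no strains")
        # valid breakpoint positions: markers, chromosome ends, and
        # midpoints of consecutive markers (breakpoints are only known
        # to marker resolution; the midpoint is the point estimate)
        grid = set(self.marker_positions_mb) | {0.0, self.chrom_length_mb}
        grid |= {
            (a + b) / 2.0
            for a, b in zip(self.marker_positions_mb[:-1], self.marker_positions_mb[1:])
        }
        for strain, ivs in self.intervals.items():
            prev_end = -np.inf
            for a, b in ivs:
                if not (0.0 <= a < b <= self.chrom_length_mb):
                    raise ValueError(
                        f"{strain}: interval [{a}, {b}) outside chromosome"
                    )
                if a < prev_end:
                    raise ValueError(f"{strain}: intervals overlap or unsorted")
                prev_end = b
                for p in (a, b):
                    if not any(abs(p - g) < 1e-9 for g in grid):
                        raise ValueError(
                            f"{strain}: endpoint {p} not on the marker grid"
                        )

    @property
    def strains(self) -> list[str]:
        return list(self.intervals)

    def atoms(self) -> list[Interval]:
        """Maximal intervals containing no breakpoint of any strain."""
        pts = {0.0, self.chrom_length_mb}
        for ivs in self.intervals.values():
            for a, b in ivs:
                pts.update((a, b))
        cuts = sorted(pts)
        return list(zip(cuts[:-1], cuts[1:]))

    def covers(self, strain: str, start: float, end: float) -> bool:
        """True if [start, end) lies inside a donor interval of strain."""
        mid = 0.5 * (start + end)
        return any(a <= mid < b for a, b in self.intervals[strain])

    def donor_length_mb(self, strain: str) -> float:
        return sum(b - a for a, b in self.intervals[strain])

    def symmetric_difference_mb(self, strain_a: str, strain_b: str) -> float:
        """Total length (Mb) on which the two strains' alleles differ."""
        total = 0.0
        for a, b in self.atoms():
            if self.covers(strain_a, a, b) != self.covers(strain_b, a, b):
                total += b - a
        return total


@dataclass(frozen=True)
class BlockPartition:
    """Ordered chromosomal blocks tiling ``[0, L)``, Block1 centromeric."""

    blocks: tuple[Interval, ...]

    @property
    def names(self) -> list[str]:
        return [f"Block{i + 1}" for i in range(len(self.blocks))]

    def __len__(self) -> int:
        return len(self.blocks)


# -- strain ordering ---------------------------------------------------


def _distance_matrix(gmap: GenotypeMap, strains: list[str]) -> np.ndarray:
    atoms = gmap.atoms()
    lengths = np.array([b - a for a, b in atoms])
    cov = np.array(
        [[gmap.covers(s, a, b) for a, b in atoms] for s in strains], dtype=bool
    )
    diff = cov[:, None, :] ^ cov[None, :, :]
    return (diff * lengths).sum(axis=2)


def order_by_similarity(
    gmap: GenotypeMap,
    anchor_parents: bool = True,
    max_exact: int = 12,
) -> list[str]:
    """Linear strain order minimizing total adjacent symmetric difference.

    Exact minimum (dynamic programming over subsets) for up to
    ``max_exact`` strains, with the host parent anchored at the start
    and the full-donor parent at the end when both are present and
    ``anchor_parents`` is true.  Ties are broken toward the
    lexicographically smallest order.  Larger panels fall back to a
    greedy nearest-neighbor heuristic with a warning.
    """
    strains = sorted(gmap.strains)
    if len(strains) < 2:
        raise ValueError("need at least 2 strains to order")
    d = _distance_matrix(gmap, strains)
    idx = {s: i for i, s in enumerate(strains)}

    anchored = (
        anchor_parents
        and gmap.host in idx
        and gmap.donor in idx
        and gmap.host != gmap.donor
    )
    if len(strains) > max_exact:
        warnings.warn(
            f"{len(strains)} strains > max_exact={max_exact}; "
            "using greedy nearest-neighbor ordering",
            stacklevel=2,
        )
        return _greedy_order(strains, d, idx, gmap if anchored else None)

    if anchored:
        start, end = idx[gmap.host], idx[gmap.donor]
        interior = [i for i in range(len(strains)) if i not in (start, end)]
    else:
        start, end, interior = None, None, list(range(len(strains)))
    order_idx = _exact_path(d, interior, start, end)
    order = [strains[i] for i in order_idx]
    if not anchored:
        # canonical orientation for the free-ends case
        if order[::-1] < order:
            order = order[::-1]
    return order


def _exact_path(
    d: np.ndarray, interior: list[int], start: int | None, end: int | None
) -> list[int]:
    """Lexicographically-smallest minimum-weight Hamiltonian path.

    ``h[(S, j)]`` is the cheapest way to stand at ``j``, still owing a
    visit to every node in frozenset ``S``, and finish at ``end`` (or
    anywhere if ``end`` is None).  Reconstruction greedily takes the
    smallest-index next node that preserves optimality.
    """
    m = len(interior)
    pos = {node: k for k, node in enumerate(interior)}
    full = (1 << m) - 1
    inf = float("inf")

    h: list[dict[int, float]] = [dict() for _ in range(1 << m)]
    for j in interior:
        h[0][j] = 0.0 if end is None else d[j, end]
    for size in range(1, m + 1):
        for S in range(1 << m):
            if bin(S).count("1") != size:
                continue
            members = [node for node in interior if S >> pos[node] & 1]
            for j in interior:
                if S >> pos[j] & 1:
                    continue
                best = inf
                for i in members:
                    cand = d[j, i] + h[S & ~(1 << pos[i])][i]
                    if cand < best:
                        best = cand
                h[S][j] = best

    path: list[int] = []
    if start is not None:
        cur, remaining = start, full
        path.append(start)
    else:
        # free start: pick the node giving minimal total, smallest index on ties
        best = inf
        cur = None
        for j in interior:
            cand = h[full & ~(1 << pos[j])][j]
            if cand < best - 1e-12 or (cand < best + 1e-12 and (cur is None or j < cur)):
                best, cur = min(best, cand), j
        remaining = full & ~(1 << pos[cur])
        path.append(cur)
    while remaining:
        target = (
            min(d[cur, i] + h[remaining & ~(1 << pos[i])][i]
                for i in interior if remaining >> pos[i] & 1)
        )
        for i in interior:
            if remaining >> pos[i] & 1:
                if d[cur, i] + h[remaining & ~(1 << pos[i])][i] <= target + 1e-9:
                    path.append(i)
                    remaining &= ~(1 << pos[i])
                    cur = i
                    break
    if end is not None:
        path.append(end)
    return path


def _greedy_order(
    strains: list[str],
    d: np.ndarray,
    idx: dict[str, int],
    gmap: GenotypeMap | None,
) -> list[str]:
    start = idx[gmap.host] if gmap is not None else 0
    unvisited = set(range(len(strains))) - {start}
    if gmap is not None:
        unvisited -= {idx[gmap.donor]}
    order = [start]
    cur = start
    while unvisited:
        nxt = min(unvisited, key=lambda j: (d[cur, j], j))
        order.append(nxt)
        unvisited.remove(nxt)
        cur = nxt
    if gmap is not None:
        order.append(idx[gmap.donor])
    return [strains[i] for i in order]


# -- block partition ---------------------------------------------------


def partition_blocks(gmap: GenotypeMap) -> BlockPartition:
    """Merge breakpoint atoms with identical allele pattern across all
    strains; number the result Block1..K from the centromeric end."""
    atoms = gmap.atoms()
    strains = gmap.strains
    patterns = [
        tuple(gmap.covers(s, a, b) for s in strains) for a, b in atoms
    ]
    merged: list[list[float]] = []
    merged_pat: list[tuple] = []
    for (a, b), pat in zip(atoms, patterns):
        if merged and pat == merged_pat[-1]:
            merged[-1][1] = b
        else:
            merged.append([a, b])
            merged_pat.append(pat)
    return BlockPartition(tuple((a, b) for a, b in merged))


# -- neighbor tests ----------------------------------------------------


@dataclass(frozen=True)
class NeighborTestReport:
    """Welch tests for each adjacent strain pair and parameter.

    ``threshold`` is the per-test Bonferroni level
    ``alpha_family / len(pairs)``.
    """

    order: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    alpha_family: float
    threshold: float
    frame: pd.DataFrame = field(compare=False)


def neighbor_tests(
    order: list[str],
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("BVTV", "TbN", "TbTh"),
    alpha_family: float = 0.05,
    extra_pairs: tuple[tuple[str, str], ...] = (),
) -> NeighborTestReport:
    """Two-sided Welch t-test per adjacent pair per parameter.

    ``extra_pairs`` allows additional comparisons beyond the simple
    path (they count toward the Bonferroni divisor).  Raises KeyError
    naming any strain absent from the phenotype table.
    """
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must be in (0, 1)")
    present = set(table["strain"])
    for s in order:
        if s not in present:
            raise KeyError(f"strain {s!r} missing from phenotype table")
    pairs = tuple(zip(order[:-1], order[1:])) + tuple(extra_pairs)
    threshold = alpha_family / len(pairs)
    groups = {s: table[table["strain"] == s] for s in order}
    rows = []
    for k, (a, b) in enumerate(pairs):
        for param in parameters:
            xa = groups[a][param].dropna().to_numpy(float)
            xb = groups[b][param].dropna().to_numpy(float)
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(
                    f"strain {a if len(xa) < 2 else b} has < 2 animals for {param}"
                )
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "pair_index": k,
                    "strain_a": a,
                    "strain_b": b,
                    "parameter": param,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "t": float(t),
                    "p": float(p),
                    "significant": bool(p < threshold),
                }
            )
    frame = pd.DataFrame(rows)
    return NeighborTestReport(
        order=tuple(order),
        pairs=pairs,
        alpha_family=alpha_family,
        threshold=threshold,
        frame=frame,
    )


# -- QTL assignment ----------------------------------------------------


@dataclass(frozen=True)
class QtlCall:
    """A localized (or candidate-set) QTL from one significant pair."""

    blocks: tuple[str, ...]
    intervals: tuple[Interval, ...]
    parameter: str
    direction: str | None  # "increase" | "decrease" of donor allele
    pair: tuple[str, str]
    p: float
    threshold: float
    ambiguous: bool


def assign_qtl(
    report: NeighborTestReport,
    partition: BlockPartition,
    gmap: GenotypeMap,
) -> list[QtlCall]:
    """Turn significant neighbor tests into block-level QTL calls.

    A pair differing in exactly one block yields a localized call; a
    pair differing in several blocks yields one ambiguous call carrying
    the whole candidate set.  The donor-allele direction is the sign of
    (donor-carrying side mean - other side mean); it is left None for
    ambiguous pairs whose differing blocks are not all carried by the
    same strain.
    """
    calls: list[QtlCall] = []
    names = partition.names
    sig = report.frame[report.frame["significant"]]
    for _, row in sig.iterrows():
        a, b = row["strain_a"], row["strain_b"]
        diff = [
            i
            for i, (s, e) in enumerate(partition.blocks)
            if gmap.covers(a, s, e) != gmap.covers(b, s, e)
        ]
        if not diff:
            raise ValueError(
                f"significant pair ({a}, {b}) has identical genotypes: "
                "inconsistent inputs"
            )
        carrier_a = all(gmap.covers(a, *partition.blocks[i]) for i in diff)
        carrier_b = all(gmap.covers(b, *partition.blocks[i]) for i in diff)
        if carrier_a:
            delta = row["mean_a"] - row["mean_b"]
            direction = "increase" if delta > 0 else "decrease"
        elif carrier_b:
            delta = row["mean_b"] - row["mean_a"]
            direction = "increase" if delta > 0 else "decrease"
        else:
            direction = None
        calls.append(
            QtlCall(
                blocks=tuple(names[i] for i in diff),
                intervals=tuple(partition.blocks[i] for i in diff),
                parameter=row["parameter"],
                direction=direction,
                pair=(a, b),
                p=row["p"],
                threshold=report.threshold,
                ambiguous=len(diff) > 1,
            )
        )
    return calls
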