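"""Evolutionary information: pairwise similarity, PSSMs, redundancy-aware splits.

The HSSP curve gives a length-dependent sequence-identity threshold above
which two proteins are expected to share structure; ``HVAL <= 0`` marks a
pair safe to place on opposite sides of a train/test boundary. The splitter
applies that rule greedily and a leakage check verifies the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PSSM_ALPHABET, Msa, Pssm

PARTITIONS = ("train", "val", "test", "dropped")


@dataclass(frozen=True)
class PairwiseAlignmentStats:
    """Identity statistics of one pairwise alignment.

    ``L`` counts match states (columns where both sequences have a residue)
    and ``n_ident`` the identical residue pairs among them.
    """

    n_ident: int
    L: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_ident <= self.L:
            raise ValueError(f"need 0 <= n_ident <= L, got {self.n_ident}, {self.L}")


def compute_pide(stats: PairwiseAlignmentStats) -> float:
    """Percentage pairwise sequence identity: 100 * n_ident / L."""
    if stats.L < 1:
        raise ValueError("PIDE undefined for alignments with no match states")
    return 100.0 * stats.n_ident / stats.L


def compute_hval(pide: float, L: int) -> float:
    """HSSP value: PIDE minus the length-dependent identity threshold.

    The threshold is 100 for L <= 11, 480 * L^(-0.32 * (1 + exp(-L/1000)))
    for 11 < L <= 450, and 19.5 for L > 450. An HVAL of zero marks the
    identity level at which structural similarity becomes likely.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 11:
        threshold = 100.0
    elif L <= 450:
        threshold = 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))
    else:
        threshold = 19.5
    return pide - threshold


def hval_from_stats(stats: PairwiseAlignmentStats) -> float:
    return compute_hval(compute_pide(stats), stats.L)


# ---------------------------------------------------------------------------
# PSSM construction


def compute_pssm(msa: Msa, pseudocount: float = 1.0, scheme: str = "frequency") -> Pssm:
    """Build a 20-column profile from the columns an MSA aligns to the query.

    Per query position i, with c(i,a) residue counts over rows carrying a
    residue in that column and n_i their number, the frequency is
    ``(c(i,a) + alpha * q_a) / (n_i + alpha)`` with uniform background
    q_a = 1/20. ``log-odds`` applies log2(f / q_a) on top. Residues outside
    the 20-letter alphabet (X) occupy no count but still contribute to n_i
    through their row only if they are standard; X is ignored entirely.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    aa_index = {a: k for k, a in enumerate(PSSM_ALPHABET)}
    L = len(msa.column_map)
    counts = np.zeros((L, 20))
    n_obs = np.zeros(L)
    for row in msa.rows:
        for i, col in enumerate(msa.column_map):
            ch = row[col]
            k = aa_index.get(ch)
            if k is not None:
                counts[i, k] += 1
                n_obs[i] += 1
    q = 1.0 / 20.0
    denom = n_obs + pseudocount
    # query residue may be X at a position nobody covers; fall back to background
    safe = denom > 0
    freq = np.full((L, 20), q)
    freq[safe] = (counts[safe] + pseudocount * q) / denom[safe, None]
    freq /= freq.sum(axis=1, keepdims=True)
    if scheme == "frequency":
        return Pssm(freq, scheme="frequency", pseudocount=pseudocount)
    if scheme == "log-odds":
        with np.errstate(divide="ignore"):
            lo = np.log2(freq / q)
        lo[~np.isfinite(lo)] = -5.0
        return Pssm(lo, scheme="log-odds", pseudocount=pseudocount)
    raise ValueError(f"unknown scheme {scheme!r}")


def pssm_feature_matrix(pssm: Pssm) -> np.ndarray:
    """Scale a PSSM into model-input range.

    Frequencies pass through in [0, 1]; log-odds are clipped to [-5, 5] and
    divided by 5 so both schemes occupy a comparable numeric range.
    """
    if pssm.scheme == "frequency":
        return pssm.values.astype(np.float32)
    return (np.clip(pssm.values, -5.0, 5.0) / 5.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Redundancy-aware data splitting


class PairwiseStatsTable:
    """Symmetric lookup of pairwise alignment stats.

    Pairs without an entry produced no alignment hit and are treated as
    dissimilar (PIDE 0, HVAL -inf).
    """

    def __init__(self, stats: dict[tuple[str, str], PairwiseAlignmentStats] | None = None):
        self._stats: dict[frozenset, PairwiseAlignmentStats] = {}
        for (a, b), s in (stats or {}).items():
            self._stats[frozenset((a, b))] = s

    def add(self, a: str, b: str, stats: PairwiseAlignmentStats) -> None:
        self._stats[frozenset((a, b))] = stats

    def pide(self, a: str, b: str) -> float:
        s = self._stats.get(frozenset((a, b)))
        return 0.0 if s is None else compute_pide(s)

    def hval(self, a: str, b: str) -> float:
        s = self._stats.get(frozenset((a, b)))
        return -math.inf if s is None else hval_from_stats(s)

    @classmethod
    def from_tsv(cls, path) -> "PairwiseStatsTable":
        df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.id1, row.id2, PairwiseAlignmentStats(int(row.n_ident), int(row.L)))
        return table

    def to_tsv(self, path) -> None:
        rows = [
            (*sorted(pair), s.n_ident, s.L) for pair, s in self._stats.items()
        ]
        pd.DataFrame(rows, columns=["id1", "id2", "n_ident", "L"]).sort_values(
            ["id1", "id2"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SplitAssignment:
    """Partition of record ids into train/val/test/dropped."""

    partition: dict[str, str]
    criteria: dict = field(default_factory=dict)

    def ids(self, part: str) -> list[str]:
        return [rid for rid, p in self.partition.items() if p == part]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.partition.items()), columns=["id", "partition"]
        )


def redundancy_split(
    ids,
    stats: PairwiseStatsTable,
    n_test: int,
    n_val: int,
    *,
    test_hval_max: float = 0.0,
    train_pide_max: float = 70.0,
    test_filter=None,
    val_filter=None,
    train_filter=None,
    seed: int = 0,
) -> SplitAssignment:
    """Greedy redundancy-reduced train/val/test split.

    Test and validation members are sampled at random (seeded) subject to
    ``HVAL <= test_hval_max`` against every already-placed test/val member;
    remaining records enter training if their HVAL against all test/val
    members stays below the cutoff and, greedily, their PIDE against every
    already-kept training record stays ``<= train_pide_max``. Violators are
    dropped. Metadata filters (e.g. deposition date, resolution, CATH
    topology) are caller-supplied per-record predicates.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    partition: dict[str, str] = {}

    def _ok_against(rid, members):
        return all(stats.hval(rid, m) <= test_hval_max for m in members)

    test: list[str] = []
    for rid in order:
        if len(test) == n_test:
            break
        if test_filter is not None and not test_filter(rid):
            continue
        if _ok_against(rid, test):
            test.append(rid)
    if len(test) < n_test:
        raise ValueError(
            f"requested test size {n_test} unattainable; maximum under the "
            f"greedy pass is {len(test)}"
        )

    val: list[str] = []
    for rid in order:
        if len(val) == n_val:
            break
        if rid in test:
            continue
        if val_filter is not None and not val_filter(rid):
            continue
        if _ok_against(rid, test) and _ok_against(rid, val):
            val.append(rid)
    if len(val) < n_val:
        raise ValueError(
            f"requested val size {n_val} unattainable; maximum under the "
            f"greedy pass is {len(val)}"
        )

    for rid in test:
        partition[rid] = "test"
    for rid in val:
        partition[rid] = "val"

    kept_train: list[str] = []
    for rid in order:
        if rid in partition:
            continue
        if train_filter is not None and not train_filter(rid):
            partition[rid] = "dropped"
            continue
        if not _ok_against(rid, test) or not _ok_against(rid, val):
            partition[rid] = "dropped"
            continue
        if any(stats.pide(rid, m) > train_pide_max for m in kept_train):
            partition[rid] = "dropped"
            continue
        kept_train.append(rid)
        partition[rid] = "train"

    return SplitAssignment(
        partition=partition,
        criteria={
            "test_hval_max": test_hval_max,
            "train_pide_max": train_pide_max,
            "n_test": n_test,
            "n_val": n_val,
            "seed": seed,
        },
    )


def verify_no_leakage(
    assignment: SplitAssignment,
    stats: PairwiseStatsTable,
    threshold: float = 0.3,
) -> pd.DataFrame:
    """List cross-partition pairs with fractional identity >= ``threshold``.

    An empty frame means the split passes the leakage check at the
    given fractional-identity threshold (default 0.3, i.e. PIDE 30).
    """
    groups = {p: assignment.ids(p) for p in ("train", "val", "test")}
    offending = []
    pairs = [("train", "val"), ("train", "test"), ("val", "test")]
    for pa, pb in pairs:
        for a in groups[pa]:
            for b in groups[pb]:
                pide = stats.pide(a, b)
                if pide / 100.0 >= threshold:
                    offending.append((a, pa, b, pb, pide))
    return pd.DataFrame(
        offending, columns=["id1", "partition1", "id2", "partition2", "pide"]
    )
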