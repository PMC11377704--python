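"""Synthetic protein families with conserved per-residue labels.

The generator emulates the statistical structure the pipeline assumes: a
family of homologs related to a query by independent substitutions and
deletions, per-residue labels with segment structure shared across the
family, and per-residue embeddings equal to a label-dependent signal vector
plus i.i.d. Gaussian noise. Column-averaging over N homologs then provably
reduces embedding noise variance by about N, which is exactly the effect
the MSA-embedding workflow exploits — so the pipeline's qualitative
behaviour (noisy embeddings gain from family averaging, clean ones do not)
is testable end to end without external data.

Randomness: one root seed; every family derives a child generator from
``(seed, family_index)`` and the embedding provider one from
``(seed, crc32(record id))``, so any record regenerates identically in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .embeddings import SyntheticProvider
from .types import SS3_ALPHABET, STANDARD_AA, LabelTrack, Msa, ProteinRecord, ungap

DEFAULT_SEGMENT_MEANS = {"H": 10.0, "E": 5.0, "O": 8.0}


def default_signal_table(labels=SS3_ALPHABET, D: int = 16,
                         separation: float = 1.0) -> dict[str, np.ndarray]:
    """Class-mean vectors at mutual Euclidean distance ``separation``.

    Scaled one-hot corners: distinct one-hots are sqrt(2) apart, so scaling
    by separation / sqrt(2) puts every pair at the requested distance.
    """
    if D < len(labels):
        raise ValueError(f"need D >= {len(labels)}")
    table = {}
    for k, lab in enumerate(labels):
        v = np.zeros(D)
        v[k] = separation / np.sqrt(2.0)
        table[lab] = v
    return table


@dataclass
class FamilySimConfig:
    """Study conditions for one synthetic family.

    ``sub_rate`` is the per-residue probability a homolog differs from the
    query (replacement uniform over all 20 amino acids, so the expected
    identity is 1 - sub_rate + sub_rate/20); ``indel_rate`` the per-residue
    deletion probability (recorded as a gap). ``label_flip_rate`` lets a
    homolog's label disagree with the query's, emulating low-conservation
    families where consensus averaging hurts.
    """

    L: int = 100
    n_homologs: int = 50
    sub_rate: float = 0.3
    indel_rate: float = 0.05
    segment_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEGMENT_MEANS))
    D: int = 16
    signal_separation: float = 1.0
    sigma: float = 1.0
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "label_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(m < 1 for m in self.segment_means.values()):
            raise ValueError("mean segment lengths must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.L < 1 or self.n_homologs < 0:
            raise ValueError("L >= 1 and n_homologs >= 0 required")

    def signal_table(self) -> dict[str, np.ndarray]:
        return default_signal_table(tuple(self.segment_means), self.D,
                                    self.signal_separation)


@dataclass
class SyntheticFamily:
    """A query, its alignment, conserved labels, and an embedding provider
    whose label oracle covers every row."""

    family_id: str
    query: ProteinRecord
    msa: Msa
    labels: LabelTrack
    row_labels: dict[str, str]
    provider: SyntheticProvider


def simulate_labels(config: FamilySimConfig, rng: np.random.Generator | None = None) -> LabelTrack:
    """First-order segment process: draw a state, a geometric run length
    with that state's mean, and repeat until ``L`` residues are emitted.
    Successive states always differ."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    states = list(config.segment_means)
    out: list[str] = []
    prev = None
    while len(out) < config.L:
        choices = [s for s in states if s != prev] if prev is not None else states
        state = choices[rng.integers(len(choices))]
        mean = config.segment_means[state]
        length = int(rng.geometric(1.0 / mean))
        out.extend(state * length)
        prev = state
    return LabelTrack.categorical("".join(out[:config.L]), alphabet=tuple(states))


def simulate_family(config: FamilySimConfig, family_id: str = "fam0",
                    family_index: int = 0) -> SyntheticFamily:
    """Query plus homologs under the configured edit process.

    Columns of the alignment are exactly the query positions (homologs
    acquire substitutions and deletions, never insertions), so labels
    attach to columns and are shared by every row up to the configured
    flip rate.
    """
    rng = np.random.default_rng([config.seed, family_index])
    aa = np.frombuffer(STANDARD_AA.encode(), dtype="S1")
    L = config.L
    query_arr = aa[rng.integers(20, size=L)]
    query_seq = b"".join(query_arr).decode()
    labels = simulate_labels(config, rng)

    qid = f"{family_id}_q"
    ids = [qid]
    rows = [query_seq]
    row_labels = {qid: labels.labels}
    for j in range(config.n_homologs):
        sub = rng.random(L) < config.sub_rate
        gap = rng.random(L) < config.indel_rate
        hom = query_arr.copy()
        hom[sub] = aa[rng.integers(20, size=int(sub.sum()))]
        chars = np.where(gap, np.bytes_("-"), hom)
        row = b"".join(chars).decode()
        hid = f"{family_id}_h{j}"
        row_lab = [labels.labels[i] for i in range(L) if not gap[i]]
        if config.label_flip_rate > 0:
            states = list(config.segment_means)
            for i in range(len(row_lab)):
                if rng.random() < config.label_flip_rate:
                    others = [s for s in states if s != row_lab[i]]
                    row_lab[i] = others[rng.integers(len(others))]
        if not ungap(row):
            continue  # fully deleted homolog carries no information
        ids.append(hid)
        rows.append(row)
        row_labels[hid] = "".join(row_lab)

    msa = Msa(ids=ids, rows=rows, query_index=0)
    provider = SyntheticProvider(
        mu=config.signal_table(), sigma=config.sigma, seed=config.seed,
        label_oracle=row_labels,
    )
    return SyntheticFamily(
        family_id=family_id,
        query=ProteinRecord(qid, query_seq),
        msa=msa,
        labels=labels,
        row_labels=row_labels,
        provider=provider,
    )


def simulate_families(n: int, config: FamilySimConfig, prefix: str = "fam",
                      start_index: int = 0) -> list[SyntheticFamily]:
    """``n`` mutually unrelated families (independent draws)."""
    return [
        simulate_family(config, family_id=f"{prefix}{start_index + i}",
                        family_index=start_index + i)
        for i in range(n)
    ]


def simulate_benchmark(outdir, n_train: int, n_val: int, n_test: int,
                       config: FamilySimConfig) -> dict:
    """Emit a train/val/test benchmark to disk and return its manifest.

    Each split gets a query FASTA, one aligned-FASTA MSA per family, a
    label TSV and an HDF5 container with the query embeddings. Families
    are independent draws, so cross-split sequence identity concentrates
    far below any leakage threshold for realistic lengths. Deterministic
    under ``config.seed``: reruns produce byte-identical manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    if any(v < 1 for v in sizes.values()):
        raise ValueError("all split sizes must be >= 1")
    manifest: dict = {
        "config": {
            **{k: v for k, v in vars(config).items() if k != "segment_means"},
            "segment_means": dict(config.segment_means),
        },
        "splits": {},
    }
    index = 0
    for split, n in sizes.items():
        split_dir = outdir / split
        (split_dir / "msa").mkdir(parents=True, exist_ok=True)
        families = simulate_families(n, config, prefix=f"{split}_fam",
                                     start_index=index)
        index += n
        fasta = split_dir / "queries.fasta"
        pio.write_fasta(fasta, [f.query for f in families])
        tracks = {f.query.id: f.labels for f in families}
        labels_path = split_dir / "labels.tsv"
        pio.write_label_tracks(labels_path, tracks)
        emb_path = split_dir / "query_embeddings.h5"
        pio.write_embeddings(
            emb_path, {f.query.id: f.provider.embed(f.query) for f in families},
            D=config.D,
        )
        msa_files = {}
        for fam in families:
            mp = split_dir / "msa" / f"{fam.query.id}.afa"
            pio.write_msa(mp, fam.msa)
            msa_files[fam.query.id] = str(mp.relative_to(outdir))
        manifest["splits"][split] = {
            "n_families": n,
            "queries": str(fasta.relative_to(outdir)),
            "labels": str(labels_path.relative_to(outdir)),
            "embeddings": str(emb_path.relative_to(outdir)),
            "msas": msa_files,
        }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def simulate_segment_task(n_proteins: int, L: int = 60, n_segments: int = 2,
                          segment_length: int = 15, end_shift=0,
                          seed: int = 0) -> list[tuple[str, str]]:
    """Paired (pred, obs) tracks with transmembrane-like segments.

    Observed tracks contain ``n_segments`` runs of type ``T`` on an ``O``
    background; predictions copy them with each segment's end shifted by
    ``end_shift`` (a scalar, or one value per protein), so the expected
    per-segment accuracy under the matching rule is exact by construction.
    """
    if np.isscalar(end_shift):
        shifts = [int(end_shift)] * n_proteins
    else:
        shifts = [int(s) for s in end_shift]
        if len(shifts) != n_proteins:
            raise ValueError("need one end_shift per protein")
    gap = (L - n_segments * segment_length) // (n_segments + 1)
    if gap < 1:
        raise ValueError("L too short for the requested segments")
    pairs = []
    for shift in shifts:
        obs = ["O"] * L
        pred = ["O"] * L
        for s in range(n_segments):
            start = gap + s * (segment_length + gap)
            end = start + segment_length
            obs[start:end] = "T" * (end - start)
            pend = min(max(end + shift, start + 1), L)
            pred[start:pend] = "T" * (pend - start)
        pairs.append(("".join(pred), "".join(obs)))
    return pairs
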