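"""Embedding providers and the MSA column-average.

A provider turns a protein sequence into an L x D matrix of per-residue
vectors. Real protein language models plug in through
:class:`PrecomputedProvider` (embeddings computed elsewhere, stored in the
package's HDF5 container); :class:`SyntheticProvider` emits label-dependent
signal plus Gaussian noise and drives all statistical tests.
"""

from __future__ import annotations

import logging
import zlib
from typing import Callable, Protocol

import numpy as np

from . import io as pio
from .types import Msa, ProteinRecord, ungap

logger = logging.getLogger(__name__)


def preprocess_for_embedding(seq: str) -> str:
    """Prepare a possibly gapped alignment row for embedding.

    Gaps are removed and rare / nonstandard residues are mapped to X.
    Raises if nothing remains.
    """
    out = pio.sanitize_sequence(ungap(seq))
    if not out:
        raise ValueError("sequence empty after gap removal")
    return out


class EmbeddingProvider(Protocol):
    """Anything that maps a protein to an L x D embedding matrix.

    ``embed`` must be deterministic for fixed provider state and return one
    row per residue.
    """

    name: str
    D: int

    def embed(self, record: ProteinRecord) -> np.ndarray: ...


class PrecomputedProvider:
    """Serve embeddings precomputed by an external language model.

    Loads the package's HDF5 container (one float32 L x D dataset per
    record id). This is the adapter surface for SeqVec / ProtBert / ProtT5
    style models, whose inference happens outside this package.
    """

    def __init__(self, path, name: str = "precomputed"):
        self.name = name
        self._table = pio.read_embeddings(path)
        widths = {m.shape[1] for m in self._table.values()}
        if len(widths) != 1:
            raise ValueError(f"mixed embedding widths in container: {sorted(widths)}")
        self.D = widths.pop()

    def embed(self, record: ProteinRecord) -> np.ndarray:
        try:
            mat = self._table[record.id]
        except KeyError:
            raise KeyError(f"no precomputed embedding for {record.id!r}") from None
        if mat.shape[0] != len(record):
            raise ValueError(
                f"embedding for {record.id!r} has {mat.shape[0]} rows, "
                f"sequence has {len(record)}"
            )
        return mat


class SyntheticProvider:
    """Label-dependent signal plus i.i.d. Gaussian noise.

    Residue i of a record with per-residue labels ``l`` embeds as
    ``mu[l_i] + N(0, sigma^2)`` per coordinate. The noise stream is
    deterministic in (seed, record id), so repeated calls agree bitwise.
    A label oracle — a mapping or callable from record id to its label
    string — must cover every record embedded.
    """

    def __init__(
        self,
        mu: dict[str, np.ndarray],
        sigma: float,
        seed: int,
        label_oracle: dict[str, str] | Callable[[str], str],
        name: str = "synthetic",
    ):
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.mu = {k: np.asarray(v, dtype=np.float64) for k, v in mu.items()}
        widths = {v.shape[0] for v in self.mu.values()}
        if len(widths) != 1:
            raise ValueError("all signal vectors must share one width")
        self.D = widths.pop()
        self.sigma = float(sigma)
        self.seed = int(seed)
        self._oracle = label_oracle
        self.name = name

    def _labels_for(self, record_id: str) -> str:
        if callable(self._oracle):
            labels = self._oracle(record_id)
        else:
            labels = self._oracle.get(record_id)
        if labels is None:
            raise KeyError(f"no label oracle entry for record {record_id!r}")
        return labels

    def embed(self, record: ProteinRecord) -> np.ndarray:
        labels = self._labels_for(record.id)
        if len(labels) != len(record):
            raise ValueError(
                f"label oracle length {len(labels)} != sequence length "
                f"{len(record)} for {record.id!r}"
            )
        signal = np.stack([self.mu[l] for l in labels])
        if self.sigma == 0:
            return signal.astype(np.float32)
        rng = np.random.default_rng([self.seed, zlib.crc32(record.id.encode())])
        noise = rng.normal(0.0, self.sigma, size=signal.shape)
        return (signal + noise).astype(np.float32)


def msa_average_embeddings(msa: Msa, provider: EmbeddingProvider,
                           max_rows: int | None = None) -> np.ndarray:
    """Average per-residue embeddings column-wise over an alignment.

    Each row is embedded independently on its own ungapped sequence; for
    every query residue position, the output is the unweighted mean over
    all rows carrying a residue in that column (the query always
    contributes, so every position has at least one contributor). Rows
    whose sequence cannot be embedded are skipped with a warning.
    """
    L = len(msa.column_map)
    sums = np.zeros((L, provider.D), dtype=np.float64)
    counts = np.zeros(L, dtype=np.int64)
    col_to_query = {int(c): i for i, c in enumerate(msa.column_map)}

    row_indices = range(msa.n_rows)
    if max_rows is not None and msa.n_rows > max_rows:
        # query always kept; truncate the rest in file order
        keep = [msa.query_index] + [i for i in row_indices if i != msa.query_index]
        row_indices = sorted(keep[:max_rows])

    for r in row_indices:
        row = msa.rows[r]
        try:
            seq = preprocess_for_embedding(row)
        except ValueError:
            if r == msa.query_index:
                raise
            logger.warning("skipping non-embeddable MSA row %s", msa.ids[r])
            continue
        emb = provider.embed(ProteinRecord(msa.ids[r], seq))
        res_pos = 0
        for col, ch in enumerate(row):
            if ch == "-":
                continue
            qi = col_to_query.get(col)
            if qi is not None:
                sums[qi] += emb[res_pos]
                counts[qi] += 1
            res_pos += 1
    return (sums / counts[:, None]).astype(np.float32)
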