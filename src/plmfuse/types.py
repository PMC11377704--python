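"""Core domain types shared across the package.

All residue coordinates are 0-based, half-open. Sequences are uppercase
strings over the 20 standard amino acids plus ``X`` (unknown / nonstandard).
Gap characters inside alignments are normalized to ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids (alphabetical one-letter codes).
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used for PSSMs on disk and in feature matrices.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Gap character used internally ('.' is normalized to '-' at parse time).
GAP = "-"

#: Three-state secondary structure alphabet: helix, strand, other.
SS3_ALPHABET = ("H", "E", "O")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: the unit of prediction.

    Parameters
    ----------
    id : str
        Unique identifier.
    seq : str
        Uppercase sequence over the 20 standard amino acids and ``X``.
        No gap characters.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.seq != self.seq.upper():
            raise ValueError(f"record {self.id!r}: sequence must be uppercase")
        bad = set(self.seq) - set(STANDARD_AA + "X")
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def ungap(row: str) -> str:
    """Remove gap characters from an alignment row."""
    return row.replace(GAP, "").replace(".", "")


@dataclass
class Msa:
    """A multiple sequence alignment anchored on a query sequence.

    ``rows`` are gapped strings sharing a common column count ``C``;
    ``column_map[i]`` gives, for query residue position ``i``, the column
    index it occupies.
    """

    ids: list[str]
    rows: list[str]
    query_index: int = 0
    column_map: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must contain at least one row")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"unequal MSA row lengths: {sorted(widths)}")
        if not 0 <= self.query_index < len(self.rows):
            raise ValueError("query_index out of range")
        q = self.rows[self.query_index]
        self.column_map = np.flatnonzero(np.frombuffer(q.encode(), dtype="S1") != b"-")
        if self.column_map.size == 0:
            raise ValueError("query row contains no residues")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> ProteinRecord:
        return ProteinRecord(self.ids[self.query_index], ungap(self.rows[self.query_index]))

    def residue_mask(self) -> np.ndarray:
        """Boolean (n_rows, C) matrix: True where a row has a residue."""
        arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in self.rows])
        return arr != b"-"


@dataclass
class LabelTrack:
    """Per-residue annotations for one protein.

    Categorical tracks hold one symbol per residue from ``alphabet``;
    continuous tracks hold one real score per residue.
    """

    kind: str  # "categorical" | "continuous"
    labels: str | None = None
    scores: np.ndarray | None = None
    alphabet: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if self.labels is None:
                raise ValueError("categorical track requires labels")
            if self.alphabet is not None:
                bad = set(self.labels) - set(self.alphabet)
                if bad:
                    raise ValueError(f"labels outside alphabet: {sorted(bad)}")
        elif self.kind == "continuous":
            if self.scores is None:
                raise ValueError("continuous track requires scores")
            self.scores = np.asarray(self.scores, dtype=float)
        else:
            raise ValueError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.labels) if self.kind == "categorical" else len(self.scores)

    @classmethod
    def categorical(cls, labels: str, alphabet: tuple[str, ...] | None = None) -> "LabelTrack":
        return cls(kind="categorical", labels=labels, alphabet=alphabet)

    @classmethod
    def continuous(cls, scores) -> "LabelTrack":
        return cls(kind="continuous", scores=np.asarray(scores, dtype=float))


@dataclass
class Pssm:
    """Position-specific scoring matrix: one 20-dim profile per residue.

    ``values`` is L x 20 in :data:`PSSM_ALPHABET` column order. In the
    ``frequency`` scheme every row is a probability vector; ``log-odds``
    holds log2(f / background).
    """

    values: np.ndarray
    scheme: str = "frequency"
    pseudocount: float = 1.0
    alphabet: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError("PSSM values must be L x 20")
        if self.scheme == "frequency":
            if (self.values < 0).any():
                raise ValueError("frequency PSSM entries must be non-negative")
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("frequency PSSM rows must sum to 1")
        elif self.scheme != "log-odds":
            raise ValueError(f"unknown PSSM scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.values)
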