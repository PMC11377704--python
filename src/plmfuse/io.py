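"""Readers and writers for the package's external formats.

Sequences travel as FASTA, alignments as aligned FASTA or A3M, per-residue
embeddings as HDF5 (one float32 L x D dataset per identifier), PSSMs and
label tracks as TSV. Also hosts the standard eight-to-three state reduction
of DSSP secondary-structure strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import GAP, PSSM_ALPHABET, STANDARD_AA, LabelTrack, Msa, ProteinRecord, Pssm

logger = logging.getLogger(__name__)

_VALID = set(STANDARD_AA + "X")

# DSSP 8-state -> 3-state: helix classes to H, strand classes to E, rest to O.
DSSP8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "O", "S": "O", "-": "O", " ": "O", "C": "O",
}


def sanitize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase ``seq`` and map nonstandard residues (U,O,B,Z,J,*,...) to X."""
    seq = seq.upper()
    out = []
    replaced = set()
    for ch in seq:
        if ch in _VALID:
            out.append(ch)
        else:
            out.append("X")
            replaced.add(ch)
    if replaced:
        logger.warning(
            "%s: mapped nonstandard residues %s to X", context or "sequence",
            "".join(sorted(replaced)),
        )
    return "".join(out)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; characters outside the 20 standard amino
    acids are mapped to ``X`` with a logged warning. Raises on empty files
    and on duplicate identifiers.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = sanitize_sequence(str(entry.seq), context=entry.id)
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_msa(path, dialect: str = "aligned-fasta", query_id: str | None = None) -> Msa:
    """Read an MSA from aligned FASTA or A3M.

    For A3M, lowercase characters are insertions relative to the query and
    are removed before building the column map; aligned FASTA keeps all
    columns. ``.`` gaps are normalized to ``-``. The query is the row named
    ``query_id``, or the first row if omitted.
    """
    if dialect not in ("aligned-fasta", "a3m"):
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    ids: list[str] = []
    rows: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq).replace(".", GAP)
        if dialect == "a3m":
            raw = "".join(ch for ch in raw if not ch.islower())
        row = "".join(
            ch if ch == GAP else _sanitize_char(ch) for ch in raw.upper()
        )
        ids.append(entry.id)
        rows.append(row)
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"unequal alignment row lengths in {path}: {sorted(widths)}")
    if query_id is None:
        query_index = 0
    else:
        try:
            query_index = ids.index(query_id)
        except ValueError:
            raise ValueError(f"query id {query_id!r} not found in {path}") from None
    return Msa(ids=ids, rows=rows, query_index=query_index)


def _sanitize_char(ch: str) -> str:
    return ch if ch in _VALID else "X"


def write_msa(path, msa: Msa) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def reduce_dssp8_to_3(dssp: str) -> LabelTrack:
    """Reduce an eight-state DSSP string to the three-state alphabet H/E/O.

    H, G and I (all helix classes) map to H; E and B (strand classes) map
    to E; every remaining class maps to O (other).
    """
    out = []
    for i, ch in enumerate(dssp):
        try:
            out.append(DSSP8_TO_3[ch.upper() if ch != " " else ch])
        except KeyError:
            raise ValueError(f"unknown DSSP symbol {ch!r} at position {i}") from None
    return LabelTrack.categorical("".join(out), alphabet=("H", "E", "O"))


def write_embeddings(path, embeddings: dict[str, np.ndarray], D: int | None = None) -> None:
    """Write a mapping id -> L x D matrix into an HDF5 container.

    ``D`` is stored as a file attribute; every matrix must match it.
    """
    if not embeddings:
        raise ValueError("no embeddings to write")
    if D is None:
        D = next(iter(embeddings.values())).shape[1]
    with h5py.File(path, "w") as fh:
        fh.attrs["D"] = D
        for rid, mat in embeddings.items():
            mat = np.asarray(mat, dtype=np.float32)
            if mat.ndim != 2 or mat.shape[1] != D:
                raise ValueError(
                    f"embedding for {rid!r} has shape {mat.shape}, expected L x {D}"
                )
            fh.create_dataset(rid, data=mat)


def read_embeddings(path, ids=None) -> dict[str, np.ndarray]:
    """Read embeddings back; raises if a requested id is missing."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        D = int(fh.attrs["D"])
        keys = list(fh.keys()) if ids is None else list(ids)
        for rid in keys:
            if rid not in fh:
                raise KeyError(f"embedding id {rid!r} not found in {path}")
            mat = fh[rid][()]
            if mat.shape[1] != D:
                raise ValueError(f"embedding {rid!r} width {mat.shape[1]} != D={D}")
            out[rid] = mat
    return out


def write_pssm(path, pssm: Pssm) -> None:
    df = pd.DataFrame(pssm.values, columns=list(PSSM_ALPHABET))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pssm(path, scheme: str = "frequency") -> Pssm:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(PSSM_ALPHABET):
        raise ValueError(f"PSSM header must be the 20 AAs in {PSSM_ALPHABET} order")
    return Pssm(df.to_numpy(dtype=float), scheme=scheme)


def write_label_tracks(path, tracks: dict[str, LabelTrack]) -> None:
    """Write tracks as TSV with columns id, position, value."""
    rows = []
    for rid, track in tracks.items():
        if track.kind == "categorical":
            for i, ch in enumerate(track.labels):
                rows.append((rid, i, ch))
        else:
            for i, s in enumerate(track.scores):
                rows.append((rid, i, repr(float(s))))
    pd.DataFrame(rows, columns=["id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_label_tracks(path, kind: str = "categorical",
                      alphabet: tuple[str, ...] | None = None) -> dict[str, LabelTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "position": int, "value": str})
    out: dict[str, LabelTrack] = {}
    for rid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        if not (grp["position"].to_numpy() == np.arange(len(grp))).all():
            raise ValueError(f"label track for {rid!r} has gaps in positions")
        if kind == "categorical":
            out[rid] = LabelTrack.categorical("".join(grp["value"]), alphabet=alphabet)
        else:
            out[rid] = LabelTrack.continuous(grp["value"].astype(float).to_numpy())
    if not out:
        raise ValueError(f"no label tracks in {path}")
    return out


def read_dssp_tracks(path) -> dict[str, LabelTrack]:
    """Read per-residue 8-state strings (TSV id/position/value) and reduce to 3 states."""
    raw = read_label_tracks(path, kind="categorical")
    return {rid: reduce_dssp8_to_3(t.labels) for rid, t in raw.items()}
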