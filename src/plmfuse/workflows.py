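"""The five end-to-end prediction strategies.

Given a query, an alignment of its family, an embedding provider and a
trained per-residue model, evolutionary information can enter at three
points: before the model (averaging embeddings over the family, or handing
the model a PSSM next to the embedding) or after it (averaging the model's
predictions over the family). The five workflows:

- ``raw``          — embed the query, predict.
- ``msa-emb``      — average embeddings column-wise over the family, predict.
- ``msacons``      — predict every family member, average predictions
                     column-wise (works for any per-residue predictor,
                     categorical or continuous).
- ``pssm-concat``  — append 20 PSSM columns to the embedding, predict with
                     a model trained on the widened input.
- ``pssm-split``   — feed embedding and PSSM to separate model branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .embeddings import EmbeddingProvider, msa_average_embeddings, preprocess_for_embedding
from .evoinfo import compute_pssm, pssm_feature_matrix
from .models import ResidueConvNet, TrainedModel
from .types import Msa, ProteinRecord

logger = logging.getLogger(__name__)

WORKFLOWS = ("raw", "msa-emb", "msacons", "pssm-concat", "pssm-split")


@dataclass
class PredictionTrack:
    """Per-residue channel values with their semantics and provenance."""

    values: np.ndarray  # L x K
    channels: tuple[str, ...]
    workflow: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.shape[0]

    def argmax_labels(self) -> str:
        """Hard labels by per-residue argmax; ties break to the lowest index."""
        return "".join(self.channels[k] for k in self.values.argmax(axis=1))


def _unwrap(model) -> ResidueConvNet:
    return model.estimator if isinstance(model, TrainedModel) else model


def _track_from(est: ResidueConvNet, features: np.ndarray, workflow: str) -> PredictionTrack:
    if est.task == "regression":
        scores = est.predict_scores([features])[0][:, None]
        return PredictionTrack(scores, channels=("score",), workflow=workflow)
    probs = est.predict_proba([features])[0]
    return PredictionTrack(probs, channels=tuple(est.classes_), workflow=workflow)


def _require_variant(est: ResidueConvNet, variant: str, workflow: str) -> None:
    if est.variant != variant:
        raise ValueError(
            f"workflow {workflow!r} needs a {variant!r} model, got {est.variant!r}"
        )


def predict_raw(record: ProteinRecord, provider: EmbeddingProvider, model) -> PredictionTrack:
    """Embed the query sequence and predict."""
    est = _unwrap(model)
    _require_variant(est, "base", "raw")
    return _track_from(est, provider.embed(record), "raw")


def predict_msa_embedding(record: ProteinRecord, msa: Msa,
                          provider: EmbeddingProvider, model,
                          max_rows: int | None = None) -> PredictionTrack:
    """Average embeddings column-wise over the family, then predict."""
    est = _unwrap(model)
    _require_variant(est, "base", "msa-emb")
    if msa.query.seq != record.seq:
        raise ValueError(f"MSA query does not match record {record.id!r}")
    features = msa_average_embeddings(msa, provider, max_rows=max_rows)
    return _track_from(est, features, "msa-emb")


def make_model_predictor(model, provider: EmbeddingProvider) -> Callable[[ProteinRecord], np.ndarray]:
    """Adapt a trained model + provider to the per-residue predictor callable
    that :func:`predict_msacons` consumes."""
    est = _unwrap(model)

    def _predict(record: ProteinRecord) -> np.ndarray:
        feats = provider.embed(record)
        if est.task == "regression":
            return est.predict_scores([feats])[0][:, None]
        return est.predict_proba([feats])[0]

    return _predict


def predict_msacons(record: ProteinRecord, msa: Msa,
                    predictor: Callable[[ProteinRecord], np.ndarray],
                    channels: tuple[str, ...],
                    max_rows: int | None = None) -> PredictionTrack:
    """Consensus prediction: predict each family member independently on its
    ungapped sequence, then average the per-residue channel vectors
    column-wise over all rows carrying a residue at each query position.

    Generic over the predictor: probability vectors (categorical tasks) and
    continuous scores average the same way. Rows whose sequences cannot be
    embedded are skipped with a warning.
    """
    if msa.query.seq != record.seq:
        raise ValueError(f"MSA query does not match record {record.id!r}")
    L = len(msa.column_map)
    K = len(channels)
    sums = np.zeros((L, K))
    counts = np.zeros(L, dtype=np.int64)
    col_to_query = {int(c): i for i, c in enumerate(msa.column_map)}

    row_indices = list(range(msa.n_rows))
    if max_rows is not None and msa.n_rows > max_rows:
        keep = [msa.query_index] + [i for i in row_indices if i != msa.query_index]
        row_indices = sorted(keep[:max_rows])

    for r in row_indices:
        row = msa.rows[r]
        try:
            seq = preprocess_for_embedding(row)
        except ValueError:
            if r == msa.query_index:
                raise
            logger.warning("msacons: skipping non-embeddable row %s", msa.ids[r])
            continue
        track = np.asarray(predictor(ProteinRecord(msa.ids[r], seq)))
        if track.shape != (len(seq), K):
            raise ValueError(
                f"predictor returned shape {track.shape} for row {msa.ids[r]!r}, "
                f"expected ({len(seq)}, {K})"
            )
        res_pos = 0
        for col, ch in enumerate(row):
            if ch == "-":
                continue
            qi = col_to_query.get(col)
            if qi is not None:
                sums[qi] += track[res_pos]
                counts[qi] += 1
            res_pos += 1
    return PredictionTrack(sums / counts[:, None], channels=channels, workflow="msacons")


def write_prediction_tracks(path, tracks: dict[str, PredictionTrack]) -> None:
    """TSV with columns id, position, then one column per channel."""
    import pandas as pd

    frames = []
    for rid, track in tracks.items():
        df = pd.DataFrame(track.values, columns=list(track.channels))
        df.insert(0, "position", np.arange(len(track)))
        df.insert(0, "id", rid)
        df["workflow"] = track.workflow
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_prediction_tracks(path) -> dict[str, PredictionTrack]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    channels = tuple(c for c in df.columns if c not in ("id", "position", "workflow"))
    out = {}
    for rid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        wf = str(grp["workflow"].iloc[0]) if "workflow" in grp else ""
        out[rid] = PredictionTrack(grp[list(channels)].to_numpy(), channels, wf)
    return out


def _pssm_features(msa: Msa, pseudocount: float, scheme: str) -> np.ndarray:
    return pssm_feature_matrix(compute_pssm(msa, pseudocount=pseudocount, scheme=scheme))


def predict_pssm_concat(record: ProteinRecord, msa: Msa,
                        provider: EmbeddingProvider, model,
                        pseudocount: float = 1.0,
                        scheme: str = "frequency") -> PredictionTrack:
    """Concatenate per-residue embedding and PSSM rows, predict with the
    widened-input model (D + 20 input channels)."""
    est = _unwrap(model)
    _require_variant(est, "concat", "pssm-concat")
    if msa.query.seq != record.seq:
        raise ValueError(f"MSA query does not match record {record.id!r}")
    emb = provider.embed(record)
    pssm = _pssm_features(msa, pseudocount, scheme)
    features = np.concatenate([emb, pssm], axis=1)
    return _track_from(est, features, "pssm-concat")


def predict_pssm_split(record: ProteinRecord, msa: Msa,
                       provider: EmbeddingProvider, model,
                       pseudocount: float = 1.0,
                       scheme: str = "frequency") -> PredictionTrack:
    """Feed embedding and PSSM to the two branches of a split model."""
    est = _unwrap(model)
    _require_variant(est, "split", "pssm-split")
    if msa.query.seq != record.seq:
        raise ValueError(f"MSA query does not match record {record.id!r}")
    emb = provider.embed(record)
    pssm = _pssm_features(msa, pseudocount, scheme)
    features = np.concatenate([emb, pssm], axis=1)
    return _track_from(est, features, "pssm-split")
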