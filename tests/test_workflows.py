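import numpy as np
import pytest

from plmfuse.models import ResidueConvNet
from plmfuse.pipeline import evaluate_workflow, train_workflow
from plmfuse.synthetic import FamilySimConfig, simulate_families, simulate_family
from plmfuse.types import Msa, ProteinRecord
from plmfuse.workflows import (
    PredictionTrack,
    make_model_predictor,
    predict_msa_embedding,
    predict_msacons,
    predict_pssm_concat,
    predict_pssm_split,
    predict_raw,
    read_prediction_tracks,
    write_prediction_tracks,
)


def _trained_base(families, **kwargs):
    kwargs.setdefault("max_epochs", 5)
    return train_workflow("raw", families[:-2], families[-2:], model_kwargs=kwargs)


@pytest.fixture(scope="module")
def small_setup():
    config = FamilySimConfig(L=30, n_homologs=6, sigma=0.5, D=8, seed=21,
                             sub_rate=0.2, indel_rate=0.1)
    families = simulate_families(8, config)
    model = _trained_base(families)
    return config, families, model


class TestRawWorkflow:
    def test_deterministic_and_length_preserving(self, small_setup):
        _, families, model = small_setup
        fam = families[0]
        t1 = predict_raw(fam.query, fam.provider, model)
        t2 = predict_raw(fam.query, fam.provider, model)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert len(t1) == len(fam.query)
        np.testing.assert_allclose(t1.values.sum(axis=1), 1.0, atol=1e-9)

    def test_requires_base_variant(self, small_setup):
        _, families, _ = small_setup
        fam = families[0]
        wrong = ResidueConvNet(variant="concat", input_width=8)
        wrong.stacks_ = wrong._init_stacks(np.random.default_rng(0))
        wrong.classes_ = wrong.classes
        with pytest.raises(ValueError, match="base"):
            predict_raw(fam.query, fam.provider, wrong)


class TestWorkflowIdentityFamily:
    """Single-row (or identical-copy) alignments collapse the MSA workflows
    onto the raw workflow exactly."""

    def _single_row_family(self):
        config = FamilySimConfig(L=25, n_homologs=0, sigma=1.0, D=8, seed=5)
        fams = simulate_families(6, config)
        model = _trained_base(fams)
        return fams[0], model

    def test_msa_embedding_reduces_to_raw(self):
        fam, model = self._single_row_family()
        raw = predict_raw(fam.query, fam.provider, model)
        msa = predict_msa_embedding(fam.query, fam.msa, fam.provider, model)
        np.testing.assert_array_equal(raw.values, msa.values)

    def test_msacons_reduces_to_raw(self):
        fam, model = self._single_row_family()
        raw = predict_raw(fam.query, fam.provider, model)
        cons = predict_msacons(fam.query, fam.msa,
                               make_model_predictor(model, fam.provider),
                               channels=raw.channels)
        np.testing.assert_array_equal(raw.values, cons.values)

    def test_identical_copies_reduce_to_raw_when_noise_free(self):
        config = FamilySimConfig(L=25, n_homologs=0, sigma=0.0, D=8, seed=5)
        fams = simulate_families(6, config)
        model = _trained_base(fams)
        fam = fams[0]
        ids = [fam.query.id, "c1", "c2"]
        labels = {i: fam.labels.labels for i in ids}
        from plmfuse.embeddings import SyntheticProvider
        provider = SyntheticProvider(fam.provider.mu, 0.0, 0, labels)
        msa = Msa(ids=ids, rows=[fam.query.seq] * 3)
        raw = predict_raw(fam.query, provider, model)
        msa_t = predict_msa_embedding(fam.query, msa, provider, model)
        cons = predict_msacons(fam.query, msa,
                               make_model_predictor(model, provider),
                               channels=raw.channels)
        np.testing.assert_allclose(raw.values, msa_t.values, atol=1e-12)
        np.testing.assert_allclose(raw.values, cons.values, atol=1e-12)


class TestMsaCons:
    def test_probability_mean_hand_example(self):
        tracks = {"q": np.array([[1.0, 0.0, 0.0]]), "h": np.array([[0.0, 1.0, 0.0]])}
        msa = Msa(ids=["q", "h"], rows=["A", "A"])
        out = predict_msacons(ProteinRecord("q", "A"), msa,
                              lambda rec: tracks[rec.id], channels=("H", "E", "O"))
        np.testing.assert_allclose(out.values, [[0.5, 0.5, 0.0]])

    def test_gapped_row_excluded_from_column_mean(self):
        # three rows; h2 gapped at position 1 contributes only to position 0
        tracks = {
            "q": np.array([[1.0, 0.0], [1.0, 0.0]]),
            "h1": np.array([[0.0, 1.0], [0.0, 1.0]]),
            "h2": np.array([[0.0, 1.0]]),
        }
        msa = Msa(ids=["q", "h1", "h2"], rows=["AC", "AC", "A-"])
        out = predict_msacons(ProteinRecord("q", "AC"), msa,
                              lambda rec: tracks[rec.id], channels=("H", "E"))
        np.testing.assert_allclose(out.values, [[1 / 3, 2 / 3], [0.5, 0.5]])

    def test_row_permutation_invariant(self, small_setup):
        _, families, model = small_setup
        fam = families[1]
        pred = make_model_predictor(model, fam.provider)
        base = predict_msacons(fam.query, fam.msa, pred, channels=("H", "E", "O"))
        msa = fam.msa
        perm = [0] + list(range(msa.n_rows - 1, 0, -1))
        shuffled = Msa(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm], query_index=0)
        out = predict_msacons(fam.query, shuffled, pred, channels=("H", "E", "O"))
        np.testing.assert_allclose(base.values, out.values, atol=1e-12)

    def test_continuous_channels_average(self):
        tracks = {"q": np.array([[2.0]]), "h": np.array([[4.0]])}
        msa = Msa(ids=["q", "h"], rows=["A", "A"])
        out = predict_msacons(ProteinRecord("q", "A"), msa,
                              lambda rec: tracks[rec.id], channels=("score",))
        np.testing.assert_allclose(out.values, [[3.0]])


@pytest.fixture(scope="module")
def pssm_models():
    config = FamilySimConfig(L=30, n_homologs=6, sigma=0.5, D=8, seed=33)
    families = simulate_families(8, config)
    concat = train_workflow("pssm-concat", families[:6], families[6:],
                            model_kwargs=dict(max_epochs=3))
    split = train_workflow("pssm-split", families[:6], families[6:],
                           model_kwargs=dict(max_epochs=3))
    return families, concat, split


class TestPssmWorkflows:
    def test_concat_feature_width_and_length(self, pssm_models):
        families, concat, _ = pssm_models
        fam = families[0]
        assert concat.estimator.feature_width == 8 + 20
        track = predict_pssm_concat(fam.query, fam.msa, fam.provider, concat)
        assert len(track) == len(fam.query)
        np.testing.assert_allclose(track.values.sum(axis=1), 1.0, atol=1e-9)

    def test_split_contract(self, pssm_models):
        families, _, split = pssm_models
        fam = families[0]
        track = predict_pssm_split(fam.query, fam.msa, fam.provider, split)
        assert len(track) == len(fam.query)
        np.testing.assert_allclose(track.values.sum(axis=1), 1.0, atol=1e-9)

    def test_uninformative_pssm_performs_like_raw(self):
        """A near-uniform profile (huge pseudocount) adds no signal: the
        concat workflow then scores within noise of the raw workflow."""
        config = FamilySimConfig(L=40, n_homologs=8, sigma=0.5, D=8, seed=44)
        families = simulate_families(26, config)
        tr, va, te = families[:16], families[16:20], families[20:]
        kwargs = dict(max_epochs=40, patience=40, seed=0)
        raw = train_workflow("raw", tr, va, model_kwargs=kwargs)
        flat = train_workflow("pssm-concat", tr, va, model_kwargs=kwargs,
                              pseudocount=1e6)
        q_raw = evaluate_workflow("raw", raw, te).mean
        q_flat = evaluate_workflow("pssm-concat", flat, te,
                                   pseudocount=1e6).mean
        assert abs(q_raw - q_flat) < 5.0


class TestTrackIO:
    def test_roundtrip(self, tmp_path):
        track = PredictionTrack(np.array([[0.5, 0.25, 0.25], [0.1, 0.2, 0.7]]),
                                channels=("H", "E", "O"), workflow="raw")
        path = tmp_path / "tracks.tsv"
        write_prediction_tracks(path, {"q": track})
        back = read_prediction_tracks(path)["q"]
        np.testing.assert_allclose(back.values, track.values, atol=1e-5)
        assert back.channels == ("H", "E", "O")
        assert back.workflow == "raw"
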