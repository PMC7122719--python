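import numpy as np
import pandas as pd
import pytest

from psychembed.corpus import EmbeddingTable, IdfTable, preprocess_text
from psychembed.embedder import (
    Question,
    Questionnaire,
    ResponseMatrix,
    SurveyVectorizer,
    build_all_surveys,
    embed_question,
    embed_survey,
)


def _q(text, qid="q1", lo=0, hi=4):
    return Question(survey_id="s", question_id=qid, text=text, scale_min=lo, scale_max=hi)


class TestEmbedQuestion:
    def test_weighted_sum(self, tiny_space):
        emb, idf = tiny_space
        np.testing.assert_allclose(embed_question(_q("a b"), emb, idf), [1.0, 2.0])

    def test_repeated_token_counted_each_occurrence(self, tiny_space):
        emb, idf = tiny_space
        np.testing.assert_allclose(embed_question(_q("a a b"), emb, idf), [2.0, 2.0])

    def test_all_oov_yields_zero_vector_with_warning(self, tiny_space, caplog):
        emb, idf = tiny_space
        with caplog.at_level("WARNING"):
            vec = embed_question(_q("zz yy"), emb, idf)
        np.testing.assert_array_equal(vec, np.zeros(2))
        assert "out of vocabulary" in caplog.text

    def test_token_missing_from_idf_skipped(self, tiny_space):
        emb, _ = tiny_space
        idf = IdfTable(n_documents=3, weights={"a": 1.0})  # no weight for b
        np.testing.assert_allclose(embed_question(_q("a b"), emb, idf), [1.0, 0.0])


def _survey(tiny_space, answers, texts=("a", "b"), lo=0, hi=4):
    emb, idf = tiny_space
    qn = Questionnaire(
        survey_id="s",
        questions=tuple(
            _q(t, qid=f"q{j + 1}", lo=lo, hi=hi) for j, t in enumerate(texts)
        ),
    )
    resp = ResponseMatrix(
        patient_ids=[f"p{i}" for i in range(len(answers))],
        question_ids=[f"q{j + 1}" for j in range(len(texts))],
        answers=np.asarray(answers, dtype=float),
    )
    return qn, resp, emb, idf


class TestEmbedSurvey:
    def test_linear_combination(self, tiny_space):
        # q1 = idf(a)*v_a = (1,0), q2 = idf(b)*v_b = (0,2); answers (3,4)
        qn, resp, emb, idf = _survey(tiny_space, [[3, 4]])
        sm = embed_survey(qn, resp, emb, idf)
        np.testing.assert_allclose(sm.matrix, [[3.0, 8.0]])

    def test_zero_answers_zero_row(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[0, 0]])
        sm = embed_survey(qn, resp, emb, idf)
        np.testing.assert_array_equal(sm.matrix, [[0.0, 0.0]])

    def test_doubling_one_answer_adds_one_question_vector(self, tiny_space):
        # raising an answer from 1 to 2 shifts the survey vector by exactly
        # that question's embedding
        qn, resp1, emb, idf = _survey(tiny_space, [[1, 1]])
        _, resp2, _, _ = _survey(tiny_space, [[1, 2]])
        v1 = embed_survey(qn, resp1, emb, idf).matrix[0]
        v2 = embed_survey(qn, resp2, emb, idf).matrix[0]
        q2_vec = embed_question(qn.questions[1], emb, idf)
        np.testing.assert_array_equal(v2 - v1, q2_vec)

    def test_unknown_question_id_raises(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 1]])
        resp.question_ids[1] = "rogue"
        with pytest.raises(ValueError, match="rogue"):
            embed_survey(qn, resp, emb, idf)

    def test_out_of_range_answer_names_question(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 9]])
        with pytest.raises(ValueError, match="out of range"):
            embed_survey(qn, resp, emb, idf)

    def test_all_missing_patient_named(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 1], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="p1"):
            embed_survey(qn, resp, emb, idf)


class TestMissingPolicies:
    def test_median_imputation_rounds_to_range(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 0], [3, 0], [np.nan, 1]])
        sm = embed_survey(qn, resp, emb, idf, missing="median")
        # median of (1,3) = 2 -> q1 contributes 2*(1,0)
        np.testing.assert_allclose(sm.matrix[2], [2.0, 2.0])

    def test_zero_policy(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 0], [np.nan, 1]])
        sm = embed_survey(qn, resp, emb, idf, missing="zero")
        np.testing.assert_allclose(sm.matrix[1], [0.0, 2.0])

    def test_drop_policy_raises_naming_patient(self, tiny_space):
        qn, resp, emb, idf = _survey(tiny_space, [[1, 0], [np.nan, 1]])
        with pytest.raises(ValueError, match="p1"):
            embed_survey(qn, resp, emb, idf, missing="drop")


def _random_fixture(rng, n_patients=6, n_questions=4, d=3, vocab=8):
    tokens = [f"w{k}" for k in range(vocab)]
    emb = EmbeddingTable(
        dimension=d, entries={t: rng.standard_normal(d) for t in tokens}
    )
    idf = IdfTable(
        n_documents=vocab, weights={t: float(rng.uniform(0.1, 3)) for t in tokens}
    )
    qs = tuple(
        Question(
            survey_id="s",
            question_id=f"q{j}",
            text=" ".join(rng.choice(tokens, size=3, replace=True)),
            scale_min=0,
            scale_max=4,
        )
        for j in range(n_questions)
    )
    qn = Questionnaire(survey_id="s", questions=qs)
    resp = ResponseMatrix(
        patient_ids=[f"p{i}" for i in range(n_patients)],
        question_ids=[f"q{j}" for j in range(n_questions)],
        answers=rng.integers(0, 5, size=(n_patients, n_questions)).astype(float),
    )
    return qn, resp, emb, idf


def triple_loop_oracle(qn, resp, emb, idf):
    """Reference survey embedding by explicit (patient, question, token) loops."""
    out = np.zeros((len(resp.patient_ids), emb.dimension))
    for i in range(len(resp.patient_ids)):
        for j, q in enumerate(qn.questions):
            for tok in preprocess_text(q.text):
                v, w = emb.get(tok), idf.get(tok)
                if v is None or w is None:
                    continue
                out[i] += resp.answers[i, j] * w * v
    return out


class TestAlgebraicProperties:
    def test_matches_triple_loop_oracle(self, tiny_space):
        rng = np.random.default_rng(11)
        for _ in range(5):
            qn, resp, emb, idf = _random_fixture(rng)
            sm = embed_survey(qn, resp, emb, idf)
            np.testing.assert_allclose(
                sm.matrix, triple_loop_oracle(qn, resp, emb, idf), atol=1e-10
            )

    def test_homogeneity(self):
        rng = np.random.default_rng(5)
        qn, resp, emb, idf = _random_fixture(rng, n_patients=4)
        base = embed_survey(qn, resp, emb, idf).matrix
        doubled = ResponseMatrix(
            resp.patient_ids, resp.question_ids, resp.answers * 2
        )
        # doubled answers stay in a widened scale
        qn2 = Questionnaire(
            "s",
            tuple(
                Question("s", q.question_id, q.text, 0, 8) for q in qn.questions
            ),
        )
        np.testing.assert_array_equal(
            embed_survey(qn2, doubled, emb, idf).matrix, 2 * base
        )

    def test_additivity_over_answer_vectors(self):
        rng = np.random.default_rng(6)
        qn, resp_a, emb, idf = _random_fixture(rng, n_patients=4)
        answers_b = rng.integers(0, 5, size=resp_a.answers.shape).astype(float)
        resp_b = ResponseMatrix(resp_a.patient_ids, resp_a.question_ids, answers_b)
        qn_wide = Questionnaire(
            "s",
            tuple(Question("s", q.question_id, q.text, 0, 8) for q in qn.questions),
        )
        resp_sum = ResponseMatrix(
            resp_a.patient_ids, resp_a.question_ids, resp_a.answers + answers_b
        )
        np.testing.assert_allclose(
            embed_survey(qn_wide, resp_sum, emb, idf).matrix,
            embed_survey(qn, resp_a, emb, idf).matrix
            + embed_survey(qn, resp_b, emb, idf).matrix,
            atol=1e-12,
        )

    def test_question_order_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        qn, resp, emb, idf = _random_fixture(rng)
        base = embed_survey(qn, resp, emb, idf).matrix
        perm = rng.permutation(len(qn.questions))
        qn_p = Questionnaire("s", tuple(qn.questions[j] for j in perm))
        np.testing.assert_allclose(
            embed_survey(qn_p, resp, emb, idf).matrix, base, atol=1e-12
        )


class TestBuildAllSurveys:
    def test_shapes_and_shared_roster(self, tiny_space):
        emb, idf = tiny_space
        qns, resps = [], {}
        for sid in ("sA", "sB"):
            qn = Questionnaire(
                sid,
                tuple(
                    Question(sid, f"q{j}", t, 0, 4)
                    for j, t in enumerate(["a b", "c a"])
                ),
            )
            qns.append(qn)
            resps[sid] = ResponseMatrix(
                patient_ids=["p2", "p0", "p1"],
                question_ids=["q0", "q1"],
                answers=(np.arange(6, dtype=float) % 5).reshape(3, 2),
            )
        out = build_all_surveys(qns, resps, emb, idf)
        assert set(out) == {"sA", "sB"}
        for sm in out.values():
            assert sm.patient_ids == ["p0", "p1", "p2"]  # lexicographic order
            assert sm.matrix.shape == (3, 2)

    def test_roster_mismatch_names_difference(self, tiny_space):
        emb, idf = tiny_space
        qns, resps = [], {}
        for sid, ids in (("sA", ["p0", "p1"]), ("sB", ["p0", "p7"])):
            qn = Questionnaire(sid, (Question(sid, "q0", "a", 0, 4),))
            qns.append(qn)
            resps[sid] = ResponseMatrix(ids, ["q0"], np.ones((2, 1)))
        with pytest.raises(ValueError, match="p7"):
            build_all_surveys(qns, resps, emb, idf)


def test_survey_vectorizer_sklearn_contract(tiny_space):
    emb, idf = tiny_space
    qn, resp, *_ = _survey(tiny_space, [[1, 2]])
    vec = SurveyVectorizer(emb, idf, qn)
    assert vec.get_params()["missing"] == "median"
    out = vec.fit().transform(resp.to_frame())
    assert out.shape == (1, 2)
    assert vec.question_vectors_.shape == (2, 2)
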