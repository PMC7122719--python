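"""Question- and survey-level embedding vectors.

The central construction: each ordinal questionnaire item is embedded as the
IDF-weighted sum of its word vectors, and each patient's survey response is
embedded as the sum of question vectors weighted by the patient's integer
ordinal answers.  A cohort answering a survey therefore becomes a
patients x d real matrix, one per survey.

`SurveyVectorizer` exposes this as a scikit-learn transformer: ``fit`` binds
a questionnaire to an embedding space and precomputes question vectors,
``transform`` maps a patient x question answer matrix to the patient x d
survey matrix.  The module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import EmbeddingTable, IdfTable, preprocess_text

logger = logging.getLogger(__name__)

__all__ = [
    "Question",
    "Questionnaire",
    "ResponseMatrix",
    "SurveyMatrix",
    "SurveyVectorizer",
    "embed_question",
    "embed_survey",
    "build_all_surveys",
    "read_questionnaires",
    "write_questionnaires",
    "read_responses",
]


@dataclass(frozen=True)
class Question:
    """One ordinal questionnaire item with its printed response range."""

    survey_id: str
    question_id: str
    text: str
    scale_min: int
    scale_max: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"question {self.question_id!r}: empty text")
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"question {self.question_id!r}: scale_min must be < scale_max"
            )


@dataclass(frozen=True)
class Questionnaire:
    survey_id: str
    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        if not self.questions:
            raise ValueError(f"survey {self.survey_id!r}: no questions")
        ids = [q.question_id for q in self.questions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"survey {self.survey_id!r}: duplicate question ids")

    @property
    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.questions]


@dataclass
class ResponseMatrix:
    """Patient x question integer answers; NaN marks a missing answer."""

    patient_ids: list[str]
    question_ids: list[str]
    answers: np.ndarray  # float array so NaN can mark missing

    def __post_init__(self) -> None:
        self.answers = np.asarray(self.answers, dtype=np.float64)
        if self.answers.shape != (len(self.patient_ids), len(self.question_ids)):
            raise ValueError("answers shape does not match id lists")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        """Build from a DataFrame indexed by patient_id, one column per question."""
        return cls(
            patient_ids=[str(i) for i in df.index],
            question_ids=[str(c) for c in df.columns],
            answers=df.to_numpy(dtype=np.float64),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.answers, index=self.patient_ids, columns=self.question_ids
        )

    def validate_against(self, qn: Questionnaire) -> None:
        scale = {q.question_id: (q.scale_min, q.scale_max) for q in qn.questions}
        unknown = [q for q in self.question_ids if q not in scale]
        if unknown:
            raise ValueError(f"unknown question ids in responses: {unknown}")
        for j, qid in enumerate(self.question_ids):
            col = self.answers[:, j]
            ok = np.isnan(col) | ((col >= scale[qid][0]) & (col <= scale[qid][1]))
            if not ok.all():
                bad = [self.patient_ids[i] for i in np.flatnonzero(~ok)]
                raise ValueError(
                    f"answers out of range for question {qid!r} (patients {bad[:5]})"
                )


@dataclass
class SurveyMatrix:
    """Patient x d survey-level embedding matrix for one survey."""

    survey_id: str
    patient_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.patient_ids):
            raise ValueError("row count does not match patient roster")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite entries in survey matrix")

    def to_frame(self) -> pd.DataFrame:
        d = self.matrix.shape[1]
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=[f"e{k + 1}" for k in range(d)],
        )


def embed_question(
    q: Question, emb: EmbeddingTable, idf: IdfTable, normalize: bool = False
) -> np.ndarray:
    """IDF-weighted sum of a question's word vectors.

    Tokens missing from either the embedding vocabulary or the IDF table are
    skipped (they contribute the zero vector); a fully out-of-vocabulary
    question yields the zero vector with a logged warning.  Repeated tokens
    are counted at each occurrence.  With ``normalize=True`` the result is
    scaled to unit length (sensitivity-analysis option; off by default).
    """
    vec = np.zeros(emb.dimension)
    n_used = 0
    for tok in preprocess_text(q.text):
        v = emb.get(tok)
        w = idf.get(tok)
        if v is None or w is None:
            continue
        vec += w * v
        n_used += 1
    if n_used == 0:
        logger.warning(
            "question %s/%s: all tokens out of vocabulary; zero vector",
            q.survey_id,
            q.question_id,
        )
    if normalize:
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
    return vec


class SurveyVectorizer(BaseEstimator, TransformerMixin):
    """Map patient x question ordinal answers to patient x d survey vectors.

    Parameters
    ----------
    embeddings : EmbeddingTable
    idf : IdfTable
    questionnaire : Questionnaire
    missing : {"median", "zero", "drop"}
        Policy for missing answers: impute the per-question median of
        observed answers rounded to the nearest in-range integer (default),
        treat as 0, or raise on any patient with missing answers ("drop"
        reports the offending patients so the caller can subset).
    normalize_questions : bool
        Unit-normalize question vectors before summation (off by default;
        the raw construction sums unnormalized vectors).

    Attributes
    ----------
    question_vectors_ : ndarray of shape (n_questions, d)
    question_ids_ : list of str
    medians_ : ndarray of per-question imputation values
    """

    def __init__(
        self,
        embeddings: EmbeddingTable,
        idf: IdfTable,
        questionnaire: Questionnaire,
        missing: str = "median",
        normalize_questions: bool = False,
    ):
        self.embeddings = embeddings
        self.idf = idf
        self.questionnaire = questionnaire
        self.missing = missing
        self.normalize_questions = normalize_questions

    def fit(self, X=None, y=None) -> "SurveyVectorizer":
        if self.missing not in ("median", "zero", "drop"):
            raise ValueError(f"unknown missing policy {self.missing!r}")
        qn = self.questionnaire
        self.question_ids_ = qn.question_ids
        self.question_vectors_ = np.vstack(
            [
                embed_question(
                    q, self.embeddings, self.idf, normalize=self.normalize_questions
                )
                for q in qn.questions
            ]
        )
        return self

    def transform(self, X: ResponseMatrix | pd.DataFrame) -> np.ndarray:
        """Return the patient x d survey matrix for a response matrix.

        Column order of ``X`` may differ from the questionnaire; answers are
        aligned by question id.  Unknown question ids raise.
        """
        if isinstance(X, pd.DataFrame):
            X = ResponseMatrix.from_frame(X)
        X.validate_against(self.questionnaire)
        missing_q = [q for q in self.question_ids_ if q not in X.question_ids]
        if missing_q:
            raise ValueError(f"responses missing question ids: {missing_q}")
        order = [X.question_ids.index(q) for q in self.question_ids_]
        answers = X.answers[:, order]

        all_missing = np.isnan(answers).all(axis=1)
        if all_missing.any():
            bad = [X.patient_ids[i] for i in np.flatnonzero(all_missing)]
            raise ValueError(f"patients with all answers missing: {bad}")
        answers = self._impute(answers, X.patient_ids)
        return answers @ self.question_vectors_

    def _impute(self, answers: np.ndarray, patient_ids: list[str]) -> np.ndarray:
        nan_mask = np.isnan(answers)
        if not nan_mask.any():
            return answers
        if self.missing == "drop":
            bad = [patient_ids[i] for i in np.flatnonzero(nan_mask.any(axis=1))]
            raise ValueError(
                f"missing answers under policy 'drop' for patients: {bad}"
            )
        answers = answers.copy()
        if self.missing == "zero":
            answers[nan_mask] = 0.0
            return answers
        qs = self.questionnaire.questions
        for j in range(answers.shape[1]):
            col = answers[:, j]
            miss = nan_mask[:, j]
            if not miss.any():
                continue
            observed = col[~miss]
            if observed.size == 0:
                fill = float(qs[j].scale_min)
            else:
                fill = float(np.rint(np.median(observed)))
                fill = min(max(fill, qs[j].scale_min), qs[j].scale_max)
            col[miss] = fill
        return answers


def embed_survey(
    qn: Questionnaire,
    responses: ResponseMatrix | pd.DataFrame,
    emb: EmbeddingTable,
    idf: IdfTable,
    missing: str = "median",
    normalize_questions: bool = False,
) -> SurveyMatrix:
    """Survey-level embedding matrix: row i = sum_j a_ij * q_j."""
    vec = SurveyVectorizer(
        emb, idf, qn, missing=missing, normalize_questions=normalize_questions
    ).fit()
    if isinstance(responses, pd.DataFrame):
        responses = ResponseMatrix.from_frame(responses)
    return SurveyMatrix(
        survey_id=qn.survey_id,
        patient_ids=list(responses.patient_ids),
        matrix=vec.transform(responses),
    )


def build_all_surveys(
    questionnaires: Sequence[Questionnaire],
    responses: Mapping[str, ResponseMatrix | pd.DataFrame],
    emb: EmbeddingTable,
    idf: IdfTable,
    missing: str = "median",
) -> dict[str, SurveyMatrix]:
    """Embed every survey over one shared, ordered patient roster.

    All response matrices must cover the same patients; a roster mismatch
    raises an error listing the symmetric difference.  Patients are ordered
    lexicographically by id in every output matrix.
    """
    rosters = {}
    for qn in questionnaires:
        resp = responses[qn.survey_id]
        if isinstance(resp, pd.DataFrame):
            resp = ResponseMatrix.from_frame(resp)
        rosters[qn.survey_id] = resp
    ids_sets = {sid: set(r.patient_ids) for sid, r in rosters.items()}
    reference = ids_sets[questionnaires[0].survey_id]
    for sid, ids in ids_sets.items():
        if ids != reference:
            diff = sorted(ids.symmetric_difference(reference))
            raise ValueError(
                f"patient roster mismatch between surveys "
                f"{questionnaires[0].survey_id!r} and {sid!r}: {diff}"
            )
    roster = sorted(reference)
    out: dict[str, SurveyMatrix] = {}
    for qn in questionnaires:
        resp = rosters[qn.survey_id]
        order = [resp.patient_ids.index(p) for p in roster]
        resp = ResponseMatrix(
            patient_ids=roster,
            question_ids=list(resp.question_ids),
            answers=resp.answers[order],
        )
        out[qn.survey_id] = embed_survey(qn, resp, emb, idf, missing=missing)
    return out


# ---------------------------------------------------------------------------
# file formats


def write_questionnaires(
    questionnaires: Sequence[Questionnaire], path: str | Path
) -> None:
    rows = [
        {
            "survey_id": q.survey_id,
            "question_id": q.question_id,
            "text": q.text,
            "scale_min": q.scale_min,
            "scale_max": q.scale_max,
        }
        for qn in questionnaires
        for q in qn.questions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_questionnaires(path: str | Path) -> list[Questionnaire]:
    """Read the questionnaire schema (TSV: survey_id, question_id, text, scale_min, scale_max)."""
    df = pd.read_csv(path, sep="\t", dtype={"survey_id": str, "question_id": str})
    required = {"survey_id", "question_id", "text", "scale_min", "scale_max"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for sid, grp in df.groupby("survey_id", sort=True):
        qs = tuple(
            Question(
                survey_id=str(sid),
                question_id=str(r.question_id),
                text=str(r.text),
                scale_min=int(r.scale_min),
                scale_max=int(r.scale_max),
            )
            for r in grp.itertuples()
        )
        out.append(Questionnaire(survey_id=str(sid), questions=qs))
    return out


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a responses CSV with a patient_id column + one column per question."""
    df = pd.read_csv(path, dtype={"patient_id": str}).set_index("patient_id")
    return ResponseMatrix.from_frame(df)
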