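"""End-to-end wiring: responses -> survey matrices -> scores -> evaluation.

Convenience layer used by the command-line interface and the analysis
scripts.  Feature sets mirror the evaluation design: per-survey first
canonical variables ("CCV", 9 features), first one or two PCs per survey
("1PC" / "2PC", 9 / 18 features), and the raw per-question ordinal columns
("raw").  The same PC/CCV machinery can be applied to the raw ordinal
response matrices to form the raw-score benchmark.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import EmbeddingTable, IdfTable
from .embedder import (
    Questionnaire,
    ResponseMatrix,
    SurveyMatrix,
    SurveyVectorizer,
    build_all_surveys,
)
from .evaluate import bootstrap_evaluate
from .scores import DsmMatrix, RdocScorer, build_score_table

__all__ = [
    "raw_survey_matrices",
    "select_features",
    "raw_feature_matrix",
    "derive_scores",
    "evaluation_table",
]

FEATURE_SETS = ("CCV", "1PC", "2PC", "raw")


def raw_survey_matrices(
    questionnaires: Sequence[Questionnaire],
    responses: Mapping[str, ResponseMatrix],
) -> dict[str, SurveyMatrix]:
    """Raw ordinal response matrices wrapped as survey matrices.

    Used to run the identical PC/CCV scoring machinery on raw ordinal
    scores as the benchmark feature set.  Missing answers are median-imputed
    with the same policy as the embedding path; patients are ordered
    lexicographically to match ``build_all_surveys``.
    """
    roster = None
    out = {}
    for qn in questionnaires:
        resp = responses[qn.survey_id]
        if isinstance(resp, pd.DataFrame):
            resp = ResponseMatrix.from_frame(resp)
        ids = sorted(resp.patient_ids)
        if roster is None:
            roster = ids
        elif ids != roster:
            raise ValueError(f"survey {qn.survey_id!r}: roster differs")
        order = [resp.patient_ids.index(p) for p in roster]
        ans = resp.answers[order]
        # reuse the vectorizer's imputation policy without any embedding
        vec = SurveyVectorizer(
            EmbeddingTable(dimension=1, entries={}),
            IdfTable(n_documents=1, weights={}),
            qn,
        )
        ans = vec._impute(ans.copy(), roster)
        out[qn.survey_id] = SurveyMatrix(
            survey_id=qn.survey_id, patient_ids=roster, matrix=ans
        )
    return out


def derive_scores(
    questionnaires: Sequence[Questionnaire],
    responses: Mapping[str, ResponseMatrix],
    embeddings: EmbeddingTable,
    idf: IdfTable,
    dsm: DsmMatrix | None = None,
    seeds: Mapping[str, Sequence[str]] | None = None,
    n_pcs: int = 2,
) -> dict:
    """Survey matrices and the full score table in one call.

    Returns a dict with ``surveys`` (embedding matrices), ``raw_surveys``,
    ``scores`` (embedding-based PC/CCV table), ``raw_scores`` (identical
    machinery on raw ordinal matrices) and, if seed words are given,
    ``rdoc`` (per-domain score table).
    """
    surveys = build_all_surveys(questionnaires, responses, embeddings, idf)
    raw = raw_survey_matrices(questionnaires, responses)
    rdoc = None
    if seeds is not None:
        roster = next(iter(surveys.values())).patient_ids
        ordered = {
            sid: _reorder(responses[sid], roster) for sid in responses
        }
        rdoc = (
            RdocScorer(embeddings, idf, seeds)
            .fit(list(questionnaires))
            .transform(ordered)
        )
    return {
        "surveys": surveys,
        "raw_surveys": raw,
        "scores": build_score_table(surveys, dsm=dsm, n_pcs=n_pcs, rdoc=rdoc),
        "raw_scores": build_score_table(raw, dsm=dsm, n_pcs=n_pcs),
        "rdoc": rdoc,
    }


def _reorder(resp: ResponseMatrix | pd.DataFrame, roster: list[str]) -> ResponseMatrix:
    if isinstance(resp, pd.DataFrame):
        resp = ResponseMatrix.from_frame(resp)
    order = [resp.patient_ids.index(p) for p in roster]
    return ResponseMatrix(
        patient_ids=list(roster),
        question_ids=list(resp.question_ids),
        answers=resp.answers[order],
    )


def select_features(score_table: pd.DataFrame, feature_set: str) -> np.ndarray:
    """Select the feature columns for one named feature set.

    ``CCV`` -> all ``*_CCV1`` columns (one per survey), ``1PC`` -> all
    ``*_PC1``, ``2PC`` -> all ``*_PC1`` and ``*_PC2``.
    """
    if feature_set == "CCV":
        cols = [c for c in score_table.columns if c.endswith("_CCV1")]
    elif feature_set == "1PC":
        cols = [c for c in score_table.columns if c.endswith("_PC1")]
    elif feature_set == "2PC":
        cols = [
            c
            for c in score_table.columns
            if c.endswith("_PC1") or c.endswith("_PC2")
        ]
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if not cols:
        raise ValueError(f"no columns for feature set {feature_set!r}")
    return score_table[sorted(cols)].to_numpy()


def raw_feature_matrix(
    responses: Mapping[str, ResponseMatrix], roster: list[str]
) -> np.ndarray:
    """All per-question ordinal columns concatenated across surveys."""
    blocks = []
    for sid in sorted(responses):
        resp = _reorder(responses[sid], roster)
        blocks.append(np.nan_to_num(resp.answers, nan=0.0))
    return np.hstack(blocks)


def evaluation_table(
    features: Mapping[str, np.ndarray],
    groups: Sequence[str],
    methods: Sequence[str] = ("logistic", "gmm"),
    contrasts: Sequence[str] = ("C_vs_CS", "CC_vs_S"),
    B: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Run bootstrap evaluation over every (method, contrast, feature set).

    Returns the tidy report: one row per metric per cell, with bootstrap
    mean and percentile 95% CI.
    """
    frames = []
    for method in methods:
        for contrast in contrasts:
            for fname, X in features.items():
                rep = bootstrap_evaluate(
                    X,
                    groups,
                    contrast,
                    method=method,
                    B=B,
                    seed=seed,
                    feature_set=fname,
                )
                frames.append(rep.to_frame())
    return pd.concat(frames, ignore_index=True)
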